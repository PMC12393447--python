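"""Exact Gaussian-process regression on sequence space.

Model: a zero-mean GP prior over landscapes with one of the package's
kernels, plus Gaussian measurement noise with covariance
``E = diag(y_var) + sigma_n^2 I`` — known per-datum assay variances when
available, and a learned uniform term ``sigma_n^2`` for sequence-independent
noise.  Hyperparameters (decay factors, prior variance, uniform noise) are
selected by maximizing the log marginal likelihood ("evidence")

    log p(y) = -1/2 y^T (K+E)^-1 y - 1/2 log|K+E| - n/2 log 2pi,

computed via Cholesky factorization with escalating jitter.  Inference is
exact and dense: this targets desk-scale problems (thousands of training
sequences), not the million-observation regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.optimize

from .errors import NumericalError, ValidationError
from .kernels import (
    ConnectednessKernel,
    GeneralProductKernel,
    GeometricKernel,
    JengaKernel,
    Kernel,
    VCKernel,
    inverse_krawtchouk_transform,
)
from .space import GenotypeTable, SequenceSpace

JITTER_START = 1e-10
JITTER_MAX = 1e-4


@dataclass
class NoiseModel:
    """Gaussian noise covariance ``E = diag(per_datum_var) + uniform_var * I``."""

    uniform_var: float = 0.0
    per_datum_var: np.ndarray | None = None

    def __post_init__(self):
        if self.uniform_var < 0:
            raise ValidationError("uniform noise variance must be >= 0")
        if self.per_datum_var is not None:
            self.per_datum_var = np.asarray(self.per_datum_var, dtype=float)
            if np.any(self.per_datum_var < 0):
                raise ValidationError("per-datum variances must be >= 0")

    def diagonal(self, n: int) -> np.ndarray:
        diag = np.full(n, self.uniform_var)
        if self.per_datum_var is not None:
            if len(self.per_datum_var) != n:
                raise ValidationError(
                    f"noise model has {len(self.per_datum_var)} per-datum variances for {n} rows"
                )
            diag = diag + self.per_datum_var
    # noise is diagonal by construction: measurements are independent
        return diag

    @classmethod
    def for_table(cls, table: GenotypeTable, uniform_var: float = 0.0) -> "NoiseModel":
        return cls(uniform_var=uniform_var, per_datum_var=table.y_var)


def _chol_with_jitter(A: np.ndarray, scale: float):
    """Cholesky of A with escalating diagonal jitter (1e-10..1e-4 times ``scale``)."""
    jitter = 0.0
    while True:
        try:
            return sla.cho_factor(A + jitter * np.eye(A.shape[0]), lower=True), jitter
        except sla.LinAlgError:
            jitter = JITTER_START * scale if jitter == 0.0 else jitter * 10.0
            if jitter > JITTER_MAX * max(scale, 1e-300):
                raise NumericalError(
                    f"Cholesky failed up to jitter {jitter:.1e}; "
                    "kernel-plus-noise matrix is badly conditioned"
                ) from None


def log_marginal_likelihood(
    table: GenotypeTable | Sequence[GenotypeTable],
    kernel: Kernel,
    noise: NoiseModel,
) -> float:
    """Evidence of the data under the GP prior, in nats.

    A list of tables sharing one sequence set is treated as independent
    replicate landscapes: their log marginal likelihoods add, with the
    Cholesky factorization shared.
    """
    tables = [table] if isinstance(table, GenotypeTable) else list(table)
    seqs = tables[0].sequences
    for t in tables[1:]:
        if t.sequences != seqs:
            raise ValidationError("pooled tables must share an identical sequence list")
    n = len(seqs)
    Y = np.column_stack([t.y for t in tables])
    K = kernel.matrix(seqs)
    A = K + np.diag(noise.diagonal(n))
    cf, _ = _chol_with_jitter(A, kernel.sigma2 if kernel.sigma2 > 0 else 1.0)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    alpha = sla.cho_solve(cf, Y)
    quad = float(np.sum(Y * alpha))
    r = Y.shape[1]
    return -0.5 * quad - 0.5 * r * logdet - 0.5 * r * n * math.log(2.0 * math.pi)


# ----------------------------------------------------------------------
# hyperparameter fitting
# ----------------------------------------------------------------------
@dataclass
class FitConfig:
    """Settings for evidence maximization.

    ``restarts`` independent optimizations from perturbed initializations are
    run and the best evidence kept; results are deterministic given ``seed``.
    ``learning_rate``/``adam_iterations`` record the reference first-order
    settings (lr 0.02, 500 iterations); the optimizer used here is L-BFGS-B
    with ``maxiter`` iterations, which satisfies the same contract.
    """

    restarts: int = 5
    maxiter: int = 500
    learning_rate: float = 0.02
    adam_iterations: int = 500
    perturb_scale: float = 0.5
    init_corr_at_max_distance: float = 0.1
    noise_init_fraction: float = 0.05


@dataclass
class GPModel:
    """A fitted GP: kernel + noise + training data + achieved evidence."""

    kernel: Kernel
    noise: NoiseModel
    train: GenotypeTable
    evidence: float
    fit_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel.to_dict(),
            "noise": {
                "uniform_var": self.noise.uniform_var,
                "per_datum_var": (
                    None
                    if self.noise.per_datum_var is None
                    else [float(v) for v in self.noise.per_datum_var]
                ),
            },
            "evidence": self.evidence,
            "fit_meta": {
                k: v for k, v in self.fit_meta.items() if k not in ("trace",)
            },
        }


@dataclass
class PosteriorPrediction:
    """Posterior mean/variance per query, optionally the full covariance."""

    sequences: list[str]
    mean: np.ndarray
    var: np.ndarray
    cov: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"sequence": self.sequences, "post_mean": self.mean, "post_var": self.var}
        )


def _logistic(t):
    return 1.0 / (1.0 + np.exp(-t))


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1.0 - p))


class _Parameterization:
    """Unconstrained reparameterization theta <-> (kernel, uniform noise).

    sigma2 and sigma_n^2 live on a log scale; decay factors pass through a
    logistic map into (0, 1); VC lambdas are per-order log-variances.
    """

    def __init__(self, family: str, space: SequenceSpace):
        if family not in ("geometric", "connectedness", "jenga", "general_product", "vc"):
            raise ValidationError(f"unknown kernel family {family!r}")
        self.family = family
        self.space = space
        if family == "geometric":
            self.n_delta = 1
        elif family == "connectedness":
            self.n_delta = space.length
        elif family == "jenga":
            self.n_delta = sum(space.alphabet_sizes)
        elif family == "general_product":
            self.n_delta = sum(a * (a - 1) // 2 for a in space.alphabet_sizes)
        else:  # vc: lambdas_0..l replace (sigma2, deltas)
            self.n_delta = space.length + 1

    @property
    def n_params(self) -> int:
        # vc: lambdas + noise; product families: sigma2 + deltas + noise
        return self.n_delta + (1 if self.family == "vc" else 2)

    def build(self, theta: np.ndarray) -> tuple[Kernel, float]:
        space = self.space
        if self.family == "vc":
            lambdas = np.exp(theta[: self.n_delta])
            noise_var = float(np.exp(theta[-1]))
            return VCKernel(space, lambdas), noise_var
        sigma2 = float(np.exp(theta[0]))
        noise_var = float(np.exp(theta[-1]))
        deltas = _logistic(theta[1:-1])
        if self.family == "geometric":
            kern = GeometricKernel(space, sigma2, float(deltas[0]))
        elif self.family == "connectedness":
            kern = ConnectednessKernel(space, sigma2, deltas)
        elif self.family == "jenga":
            parts, i = [], 0
            for a in space.alphabet_sizes:
                parts.append(deltas[i : i + a])
                i += a
            kern = JengaKernel(space, sigma2, parts)
        else:
            mats, i = [], 0
            for a in space.alphabet_sizes:
                m = np.zeros((a, a))
                iu = np.triu_indices(a, k=1)
                npair = a * (a - 1) // 2
                m[iu] = deltas[i : i + npair]
                m += m.T
                i += npair
                mats.append(m)
            kern = GeneralProductKernel(space, sigma2, mats)
        return kern, noise_var

    def initial(self, y_var_emp: float, config: FitConfig) -> np.ndarray:
        """Spec'd initialization: prior variance = empirical phenotype variance,
        uniform decay factors whose product reaches ``init_corr_at_max_distance``
        at the maximal Hamming distance in the space."""
        D = self.space.length  # maximal Hamming distance of the full space
        delta0 = 1.0 - config.init_corr_at_max_distance ** (1.0 / D)
        sigma2_0 = max(y_var_emp, 1e-8)
        noise0 = max(config.noise_init_fraction * sigma2_0, 1e-10)
        if self.family == "vc":
            kd = sigma2_0 * (1.0 - delta0) ** np.arange(self.space.length + 1)
            lam = np.clip(inverse_krawtchouk_transform(self.space, kd), 1e-12, None)
            return np.concatenate([np.log(lam), [np.log(noise0)]])
        return np.concatenate(
            [[np.log(sigma2_0)], np.full(self.n_delta, _logit(delta0)), [np.log(noise0)]]
        )


def initial_decay_factor(max_distance: int, corr_at_max: float = 0.1) -> float:
    """Uniform starting decay factor: ``(1 - delta)^D = corr_at_max``."""
    return 1.0 - corr_at_max ** (1.0 / max_distance)


def fit_hyperparameters(
    table: GenotypeTable | Sequence[GenotypeTable],
    family: str,
    config: FitConfig | None = None,
    seed: int = 0,
) -> GPModel:
    """Fit kernel hyperparameters and uniform noise by evidence maximization.

    Runs ``config.restarts`` independent optimizations (the first from the
    deterministic initialization, the rest from seeded perturbations) and
    returns the model with the best evidence.  A list of tables sharing one
    sequence set is fit jointly as pooled replicate landscapes.
    """
    config = config or FitConfig()
    tables = [table] if isinstance(table, GenotypeTable) else list(table)
    main = tables[0]
    if len(set(main.sequences)) < 2:
        raise ValidationError("need at least 2 distinct training sequences")
    space = main.space
    if family == "vc" and not space.is_uniform:
        raise ValidationError("the VC family requires a uniform alphabet size")

    y_all = np.concatenate([t.y for t in tables])
    y_var_emp = float(np.var(y_all))
    if y_var_emp == 0:
        warnings.warn("constant phenotype: returning a near-zero-variance model")
        param = _Parameterization(family, space)
        theta = param.initial(1e-12, config)
        kern, nv = param.build(theta)
        noise = NoiseModel(uniform_var=nv, per_datum_var=main.y_var)
        ev = log_marginal_likelihood(tables, kern, noise)
        return GPModel(kern, noise, main, ev, {"constant_y": True, "seed": seed})

    param = _Parameterization(family, space)
    theta0 = param.initial(y_var_emp, config)
    per_datum = main.y_var

    def objective(theta: np.ndarray) -> float:
        try:
            kern, nv = param.build(theta)
            noise = NoiseModel(uniform_var=nv, per_datum_var=per_datum)
            val = -log_marginal_likelihood(tables, kern, noise)
            return val if np.isfinite(val) else 1e12
        except (NumericalError, FloatingPointError, ValidationError, ValueError):
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    trace = []
    for r in range(config.restarts):
        start = theta0 if r == 0 else theta0 + rng.normal(scale=config.perturb_scale, size=theta0.shape)
        # bounds keep exp/logistic well away from overflow; at |theta|=30 the
        # mapped parameters are saturated to ~1e-13 precision anyway
        res = scipy.optimize.minimize(
            objective,
            np.clip(start, -29.0, 29.0),
            method="L-BFGS-B",
            bounds=[(-30.0, 30.0)] * len(start),
            options={"maxiter": config.maxiter},
        )
        trace.append({"restart": r, "evidence": -float(res.fun), "nit": int(res.nit)})
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.copy(), r)
    if best is None or not np.isfinite(best[0]):
        raise NumericalError(f"all restarts diverged; traces: {trace}")

    kern, nv = param.build(best[1])
    noise = NoiseModel(uniform_var=nv, per_datum_var=per_datum)
    evidence = log_marginal_likelihood(tables, kern, noise)
    return GPModel(
        kernel=kern,
        noise=noise,
        train=main,
        evidence=evidence,
        fit_meta={
            "seed": seed,
            "restart": best[2],
            "trace": trace,
            "family": family,
            "n_tables": len(tables),
            "config": {
                "restarts": config.restarts,
                "maxiter": config.maxiter,
            },
        },
    )


# ----------------------------------------------------------------------
# posterior prediction
# ----------------------------------------------------------------------
def posterior_predict(
    model: GPModel, queries: Sequence[str], want_cov: bool = False
) -> PosteriorPrediction:
    """Posterior mean and variance of the latent landscape at query genotypes.

    ``mean = k_x^T (K+E)^-1 y``; ``var = k(x,x) - k_x^T (K+E)^-1 k_x``.
    Tiny negative variances from round-off are clipped to zero (with a
    warning when they exceed the numerical tolerance).
    """
    queries = list(queries)
    train = model.train
    n = len(train)
    K = model.kernel.matrix(train.sequences)
    A = K + np.diag(model.noise.diagonal(n))
    scale = model.kernel.sigma2 if model.kernel.sigma2 > 0 else 1.0
    cf, _ = _chol_with_jitter(A, scale)
    alpha = sla.cho_solve(cf, train.y)
    if not queries:
        return PosteriorPrediction([], np.empty(0), np.empty(0))
    Kq = model.kernel.matrix(queries, train.sequences)  # (m, n)
    mean = Kq @ alpha
    V = sla.cho_solve(cf, Kq.T)  # (n, m)
    # every kernel in the package has constant diagonal k(x, x) = sigma2
    prior = np.full(len(queries), model.kernel.sigma2)
    var = prior - np.sum(Kq.T * V, axis=0)
    if np.any(var < -1e-9 * scale):
        warnings.warn(
            f"posterior variance fell below the numerical tolerance "
            f"(min {var.min():.3e}); clipping to zero"
        )
    var = np.clip(var, 0.0, None)
    cov = None
    if want_cov:
        cov = model.kernel.matrix(queries, queries) - Kq @ V
        cov = 0.5 * (cov + cov.T)
    return PosteriorPrediction(queries, mean, var, cov)


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------
def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination ``1 - SSE/SStot`` about the held-out mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / sstot


def cross_validate(
    table: GenotypeTable,
    family: str,
    fractions: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
    config: FitConfig | None = None,
):
    """Held-out R^2 per training fraction, over seeded random splits.

    For each fraction, ``replicates`` random training subsets are drawn
    without replacement; a model is fit on each and scored on the held-out
    rows.  Returns a DataFrame (fraction, replicate, r2, n_train, n_test);
    splits with degenerate held-out variance report r2 = NaN.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    rows = []
    for frac in fractions:
        n_train = int(round(frac * len(table)))
        if n_train < 2 or n_train >= len(table):
            raise ValidationError(
                f"fraction {frac} leaves {n_train} training rows out of {len(table)}"
            )
        for rep in range(replicates):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            idx = rng.permutation(len(table))
            tr, te = idx[:n_train], idx[n_train:]
            fit_seed = int(child.generate_state(1)[0] % (2**31))
            model = fit_hyperparameters(table.subset(tr), family, config=config, seed=fit_seed)
            pred = posterior_predict(model, [table.sequences[i] for i in te])
            rows.append(
                {
                    "fraction": frac,
                    "replicate": rep,
                    "r2": r_squared(table.y[te], pred.mean),
                    "n_train": len(tr),
                    "n_test": len(te),
                }
            )
    return pd.DataFrame(rows)
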