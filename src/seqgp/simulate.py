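"""Random fitness landscapes sampled from the kernel priors.

Every kernel in the package defines a generative model: a landscape is a
zero-mean multivariate Gaussian over the full (enumerable) sequence space
with covariance given by the kernel matrix.  This module draws such
landscapes and turns them into noisy genotype-phenotype datasets — the
package's synthetic stand-in for deep-mutational-scanning and segregant
data.  All randomness flows through ``numpy`` SeedSequence sub-streams so
landscape draw, genotype subsampling and measurement noise are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import NumericalError, ValidationError
from .gp import NoiseModel
from .kernels import Kernel, validate_psd
from .space import GenotypeTable


@dataclass
class SimulationConfig:
    """One noisy dataset draw: kernel prior, noise, subsampling, seed."""

    kernel: Kernel
    seed: int
    n_obs: int | None = None  # None: keep the full space
    subsample: Sequence[str] | float | None = None  # explicit genotypes or fraction
    noise_var: float | np.ndarray = 0.0  # scalar or per-observation variance
    record_y_var: bool = True


def sample_landscape(
    kernel: Kernel, n_draws: int, seed: int, check_psd: bool = True
) -> tuple[list[str], np.ndarray]:
    """Draw zero-mean Gaussian landscapes with covariance = full-space kernel.

    Returns ``(genotypes, draws)`` with ``draws`` of shape
    ``(n_draws, space size)``; columns follow the lexicographic enumeration
    order.  Sampling uses the symmetric eigendecomposition of the kernel
    matrix (rank-deficient kernels such as the constant landscape are fine);
    bit-identical given the seed.
    """
    space = kernel.space
    genotypes = space.enumerate_sequences()
    if kernel.sigma2 == 0:
        return genotypes, np.zeros((n_draws, len(genotypes)))
    if check_psd:
        report = validate_psd(kernel, "domain_check")
        if not report:
            report = validate_psd(kernel, "eigen_check")
            if not report:
                raise NumericalError(f"kernel is not positive semidefinite: {report.message}")
    K = kernel.matrix(genotypes)
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)[None, :]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, len(genotypes)))
    return genotypes, z @ root.T


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeTable, np.ndarray]:
    """Draw one landscape, subsample genotypes, add Gaussian noise.

    Returns the noisy :class:`GenotypeTable` plus the latent (noise-free)
    phenotypes of the selected genotypes, for parameter/landscape-recovery
    tests.  Subsampling is without replacement.
    """
    kernel = config.kernel
    space = kernel.space
    ss = np.random.SeedSequence(config.seed)
    s_land, s_sub, s_noise = ss.spawn(3)

    genotypes, draws = sample_landscape(
        kernel, 1, seed=int(s_land.generate_state(1)[0] % (2**31))
    )
    f = draws[0]

    if isinstance(config.subsample, (list, tuple)):
        index = {g: i for i, g in enumerate(genotypes)}
        try:
            idx = np.array([index[g] for g in config.subsample])
        except KeyError as e:
            raise ValidationError(f"subsample genotype {e.args[0]!r} not in space") from None
    else:
        n = len(genotypes)
        if isinstance(config.subsample, float):
            n_obs = int(round(config.subsample * n))
        elif config.n_obs is not None:
            n_obs = config.n_obs
        else:
            n_obs = n
        if not 1 <= n_obs <= n:
            raise ValidationError(f"n_obs={n_obs} outside 1..{n} (without replacement)")
        rng_sub = np.random.default_rng(s_sub)
        idx = np.sort(rng_sub.choice(n, size=n_obs, replace=False))

    selected = [genotypes[i] for i in idx]
    truth = f[idx]
    noise_var = np.broadcast_to(np.asarray(config.noise_var, dtype=float), truth.shape).copy()
    if np.any(noise_var < 0):
        raise ValidationError("noise variances must be >= 0")
    rng_noise = np.random.default_rng(s_noise)
    y = truth + rng_noise.standard_normal(truth.shape) * np.sqrt(noise_var)
    table = GenotypeTable(
        space=space,
        sequences=selected,
        y=y,
        y_var=noise_var if config.record_y_var and np.any(noise_var > 0) else None,
    )
    return table, truth


def simulate_replicate_tables(
    kernel: Kernel, n_landscapes: int, seed: int, noise_var: float = 0.0
) -> list[GenotypeTable]:
    """Independent full-space landscapes from one prior, as pooled-fit input."""
    genotypes, draws = sample_landscape(kernel, n_landscapes, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    tables = []
    for f in draws:
        y = f + rng.standard_normal(f.shape) * np.sqrt(noise_var) if noise_var else f
        tables.append(GenotypeTable(space=kernel.space, sequences=genotypes, y=y))
    return tables


def _noise_model_from_table(table: GenotypeTable, uniform_var: float = 0.0) -> NoiseModel:
    return NoiseModel(uniform_var=uniform_var, per_datum_var=table.y_var)
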