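"""Anisotropic product kernels and isotropic kernels on sequence space.

Five prior families over genotype-phenotype maps, forming a nested hierarchy:

geometric ⊂ connectedness ⊂ Jenga ⊂ general product, plus the isotropic
variance-component (VC) family.

All product-family kernels share the form

    k(x, x') = sigma2 * prod_{p : x_p != x'_p} f_p(x_p, x'_p)

where the per-site factor ``f_p`` depends on the family:

==================  ==========================================================
geometric           1 - delta                      (one shared decay factor)
connectedness       1 - delta_p                    (site-specific)
Jenga               sqrt((1 - delta_p^a)(1 - delta_p^a'))   (allele-specific)
general product     1 - delta_p^{a,a'}             (mutation-specific)
==================  ==========================================================

A decay factor ``delta`` is the fractional loss of correlation — in both
phenotypes and mutational effects — caused by that mutation; factors for
multiple differing sites multiply.  ``delta = 0`` means the mutation leaves
the landscape perfectly correlated; ``delta = 1`` decorrelates it entirely
(the House-of-Cards limit when all factors are 1).

The VC kernel is isotropic: ``k(d) = sum_k lambda_k W_k(d)`` with ``W_k`` the
normalized Krawtchouk polynomial of order ``k`` and ``lambda_k >= 0`` the
expected variance contributed by order-``k`` interactions.
"""

from __future__ import annotations

import json
import math
from abc import ABC, abstractmethod
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import NumericalError, ValidationError
from .space import SequenceSpace, hamming_distance_matrix

PSD_EIGEN_CAP = 4096
PSD_EIGEN_TOL = 1e-9


# ----------------------------------------------------------------------
# Krawtchouk polynomials
# ----------------------------------------------------------------------
def krawtchouk(k: int, d: int, length: int, alpha: int) -> float:
    """Normalized Krawtchouk polynomial ``W_k(d) = K_k(d) / K_k(0)``.

    ``K_k(d) = sum_q (-1)^q (alpha-1)^{k-q} C(d, q) C(length-d, k-q)`` and
    ``K_k(0) = C(length, k) (alpha-1)^k``, so ``W_k(0) = 1``.  Computed with
    exact integer arithmetic before the final division.
    """
    if not (0 <= k <= length and 0 <= d <= length):
        raise ValidationError(f"need 0 <= k, d <= length; got k={k}, d={d}, length={length}")
    if alpha < 2:
        raise ValidationError("alphabet size must be >= 2")
    num = sum(
        (-1) ** q * (alpha - 1) ** (k - q) * math.comb(d, q) * math.comb(length - d, k - q)
        for q in range(k + 1)
    )
    den = math.comb(length, k) * (alpha - 1) ** k
    return num / den


def krawtchouk_matrix(length: int, alpha: int) -> np.ndarray:
    """Matrix ``W[k, d]`` of normalized Krawtchouk values, shape (l+1, l+1)."""
    return np.array(
        [[krawtchouk(k, d, length, alpha) for d in range(length + 1)] for k in range(length + 1)]
    )


def eigenspace_dimensions(length: int, alpha: int) -> np.ndarray:
    """Multiplicities ``dim V_k = C(l, k) (alpha-1)^k`` of the Hamming-graph eigenspaces."""
    return np.array(
        [math.comb(length, k) * (alpha - 1) ** k for k in range(length + 1)], dtype=float
    )


# ----------------------------------------------------------------------
# connectedness-model parameter conversion
# ----------------------------------------------------------------------
def mu_to_delta(mu, alpha: float):
    """Convert per-site epistatic probabilities ``mu_p`` to decay factors.

    ``delta_p = alpha * mu_p / (1 + (alpha - 1) * mu_p)``; the classical
    connectedness-model parameterization maps onto decay factors this way.
    """
    mu = np.asarray(mu, dtype=float)
    if alpha < 1:
        raise ValidationError("alpha must be >= 1")
    if np.any((mu < 0) | (mu > 1)):
        raise ValidationError("mu must lie in [0, 1]")
    return alpha * mu / (1.0 + (alpha - 1.0) * mu)


def delta_to_mu(delta, alpha: float):
    """Inverse of :func:`mu_to_delta`: ``mu_p = delta_p / (alpha - (alpha-1) delta_p)``."""
    delta = np.asarray(delta, dtype=float)
    if alpha < 1:
        raise ValidationError("alpha must be >= 1")
    return delta / (alpha - (alpha - 1.0) * delta)


# ----------------------------------------------------------------------
# kernel base class
# ----------------------------------------------------------------------
class Kernel(ABC):
    """Covariance function over a :class:`SequenceSpace`."""

    family: str

    def __init__(self, space: SequenceSpace, sigma2: float):
        if sigma2 < 0:
            raise ValidationError("sigma2 must be nonnegative")
        self.space = space
        self.sigma2 = float(sigma2)

    # -- evaluation ----------------------------------------------------
    @abstractmethod
    def matrix_encoded(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
        """Covariance matrix for encoded sequence arrays."""

    def matrix(self, X: Sequence[str], X2: Sequence[str] | None = None) -> np.ndarray:
        """Covariance matrix for lists of sequence strings."""
        Xe = self.space.encode(list(X))
        X2e = None if X2 is None else self.space.encode(list(X2))
        return self.matrix_encoded(Xe, X2e)

    def pair(self, x: str, x2: str) -> float:
        """Covariance between two genotypes."""
        return float(self.matrix([x], [x2])[0, 0])

    def correlation(self, x: str, x2: str) -> float:
        """Prior correlation ``k(x, x') / sigma2`` between two genotypes."""
        if self.sigma2 == 0:
            raise ValidationError("correlation undefined for sigma2 = 0")
        return self.pair(x, x2) / self.sigma2

    # -- bookkeeping ---------------------------------------------------
    @property
    @abstractmethod
    def n_decay_factors(self) -> int:
        """Number of free decay-factor (or spectrum) hyperparameters."""

    @abstractmethod
    def _params_dict(self) -> dict:
        """Family-specific parameters keyed by site label / allele symbols."""

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "sigma2": self.sigma2,
            "space": {
                "alphabets": ["".join(a) for a in self.space.alphabets],
                "site_labels": list(self.space.site_labels),
            },
            "parameters": self._params_dict(),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @staticmethod
    def from_dict(doc: dict) -> "Kernel":
        space = SequenceSpace(
            alphabets=doc["space"]["alphabets"], site_labels=doc["space"]["site_labels"]
        )
        family = doc["family"]
        sigma2 = doc["sigma2"]
        params = doc["parameters"]
        if family == "geometric":
            return GeometricKernel(space, sigma2, params["delta"])
        if family == "connectedness":
            delta = [params["delta"][lab] for lab in space.site_labels]
            return ConnectednessKernel(space, sigma2, delta)
        if family == "jenga":
            delta = [
                [params["delta"][lab][a] for a in space.alphabets[p]]
                for p, lab in enumerate(space.site_labels)
            ]
            return JengaKernel(space, sigma2, delta)
        if family == "general_product":
            mats = []
            for p, lab in enumerate(space.site_labels):
                alpha = space.alphabets[p]
                m = np.zeros((len(alpha), len(alpha)))
                for key, val in params["delta"][lab].items():
                    a, a2 = key.split("/")
                    i, j = alpha.index(a), alpha.index(a2)
                    m[i, j] = m[j, i] = val
                mats.append(m)
            return GeneralProductKernel(space, sigma2, mats)
        if family == "vc":
            return VCKernel(space, params["lambdas"])
        raise ValidationError(f"unknown kernel family {family!r}")

    @staticmethod
    def from_json(source: str | Path) -> "Kernel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return Kernel.from_dict(json.loads(text))


# ----------------------------------------------------------------------
# product-family kernels
# ----------------------------------------------------------------------
class ProductKernel(Kernel):
    """Common machinery: per-site factor matrices with unit diagonal.

    ``site_factor(p)`` returns the ``alpha_p x alpha_p`` matrix ``F_p`` with
    ``F_p[a, a] = 1`` and off-diagonal entries equal to the family's decay
    term; the kernel is ``sigma2 * prod_p F_p[x_p, x'_p]``.
    """

    @abstractmethod
    def site_factor(self, p: int) -> np.ndarray:
        ...

    def matrix_encoded(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
        if X2 is None:
            X2 = X
        K = np.full((X.shape[0], X2.shape[0]), self.sigma2)
        for p in range(self.space.length):
            F = self.site_factor(p)
            K *= F[X[:, p][:, None], X2[:, p][None, :]]
        return K


def _check_delta(delta: np.ndarray, allow_extended: bool, what: str) -> None:
    if np.any(delta < 0):
        raise ValidationError(f"{what}: decay factors must be >= 0")
    if not allow_extended and np.any(delta > 1):
        raise ValidationError(
            f"{what}: decay factors above 1 require allow_extended=True "
            "(validity then checked by eigen_check)"
        )


class GeometricKernel(ProductKernel):
    """Isotropic geometric decay: ``k = sigma2 (1-delta)^d(x, x')``."""

    family = "geometric"

    def __init__(
        self, space: SequenceSpace, sigma2: float, delta: float, allow_extended: bool = False
    ):
        super().__init__(space, sigma2)
        self.delta = float(delta)
        _check_delta(np.array([self.delta]), allow_extended, "geometric kernel")

    def site_factor(self, p: int) -> np.ndarray:
        alpha = len(self.space.alphabets[p])
        F = np.full((alpha, alpha), 1.0 - self.delta)
        np.fill_diagonal(F, 1.0)
        return F

    def matrix_encoded(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
        D = hamming_distance_matrix(X, X if X2 is None else X2)
        return self.sigma2 * (1.0 - self.delta) ** D

    @property
    def n_decay_factors(self) -> int:
        return 1

    def _params_dict(self) -> dict:
        return {"delta": self.delta}

    def as_connectedness(self) -> "ConnectednessKernel":
        return ConnectednessKernel(
            self.space, self.sigma2, [self.delta] * self.space.length, allow_extended=True
        )


class ConnectednessKernel(ProductKernel):
    """Site-specific decay factors: ``k = sigma2 prod_{p differs} (1 - delta_p)``."""

    family = "connectedness"

    def __init__(
        self,
        space: SequenceSpace,
        sigma2: float,
        delta: Sequence[float],
        allow_extended: bool = False,
    ):
        super().__init__(space, sigma2)
        self.delta = np.asarray(delta, dtype=float)
        if self.delta.shape != (space.length,):
            raise ValidationError(
                f"need one decay factor per site: expected {space.length}, got {self.delta.shape}"
            )
        _check_delta(self.delta, allow_extended, "connectedness kernel")

    def site_factor(self, p: int) -> np.ndarray:
        alpha = len(self.space.alphabets[p])
        F = np.full((alpha, alpha), 1.0 - self.delta[p])
        np.fill_diagonal(F, 1.0)
        return F

    @property
    def n_decay_factors(self) -> int:
        return self.space.length

    def _params_dict(self) -> dict:
        return {
            "delta": {lab: float(d) for lab, d in zip(self.space.site_labels, self.delta)}
        }

    def as_jenga(self) -> "JengaKernel":
        """Equivalent Jenga kernel (every allele at site p shares delta_p)."""
        return JengaKernel(
            self.space,
            self.sigma2,
            [[self.delta[p]] * len(a) for p, a in enumerate(self.space.alphabets)],
        )


class JengaKernel(ProductKernel):
    """Allele-specific decay factors.

    A differing site with alleles ``a, a'`` contributes the geometric mean
    ``sqrt((1 - delta_p^a)(1 - delta_p^a'))``; with all factors equal to 1
    this is the House-of-Cards kernel (``sigma2`` times the identity on
    genotypes).  Decay factors are restricted to [0, 1]: the geometric-mean
    form has no real value when exactly one factor exceeds 1.
    """

    family = "jenga"

    def __init__(self, space: SequenceSpace, sigma2: float, delta: Sequence[Sequence[float]]):
        super().__init__(space, sigma2)
        if len(delta) != space.length:
            raise ValidationError(
                f"need per-site allele decay factors for all {space.length} sites"
            )
        self.delta = []
        for p, (d_p, alpha) in enumerate(zip(delta, space.alphabets)):
            d_p = np.asarray(d_p, dtype=float)
            if d_p.shape != (len(alpha),):
                raise ValidationError(
                    f"site {space.site_labels[p]}: expected {len(alpha)} allele decay "
                    f"factors for alphabet {''.join(alpha)!r}, got shape {d_p.shape}"
                )
            if np.any((d_p < 0) | (d_p > 1)):
                raise ValidationError(
                    f"site {space.site_labels[p]}: Jenga decay factors must lie in [0, 1]"
                )
            self.delta.append(d_p)

    def site_factor(self, p: int) -> np.ndarray:
        r = np.sqrt(1.0 - self.delta[p])  # per-allele correlation roots
        F = np.outer(r, r)
        np.fill_diagonal(F, 1.0)
        return F

    @property
    def n_decay_factors(self) -> int:
        return int(sum(len(d) for d in self.delta))

    def _params_dict(self) -> dict:
        return {
            "delta": {
                lab: {a: float(d) for a, d in zip(alpha, d_p)}
                for lab, alpha, d_p in zip(self.space.site_labels, self.space.alphabets, self.delta)
            }
        }

    def as_general_product(self) -> "GeneralProductKernel":
        """Equivalent mutation-specific kernel: ``delta^{a,a'} = 1 - sqrt((1-d^a)(1-d^a'))``."""
        mats = []
        for p in range(self.space.length):
            F = self.site_factor(p)
            mats.append(1.0 - F + np.diag(np.diag(F) - 1.0))
        return GeneralProductKernel(self.space, self.sigma2, mats)


class GeneralProductKernel(ProductKernel):
    """Mutation-specific decay factors ``delta_p^{a,a'}``, one per unordered allele pair."""

    family = "general_product"

    def __init__(
        self,
        space: SequenceSpace,
        sigma2: float,
        delta: Sequence[np.ndarray],
        allow_extended: bool = False,
    ):
        super().__init__(space, sigma2)
        if len(delta) != space.length:
            raise ValidationError(f"need one decay matrix per site ({space.length})")
        self.delta = []
        for p, (m, alpha) in enumerate(zip(delta, space.alphabets)):
            m = np.asarray(m, dtype=float)
            if m.shape != (len(alpha), len(alpha)):
                raise ValidationError(
                    f"site {space.site_labels[p]}: decay matrix must be "
                    f"{len(alpha)}x{len(alpha)}, got {m.shape}"
                )
            if not np.allclose(m, m.T):
                raise ValidationError(
                    f"site {space.site_labels[p]}: decay matrix must be symmetric"
                )
            if np.any(np.abs(np.diag(m)) > 0):
                raise ValidationError(
                    f"site {space.site_labels[p]}: decay matrix diagonal must be zero"
                )
            off = m[~np.eye(len(alpha), dtype=bool)]
            _check_delta(off, allow_extended, f"site {space.site_labels[p]}")
            self.delta.append(m)

    def site_factor(self, p: int) -> np.ndarray:
        return 1.0 - self.delta[p]

    @property
    def n_decay_factors(self) -> int:
        return int(sum(len(a) * (len(a) - 1) // 2 for a in self.space.alphabets))

    def _params_dict(self) -> dict:
        out = {}
        for lab, alpha, m in zip(self.space.site_labels, self.space.alphabets, self.delta):
            out[lab] = {
                f"{alpha[i]}/{alpha[j]}": float(m[i, j])
                for i in range(len(alpha))
                for j in range(i + 1, len(alpha))
            }
        return {"delta": out}


def hoc_kernel(space: SequenceSpace, sigma2: float = 1.0) -> JengaKernel:
    """House-of-Cards kernel: every decay factor 1, i.e. ``sigma2 * I`` on genotypes."""
    return JengaKernel(space, sigma2, [[1.0] * len(a) for a in space.alphabets])


# ----------------------------------------------------------------------
# variance-component kernel
# ----------------------------------------------------------------------
class VCKernel(Kernel):
    """Isotropic kernel parameterized by per-order variances ``lambda_0..lambda_l``.

    ``k(d) = sum_k lambda_k W_k(d)``; the prior variance is ``sum_k lambda_k``
    since ``W_k(0) = 1``.  ``lambda_0`` is the (usually zero) constant
    component.  Requires a uniform alphabet.
    """

    family = "vc"

    def __init__(self, space: SequenceSpace, lambdas: Sequence[float]):
        if not space.is_uniform:
            raise ValidationError("the VC kernel requires a uniform alphabet size")
        lambdas = np.asarray(lambdas, dtype=float)
        if lambdas.shape != (space.length + 1,):
            raise ValidationError(
                f"need lambda_0..lambda_{space.length}, got shape {lambdas.shape}"
            )
        if np.any(lambdas < 0):
            raise ValidationError("per-order variances lambda_k must be nonnegative")
        super().__init__(space, float(lambdas.sum()))
        self.lambdas = lambdas
        self._kd = self.lambdas @ krawtchouk_matrix(space.length, space.uniform_alphabet_size)

    def covariance_at_distance(self, d) -> np.ndarray:
        """Covariance as a function of Hamming distance."""
        return self._kd[np.asarray(d)]

    def matrix_encoded(self, X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
        D = hamming_distance_matrix(X, X if X2 is None else X2)
        return self._kd[D]

    @property
    def n_decay_factors(self) -> int:
        return self.space.length + 1

    def _params_dict(self) -> dict:
        return {"lambdas": [float(v) for v in self.lambdas]}

    @classmethod
    def from_distance_covariance(cls, space: SequenceSpace, kd: Sequence[float]) -> "VCKernel":
        """Build a VC kernel matching a distance-covariance profile ``k(d)``.

        Inverse Krawtchouk transform: ``lambda_k = (m_k / alpha^l) *
        sum_d C(l,d)(alpha-1)^d W_k(d) k(d)``.  Raises if the profile is not
        positive semidefinite on the Hamming graph (negative lambda).
        """
        kd = np.asarray(kd, dtype=float)
        lam = inverse_krawtchouk_transform(space, kd)
        if np.any(lam < -1e-9 * max(np.abs(lam).sum(), 1e-300)):
            raise NumericalError(f"distance profile is not a valid kernel: lambdas {lam}")
        return cls(space, np.clip(lam, 0.0, None))


def inverse_krawtchouk_transform(space: SequenceSpace, kd: Sequence[float]) -> np.ndarray:
    """Per-order variances of an isotropic distance profile ``k(d)``."""
    alpha = space.uniform_alphabet_size
    length = space.length
    kd = np.asarray(kd, dtype=float)
    if kd.shape != (length + 1,):
        raise ValidationError(f"need k(d) for d=0..{length}")
    W = krawtchouk_matrix(length, alpha)
    m = eigenspace_dimensions(length, alpha)
    N = np.array([math.comb(length, d) * (alpha - 1) ** d for d in range(length + 1)], dtype=float)
    return m * ((W * N[None, :]) @ kd) / alpha**length


# ----------------------------------------------------------------------
# positive-definiteness checks
# ----------------------------------------------------------------------
class PSDReport:
    """Outcome of a positive-definiteness validation."""

    def __init__(self, passed: bool, mode: str, message: str, min_eig=None, max_eig=None):
        self.passed = passed
        self.mode = mode
        self.message = message
        self.min_eig = min_eig
        self.max_eig = max_eig

    def __bool__(self) -> bool:
        return self.passed

    def __repr__(self) -> str:
        return f"PSDReport(passed={self.passed}, mode={self.mode!r}, message={self.message!r})"


def _all_deltas(kernel: Kernel) -> np.ndarray:
    if isinstance(kernel, GeometricKernel):
        return np.array([kernel.delta])
    if isinstance(kernel, ConnectednessKernel):
        return kernel.delta
    if isinstance(kernel, JengaKernel):
        return np.concatenate(kernel.delta)
    if isinstance(kernel, GeneralProductKernel):
        return np.concatenate(
            [m[~np.eye(m.shape[0], dtype=bool)] for m in kernel.delta]
        )
    raise ValidationError(f"domain_check does not apply to family {kernel.family!r}")


def validate_psd(kernel: Kernel, mode: str = "domain_check", tol: float = PSD_EIGEN_TOL) -> PSDReport:
    """Check that a kernel is positive semidefinite on its full space.

    ``domain_check`` is the cheap sufficient condition (all decay factors in
    [0, 1]; always true for VC kernels with nonnegative lambdas).
    ``eigen_check`` builds the full-space kernel matrix (refused above
    4096 genotypes) and passes iff the minimum eigenvalue is at least
    ``-tol`` times the maximum — this admits some decay factors above 1.
    """
    if mode == "domain_check":
        if isinstance(kernel, VCKernel):
            return PSDReport(True, mode, "nonnegative lambdas: PSD by construction")
        if isinstance(kernel, GeneralProductKernel):
            # the full kernel is the Kronecker product of the per-site factor
            # matrices, so per-site PSD-ness is sufficient at any space size;
            # decay factors in [0, 1] alone are NOT sufficient for alpha >= 3
            for p in range(kernel.space.length):
                F = kernel.site_factor(p)
                lo = float(np.linalg.eigvalsh(F)[0])
                if lo < -PSD_EIGEN_TOL:
                    return PSDReport(
                        False,
                        mode,
                        f"site {kernel.space.site_labels[p]}: factor matrix has "
                        f"min eigenvalue {lo:.3e}; run eigen_check or reparameterize",
                    )
            return PSDReport(True, mode, "all per-site factor matrices PSD (sufficient)")
        deltas = _all_deltas(kernel)
        ok = bool(np.all((deltas >= 0) & (deltas <= 1)))
        msg = (
            "all decay factors in [0, 1] (sufficient condition)"
            if ok
            else "decay factors outside [0, 1]; run eigen_check to decide validity"
        )
        return PSDReport(ok, mode, msg)
    if mode == "eigen_check":
        n = kernel.space.size
        if n > PSD_EIGEN_CAP:
            raise ValidationError(
                f"eigen_check needs an enumerable space: {n} genotypes exceeds cap {PSD_EIGEN_CAP}"
            )
        seqs = kernel.space.enumerate_sequences()
        K = kernel.matrix(seqs)
        eig = np.linalg.eigvalsh(K)
        lo, hi = float(eig[0]), float(eig[-1])
        ok = lo >= -tol * max(hi, 0.0)
        return PSDReport(
            ok,
            mode,
            f"min eigenvalue {lo:.3e}, max {hi:.3e}" + ("" if ok else ": not PSD"),
            min_eig=lo,
            max_eig=hi,
        )
    raise ValidationError(f"unknown validation mode {mode!r}")


KERNEL_FAMILIES = ("geometric", "connectedness", "jenga", "general_product", "vc")
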