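"""Variance-component decomposition and empirical distance correlations.

The Hamming graph on a uniform-alphabet space decomposes the landscape space
into orthogonal eigenspaces V_0..V_l, one per interaction order.  Projecting
a kernel onto them yields per-order expected variances lambda_k — how much
landscape variance the prior assigns to additive effects (k=1), pairwise
interactions (k=2) and so on.  Two routes are provided:

* ``projector_bruteforce`` — exact spectral projection of the full-space
  kernel matrix; works for any kernel (including anisotropic product
  kernels) on spaces small enough to enumerate.
* ``analytic_isotropic`` — inverse Krawtchouk transform of the distance
  profile k(d); only for isotropic kernels, but needs no matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kernels import (
    GeometricKernel,
    Kernel,
    VCKernel,
    eigenspace_dimensions,
    inverse_krawtchouk_transform,
    krawtchouk_matrix,
)
from .space import GenotypeTable, SequenceSpace, hamming_distance_matrix

PROJECTOR_SPACE_CAP = 4096
PAIR_CAP = 5_000_000


@dataclass
class SpectralDecomposition:
    """Per-order variances of a kernel: ``lambdas[k]`` for orders 0..l."""

    lambdas: np.ndarray
    space: SequenceSpace
    method: str

    @property
    def total_variance(self) -> float:
        return float(self.lambdas.sum())

    @property
    def fractions(self) -> np.ndarray:
        return self.lambdas / self.total_variance

    def epistatic_fraction(self) -> float:
        """Fraction of non-constant variance carried by orders k >= 2."""
        nonconst = self.lambdas[1:].sum()
        return float(self.lambdas[2:].sum() / nonconst)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": np.arange(len(self.lambdas)),
                "lambda": self.lambdas,
                "fraction_of_variance": self.fractions,
            }
        )


def order_projectors(space: SequenceSpace) -> np.ndarray:
    """Projectors onto the order-k eigenspaces, shape ``(l+1, S, S)``.

    ``P_k(x, x') = (dim V_k / alpha^l) * W_k(d(x, x'))``.  The projectors are
    symmetric, idempotent, mutually orthogonal and sum to the identity.
    """
    if not space.is_uniform:
        raise ValidationError("order projectors require a uniform alphabet size")
    n = space.size
    if n > PROJECTOR_SPACE_CAP:
        raise ValidationError(
            f"space has {n} genotypes, above the projector cap {PROJECTOR_SPACE_CAP}"
        )
    alpha = space.uniform_alphabet_size
    length = space.length
    X = space.encode(space.enumerate_sequences())
    D = hamming_distance_matrix(X)
    W = krawtchouk_matrix(length, alpha)
    m = eigenspace_dimensions(length, alpha)
    return np.stack([m[k] / n * W[k][D] for k in range(length + 1)])


def variance_components(kernel: Kernel, method: str = "auto") -> SpectralDecomposition:
    """Per-order expected variances ``lambda_k`` of a kernel.

    Brute-force route: ``lambda_k = trace(P_k K) / alpha^l`` with K the
    full-space kernel matrix.  Analytic route (isotropic kernels only):
    inverse Krawtchouk transform of k(d).  Both agree where both apply; for
    a VC kernel the input spectrum is recovered exactly.
    """
    space = kernel.space
    if method == "auto":
        method = (
            "analytic_isotropic"
            if isinstance(kernel, (VCKernel, GeometricKernel))
            else "projector_bruteforce"
        )
    if method == "analytic_isotropic":
        if isinstance(kernel, VCKernel):
            kd = kernel.covariance_at_distance(np.arange(space.length + 1))
        elif isinstance(kernel, GeometricKernel):
            kd = kernel.sigma2 * (1.0 - kernel.delta) ** np.arange(space.length + 1)
        else:
            raise ValidationError(
                f"analytic route needs an isotropic kernel, got family {kernel.family!r}"
            )
        lam = inverse_krawtchouk_transform(space, np.asarray(kd, dtype=float))
    elif method == "projector_bruteforce":
        P = order_projectors(space)
        K = kernel.matrix(space.enumerate_sequences())
        lam = np.einsum("kij,ji->k", P, K) / space.size
    else:
        raise ValidationError(f"unknown method {method!r}")
    return SpectralDecomposition(lambdas=lam, space=space, method=method)


# ----------------------------------------------------------------------
# empirical distance correlation
# ----------------------------------------------------------------------
def _pair_indices(n: int, cap: int, rng: np.random.Generator | None) -> np.ndarray:
    """All unordered pairs (i < j), uniformly subsampled beyond ``cap``."""
    total = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu)
    if total > cap:
        if rng is None:
            rng = np.random.default_rng(0)
        keep = rng.choice(total, size=cap, replace=False)
        pairs = pairs[keep]
    return pairs


def empirical_distance_correlation(
    table: GenotypeTable,
    stratify: str = "distance_only",
    min_pairs: int = 2,
    max_pairs: int = PAIR_CAP,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Average phenotype correlation per Hamming-distance class.

    For each class, ``corr(d) = c(d) / c(0)`` where ``c(d)`` is the mean of
    ``(y_x - ybar)(y_x' - ybar)`` over unordered pairs at distance ``d`` and
    ``c(0)`` the mean squared deviation over all sequences.  With
    ``stratify="by_site_set"`` pairs are additionally grouped by the set of
    sites at which they differ (reported as comma-joined site labels).
    Classes with fewer than ``min_pairs`` pairs are suppressed.
    """
    if stratify not in ("distance_only", "by_site_set"):
        raise ValidationError(f"unknown stratification {stratify!r}")
    y = table.y
    ybar = y.mean()
    resid = y - ybar
    c0 = float(np.mean(resid**2))
    if c0 == 0:
        raise ValidationError("zero total phenotypic variance; correlations undefined")
    X = table.encoded()
    rng = None if seed is None else np.random.default_rng(seed)
    pairs = _pair_indices(len(table), max_pairs, rng)
    diff = X[pairs[:, 0]] != X[pairs[:, 1]]  # (n_pairs, l)
    d = diff.sum(axis=1)
    prod = resid[pairs[:, 0]] * resid[pairs[:, 1]]

    rows = []
    if stratify == "distance_only":
        for dist in np.unique(d):
            mask = d == dist
            if int(dist) > 0 and mask.sum() < min_pairs:
                continue
            rows.append(
                {
                    "distance": int(dist),
                    "correlation": float(prod[mask].mean() / c0),
                    "n_pairs": int(mask.sum()),
                }
            )
        # distance 0 is a definition (corr = 1) even without duplicate rows
        if not any(r["distance"] == 0 for r in rows):
            rows.insert(0, {"distance": 0, "correlation": 1.0, "n_pairs": len(table)})
    else:
        labels = np.array(table.space.site_labels)
        keys = [",".join(labels[row]) for row in diff]
        frame = pd.DataFrame({"key": keys, "d": d, "prod": prod})
        for (key, dist), grp in frame.groupby(["key", "d"], sort=True):
            if int(dist) > 0 and len(grp) < min_pairs:
                continue
            rows.append(
                {
                    "distance": int(dist),
                    "site_set": key,
                    "correlation": float(grp["prod"].mean() / c0),
                    "n_pairs": len(grp),
                }
            )
    return pd.DataFrame(rows).sort_values("distance", kind="stable").reset_index(drop=True)
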