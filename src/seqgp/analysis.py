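"""Interpretable downstream outputs of a fitted model or sampled landscape.

* posterior distributions of single-mutation effects in chosen genetic
  backgrounds (with full covariance bookkeeping),
* the gamma statistic — the correlation of mutational effects between
  genetic backgrounds separated by a focal mutation; under the
  site-specific-decay prior its expectation is the product of (1 - delta)
  over the separating sites,
* hyperparameter accounting per kernel family,
* exhaustive posterior reconstruction of combinatorial sub-landscapes over a
  chosen set of focal sites.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gp import GPModel, posterior_predict
from .space import GenotypeTable, SequenceSpace, hamming_distance


@dataclass
class MutationalEffect:
    """Posterior of ``f(background with site -> to_allele) - f(background)``."""

    background: str
    site: str
    from_allele: str
    to_allele: str
    post_mean: float
    post_sd: float


def mutational_effect_posterior(
    model: GPModel,
    background: str,
    mutations: Sequence[tuple[str | int, str]],
) -> list[MutationalEffect]:
    """Posterior mean and sd of single-mutation effects in one background.

    ``mutations`` is a list of (site label, new allele) pairs.  Effects are
    differences of the latent landscape, so their posterior variance uses the
    joint posterior covariance of mutant and background:
    ``var = var(mut) + var(bg) - 2 cov(mut, bg)``.
    """
    space = model.kernel.space
    space.validate_sequence(background)
    mutants, records = [], []
    for site, allele in mutations:
        p = space.site_index(site)
        from_allele = background[p]
        if allele == from_allele:
            warnings.warn(
                f"mutation {space.site_labels[p]}:{allele} equals the background allele; "
                "zero effect by construction"
            )
        mutants.append(space.mutate(background, p, allele))
        records.append((space.site_labels[p], from_allele, allele))

    pred = posterior_predict(model, [background] + mutants, want_cov=True)
    cov = pred.cov
    out = []
    for i, (label, from_allele, to_allele) in enumerate(records, start=1):
        mean = float(pred.mean[i] - pred.mean[0])
        var = float(cov[i, i] + cov[0, 0] - 2.0 * cov[i, 0])
        out.append(
            MutationalEffect(
                background=background,
                site=label,
                from_allele=from_allele,
                to_allele=to_allele,
                post_mean=mean,
                post_sd=float(np.sqrt(max(var, 0.0))),
            )
        )
    return out


def effects_to_frame(effects: Sequence[MutationalEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "background": [e.background for e in effects],
            "site": [e.site for e in effects],
            "from_allele": [e.from_allele for e in effects],
            "to_allele": [e.to_allele for e in effects],
            "post_mean": [e.post_mean for e in effects],
            "post_sd": [e.post_sd for e in effects],
        }
    )


# ----------------------------------------------------------------------
# gamma statistic
# ----------------------------------------------------------------------
def _landscape_lookup(values, space: SequenceSpace):
    """Map input to (values matrix (n_draws, S), index dict) over the full space."""
    if isinstance(values, GenotypeTable):
        index = {}
        y = []
        for seq, val in zip(values.sequences, values.y):
            if seq in index:  # replicate rows: average
                i = index[seq]
                y[i] = 0.5 * (y[i] + val)
            else:
                index[seq] = len(y)
                y.append(val)
        return np.asarray(y)[None, :], index, list(index.keys())
    mat = np.atleast_2d(np.asarray(values, dtype=float))
    genotypes = space.enumerate_sequences()
    if mat.shape[1] != len(genotypes):
        raise ValidationError(
            f"landscape matrix has {mat.shape[1]} columns; full space has {len(genotypes)}"
        )
    return mat, {g: i for i, g in enumerate(genotypes)}, genotypes


def gamma_statistic(
    values,
    space: SequenceSpace,
    focal_site: str | int | Sequence[str | int],
    focal_mutation: tuple[str, str] | None = None,
) -> float:
    """Correlation of mutational effects across backgrounds split by focal site(s).

    ``values`` is either a :class:`GenotypeTable` or an array of full-space
    landscapes (``n_draws x space size`` in enumeration order).  Background
    pairs differing exactly at the focal site(s) are found; for every
    non-focal single mutation measurable in both backgrounds, the pair of
    effects is recorded; the statistic is the Pearson correlation over all
    such pairs, pooled across landscape draws.  ``focal_mutation`` restricts
    the pairs to a specific unordered allele pair at a single focal site.
    """
    if isinstance(focal_site, (str, int, np.integer)):
        focal = [space.site_index(focal_site)]
    else:
        focal = sorted(space.site_index(s) for s in focal_site)
    if focal_mutation is not None and len(focal) != 1:
        raise ValidationError("focal_mutation applies to a single focal site")

    mat, index, genotypes = _landscape_lookup(values, space)
    nonfocal = [p for p in range(space.length) if p not in focal]
    if not nonfocal:
        raise ValidationError("gamma needs at least one non-focal site")

    # group genotypes by their identity outside the focal sites
    groups: dict[str, list[str]] = {}
    for g in genotypes:
        key = "".join(g[p] for p in nonfocal)
        groups.setdefault(key, []).append(g)

    eff_a, eff_b = [], []
    for members in groups.values():
        for g, g2 in itertools.combinations(members, 2):
            if any(g[p] == g2[p] for p in focal):
                continue  # must differ at every focal site
            if focal_mutation is not None:
                pair = {g[focal[0]], g2[focal[0]]}
                if pair != set(focal_mutation):
                    continue
            for q in nonfocal:
                for b in space.alphabets[q]:
                    if b == g[q]:
                        continue
                    m1, m2 = space.mutate(g, q, b), space.mutate(g2, q, b)
                    if m1 not in index or m2 not in index:
                        continue
                    eff_a.append(mat[:, index[m1]] - mat[:, index[g]])
                    eff_b.append(mat[:, index[m2]] - mat[:, index[g2]])
    if len(eff_a) < 3:
        raise ValidationError(
            f"only {len(eff_a)} paired mutational effects available; need >= 3"
        )
    a = np.concatenate(eff_a)
    b = np.concatenate(eff_b)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValidationError("degenerate mutational effects: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


# ----------------------------------------------------------------------
# hyperparameter accounting
# ----------------------------------------------------------------------
def count_hyperparameters(
    family: str, space: SequenceSpace, include_scalars: bool = False
) -> dict:
    """Free-hyperparameter counts per kernel family on a given space.

    ``decay_factors`` counts the family-specific shape parameters (for the
    VC family, the per-order variances including the constant term);
    ``scalars`` is always 2 (prior variance and uniform noise); ``total``
    adds them when ``include_scalars``.
    """
    length = space.length
    if family == "geometric":
        n = 1
    elif family == "connectedness":
        n = length
    elif family == "jenga":
        n = sum(space.alphabet_sizes)
    elif family == "general_product":
        n = sum(a * (a - 1) // 2 for a in space.alphabet_sizes)
    elif family == "vc":
        n = length + 1
    else:
        raise ValidationError(f"unknown kernel family {family!r}")
    scalars = 2
    return {
        "decay_factors": n,
        "scalars": scalars,
        "total": n + scalars if include_scalars else n,
    }


# ----------------------------------------------------------------------
# combinatorial sub-landscape reconstruction
# ----------------------------------------------------------------------
def reconstruct_sublandscape(
    model: GPModel,
    focal_sites: Sequence[str | int],
    fixed_background: str,
    reference: str | None = None,
    cap: int = 2**20,
) -> pd.DataFrame:
    """Posterior over all allele combinations at focal sites, background fixed.

    Enumerates the combinatorial subspace (refused with its size if above
    ``cap``), computes the posterior mean and variance per genotype and the
    Hamming distance to ``reference`` (the fixed background by default).
    """
    space = model.kernel.space
    space.validate_sequence(fixed_background)
    focal = [space.site_index(s) for s in focal_sites]
    if len(set(focal)) != len(focal):
        raise ValidationError("duplicate focal sites")
    size = 1
    for p in focal:
        size *= len(space.alphabets[p])
    if size > cap:
        raise ValidationError(f"subspace has {size} genotypes, above the cap {cap}")

    template = list(fixed_background)
    seqs = []
    for combo in itertools.product(*(space.alphabets[p] for p in focal)):
        s = template[:]
        for p, allele in zip(focal, combo):
            s[p] = allele
        seqs.append("".join(s))
    pred = posterior_predict(model, seqs)
    ref = fixed_background if reference is None else reference
    space.validate_sequence(ref)
    df = pred.to_frame()
    df["distance_to_reference"] = [hamming_distance(s, ref) for s in seqs]
    return df
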