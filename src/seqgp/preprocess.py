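"""Dataset-preparation transforms for count, replicate and segregant data.

Three standalone steps that turn raw high-throughput measurements into
genotype tables with per-sequence variances:

* :func:`log_enrichment` — selection-experiment read counts to wild-type-
  anchored log-enrichment scores with pseudocount-based error variances.
* :func:`lognormal_variance` — replicate log-enrichment estimates to a
  delta-method variance under a log-normal measurement model.
* :func:`genome_uncertainty` — biallelic genotype-probability matrices to a
  per-individual uncertainty score, used to retain only confidently
  genotyped segregants and hard-call their genotypes.

Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .space import GenotypeTable, SequenceSpace


def log_enrichment(
    counts: pd.DataFrame,
    wildtype: str | None = None,
    space: SequenceSpace | str = "infer",
    pseudocount: float = 0.5,
) -> GenotypeTable:
    """Wild-type-anchored log-enrichment scores from selection read counts.

    ``counts`` needs columns ``sequence``, ``count_input``, ``count_selected``
    and either a boolean ``wildtype`` column or an explicit ``wildtype``
    sequence.  For each sequence x,

        y_x  = log((c_sel + 0.5) / (c_in + 0.5)) - (same for wild type)
        var  = 1/(c_in + 0.5) + 1/(c_sel + 0.5) + (same two wild-type terms)

    so poorly covered sequences carry large measurement variances.
    """
    required = {"sequence", "count_input", "count_selected"}
    if not required.issubset(counts.columns):
        raise ValidationError(f"count table needs columns {sorted(required)}")
    seqs = [str(s) for s in counts["sequence"]]
    c_in = counts["count_input"].to_numpy(float)
    c_sel = counts["count_selected"].to_numpy(float)
    if np.any(c_in < 0) or np.any(c_sel < 0):
        raise ValidationError("read counts must be nonnegative")

    if wildtype is None:
        if "wildtype" not in counts.columns:
            raise ValidationError("designate the wild type (column or argument)")
        wt_idx = np.flatnonzero(counts["wildtype"].to_numpy(bool))
        if len(wt_idx) != 1:
            raise ValidationError(f"exactly one wildtype row required, found {len(wt_idx)}")
        wt_idx = int(wt_idx[0])
    else:
        try:
            wt_idx = seqs.index(wildtype)
        except ValueError:
            raise ValidationError(f"wildtype sequence {wildtype!r} not in the count table") from None

    ci = c_in + pseudocount
    cs = c_sel + pseudocount
    log_ratio = np.log(cs / ci)
    y = log_ratio - log_ratio[wt_idx]
    y_var = 1.0 / ci + 1.0 / cs + 1.0 / ci[wt_idx] + 1.0 / cs[wt_idx]
    if isinstance(space, str):
        space = SequenceSpace.from_sequences(seqs)
    return GenotypeTable(space=space, sequences=seqs, y=y, y_var=y_var)


@dataclass
class ReplicateSet:
    """Per-sequence phenotype estimates with replicate sample variances.

    ``y`` is the (bias-corrected) log-scale phenotype estimate, ``s2`` the
    sample variance of the log-enrichment ratio across replicates (NaN where
    unavailable), ``n_reps`` the number of strictly positive replicates.
    """

    y: np.ndarray
    s2: np.ndarray
    n_reps: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        self.n_reps = np.asarray(self.n_reps, dtype=int)
        if not (self.y.shape == self.s2.shape == self.n_reps.shape):
            raise ValidationError("y, s2 and n_reps must be aligned")
        if np.any(self.s2[~np.isnan(self.s2)] < 0):
            raise ValidationError("replicate sample variances must be >= 0")


def lognormal_variance(reps: ReplicateSet) -> np.ndarray:
    """Measurement variance under a log-normal replicate model.

    ``sigma_x^2 = (exp(s_x^2) - 1) * exp(2 y_x + s_x^2)`` — the variance of a
    log-normal variable whose log has mean ``y_x`` and variance ``s_x^2``.
    Sequences with fewer than two strictly positive replicates fall back on
    the median ``s^2`` across qualifying sequences.
    """
    qualifying = (reps.n_reps >= 2) & ~np.isnan(reps.s2)
    if not qualifying.any():
        raise ValidationError(
            "no sequence has >= 2 positive replicates; median fallback undefined"
        )
    median_s2 = float(np.median(reps.s2[qualifying]))
    s2 = np.where(qualifying, reps.s2, median_s2)
    return (np.exp(s2) - 1.0) * np.exp(2.0 * reps.y + s2)


@dataclass
class SegregantGenotypes:
    """Genotype probabilities for haploid segregants at biallelic loci.

    ``p[x, i]`` is the probability that individual x carries the alternate
    (``"1"``) allele at locus i.
    """

    p: np.ndarray
    ids: list | None = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2:
            raise ValidationError("genotype probabilities must be a 2-D matrix")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValidationError("genotype probabilities must lie in [0, 1]")
        if self.ids is not None and len(self.ids) != self.p.shape[0]:
            raise ValidationError("ids must align with rows of p")

    @property
    def n_loci(self) -> int:
        return self.p.shape[1]


def genome_uncertainty_scores(geno: SegregantGenotypes) -> np.ndarray:
    """Per-individual genome uncertainty ``U_x = (4/l) sum_i p_{x,i}(1 - p_{x,i})``.

    0 when every locus is called with certainty, 1 when every locus is a
    coin flip; invariant under allele relabeling (p -> 1-p).
    """
    length = geno.n_loci
    return 4.0 / length * np.sum(geno.p * (1.0 - geno.p), axis=1)


def genome_uncertainty(
    geno: SegregantGenotypes, keep_fraction: float = 0.20
) -> tuple[SegregantGenotypes, np.ndarray, list[str]]:
    """Retain the most confidently genotyped segregants and hard-call them.

    Keeps the ``ceil(keep_fraction * n)`` individuals with lowest genome
    uncertainty (ties broken by stable input order) and hard-calls their
    alleles as ``"1"`` where ``p >= 0.5`` else ``"0"``.  Returns the filtered
    probabilities, the kept row indices and the hard-called sequences.
    """
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must lie in (0, 1]")
    U = genome_uncertainty_scores(geno)
    n_keep = int(np.ceil(keep_fraction * len(U)))
    keep = np.argsort(U, kind="stable")[:n_keep]
    keep = np.sort(keep)  # stable input order among the retained
    p_kept = geno.p[keep]
    calls = np.where(p_kept >= 0.5, "1", "0")
    sequences = ["".join(row) for row in calls]
    filtered = SegregantGenotypes(
        p=p_kept, ids=None if geno.ids is None else [geno.ids[i] for i in keep]
    )
    return filtered, keep, sequences
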