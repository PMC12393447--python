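"""Discrete sequence spaces, genotype encodings and genotype-table I/O.

A :class:`SequenceSpace` is the product of per-site alphabets: ``l`` sites,
site ``p`` carrying ``alpha_p >= 2`` symbols.  Genotypes are plain strings of
length ``l`` (one character per site).  The space size ``prod(alpha_p)`` is
kept as a Python integer so astronomically large spaces (e.g. 20^28) are
represented exactly without overflow.

Phenotype data are held in a :class:`GenotypeTable`: aligned sequences, a
real-valued phenotype ``y`` per sequence and an optional per-sequence
measurement variance ``y_var`` (assay units squared).  Duplicate sequences
are legal and treated as replicate measurements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: default refusal threshold for full-space enumeration
DEFAULT_ENUMERATION_CAP = 2**24

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"
BINARY_ALPHABET = "01"


@dataclass(frozen=True)
class SequenceSpace:
    """Product space of per-site alphabets with the Hamming metric.

    Parameters
    ----------
    alphabets
        One ordered symbol string/tuple per site; every site needs at least
        two distinct single-character symbols.
    site_labels
        Optional user-facing labels (e.g. protein positions ``"39"``,
        ``"41"`` or splice-site coordinates ``"-3"``, ``"+2"``).  Defaults
        to 1-based positions.
    """

    alphabets: tuple[tuple[str, ...], ...]
    site_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __init__(
        self,
        alphabets: Sequence[Sequence[str]],
        site_labels: Sequence[str] | None = None,
    ):
        alphabets = tuple(tuple(a) for a in alphabets)
        if not alphabets:
            raise ValidationError("a sequence space needs at least one site")
        for p, alpha in enumerate(alphabets):
            if len(alpha) < 2:
                raise ValidationError(
                    f"site {p + 1}: alphabet must contain at least 2 symbols, got {alpha!r}"
                )
            if len(set(alpha)) != len(alpha):
                raise ValidationError(f"site {p + 1}: duplicate symbols in {alpha!r}")
            for s in alpha:
                if len(s) != 1:
                    raise ValidationError(
                        f"site {p + 1}: symbols must be single characters, got {s!r}"
                    )
        if site_labels is None:
            site_labels = tuple(str(p + 1) for p in range(len(alphabets)))
        else:
            site_labels = tuple(str(s) for s in site_labels)
            if len(site_labels) != len(alphabets):
                raise ValidationError("site_labels length must match the number of sites")
        object.__setattr__(self, "alphabets", alphabets)
        object.__setattr__(self, "site_labels", site_labels)
        object.__setattr__(
            self,
            "_index",
            tuple({s: i for i, s in enumerate(a)} for a in alphabets),
        )

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def uniform(
        cls,
        length: int,
        alphabet: Sequence[str] | int,
        site_labels: Sequence[str] | None = None,
    ) -> "SequenceSpace":
        """Space with the same alphabet at every one of ``length`` sites.

        ``alphabet`` may be a symbol string (``"ACGT"``) or an integer
        ``alpha``, in which case digits/letters ``0..alpha-1`` are used.
        """
        if length < 1:
            raise ValidationError("length must be >= 1")
        if isinstance(alphabet, int):
            if alphabet < 2:
                raise ValidationError("alphabet size must be >= 2")
            symbols = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
            if alphabet > len(symbols):
                raise ValidationError("integer alphabet shorthand supports up to 36 symbols")
            alphabet = symbols[:alphabet]
        return cls([tuple(alphabet)] * length, site_labels)

    @classmethod
    def from_sequences(
        cls, sequences: Iterable[str], site_labels: Sequence[str] | None = None
    ) -> "SequenceSpace":
        """Infer per-site alphabets as the sorted union of observed symbols."""
        seqs = list(sequences)
        if not seqs:
            raise ValidationError("cannot infer a space from zero sequences")
        length = len(seqs[0])
        for s in seqs:
            if len(s) != length:
                raise FormatError(
                    f"ragged sequence lengths: expected {length}, got {len(s)} in {s!r}"
                )
        alphabets = [sorted({s[p] for s in seqs}) for p in range(length)]
        for p, a in enumerate(alphabets):
            if len(a) < 2:
                # pad monomorphic sites so the space remains valid; the extra
                # symbol is never observed and carries no data
                raise ValidationError(
                    f"site {p + 1} is monomorphic ({a[0]!r}); declare the space explicitly"
                )
        return cls(alphabets, site_labels)

    # ------------------------------------------------------------------
    # basic properties
    # ------------------------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.alphabets)

    @property
    def alphabet_sizes(self) -> tuple[int, ...]:
        return tuple(len(a) for a in self.alphabets)

    @property
    def size(self) -> int:
        """Exact number of genotypes, as an arbitrary-precision integer."""
        return math.prod(self.alphabet_sizes)

    @property
    def is_uniform(self) -> bool:
        return len(set(self.alphabets)) == 1

    @property
    def uniform_alphabet_size(self) -> int:
        if not self.is_uniform:
            raise ValidationError("space does not have a uniform alphabet")
        return len(self.alphabets[0])

    def site_index(self, label: str | int) -> int:
        """Map a user-facing site label (or 0-based int) to the 0-based index."""
        if isinstance(label, (int, np.integer)):
            p = int(label)
            if not 0 <= p < self.length:
                raise ValidationError(f"site index {p} out of range 0..{self.length - 1}")
            return p
        try:
            return self.site_labels.index(str(label))
        except ValueError:
            raise ValidationError(
                f"unknown site label {label!r}; known labels: {list(self.site_labels)}"
            ) from None

    # ------------------------------------------------------------------
    # sequence handling
    # ------------------------------------------------------------------
    def validate_sequence(self, seq: str, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        if len(seq) != self.length:
            raise FormatError(
                f"sequence {seq!r}{where} has length {len(seq)}, expected {self.length}"
            )
        for p, s in enumerate(seq):
            if s not in self._index[p]:
                raise ValidationError(
                    f"sequence {seq!r}{where}: symbol {s!r} at site "
                    f"{self.site_labels[p]} is not in alphabet {''.join(self.alphabets[p])!r}"
                )

    def encode(self, sequences: Sequence[str]) -> np.ndarray:
        """Encode sequences into an ``(n, l)`` int array of allele indices."""
        out = np.empty((len(sequences), self.length), dtype=np.int64)
        for i, seq in enumerate(sequences):
            self.validate_sequence(seq, row=i)
            for p, s in enumerate(seq):
                out[i, p] = self._index[p][s]
        return out

    def decode(self, encoded: np.ndarray) -> list[str]:
        encoded = np.asarray(encoded)
        return [
            "".join(self.alphabets[p][int(idx[p])] for p in range(self.length))
            for idx in encoded
        ]

    def enumerate_sequences(self, cap: int = DEFAULT_ENUMERATION_CAP) -> list[str]:
        """All genotypes in lexicographic order over the declared alphabets.

        Refuses (with the exact size in the message) if the space exceeds
        ``cap`` genotypes.
        """
        n = self.size
        if n > cap:
            raise ValidationError(
                f"space has {n} genotypes, above the enumeration cap of {cap}"
            )
        return ["".join(t) for t in itertools.product(*self.alphabets)]

    def mutate(self, seq: str, site: str | int, allele: str) -> str:
        """Return ``seq`` with ``allele`` substituted at ``site`` (label or index)."""
        p = self.site_index(site)
        if allele not in self._index[p]:
            raise ValidationError(
                f"allele {allele!r} not in alphabet of site {self.site_labels[p]}"
            )
        return seq[:p] + allele + seq[p + 1 :]


def hamming_distance(x: str, x2: str) -> int:
    """Number of sites at which two equal-length sequences differ."""
    if len(x) != len(x2):
        raise ValidationError(
            f"length mismatch: {len(x)} vs {len(x2)} for {x!r} / {x2!r}"
        )
    return sum(a != b for a, b in zip(x, x2))


def hamming_distance_matrix(X: np.ndarray, X2: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Hamming distances between rows of encoded sequence arrays."""
    if X2 is None:
        X2 = X
    return (X[:, None, :] != X2[None, :, :]).sum(axis=2)


# ----------------------------------------------------------------------
# genotype tables
# ----------------------------------------------------------------------
@dataclass
class GenotypeTable:
    """Aligned sequences with phenotypes and optional measurement variances."""

    space: SequenceSpace
    sequences: list[str]
    y: np.ndarray
    y_var: np.ndarray | None = None

    def __post_init__(self):
        self.sequences = list(self.sequences)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1 or len(self.y) != len(self.sequences):
            raise ValidationError("y must be 1-D and aligned with sequences")
        for i, seq in enumerate(self.sequences):
            self.space.validate_sequence(seq, row=i)
        if self.y_var is not None:
            self.y_var = np.asarray(self.y_var, dtype=float)
            if self.y_var.shape != self.y.shape:
                raise ValidationError("y_var must align 1:1 with sequences")
            bad = np.flatnonzero(self.y_var < 0)
            if bad.size:
                raise ValidationError(
                    f"negative measurement variance at row(s) {bad.tolist()}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        return self.space.encode(self.sequences)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sequence": self.sequences, "y": self.y})
        if self.y_var is not None:
            df["y_var"] = self.y_var
        return df

    def subset(self, idx: np.ndarray | Sequence[int]) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            space=self.space,
            sequences=[self.sequences[i] for i in idx],
            y=self.y[idx],
            y_var=None if self.y_var is None else self.y_var[idx],
        )


def parse_genotype_table(
    path: str | Path,
    space: SequenceSpace | str = "infer",
    uppercase: bool = True,
    sep: str | None = None,
) -> GenotypeTable:
    """Read a delimited genotype table (columns ``sequence``, ``y``, optional ``y_var``).

    The delimiter is sniffed from the extension (``.csv`` vs anything else →
    tab) unless ``sep`` is given.  With ``space="infer"`` the per-site
    alphabets are the union of observed symbols.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    # sequence column must stay textual ("0000" is a genotype, not a number)
    df = pd.read_csv(path, sep=sep, dtype={"sequence": str})
    required = {"sequence", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected header columns {sorted(required)}, got {list(df.columns)}"
        )
    sequences = [str(s) for s in df["sequence"]]
    if uppercase:
        sequences = [s.upper() for s in sequences]
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise FormatError(f"{path}: ragged sequence lengths {sorted(lengths)}")
    if isinstance(space, str):
        if space != "infer":
            raise ValidationError(f"unknown space directive {space!r}")
        space = SequenceSpace.from_sequences(sequences)
    y_var = df["y_var"].to_numpy(float) if "y_var" in df.columns else None
    return GenotypeTable(space=space, sequences=sequences, y=df["y"].to_numpy(float), y_var=y_var)


def write_genotype_table(table: GenotypeTable, path: str | Path, sep: str | None = None) -> None:
    """Write a genotype table; inverse of :func:`parse_genotype_table`."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.to_frame().to_csv(path, sep=sep, index=False)
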