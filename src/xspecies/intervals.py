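"""Genomic interval and sequence primitives shared by every pipeline stage.

Coordinates are 0-based half-open (BED convention) throughout.  Model input
windows are peak summit +/- ``flank`` under the half-open convention, i.e.
``[summit - flank, summit + flank)`` — exactly ``2 * flank`` bases, so the
default flank of 250 gives the 500 bp windows the models consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ValidationError(ValueError):
    """Raised when an interval/peak violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a chromosome of one species."""

    species: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share at least one base (bedtools default).

    Intervals on different species or chromosomes never overlap.
    """
    if a.species != b.species or a.chrom != b.chrom:
        return False
    return a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Peak:
    """A called peak with its summit (absolute coordinate), tissue-tagged."""

    interval: GenomicInterval
    summit: int
    tissue: str = ""
    dataset_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValidationError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def species(self) -> str:
        return self.interval.species

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-length sequence window ready for one-hot encoding."""

    species: str
    interval: GenomicInterval
    strand: str
    seq: str
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")
        if len(self.seq) != self.interval.length:
            raise ValidationError(
                f"sequence length {len(self.seq)} != interval length "
                f"{self.interval.length}"
            )

    def reverse_complement(self) -> "SequenceWindow":
        return SequenceWindow(
            species=self.species,
            interval=self.interval,
            strand="-" if self.strand == "+" else "+",
            seq=reverse_complement(self.seq),
            region_id=self.region_id,
        )


def reverse_complement(seq: str) -> str:
    """Standard DNA reverse complement; N maps to N. Involution."""
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot(seq: str, mask_lowercase: bool = False) -> np.ndarray:
    """One-hot encode a DNA sequence into an ``(L, 4)`` float32 matrix.

    Column order is (A, C, G, T); N encodes as an all-zero row.  Encoding is
    case-insensitive unless ``mask_lowercase`` is set, in which case
    soft-masked (lowercase) bases are also zeroed.

    Raises ``ValueError`` on characters outside {A, C, G, T, N}.
    """
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq):
        if mask_lowercase and ch.islower():
            if ch.upper() not in "ACGTN":
                raise ValueError(f"invalid base {ch!r} at position {i}")
            continue
        c = ch.upper()
        if c == "N":
            continue
        try:
            out[i, _BASE_INDEX[c]] = 1.0
        except KeyError:
            raise ValueError(f"invalid base {ch!r} at position {i}") from None
    return out


def one_hot_batch(seqs: Sequence[str], mask_lowercase: bool = False) -> np.ndarray:
    """Stack one-hot encodings of equal-length sequences into ``(N, L, 4)``."""
    return np.stack([one_hot(s, mask_lowercase) for s in seqs])


def reverse_complement_one_hot(x: np.ndarray) -> np.ndarray:
    """Reverse complement in one-hot space: reverse positions and columns.

    With column order (A, C, G, T), complementation is exactly a column
    reversal, so rc = ``x[::-1, ::-1]`` (batched over leading axes).
    """
    return x[..., ::-1, ::-1]


def summit_window(
    peak: Peak, flank: int = 250, chrom_size: Optional[int] = None
) -> tuple[Optional[GenomicInterval], bool]:
    """Window ``[summit - flank, summit + flank)`` around a peak summit.

    Returns ``(interval, in_bounds)``.  When the window would extend past the
    chromosome start (or past ``chrom_size`` if given) the interval is not
    fabricated: ``(None, False)`` is returned and the caller drops the peak.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    start = peak.summit - flank
    end = peak.summit + flank
    if start < 0 or (chrom_size is not None and end > chrom_size):
        return None, False
    return GenomicInterval(peak.species, peak.chrom, start, end), True


def chromosome_split(
    peaks: Iterable[Peak],
    split_spec: Mapping[str, str],
    reference_chrom: Optional[Mapping[str, str]] = None,
) -> dict[str, list[Peak]]:
    """Partition peaks into train/validation/test by chromosome.

    ``split_spec`` maps each chromosome (of the reference species) to a
    partition name.  Non-reference-species peaks are assigned by the
    chromosome of their reference-species ortholog, supplied via
    ``reference_chrom`` (peak.name -> reference chromosome); the partition of
    a region follows its reference ortholog, so e.g. a macaque peak whose
    reference ortholog lies on a test chromosome lands in the test partition.

    A peak whose (mapped) chromosome is absent from ``split_spec`` raises.
    """
    parts: dict[str, list[Peak]] = {}
    for p in peaks:
        chrom = p.chrom
        if reference_chrom is not None and p.name in reference_chrom:
            chrom = reference_chrom[p.name]
        if chrom not in split_spec:
            raise KeyError(
                f"chromosome {chrom!r} (peak {p.name or p.interval}) missing "
                "from split_spec"
            )
        parts.setdefault(split_spec[chrom], []).append(p)
    return parts


@dataclass
class UnionPeaks:
    """Queryable union of interval sets: membership by >=1 bp overlap.

    Backs the "union pooled peaks" concept: the union of peaks called from
    replicate-pooled reads across all datasets of one species/tissue.  No
    coordinate merging is performed; only overlap queries are supported.
    """

    species: str = ""
    tissue: str = ""
    _trees: dict = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], species: str = "", tissue: str = ""
    ) -> "UnionPeaks":
        from intervaltree import IntervalTree

        obj = cls(species=species, tissue=tissue)
        for iv in intervals:
            obj._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        return obj

    @classmethod
    def from_peaks(
        cls, peak_sets: Iterable[Iterable[Peak]], species: str = "", tissue: str = ""
    ) -> "UnionPeaks":
        ivs = [p.interval for peaks in peak_sets for p in peaks]
        return cls.from_intervals(ivs, species=species, tissue=tissue)

    def overlaps(self, interval: GenomicInterval) -> bool:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return False
        return bool(tree.overlap(interval.start, interval.end))

    def overlaps_span(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(start, end))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())
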