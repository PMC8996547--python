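"""Positive-set filtering and the six negative-set construction strategies.

The novel negative class is the "non-OCR ortholog of an OCR": a region closed
in species A whose ortholog in species B is open in the same tissue.  The
other strategies (flanking regions, other-tissue OCRs, G/C- and
repeat-matched regions at two ratios, dinucleotide-shuffled positives) are
the standard alternatives it is compared against.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import (
    GenomicInterval,
    Peak,
    SequenceWindow,
    UnionPeaks,
    chromosome_split,
    summit_window,
)
from .io import OrthologMap

logger = logging.getLogger(__name__)


def filter_candidate_ocrs(
    peaks: Sequence[Peak],
    exons: Sequence[GenomicInterval],
    tss: Sequence[int] | Sequence[GenomicInterval],
    max_len: int = 1000,
    min_tss_dist: int = 20000,
) -> list[Peak]:
    """Keep non-exonic peaks, >= ``min_tss_dist`` from every TSS, <= ``max_len`` long.

    TSS may be given as point positions (with all peaks on one chromosome) or
    as 1-bp-anchored intervals; distance is measured from the nearest TSS to
    the closest edge of the peak interval.
    """
    exon_union = UnionPeaks.from_intervals(exons)
    tss_by_chrom: dict[str, list[int]] = defaultdict(list)
    for t in tss:
        if isinstance(t, GenomicInterval):
            tss_by_chrom[t.chrom].append(t.start)
        else:
            raise TypeError("tss must be GenomicIntervals (1 bp anchored at start)")
    for positions in tss_by_chrom.values():
        positions.sort()

    kept = []
    for p in peaks:
        if p.interval.length > max_len:
            continue
        if exon_union.overlaps(p.interval):
            continue
        positions = tss_by_chrom.get(p.chrom, [])
        if positions and _min_dist_to_points(p.interval, positions) < min_tss_dist:
            continue
        kept.append(p)
    return kept


def _min_dist_to_points(interval: GenomicInterval, sorted_points: list[int]) -> int:
    arr = np.asarray(sorted_points)
    i = np.searchsorted(arr, interval.start)
    best = None
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(arr):
            pos = arr[j]
            if interval.start <= pos < interval.end:
                return 0
            d = min(abs(pos - interval.start), abs(pos - (interval.end - 1)))
            best = d if best is None else min(best, d)
    return best if best is not None else 10**12


def union_pooled_peaks(
    peak_sets: Iterable[Iterable[Peak]], species: str = "", tissue: str = ""
) -> UnionPeaks:
    """Union of pooled-replicate peak sets, queryable by overlap."""
    return UnionPeaks.from_peaks(peak_sets, species=species, tissue=tissue)


def loose_ocrs(
    base_peaks: Sequence[Peak],
    other_pooled_peak_sets: Sequence[UnionPeaks],
    exons: Sequence[GenomicInterval],
    tss: Sequence[GenomicInterval],
    max_len: int = 1000,
    min_tss_dist: int = 20000,
    allow_single_dataset: bool = False,
) -> list[Peak]:
    """Relaxed OCR set used to source negatives.

    Base peaks passing the candidate-OCR filters that additionally intersect
    at least one peak from the pooled reads of *every* other dataset for the
    same species/tissue.  The loose OCR's summit is the base peak's summit.

    With a single dataset there are no "other datasets"; by default this is
    an error, with ``allow_single_dataset`` the criterion is vacuous and the
    base filters alone apply.
    """
    if not other_pooled_peak_sets and not allow_single_dataset:
        raise ValueError(
            "loose_ocrs requires >=1 other dataset (or allow_single_dataset=True)"
        )
    candidates = filter_candidate_ocrs(base_peaks, exons, tss, max_len, min_tss_dist)
    out = []
    for p in candidates:
        if all(up.overlaps(p.interval) for up in other_pooled_peak_sets):
            out.append(p)
    return out


def non_ocr_orthologs_of_ocrs(
    source_loose_ocrs: Sequence[Peak],
    ortholog_map: OrthologMap,
    target_species: str,
    target_union_peaks: UnionPeaks,
) -> list[Peak]:
    """Orthologs (in ``target_species``) of loose OCRs that land in closed chromatin.

    The returned peaks carry the mapped interval and mapped base-peak summit;
    orthologs overlapping any target union pooled peak are excluded, and
    orthologs without a mapped summit are skipped (counted in the log).
    """
    out = []
    n_no_summit = 0
    for p in source_loose_ocrs:
        rec = ortholog_map.get(p.species, p.name, target_species)
        if rec is None:
            continue
        if rec.summit is None:
            n_no_summit += 1
            continue
        if target_union_peaks.overlaps(rec.interval):
            continue
        out.append(
            Peak(
                interval=rec.interval,
                summit=rec.summit,
                tissue=p.tissue,
                dataset_id=f"nonocr_orth_of_{p.species}",
                name=f"{p.name}|{target_species}",
            )
        )
    if n_no_summit:
        logger.info(
            "non_ocr_orthologs_of_ocrs: skipped %d orthologs without mapped summit",
            n_no_summit,
        )
    return out


# ---------------------------------------------------------------------------
# dinucleotide shuffle (Altschul-Erickson Eulerian-path shuffle)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(
    seq: str, n_copies: int = 10, seed: int | np.random.Generator = 0
) -> list[str]:
    """Shuffles preserving the exact dinucleotide multiset of the input.

    Altschul-Erickson: pick a random last-exit edge per vertex forming an
    arborescence into the final character, shuffle the remaining edge orders
    and walk the Euler path.  Each output has identical dinucleotide counts
    (and hence mononucleotide counts and first/last base) to the input.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [_euler_shuffle(seq, rng) for _ in range(n_copies)]


def _euler_shuffle(seq: str, rng: np.random.Generator) -> str:
    adj: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        adj[a].append(b)
    last = seq[-1]
    vertices = list(adj)
    internal = [v for v in vertices if v != last]
    # choose random last-exit edges until they form an arborescence into `last`
    while True:
        last_edges = {v: adj[v][int(rng.integers(len(adj[v])))] for v in internal}
        ok = True
        for v in internal:
            seen = set()
            u = v
            while u != last and u in last_edges and u not in seen:
                seen.add(u)
                u = last_edges[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    walk_adj: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(adj[v])
        if v != last:
            edges.remove(last_edges[v])
        idx = rng.permutation(len(edges))
        edges = [edges[i] for i in idx]
        if v != last:
            edges.append(last_edges[v])
        walk_adj[v] = edges
    ptr = {v: 0 for v in vertices}
    out = [seq[0]]
    u = seq[0]
    while True:
        edges = walk_adj.get(u)
        if edges is None or ptr[u] >= len(edges):
            break
        w = edges[ptr[u]]
        ptr[u] += 1
        out.append(w)
        u = w
    return "".join(out)


def dinucleotide_counts(seq: str) -> np.ndarray:
    """16-bin dinucleotide count vector (AA, AC, ... TT); N pairs ignored."""
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros(16, dtype=int)
    s = seq.upper()
    for a, b in zip(s, s[1:]):
        if a in idx and b in idx:
            counts[idx[a] * 4 + idx[b]] += 1
    return counts


# ---------------------------------------------------------------------------
# G/C- and repeat-matched negatives
# ---------------------------------------------------------------------------

def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


def repeat_fraction(seq: str) -> float:
    """Soft-masked (lowercase) base fraction, the usual repeat proxy."""
    if not seq:
        return 0.0
    return sum(1 for c in seq if c.islower()) / len(seq)


def _gc_repeat_bin(seq: str, n_gc_bins: int, n_rep_bins: int) -> tuple[int, int]:
    g = min(int(gc_fraction(seq) * n_gc_bins), n_gc_bins - 1)
    r = min(int(repeat_fraction(seq) * n_rep_bins), n_rep_bins - 1)
    return g, r


def gc_repeat_matched_negatives(
    positive_seqs: Sequence[str],
    candidate_pool: Sequence[tuple[Peak, str]],
    ratio: float,
    seed: int = 0,
    n_gc_bins: int = 10,
    n_rep_bins: int = 4,
) -> list[Peak]:
    """Sample ~``ratio`` x len(positives) pool regions matching each positive's
    joint (G/C fraction, repeat fraction) bin.

    Bins are fixed-width: G/C deciles x repeat-fraction quartiles.  Sampling
    is without replacement and deterministic under ``seed``; an exhausted bin
    falls back to the nearest nonempty bin (Manhattan distance, logged).
    """
    if not candidate_pool:
        raise ValueError("empty candidate pool")
    rng = np.random.default_rng(seed)
    pool_bins: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, (_, seq) in enumerate(candidate_pool):
        pool_bins[_gc_repeat_bin(seq, n_gc_bins, n_rep_bins)].append(i)
    for b in pool_bins.values():
        rng.shuffle(b)

    per_positive = int(round(ratio))
    chosen: list[int] = []
    n_fallback = 0
    for seq in positive_seqs:
        b = _gc_repeat_bin(seq, n_gc_bins, n_rep_bins)
        for _ in range(per_positive):
            src = b
            if not pool_bins.get(src):
                src = _nearest_nonempty_bin(b, pool_bins)
                if src is None:
                    break
                n_fallback += 1
            chosen.append(pool_bins[src].pop())
    if n_fallback:
        logger.info("gc_repeat_matched_negatives: %d fallback draws", n_fallback)
    return [candidate_pool[i][0] for i in chosen]


def _nearest_nonempty_bin(b, pool_bins):
    best, best_d = None, None
    for key, items in pool_bins.items():
        if not items:
            continue
        d = abs(key[0] - b[0]) + abs(key[1] - b[1])
        if best_d is None or d < best_d or (d == best_d and key < best):
            best, best_d = key, d
    return best


def flanking_negatives(
    positives: Sequence[Peak],
    offset: int,
    tissue_union_peaks: UnionPeaks,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    flank: int = 250,
) -> list[Peak]:
    """Windows at summit +/- ``offset`` (both sides) clear of tissue peaks.

    Out-of-bounds flanks and flanks overlapping the tissue's union pooled
    peaks are dropped; each positive therefore yields 0, 1 or 2 negatives.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    out = []
    for p in positives:
        for sign, tag in ((-1, "L"), (+1, "R")):
            center = p.summit + sign * offset
            size = None if chrom_sizes is None else chrom_sizes.get(p.chrom)
            start, end = center - flank, center + flank
            if start < 0 or (size is not None and end > size):
                continue
            iv = GenomicInterval(p.species, p.chrom, start, end)
            if tissue_union_peaks.overlaps(iv):
                continue
            out.append(
                Peak(interval=iv, summit=center, tissue=p.tissue,
                     dataset_id="flanking", name=f"{p.name}|flank{tag}")
            )
    return out


def other_tissue_negatives(
    evaluation_tissue_ocrs: Sequence[Peak], training_tissue_union_peaks: UnionPeaks
) -> list[Peak]:
    """Evaluation-tissue OCRs with no overlap with the training tissue's peaks."""
    return [
        p for p in evaluation_tissue_ocrs
        if not training_tissue_union_peaks.overlaps(p.interval)
    ]


# ---------------------------------------------------------------------------
# Training-set assembly
# ---------------------------------------------------------------------------

ORIGINS = (
    "positive",
    "flanking",
    "other_tissue",
    "gc_repeat_matched_large",
    "gc_repeat_matched_small",
    "dinuc_shuffled",
    "non_ocr_ortholog",
)


@dataclass(frozen=True)
class LabeledExample:
    window: SequenceWindow
    label: int
    weight: float
    origin: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class TrainingSet:
    """Per-partition labeled examples plus class weights.

    Each class's weight is the fraction of examples in the *other* class:
    ``class_weight[1] = n_neg / (n_pos + n_neg)`` and symmetrically for 0,
    computed from the training partition.  Counts are distinct regions
    (before reverse-complement augmentation); with ``augment_rc`` each region
    contributes both strands, sharing label and weight.
    """

    examples: dict[str, list[LabeledExample]] = field(default_factory=dict)
    class_weight: dict[int, float] = field(default_factory=dict)
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @staticmethod
    def compute_class_weights(n_pos: int, n_neg: int) -> dict[int, float]:
        total = n_pos + n_neg
        if total == 0:
            raise ValueError("empty training set")
        return {1: n_neg / total, 0: n_pos / total}


def assemble_training_set(
    positives_by_species: Mapping[str, Sequence[tuple[SequenceWindow, str]]],
    negatives_by_species: Mapping[str, Sequence[tuple[SequenceWindow, str]]],
    split_spec: Mapping[str, str],
    reference_chrom: Optional[Mapping[str, str]] = None,
    augment_rc: bool = True,
) -> TrainingSet:
    """Assemble a chromosome-split training set from per-species windows.

    Inputs are (window, origin) pairs.  Partition assignment uses the
    window's chromosome for the reference species and the reference
    ortholog's chromosome (``reference_chrom``: region_id -> chrom) for other
    species.  Class weights follow the training-partition class balance.
    """
    parts: dict[str, list[LabeledExample]] = defaultdict(list)
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])

    def partition_of(win: SequenceWindow) -> str:
        chrom = win.interval.chrom
        if reference_chrom is not None and win.region_id in reference_chrom:
            chrom = reference_chrom[win.region_id]
        if chrom not in split_spec:
            raise KeyError(f"chromosome {chrom!r} missing from split_spec")
        return split_spec[chrom]

    staged: dict[str, list[tuple[SequenceWindow, int, str]]] = defaultdict(list)
    for label, by_species in ((1, positives_by_species), (0, negatives_by_species)):
        for species, items in by_species.items():
            if label == 1 and not negatives_by_species.get(species):
                logger.warning("species %s has positives but no negatives", species)
            for win, origin in items:
                part = partition_of(win)
                staged[part].append((win, label, origin))
                counts[part][label] += 1

    n_pos, n_neg = counts.get("train", [0, 0])[1], counts.get("train", [0, 0])[0]
    weights = TrainingSet.compute_class_weights(n_pos, n_neg)
    for part, items in staged.items():
        for win, label, origin in items:
            w = weights[label]
            parts[part].append(LabeledExample(win, label, w, origin))
            if augment_rc:
                parts[part].append(LabeledExample(win.reverse_complement(), label, w, origin))

    return TrainingSet(
        examples=dict(parts),
        class_weight=weights,
        counts={p: (c[1], c[0]) for p, c in counts.items()},
    )
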