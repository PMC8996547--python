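"""Evaluation-set constructors and metrics for lineage-, clade-, species- and
tissue-specific open-chromatin accuracy, plus conservation-score comparisons.

Overall test-set performance is dominated by regions that are open or closed
everywhere; these constructors isolate the regions whose status *differs*
between lineages or tissues, which is where a conservation predictor earns
its keep.  When an evaluation set has more positives than negatives the
precision-recall curve of the negative class (the NPV-specificity curve) is
the informative summary, reported as ``npv_spec_auc``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import Peak, UnionPeaks
from .io import OrthologMap
from .datasets import non_ocr_orthologs_of_ocrs


@dataclass
class EvaluationSet:
    """Named positive/negative region sets with a base (sequence) species."""

    name: str
    positives: list[Peak] = field(default_factory=list)
    negatives: list[Peak] = field(default_factory=list)
    base_species: str = ""

    def __post_init__(self) -> None:
        pos = {(p.species, p.chrom, p.interval.start, p.interval.end) for p in self.positives}
        neg = {(p.species, p.chrom, p.interval.start, p.interval.end) for p in self.negatives}
        if pos & neg:
            raise ValueError(f"{self.name}: positives and negatives overlap")


def lineage_diff_set(
    source_species: str,
    source_ocrs: Sequence[Peak],
    source_union_peaks: UnionPeaks,
    target_species: str,
    target_ocrs: Sequence[Peak],
    target_union_peaks: UnionPeaks,
    ortholog_map: OrthologMap,
    name: str = "",
) -> EvaluationSet:
    """OCR orthologs whose open chromatin status differs between two species.

    Positives: source OCRs whose target ortholog overlaps no target union
    pooled peak (open in source, closed in target).  Negatives: source
    non-OCR orthologs of target OCRs (closed in source, open in target).
    Sequences are taken from the source species; windows are emitted on both
    strands downstream.
    """
    positives = []
    for p in source_ocrs:
        rec = ortholog_map.get(source_species, p.name, target_species)
        if rec is None:
            continue
        if not target_union_peaks.overlaps(rec.interval):
            positives.append(p)
    negatives = non_ocr_orthologs_of_ocrs(
        target_ocrs, ortholog_map, source_species, source_union_peaks
    )
    return EvaluationSet(
        name=name or f"{source_species}!={target_species}",
        positives=positives,
        negatives=negatives,
        base_species=source_species,
    )


def clade_specific_sets(
    ocrs_by_species: Mapping[str, Sequence[Peak]],
    dataset_pooled_peaks: Mapping[str, Sequence[UnionPeaks]],
    union_peaks: Mapping[str, UnionPeaks],
    clades: Mapping[str, Sequence[str]],
    base_species_by_clade: Mapping[str, str],
    ortholog_map: OrthologMap,
) -> dict[str, EvaluationSet]:
    """Clade-specific OCRs (positives) and clade-specific non-OCRs (negatives).

    Clade-active: a base-species OCR whose ortholog in every *other* species
    of the clade overlaps a pooled-reads peak from all of that species'
    datasets (a reproducible peak is not required in the non-base species).
    Clade-specific: clade-active with orthologs in all other-clade species
    overlapping no union pooled peaks.  Negatives for a clade are base-species
    orthologs of the other clades' clade-active OCRs whose within-clade
    orthologs overlap no union pooled peaks.  Sequences from the base species.
    """
    if len(clades) < 2:
        raise ValueError("need >= 2 clades")
    for clade in clades:
        if clade not in base_species_by_clade:
            raise ValueError(f"clade {clade!r} has no base species")

    def clade_active(clade: str) -> list[Peak]:
        base = base_species_by_clade[clade]
        others = [s for s in clades[clade] if s != base]
        out = []
        for p in ocrs_by_species.get(base, []):
            ok = True
            for sp in others:
                rec = ortholog_map.get(base, p.name, sp)
                if rec is None or not all(
                    dp.overlaps(rec.interval) for dp in dataset_pooled_peaks[sp]
                ):
                    ok = False
                    break
            if ok:
                out.append(p)
        return out

    def closed_in_all(peak: Peak, source_species: str, species_list) -> bool:
        """True iff orthologs exist in every listed species and none is open."""
        for sp in species_list:
            rec = ortholog_map.get(source_species, peak.name, sp)
            if rec is None:
                return False
            if union_peaks[sp].overlaps(rec.interval):
                return False
        return True

    active = {clade: clade_active(clade) for clade in clades}
    out: dict[str, EvaluationSet] = {}
    for clade in clades:
        base = base_species_by_clade[clade]
        other_clades = [c for c in clades if c != clade]
        other_species = [s for c in other_clades for s in clades[c]]
        positives = [
            p for p in active[clade] if closed_in_all(p, base, other_species)
        ]
        negatives = []
        for oc in other_clades:
            obase = base_species_by_clade[oc]
            for p in active[oc]:
                rec = ortholog_map.get(obase, p.name, base)
                if rec is None or rec.summit is None:
                    continue
                if closed_in_all(p, obase, clades[clade]):
                    negatives.append(
                        Peak(interval=rec.interval, summit=rec.summit, tissue=p.tissue,
                             dataset_id=f"cladespec_nonocr_{oc}", name=f"{p.name}|{base}")
                    )
        out[clade] = EvaluationSet(
            name=f"{clade}_specific", positives=positives, negatives=negatives,
            base_species=base,
        )
    return out


def closest_species(tree, species: str, candidates: Sequence[str]) -> str:
    """Unique closest relative by patristic distance; a tie is an error."""
    import dendropy

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    dists = sorted(
        (pdm.patristic_distance(taxa[species], taxa[c]), c)
        for c in candidates
        if c != species
    )
    if not dists:
        raise ValueError(f"no candidate relatives for {species}")
    if len(dists) > 1 and math.isclose(dists[0][0], dists[1][0]):
        raise ValueError(
            f"tie in closest species for {species}: {dists[0][1]} vs {dists[1][1]}; "
            "specify the neighbor explicitly"
        )
    return dists[0][1]


def species_specific_sets(
    ocrs_by_species: Mapping[str, Sequence[Peak]],
    union_peaks: Mapping[str, UnionPeaks],
    tree,
    ortholog_map: OrthologMap,
    neighbors: Optional[Mapping[str, str]] = None,
) -> dict[str, EvaluationSet]:
    """Per-species OCRs open in that species but closed in its single closest
    assayed relative (positives), and the mirror-image non-OCRs (negatives)."""
    species_list = list(ocrs_by_species)
    neighbors = neighbors or {}
    out = {}
    for sp in species_list:
        nb = neighbors.get(sp) or closest_species(tree, sp, species_list)
        positives = []
        for p in ocrs_by_species[sp]:
            rec = ortholog_map.get(sp, p.name, nb)
            if rec is None:
                continue
            if not union_peaks[nb].overlaps(rec.interval):
                positives.append(p)
        negatives = non_ocr_orthologs_of_ocrs(
            ocrs_by_species[nb], ortholog_map, sp, union_peaks[sp]
        )
        out[sp] = EvaluationSet(
            name=f"{sp}_specific", positives=positives, negatives=negatives,
            base_species=sp,
        )
    return out


def tissue_specific_sets(
    training_tissue_ocrs: Sequence[Peak],
    eval_tissue_ocrs: Sequence[Peak],
    eval_union_peaks: UnionPeaks,
    train_union_peaks: UnionPeaks,
    name: str = "",
) -> EvaluationSet:
    """Shared-vs-exclusive tissue evaluation within one species.

    Positives: training-tissue OCRs overlapping at least one evaluation-
    tissue OCR (the evaluation tissue may include peaks longer than 1 kb).
    Negatives: evaluation-tissue OCRs overlapping no training-tissue union
    pooled peak.  Positive windows center on the training-tissue summit,
    negative windows on the evaluation-tissue summit.
    """
    eval_ocr_union = UnionPeaks.from_peaks([eval_tissue_ocrs])
    positives = [p for p in training_tissue_ocrs if eval_ocr_union.overlaps(p.interval)]
    negatives = [
        p for p in eval_tissue_ocrs if not train_union_peaks.overlaps(p.interval)
    ]
    return EvaluationSet(
        name=name or "tissue_shared_vs_exclusive",
        positives=positives,
        negatives=negatives,
        base_species=positives[0].species if positives else
        (negatives[0].species if negatives else ""),
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    auroc: float
    auprc: float
    npv_spec_auc: float
    recall_at_p80: float
    n_pos: int
    n_neg: int


def metric_report(scores: Sequence[float], labels: Sequence[int]) -> MetricReport:
    """AUROC, AUPRC, NPV-specificity AUC and recall@80% precision.

    ``npv_spec_auc`` is the AUPRC of the class-swapped problem,
    ``auprc(1 - scores, 1 - labels)`` — exactly the area under the NPV vs
    specificity curve.  PR areas use the step-wise (average-precision)
    convention with ties grouped by score.  Metrics undefined for
    single-class input are reported as NaN.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score
    from .cnn import recall_at_precision

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        nan = math.nan
        rp = math.nan if n_pos == 0 else recall_at_precision(s, y)
        return MetricReport(nan, nan, nan, rp, n_pos, n_neg)
    return MetricReport(
        auroc=float(roc_auc_score(y, s)),
        auprc=float(average_precision_score(y, s)),
        npv_spec_auc=float(average_precision_score(1 - y, 1.0 - s)),
        recall_at_p80=recall_at_precision(s, y),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def mean_conservation(track, peak: Peak, flank: int = 250) -> float:
    """Mean conservation score over the summit +/- ``flank`` window.

    Averages covered bases only; NaN when the window is entirely uncovered.
    """
    mean, _coverage = track.window_mean(peak.chrom, peak.summit - flank, peak.summit + flank)
    return mean


def compare_groups_ranksum(
    values_a: Sequence[float],
    values_b: Sequence[float],
    bonferroni_factor: int = 1,
) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum with Bonferroni-multiplied p, capped at 1.

    Uses the exact Mann-Whitney null distribution for small tie-free samples
    (n_a + n_b <= 50) and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (not has_ties and len(a) + len(b) <= 50) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    raw_p = float(res.pvalue)
    return float(res.statistic), raw_p, min(1.0, raw_p * bonferroni_factor)


def rank_comparison_signrank(
    predictions: Sequence[float],
    cons_scores: Sequence[float],
    conserved_flags: Sequence[bool],
) -> tuple[float, float]:
    """Compare how predictions vs a conservation score rank the same OCRs.

    Both scores rank the pooled (conserved + non-conserved) OCR set; a
    Wilcoxon sign-rank test on the paired per-OCR rank differences is run
    restricted to the conserved OCRs and separately to the non-conserved
    ones.  Fewer than 2 pairs in a stratum gives NaN; identical rankings give
    p = 1.
    """
    pred = np.asarray(predictions, dtype=float)
    cons = np.asarray(cons_scores, dtype=float)
    flags = np.asarray(conserved_flags, dtype=bool)
    r_pred = stats.rankdata(pred)
    r_cons = stats.rankdata(cons)
    out = []
    for mask in (flags, ~flags):
        if mask.sum() < 2:
            out.append(math.nan)
            continue
        diffs = r_pred[mask] - r_cons[mask]
        if np.allclose(diffs, 0):
            out.append(1.0)
            continue
        res = stats.wilcoxon(diffs, alternative="two-sided")
        out.append(float(res.pvalue))
    return out[0], out[1]
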