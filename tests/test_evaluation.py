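"""Evaluation-set constructors against brute-force enumeration; metrics
against exhaustive threshold sweeps; conservation comparisons."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from xspecies.evaluation import (
    EvaluationSet,
    clade_specific_sets,
    closest_species,
    compare_groups_ranksum,
    lineage_diff_set,
    mean_conservation,
    metric_report,
    rank_comparison_signrank,
    species_specific_sets,
    tissue_specific_sets,
)
from xspecies.intervals import GenomicInterval, Peak, UnionPeaks
from xspecies.io import ConservationTrack, OrthRecord, OrthologMap

from conftest import make_peak


def _peak(species, name, start, tissue="brain"):
    return make_peak(species=species, name=name, start=start, end=start + 500,
                     summit=start + 250, tissue=tissue)


def _map_pairs(pairs):
    """pairs: (src_species, src_id, tgt_species, tgt_start)"""
    omap = OrthologMap()
    for src_sp, src_id, tgt_sp, start in pairs:
        omap.add(src_sp, src_id, tgt_sp,
                 OrthRecord(GenomicInterval(tgt_sp, "chr1", start, start + 500),
                            start + 250))
    return omap


class TestLineageDiffSet:
    def test_three_peak_fixture_matches_enumeration(self):
        # mouse peaks m1 (open both), m2 (open mouse only), m3 (no ortholog)
        mouse = [_peak("mouse", "m1", 1000), _peak("mouse", "m2", 10_000),
                 _peak("mouse", "m3", 20_000)]
        # macaque OCR q1 whose mouse ortholog (at 50,000) is closed in mouse
        macaque = [_peak("macaque", "q1", 7000)]
        omap = _map_pairs([
            ("mouse", "m1", "macaque", 1000),
            ("mouse", "m2", "macaque", 10_000),
            ("macaque", "q1", "mouse", 50_000),
        ])
        macaque_union = UnionPeaks.from_intervals(
            [GenomicInterval("macaque", "chr1", 900, 1600)]  # covers m1's ortholog
        )
        mouse_union = UnionPeaks.from_peaks([mouse])
        es = lineage_diff_set("mouse", mouse, mouse_union, "macaque", macaque,
                              macaque_union, omap, name="MouseBr!=OtherBr")
        assert [p.name for p in es.positives] == ["m2"]  # open mouse, closed macaque
        assert [p.name for p in es.negatives] == ["q1|mouse"]
        assert es.negatives[0].interval.start == 50_000

    def test_positive_and_negative_sets_disjoint_enforced(self):
        p = _peak("mouse", "x", 100)
        with pytest.raises(ValueError):
            EvaluationSet("bad", positives=[p], negatives=[p])


def _brute_force_clade_specific(labels, clades):
    """labels: {species: {region: bool}} — exhaustive enumeration oracle."""
    out = {}
    for clade, members in clades.items():
        others = [s for c, m in clades.items() if c != clade for s in m]
        regions = set(next(iter(labels.values())))
        out[clade] = {
            r for r in regions
            if all(labels[s][r] for s in members) and not any(labels[s][r] for s in others)
        }
    return out


class TestCladeSpecificSets:
    def _build(self, labels, clades, bases):
        regions = sorted(next(iter(labels.values())))
        starts = {r: 1000 + 10_000 * i for i, r in enumerate(regions)}
        peaks = {
            sp: [_peak(sp, r, starts[r]) for r in regions if labels[sp][r]]
            for sp in labels
        }
        omap = OrthologMap()
        for src in labels:
            for r in regions:
                for tgt in labels:
                    if tgt != src:
                        omap.add(src, r, tgt,
                                 OrthRecord(GenomicInterval(tgt, "chr1", starts[r],
                                                            starts[r] + 500),
                                            starts[r] + 250))
        unions = {sp: UnionPeaks.from_peaks([peaks[sp]]) for sp in labels}
        pooled = {sp: [unions[sp]] for sp in labels}
        return clade_specific_sets(peaks, pooled, unions, clades, bases, omap)

    def test_toy_table_matches_enumeration(self):
        clades = {"A": ["s1", "s2"], "B": ["s3", "s4"]}
        regions = [f"r{i}" for i in range(6)]
        patterns = {
            "r0": (1, 1, 0, 0),  # A-specific
            "r1": (1, 0, 0, 0),  # s1 only: not clade-specific
            "r2": (1, 1, 1, 1),  # open everywhere
            "r3": (0, 0, 1, 1),  # B-specific
            "r4": (0, 0, 0, 0),  # closed everywhere
            "r5": (1, 1, 1, 0),  # open in one B species: excluded
        }
        labels = {s: {r: bool(patterns[r][i]) for r in regions}
                  for i, s in enumerate(["s1", "s2", "s3", "s4"])}
        got = self._build(labels, clades, {"A": "s1", "B": "s3"})
        oracle = _brute_force_clade_specific(labels, clades)
        assert {p.name for p in got["A"].positives} == oracle["A"] == {"r0"}
        assert {p.name for p in got["B"].positives} == oracle["B"] == {"r3"}
        # negatives for A are base-A orthologs of B-specific OCRs
        assert {p.name.split("|")[0] for p in got["A"].negatives} == {"r3"}
        assert {p.name.split("|")[0] for p in got["B"].negatives} == {"r0"}

    def test_missing_base_species_errors(self):
        labels = {"s1": {"r0": True}, "s2": {"r0": True}}
        with pytest.raises(ValueError, match="base species"):
            self._build(labels, {"A": ["s1"], "B": ["s2"]}, {"A": "s1"})


class TestSpeciesSpecificSets:
    def _tree(self, newick):
        import dendropy

        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = True
        return t

    def test_open_in_rat_closed_in_mouse(self):
        tree = self._tree("((rat:10,mouse:10):40,human:50);")
        rat = [_peak("rat", "r1", 1000), _peak("rat", "r2", 10_000)]
        mouse = [_peak("mouse", "r2", 10_000)]
        human = [_peak("human", "r1", 1000)]
        omap = OrthologMap()
        for r, start in (("r1", 1000), ("r2", 10_000)):
            for src, tgt in itertools.permutations(["rat", "mouse", "human"], 2):
                omap.add(src, r, tgt,
                         OrthRecord(GenomicInterval(tgt, "chr1", start, start + 500),
                                    start + 250))
        peaks = {"rat": rat, "mouse": mouse, "human": human}
        unions = {sp: UnionPeaks.from_peaks([peaks[sp]]) for sp in peaks}
        # human is equidistant from rat and mouse: name its neighbor explicitly
        out = species_specific_sets(peaks, unions, tree, omap,
                                    neighbors={"human": "mouse"})
        # r1 open in rat, closed in mouse (closest) -> rat-specific positive
        assert {p.name for p in out["rat"].positives} == {"r1"}
        # r2 open in both rat and mouse -> excluded
        assert all(p.name != "r2" for p in out["rat"].positives)

    def test_equidistant_neighbors_error(self):
        tree = self._tree("((a:10,b:10):10,c:20);")
        with pytest.raises(ValueError, match="tie"):
            closest_species(tree, "c", ["a", "b", "c"])


class TestTissueSpecificSets:
    def test_shared_and_exclusive(self):
        brain = [_peak("mouse", "b1", 1000), _peak("mouse", "b2", 10_000)]
        liver = [_peak("mouse", "l1", 1200, tissue="liver"),
                 _peak("mouse", "l2", 50_000, tissue="liver")]
        es = tissue_specific_sets(
            brain, liver,
            eval_union_peaks=UnionPeaks.from_peaks([liver]),
            train_union_peaks=UnionPeaks.from_peaks([brain]),
            name="MouseBrVsLv",
        )
        assert [p.name for p in es.positives] == ["b1"]   # overlaps liver OCR
        assert [p.name for p in es.negatives] == ["l2"]   # liver-only

    def test_empty_inputs(self):
        es = tissue_specific_sets([], [], UnionPeaks.from_intervals([]),
                                  UnionPeaks.from_intervals([]))
        assert es.positives == [] and es.negatives == []


def _brute_force_pr_metrics(scores, labels):
    """Exhaustive threshold sweep: AUROC via pair counting, AUPRC via
    average precision over distinct thresholds."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    auroc = wins / (len(pos) * len(neg))
    order = np.argsort(-s, kind="mergesort")
    ys, ss = y[order], s[order]
    ap, tp = 0.0, 0
    prev_recall = 0.0
    n_pos = ys.sum()
    i = 0
    while i < len(ys):
        j = i
        while j < len(ys) and ss[j] == ss[i]:
            j += 1
        tp += ys[i:j].sum()
        recall = tp / n_pos
        precision = tp / j
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(auroc), float(ap)


class TestMetricReport:
    def test_perfect_separation_all_ones(self):
        r = metric_report([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (r.auroc, r.auprc, r.npv_spec_auc, r.recall_at_p80) == (1, 1, 1, 1)

    def test_constant_scores_auroc_half(self):
        r = metric_report([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert r.auroc == pytest.approx(0.5)

    def test_eight_point_vector_matches_sweep(self, rng):
        for _ in range(50):
            s = rng.choice([0.1, 0.3, 0.3, 0.6, 0.9], size=8)
            y = rng.integers(0, 2, 8)
            if y.sum() in (0, 8):
                y[0], y[1] = 0, 1
            r = metric_report(s, y)
            auroc, auprc = _brute_force_pr_metrics(s, y)
            assert r.auroc == pytest.approx(auroc)
            assert r.auprc == pytest.approx(auprc)

    def test_npv_spec_is_class_swapped_auprc(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            s = rng.random(n)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            r = metric_report(s, y)
            _, swapped = _brute_force_pr_metrics(1 - s, 1 - y)
            assert r.npv_spec_auc == pytest.approx(swapped)

    def test_single_class_reported_as_nan(self):
        r = metric_report([0.4, 0.6], [1, 1])
        assert math.isnan(r.auroc) and math.isnan(r.auprc)
        assert r.n_pos == 2 and r.n_neg == 0


class TestMeanConservation:
    def test_constant_track(self):
        t = ConservationTrack.from_arrays({"chr1": np.full(2000, 0.8)})
        assert mean_conservation(t, make_peak(start=500, end=1000, summit=750)) == \
            pytest.approx(0.8)

    def test_partial_coverage_averages_covered(self):
        arr = np.full(2000, np.nan)
        arr[500:900] = 1.0
        t = ConservationTrack.from_arrays({"chr1": arr})
        m = mean_conservation(t, make_peak(start=500, end=1000, summit=750))
        assert m == pytest.approx(1.0)

    def test_fully_missing_is_nan(self):
        t = ConservationTrack.from_arrays({"chr2": np.ones(10)})
        assert math.isnan(mean_conservation(t, make_peak(start=500, end=1000, summit=750)))


def _exact_ranksum_p(a, b):
    """Exact two-sided permutation p for the rank-sum statistic (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(a)].sum()
    n = len(pooled)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), len(a)):
        stat = ranks[list(combo)].sum()
        total += 1
        if abs(stat - n * (n + 1) / 4 * 2 * len(a) / n) >= abs(obs - len(a) * (n + 1) / 2) - 1e-9:
            count += 1
    return count / total


class TestRankTests:
    def test_identical_groups_p_near_one(self):
        _, p, _ = compare_groups_ranksum([1, 2, 3, 4.5], [1, 2, 3, 4.5])
        assert p > 0.6

    def test_exact_permutation_oracle_small_n(self, rng):
        a = rng.normal(0, 1, 6)
        b = rng.normal(0.5, 1, 5)
        _, p, _ = compare_groups_ranksum(a, b)
        # exact permutation oracle: count statistics as extreme as observed
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        obs_dev = abs(ranks[:6].sum() - 6 * (len(pooled) + 1) / 2)
        count = sum(
            abs(ranks[list(c)].sum() - 6 * (len(pooled) + 1) / 2) >= obs_dev - 1e-9
            for c in itertools.combinations(range(len(pooled)), 6)
        )
        assert p == pytest.approx(count / math.comb(11, 6))

    def test_bonferroni_capped_at_one(self):
        _, raw, adj = compare_groups_ranksum([1, 2, 3], [1.5, 2.5, 3.5],
                                             bonferroni_factor=40)
        assert adj == min(1.0, raw * 40) and adj <= 1.0

    def test_disjoint_groups_significant_after_x20(self, rng):
        a = rng.normal(0, 0.1, 20)
        b = rng.normal(10, 0.1, 20)
        _, raw, adj = compare_groups_ranksum(a, b, bonferroni_factor=20)
        assert adj == pytest.approx(min(1.0, raw * 20))
        assert adj < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_ranksum([], [1.0])


class TestSignRankComparison:
    def test_monotone_transform_gives_p_one(self):
        pred = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        cons = pred ** 2  # same ranking
        flags = np.array([True, True, True, False, False, False])
        p_c, p_n = rank_comparison_signrank(pred, cons, flags)
        assert p_c == 1.0 and p_n == 1.0

    def test_single_pair_undefined(self):
        p_c, p_n = rank_comparison_signrank([0.1, 0.9], [0.9, 0.1], [True, False])
        assert math.isnan(p_c) and math.isnan(p_n)

    def test_toy_example_matches_hand_computed_ranks(self):
        # predictions rank conserved OCRs 1,2,3; conservation ranks them 4,5,6
        pred = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        cons = np.array([0.1, 0.2, 0.3, 0.9, 0.8, 0.7])
        flags = np.array([True, True, True, False, False, False])
        # paired rank differences for conserved: (6-3, 5-2, 4-1) = (3, 3, 3)
        p_c, _ = rank_comparison_signrank(pred, cons, flags)
        res = stats.wilcoxon([3.0, 3.0, 3.0], alternative="two-sided")
        assert p_c == pytest.approx(float(res.pvalue))
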