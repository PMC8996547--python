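"""Positive-set filtering, the six negative-set strategies, assembly."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xspecies.datasets import (
    LabeledExample,
    TrainingSet,
    assemble_training_set,
    dinucleotide_counts,
    dinucleotide_shuffle,
    filter_candidate_ocrs,
    flanking_negatives,
    gc_fraction,
    gc_repeat_matched_negatives,
    loose_ocrs,
    non_ocr_orthologs_of_ocrs,
    other_tissue_negatives,
    repeat_fraction,
    union_pooled_peaks,
)
from xspecies.intervals import GenomicInterval, Peak, SequenceWindow, UnionPeaks
from xspecies.io import OrthRecord, OrthologMap

from conftest import make_peak


def iv(start, end, chrom="chr1", species="mouse"):
    return GenomicInterval(species, chrom, start, end)


class TestCandidateFilter:
    def test_good_peak_kept(self):
        p = make_peak(start=100_000, end=100_900)
        kept = filter_candidate_ocrs([p], exons=[], tss=[iv(130_000, 130_001)])
        assert kept == [p]

    def test_too_long_removed(self):
        p = make_peak(start=0, end=1001, summit=500)
        assert filter_candidate_ocrs([p], [], []) == []
        p2 = make_peak(start=0, end=1000, summit=500)
        assert filter_candidate_ocrs([p2], [], []) == [p2]

    def test_single_base_exon_overlap_removed(self):
        p = make_peak(start=100_000, end=100_500)
        assert filter_candidate_ocrs([p], exons=[iv(100_499, 100_600)], tss=[]) == []
        assert filter_candidate_ocrs([p], exons=[iv(100_500, 100_600)], tss=[]) == [p]

    def test_tss_distance_boundary(self):
        p = make_peak(start=100_000, end=100_500)
        # nearest TSS exactly 20 kb from the right edge -> kept
        assert filter_candidate_ocrs([p], [], [iv(120_499, 120_500)]) == [p]
        assert filter_candidate_ocrs([p], [], [iv(120_498, 120_499)]) == []


class TestUnionAndLoose:
    def test_union_membership_by_overlap(self):
        up = union_pooled_peaks([[make_peak(start=0, end=10, summit=5)],
                                [make_peak(start=5, end=15, summit=10)]])
        assert up.overlaps(iv(9, 11))
        assert not up.overlaps(iv(15, 20))  # half-open

    def test_empty_union_overlaps_nothing(self):
        up = union_pooled_peaks([])
        assert not up.overlaps(iv(0, 10))

    def test_loose_requires_overlap_in_every_other_dataset(self):
        base = make_peak(start=100_000, end=100_500)
        hit = UnionPeaks.from_intervals([iv(100_100, 100_200)])
        miss = UnionPeaks.from_intervals([iv(500_000, 500_100)])
        assert loose_ocrs([base], [hit, hit], [], []) == [base]
        assert loose_ocrs([base], [hit, miss], [], []) == []

    def test_zero_other_datasets(self):
        base = make_peak(start=100_000, end=100_500)
        with pytest.raises(ValueError):
            loose_ocrs([base], [], [], [])
        assert loose_ocrs([base], [], [], [], allow_single_dataset=True) == [base]


class TestNonOcrOrthologs:
    def _setup(self):
        # the motivating example: a region closed in mouse whose human
        # ortholog is an OCR
        human_ocr = make_peak(chrom="chr1", start=34_684_126, end=34_684_689,
                              summit=34_684_400, species="human", name="h1")
        omap = OrthologMap()
        omap.add("human", "h1", "mouse",
                 OrthRecord(GenomicInterval("mouse", "chr4", 127_435_564, 127_436_049),
                            127_435_800))
        return human_ocr, omap

    def test_closed_ortholog_becomes_negative(self):
        human_ocr, omap = self._setup()
        mouse_union = UnionPeaks.from_intervals([])
        (neg,) = non_ocr_orthologs_of_ocrs([human_ocr], omap, "mouse", mouse_union)
        assert (neg.chrom, neg.interval.start, neg.interval.end) == \
            ("chr4", 127_435_564, 127_436_049)
        assert neg.summit == 127_435_800

    def test_open_ortholog_excluded(self):
        human_ocr, omap = self._setup()
        mouse_union = UnionPeaks.from_intervals(
            [GenomicInterval("mouse", "chr4", 127_435_000, 127_436_000)]
        )
        assert non_ocr_orthologs_of_ocrs([human_ocr], omap, "mouse", mouse_union) == []

    def test_no_ortholog_contributes_nothing(self):
        human_ocr, _ = self._setup()
        assert non_ocr_orthologs_of_ocrs(
            [human_ocr], OrthologMap(), "mouse", UnionPeaks.from_intervals([])
        ) == []

    def test_output_never_overlaps_target_union(self, tiny_cohort):
        """Exhaustive invariant on the simulated cohort."""
        c = tiny_cohort
        union = c.union_pooled("mouse", "brain")
        negs = non_ocr_orthologs_of_ocrs(
            c.peaks_for("human", "brain"), c.ortholog_map, "mouse", union
        )
        assert negs, "expected some non-OCR orthologs in the cohort"
        assert not any(union.overlaps(n.interval) for n in negs)


class TestDinucleotideShuffle:
    def test_homopolymer_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", n_copies=3, seed=0) == ["AAAA"] * 3

    def test_counts_conserved_on_random_sequences(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(25):
            seq = "".join(rng.choice(bases, size=500))
            for s in dinucleotide_shuffle(seq, n_copies=4, seed=int(rng.integers(2**31))):
                assert np.array_equal(dinucleotide_counts(s), dinucleotide_counts(seq))
                assert len(s) == len(seq)

    def test_deterministic_under_seed(self):
        seq = "ACGTACGGTTACGATCG" * 10
        assert dinucleotide_shuffle(seq, 5, seed=42) == dinucleotide_shuffle(seq, 5, seed=42)

    def test_tenfold_expansion(self):
        seqs = ["ACGTACGTAC", "GGGTTTAACC"]
        total = sum(len(dinucleotide_shuffle(s, n_copies=10, seed=1)) for s in seqs)
        assert total == 10 * len(seqs)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dinucleotide_shuffle("A", 1, 0)


class TestGcRepeatMatched:
    def _pool(self, rng, n=600):
        pool = []
        bases = np.array(list("ACGT"))
        for i in range(n):
            seq = "".join(rng.choice(bases, size=100, p=[0.4, 0.1, 0.2, 0.3]))
            if i % 3 == 0:
                seq = seq[:50].lower() + seq[50:]
            start = 1000 * (i + 1)
            pool.append((make_peak(start=start, end=start + 100, name=f"n{i}"), seq))
        return pool

    def test_ratio_and_bin_matching(self, rng):
        pool = self._pool(rng)
        positives = [seq for _, seq in self._pool(np.random.default_rng(77), n=50)]
        negs = gc_repeat_matched_negatives(positives, pool, ratio=2, seed=5)
        assert len(negs) == 2 * len(positives)
        # recount joint bins: each negative's bin should be among positive bins
        by_name = {p.name: s for p, s in pool}
        def joint(seq):
            return (min(int(gc_fraction(seq) * 10), 9), min(int(repeat_fraction(seq) * 4), 3))
        pos_bins = Counter(joint(s) for s in positives)
        neg_bins = Counter(joint(by_name[n.name]) for n in negs)
        # most draws land in the exact bin (fallbacks allowed when exhausted)
        exact = sum(min(neg_bins[b], 2 * c) for b, c in pos_bins.items())
        assert exact >= 0.8 * len(negs)

    def test_sampling_without_replacement_and_deterministic(self, rng):
        pool = self._pool(rng)
        positives = [s for _, s in self._pool(np.random.default_rng(3), n=30)]
        a = gc_repeat_matched_negatives(positives, pool, 2, seed=9)
        b = gc_repeat_matched_negatives(positives, pool, 2, seed=9)
        assert [p.name for p in a] == [p.name for p in b]
        assert len({p.name for p in a}) == len(a)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError):
            gc_repeat_matched_negatives(["ACGT"], [], 2, 0)


class TestFlankingAndOtherTissue:
    def test_flank_arithmetic_and_bounds(self):
        p = make_peak(start=9_750, end=10_250, summit=10_000)
        union = UnionPeaks.from_intervals([])
        negs = flanking_negatives([p], offset=10_000, tissue_union_peaks=union)
        # left flank centered at 0 is out of bounds; right at 20,000 survives
        assert [n.summit for n in negs] == [20_000]
        assert negs[0].interval.length == 500

    def test_flank_overlapping_ocr_excluded(self):
        p = make_peak(start=9_750, end=10_250, summit=10_000)
        union = UnionPeaks.from_intervals([iv(19_900, 20_100)])
        assert flanking_negatives([p], 10_000, union) == []

    def test_per_positive_yield_bounded(self, rng):
        union = UnionPeaks.from_intervals([iv(0, 30_000)])
        for _ in range(20):
            s = int(rng.integers(5_000, 200_000))
            p = make_peak(start=s - 250, end=s + 250, summit=s)
            n = len(flanking_negatives([p], 20_000, union))
            assert 0 <= n <= 2

    def test_other_tissue_negatives(self):
        liver = [make_peak(start=0, end=500, tissue="liver", name="lv1"),
                 make_peak(start=10_000, end=10_500, tissue="liver", name="lv2")]
        brain_union = UnionPeaks.from_intervals([iv(400, 600)])
        negs = other_tissue_negatives(liver, brain_union)
        assert [n.name for n in negs] == ["lv2"]
        assert other_tissue_negatives([], brain_union) == []


def _window(chrom, start, species="mouse", rid="", seq=None):
    seq = seq or "ACGT" * 125
    return SequenceWindow(
        species=species,
        interval=GenomicInterval(species, chrom, start, start + 500),
        strand="+", seq=seq, region_id=rid,
    )


class TestAssembly:
    def test_class_weights_match_published_counts(self):
        # mouse-only brain model: 21,594 positives / 25,086 negatives
        w = TrainingSet.compute_class_weights(21_594, 25_086)
        assert w[1] == pytest.approx(25_086 / 46_680)
        assert w[0] == pytest.approx(21_594 / 46_680)
        assert w[1] == pytest.approx(0.5374, abs=1e-4)
        assert 25_086 / 21_594 == pytest.approx(1.16, abs=5e-3)

    def test_balanced_weights_are_half(self):
        w = TrainingSet.compute_class_weights(10, 10)
        assert w == {1: 0.5, 0: 0.5}

    def test_assembly_counts_weights_and_rc(self):
        pos = {"mouse": [(_window("chr3", 0, rid="a"), "positive")]}
        neg = {"mouse": [(_window("chr3", 2000, rid="b"), "non_ocr_ortholog"),
                         (_window("chr1", 0, rid="c"), "non_ocr_ortholog")]}
        spec = {"chr1": "test", "chr3": "train"}
        ts = assemble_training_set(pos, neg, spec)
        assert ts.counts["train"] == (1, 1)
        assert ts.counts["test"] == (0, 1)
        assert ts.class_weight == {1: 0.5, 0: 0.5}
        # rc augmentation doubles examples; strands share label and weight
        assert len(ts.examples["train"]) == 4
        strands = {e.window.strand for e in ts.examples["train"]}
        assert strands == {"+", "-"}

    def test_partition_follows_reference_ortholog(self):
        pos = {"macaque": [(_window("chr9", 0, species="macaque", rid="m1"), "positive")],
               "mouse": [(_window("chr3", 0, rid="m0"), "positive")]}
        neg = {"mouse": [(_window("chr3", 5000, rid="n0"), "non_ocr_ortholog")]}
        spec = {"chr1": "test", "chr3": "train", "chr9": "train"}
        ts = assemble_training_set(pos, neg, spec, reference_chrom={"m1": "chr1"})
        test_ids = {e.window.region_id for e in ts.examples["test"]}
        assert test_ids == {"m1"}

    def test_no_training_window_on_test_chromosome(self, tiny_cohort):
        """Chromosome-split isolation on the simulated cohort."""
        from xspecies.pipeline import cohort_training_examples, default_split_spec

        man, _ = cohort_training_examples(tiny_cohort, "brain")
        split = default_split_spec(tiny_cohort)
        train_chroms = {c for c, p in split.items() if p == "train"}
        test_chroms = {c for c, p in split.items() if p == "test"}
        assert man.chrom.isin(train_chroms | test_chroms | {"chr2"}).all()
        assert not man.loc[man.chrom.map(split) == "train", "chrom"].isin(test_chroms).any()

    def test_labeled_example_validation(self):
        w = _window("chr1", 0)
        with pytest.raises(ValueError):
            LabeledExample(w, 2, 1.0, "positive")
        with pytest.raises(ValueError):
            LabeledExample(w, 1, 0.0, "positive")
        with pytest.raises(ValueError):
            LabeledExample(w, 1, 1.0, "mystery")
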