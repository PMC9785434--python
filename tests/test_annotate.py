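"""Peak calling, feature classification, enrichment, width statistics."""

import numpy as np
import pandas as pd
import pytest

from ocratlas.annotate import (
    CLASS_ORDER,
    annotate_peaks,
    call_peaks_simple,
    feature_distribution,
    relative_enrichment,
    width_stats,
)
from ocratlas.intervals import GenomeAnnotation, IntervalSet, intersect_count

from conftest import random_interval_set, toy_annotation


def classify_oracle(center, chrom, annotation, bins=(1000, 2000, 3000), downstream=300):
    """Slow per-peak rule evaluation, independent of the vectorized path."""
    genes = annotation.genes[annotation.genes["chrom"] == chrom]
    if len(genes):
        d = (genes["tss"] - center).abs()
        best = d.min()
        if best <= bins[0]:
            return CLASS_ORDER[0]
        if best <= bins[1]:
            return CLASS_ORDER[1]
        if best <= bins[2]:
            return CLASS_ORDER[2]
    for df, label in (
        (annotation.five_prime_utr, "5' UTR"),
        (annotation.three_prime_utr, "3' UTR"),
        (annotation.exons, "Exon"),
    ):
        sub = df[df["chrom"] == chrom]
        if ((sub["start"] <= center) & (center < sub["end"])).any():
            return label
    if ((genes["start"] <= center) & (center < genes["end"])).any():
        return "Intron"
    for r in genes.itertuples(index=False):
        if r.strand == "+" and r.end <= center < r.end + downstream:
            return "Downstream (<=300)"
        if r.strand == "-" and r.start - downstream <= center < r.start:
            return "Downstream (<=300)"
    return "Distal Intergenic"


class TestCallPeaks:
    def test_spike_gives_single_peak_with_summit(self):
        sizes = {"chr1": 100_000}
        # 100 fragments stacking cut sites at 50000 and 50149
        frags = IntervalSet([("chr1", 50_000, 50_150)] * 100, sizes)
        peaks = call_peaks_simple(frags, sizes)
        assert len(peaks) == 1
        iv = peaks.intervals[0]
        assert iv.start <= 50_000 < iv.end
        # leftmost maximum of the pileup wins the summit tie
        assert peaks.summits[0] == 50_000

    def test_empty_fragments_empty_peakset(self):
        peaks = call_peaks_simple(IntervalSet(), {"chr1": 1000})
        assert len(peaks) == 0

    def test_uniform_background_false_positive_calibration(self):
        sizes = {"chr1": 1_000_000}
        rng = np.random.default_rng(31)
        n = 200_000
        starts = rng.integers(0, 999_800, size=n)
        frags = IntervalSet(
            pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 150}),
            sizes,
        )
        p_cut = 1e-3
        peaks = call_peaks_simple(frags, sizes, p_cut=p_cut)
        n_windows = len(np.arange(0, 1_000_000 - 150 + 1, 50))
        # discrete Poisson tails make the realized rate <= p_cut; merged
        # peaks should stay within 3x of the nominal false-positive budget
        assert len(peaks) <= 3 * p_cut * n_windows

    def test_depth_doubling_keeps_peaks(self, small_study):
        sizes = small_study.annotation.chrom_sizes
        f1 = small_study.fragments[("Y", 1)]
        doubled = IntervalSet(
            pd.concat([f1.df, f1.df], ignore_index=True), sizes
        )
        p1 = call_peaks_simple(f1, sizes)
        p2 = call_peaks_simple(doubled, sizes)
        # every peak called at depth 1x is recovered (covered) at 2x
        assert (intersect_count(p1.intervals, p2.intervals) > 0).all()


class TestAnnotatePeaks:
    def test_promoter_definition(self):
        ann = toy_annotation()
        # center 9500: 500 bp upstream of gene_a TSS (10000)
        out = annotate_peaks(IntervalSet([("chr1", 9450, 9550, "p")]), ann)
        assert out.loc[0, "feature_class"] == "Promoter (<=1kb)"
        assert out.loc[0, "tss_distance"] == 500

    def test_promoter_priority_over_exon(self):
        # a center inside gene_a's second exon (14000-16000) but within the
        # 2-3 kb promoter window of gene_a's own TSS: promoter bin wins
        ann = toy_annotation()
        out = annotate_peaks(IntervalSet([("chr1", 12400, 12600, "p")]), ann)
        # center 12500: 2500 from TSS 10000 -> Promoter (2-3kb), inside intron
        assert out.loc[0, "feature_class"] == "Promoter (2-3kb)"

    def test_downstream_and_distal(self):
        ann = toy_annotation()
        # gene_a + strand ends at 16000; center 16100 is downstream <= 300
        # but 16100 is also 6100 from TSS -> not promoter
        out = annotate_peaks(IntervalSet([("chr1", 16050, 16150, "p")]), ann)
        assert out.loc[0, "feature_class"] == "Downstream (<=300)"
        out = annotate_peaks(IntervalSet([("chr1", 20950, 21050, "p")]), ann)
        assert out.loc[0, "feature_class"] == "Distal Intergenic"

    def test_geneless_chromosome_distal(self):
        ann = toy_annotation()
        out = annotate_peaks(IntervalSet([("chr2", 100, 200, "p")]), ann)
        assert out.loc[0, "feature_class"] == "Distal Intergenic"

    def test_exhaustive_rule_oracle(self, small_study, rng):
        ann = small_study.annotation
        peaks = random_interval_set(rng, 1000, ann.chrom_sizes, max_width=600)
        out = annotate_peaks(peaks, ann)
        centers = peaks.centers
        chroms = peaks.df["chrom"].to_numpy()
        for i in range(len(peaks)):
            assert out.loc[i, "feature_class"] == classify_oracle(
                centers[i], chroms[i], ann
            ), f"peak {i} at {chroms[i]}:{centers[i]}"

    def test_every_peak_gets_exactly_one_class(self, small_study, rng):
        ann = small_study.annotation
        peaks = random_interval_set(rng, 500, ann.chrom_sizes)
        out = annotate_peaks(peaks, ann)
        assert out["feature_class"].isin(CLASS_ORDER).all()
        assert len(out) == len(peaks)


class TestFeatureDistribution:
    def test_sums_to_100_and_collapse(self, small_study, rng):
        ann = small_study.annotation
        out = annotate_peaks(random_interval_set(rng, 300, ann.chrom_sizes), ann)
        dist = feature_distribution(out)
        assert abs(dist.sum() - 100.0) < 1e-9
        coll = feature_distribution(out, collapse_promoters=True)
        assert abs(coll.sum() - 100.0) < 1e-9
        assert "Promoter (<=3kb)" in coll.index

    def test_order_invariance(self, small_study, rng):
        ann = small_study.annotation
        out = annotate_peaks(random_interval_set(rng, 200, ann.chrom_sizes), ann)
        shuffled = out.sample(frac=1, random_state=0)
        pd.testing.assert_series_equal(
            feature_distribution(out), feature_distribution(shuffled)
        )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            feature_distribution(pd.DataFrame({"feature_class": []}))

    def test_planted_promoter_share_exceeds_uniform(self, small_study, small_cfg):
        out = annotate_peaks(small_study.truth.true_peaks(), small_study.annotation)
        dist = feature_distribution(out, collapse_promoters=True)
        # uniform placement would put ~ promoter-bp share of the genome here;
        # the landscape planted half the peaks at promoters
        assert dist["Promoter (<=3kb)"] > 40.0


class TestRelativeEnrichment:
    def test_observed_and_expected_conserve_peak_count(self, small_study, rng):
        ann = small_study.annotation
        peaks = random_interval_set(rng, 120, ann.chrom_sizes)
        table = relative_enrichment(peaks, ann, ann.chrom_sizes, n_shuffles=50, seed=4)
        assert table["observed"].sum() == len(peaks)
        assert abs(table["expected"].sum() - len(peaks)) < 1e-9

    def test_degenerate_single_class_ratio_one(self):
        # no genes at all: everything is Distal Intergenic, observed == expected
        ann = GenomeAnnotation(
            genes=pd.DataFrame(columns=["gene_id", "chrom", "strand", "start", "end", "tss"]),
            exons=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
            five_prime_utr=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
            three_prime_utr=pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]),
            chrom_sizes={"chr1": 100_000},
        )
        peaks = IntervalSet([("chr1", i * 1000, i * 1000 + 400) for i in range(50)])
        table = relative_enrichment(peaks, ann, ann.chrom_sizes, n_shuffles=20, seed=1)
        assert table.loc["Distal Intergenic", "ratio"] == 1.0

    def test_promoter_planted_enrichment(self, small_study):
        ann = small_study.annotation
        table = relative_enrichment(
            small_study.truth.true_peaks(), ann, ann.chrom_sizes,
            n_shuffles=500, seed=8,
        )
        assert table.loc["Promoter (<=1kb)", "ratio"] > 1.5
        assert table.loc["Promoter (<=1kb)", "p_empirical"] <= 0.01

    def test_null_ratio_converges_with_shuffles(self, small_study, rng):
        ann = small_study.annotation
        peaks = random_interval_set(rng, 400, ann.chrom_sizes)
        # more shuffles stabilise the expected counts: the seed-to-seed
        # jitter of the expectation shrinks from 100 to 1000 shuffles
        t100 = relative_enrichment(peaks, ann, ann.chrom_sizes, n_shuffles=100, seed=6)
        t1000 = relative_enrichment(peaks, ann, ann.chrom_sizes, n_shuffles=1000, seed=6)
        b100 = relative_enrichment(peaks, ann, ann.chrom_sizes, n_shuffles=100, seed=7)
        b1000 = relative_enrichment(peaks, ann, ann.chrom_sizes, n_shuffles=1000, seed=7)
        jitter100 = (t100["expected"] - b100["expected"]).abs().max()
        jitter1000 = (t1000["expected"] - b1000["expected"]).abs().max()
        assert jitter1000 < jitter100

    def test_default_shuffle_count_recorded(self, small_study):
        peaks = small_study.truth.true_peaks()
        ann = small_study.annotation
        t = relative_enrichment(peaks.df.pipe(IntervalSet), ann, ann.chrom_sizes,
                                n_shuffles=25, seed=0)
        assert (t["n_shuffles"] == 25).all()
        import inspect

        assert inspect.signature(relative_enrichment).parameters["n_shuffles"].default == 5000


class TestWidthStats:
    @staticmethod
    def _frame(widths_by_class):
        rows = []
        for c, ws in widths_by_class.items():
            rows += [(c, w) for w in ws]
        return pd.DataFrame(rows, columns=["feature_class", "width"])

    def test_identical_width_multisets_share_letter(self):
        df = self._frame({"Exon": [100, 200, 300], "Intron": [100, 200, 300]})
        ws = width_stats(df)
        letters = dict(zip(ws.per_class["feature_class"], ws.per_class["letters"]))
        assert letters["Exon"] == letters["Intron"]

    def test_separated_classes_distinct_letters(self, rng):
        # constants with tiny jitter: textbook one-way F is enormous
        a = 100 + rng.normal(0, 0.5, 30)
        b = 300 + rng.normal(0, 0.5, 30)
        df = self._frame({"Exon": a, "Intron": b})
        ws = width_stats(df)
        assert ws.anova_p < 0.01
        letters = dict(zip(ws.per_class["feature_class"], ws.per_class["letters"]))
        assert set(letters["Exon"]) & set(letters["Intron"]) == set()
        # F statistic equals the textbook formula
        grand = np.concatenate([a, b]).mean()
        ssb = 30 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ssb / 1) / (ssw / 58)
        assert np.isclose(ws.anova_f, f_oracle)

    def test_means_match_arithmetic(self, small_study, rng):
        ann = small_study.annotation
        out = annotate_peaks(random_interval_set(rng, 400, ann.chrom_sizes), ann)
        ws = width_stats(out)
        for r in ws.per_class.itertuples(index=False):
            manual = out.loc[out["feature_class"] == r.feature_class, "width"].mean()
            assert np.isclose(r.mean, manual)

    def test_small_classes_flagged_untested(self):
        df = self._frame({"Exon": [100, 120, 140], "Intron": [200, 220, 260],
                          "3' UTR": [500]})
        ws = width_stats(df)
        row = ws.per_class.set_index("feature_class").loc["3' UTR"]
        assert not row["tested"]
        assert row["letters"] == ""
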