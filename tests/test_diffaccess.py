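"""Consensus, summit windows, counting, normalization, NB Wald test."""

import numpy as np
import pandas as pd
import pytest

from ocratlas.diffaccess import (
    CountMatrix,
    consensus_peaks,
    count_cut_sites,
    estimate_dispersion,
    fragment_length_histogram,
    nb_wald_test,
    redefine_peaks,
    sample_correlation,
    size_factors,
)
from ocratlas.intervals import IntervalSet, PeakSet, ValidationError, merge

from conftest import random_interval_set


def _peakset(intervals, sample=""):
    return PeakSet(intervals, sample=sample)


def _nb_matrix(rng, n, mu, alpha, n_per_group=3):
    """NB counts for a CY/Y two-group layout."""
    mu = np.broadcast_to(
        np.atleast_1d(np.asarray(mu, dtype=float))[:, None], (n, 2 * n_per_group)
    )
    alpha = np.full(n, float(alpha)) if np.isscalar(alpha) else np.asarray(alpha)
    if np.all(alpha > 0):
        lam = rng.gamma(1.0 / alpha[:, None], mu * alpha[:, None])
    else:
        lam = mu
    y = rng.poisson(lam)
    cols = [f"CY_{i+1}" for i in range(n_per_group)] + [
        f"Y_{i+1}" for i in range(n_per_group)
    ]
    counts = pd.DataFrame(y, columns=cols, index=[f"f{i:05d}" for i in range(n)])
    return CountMatrix(counts, {c: c.split("_")[0] for c in cols})


class TestConsensus:
    def test_single_sample_peak_dropped_identical_retained(self):
        sizes = {"chr1": 100_000}
        shared = ("chr1", 1_000, 1_500)
        only_s1 = ("chr1", 50_000, 50_400)
        peaks = {
            "Y_1": _peakset(IntervalSet([shared, only_s1], sizes)),
            "Y_2": _peakset(IntervalSet([shared], sizes)),
            "Y_3": _peakset(IntervalSet([shared], sizes)),
        }
        cons = consensus_peaks(peaks, {s: "Y" for s in peaks}, min_samples=2)
        df = cons["Y"].intervals.df
        assert len(df) == 1
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (1_000, 1_500)
        assert df.loc[0, "score"] == 3  # supported by all three samples

    def test_too_few_samples_errors(self):
        sizes = {"chr1": 10_000}
        peaks = {"Y_1": _peakset(IntervalSet([("chr1", 0, 100)], sizes))}
        with pytest.raises(ValidationError, match="min_samples"):
            consensus_peaks(peaks, {"Y_1": "Y"}, min_samples=2)

    def test_support_matches_brute_force(self, rng):
        sizes = {"chr1": 50_000, "chr2": 40_000}
        samples = {
            f"Y_{i+1}": _peakset(random_interval_set(rng, 60, sizes, max_width=900))
            for i in range(3)
        }
        cons = consensus_peaks(samples, {s: "Y" for s in samples}, min_samples=2)
        union = merge(
            IntervalSet(
                pd.concat([p.intervals.df[["chrom", "start", "end"]]
                           for p in samples.values()], ignore_index=True),
                sizes,
            )
        )
        kept = set(
            map(tuple, cons["Y"].intervals.df[["chrom", "start", "end"]].values)
        )
        for r in union.df.itertuples(index=False):
            support = 0
            for p in samples.values():
                df = p.intervals.df
                hit = (
                    (df["chrom"] == r.chrom)
                    & (df["start"] < r.end)
                    & (df["end"] > r.start)
                ).any()
                support += bool(hit)
            assert ((r.chrom, r.start, r.end) in kept) == (support >= 2)


class TestRedefine:
    @staticmethod
    def _frag_stack(pos, n, sizes, width=100):
        return IntervalSet([("chr1", pos, pos + width)] * n, sizes)

    def test_summit_window(self):
        sizes = {"chr1": 100_000}
        cons = _peakset(IntervalSet([("chr1", 800, 1_400)], sizes))
        # cut-site spike at 1000 (fragment starts)
        frags = {"Y_1": self._frag_stack(1_000, 30, sizes)}
        out = redefine_peaks(cons, frags, sizes)
        iv = out.intervals[0]
        assert (iv.start, iv.end) == (800, 1_200)
        assert out.summits[0] == 1_000
        assert iv.score == 0.0  # not clipped

    def test_clipping_flagged(self):
        sizes = {"chr1": 100_000}
        cons = _peakset(IntervalSet([("chr1", 0, 300)], sizes))
        frags = {"Y_1": self._frag_stack(50, 20, sizes)}
        out = redefine_peaks(cons, frags, sizes)
        iv = out.intervals[0]
        assert (iv.start, iv.end) == (0, 250)
        assert iv.score == 1.0  # clipped window flagged

    def test_summit_tie_leftmost(self):
        sizes = {"chr1": 100_000}
        cons = _peakset(IntervalSet([("chr1", 900, 1_500)], sizes))
        frags = {
            "Y_1": IntervalSet(
                [("chr1", 1_000, 1_100)] * 10 + [("chr1", 1_200, 1_300)] * 10, sizes
            )
        }
        out = redefine_peaks(cons, frags, sizes)
        assert out.summits[0] == 1_000

    def test_overlapping_windows_not_remerged(self):
        sizes = {"chr1": 100_000}
        cons = {
            "CY": _peakset(IntervalSet([("chr1", 800, 1_200)], sizes)),
            "Y": _peakset(IntervalSet([("chr1", 1_250, 1_650)], sizes)),
        }
        frags = {
            "Y_1": IntervalSet(
                [("chr1", 1_000, 1_100)] * 5 + [("chr1", 1_300, 1_400)] * 5, sizes
            )
        }
        out = redefine_peaks(cons, frags, sizes)
        assert len(out) == 2  # two overlapping 400 bp windows kept distinct
        w = out.intervals.widths
        assert (w == 400).all()


class TestCountCutSites:
    def test_fragment_fully_inside_counts_two(self):
        sizes = {"chr1": 10_000}
        peaks = _peakset(IntervalSet([("chr1", 1_000, 2_000, "pk")], sizes))
        inside = IntervalSet([("chr1", 1_200, 1_600)], sizes)
        straddle = IntervalSet([("chr1", 1_900, 2_500)], sizes)
        outside = IntervalSet([("chr1", 5_000, 5_200)], sizes)
        cm = count_cut_sites({"Y_1": inside, "Y_2": straddle, "Y_3": outside},
                             peaks, {"Y_1": "Y", "Y_2": "Y", "Y_3": "Y"})
        assert cm.counts.loc["pk", "Y_1"] == 2
        assert cm.counts.loc["pk", "Y_2"] == 1  # only the start lies inside
        assert cm.counts.loc["pk", "Y_3"] == 0

    def test_brute_force_oracle_with_overlapping_peaks(self, rng):
        sizes = {"chr1": 30_000, "chr2": 20_000}
        peaks_iv = random_interval_set(rng, 40, sizes, max_width=2_000)
        peaks = _peakset(peaks_iv)
        frags = random_interval_set(rng, 10_000, sizes, max_width=250)
        cm = count_cut_sites({"s": frags}, peaks, {"s": "Y"})
        fdf = frags.df
        for i, r in enumerate(peaks_iv.df.itertuples(index=False)):
            same = fdf[fdf["chrom"] == r.chrom]
            starts = same["start"].to_numpy()
            ends = same["end"].to_numpy() - 1
            expect = int(((starts >= r.start) & (starts < r.end)).sum()
                         + ((ends >= r.start) & (ends < r.end)).sum())
            assert cm.counts.iloc[i, 0] == expect

    def test_conservation_bound(self, small_study):
        peaks = _peakset(small_study.truth.true_peaks())
        frags = small_study.fragments_by_sample()
        cm = count_cut_sites(frags, peaks, small_study.sample_groups)
        for s, f in frags.items():
            assert cm.counts[s].sum() <= 2 * len(f)

    def test_fragment_mode_counts_overlaps(self):
        sizes = {"chr1": 10_000}
        peaks = _peakset(IntervalSet([("chr1", 1_000, 2_000, "pk")], sizes))
        straddle = IntervalSet([("chr1", 900, 1_050)], sizes)
        cm = count_cut_sites({"s": straddle}, peaks, {"s": "Y"}, mode="fragments")
        assert cm.counts.loc["pk", "s"] == 1


class TestSizeFactors:
    def test_identical_samples_equal_factors(self, rng):
        cm = _nb_matrix(rng, 100, 50.0, 0.1)
        dup = cm.counts.copy()
        dup["Y_1"] = dup["CY_1"]
        f = size_factors(dup)
        assert np.isclose(f["Y_1"], f["CY_1"])

    def test_doubled_sample_factor_ratio_two(self, rng):
        cm = _nb_matrix(rng, 200, 80.0, 0.05)
        counts = cm.counts.copy()
        counts["Y_3"] = 2 * counts["CY_1"]
        f = size_factors(counts)
        assert np.isclose(f["Y_3"] / f["CY_1"], 2.0)

    def test_matches_direct_formula(self, rng):
        cm = _nb_matrix(rng, 300, 60.0, 0.2)
        x = cm.counts.to_numpy(dtype=float)
        allpos = (x > 0).all(axis=1)
        gm = np.exp(np.mean(np.log(x[allpos]), axis=1))
        expect = np.median(x[allpos] / gm[:, None], axis=0)
        np.testing.assert_allclose(size_factors(cm.counts).to_numpy(), expect)

    def test_no_allpositive_feature_fallback_warns(self):
        counts = pd.DataFrame(
            {"a": [5, 0, 3], "b": [0, 7, 0]}, index=["f1", "f2", "f3"]
        )
        with pytest.warns(UserWarning, match="positive"):
            f = size_factors(counts)
        assert (f > 0).all()


class TestDispersion:
    def test_poisson_counts_near_zero_alpha(self, rng):
        cm = _nb_matrix(rng, 2_000, 100.0, 0.0)
        f = size_factors(cm.counts)
        a = estimate_dispersion(cm.counts, f, cm.sample_groups)
        assert a.median() <= 0.01

    def test_nb_alpha_recovered(self, rng):
        cm = _nb_matrix(rng, 2_000, 100.0, 0.2)
        f = size_factors(cm.counts)
        a = estimate_dispersion(cm.counts, f, cm.sample_groups)
        assert 0.1 <= a.median() <= 0.3

    def test_constant_counts_floor(self):
        counts = pd.DataFrame(
            {c: [10, 20, 30] for c in ["CY_1", "CY_2", "CY_3", "Y_1", "Y_2", "Y_3"]},
            index=["f1", "f2", "f3"],
        )
        cm = CountMatrix(counts, {c: c.split("_")[0] for c in counts.columns})
        a = estimate_dispersion(cm.counts, size_factors(counts), cm.sample_groups)
        assert (a <= 1e-6).all()

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"CY_1": [5], "Y_1": [6]}, index=["f"])
        cm = CountMatrix(counts, {"CY_1": "CY", "Y_1": "Y"})
        with pytest.raises(ValidationError, match="replicate"):
            estimate_dispersion(counts, size_factors(counts), cm.sample_groups)


class TestNbWald:
    def test_call_thresholds_exact(self, rng):
        cm = _nb_matrix(rng, 800, 150.0, 0.05)
        # plant some strong effects
        counts = cm.counts.copy()
        counts.iloc[:40, :3] = (counts.iloc[:40, :3] * 4).astype(int)
        cm2 = CountMatrix(counts, cm.sample_groups)
        res = nb_wald_test(cm2)
        up = (res["log2FC"] >= 0.58) & (res["q"] <= 0.05)
        down = (res["log2FC"] <= -0.58) & (res["q"] <= 0.05)
        assert ((res["call"] == "up") == up.fillna(False)).all()
        assert ((res["call"] == "down") == down.fillna(False)).all()
        assert (res["call"] == "up").sum() >= 30

    def test_all_zero_feature_excluded(self, rng):
        cm = _nb_matrix(rng, 50, 100.0, 0.1)
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        res = nb_wald_test(CountMatrix(counts, cm.sample_groups))
        assert np.isnan(res.iloc[0]["p"])
        assert res.iloc[0]["call"] == "ns"

    def test_one_zero_group_finite_fc(self, rng):
        cm = _nb_matrix(rng, 50, 100.0, 0.1)
        counts = cm.counts.copy()
        counts.iloc[0, :3] = 0  # CY all zero, Y positive
        res = nb_wald_test(CountMatrix(counts, cm.sample_groups))
        assert np.isfinite(res.iloc[0]["log2FC"])
        assert res.iloc[0]["log2FC"] < 0

    def test_bh_q_monotone_in_p(self, rng):
        cm = _nb_matrix(rng, 1_000, 100.0, 0.1)
        res = nb_wald_test(cm).dropna(subset=["p"]).sort_values("p")
        q = res["q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert (q <= 1.0 + 1e-12).all()

    def test_estimated_lfc_unbiased(self, rng):
        # plant a 2x effect in 20% of features; the rest anchor the size
        # factors so normalization does not absorb the planted shift
        # balanced up/down directions so median-of-ratios stays identifiable
        n, n_pl = 1_000, 200
        mu = np.full(n, 300.0)
        cm = _nb_matrix(rng, n, mu, 0.05)
        counts = cm.counts.copy()
        half = n_pl // 2
        fold = np.concatenate([np.full(half, 2.0), np.full(half, 0.5)])
        planted = rng.poisson(
            rng.gamma(1 / 0.05, fold[:, None] * mu[:n_pl, None] * 0.05, size=(n_pl, 3))
        )
        counts.iloc[:n_pl, :3] = planted
        res = nb_wald_test(CountMatrix(counts, cm.sample_groups))
        assert abs(np.median(res["log2FC"].iloc[:half]) - 1.0) <= 0.1
        assert abs(np.median(res["log2FC"].iloc[half:n_pl]) + 1.0) <= 0.1
        assert abs(np.median(res["log2FC"].iloc[n_pl:])) <= 0.05


class TestSampleLevel:
    def test_duplicate_samples_correlation_one(self, rng):
        cm = _nb_matrix(rng, 200, 50.0, 0.1)
        counts = cm.counts.copy()
        counts["Y_3"] = counts["CY_1"]
        corr = sample_correlation(counts)
        assert np.isclose(corr.loc["Y_3", "CY_1"], 1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_zero_variance_sample_flagged(self, rng):
        cm = _nb_matrix(rng, 100, 50.0, 0.1)
        counts = cm.counts.copy()
        counts["Y_3"] = 7
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = sample_correlation(counts)
        assert np.isnan(corr.loc["Y_3", "CY_1"])

    def test_fragment_length_histogram_sums(self, small_study):
        frags = small_study.fragments[("Y", 2)]
        hist = fragment_length_histogram(frags)
        assert hist.sum() == len(frags)
        assert (hist.index > 0).all()
        # order invariance
        shuffled = IntervalSet(
            frags.df.sample(frac=1, random_state=1).reset_index(drop=True),
            frags.chrom_sizes,
        )
        pd.testing.assert_series_equal(hist, fragment_length_histogram(shuffled))
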