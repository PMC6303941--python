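"""Bias-curve fitting, correction/scaling, and the full inference pipeline."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import pearsonr

from strandmeth import (
    CpGGroupProfile,
    InsufficientDynamicRangeError,
    StrandBinCounts,
    BinScheme,
    combine_strands,
    correct_and_scale,
    fit_linear_bias,
    fit_sigmoid_bias,
    group_by_cpg,
    halve_and_mirror,
    infer_from_counts,
    merge_strands,
    simulate_dataset,
    SimulationConfig,
)


def make_profile(n, means, bins_per_group=100):
    n = np.asarray(n)
    means = np.asarray(means, dtype=float)
    return CpGGroupProfile(
        n_cpg=n,
        mean_reads=means,
        n_bins=np.full(len(n), bins_per_group, dtype=np.int64),
        var_reads=np.zeros(len(n)),
        usable=np.full(len(n), True),
        min_bins_per_group=10,
    )


class TestGroupByCpG:
    def test_small_example(self):
        p = group_by_cpg(np.array([2.0, 4, 6, 8]), np.array([1, 1, 2, 2]),
                         min_bins_per_group=1)
        assert p.n_cpg.tolist() == [1, 2]
        assert p.mean_reads.tolist() == [3.0, 7.0]
        assert p.n_bins.tolist() == [2, 2]

    def test_absent_group_is_absent_not_zero(self):
        p = group_by_cpg(np.array([1.0, 1.0]), np.array([4, 6]), 1)
        assert 5 not in p.n_cpg

    def test_group_means_match_groupby_oracle(self, rng):
        n = rng.integers(0, 15, size=10_000)
        y = rng.poisson(3.0, size=10_000).astype(float)
        p = group_by_cpg(y, n, min_bins_per_group=10)
        for i, g in enumerate(p.n_cpg):
            sel = n == g
            assert p.n_bins[i] == sel.sum()
            assert p.mean_reads[i] == pytest.approx(y[sel].mean(), abs=1e-12)
        assert p.n_bins.sum() == 10_000

    def test_small_groups_flagged_unusable(self):
        y = np.r_[np.ones(20), [5.0]]
        n = np.r_[np.ones(20, dtype=int), [9]]
        p = group_by_cpg(y, n, min_bins_per_group=10)
        assert p.usable.tolist() == [True, False]


class TestSigmoidFit:
    def test_exact_recovery_with_known_asymptote(self):
        """Groups built from a known sigmoid invert to the exact parameters."""
        n = np.arange(1, 8)
        y_max = 37.0
        means = y_max * expit(-4.0 + 0.5 * n)
        fit = fit_sigmoid_bias(make_profile(n, means), y_max=y_max)
        assert fit.beta0 == pytest.approx(-4.0, abs=1e-9)
        assert fit.beta1 == pytest.approx(0.5, abs=1e-9)

    def test_high_cpg_groups_excluded_from_fit(self):
        """Groups at and beyond the argmax (hypomethylated regime) never
        enter the regression."""
        n = np.arange(1, 11)
        means = np.r_[expit(-4 + 0.5 * n[:6]) * 40, [41.0, 30, 20, 10]]
        fit = fit_sigmoid_bias(make_profile(n, means))
        assert fit.n_fit.max() < 7

    def test_two_usable_groups_is_error(self):
        with pytest.raises(InsufficientDynamicRangeError):
            fit_sigmoid_bias(make_profile([1, 2, 3], [1.0, 2.0, 10.0]))

    def test_poisson_noised_recovery_within_three_stderr(self, rng):
        n = np.arange(1, 13)
        y_max = 30.0
        lam = y_max * expit(-4.0 + 0.5 * n)
        bins_per_group = 400
        means = np.array(
            [rng.poisson(l, size=bins_per_group).mean() for l in lam])
        fit = fit_sigmoid_bias(make_profile(n, means, bins_per_group),
                               y_max=y_max)
        assert abs(fit.beta1 - 0.5) < 3 * fit.stderr_beta1

    def test_negative_slope_warns(self, caplog):
        n = np.arange(1, 8)
        means = 10.0 * expit(2.0 - 0.5 * n)
        means[-1] = 11.0  # force argmax to the last group
        with caplog.at_level("WARNING"):
            fit = fit_sigmoid_bias(make_profile(n, means))
        assert fit.beta1 < 0
        assert any("slope" in r.message for r in caplog.records)


class TestLinearFit:
    def test_exact_line_through_low_groups(self):
        n = np.arange(1, 6)
        fit = fit_linear_bias(make_profile(n, 2.0 + 3.0 * n))
        assert fit.beta1 == pytest.approx(3.0, abs=1e-12)
        assert fit.beta0 == pytest.approx(2.0, abs=1e-12)

    def test_flat_groups_give_zero_slope(self):
        fit = fit_linear_bias(make_profile(np.arange(1, 6), np.full(5, 4.0)))
        assert fit.beta1 == pytest.approx(0.0)
        assert np.allclose(fit.bias(np.arange(20)), 4.0)

    def test_noisy_line_matches_ols_oracle(self, rng):
        n = np.arange(1, 11).astype(float)
        y = 1.5 + 2.0 * n + rng.normal(0, 0.3, size=10)
        y[-1] = y.max() + 1  # keep argmax at the top so all others fit
        fit = fit_linear_bias(make_profile(n.astype(int), y))
        x = n[:-1]
        z = y[:-1]
        slope = ((x - x.mean()) * (z - z.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = z.mean() - slope * x.mean()
        assert fit.beta1 == pytest.approx(slope, abs=1e-10)
        assert fit.beta0 == pytest.approx(intercept, abs=1e-10)

    def test_extrapolated_bias_is_floored_positive(self):
        n = np.arange(1, 6)
        fit = fit_linear_bias(make_profile(n, 10.0 - 0.0 * n + n * -0.0 + (5.0 - n)))
        # decreasing line goes negative at large n; floor keeps it positive
        assert (fit.bias(np.arange(0, 200)) > 0).all()


class TestCorrectAndScale:
    def setup_method(self):
        self.fit = fit_sigmoid_bias(
            make_profile(np.arange(1, 8),
                         20 * expit(-4 + 0.5 * np.arange(1, 8))),
            y_max=20.0,
        )

    def test_zero_count_bins_are_exactly_zero(self):
        y = np.array([0.0, 5.0, 3.0])
        n = np.array([2, 5, 9])
        out = correct_and_scale(y, n, self.fit)
        assert out[0] == 0.0

    def test_two_nonzero_bins_scale_to_zero_and_one(self):
        out = correct_and_scale(np.array([2.0, 9.0]), np.array([3, 3]), self.fit)
        assert sorted(out.tolist()) == [0.0, 1.0]

    def test_constant_methylation_leaves_no_density_trend(self, rng):
        """Fully methylated bins, counts ~ Poisson(depth * f(n)): after
        correction the track is uncorrelated with CpG density."""
        n = rng.integers(1, 15, size=20_000)
        f = expit(-4 + 0.5 * n)
        y = rng.poisson(60.0 * f).astype(float)
        profile = group_by_cpg(y, n)
        fit = fit_sigmoid_bias(profile)
        out = correct_and_scale(y, n, fit)
        nz = y > 0
        assert abs(pearsonr(out[nz], n[nz]).statistic) < 0.1

    def test_all_zero_bins_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="zero"):
            out = correct_and_scale(np.zeros(4), np.arange(1, 5), self.fit)
        assert out.tolist() == [0, 0, 0, 0]

    def test_degenerate_scale_sets_nonzero_bins_to_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = correct_and_scale(np.array([0.0, 4.0]), np.array([2, 2]),
                                    self.fit)
        assert out.tolist() == [0.0, 1.0]

    def test_scale_invariance_under_count_rescaling(self, rng):
        """Multiplying all counts by c > 0 leaves the track unchanged."""
        n = rng.integers(1, 12, size=500)
        y = rng.poisson(8 * expit(-3 + 0.5 * n)).astype(float)
        a = correct_and_scale(y, n, self.fit)
        b = correct_and_scale(7.5 * y, n, self.fit)
        assert np.allclose(a, b, atol=1e-12)

    def test_monotone_bias_shrinks_dense_bins_more(self):
        """With beta1 > 0 the correction divides dense bins by a larger
        factor: equal raw counts yield smaller corrected signal at higher n."""
        f = self.fit.bias(np.arange(1, 20))
        assert (np.diff(f) > 0).all()
        y = np.full(19, 10.0)
        out = correct_and_scale(y, np.arange(1, 20), self.fit)
        assert (np.diff(out) < 0).all()


class TestMergeAndPipeline:
    def test_merge_examples(self):
        assert merge_strands(np.array([0.2]), np.array([0.6]))[0] == pytest.approx(0.4)
        t = np.array([0.1, 0.9, 0.5])
        assert np.array_equal(merge_strands(t, t), t)

    def test_merge_uses_present_strand_when_other_missing(self):
        out = merge_strands(np.array([np.nan, 0.4]), np.array([0.8, np.nan]))
        assert out.tolist() == [0.8, 0.4]

    def test_merge_matches_mean_oracle(self, rng):
        p, m = rng.random(100), rng.random(100)
        assert np.allclose(merge_strands(p, m), (p + m) / 2)

    def test_symmetric_counts_give_identical_strand_tracks(self, small_sim):
        d = small_sim
        sym = StrandBinCounts(d.scheme, d.counts.plus.copy(),
                              d.counts.plus.copy(), 50)
        track = infer_from_counts(sym, d.n_cpg)
        assert np.array_equal(track.plus, track.minus)
        assert np.allclose(track.merged, track.plus)

    def test_halve_and_mirror_matches_combined_inference(self, small_sim):
        """Splitting symmetric half-counts changes nothing: strand-specific
        processing reduces to the strand-blind pipeline when the strands
        carry identical reads."""
        d = small_sim
        total = combine_strands(d.counts)
        mirrored = halve_and_mirror(total, d.scheme)
        for model in ("sigmoid", "linear"):
            split = infer_from_counts(mirrored, d.n_cpg, model, True)
            nosplit = infer_from_counts(d.counts, d.n_cpg, model, False)
            assert np.allclose(split.merged, nosplit.merged, atol=1e-12)

    def test_track_values_span_unit_interval(self, small_sim):
        d = small_sim
        track = infer_from_counts(d.counts, d.n_cpg)
        for t in (track.plus, track.minus, track.merged):
            assert np.nanmin(t) >= 0 and np.nanmax(t) <= 1
        # per-strand min-max scaling pins the extremes
        assert track.plus.min() == 0.0 and track.plus.max() == 1.0

    def test_merged_track_beats_single_strand_on_opposite_truth(self):
        """With asymmetric strands, the merged track tracks the combined
        truth better than one strand's track matches the *other* strand's
        truth."""
        d = simulate_dataset(SimulationConfig(n_bins=5000, strand_rho=0.5,
                                              seed=21))
        track = infer_from_counts(d.counts, d.n_cpg)
        mask = d.n_cpg >= 4

        def pcc(a, b):
            return pearsonr(a[mask], b[mask]).statistic

        merged_vs_truth = pcc(track.merged, d.bin_meth_combined)
        cross = pcc(track.plus, d.bin_meth_minus)
        assert merged_vs_truth > cross
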