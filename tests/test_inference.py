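import numpy as np
import pytest

from tfocc.chip import ChIPProfile
from tfocc.inference import (
    FitGrid,
    RegionSummary,
    analysis_locus_mask,
    genome_wide_regions,
    ks_two_sample,
    normalized_mse_1kb,
    pearson_correlation,
    select_optimum,
)
from tfocc.model import AccessibilityTrack


def prof(values, provenance="simulated"):
    return ChIPProfile("chr", np.asarray(values, dtype=float), provenance=provenance)


class TestPearson:
    def test_identical_profiles(self):
        p = prof([1, 2, 3, 4])
        assert pearson_correlation(p, p) == pytest.approx(1.0)

    def test_anticorrelated(self):
        assert pearson_correlation(prof([1, 2, 3]), prof([5, 3, 1])) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # independent textbook computation: r = cov(x, y) / (sd_x sd_y)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 100.0])
        cx, cy = x - x.mean(), y - y.mean()
        expected = float((cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum()))
        assert pearson_correlation(prof(x), prof(y)) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_raises_distinct_error(self):
        with pytest.raises(ZeroDivisionError):
            pearson_correlation(prof([1, 1, 1]), prof([1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson_correlation(prof([1, 2]), prof([1, 2, 3]))


class TestNormalizedMSE:
    def test_identical_is_zero(self):
        p = prof(np.arange(3000.0))
        assert normalized_mse_1kb(p, p) == 0.0

    def test_mean_mode_scale_invariant(self):
        # documents the behaviour of the scale-free "mean" normalization
        obs = prof(np.arange(3000.0) + 1, provenance="observed")
        pred = prof(2 * (np.arange(3000.0) + 1))
        assert normalized_mse_1kb(pred, obs, normalization="mean") == pytest.approx(0.0, abs=1e-18)

    def test_nmse_mode_is_scale_sensitive(self):
        obs = prof(np.arange(3000.0) + 1, provenance="observed")
        pred = prof(2 * (np.arange(3000.0) + 1))
        assert normalized_mse_1kb(pred, obs) > 0.5

    def test_three_bin_hand_computation(self):
        # bins means: pred (1, 2, 3), obs (2, 2, 5); spreadsheet arithmetic:
        # nmse = ((1-2)^2 + 0 + (3-5)^2) / 3 / ((4+4+25)/3) = 5/33
        pred = prof(np.repeat([1.0, 2.0, 3.0], 1000))
        obs = prof(np.repeat([2.0, 2.0, 5.0], 1000), provenance="observed")
        assert normalized_mse_1kb(pred, obs) == pytest.approx(5 / 33, rel=1e-12)
        # mean mode: pred/2 = (.5, 1, 1.5), obs/3 = (2/3, 2/3, 5/3)
        expected = np.mean((np.array([0.5, 1, 1.5]) - np.array([2 / 3, 2 / 3, 5 / 3])) ** 2)
        assert normalized_mse_1kb(pred, obs, normalization="mean") == pytest.approx(expected)

    def test_short_region_single_bin_with_warning(self):
        with pytest.warns(UserWarning, match="single-bin"):
            v = normalized_mse_1kb(prof([1.0, 3.0]), prof([2.0, 2.0]))
        assert v == pytest.approx(0.0)  # equal means

    def test_unknown_normalization(self):
        with pytest.raises(ValueError):
            normalized_mse_1kb(prof([1.0] * 2000), prof([2.0] * 2000), normalization="zscore")


class TestSelectOptimum:
    def grid(self, mse, rho):
        mse = np.asarray(mse, dtype=float)
        return FitGrid(
            N_values=np.array([10.0, 100.0, 1000.0][: mse.shape[0]]),
            lambda_values=np.array([0.5, 1.0, 1.5][: mse.shape[1]]),
            rho=np.asarray(rho, dtype=float),
            mse=mse,
        )

    def test_joint_optimum_cell(self):
        g = self.grid([[1.0, 0.1], [0.8, 0.9]], [[0.2, 0.9], [0.3, 0.1]])
        r = select_optimum(g)
        assert (r.N_opt, r.lambda_opt) == (10.0, 1.0)
        assert not r.fallback
        assert (10.0, 1.0) in r.intersection_cells

    def test_full_band_fraction_returns_global_minimum(self):
        g = self.grid([[1.0, 0.1], [0.8, 0.9]], [[0.2, 0.9], [0.3, 0.1]])
        r = select_optimum(g, band_fraction=1.0)
        assert len(r.intersection_cells) == 4
        assert r.mse_at_opt == 0.1

    def test_disjoint_bands_fall_back_to_mse_minimum(self):
        # rho best where mse is worst and vice versa
        mse = [[0.0, 5.0, 9.0], [5.0, 5.0, 5.0], [9.0, 5.0, 10.0]]
        rho = [[0.0, 0.5, 1.0], [0.5, 0.5, 0.5], [0.9, 0.5, 0.1]]
        r = select_optimum(self.grid(mse, rho), band_fraction=0.12)
        assert r.fallback
        assert r.mse_at_opt == 0.0 and (r.N_opt, r.lambda_opt) == (10.0, 0.5)

    def test_tie_breaks_toward_smallest_n_then_lambda(self):
        mse = [[1.0, 1.0], [1.0, 1.0]]
        rho = [[0.5, 0.5], [0.5, 0.5]]
        r = select_optimum(self.grid(mse, rho))
        assert (r.N_opt, r.lambda_opt) == (10.0, 0.5)
        assert r.degenerate

    def test_optimum_never_beaten_within_intersection(self):
        rng = np.random.default_rng(5)
        g = self.grid(rng.uniform(0, 1, (3, 3)), rng.uniform(-1, 1, (3, 3)))
        r = select_optimum(g)
        for N, lam in r.intersection_cells:
            i = list(g.N_values).index(N)
            j = list(g.lambda_values).index(lam)
            assert r.mse_at_opt <= g.mse[i, j]

    def test_invariants_of_result(self):
        rng = np.random.default_rng(6)
        g = self.grid(rng.uniform(0, 1, (3, 3)), rng.uniform(-1, 1, (3, 3)))
        r = select_optimum(g)
        assert r.mse_at_opt >= r.mse_min
        assert r.rho_at_opt <= r.rho_max

    def test_non_finite_grid_rejected(self):
        with pytest.raises(ValueError):
            select_optimum(self.grid([[np.nan, 1.0]], [[0.1, 0.2]]))


class TestGenomeWideRegions:
    def test_boundary_semantics_of_background_filter(self):
        # uniform signal equals B everywhere: nothing passes the strict > B
        # filter, everything passes > 0.5 B
        obs = prof(np.ones(60_000), provenance="observed")
        pred = prof(np.ones(60_000))
        acc = AccessibilityTrack("chr", np.ones(60_000))
        strict = genome_wide_regions(obs, pred, acc, region_bp=20_000, background_mult=1.0)
        assert all(not r.passes_background for r in strict)
        half = genome_wide_regions(obs, pred, acc, region_bp=20_000, background_mult=0.5)
        assert all(r.passes_background for r in half)

    def test_inaccessible_regions_excluded(self):
        accvals = np.ones(60_000)
        accvals[20_000:40_000] = 0.0
        obs = prof(np.arange(60_000, dtype=float), provenance="observed")
        out = genome_wide_regions(obs, obs, AccessibilityTrack("chr", accvals), region_bp=20_000)
        assert [(r.start, r.end) for r in out] == [(0, 20_000), (40_000, 60_000)]

    def test_signal_concentrated_regions_pass(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 0.1, 200_000)
        v[30_000:50_000] += 5.0
        v[110_000:130_000] += 5.0
        obs = prof(v, provenance="observed")
        acc = AccessibilityTrack("chr", np.ones(200_000))
        out = genome_wide_regions(obs, obs, acc, region_bp=20_000, background_mult=1.0)
        passing = [(r.start, r.end) for r in out if r.passes_background]
        assert passing == [(20_000, 40_000), (40_000, 60_000), (100_000, 120_000), (120_000, 140_000)]

    def test_zero_variance_region_has_none_rho(self):
        obs = prof(np.ones(20_000), provenance="observed")
        predv = np.ones(20_000)
        predv[0] = 2.0
        out = genome_wide_regions(obs, prof(predv), AccessibilityTrack("chr", np.ones(20_000)))
        assert out[0].rho is None


class TestKSTwoSample:
    def test_identical_samples(self):
        x = np.arange(20.0)
        stat, p = ks_two_sample(x, x)
        assert stat == 0.0

    def test_disjoint_supports(self):
        stat, _ = ks_two_sample(np.arange(10.0), np.arange(100.0, 110.0))
        assert stat == 1.0

    def test_ecdf_enumeration_value(self):
        with pytest.warns(UserWarning, match="unreliable"):
            stat, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert stat == pytest.approx(1 / 3)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])


class TestAnalysisLocusMask:
    def test_keeps_only_strong_segments(self):
        obs = np.zeros(10_000)
        acc = np.zeros(10_000)
        acc[1000:2000] = 1  # strong locus
        acc[6000:7000] = 1  # weak locus
        obs[900:2100] = 5.0
        obs[5900:7100] = 0.1
        masks = analysis_locus_mask({"c": obs}, {"c": acc}, dilate=100)
        assert masks["c"][1500] and not masks["c"][6500]

    def test_no_accessibility_raises(self):
        with pytest.raises(ValueError):
            analysis_locus_mask({"c": np.ones(10)}, {"c": np.zeros(10)})

    def test_fallback_when_nothing_passes(self):
        obs = np.ones(1000)
        acc = np.zeros(1000)
        acc[100:200] = 1
        masks = analysis_locus_mask({"c": obs}, {"c": acc}, dilate=0)
        # uniform signal: no segment strictly exceeds B, falls back to all
        # accessible segments
        assert masks["c"][150] and not masks["c"][500]
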