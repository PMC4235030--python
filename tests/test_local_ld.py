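"""The Gamma GLM decay fit, LD-map tracks, and chromosome-level alpha."""

import numpy as np
import pytest

from ldscape.local_ld import (
    chromosome_alpha,
    expected_r2,
    fit_alpha,
    ld_map,
    sved_expected_r2,
)
from ldscape.synthetic import (
    SyntheticSpec,
    _mosaic_haplotypes,
    gen_glm_pairs,
    gen_mosaic_population,
)

from conftest import make_panel


class TestFitAlpha:
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_noise_free_exact_recovery(self, alpha):
        d = np.arange(0.1, 10.01, 0.1)
        r2 = 1.0 / (1.0 + alpha * d)
        fit = fit_alpha(d, r2)
        assert fit.converged
        assert fit.alpha_hat == pytest.approx(alpha, rel=1e-6)

    def test_zero_r2_pairs_excluded_from_fit(self):
        d = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        r2 = np.array([0.5, 0.0, 0.25, 0.0, 1e-13])
        fit = fit_alpha(d, r2)
        assert fit.n_used == 2

    def test_matches_statsmodels_gamma_glm_with_offset(self):
        import statsmodels.api as sm

        df = gen_glm_pairs(5.0, 4000, gamma_shape=1.0, seed=3)
        y, d = df["r2"].to_numpy(), df["d"].to_numpy()
        keep = y > 1e-12
        y, d = y[keep], d[keep]
        fit = fit_alpha(d, y)
        oracle = sm.GLM(
            y,
            d[:, None],
            family=sm.families.Gamma(link=sm.families.links.InversePower()),
            offset=np.ones(y.size),
        ).fit()
        assert fit.alpha_hat == pytest.approx(oracle.params[0], rel=1e-8)
        assert fit.std_err == pytest.approx(oracle.bse[0], rel=1e-6)

    def test_gamma_noise_recovery_within_monte_carlo_ci(self):
        alphas = np.array(
            [
                fit_alpha(*gen_glm_pairs(5.0, 10_000, gamma_shape=1.0, seed=s)
                          .to_numpy().T).alpha_hat
                for s in range(200)
            ]
        )
        se = alphas.std(ddof=1) / np.sqrt(alphas.size)
        assert abs(alphas.mean() - 5.0) < 3.5 * se

    def test_invariant_to_pair_order_and_duplication(self, rng):
        df = gen_glm_pairs(2.0, 500, gamma_shape=1.0, seed=1)
        d, r2 = df["d"].to_numpy(), df["r2"].to_numpy()
        base = fit_alpha(d, r2).alpha_hat
        perm = rng.permutation(d.size)
        assert fit_alpha(d[perm], r2[perm]).alpha_hat == pytest.approx(base, abs=1e-9)
        assert fit_alpha(np.tile(d, 2), np.tile(r2, 2)).alpha_hat == pytest.approx(
            base, abs=1e-9
        )

    def test_negative_alpha_reported_unclamped(self):
        d = np.array([0.5, 1.0, 2.0, 4.0])
        r2 = 1.0 / (1.0 - 0.1 * d)  # LD rising with distance
        fit = fit_alpha(d, r2)
        assert fit.converged
        assert fit.alpha_hat == pytest.approx(-0.1, rel=1e-6)

    def test_too_few_usable_pairs_is_error(self):
        with pytest.raises(ValueError, match="pairs"):
            fit_alpha([1.0, 2.0], [0.5, 0.0])
        with pytest.raises(ValueError, match="distinct"):
            fit_alpha([1.0, 1.0], [0.5, 0.4])

    def test_free_intercept_diagnostic_recovers_both_parameters(self):
        d = np.arange(0.1, 8.0, 0.1)
        r2 = 1.0 / (1.5 + 3.0 * d)
        fit = fit_alpha(d, r2, free_intercept=True)
        assert fit.intercept == pytest.approx(1.5, rel=1e-3)
        assert fit.alpha_hat == pytest.approx(3.0, rel=1e-3)


class TestExpectedR2:
    def test_closed_form_points(self):
        assert expected_r2(7.3, 0.0) == pytest.approx(1.0)
        assert expected_r2(0.0, 123.4) == pytest.approx(1.0)
        assert expected_r2(9.0, 1.0) == pytest.approx(0.1)

    def test_invalid_domain_is_error(self):
        with pytest.raises(ValueError):
            expected_r2(-2.0, 1.0)

    def test_strictly_decreasing_in_distance_for_positive_alpha(self):
        d = np.linspace(0, 10, 50)
        vals = expected_r2(3.0, d)
        assert (np.diff(vals) < 0).all()

    def test_sved_equivalence_under_alpha_4Nec(self):
        # alpha = 4 * Ne * c_per_Mb makes the two forms identical
        Ne, c_per_mb = 120.0, 0.013
        for d in (0.1, 1.0, 7.5):
            assert expected_r2(4 * Ne * c_per_mb, d) == pytest.approx(
                sved_expected_r2(c_per_mb * d, Ne), rel=1e-12
            )


class TestSvedExpectedR2:
    def test_closed_form_points(self):
        assert sved_expected_r2(0.0, 1000) == pytest.approx(1.0)
        assert sved_expected_r2(0.25, 1) == pytest.approx(0.5)
        assert sved_expected_r2(0.5, 100) == pytest.approx(1 / 201)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sved_expected_r2(-0.1, 100)
        with pytest.raises(ValueError):
            sved_expected_r2(0.1, 0)


class TestLdMap:
    def _panel(self, n_markers, seed=4):
        return gen_mosaic_population(
            SyntheticSpec(
                n_markers=n_markers + 40,  # headroom for monomorphic drops
                chrom_length_bp=(n_markers + 40) * 100_000,
                n_individuals=30,
                ne=30,
                seed=seed,
            )
        )

    def test_window_count_is_m_minus_n_plus_1(self):
        panel = self._panel(80)
        track = ld_map(panel, N=30, d_fixed=10.0)
        assert len(track.table) == panel.n_markers - 30 + 1

    def test_exactly_n_markers_give_one_window(self):
        panel = self._panel(80)
        sub = panel.subset_markers(np.arange(30))
        assert len(ld_map(sub, N=30).table) == 1

    def test_middle_marker_advances_one_per_window(self):
        panel = self._panel(60)
        sub = panel.subset_markers(np.arange(32))  # N + 2 -> 3 windows
        track = ld_map(sub, N=30).table
        assert len(track) == 3
        mids = [m.pos for m in sub.markers[15:18]]  # floor(30/2) = 15
        assert list(track["mid_pos"]) == mids

    def test_short_chromosome_skipped(self):
        panel = self._panel(40)
        track = ld_map(panel, N=panel.n_markers + 1)
        assert len(track.table) == 0

    def test_expected_r2_column_matches_alpha_transform(self):
        panel = self._panel(60)
        track = ld_map(panel, N=30, d_fixed=10.0).table
        ok = track["converged"] & track["expected_r2"].notna()
        a = track.loc[ok, "alpha_hat"]
        np.testing.assert_allclose(
            track.loc[ok, "expected_r2"], 1.0 / (1.0 + a * 10.0), atol=1e-12
        )

    def test_high_recombination_segment_elevates_alpha_track(self, rng):
        # mosaic with a 10x switch-intensity burst in the middle third
        m, n_hap = 120, 80
        pos = np.arange(1, m + 1) * 100_000
        founders = rng.integers(0, 2, size=(6, m), dtype=np.int8)
        gaps_mb = np.diff(pos) / 1e6
        rho = np.full(m - 1, 0.5)
        rho[40:80] = 15.0
        psw = 1.0 - np.exp(-rho * gaps_mb)
        H = _mosaic_haplotypes(founders, n_hap, psw, rng)
        p = H.mean(axis=1)
        keep = (p > 0) & (p < 1)
        panel = make_panel(H[keep], pos[keep])
        track = ld_map(panel, N=20, d_fixed=10.0).table
        mid_pos = track["mid_pos"].to_numpy()
        alpha = track["alpha_hat"].to_numpy()
        inside = (mid_pos > 4_500_000) & (mid_pos < 7_500_000)
        outside = (mid_pos < 3_500_000) | (mid_pos > 8_500_000)
        assert np.nanmedian(alpha[inside]) > np.nanmedian(alpha[outside])


class TestChromosomeAlpha:
    def _panel(self, rho=1.0, seed=6):
        return gen_mosaic_population(
            SyntheticSpec(n_markers=250, chrom_length_bp=25_000_000,
                          rho=rho, n_individuals=40, ne=40, seed=seed)
        )

    def test_same_seed_reproduces_exactly(self):
        panel = self._panel()
        a = chromosome_alpha(panel, "1", n_pairs=1000, n_replicates=8, seed=11)
        b = chromosome_alpha(panel, "1", n_pairs=1000, n_replicates=8, seed=11)
        assert (a.mean_alpha, a.sd_alpha) == (b.mean_alpha, b.sd_alpha)

    def test_degenerate_sampling_when_pairs_exhausted(self):
        # requesting more pairs than exist -> every replicate fits all pairs
        panel = self._panel()
        total = panel.n_markers * (panel.n_markers - 1) // 2
        ca = chromosome_alpha(panel, "1", n_pairs=total + 1000, n_replicates=5, seed=0)
        assert ca.n_pairs_per_replicate == total
        assert ca.sd_alpha == pytest.approx(0.0, abs=1e-12)

    def test_mean_alpha_increases_with_recombination_intensity(self):
        means = [
            chromosome_alpha(self._panel(rho=r, seed=6), "1",
                             n_pairs=2000, n_replicates=10, seed=1).mean_alpha
            for r in (0.5, 4.0)
        ]
        assert means[0] < means[1]

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(ValueError):
            chromosome_alpha(self._panel(), "99", n_pairs=10, n_replicates=2, seed=0)
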