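"""T1 fitting, relaxivity regression, T1-based enhancement."""

import numpy as np
import pytest

from voxreflect import (
    PhantomSpec,
    TubeSpec,
    Volume3D,
    fit_relaxivity,
    fit_t1_map,
    generate_tr_series,
    t1_enhancement,
)

PAPER_TRS = [6000.0, 4700.0, 3600.0, 2800.0, 2200.0, 1700.0, 1300.0, 1000.0, 800.0]


def saturation_series(t1_grid, s0_grid, trs, rng=None, sigma=0.0):
    vols = []
    for tr in trs:
        s = s0_grid * (1.0 - np.exp(-tr / t1_grid))
        if sigma > 0:
            g1 = rng.normal(0, sigma, s.shape)
            g2 = rng.normal(0, sigma, s.shape)
            s = np.sqrt((s + g1) ** 2 + g2**2)
        vols.append(Volume3D(s, (1, 1, 1)))
    return vols


class TestFitT1:
    def test_noiseless_nine_tr_recovery_within_0p1_percent(self):
        t1 = np.full((3, 3, 2), 1200.0)
        s0 = np.full((3, 3, 2), 1000.0)
        series = saturation_series(t1, s0, PAPER_TRS)
        fit = fit_t1_map(series, PAPER_TRS)
        assert fit.fit_mask.all()
        np.testing.assert_allclose(fit.t1_ms, 1200.0, rtol=1e-3)
        np.testing.assert_allclose(fit.s0, 1000.0, rtol=1e-3)
        assert np.all(fit.rmse < 1e-3)

    def test_mixed_t1_values_recovered(self):
        t1 = np.array([[[300.0, 800.0, 1500.0, 3000.0]]])
        s0 = np.full_like(t1, 500.0)
        fit = fit_t1_map(saturation_series(t1, s0, PAPER_TRS), PAPER_TRS)
        np.testing.assert_allclose(fit.t1_ms, t1, rtol=1e-3)

    def test_rician_noise_median_error_below_5_percent(self, rng):
        shape = (8, 8, 4)  # 256 voxels (the full 1000-voxel study runs in the
        # acceptance suite)
        t1 = np.full(shape, 1200.0)
        s0 = np.full(shape, 1000.0)
        series = saturation_series(t1, s0, PAPER_TRS, rng, sigma=20.0)
        fit = fit_t1_map(series, PAPER_TRS)
        rel = np.abs(fit.t1_ms[fit.fit_mask] - 1200.0) / 1200.0
        assert np.median(rel) < 0.05

    def test_constant_signal_flagged_not_fitted(self):
        vols = [Volume3D(np.full((2, 2, 1), 7.0), (1, 1, 1)) for _ in range(5)]
        fit = fit_t1_map(vols, PAPER_TRS[:5])
        assert not fit.fit_mask.any()
        assert set(fit.exclusion_reason.values()) == {"no_tr_dependence"}

    def test_scaling_series_changes_s0_only(self):
        t1 = np.full((2, 2, 2), 900.0)
        s0 = np.full((2, 2, 2), 400.0)
        f1 = fit_t1_map(saturation_series(t1, s0, PAPER_TRS), PAPER_TRS)
        f2 = fit_t1_map(saturation_series(t1, 5.0 * s0, PAPER_TRS), PAPER_TRS)
        np.testing.assert_allclose(f2.t1_ms, f1.t1_ms, rtol=1e-6)
        np.testing.assert_allclose(f2.s0, 5.0 * f1.s0, rtol=1e-6)

    def test_error_decreases_with_snr(self, rng):
        t1 = np.full((6, 6, 3), 1200.0)
        s0 = np.full((6, 6, 3), 1000.0)
        errs = []
        for snr in (10, 25, 50, 100):
            series = saturation_series(t1, s0, PAPER_TRS, rng, sigma=1000.0 / snr)
            fit = fit_t1_map(series, PAPER_TRS)
            rel = np.abs(fit.t1_ms[fit.fit_mask] - 1200.0) / 1200.0
            errs.append(np.median(rel))
        assert errs == sorted(errs, reverse=True)

    def test_too_few_trs_rejected(self):
        vols = [Volume3D(np.ones((2, 2, 1)), (1, 1, 1))] * 2
        with pytest.raises(ValueError, match="3 distinct"):
            fit_t1_map(vols, [1000.0, 2000.0])

    def test_series_roundtrip_through_phantom_generator(self):
        tubes = (
            TubeSpec((6.0, 6.0, 8.0), 2.5, 8.0, t1_ms=600.0, s0=800.0, role="test"),
            TubeSpec((14.0, 6.0, 8.0), 2.5, 8.0, t1_ms=1800.0, s0=800.0, role="control"),
        )
        spec = PhantomSpec((21, 13, 17), (1, 1, 1), tubes, noise_sigma=0.0)
        series = generate_tr_series(spec, PAPER_TRS)
        from voxreflect.phantom import _labels_and_ideal

        labels, _ = _labels_and_ideal(spec, [0.0, 0.0])
        fit = fit_t1_map(series, PAPER_TRS, mask=labels > 0)
        np.testing.assert_allclose(fit.t1_ms[labels == 1], 600.0, rtol=1e-3)
        np.testing.assert_allclose(fit.t1_ms[labels == 2], 1800.0, rtol=1e-3)


class TestRelaxivity:
    def closed_form_slope(self, x, y):
        x, y = np.asarray(x), np.asarray(y)
        sx = x - x.mean()
        return float((sx * (y - y.mean())).sum() / (sx**2).sum())

    def test_exact_line_recovers_slope_and_r2(self):
        conc = np.array([0.0, 0.1, 0.25, 0.5])
        r1 = 0.4 + 3.75 * conc  # s^-1
        fit = fit_relaxivity(conc, 1000.0 / r1)
        assert fit.r1_per_mM_per_s == pytest.approx(3.75, abs=1e-10)
        assert fit.intercept_per_s == pytest.approx(0.4, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_closed_form_least_squares(self, rng):
        conc = rng.uniform(0, 1, 9)
        t1 = rng.uniform(300, 3000, 9)
        fit = fit_relaxivity(conc, t1)
        assert fit.r1_per_mM_per_s == pytest.approx(
            self.closed_form_slope(conc, 1000.0 / t1), abs=1e-10
        )

    def test_two_points_exact_interpolation(self):
        fit = fit_relaxivity([0.0, 1.0], [1000.0 / 0.5, 1000.0 / 4.25])
        assert fit.r1_per_mM_per_s == pytest.approx(3.75, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_slope_within_10_percent_over_repeats(self, rng):
        conc = np.linspace(0, 0.7, 8)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            r1 = 0.4 + 3.75 * conc
            r1_noisy = r1 * (1 + rng.normal(0, 0.02, r1.shape))
            fit = fit_relaxivity(conc, 1000.0 / r1_noisy)
            hits += abs(fit.r1_per_mM_per_s - 3.75) / 3.75 < 0.10
        assert hits == n_rep

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_relaxivity([0.5, 0.5, 0.5], [1000.0, 900.0, 800.0])

    def test_nonpositive_t1_rejected(self):
        with pytest.raises(ValueError):
            fit_relaxivity([0.0, 0.5], [1000.0, -100.0])


class TestT1Enhancement:
    def _map(self, t1_value, shape=(2, 2, 2)):
        from voxreflect.relaxometry import T1Map

        arr = np.full(shape, float(t1_value))
        return T1Map(arr, np.ones(shape), np.zeros(shape), np.ones(shape, bool))

    def test_identical_maps_zero(self):
        out = t1_enhancement(self._map(1500.0), self._map(1500.0))
        assert out["enhancement_percent"] == pytest.approx(0.0, abs=1e-12)

    def test_halved_t1_doubles_rate(self):
        out = t1_enhancement(self._map(1000.0), self._map(2000.0))
        assert out["enhancement_percent"] == pytest.approx(100.0, abs=1e-9)
        assert out["mode"] == "rates"

    def test_ground_truth_propagation_through_fit(self):
        t1_t = np.full((3, 3, 1), 700.0)
        t1_c = np.full((3, 3, 1), 1400.0)
        s0 = np.full((3, 3, 1), 1000.0)
        ft = fit_t1_map(saturation_series(t1_t, s0, PAPER_TRS), PAPER_TRS)
        fc = fit_t1_map(saturation_series(t1_c, s0, PAPER_TRS), PAPER_TRS)
        out = t1_enhancement(ft, fc)
        expected = (1.0 / 700.0 - 1.0 / 1400.0) / (1.0 / 1400.0) * 100.0
        assert out["enhancement_percent"] == pytest.approx(expected, rel=1e-2)

    def test_empty_overlap_rejected(self):
        a, b = self._map(1000.0), self._map(1000.0)
        b.fit_mask[:] = False
        with pytest.raises(ValueError, match="overlap"):
            t1_enhancement(a, b)
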