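"""Calibration, age-depth inference, rate profiling and peat-loss arithmetic."""

import numpy as np
import pytest

from ghostpeat.chronology import (
    AgeDepthConfig,
    CalibrationCurve,
    ProxySeries,
    RadiocarbonDate,
    RateInterval,
    RateProfile,
    calibrate_date,
    detect_ghost,
    fit_age_depth,
    fraction_offset,
    mix_calibration_curves,
    peat_loss,
    proxy_envelope,
    rate_profile,
    restore_depths,
    scan_ghost_breakpoints,
)
from ghostpeat.synthetic import synth_curve


def linear_curve(sigma=20.0, lo=0.0, hi=10000.0, step=5.0):
    cal = np.arange(lo, hi + step / 2, step)
    return CalibrationCurve(cal, cal.copy(), np.full_like(cal, sigma))


# ---------------------------------------------------------------------------
# Curve mixing
# ---------------------------------------------------------------------------


class TestMixCurves:
    def test_identical_curves_are_a_fixed_point(self):
        c = linear_curve()
        m = mix_calibration_curves(c, c, 0.5)
        np.testing.assert_allclose(m.c14_age, np.interp(m.cal_age, c.cal_age, c.c14_age))
        np.testing.assert_allclose(m.sigma, 20.0)

    def test_degenerate_weight_returns_first_curve(self):
        a = linear_curve()
        b = CalibrationCurve(a.cal_age, a.c14_age + 300.0, a.sigma)
        m = mix_calibration_curves(a, b, 1.0)
        np.testing.assert_allclose(m.c14_age, a.c14_age)
        np.testing.assert_allclose(m.sigma, a.sigma)

    def test_mixture_moments_match_closed_form(self):
        # mu_a=1000, mu_b=1100, sigma=20 each, w=0.5:
        # mu = 1050; var = 0.5*400 + 0.5*400 + 0.25*100^2 = 2900
        cal = np.array([0.0, 1.0])
        a = CalibrationCurve(cal, np.full(2, 1000.0), np.full(2, 20.0))
        b = CalibrationCurve(cal, np.full(2, 1100.0), np.full(2, 20.0))
        m = mix_calibration_curves(a, b, 0.5)
        np.testing.assert_allclose(m.c14_age, 1050.0)
        np.testing.assert_allclose(m.sigma, np.sqrt(2900.0))

    def test_mixture_moments_match_monte_carlo(self, rng):
        a = CalibrationCurve([0.0, 1.0], [1000.0, 1000.0], [20.0, 20.0])
        b = CalibrationCurve([0.0, 1.0], [1100.0, 1100.0], [35.0, 35.0])
        w = 0.3
        m = mix_calibration_curves(a, b, w)
        n = 100_000
        comp = rng.random(n) < w
        draws = np.where(
            comp, rng.normal(1000.0, 20.0, n), rng.normal(1100.0, 35.0, n)
        )
        se_mean = draws.std() / np.sqrt(n)
        assert abs(draws.mean() - m.c14_age[0]) < 3 * se_mean
        se_sd = draws.std() / np.sqrt(2 * (n - 1))
        assert abs(draws.std(ddof=1) - m.sigma[0]) < 3 * se_sd

    def test_disjoint_ranges_raise_with_gap_named(self):
        a = linear_curve(lo=0.0, hi=100.0)
        b = linear_curve(lo=200.0, hi=300.0)
        with pytest.raises(ValueError, match="overlap"):
            mix_calibration_curves(a, b, 0.5)

    def test_invalid_weight_rejected(self):
        c = linear_curve()
        with pytest.raises(ValueError):
            mix_calibration_curves(c, c, 1.5)


# ---------------------------------------------------------------------------
# Single-date calibration
# ---------------------------------------------------------------------------


class TestCalibrateDate:
    def test_identity_curve_gives_normal_posterior(self):
        curve = CalibrationCurve(
            np.arange(0.0, 3000.0, 1.0),
            np.arange(0.0, 3000.0, 1.0),
            np.full(3000, 1e-6),
        )
        post = calibrate_date(RadiocarbonDate(10.0, 1000.0, 50.0), curve)
        expected = np.exp(-0.5 * ((post["cal_age"] - 1000.0) / 50.0) ** 2)
        expected /= np.trapezoid(expected, post["cal_age"])
        np.testing.assert_allclose(post["density"], expected, atol=1e-9)

    def test_posterior_normalizes_to_one(self):
        curve = synth_curve(cal_max=5000.0, seed=1)
        post = calibrate_date(RadiocarbonDate(50.0, 2200.0, 40.0), curve)
        assert abs(np.trapezoid(post["density"], post["cal_age"]) - 1.0) < 1e-9

    def test_matches_fine_grid_oracle(self):
        # brute-force evaluation on a 10x-denser grid, renormalised
        curve = synth_curve(cal_max=4000.0, seed=3, step=10.0, wiggle_amp=0.5)
        date = RadiocarbonDate(50.0, 1800.0, 35.0)
        post = calibrate_date(date, curve)
        fine_cal = np.linspace(curve.cal_age[0], curve.cal_age[-1], 10 * len(curve.cal_age))
        mu, sig = curve.interp(fine_cal)
        s2 = date.error**2 + sig**2
        dens = np.exp(-0.5 * (date.c14_age - mu) ** 2 / s2) / np.sqrt(s2)
        norm = np.trapezoid(dens, fine_cal)
        mu_n, sig_n = curve.interp(post["cal_age"].to_numpy())
        s2_n = date.error**2 + sig_n**2
        oracle = np.exp(-0.5 * (date.c14_age - mu_n) ** 2 / s2_n) / np.sqrt(s2_n) / norm
        np.testing.assert_allclose(post["density"], oracle, atol=1e-6)

    def test_date_outside_support_rejected(self):
        curve = linear_curve(lo=0.0, hi=1000.0)
        with pytest.raises(ValueError, match="outside"):
            calibrate_date(RadiocarbonDate(10.0, 50000.0, 30.0), curve)


# ---------------------------------------------------------------------------
# Fraction offsets and depth restoration
# ---------------------------------------------------------------------------


class TestFractionOffset:
    def test_single_pair_offset_and_propagated_error(self):
        # coarse root-bearing fraction younger than fine: offset 670 +/- 150
        coarse = RadiocarbonDate(296.5, 4330.0, 112.0, fraction="coarse")
        fine = RadiocarbonDate(296.5, 5000.0, 100.0, fraction="fine")
        mean, sd = fraction_offset([(coarse, fine)])
        assert mean == pytest.approx(670.0)
        assert sd == pytest.approx(150.0, abs=0.2)

    def test_identical_dates_give_zero_with_sqrt2_error(self):
        d = RadiocarbonDate(10.0, 3000.0, 50.0)
        mean, sd = fraction_offset([(d, d)])
        assert mean == 0.0
        assert sd == pytest.approx(np.sqrt(2) * 50.0)

    def test_simulated_offset_recovered_within_two_se(self, rng):
        true_offset, sigma, n = 500.0, 60.0, 12
        pairs = []
        for i in range(n):
            base = rng.uniform(2000, 8000)
            coarse = RadiocarbonDate(float(i), base + rng.normal(0, sigma), sigma)
            fine = RadiocarbonDate(float(i), base + true_offset + rng.normal(0, sigma), sigma)
            pairs.append((coarse, fine))
        mean, se = fraction_offset(pairs)
        assert abs(mean - true_offset) < 2 * se

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fraction_offset([])


class TestRestoreDepths:
    def test_linear_rescale_of_compacted_drive(self):
        # 50-cm drive recovering 45 cm: the bottom sample restores to +50
        sections = [(100.0, 50.0, 45.0)]
        np.testing.assert_allclose(restore_depths(sections, [(0, 45.0)]), [150.0])

    def test_full_recovery_is_identity_and_zero_offset_maps_to_top(self):
        sections = [(0.0, 50.0, 50.0)]
        np.testing.assert_allclose(
            restore_depths(sections, [(0, 0.0), (0, 33.0)]), [0.0, 33.0]
        )

    def test_offset_beyond_recovered_length_rejected(self):
        with pytest.raises(ValueError):
            restore_depths([(0.0, 50.0, 45.0)], [(0, 46.0)])


# ---------------------------------------------------------------------------
# Bayesian age-depth model
# ---------------------------------------------------------------------------


class TestFitAgeDepth:
    def test_linear_truth_recovered(self):
        """8 noisy dates on a 10 yr/cm core: truth inside the 95% band."""
        curve = linear_curve(sigma=5.0, hi=3000.0)
        rng = np.random.default_rng(11)
        depths = np.linspace(20, 200, 8)
        truth = 10.0 * depths
        dates = [
            RadiocarbonDate(d, t + rng.normal(0, 30.0), 30.0)
            for d, t in zip(depths, truth)
        ]
        cfg = AgeDepthConfig(section_thickness=10.0, n_iter=3000, burn=800, seed=1)
        model = fit_age_depth(dates, curve, top_age=0.0, config=cfg)
        s = model.summaries
        true_grid = 10.0 * s["depth"].to_numpy()
        covered = (true_grid >= s["lo95"]) & (true_grid <= s["hi95"])
        assert covered.mean() >= 0.90
        inside_band = (s["median"] >= s["lo95"]) & (s["median"] <= s["hi95"])
        assert inside_band.all()

    def test_noise_free_dates_give_true_slope(self):
        curve = linear_curve(sigma=1.0, hi=3000.0)
        depths = np.linspace(10, 200, 10)
        dates = [RadiocarbonDate(d, 10.0 * d, 5.0) for d in depths]
        cfg = AgeDepthConfig(section_thickness=10.0, n_iter=3000, burn=800, seed=2)
        model = fit_age_depth(dates, curve, top_age=0.0, config=cfg)
        net_slope = (
            np.median(model.ages_at([200.0])) - np.median(model.ages_at([0.0]))
        ) / 200.0
        assert net_slope == pytest.approx(10.0, rel=0.05)

    def test_draws_monotone_even_for_reversed_ages(self):
        """Age reversals cannot break monotonicity: alpha_j > 0 by construction."""
        curve = linear_curve(sigma=5.0, hi=5000.0)
        dates = [
            RadiocarbonDate(50.0, 2000.0, 40.0),
            RadiocarbonDate(100.0, 1500.0, 40.0),  # reversed
            RadiocarbonDate(150.0, 2500.0, 40.0),
        ]
        cfg = AgeDepthConfig(section_thickness=25.0, n_iter=1500, burn=400, seed=3)
        model = fit_age_depth(dates, curve, config=cfg)
        ages = model.ages_at(np.linspace(0, 150, 31))
        assert (np.diff(ages, axis=1) > 0).all()

    def test_fewer_than_three_dates_rejected(self):
        curve = linear_curve()
        with pytest.raises(ValueError):
            fit_age_depth([RadiocarbonDate(10.0, 100.0, 10.0)], curve)


# ---------------------------------------------------------------------------
# Rate profiles, ghost detection and peat loss
# ---------------------------------------------------------------------------


def profile_from_rates(rates):
    edges = np.arange(len(rates) + 1) * 100.0
    return RateProfile(
        [
            RateInterval(edges[i], edges[i + 1], r, 0.05)
            for i, r in enumerate(rates)
        ]
    )


class TestGhostDetection:
    def test_study_geometry_rates_flag_middle_interval(self):
        profile = profile_from_rates([0.50, 0.09, 0.74])
        flagged = detect_ghost(profile, 5.0)
        assert flagged is profile.intervals[1]
        assert 0.50 / 0.09 == pytest.approx(5.6, abs=0.05)
        assert 0.74 / 0.09 == pytest.approx(8.2, abs=0.05)

    def test_uniform_rates_flag_nothing(self):
        assert detect_ghost(profile_from_rates([0.5, 0.5, 0.5]), 5.0) is None

    def test_sub_threshold_contrast_not_flagged(self):
        assert detect_ghost(profile_from_rates([0.5, 0.2, 0.74]), 5.0) is None

    def test_needs_three_intervals(self):
        with pytest.raises(ValueError):
            detect_ghost(profile_from_rates([0.5, 0.1]), 5.0)


class TestRateProfile:
    def test_recovers_generator_rates(self, world, age_model):
        prof = rate_profile(age_model, [world.ghost_top, world.ghost_bottom])
        recovered = prof.rates
        truth = np.array([world.rate_above, world.rate_ghost, world.rate_below])
        # within a generous multiple of the posterior sd (memory-prior smoothing
        # biases section rates slightly toward their neighbours)
        sds = np.array([iv.rate_sd for iv in prof.intervals])
        assert np.all(np.abs(recovered - truth) < np.maximum(10 * sds, 0.25 * truth))

    def test_whole_core_interval_equals_net_rate(self, age_model):
        mid = 0.5 * (age_model.depth_top + age_model.depth_bottom)
        prof = rate_profile(age_model, [mid])
        ages = np.median(
            age_model.ages_at([age_model.depth_top, age_model.depth_bottom]), axis=0
        )
        net = (age_model.depth_bottom - age_model.depth_top) * 10.0 / (ages[1] - ages[0])
        thick = np.array([iv.depth_bottom - iv.depth_top for iv in prof.intervals])
        durations = thick * 10.0 / prof.rates
        combined = thick.sum() * 10.0 / durations.sum()
        assert combined == pytest.approx(net, rel=1e-6)

    def test_scan_finds_ghost_without_given_breakpoints(self, world, age_model):
        top, bottom = scan_ghost_breakpoints(age_model)
        assert abs(top - world.ghost_top) <= 20.0
        assert abs(bottom - world.ghost_bottom) <= 20.0


class TestPeatLoss:
    def test_worked_examples(self):
        assert peat_loss(0.50, 5500.0, 390.0) == pytest.approx(2.36)
        assert peat_loss(0.74, 5500.0, 390.0) == pytest.approx(3.68)

    def test_no_net_loss_floors_at_zero(self):
        assert peat_loss(0.5, 1000.0, 500.0) == 0.0

    def test_linear_in_rate_and_duration(self, rng):
        r, T, rem = rng.uniform(0.1, 1.0), rng.uniform(1000, 9000), 1.0
        base = peat_loss(r, T, rem)
        assert peat_loss(2 * r, T, rem) + rem / 1000 == pytest.approx(2 * (base + rem / 1000))
        assert peat_loss(r, 2 * T, rem) + rem / 1000 == pytest.approx(2 * (base + rem / 1000))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            peat_loss(0.0, 100.0, 10.0)


# ---------------------------------------------------------------------------
# Proxy envelopes
# ---------------------------------------------------------------------------


class TestProxyEnvelope:
    def test_zero_noise_single_draw_collapses(self, age_model):
        from ghostpeat.chronology import AgeDepthModel

        one = AgeDepthModel(
            section_edges=age_model.section_edges,
            x0=age_model.x0[:1],
            alpha=age_model.alpha[:1],
            w=age_model.w[:1],
        )
        series = ProxySeries(
            depth=np.linspace(10, 290, 15),
            value=np.sin(np.linspace(0, 3, 15)),
            analytical_sd=np.zeros(15),
        )
        env = proxy_envelope(series, one, n_draws=200, seed=0)
        np.testing.assert_allclose(env["lo95"], env["hi95"], atol=1e-12)
        np.testing.assert_allclose(env["median"], env["lo68"], atol=1e-12)

    def test_bands_nest(self, age_model):
        series = ProxySeries(
            depth=np.linspace(10, 290, 20),
            value=np.linspace(-160, -150, 20),
            analytical_sd=np.full(20, 2.0),
        )
        env = proxy_envelope(series, age_model, n_draws=300, seed=1)
        assert (env["lo95"] <= env["lo68"]).all()
        assert (env["hi68"] <= env["hi95"]).all()
        assert ((env["lo68"] <= env["median"]) & (env["median"] <= env["hi68"])).all()

    def test_true_signal_inside_95_band(self, world, age_model):
        depths = np.linspace(10, 290, 25)
        true_vals = world.true_dD(world.true_age(depths))
        rng = np.random.default_rng(5)
        series = ProxySeries(
            depth=depths, value=true_vals + rng.normal(0, 2.0, depths.size),
            analytical_sd=np.full(depths.size, 2.0),
        )
        env = proxy_envelope(series, age_model, n_draws=400, seed=2)
        truth_on_grid = world.true_dD(env["age"].to_numpy())
        inside = (truth_on_grid >= env["lo95"]) & (truth_on_grid <= env["hi95"])
        assert inside.mean() >= 0.90

    def test_small_n_draws_warns(self, age_model):
        series = ProxySeries(depth=[50.0, 100.0, 200.0], value=[1.0, 2.0, 3.0],
                             analytical_sd=[0.1, 0.1, 0.1])
        with pytest.warns(UserWarning, match="n_draws"):
            proxy_envelope(series, age_model, n_draws=10, seed=0)
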