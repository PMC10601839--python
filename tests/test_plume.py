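"""Plume simulator: puff kinetics, wind schedules, concentration sampling
and centreline geometry."""

import math

import numpy as np
import pytest
from scipy.stats import binomtest

from plumetrack.plume import (NO_CENTRELINE, PlumeConfig, PlumeSimulator,
                              Puff, WindSchedule, config_for_regime,
                              emit_puffs, local_centreline_angle,
                              sample_concentration, step_puff,
                              wind_direction)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PlumeConfig(birth_rate=-1.0)
        with pytest.raises(ValueError):
            PlumeConfig(dt_sim=0.0)
        with pytest.raises(ValueError):
            PlumeConfig(r0=0.0)

    def test_default_arena_area_is_120_m2(self):
        assert PlumeConfig().arena_area == pytest.approx(120.0)

    def test_regime_folds(self):
        assert config_for_regime("sparse").birth_fold == 0.4
        sparser = config_for_regime("sparser")
        assert sparser.birth_fold == 0.4 and sparser.diffusion_fold == 0.5
        with pytest.raises(ValueError):
            config_for_regime("windy")


class TestEmission:
    def test_zero_birth_rate_emits_nothing(self):
        cfg = PlumeConfig(birth_rate=0.0)
        rng = np.random.default_rng(0)
        assert all(len(emit_puffs(cfg, rng)) == 0 for _ in range(100))

    def test_baseline_birth_mean_matches_poisson_rate(self):
        # 10,000 iterations: sample mean within 3 standard errors of 1.0
        sim = PlumeSimulator(PlumeConfig(), seed=42)
        births = []
        for _ in range(10_000):
            sim.step()
            births.append(sim.last_births)
        mean = np.mean(births)
        se = np.std(births, ddof=1) / math.sqrt(len(births))
        assert abs(mean - 1.0) < 3 * se

    def test_sparse_birth_ratio(self):
        counts = {}
        for regime in ("constant", "sparse"):
            sim = PlumeSimulator(config_for_regime(regime), seed=7)
            total = 0
            for _ in range(10_000):
                sim.step()
                total += sim.last_births
            counts[regime] = total
        ratio = counts["sparse"] / counts["constant"]
        assert ratio == pytest.approx(0.4, rel=0.05)


class TestPuffKinetics:
    def test_radius_and_concentration_closed_form(self):
        # r grows linearly; after 1 s, r doubles and c falls 8-fold
        cfg = PlumeConfig()
        p = Puff(0.0, 0.0, cfg.r0, cfg.c0, 0.0, is_centreline=True)
        for _ in range(100):
            p = step_puff(p, (0.0, 0.0), cfg)
        assert p.radius == pytest.approx(0.02)
        assert p.concentration == pytest.approx(cfg.c0 / 8.0)

    def test_centreline_advection_is_exact(self):
        cfg = PlumeConfig()
        p = Puff(0.0, 0.0, cfg.r0, cfg.c0, 0.0, is_centreline=True)
        for _ in range(100):
            p = step_puff(p, (0.5, 0.0), cfg)
        assert p.x == pytest.approx(0.5)
        assert p.y == 0.0

    def test_crosswind_velocity_sd(self):
        # empirical sd of the per-iteration velocity perturbation ~ 0.005
        sim = PlumeSimulator(PlumeConfig(), seed=3)
        sim.run(1.0)  # populate
        draws = []
        for _ in range(10_000):
            sim.step()
            draws.append(sim.last_noise_velocities)
        sd = np.concatenate(draws).std()
        assert sd == pytest.approx(0.005, rel=0.05)

    def test_mass_conservation_and_monotonicity(self):
        # c * r^3 invariant at machine precision; r increases, c decreases
        sim = PlumeSimulator(PlumeConfig(), seed=1)
        sim.run(3.0)
        cfg = sim.config
        np.testing.assert_allclose(sim.concentration * sim.r ** 3,
                                   cfg.c0 * cfg.r0 ** 3, rtol=1e-12)
        r_before = sim.r.copy()
        c_before = sim.concentration.copy()
        n = r_before.size
        sim.step()
        assert np.all(sim.r[:n] > r_before)
        assert np.all(sim.concentration[:n] < c_before)

    def test_sparser_growth_rate_is_half_baseline(self):
        slopes = {}
        for regime in ("constant", "sparser"):
            cfg = config_for_regime(regime)
            p = Puff(0.0, 0.0, cfg.r0, cfg.c0, 0.0, is_centreline=True)
            t, radii = [0.0], [p.radius]
            for i in range(500):
                p = step_puff(p, (0.5, 0.0), cfg)
                t.append((i + 1) * cfg.dt_sim)
                radii.append(p.radius)
            slopes[regime] = np.polyfit(t, radii, 1)[0]
        assert slopes["constant"] == pytest.approx(0.01, rel=1e-9)
        assert slopes["sparser"] / slopes["constant"] == pytest.approx(0.5)


class TestWindSchedules:
    def test_constant_regimes_return_zero(self):
        for regime in ("constant", "sparse", "sparser"):
            sched = WindSchedule(regime)
            assert all(wind_direction(t, sched) == 0.0
                       for t in (0.0, 5.0, 100.0))

    def test_switch_once(self):
        sched = WindSchedule("switch-once", switch_time=10.0)
        assert sched.direction(9.99) == 0.0
        assert sched.direction(10.0) == 45.0
        assert sched.direction(500.0) == 45.0

    def test_switch_many_increments_and_spacing(self):
        sched = WindSchedule("switch-many", seed=5)
        inc = sched.increments(10_000)
        assert np.max(np.abs(inc)) <= 60.0
        times = sched.event_times(1000.0)
        intervals = np.diff(np.concatenate([[0.0], times]))
        assert np.mean(intervals) == pytest.approx(3.0, rel=0.1)

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            WindSchedule("gusty")


class TestConcentrationSampling:
    def test_no_puffs_gives_zero(self):
        sim = PlumeSimulator(PlumeConfig(birth_rate=0.0), seed=0)
        sim.run(1.0)
        assert sim.sample_concentration((1.0, 0.0)) == 0.0

    def test_superposition_matches_brute_force(self):
        # vectorized sampling == exhaustive loop over all covering puffs
        sim = PlumeSimulator(PlumeConfig(), seed=9)
        sim.run(10.0)
        fr = sim.frame()
        rng = np.random.default_rng(2)
        for _ in range(20):
            pt = (rng.uniform(0, 5), rng.uniform(-0.3, 0.3))
            brute = sum(
                c for x, y, r, c in zip(fr.x, fr.y, fr.radius,
                                        fr.concentration)
                if (x - pt[0]) ** 2 + (y - pt[1]) ** 2 <= r ** 2)
            assert sim.sample_concentration(pt) == pytest.approx(brute)

    def test_single_covering_puff_returns_its_concentration(self):
        fr = PlumeSimulator(PlumeConfig(birth_rate=0.0), seed=0).frame()
        fr.x = np.array([1.0])
        fr.y = np.array([0.0])
        fr.radius = np.array([0.1])
        fr.concentration = np.array([0.25])
        assert sample_concentration((1.05, 0.0), fr) == pytest.approx(0.25)
        assert sample_concentration((2.0, 0.0), fr) == 0.0

    def test_crosswind_profile_symmetric_about_centreline(self):
        # time-averaged cross-wind mass at fixed x is symmetric about y=0:
        # two-sided sign test on per-frame left/right mass differences
        sim = PlumeSimulator(PlumeConfig(), seed=13)
        sim.run(20.0)
        ys = np.linspace(-0.3, 0.3, 31)
        signs = []
        profile = np.zeros(ys.size)
        for _ in range(240):
            for _ in range(25):
                sim.step()
            conc = np.array([sim.sample_concentration((2.0, y)) for y in ys])
            profile += conc
            d = conc[ys < 0].sum() - conc[ys > 0].sum()
            if d != 0:
                signs.append(d > 0)
        k = int(np.sum(signs))
        assert binomtest(k, len(signs), 0.5).pvalue > 0.01
        # unimodal: the peak sits at the centre of the time-averaged profile
        assert abs(ys[np.argmax(profile)]) <= 0.05


class TestCentreline:
    def test_centreline_is_deterministic_integral_of_wind(self):
        # noiseless puffs advect exactly along the wind schedule
        sim = PlumeSimulator(PlumeConfig(), WindSchedule("constant"), seed=4)
        sim.run(5.0)
        np.testing.assert_array_equal(sim.cy, np.zeros_like(sim.cy))
        expected_x = (sim.t - sim.cbirth - sim.config.dt_sim) * 0.5
        np.testing.assert_allclose(sim.cx, expected_x, atol=1e-12)

    def test_constant_wind_angle_is_zero_everywhere(self):
        sim = PlumeSimulator(PlumeConfig(), WindSchedule("constant"), seed=4)
        sim.run(6.0)
        for x in (0.5, 1.0, 2.0):
            assert sim.local_centreline_angle(x) == pytest.approx(0.0,
                                                                  abs=1e-9)

    def test_empty_band_returns_sentinel(self):
        sim = PlumeSimulator(PlumeConfig(), WindSchedule("constant"), seed=4)
        sim.run(2.0)  # centreline reaches x ~ 1 m
        assert math.isnan(sim.local_centreline_angle(5.0))

    def test_switch_once_post_switch_segment_is_45_degrees(self):
        # simulate noiseless puffs through the switch and measure the angle
        sched = WindSchedule("switch-once", switch_time=5.0)
        sim = PlumeSimulator(PlumeConfig(), sched, seed=4)
        sim.run(9.0)
        # puffs emitted after the switch advect at 45 deg from the origin;
        # that segment spans x in (0, 4 s * 0.5 m/s * cos 45)
        ang = sim.local_centreline_angle(0.7)
        assert ang == pytest.approx(45.0, abs=1.0)
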