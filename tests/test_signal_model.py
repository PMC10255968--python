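"""Generator contracts: stage phenomenology, determinism, ground truth."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ethylene_kinetics.signal_model import (ConfigurationError, CycleConfig,
                                            RipeningTableConfig,
                                            RipeningTrajectoryConfig,
                                            SensorTrace, cycle_curve,
                                            default_ripening_trajectory_config,
                                            demo_cycle_config,
                                            generate_cycle,
                                            generate_cycle_ensemble,
                                            generate_ripening_table,
                                            generate_ripening_trajectory,
                                            ripening_curve)


class TestSensorTrace:
    def test_rejects_non_uniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            SensorTrace(np.array([0.0, 1.0, 3.0]), np.zeros(3), 0.5, 2.5)

    def test_rejects_markers_outside_range(self):
        with pytest.raises(ValueError, match="inside the time range"):
            SensorTrace(np.arange(5.0), np.zeros(5), 1.0, 9.0)

    def test_rejects_inverted_markers(self):
        with pytest.raises(ValueError, match="precede"):
            SensorTrace(np.arange(5.0), np.zeros(5), 3.0, 1.0)


class TestGenerateCycle:
    def test_demo_curve_hits_published_levels(self, demo_cycle):
        """Maximum 20.4 ppm; plateau settles to within 0.01 of 20.15 ppm."""
        trace, truth = demo_cycle
        assert trace.values.max() == pytest.approx(20.4, abs=1e-9)
        s3_end = trace.values[trace.index_at(trace.gas_out) - 1]
        assert abs(s3_end - 20.15) < 0.01

    def test_zero_config_gives_flat_zero_trace(self):
        cfg = dataclasses.replace(demo_cycle_config(), plateau_ppm=0.0,
                                  overshoot_ppm=0.0)
        trace, _ = generate_cycle(cfg)
        assert np.all(trace.values == 0.0)

    def test_same_seed_bit_identical(self):
        cfg = dataclasses.replace(demo_cycle_config(), noise_sd=0.3, seed=42)
        t1, _ = generate_cycle(cfg)
        t2, _ = generate_cycle(cfg)
        assert np.array_equal(t1.values, t2.values)

    def test_invalid_durations_rejected(self):
        with pytest.raises(ConfigurationError):
            CycleConfig(stage_durations=(60.0, -1.0, 330.0, 60.0, 120.0, 240.0))
        with pytest.raises(ConfigurationError):
            CycleConfig(sample_interval=0.0)

    def test_plateau_stays_within_overshoot_noise_band(self):
        cfg = CycleConfig(noise_sd=0.1, seed=5)
        trace, truth = generate_cycle(cfg)
        t = trace.times
        s3 = (t >= truth.stage_bounds[2][0]) & (t < truth.stage_bounds[2][1])
        band = cfg.overshoot_ppm + 3 * cfg.noise_sd
        assert np.all(np.abs(trace.values[s3] - cfg.plateau_ppm) <= band + 1e-9)

    def test_ground_truth_matches_config(self):
        cfg = CycleConfig(noise_sd=0.0)
        _, truth = generate_cycle(cfg)
        assert truth.xa == cfg.baseline_ppm
        assert truth.xg == cfg.plateau_ppm
        assert truth.xm == cfg.plateau_ppm + cfg.overshoot_ppm
        starts = [a for a, _ in truth.stage_bounds]
        assert starts == sorted(starts)
        assert truth.stage_bounds[1][0] == cfg.gas_in
        assert truth.stage_bounds[3][0] == cfg.gas_out


class TestCycleEnsemble:
    def test_zero_cv_and_noise_gives_identical_cycles(self):
        cfg = dataclasses.replace(demo_cycle_config(), noise_sd=0.0)
        ens = generate_cycle_ensemble(cfg, 4, between_cycle_cv=0.0)
        ref = ens[0][0].values
        assert all(np.array_equal(tr.values, ref) for tr, _ in ens[1:])

    def test_single_cycle_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cycle_ensemble(CycleConfig(), 1)
        with pytest.raises(ConfigurationError):
            generate_cycle_ensemble(CycleConfig(), 5, between_cycle_cv=-1.0)

    def test_plateau_dispersion_matches_requested_cv(self):
        """Sample CV of the true per-cycle plateau lands in a band around
        the requested 2.4% at n=10 (stochastic, fixed seed)."""
        cfg = dataclasses.replace(CycleConfig(), noise_sd=0.0, seed=11)
        ens = generate_cycle_ensemble(cfg, 10, between_cycle_cv=2.4)
        plateaus = np.array([truth.xg for _, truth in ens])
        cv = 100 * plateaus.std(ddof=1) / plateaus.mean()
        assert 1.0 <= cv <= 4.0

    def test_ensemble_deterministic(self):
        ens1 = generate_cycle_ensemble(CycleConfig(seed=3), 3)
        ens2 = generate_cycle_ensemble(CycleConfig(seed=3), 3)
        for (t1, _), (t2, _) in zip(ens1, ens2):
            assert np.array_equal(t1.values, t2.values)


class TestRipeningTrajectory:
    def test_derivative_minima_fall_in_decline_windows(self):
        cfg = dataclasses.replace(default_ripening_trajectory_config(),
                                  noise_sd=0.0)
        trace = generate_ripening_trajectory(cfg)
        d = np.gradient(trace.values, trace.dt)
        t = trace.times
        early = t <= 1500
        t_min1 = t[early][np.argmin(d[early])]
        assert 600 <= t_min1 <= 700
        late = t >= 1500
        t_min2 = t[late][np.argmin(d[late])]
        assert 2200 <= t_min2 <= 2400

    def test_zero_peak_gives_flat_zero(self):
        cfg = dataclasses.replace(RipeningTrajectoryConfig(), peak_ppm=0.0,
                                  noise_sd=0.0)
        trace = generate_ripening_trajectory(cfg)
        assert np.all(trace.values == 0.0)

    def test_trapezoid_integral_matches_fine_riemann(self):
        """Numeric trapezoid on the 1-min grid vs a midpoint Riemann sum at
        10x resolution of the closed-form curve."""
        cfg = dataclasses.replace(default_ripening_trajectory_config(),
                                  noise_sd=0.0)
        trace = generate_ripening_trajectory(cfg)
        coarse = np.trapezoid(trace.values, trace.times)
        fine_dt = cfg.sample_interval / 10.0
        mids = np.arange(fine_dt / 2, cfg.duration, fine_dt)
        riemann = float(np.sum(ripening_curve(cfg, mids)) * fine_dt)
        assert abs(coarse - riemann) / riemann < 1e-3

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            RipeningTrajectoryConfig(decline1_window=(600.0, 2300.0),
                                     decline2_window=(2200.0, 2400.0))


class TestRipeningTable:
    def test_zero_sd_reproduces_configured_factor_arithmetic(self):
        cfg = RipeningTableConfig(rel_sd=0.0)
        cfg = dataclasses.replace(cfg, factors={
            **cfg.factors, "hardness": (0.115, 0.247, 0.2, 0.5)})
        table = generate_ripening_table(cfg)
        day1 = table[(table.group == "A") & (table.day == "day1")].hardness
        day2 = table[(table.group == "A") & (table.day == "day2")].hardness
        assert day1.iloc[0] == pytest.approx(9234.093 * 0.115, abs=0.01)  # 1061.92 g
        assert day2.iloc[0] == pytest.approx(9234.093 * 0.115 * 0.247, abs=0.01)

    def test_unit_factors_mean_no_change(self):
        cfg = RipeningTableConfig(rel_sd=0.0)
        cfg = dataclasses.replace(
            cfg, factors={m: (1.0, 1.0, 1.0, 1.0) for m in cfg.factors})
        table = generate_ripening_table(cfg)
        for m in ("hardness", "chewiness"):
            assert table[m].nunique() == 1

    def test_same_seed_identical_table(self):
        t1 = generate_ripening_table(RipeningTableConfig(seed=9))
        t2 = generate_ripening_table(RipeningTableConfig(seed=9))
        assert t1.equals(t2)

    def test_invalid_factor_rejected(self):
        cfg = RipeningTableConfig()
        with pytest.raises(ConfigurationError):
            dataclasses.replace(cfg, factors={
                **cfg.factors, "hardness": (1.5, 0.2, 0.2, 0.5)})
        with pytest.raises(ConfigurationError):
            # treated group must not soften slower than the control
            dataclasses.replace(cfg, factors={
                **cfg.factors, "hardness": (0.5, 0.5, 0.2, 0.5)})


@given(st.floats(min_value=5.0, max_value=60.0))
def test_rise_is_monotone_in_time_constant(rise_tau):
    """A slower rise never overtakes a faster one during stage 2."""
    base = dataclasses.replace(demo_cycle_config(), rise_tau=rise_tau)
    faster = dataclasses.replace(base, rise_tau=rise_tau * 0.8)
    t = np.linspace(base.gas_in, base.gas_in + base.stage_durations[1], 50,
                    endpoint=False)
    assert np.all(cycle_curve(faster, t) >= cycle_curve(base, t) - 1e-12)
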