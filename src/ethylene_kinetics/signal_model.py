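"""Synthetic ethylene-sensor signal models.

This module generates the three kinds of data the analysis pipeline consumes:

* single response/recovery cycles of an electrochemical ethylene sensor,
  built from a six-stage phenomenological model (air baseline, rapid rise,
  dynamically stable plateau, rapid decline, slow recovery tail, final
  recovery);
* ensembles of repeated cycles with realistic cycle-to-cycle dispersion,
  emulating a repeatability experiment (ten-odd cycles at a fixed nominal
  concentration);
* day-scale ethylene emission trajectories of climacteric fruit during
  postharvest ripening (rise to a climacteric peak followed by a decline
  with two accelerated-decline phases), plus texture-analyzer ripening
  tables for an ethylene-treated group A and an air-control group B.

Every generator is deterministic for a fixed seed and returns the ground
truth used to build the signal, so downstream extraction code can be tested
for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Core trace container
# ---------------------------------------------------------------------------


@dataclass
class SensorTrace:
    """A uniformly sampled concentration time series with gas event markers.

    ``times`` and ``values`` are equal-length arrays; ``gas_in``/``gas_out``
    mark when the target gas entered and left the chamber (for continuous
    monitoring records they span the whole trace).  ``meta`` carries
    free-form labels such as the gas name, the nominal concentration and
    the time unit ('s' or 'min').
    """

    times: np.ndarray
    values: np.ndarray
    gas_in: float
    gas_out: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-9:
            raise ValueError("times must form a uniform grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not (self.gas_in < self.gas_out):
            raise ValueError("gas_in must precede gas_out")
        if self.gas_in < self.times[0] - 1e-9 or self.gas_out > self.times[-1] + 1e-9:
            raise ValueError("gas markers must lie inside the time range")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def index_at(self, t: float) -> int:
        """Index of the grid sample nearest to time ``t``."""
        return int(round((t - self.times[0]) / self.dt))

    def copy_with(self, values: np.ndarray, **meta_updates) -> "SensorTrace":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return SensorTrace(self.times.copy(), np.asarray(values, dtype=float),
                           self.gas_in, self.gas_out, meta)


# ---------------------------------------------------------------------------
# Single-cycle model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleConfig:
    """Parameters of one six-stage sensor response cycle.

    Concentrations are in ppm, times in seconds.  ``stage_durations`` gives
    the construction lengths of the six stages; the gas enters at the end of
    stage 1 and leaves at the end of stage 3.  The rise is a first-order
    exponential normalized so that the curve attains exactly
    ``plateau_ppm + overshoot_ppm`` at the stage-2/3 boundary; during stage 3
    the overshoot relaxes toward the plateau; the recovery is a fast/slow
    double exponential (``tail_weight`` is the slow fraction).
    """

    baseline_ppm: float = 0.388
    plateau_ppm: float = 20.6
    overshoot_ppm: float = 0.9
    rise_tau: float = 23.7
    decay_tau: float = 35.0
    tail_tau: float = 150.0
    tail_weight: float = 0.12
    overshoot_tau: float | None = None  # default: stage-3 duration / 5
    stage_durations: tuple = (60.0, 90.0, 330.0, 60.0, 120.0, 240.0)
    noise_sd: float = 0.2
    drift_rate: float = 0.0
    disturbance_amplitude: float = 0.0
    disturbance_period: float = 60.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    sample_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_durations) != 6 or any(d <= 0 for d in self.stage_durations):
            raise ConfigurationError("stage_durations must be six positive durations")
        if self.sample_interval <= 0:
            raise ConfigurationError("sample_interval must be positive")
        if self.plateau_ppm < self.baseline_ppm or self.baseline_ppm < 0:
            raise ConfigurationError("need plateau_ppm >= baseline_ppm >= 0")
        if self.overshoot_ppm < 0:
            raise ConfigurationError("overshoot_ppm must be >= 0")
        if min(self.rise_tau, self.decay_tau, self.tail_tau) <= 0:
            raise ConfigurationError("time constants must be positive")
        if self.tail_tau <= self.decay_tau:
            raise ConfigurationError("tail_tau must exceed decay_tau (slow tail)")
        if not (0.0 <= self.tail_weight < 1.0):
            raise ConfigurationError("tail_weight must be in [0, 1)")
        if self.noise_sd < 0 or self.spike_rate < 0 or self.spike_rate > 1:
            raise ConfigurationError("noise_sd >= 0 and spike_rate in [0, 1] required")

    @property
    def gas_in(self) -> float:
        return float(self.stage_durations[0])

    @property
    def gas_out(self) -> float:
        return float(sum(self.stage_durations[:3]))

    @property
    def total_duration(self) -> float:
        return float(sum(self.stage_durations))

    @property
    def xm(self) -> float:
        return self.plateau_ppm + self.overshoot_ppm

    @property
    def settle_tau(self) -> float:
        return self.overshoot_tau if self.overshoot_tau is not None else self.stage_durations[2] / 5.0


@dataclass
class CycleGroundTruth:
    """Generating values behind one cycle, for parameter-recovery tests."""

    xa: float
    xg: float
    xm: float
    gas_in: float
    gas_out: float
    stage_bounds: list          # six (start, end) tuples, seconds
    response_time: float        # analytic 70%-of-excursion crossing, from gas_in
    recovery_time: float        # analytic fall to 30% of excursion, from gas_out
    max_rise_slope: float       # analytic maximum first derivative, ppm/s
    clean_values: np.ndarray    # noise/drift/spike-free curve on the grid
    spike_indices: np.ndarray   # indices where spikes were injected


def _rise_fraction(u: np.ndarray | float, tau: float, d2: float):
    """Normalized first-order rise: 0 at u=0, exactly 1 at u=d2."""
    return -np.expm1(-np.asarray(u, dtype=float) / tau) / -math.expm1(-d2 / tau)


def cycle_curve(config: CycleConfig, times: np.ndarray) -> np.ndarray:
    """Noise-free six-stage cycle evaluated at arbitrary times (seconds)."""
    t = np.asarray(times, dtype=float)
    xa, xm, xg = config.baseline_ppm, config.xm, config.plateau_ppm
    d2 = config.stage_durations[1]
    gi, go = config.gas_in, config.gas_out
    t_peak = gi + d2

    v = np.full_like(t, xa)
    rise = (t >= gi) & (t < t_peak)
    v[rise] = xa + (xm - xa) * _rise_fraction(t[rise] - gi, config.rise_tau, d2)
    plateau = (t >= t_peak) & (t < go)
    v[plateau] = xg + (xm - xg) * np.exp(-(t[plateau] - t_peak) / config.settle_tau)

    v_go = xg + (xm - xg) * math.exp(-(go - t_peak) / config.settle_tau)
    rec = t >= go
    u = t[rec] - go
    w = config.tail_weight
    v[rec] = xa + (v_go - xa) * ((1 - w) * np.exp(-u / config.decay_tau)
                                 + w * np.exp(-u / config.tail_tau))
    return v


def _recovery_crossing(config: CycleConfig, frac: float) -> float:
    """Time after gas_out at which the clean curve falls to xa + frac*(xm - xa)."""
    xa, xm = config.baseline_ppm, config.xm
    if xm <= xa:
        return 0.0
    go = config.gas_out
    d2 = config.stage_durations[1]
    v_go = config.plateau_ppm + (xm - config.plateau_ppm) * math.exp(
        -(go - config.gas_in - d2) / config.settle_tau)
    target = frac * (xm - xa) / (v_go - xa)
    w = config.tail_weight

    def f(u: float) -> float:
        return ((1 - w) * math.exp(-u / config.decay_tau)
                + w * math.exp(-u / config.tail_tau) - target)

    hi = sum(config.stage_durations[3:])
    if f(hi) > 0:            # never recovers that far within the trace
        return float(hi)
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def analytic_response_time(config: CycleConfig, frac: float = 0.7) -> float:
    """Time after gas_in at which the clean rise reaches ``frac`` of the excursion."""
    if config.xm <= config.baseline_ppm:
        return 0.0
    d2 = config.stage_durations[1]
    target = frac * -math.expm1(-d2 / config.rise_tau)
    return float(-config.rise_tau * math.log1p(-target))


def rise_tau_for_response_time(t_frac: float, stage2_duration: float,
                               frac: float = 0.7) -> float:
    """Rise time constant giving a ``frac`` crossing ``t_frac`` seconds after gas-in."""

    def f(tau: float) -> float:
        target = frac * -math.expm1(-stage2_duration / tau)
        return -tau * math.log1p(-target) - t_frac

    return float(brentq(f, 1e-3, stage2_duration * 50))


def _stage_bounds(config: CycleConfig) -> list:
    """Ground-truth stage boundaries from the clean curve's threshold crossings.

    Stages follow the operational definition used by the segmentation code:
    S2 ends at the first attainment of 95% of the maximum, S4 at recovery to
    30% of the excursion above baseline, S5 at recovery to 5%.
    """
    xa, xm = config.baseline_ppm, config.xm
    gi, go, end = config.gas_in, config.gas_out, config.total_duration
    t0 = 0.0
    if xm <= xa:
        return [(t0, gi), (gi, gi), (gi, go), (go, go), (go, go), (go, end)]
    d2 = config.stage_durations[1]
    frac95 = (0.95 * xm - xa) / (xm - xa)
    if frac95 <= 0:
        t95 = gi
    else:
        norm = -math.expm1(-d2 / config.rise_tau)
        t95 = gi + (-config.rise_tau * math.log1p(-min(frac95 * norm, 1 - 1e-12)))
        t95 = min(t95, gi + d2)
    t30 = go + _recovery_crossing(config, 0.30)
    t05 = go + _recovery_crossing(config, 0.05)
    return [(t0, gi), (gi, t95), (t95, go), (go, t30), (t30, max(t05, t30)),
            (max(t05, t30), end)]


def generate_cycle(config: CycleConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[SensorTrace, CycleGroundTruth]:
    """Generate one six-stage response cycle plus its ground truth.

    Additive Gaussian noise, linear drift, a sinusoidal disturbance and
    optional sparse spikes are superimposed on the clean piecewise curve.
    Deterministic for a fixed ``config.seed`` (unless an external ``rng``
    is supplied for ensemble use).
    """
    n = int(round(config.total_duration / config.sample_interval)) + 1
    times = np.arange(n) * config.sample_interval
    clean = cycle_curve(config, times)

    rng = np.random.default_rng(config.seed) if rng is None else rng
    values = clean + config.drift_rate * times
    if config.disturbance_amplitude:
        values = values + config.disturbance_amplitude * np.sin(
            2 * np.pi * times / config.disturbance_period)
    if config.noise_sd:
        values = values + rng.normal(0.0, config.noise_sd, size=n)
    spike_idx = np.array([], dtype=int)
    if config.spike_rate > 0 and config.spike_amplitude > 0:
        mask = rng.random(n) < config.spike_rate
        spike_idx = np.flatnonzero(mask)
        signs = rng.choice([-1.0, 1.0], size=spike_idx.size)
        values[spike_idx] += signs * config.spike_amplitude

    trace = SensorTrace(times, values, config.gas_in, config.gas_out,
                        meta={"gas": "C2H4", "nominal_ppm": config.plateau_ppm,
                              "time_unit": "s"})
    d2 = config.stage_durations[1]
    norm = -math.expm1(-d2 / config.rise_tau) if config.rise_tau > 0 else 1.0
    truth = CycleGroundTruth(
        xa=config.baseline_ppm,
        xg=config.plateau_ppm,
        xm=config.xm,
        gas_in=config.gas_in,
        gas_out=config.gas_out,
        stage_bounds=_stage_bounds(config),
        response_time=analytic_response_time(config),
        recovery_time=_recovery_crossing(config, 0.30),
        max_rise_slope=(config.xm - config.baseline_ppm) / (config.rise_tau * norm),
        clean_values=clean,
        spike_indices=spike_idx,
    )
    return trace, truth


def demo_cycle_config(seed: int = 0) -> CycleConfig:
    """Noise-free demonstration cycle: baseline 0 ppm, plateau 20.15 ppm,
    maximum 20.4 ppm, 70% response crossing 25 s after gas-in."""
    # rise_tau solved so the normalized first-order rise over a 90 s stage
    # crosses 70% of the excursion at exactly 25 s
    return CycleConfig(baseline_ppm=0.0, plateau_ppm=20.15, overshoot_ppm=0.25,
                       rise_tau=_DEMO_RISE_TAU, noise_sd=0.0, seed=seed)


def _solve_demo_rise_tau(t70: float = 25.0, d2: float = 90.0) -> float:
    def f(tau: float) -> float:
        target = 0.7 * -math.expm1(-d2 / tau)
        return -tau * math.log1p(-target) - t70
    return float(brentq(f, 1.0, 200.0))


_DEMO_RISE_TAU = _solve_demo_rise_tau()


# ---------------------------------------------------------------------------
# Repeated-cycle ensembles
# ---------------------------------------------------------------------------


def generate_cycle_ensemble(config: CycleConfig, n_cycles: int,
                            between_cycle_cv: float = 2.4,
                            ) -> list[tuple[SensorTrace, CycleGroundTruth]]:
    """Generate ``n_cycles`` repeated cycles with cycle-to-cycle dispersion.

    ``between_cycle_cv`` (percent) is the relative SD applied to the
    concentration levels (baseline, plateau).  The remaining per-cycle
    jitters scale with it, calibrated to the dispersion structure observed
    in repeated fixed-concentration sensor tests: time constants vary
    roughly 1.75x more than levels, the manually timed gas-exposure
    duration about 4x more, and the small overshoot, slow-tail weight and
    baseline drift are the least repeatable components (dominating the
    spread of the maximum response and of the late-recovery readings).

    Sub-seeds are derived deterministically from ``config.seed``.
    """
    if n_cycles < 2:
        raise ConfigurationError("an ensemble needs at least 2 cycles")
    if between_cycle_cv < 0:
        raise ConfigurationError("between_cycle_cv must be >= 0")

    cv = between_cycle_cv / 100.0
    children = np.random.SeedSequence(config.seed).spawn(n_cycles)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        z = rng.normal(size=10)
        d = list(config.stage_durations)
        d[1] = max(d[1] * (1 + 2.0 * cv * z[6]), 5 * config.sample_interval)
        d[2] = max(d[2] * (1 + 6.0 * cv * z[7]), 5 * config.sample_interval)
        jittered = replace(
            config,
            baseline_ppm=max(config.baseline_ppm * (1 + cv * z[0]), 0.0),
            plateau_ppm=max(config.plateau_ppm * (1 + cv * z[1]),
                            config.baseline_ppm * (1 + cv * z[0]) + 1e-9),
            overshoot_ppm=max(config.overshoot_ppm * (1 + 20.0 * cv * z[2]), 0.0),
            rise_tau=config.rise_tau * max(1 + 1.4 * cv * z[3], 0.1),
            decay_tau=config.decay_tau * max(1 + cv * z[4], 0.1),
            tail_tau=max(config.tail_tau * max(1 + cv * z[5], 0.1),
                         config.decay_tau * max(1 + cv * z[4], 0.1) * 1.5),
            tail_weight=min(max(config.tail_weight * (1 + 5.0 * cv * z[8]), 0.0), 0.9),
            drift_rate=config.drift_rate + 3.3e-3 * cv * z[9],
            stage_durations=tuple(d),
        )
        out.append(generate_cycle(jittered, rng=rng))
    return out


# ---------------------------------------------------------------------------
# Ripening trajectory (day-scale ethylene emission)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RipeningTrajectoryConfig:
    """Ethylene emission during postharvest ripening, minutes time base.

    The noise-free curve rises first-order to a climacteric peak and then
    declines monotonically, with two accelerated-decline phases centred in
    ``decline1_window`` and ``decline2_window``: each phase drops the
    current level by the configured fraction through a smooth logistic
    step, and the inter-phase baseline decline steepens from ``pre_slope``
    to ``mid_slope`` to ``tail_slope`` (ppm/min).
    """

    peak_ppm: float = 20.0
    peak_time: float = 150.0
    duration: float = 3000.0
    decline1_window: tuple = (600.0, 700.0)
    decline2_window: tuple = (2200.0, 2400.0)
    decline1_frac: float = 0.88
    decline2_frac: float = 0.55
    pre_slope: float = 0.002
    mid_slope: float = 0.0004
    tail_slope: float = 0.0002
    decline1_sharpness: float = 12.0
    decline2_sharpness: float = 25.0
    noise_sd: float = 0.05
    sample_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        w1, w2 = self.decline1_window, self.decline2_window
        if not (0 < w1[0] < w1[1] <= w2[0] < w2[1] <= self.duration):
            raise ConfigurationError(
                "decline windows must be ordered, non-overlapping and inside the trace")
        if self.peak_ppm < 0:
            raise ConfigurationError("peak_ppm must be >= 0")
        if not (0 <= self.decline1_frac < 1 and 0 <= self.decline2_frac < 1):
            raise ConfigurationError("decline fractions must be in [0, 1)")
        if self.sample_interval <= 0:
            raise ConfigurationError("sample_interval must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _softstep(x: np.ndarray | float, s: float):
    """Logistic step 0 -> 1 with scale s."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float) / s))


def _softramp(x: np.ndarray | float, s: float):
    """Smooth ramp: 0 for x << 0, ~x for x >> 0; derivative = _softstep."""
    x = np.asarray(x, dtype=float)
    return s * np.logaddexp(0.0, x / s)


def ripening_curve(config: RipeningTrajectoryConfig,
                   times: np.ndarray) -> np.ndarray:
    """Noise-free ripening trajectory at arbitrary times (minutes)."""
    t = np.asarray(times, dtype=float)
    c1 = 0.5 * (config.decline1_window[0] + config.decline1_window[1])
    c2 = 0.5 * (config.decline2_window[0] + config.decline2_window[1])
    s1, s2 = config.decline1_sharpness, config.decline2_sharpness
    tau_r = max(config.peak_time / 5.0, 1e-6)

    def base(tt):
        return (config.peak_ppm * -np.expm1(-np.asarray(tt, dtype=float) / tau_r)
                - config.pre_slope * _softramp(tt, 5.0)
                - (config.mid_slope - config.pre_slope) * _softramp(np.asarray(tt) - c1, s1)
                - (config.tail_slope - config.mid_slope) * _softramp(np.asarray(tt) - c2, s2))

    level1 = float(base(config.decline1_window[0]))
    d1 = config.decline1_frac * max(level1, 0.0)
    level2 = float(base(config.decline2_window[0])) - d1
    d2 = config.decline2_frac * max(level2, 0.0)
    v = base(t) - d1 * _softstep(t - c1, s1) - d2 * _softstep(t - c2, s2)
    return np.maximum(v, 0.0)


def generate_ripening_trajectory(config: RipeningTrajectoryConfig) -> SensorTrace:
    """Generate a noisy ripening ethylene trajectory (times in minutes)."""
    n = int(round(config.duration / config.sample_interval)) + 1
    times = np.arange(n) * config.sample_interval
    values = ripening_curve(config, times)
    if config.noise_sd:
        rng = np.random.default_rng(config.seed)
        values = values + rng.normal(0.0, config.noise_sd, size=n)
    return SensorTrace(times, values, gas_in=float(times[0]), gas_out=float(times[-1]),
                       meta={"gas": "C2H4", "time_unit": "min",
                             "record": "ripening-trajectory"})


def ripening_config_for_segment_means(
        targets: Sequence[float],
        base: RipeningTrajectoryConfig | None = None) -> RipeningTrajectoryConfig:
    """Calibrate (peak_ppm, decline1_frac, decline2_frac) so the noise-free
    trajectory's mean level before window 1, between the windows, and after
    window 2 equals ``targets``.

    Used to build demonstration fixtures whose response-family change
    amplitudes take prescribed values.  Deterministic.
    """
    base = base or RipeningTrajectoryConfig()
    m0, m1, m2 = (float(x) for x in targets)
    if not (m0 > m1 > m2 >= 0):
        raise ConfigurationError("segment-mean targets must decline")

    def seg_means(cfg: RipeningTrajectoryConfig) -> np.ndarray:
        tt = np.arange(0.0, cfg.duration + 1e-9, cfg.sample_interval)
        v = ripening_curve(cfg, tt)
        w1, w2 = cfg.decline1_window, cfg.decline2_window
        seg0 = v[tt < w1[0]]
        seg1 = v[(tt >= w1[1]) & (tt < w2[0])]
        seg2 = v[tt >= w2[1]]
        return np.array([seg0.mean(), seg1.mean(), seg2.mean()])

    def residual(x):
        peak, f1, f2 = x
        cfg = replace(base, peak_ppm=float(peak), decline1_frac=float(f1),
                      decline2_frac=float(f2))
        return seg_means(cfg) - np.array([m0, m1, m2])

    x0 = np.array([min(m0 * 1.1, 49.0), min(1 - m1 / m0, 0.95),
                   min(1 - m2 / m1, 0.95)])
    sol = least_squares(residual, x0, bounds=([0.1, 0.0, 0.0], [50.0, 0.999, 0.999]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    peak, f1, f2 = sol.x
    cfg = replace(base, peak_ppm=float(peak), decline1_frac=float(f1),
                  decline2_frac=float(f2))
    if np.max(np.abs(seg_means(cfg) - np.array([m0, m1, m2]))) > 1e-6 * max(m0, 1.0):
        raise ConfigurationError("segment-mean calibration did not converge")
    return cfg


def default_ripening_trajectory_config(seed: int = 0) -> RipeningTrajectoryConfig:
    """Default ripening scenario: a strong climacteric ethylene burst whose
    emission decline parallels the fruit-softening trajectory (segment mean
    levels 18.5 -> 1.85 -> 0.555 ppm, i.e. 90%/70% declines)."""
    cfg = ripening_config_for_segment_means((18.5, 1.85, 0.555))
    return replace(cfg, seed=seed)


def demo_ripening_trajectory_config(seed: int = 0) -> RipeningTrajectoryConfig:
    """Demonstration fixture with segment mean levels 18 -> 13 -> 8.77 ppm,
    i.e. response change amplitudes of 27.78% and 32.53%."""
    cfg = ripening_config_for_segment_means((18.0, 13.0, 8.77))
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Ripening tables (texture profile analysis)
# ---------------------------------------------------------------------------

TEXTURE_METRICS = ("hardness", "springiness", "cohesiveness",
                   "adhesiveness", "chewiness", "resilience")
DAYS = ("before", "day1", "day2")
SHARED_BEFORE_GROUP = "both"   # pre-ripening pool is group-independent


@dataclass(frozen=True)
class RipeningTableConfig:
    """Generator settings for a two-group (ethylene-treated A vs air-control
    B) texture-profile ripening table.

    ``factors`` maps each texture metric to the per-day multiplicative decay
    (day1 relative to before; day2 relative to day1) for groups A and B.
    Treated fruit softens faster, so every A factor must be below the
    matching B factor.  Per-sample values are drawn lognormally around the
    group-day mean with relative SD ``rel_sd``.
    """

    n_per_group: int = 3
    baselines: dict = field(default_factory=lambda: {
        "hardness": 9234.093, "springiness": 0.55, "cohesiveness": 0.35,
        "adhesiveness": 120.0, "chewiness": 1800.0, "resilience": 0.20})
    factors: dict = field(default_factory=lambda: {
        #               A day1   A day2   B day1   B day2
        "hardness":     (0.1147, 0.2472, 0.17247, 0.41261),
        "springiness":  (0.80,   0.85,   0.90,    0.92),
        "cohesiveness": (0.75,   0.80,   0.85,    0.88),
        "adhesiveness": (0.0471, 0.2528, 0.10,    0.45),
        "chewiness":    (0.0482, 0.2575, 0.11,    0.46),
        "resilience":   (0.70,   0.78,   0.82,    0.86)})
    rel_sd: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.rel_sd < 0:
            raise ConfigurationError("rel_sd must be >= 0")
        for metric in TEXTURE_METRICS:
            if metric not in self.baselines or metric not in self.factors:
                raise ConfigurationError(f"missing settings for metric {metric!r}")
            a1, a2, b1, b2 = self.factors[metric]
            for f in (a1, a2, b1, b2):
                if not (0 < f <= 1):
                    raise ConfigurationError(
                        f"decay factors must be in (0, 1]; got {f} for {metric}")
            if not (a1 <= b1 and a2 <= b2):
                raise ConfigurationError(
                    f"group A must decay at least as fast as group B ({metric})")


def generate_ripening_table(config: RipeningTableConfig) -> pd.DataFrame:
    """Generate a tidy ripening table (one row per sample/group/day).

    Columns: sample, group, day, ripeness_stage and the six texture metrics.
    The pre-ripening pool is shared between groups (group label 'both').
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.rel_sd ** 2)) if config.rel_sd else 0.0

    def draw(mean: float, size: int) -> np.ndarray:
        if sigma == 0.0 or mean == 0.0:
            return np.full(size, mean)
        return mean * np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma ** 2)

    stage = {("both", "before"): "unripe",
             ("A", "day1"): "medium ripe", ("A", "day2"): "fully ripe",
             ("B", "day1"): "unripe", ("B", "day2"): "medium ripe"}

    rows: list[dict] = []
    n = config.n_per_group

    def add_rows(group: str, day: str, means: dict) -> None:
        samples = {m: draw(means[m], n) for m in TEXTURE_METRICS}
        for i in range(n):
            row = {"sample": f"{group}{day}-{i + 1}", "group": group, "day": day,
                   "ripeness_stage": stage[(group, day)]}
            row.update({m: float(samples[m][i]) for m in TEXTURE_METRICS})
            rows.append(row)

    before_means = dict(config.baselines)
    add_rows(SHARED_BEFORE_GROUP, "before", before_means)
    for group, (i1, i2) in (("A", (0, 1)), ("B", (2, 3))):
        day1 = {m: config.baselines[m] * config.factors[m][i1] for m in TEXTURE_METRICS}
        day2 = {m: day1[m] * config.factors[m][i2] for m in TEXTURE_METRICS}
        add_rows(group, "day1", day1)
        add_rows(group, "day2", day2)

    return pd.DataFrame(rows)
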