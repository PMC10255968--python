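"""Stage segmentation and kinetic feature extraction for sensor cycles.

A response/recovery cycle is decomposed into six stages:

S1  air baseline before gas entry
S2  rapid rise (gas entry until 95% of the maximum response)
S3  dynamically stable plateau (until gas removal)
S4  rapid decline (until recovery to 30% of the excursion above baseline)
S5  slow recovery tail (until recovery to 5% of the excursion)
S6  final recovery back to the air baseline

From a preprocessed cycle and its stages, 23 characteristic parameters are
extracted: six response levels (Xa, Xg, Xm, Xres, Xrec, Xrecair), first- and
second-derivative extrema with their times (Dres, Drec, Dresn, Dresx, Drecn,
Drecx, tDres, tDrec, tDresn, tDresx, tDrecn, tDrecx), response and recovery
times (tres, trec), and three trapezoid integrals (intT, intPres, intPrec).

Conventions: all stage intervals are half-open [start, end); times are
offsets from the relevant gas marker; Dres/Drec are reported as absolute
values while the second-derivative extrema keep their sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .signal_model import SensorTrace

RESPONSE_PARAMS = ("Xa", "Xg", "Xm", "Xres", "Xrec", "Xrecair")
FIRST_DERIV_PARAMS = ("Dres", "Drec")
SECOND_DERIV_PARAMS = ("Dresn", "Dresx", "Drecn", "Drecx")
TIME_PARAMS = ("tres", "trec", "tDres", "tDrec", "tDresn", "tDresx", "tDrecn", "tDrecx")
INTEGRAL_PARAMS = ("intT", "intPres", "intPrec")
ALL_PARAMS = (RESPONSE_PARAMS + FIRST_DERIV_PARAMS + SECOND_DERIV_PARAMS
              + TIME_PARAMS + INTEGRAL_PARAMS)

# thresholds of the operational stage/time definitions (fractions of the
# excursion above baseline, except the S2/S3 bound which uses the maximum)
RISE_STAGE_FRAC = 0.95      # of Xm: end of rapid-rise stage
RESPONSE_FRAC = 0.70        # response time: rise to 70% of excursion
RECOVERY_FRAC = 0.30        # recovery time / end of rapid decline
TAIL_FRAC = 0.05            # end of slow-recovery tail
XRES_OFFSET = 60.0          # s after gas entry (response value at 1 min)
XREC_OFFSET = 180.0         # s after gas out (recovery value at 3 min)


class SegmentationError(RuntimeError):
    """Raised when a cycle cannot be decomposed into the six stages."""


class InputError(ValueError):
    pass


@dataclass
class StageBoundaries:
    """Six contiguous half-open [start, end) stage intervals, in trace time
    units.  ``flags`` records degenerate boundaries (e.g. a recovery
    threshold never reached, in which case the boundary is clamped to the
    trace end)."""

    intervals: list
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.intervals) != 6:
            raise ValueError("expected six stage intervals")
        for (a, b), (c, _) in zip(self.intervals, self.intervals[1:]):
            if b < a or abs(b - c) > 1e-9:
                raise ValueError("stage intervals must be ordered and contiguous")

    def __getitem__(self, i: int) -> tuple:
        return self.intervals[i]


@dataclass
class ResponseFeatures:
    """The 23 characteristic parameters of one cycle.

    Levels in ppm, derivatives in ppm per time unit (and per unit squared),
    times in trace time units, integrals in ppm x time unit.  Fields that
    could not be evaluated (e.g. a marker offset past the end of the trace)
    are NaN and listed in ``missing``.
    """

    Xa: float = np.nan
    Xg: float = np.nan
    Xm: float = np.nan
    Xres: float = np.nan
    Xrec: float = np.nan
    Xrecair: float = np.nan
    Dres: float = np.nan
    Drec: float = np.nan
    Dresn: float = np.nan
    Dresx: float = np.nan
    Drecn: float = np.nan
    Drecx: float = np.nan
    tres: float = np.nan
    trec: float = np.nan
    tDres: float = np.nan
    tDrec: float = np.nan
    tDresn: float = np.nan
    tDresx: float = np.nan
    tDrecn: float = np.nan
    tDrecx: float = np.nan
    intT: float = np.nan
    intPres: float = np.nan
    intPrec: float = np.nan
    missing: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "missing"}


def differentiate(trace: SensorTrace, order: int = 1) -> SensorTrace:
    """First or second time derivative on the uniform grid.

    Central differences on interior points, one-sided at the ends
    (numpy.gradient applied ``order`` times).  Units become ppm per time
    unit (order 1) or ppm per time unit squared (order 2).
    """
    if order not in (1, 2):
        raise InputError("order must be 1 or 2")
    if trace.values.size < order + 1:
        raise InputError(f"need at least {order + 1} samples for order {order}")
    d = trace.values
    for _ in range(order):
        d = np.gradient(d, trace.dt)
    unit = trace.meta.get("time_unit", "s")
    return trace.copy_with(d, derivative_order=order,
                           value_unit=f"ppm/{unit}^{order}" if order > 1 else f"ppm/{unit}")


def _first_index_at_or_after(trace: SensorTrace, t: float) -> int:
    return int(np.searchsorted(trace.times, t - 1e-9))


def segment_stages(trace: SensorTrace) -> StageBoundaries:
    """Decompose a cycle into the six stages using threshold crossings.

    Raises :class:`SegmentationError` if the response never attains 95% of
    its maximum before gas removal.  Recovery thresholds that are never
    reached clamp the corresponding boundary to the trace end and are
    flagged rather than raising.
    """
    t, v = trace.times, trace.values
    gi, go = trace.gas_in, trace.gas_out
    i_gi, i_go = _first_index_at_or_after(trace, gi), _first_index_at_or_after(trace, go)
    if i_gi == 0:
        raise SegmentationError("no air-baseline samples before gas_in")

    xa = float(np.mean(v[:i_gi]))
    window = v[i_gi:i_go + 1]
    if window.size == 0:
        raise SegmentationError("no samples between gas_in and gas_out")
    xm = float(np.max(window))

    flags: list = []
    rise_thr = RISE_STAGE_FRAC * xm
    rel = np.flatnonzero(window >= rise_thr - 1e-12)
    t95 = float(t[i_gi + rel[0]])
    # a response still rising at gas removal has no stable stage: the 95%
    # crossing must leave a non-trivial S3 behind it
    if xm > xa and (go - t95) < 0.1 * (go - gi):
        raise SegmentationError(
            f"response reached {RISE_STAGE_FRAC:.0%} of its maximum only "
            f"{go - t95:.3g} time units before gas_out: no stable stage")

    excursion = xm - xa
    rec = v[i_go:]
    rec_t = t[i_go:]

    def crossing(frac: float, label: str) -> float:
        thr = xa + frac * excursion
        below = np.flatnonzero(rec <= thr + 1e-12)
        if below.size == 0:
            flags.append(f"{label}: never recovered to {frac:.0%} of excursion")
            return float(t[-1])
        return float(rec_t[below[0]])

    t30 = crossing(RECOVERY_FRAC, "S4/S5")
    t05 = max(crossing(TAIL_FRAC, "S5/S6"), t30)
    intervals = [(float(t[0]), gi), (gi, t95), (t95, go),
                 (go, t30), (t30, t05), (t05, float(t[-1]))]
    return StageBoundaries(intervals, flags)


def _mean_over(trace: SensorTrace, start: float, end: float) -> float:
    i0 = _first_index_at_or_after(trace, start)
    i1 = _first_index_at_or_after(trace, end)
    if i1 <= i0:
        i1 = i0 + 1
    return float(np.mean(trace.values[i0:i1]))


def _trapz_between(trace: SensorTrace, start: float, end: float) -> float:
    i0 = _first_index_at_or_after(trace, start)
    i1 = _first_index_at_or_after(trace, end)
    if i1 <= i0:
        return 0.0
    return float(np.trapezoid(trace.values[i0:i1 + 1], trace.times[i0:i1 + 1]))


def extract_features(trace: SensorTrace,
                     stages: StageBoundaries | None = None) -> ResponseFeatures:
    """Extract the 23 characteristic parameters from a preprocessed cycle.

    ``stages`` defaults to :func:`segment_stages` on the same trace.  A
    marker offset falling outside the trace (e.g. gas_out + 3 min past the
    end) yields NaN for that field, recorded in ``ResponseFeatures.missing``
    instead of raising.
    """
    if stages is None:
        stages = segment_stages(trace)
    t, v = trace.times, trace.values
    gi, go = trace.gas_in, trace.gas_out
    f = ResponseFeatures()
    missing = f.missing

    # offsets defined on a seconds time base; convert if the trace is in minutes
    unit_scale = 1.0 / 60.0 if trace.meta.get("time_unit") == "min" else 1.0
    xres_off = XRES_OFFSET * unit_scale
    xrec_off = XREC_OFFSET * unit_scale

    (s1a, s1b), _, (s3a, s3b), _, _, (s6a, s6b) = stages.intervals
    f.Xa = _mean_over(trace, s1a, s1b)
    f.Xg = _mean_over(trace, s3b - 0.2 * (s3b - s3a), s3b) if s3b > s3a else float("nan")
    if s3b <= s3a:
        missing.add("Xg")
    i_gi, i_go = _first_index_at_or_after(trace, gi), _first_index_at_or_after(trace, go)
    f.Xm = float(np.max(v[i_gi:i_go + 1]))

    for name, at in (("Xres", gi + xres_off), ("Xrec", go + xrec_off)):
        if at > t[-1] + 1e-9:
            missing.add(name)
        else:
            setattr(f, name, float(v[trace.index_at(at)]))
    f.Xrecair = _mean_over(trace, s6b - 0.1 * (s6b - s6a), s6b) if s6b > s6a else float("nan")
    if s6b <= s6a:
        missing.add("Xrecair")

    excursion = f.Xm - f.Xa
    rise = np.flatnonzero(v[i_gi:] >= f.Xa + RESPONSE_FRAC * excursion - 1e-12)
    if rise.size == 0:
        missing.add("tres")
    else:
        f.tres = float(t[i_gi + rise[0]] - gi)
    fall = np.flatnonzero(v[i_go:] <= f.Xa + RECOVERY_FRAC * excursion + 1e-12)
    if fall.size == 0:
        missing.add("trec")
    else:
        f.trec = float(t[i_go + fall[0]] - go)

    d1 = differentiate(trace, 1).values
    d2 = differentiate(trace, 2).values
    resp = slice(i_gi, i_go + 1)
    rec = slice(i_go, len(v))

    i = int(np.argmax(d1[resp])) + i_gi
    f.Dres, f.tDres = abs(float(d1[i])), float(t[i] - gi)
    i = int(np.argmin(d1[rec])) + i_go
    f.Drec, f.tDrec = abs(float(d1[i])), float(t[i] - go)

    i = int(np.argmin(d2[resp])) + i_gi
    f.Dresn, f.tDresn = float(d2[i]), float(t[i] - gi)
    i = int(np.argmax(d2[resp])) + i_gi
    f.Dresx, f.tDresx = float(d2[i]), float(t[i] - gi)
    i = int(np.argmin(d2[rec])) + i_go
    f.Drecn, f.tDrecn = float(d2[i]), float(t[i] - go)
    i = int(np.argmax(d2[rec])) + i_go
    f.Drecx, f.tDrecx = float(d2[i]), float(t[i] - go)

    f.intT = _trapz_between(trace, gi, go)
    if not np.isnan(f.tres):
        f.intPres = _trapz_between(trace, gi, gi + f.tres)
    else:
        missing.add("intPres")
    if not np.isnan(f.trec):
        f.intPrec = _trapz_between(trace, go, go + f.trec)
    else:
        missing.add("intPrec")
    return f
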