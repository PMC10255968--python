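"""Linking sensor kinetics to fruit-ripening characterization.

During postharvest ripening, texture-analyzer parameters (hardness,
adhesiveness, chewiness, ...) of ethylene-treated fruit collapse in two
clear steps: before ripening -> day 1 -> day 2.  The same two-phase decline
appears in the ethylene emission trajectory recorded by the sensor.  This
module quantifies both with *change amplitude vectors*

    Change I  = 100 * (m0 - m1) / m0      (before -> day 1 / phase 1)
    Change II = 100 * (m1 - m2) / m1      (day 1 -> day 2 / phase 2)

computed on per-(group, day) means for the ripening table and on per-phase
segment summaries for the kinetic trace, and then scores each kinetic
parameter family (response level, first derivative, second derivative,
cumulative integral) by its *difference ratio* against the ripening
reference — the mean change of the strongly responding texture parameters.
Families whose summaries do not decline in both phases are ineligible; the
remaining ones are ranked ascending by difference ratio, smaller meaning
more concordant with ripening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import differentiate
from .signal_model import SensorTrace, TEXTURE_METRICS

KINETIC_FAMILIES = ("response", "first_derivative", "second_derivative", "integral")
#: texture parameters that respond strongly to ripening and form the
#: reference change vector (color changes are ordinal-only and excluded)
REFERENCE_METRICS = ("hardness", "adhesiveness", "chewiness")


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseWindows:
    """The two accelerated-decline intervals of a ripening trajectory, in
    the trace's time unit (minutes for day-scale records)."""

    window1: tuple
    window2: tuple

    def __post_init__(self) -> None:
        w1, w2 = self.window1, self.window2
        if not (w1[0] < w1[1] <= w2[0] < w2[1]):
            raise InputError("phase windows must be ordered and non-overlapping")


@dataclass
class ChangeAmplitudeVector:
    """Per-parameter phase-to-phase relative changes, in percent.

    ``changes`` maps a parameter label to (Change I, Change II);
    ``undefined`` lists parameters with a zero denominator; ``summaries``
    keeps the three underlying phase values for inspection.
    """

    changes: dict
    undefined: set = field(default_factory=set)
    summaries: dict = field(default_factory=dict)

    def __getitem__(self, label: str) -> tuple:
        return self.changes[label]

    @property
    def labels(self) -> list:
        return list(self.changes)


def _changes_from_values(v0: float, v1: float, v2: float) -> tuple:
    c1 = 100.0 * (v0 - v1) / v0 if v0 != 0 else np.nan
    c2 = 100.0 * (v1 - v2) / v1 if v1 != 0 else np.nan
    return c1, c2


def validate_ripening_table(table: pd.DataFrame,
                            metrics: tuple = ()) -> None:
    """A ripening table needs group/day labels and at least one texture
    metric; ``metrics`` lists the columns the caller is about to use."""
    required = {"group", "day", *metrics}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"ripening table missing columns: {sorted(missing)}")
    if not set(TEXTURE_METRICS) & set(table.columns):
        raise InputError("ripening table has no texture metric columns")


def change_vector(table: pd.DataFrame, group: str,
                  metrics: tuple = TEXTURE_METRICS) -> ChangeAmplitudeVector:
    """Change amplitude vector of the ripening parameters for one group.

    The pre-ripening pool is group-independent: all ``day == 'before'`` rows
    enter the m0 mean regardless of their group label.  Requires day1 and
    day2 rows for the requested group.
    """
    validate_ripening_table(table, tuple(metrics))
    before = table[table["day"] == "before"]
    day1 = table[(table["day"] == "day1") & (table["group"] == group)]
    day2 = table[(table["day"] == "day2") & (table["group"] == group)]
    for name, df in (("before", before), ("day1", day1), ("day2", day2)):
        if df.empty:
            raise InputError(f"group {group!r} has no {name} rows")

    changes, undefined, summaries = {}, set(), {}
    for metric in metrics:
        m0 = float(before[metric].mean())
        m1 = float(day1[metric].mean())
        m2 = float(day2[metric].mean())
        summaries[metric] = (m0, m1, m2)
        c1, c2 = _changes_from_values(m0, m1, m2)
        changes[metric] = (c1, c2)
        if np.isnan(c1) or np.isnan(c2):
            undefined.add(metric)
    return ChangeAmplitudeVector(changes, undefined, summaries)


def _phase_slices(trace: SensorTrace, windows: PhaseWindows) -> tuple:
    t = trace.times
    if windows.window1[0] <= t[0] or windows.window2[1] >= t[-1]:
        raise InputError("phase windows must lie strictly inside the trace")
    w1, w2 = windows.window1, windows.window2
    seg0 = (t >= t[0]) & (t < w1[0])
    seg1 = (t >= w1[1]) & (t < w2[0])
    seg2 = t >= w2[1]
    in_w1 = (t >= w1[0]) & (t < w1[1])
    in_w2 = (t >= w2[0]) & (t < w2[1])
    if not (seg0.any() and seg1.any() and seg2.any() and in_w1.any() and in_w2.any()):
        raise InputError("phase windows leave an empty segment")
    return seg0, seg1, seg2, in_w1, in_w2


def kinetic_change_vector(trace: SensorTrace, windows: PhaseWindows,
                          features: tuple = KINETIC_FAMILIES
                          ) -> ChangeAmplitudeVector:
    """Change amplitude vector of the kinetic parameter families.

    Phase summaries on a preprocessed trajectory, per family:

    * ``response`` — mean concentration over the segments before window 1,
      between the windows, and after window 2;
    * ``first_derivative`` / ``second_derivative`` — the fastest decline
      (signed minimum of the derivative) inside the decline window adjacent
      to each segment: window 1, window 2, and the residual tail segment;
    * ``integral`` — mean of the cumulative emission integral over the three
      segments (the integral curve keeps growing, so this family does not
      share the decline trend).

    The same relative-change formula is applied to all summaries, so
    derivative-based changes may exceed 100% or be negative.
    """
    seg0, seg1, seg2, in_w1, in_w2 = _phase_slices(trace, windows)
    v = trace.values
    d1 = differentiate(trace, 1).values
    d2 = differentiate(trace, 2).values
    cum = np.concatenate(([0.0], np.cumsum(
        0.5 * (v[1:] + v[:-1]) * np.diff(trace.times))))

    phase_values = {
        "response": (v[seg0].mean(), v[seg1].mean(), v[seg2].mean()),
        "first_derivative": (d1[in_w1].min(), d1[in_w2].min(), d1[seg2].min()),
        "second_derivative": (d2[in_w1].min(), d2[in_w2].min(), d2[seg2].min()),
        "integral": (cum[seg0].mean(), cum[seg1].mean(), cum[seg2].mean()),
    }

    changes, undefined, summaries = {}, set(), {}
    for family in features:
        if family not in phase_values:
            raise InputError(f"unknown kinetic family {family!r}")
        v0, v1, v2 = (float(x) for x in phase_values[family])
        summaries[family] = (v0, v1, v2)
        c1, c2 = _changes_from_values(v0, v1, v2)
        changes[family] = (c1, c2)
        if np.isnan(c1) or np.isnan(c2):
            undefined.add(family)
    return ChangeAmplitudeVector(changes, undefined, summaries)


@dataclass
class FamilyScore:
    score: float
    eligible: bool
    change1: float
    change2: float
    note: str = ""


def difference_ratio(ripening: ChangeAmplitudeVector,
                     kinetic: ChangeAmplitudeVector,
                     reference_metrics: tuple = REFERENCE_METRICS) -> dict:
    """Score each kinetic family against the ripening reference change.

    The reference (dr1, dr2) is the mean Change I / Change II over the
    strongly responding ripening parameters.  A family's score is the mean
    over the two phases of |dk - dr| / |dr| — zero for perfect concordance,
    one when the kinetic change is double the reference.  Declining in both
    phases (Change I > 0 and Change II > 0) is a hard eligibility
    prerequisite; ineligible families keep their score for inspection but
    are excluded from the optimal-parameter ranking.
    """
    refs = [ripening.changes[m] for m in reference_metrics
            if m in ripening.changes and m not in ripening.undefined]
    if not refs:
        raise InputError("no usable reference ripening parameters")
    dr1 = float(np.mean([c1 for c1, _ in refs]))
    dr2 = float(np.mean([c2 for _, c2 in refs]))
    if dr1 == 0 or dr2 == 0:
        raise InputError("ripening reference change is zero; ratio undefined")

    scores: dict = {}
    for family, (k1, k2) in kinetic.changes.items():
        if np.isnan(k1) or np.isnan(k2):
            scores[family] = FamilyScore(np.nan, False, k1, k2,
                                         note="change undefined")
            continue
        score = 0.5 * (abs(k1 - dr1) / abs(dr1) + abs(k2 - dr2) / abs(dr2))
        eligible = (k1 > 0) and (k2 > 0)
        note = "" if eligible else "does not decline in both phases"
        scores[family] = FamilyScore(float(score), eligible, float(k1),
                                     float(k2), note)
    return scores


def select_optimal_parameters(scores: dict) -> list:
    """Eligible kinetic families, ranked ascending by difference ratio."""
    if len(scores) < 2:
        raise InputError("need at least two scored kinetic families")
    eligible = [(fs.score, fam) for fam, fs in scores.items() if fs.eligible]
    return [fam for _, fam in sorted(eligible)]


def compare_groups(table: pd.DataFrame, metric: str = "hardness") -> pd.DataFrame:
    """Per-day comparison of the treated (A) vs control (B) group.

    Returns a day-indexed DataFrame with group means, their difference and a
    Welch (unequal-variance) two-sample t-test p-value, reported
    descriptively.  Cells with fewer than two samples report means with the
    test flagged unavailable.
    """
    validate_ripening_table(table, (metric,))
    rows = []
    for day in ("day1", "day2"):
        a = table[(table["day"] == day) & (table["group"] == "A")][metric].to_numpy()
        b = table[(table["day"] == day) & (table["group"] == "B")][metric].to_numpy()
        row = {"day": day, "n_A": a.size, "n_B": b.size,
               "mean_A": float(np.mean(a)) if a.size else np.nan,
               "mean_B": float(np.mean(b)) if b.size else np.nan}
        row["mean_diff"] = row["mean_A"] - row["mean_B"]
        if a.size >= 2 and b.size >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            row["t_welch"], row["p_value"], row["flag"] = float(t), float(p), ""
        else:
            row["t_welch"] = row["p_value"] = np.nan
            row["flag"] = "test unavailable (fewer than 2 samples per group)"
        rows.append(row)
    return pd.DataFrame(rows).set_index("day")
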