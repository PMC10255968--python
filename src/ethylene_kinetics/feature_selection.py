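"""Correlation analysis and rule-based selection of the feature subset.

Among the 23 characteristic parameters many carry overlapping information.
The selection scheme combines the repeatability ranking (coefficient of
variation) with Pearson correlation structure to retain one compact subset
that still spans the response, time, derivative and integral families:

1. response levels — keep the most repeatable in-air parameter (the
   baseline) and the most repeatable in-gas parameter (the steady state);
2. time parameters — among those repeatable enough (|CV| below threshold),
   keep the pair sharing the most information with the other time
   parameters (largest mean absolute off-diagonal correlation);
3. derivatives — keep the first-order pair when the first-order family is
   more repeatable than the second-order family;
4. integrals — keep the integral least correlated with the steady-state
   response, i.e. the one adding the most independent information.

With repeatability and correlation structure like that of a typical
fixed-concentration repeatability experiment, the selected subset is
{Xa, Xg, tres, trec, Dres, Drec, intT}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .ensemble_stats import StatsSummary, features_frame
from .kinetics import ResponseFeatures


class InputError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over parameter labels.

    ``r`` is a labels x labels DataFrame with unit diagonal; ``n`` is the
    number of cycles used; ``constant`` lists columns with zero variance,
    whose pairwise correlations are undefined (NaN).
    """

    r: pd.DataFrame
    n: int
    constant: set = field(default_factory=set)

    @property
    def labels(self) -> list:
        return list(self.r.index)

    def mean_abs_offdiag(self, label: str) -> float:
        """Mean |r| between ``label`` and every other (non-constant) label."""
        row = self.r.loc[label].drop(label).abs().dropna()
        return float(row.mean()) if row.size else np.nan


def pearson_matrix(features: Sequence[ResponseFeatures] | pd.DataFrame,
                   labels: Iterable[str]) -> CorrelationMatrix:
    """Product-moment correlation between parameter columns, pairwise complete.

    Requires at least three cycles.  Constant columns are flagged and their
    correlations left NaN rather than raising.
    """
    df = features if isinstance(features, pd.DataFrame) else features_frame(features)
    labels = list(labels)
    missing = [lab for lab in labels if lab not in df.columns]
    if missing:
        raise InputError(f"unknown parameter labels: {missing}")
    sub = df[labels].astype(float)
    if len(sub) < 3:
        raise InputError("correlation needs at least 3 cycles")
    constant = {lab for lab in labels if sub[lab].dropna().nunique() <= 1}
    r = sub.corr(method="pearson", min_periods=2)
    for lab in labels:            # unit diagonal even for constant columns
        r.loc[lab, lab] = 1.0
    return CorrelationMatrix(r=r, n=len(sub), constant=constant)


@dataclass(frozen=True)
class SelectionRules:
    """Thresholds of the subset-selection scheme.

    ``cv_threshold`` (percent) bounds the |CV| a parameter may have to be
    considered repeatable.  The default of 5% keeps baseline, steady-state,
    response/recovery-time and first-derivative parameters of a typical
    repeatability experiment while excluding late-recovery levels and the
    derivative-extremum times.
    """

    cv_threshold: float = 5.0


@dataclass
class SelectionResult:
    selected: list
    trace: dict


def _argmin_cv(summary: StatsSummary, candidates: Sequence[str]) -> str:
    scored = []
    for lab in candidates:
        cv = summary.table.loc[lab, "cv_percent"]
        scored.append((np.inf if np.isnan(cv) else abs(float(cv)), lab))
    return min(scored)[1]


def select_feature_subset(summary: StatsSummary,
                          time_corr: CorrelationMatrix,
                          deriv_corr: CorrelationMatrix,
                          integral_corr: CorrelationMatrix,
                          rules: SelectionRules = SelectionRules()
                          ) -> SelectionResult:
    """Apply the four family rules and return the selected labels in the
    order (air level, gas level, time pair, first derivatives, integral).

    ``integral_corr`` must include the steady-state response Xg alongside
    the three integrals (the "least correlated with Xg" rule).  A tie in
    that rule picks the lexicographically first integral and flags it.
    """
    trace: dict = {"cv_threshold": rules.cv_threshold}

    needed = set(kinetics.ALL_PARAMS)
    if not needed.issubset(summary.labels):
        raise InputError(
            f"summary is missing parameters: {sorted(needed - set(summary.labels))}")
    for mat, labs in ((time_corr, kinetics.TIME_PARAMS),
                      (deriv_corr, kinetics.FIRST_DERIV_PARAMS
                       + kinetics.SECOND_DERIV_PARAMS),
                      (integral_corr, ("Xg",) + kinetics.INTEGRAL_PARAMS)):
        if not set(labs).issubset(mat.labels):
            raise InputError(f"correlation matrix missing labels {set(labs) - set(mat.labels)}")

    # (1) response levels: most repeatable in-air and in-gas parameter
    air = _argmin_cv(summary, ("Xa", "Xrec", "Xrecair"))
    gas = _argmin_cv(summary, ("Xg", "Xm", "Xres"))
    trace["air_level"] = air
    trace["gas_level"] = gas

    # (2) time parameters: repeatable ones, ranked by shared information
    eligible = [lab for lab in kinetics.TIME_PARAMS
                if not np.isnan(summary.table.loc[lab, "cv_percent"])
                and abs(summary.cv(lab)) <= rules.cv_threshold]
    if len(eligible) < 2:
        raise InputError(
            f"fewer than two time parameters pass |CV| <= {rules.cv_threshold}%")
    ranked = sorted(eligible,
                    key=lambda lab: (-time_corr.mean_abs_offdiag(lab), lab))
    time_pair = sorted(ranked[:2], key=kinetics.TIME_PARAMS.index)
    trace["time_eligible"] = eligible
    trace["time_pair"] = time_pair

    # (3) derivatives: first order if its family is the more repeatable
    cv1 = float(np.nanmean([abs(summary.cv(lab)) for lab in kinetics.FIRST_DERIV_PARAMS]))
    cv2 = float(np.nanmean([abs(summary.cv(lab)) for lab in kinetics.SECOND_DERIV_PARAMS]))
    deriv = list(kinetics.FIRST_DERIV_PARAMS if cv1 <= cv2
                 else kinetics.SECOND_DERIV_PARAMS)
    trace["first_order_mean_abs_cv"] = cv1
    trace["second_order_mean_abs_cv"] = cv2
    trace["derivatives"] = deriv

    # (4) integrals: least |r| against the steady-state response
    scored = []
    for lab in kinetics.INTEGRAL_PARAMS:
        r = integral_corr.r.loc[lab, "Xg"]
        scored.append((np.inf if np.isnan(r) else abs(float(r)), lab))
    scored.sort()
    integral = scored[0][1]
    tie = len(scored) > 1 and np.isclose(scored[0][0], scored[1][0], rtol=0, atol=1e-12)
    trace["integral"] = integral
    trace["integral_abs_r_vs_Xg"] = {lab: s for s, lab in scored}
    if tie:
        trace["integral_tie"] = sorted(lab for s, lab in scored if s == scored[0][0])

    selected = [air, gas, *time_pair, *deriv, integral]
    return SelectionResult(selected=selected, trace=trace)
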