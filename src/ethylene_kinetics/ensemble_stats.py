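"""Repeatability and stability statistics over repeated-cycle ensembles.

For each characteristic parameter measured over n repeated cycles under
identical nominal conditions, the summary holds the sample mean, the sample
(n-1) variance and SD, and the coefficient of variation CV = 100 * SD/mean
in percent.  The CV carries the sign of the mean (a parameter whose mean is
negative reports a negative CV, as is conventional in sensor repeatability
tables); rankings use |CV|.  A small |CV| indicates a stable, repeatable
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinetics import ResponseFeatures


class InputError(ValueError):
    pass


@dataclass
class StatsSummary:
    """Per-parameter repeatability statistics.

    ``table`` is indexed by parameter label with columns
    ``mean, variance, sd, cv_percent, n``.  Parameters whose mean is zero
    have an undefined CV (NaN) and are listed in ``undefined_cv``.
    """

    table: pd.DataFrame
    undefined_cv: set = field(default_factory=set)

    def cv(self, label: str) -> float:
        return float(self.table.loc[label, "cv_percent"])

    def mean(self, label: str) -> float:
        return float(self.table.loc[label, "mean"])

    @property
    def labels(self) -> list:
        return list(self.table.index)


def features_frame(features: Iterable[ResponseFeatures]) -> pd.DataFrame:
    """Stack per-cycle feature records into a cycles x parameters DataFrame."""
    return pd.DataFrame([f.to_dict() for f in features])


def summarize_ensemble(features: Sequence[ResponseFeatures] | pd.DataFrame
                       ) -> StatsSummary:
    """Mean, sample variance/SD and signed CV per parameter over an ensemble.

    Requires at least two cycles.  NaN feature values (flagged missing at
    extraction) are dropped per parameter, with the effective n recorded.
    """
    df = features if isinstance(features, pd.DataFrame) else features_frame(features)
    if len(df) < 2:
        raise InputError("an ensemble summary needs at least 2 cycles")

    rows = {}
    undefined = set()
    for col in df.columns:
        x = df[col].dropna().to_numpy(dtype=float)
        n = x.size
        if n < 2:
            rows[col] = dict(mean=np.nan, variance=np.nan, sd=np.nan,
                             cv_percent=np.nan, n=n)
            undefined.add(col)
            continue
        mean = float(np.mean(x))
        var = float(np.var(x, ddof=1))
        sd = float(np.sqrt(var))
        if mean == 0.0:
            cv = np.nan
            undefined.add(col)
        else:
            cv = 100.0 * sd / mean     # signed: carries the sign of the mean
        rows[col] = dict(mean=mean, variance=var, sd=sd, cv_percent=cv, n=n)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return StatsSummary(table, undefined)


def rank_stability(summary: StatsSummary, cv_threshold: float) -> list:
    """Parameters with |CV| <= threshold (percent), ascending by |CV|.

    Ties are broken alphabetically by parameter label; parameters with an
    undefined CV are excluded.
    """
    rows = []
    for label in summary.labels:
        cv = summary.table.loc[label, "cv_percent"]
        if np.isnan(cv) or abs(cv) > cv_threshold:
            continue
        rows.append((abs(float(cv)), label))
    return [label for _, label in sorted(rows)]
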