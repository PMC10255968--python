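"""Reference measurements packaged with the library.

Two kinds of worked-example data ship with the package, both from a
characterization study of an electrochemical ethylene sensor used for
avocado ripening monitoring:

* the avocado hardness table (grams, texture analyzer) for an
  ethylene-treated group A and an air-control group B, measured before
  ripening and after one and two days — the worked example for the change
  amplitude vector analysis;
* the repeatability statistics (means and coefficients of variation) and
  Pearson correlation tables of the 23 characteristic parameters over ten
  repeated fixed-concentration cycles — the worked example for stability
  ranking and feature-subset selection.

The sensor recordings behind the statistics tables were not published;
only the aggregated tables are available and are reproduced here verbatim.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .ensemble_stats import StatsSummary
from .feature_selection import CorrelationMatrix
from .kinetics import ALL_PARAMS

#: avocado hardness during ripening, grams; the pre-ripening pool is shared
#: between groups (group label 'both')
AVOCADO_HARDNESS_CSV = """\
sample,group,day,hardness
Sample A,both,before,9225.428
Sample B,both,before,9070.682
Sample C,both,before,9406.169
Sample A,B,day1,772.574
Sample B,B,day1,2360.329
Sample C,B,day1,1645.132
Sample A,A,day1,800.262
Sample B,A,day1,1145.055
Sample C,A,day1,1232.887
Sample A,B,day2,702.202
Sample B,B,day2,509.614
Sample C,B,day2,759.652
Sample A,A,day2,492.847
Sample B,A,day2,286.187
Sample C,A,day2,6.768
"""


def load_avocado_hardness() -> pd.DataFrame:
    """The packaged avocado hardness ripening table (grams)."""
    return pd.read_csv(io.StringIO(AVOCADO_HARDNESS_CSV))


#: per-parameter (mean, CV%) over ten repeated 21 ppm cycles
REFERENCE_STATS = {
    # response levels, ppm
    "Xa": (0.388, 2.21), "Xg": (20.6, 2.42), "Xm": (21.5, 3.54),
    "Xres": (19.81, 2.84), "Xrec": (1.87, 16.32), "Xrecair": (0.74, 57.76),
    # time parameters, s
    "tres": (26.7, 4.69), "trec": (52.4, 2.05),
    "tDres": (12.3, 7.71), "tDrec": (12.9, 9.28),
    "tDresn": (16.3, 6.5), "tDresx": (6.2, 14.82),
    "tDrecn": (6.7, 17.31), "tDrecx": (16.3, 6.50),
    # derivative extrema, ppm/s and ppm/s^2 (second-order extrema signed)
    "Dres": (2.31, 3.28), "Drec": (2.41, 3.51),
    "Dresn": (-0.25, -5.22), "Dresx": (0.54, 6.31),
    "Drecn": (-0.64, -3.29), "Drecx": (0.47, 4.52),
    # integrals, ppm*s: only correlations were reported; means are not
    # available and are left NaN (they do not enter the selection rules)
    "intT": (np.nan, np.nan), "intPres": (np.nan, np.nan),
    "intPrec": (np.nan, np.nan),
}

_REFERENCE_N = 10

_TIME_CORR_LOWER = """\
,tres,trec,tDres,tDrec,tDresn,tDresx,tDrecn,tDrecx
tres,1,,,,,,,
trec,-0.06606,1,,,,,,
tDres,0.364932,-0.02179,1,,,,,
tDrec,0.42264,0.120869,-0.26414,1,,,,
tDresn,0.075418,0.565914,0.011056,0.113891,1,,,
tDresx,0.251164,0.584898,-0.20393,0.020199,0.616348,1,,
tDrecn,-0.14546,0.730978,0.292929,-0.10405,0.17187,0.166848,1,
tDrecx,-0.51116,0.2732,0.121616,0.113891,0.207921,-0.29676,0.53370,1
"""

_DERIV_CORR_LOWER = """\
,Dres,Drec,Dresn,Dresx,Drecn,Drecx
Dres,1,,,,,
Drec,0.071136,1,,,,
Dresn,-0.49589,0.276845,1,,,
Dresx,0.202957,0.416269,0.06747,1,,
Drecn,-0.65594,-0.01297,0.297729,-0.10284,1,
Drecx,-0.02493,0.38014,-0.38383,0.288566,-0.13551,1
"""

_INTEGRAL_CORR_LOWER = """\
,Xg,intT,intPres,intPrec
Xg,1,,,
intT,0.12053,1,,
intPres,-0.6605,-0.29101,1,
intPrec,0.123797,-0.27378,0.114264,1
"""


def _symmetric(lower_csv: str) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(lower_csv), index_col=0).astype(float)
    m = df.to_numpy()
    iu = np.triu_indices_from(m, k=1)
    m[iu] = m.T[iu]
    return pd.DataFrame(m, index=df.index, columns=df.columns)


def reference_stats_summary() -> StatsSummary:
    """Repeatability statistics of the reference experiment as a summary.

    SD and variance are reconstructed from mean and CV; parameters without
    published statistics (the integrals) carry NaN and an undefined CV.
    """
    rows, undefined = {}, set()
    for label in ALL_PARAMS:
        mean, cv = REFERENCE_STATS[label]
        if np.isnan(mean):
            rows[label] = dict(mean=np.nan, variance=np.nan, sd=np.nan,
                               cv_percent=np.nan, n=_REFERENCE_N)
            undefined.add(label)
            continue
        sd = abs(cv) * abs(mean) / 100.0
        rows[label] = dict(mean=mean, variance=sd ** 2, sd=sd,
                           cv_percent=cv, n=_REFERENCE_N)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return StatsSummary(table, undefined)


def reference_time_correlations() -> CorrelationMatrix:
    """Pearson correlations among the eight time parameters."""
    return CorrelationMatrix(_symmetric(_TIME_CORR_LOWER), n=_REFERENCE_N)


def reference_derivative_correlations() -> CorrelationMatrix:
    """Pearson correlations among the six derivative extrema."""
    return CorrelationMatrix(_symmetric(_DERIV_CORR_LOWER), n=_REFERENCE_N)


def reference_integral_correlations() -> CorrelationMatrix:
    """Pearson correlations of the three integrals with the steady-state
    response Xg."""
    return CorrelationMatrix(_symmetric(_INTEGRAL_CORR_LOWER), n=_REFERENCE_N)
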