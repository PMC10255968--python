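"""End-to-end analysis pipeline and its run configuration.

The stages run in the order of the underlying test method: preprocess the
raw cycles, extract the characteristic parameters, compute repeatability
statistics and correlation matrices, select the feature subset, then run
the ripening correlation analysis (change amplitude vectors, difference
ratios, optimal kinetic parameters, group comparison).  A run is fully
reproducible: the report embeds the package version, the seed and a hash
of the canonical config JSON, and identical configs yield byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .datasets import load_avocado_hardness
from .ensemble_stats import features_frame, rank_stability, summarize_ensemble
from .feature_selection import SelectionRules, pearson_matrix, select_feature_subset
from . import kinetics as _kin
from .kinetics import extract_features, segment_stages
from .preprocessing import FilterConfig, preprocess
from .ripening import (PhaseWindows, change_vector, compare_groups,
                       difference_ratio, kinetic_change_vector,
                       select_optimal_parameters)
from .signal_model import (CycleConfig, RipeningTableConfig,
                           RipeningTrajectoryConfig,
                           default_ripening_trajectory_config,
                           generate_cycle_ensemble,
                           generate_ripening_table,
                           generate_ripening_trajectory)


@dataclass(frozen=True)
class RunConfig:
    """Complete settings of one pipeline run.

    Every threshold used by any stage appears here with its default, so a
    serialized config fully determines the run.  ``ripening_table_path``
    may be a CSV path or ``"packaged"`` for the bundled avocado hardness
    worked example; ``None`` generates a synthetic table.
    """

    seed: int = 0
    n_cycles: int = 10
    between_cycle_cv: float = 2.4
    cycle: CycleConfig = field(default_factory=CycleConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    rules: SelectionRules = field(default_factory=SelectionRules)
    trajectory: RipeningTrajectoryConfig | None = None
    ripening_table_path: str | None = "packaged"
    ripening_table: RipeningTableConfig = field(default_factory=RipeningTableConfig)
    phase_window1: tuple = (600.0, 700.0)
    phase_window2: tuple = (2200.0, 2400.0)
    trajectory_filter_window: int = 31

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=_plain)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    if obj is None:
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return None if np.isnan(x) else round(float(x), nd)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the JSON-serializable report."""
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "defaults": {
            "mean_filter_window": config.filter.window_length,
            "outlier_window": config.filter.outlier_window,
            "outlier_threshold": config.filter.outlier_threshold,
            "cv_threshold_percent": config.rules.cv_threshold,
            "response_time_fraction": _kin.RESPONSE_FRAC,
            "recovery_time_fraction": _kin.RECOVERY_FRAC,
            "rise_stage_fraction": _kin.RISE_STAGE_FRAC,
            "cv_definition": "sample (n-1) SD; signed CV = 100*SD/mean",
        },
    }

    # --- repeatability experiment: ensemble -> features -> stats -> selection
    cycle_cfg = dataclasses.replace(config.cycle, seed=config.seed)
    try:
        ensemble = generate_cycle_ensemble(cycle_cfg, config.n_cycles,
                                           config.between_cycle_cv)
        feats = []
        for trace, _truth in ensemble:
            clean = preprocess(trace, config.filter)
            feats.append(extract_features(clean, segment_stages(clean)))
    except Exception as exc:
        raise RuntimeError(f"stage 'extract' failed on synthetic ensemble: {exc}") from exc

    df = features_frame(feats)
    report["features"] = {"n_cycles": len(feats),
                          "n_parameters": df.shape[1],
                          "per_cycle": _round(df.to_dict(orient="records"))}

    summary = summarize_ensemble(df)
    report["stats"] = _round(summary.table.to_dict(orient="index"))
    report["stable_parameters"] = rank_stability(summary, config.rules.cv_threshold)

    time_corr = pearson_matrix(df, _kin.TIME_PARAMS)
    deriv_corr = pearson_matrix(df, _kin.FIRST_DERIV_PARAMS + _kin.SECOND_DERIV_PARAMS)
    integral_corr = pearson_matrix(df, ("Xg",) + _kin.INTEGRAL_PARAMS)
    report["correlations"] = {
        "time": _round(time_corr.r.to_dict(orient="index")),
        "derivative": _round(deriv_corr.r.to_dict(orient="index")),
        "integral": _round(integral_corr.r.to_dict(orient="index")),
    }
    selection = select_feature_subset(summary, time_corr, deriv_corr,
                                      integral_corr, config.rules)
    report["selection"] = {"selected": selection.selected,
                           "trace": _round(selection.trace)}

    # --- ripening experiment: table + trajectory -> change vectors -> ranking
    if config.ripening_table_path == "packaged":
        table = load_avocado_hardness()
        table_src = "packaged avocado hardness"
    elif config.ripening_table_path is not None:
        from .traceio import read_ripening_table
        table = read_ripening_table(config.ripening_table_path)
        table_src = str(config.ripening_table_path)
    else:
        tbl_cfg = dataclasses.replace(config.ripening_table, seed=config.seed)
        table = generate_ripening_table(tbl_cfg)
        table_src = "synthetic"

    metrics = tuple(m for m in ("hardness", "springiness", "cohesiveness",
                                "adhesiveness", "chewiness", "resilience")
                    if m in table.columns)
    ripening_cav = change_vector(table, "A", metrics)
    report["ripening"] = {
        "table_source": table_src,
        "change_amplitude_A": _round(ripening_cav.changes),
        "group_comparison": _round(compare_groups(table).reset_index()
                                   .to_dict(orient="records")),
    }

    traj_cfg = config.trajectory or default_ripening_trajectory_config()
    traj_cfg = dataclasses.replace(traj_cfg, seed=config.seed)
    traj = generate_ripening_trajectory(traj_cfg)
    from .preprocessing import mean_filter
    traj_clean = mean_filter(traj, config.trajectory_filter_window)
    windows = PhaseWindows(config.phase_window1, config.phase_window2)
    kin_cav = kinetic_change_vector(traj_clean, windows)
    reference = tuple(m for m in ("hardness", "adhesiveness", "chewiness")
                      if m in metrics)
    scores = difference_ratio(ripening_cav, kin_cav, reference)
    report["ripening"]["kinetic_change_amplitude"] = _round(kin_cav.changes)
    report["ripening"]["difference_ratio"] = _round(
        {fam: dataclasses.asdict(fs) for fam, fs in scores.items()})
    report["ripening"]["optimal_parameters"] = select_optimal_parameters(scores)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n",
                          encoding="utf-8")
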