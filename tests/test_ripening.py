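"""Change amplitude vectors, difference ratios and group comparison."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ethylene_kinetics.preprocessing import mean_filter
from ethylene_kinetics.ripening import (ChangeAmplitudeVector, InputError,
                                        PhaseWindows, change_vector,
                                        compare_groups, difference_ratio,
                                        kinetic_change_vector,
                                        select_optimal_parameters)
from ethylene_kinetics.signal_model import (RipeningTableConfig,
                                            default_ripening_trajectory_config,
                                            demo_ripening_trajectory_config,
                                            generate_ripening_table,
                                            generate_ripening_trajectory)

WINDOWS = PhaseWindows((600.0, 700.0), (2200.0, 2400.0))


def _table(m0, m1a, m2a, m1b=None, m2b=None):
    rows = [{"group": "both", "day": "before", "hardness": v} for v in m0]
    rows += [{"group": "A", "day": "day1", "hardness": v} for v in m1a]
    rows += [{"group": "A", "day": "day2", "hardness": v} for v in m2a]
    rows += [{"group": "B", "day": "day1", "hardness": v} for v in (m1b or m1a)]
    rows += [{"group": "B", "day": "day2", "hardness": v} for v in (m2b or m2a)]
    return pd.DataFrame(rows)


class TestChangeVector:
    def test_packaged_hardness_changes(self, hardness_table):
        """Group A avocado hardness: Change I 88.53%, Change II 75.28%."""
        cav = change_vector(hardness_table, "A", ("hardness",))
        c1, c2 = cav["hardness"]
        assert round(c1, 2) == 88.53
        assert round(c2, 2) == 75.28

    def test_constant_means_zero_changes(self):
        cav = change_vector(_table([5.0], [5.0], [5.0]), "A", ("hardness",))
        assert cav["hardness"] == (0.0, 0.0)

    def test_halving_means_fifty_percent_changes(self):
        cav = change_vector(_table([100.0], [50.0], [25.0]), "A", ("hardness",))
        assert cav["hardness"] == pytest.approx((50.0, 50.0), abs=1e-12)

    def test_zero_denominator_flagged(self):
        cav = change_vector(_table([5.0], [0.0], [1.0]), "A", ("hardness",))
        assert "hardness" in cav.undefined

    def test_missing_day_rejected(self):
        t = _table([5.0], [4.0], [3.0])
        with pytest.raises(InputError):
            change_vector(t[t.day != "day2"], "A", ("hardness",))

    def test_generated_table_changes_match_configured_factors(self):
        """With zero spread, Change I = 100(1-f1) and Change II = 100(1-f2)."""
        cfg = RipeningTableConfig(rel_sd=0.0)
        table = generate_ripening_table(cfg)
        cav = change_vector(table, "A")
        for metric, (f1, f2, _, _) in cfg.factors.items():
            c1, c2 = cav[metric]
            assert c1 == pytest.approx(100 * (1 - f1), abs=1e-9)
            assert c2 == pytest.approx(100 * (1 - f2), abs=1e-9)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_unit_rescaling_invariance(self, c):
        t1 = _table([100.0, 90.0], [40.0], [10.0])
        t2 = t1.copy()
        t2["hardness"] *= c
        cav1 = change_vector(t1, "A", ("hardness",))
        cav2 = change_vector(t2, "A", ("hardness",))
        assert cav2["hardness"] == pytest.approx(cav1["hardness"], rel=1e-9)


class TestKineticChangeVector:
    def test_demo_trajectory_reproduces_response_changes(self):
        """Segment means 18 -> 13 -> 8.77 ppm give response changes of
        27.78% and 32.54%."""
        cfg = dataclasses.replace(demo_ripening_trajectory_config(), noise_sd=0.0)
        trace = generate_ripening_trajectory(cfg)
        cav = kinetic_change_vector(trace, WINDOWS)
        c1, c2 = cav["response"]
        assert c1 == pytest.approx(27.78, abs=0.05)
        assert c2 == pytest.approx(32.53, abs=0.05)

    def test_flat_trace_all_zero_changes(self):
        cfg = dataclasses.replace(default_ripening_trajectory_config(),
                                  peak_ppm=0.0, noise_sd=0.0)
        trace = generate_ripening_trajectory(cfg)
        trace = trace.copy_with(trace.values + 3.0)   # flat nonzero level
        cav = kinetic_change_vector(trace, WINDOWS)
        assert cav["response"] == pytest.approx((0.0, 0.0), abs=1e-9)
        assert cav["integral"][0] < 0    # cumulative integral still grows

    def test_derivative_changes_may_leave_0_100(self):
        """The relative-change formula is applied unchanged to derivative
        extrema, so values outside [0, 100]% are legitimate."""
        cfg = dataclasses.replace(default_ripening_trajectory_config(), noise_sd=0.0)
        trace = generate_ripening_trajectory(cfg)
        cav = kinetic_change_vector(trace, WINDOWS)
        c1_int, _ = cav["integral"]
        assert c1_int < 0    # growing cumulative integral: negative "decline"

    def test_window_outside_trace_rejected(self):
        cfg = default_ripening_trajectory_config()
        trace = generate_ripening_trajectory(cfg)
        with pytest.raises(InputError):
            kinetic_change_vector(trace, PhaseWindows((600.0, 700.0),
                                                      (2900.0, 3200.0)))


class TestDifferenceRatio:
    def _ripening(self):
        return ChangeAmplitudeVector({"hardness": (60.0, 40.0)})

    def test_identical_vectors_score_zero(self):
        kin = ChangeAmplitudeVector({"response": (60.0, 40.0)})
        scores = difference_ratio(self._ripening(), kin, ("hardness",))
        assert scores["response"].score == pytest.approx(0.0, abs=1e-12)
        assert scores["response"].eligible

    def test_doubled_changes_score_one(self):
        kin = ChangeAmplitudeVector({"response": (120.0, 80.0)})
        scores = difference_ratio(self._ripening(), kin, ("hardness",))
        assert scores["response"].score == pytest.approx(1.0, abs=1e-12)

    def test_non_declining_family_ineligible(self):
        kin = ChangeAmplitudeVector({"integral": (-30.0, 20.0)})
        scores = difference_ratio(self._ripening(), kin, ("hardness",))
        assert not scores["integral"].eligible

    def test_default_scenario_ranks_response_and_first_derivative_first(
            self, hardness_table):
        """On the default synthetic ripening scenario the response and
        first-derivative families are the two most ripening-concordant."""
        rip = change_vector(hardness_table, "A", ("hardness",))
        cfg = default_ripening_trajectory_config(seed=4)
        trace = mean_filter(generate_ripening_trajectory(cfg), 31)
        scores = difference_ratio(rip, kinetic_change_vector(trace, WINDOWS),
                                  ("hardness",))
        ranking = select_optimal_parameters(scores)
        assert set(ranking[:2]) == {"response", "first_derivative"}
        eligible_scores = sorted(fs.score for fs in scores.values() if fs.eligible)
        assert [scores[f].score for f in ranking] == eligible_scores


class TestCompareGroups:
    def test_packaged_table_day_means(self, hardness_table):
        out = compare_groups(hardness_table)
        assert out.loc["day1", "mean_A"] == pytest.approx(1059.40, abs=0.01)
        assert out.loc["day1", "mean_B"] == pytest.approx(1592.68, abs=0.01)
        assert out.loc["day2", "mean_A"] == pytest.approx(261.93, abs=0.01)
        assert out.loc["day2", "mean_B"] == pytest.approx(657.16, abs=0.01)
        assert (out["mean_A"] < out["mean_B"]).all()

    def test_identical_groups_zero_difference(self):
        t = _table([9.0], [4.0, 5.0], [2.0, 3.0])
        out = compare_groups(t)
        assert np.allclose(out["mean_diff"], 0.0)

    def test_single_sample_flags_test_unavailable(self):
        t = _table([9.0], [4.0], [2.0])
        out = compare_groups(t)
        assert out.loc["day1", "mean_A"] == 4.0
        assert np.isnan(out.loc["day1", "p_value"])
        assert "unavailable" in out.loc["day1", "flag"]
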