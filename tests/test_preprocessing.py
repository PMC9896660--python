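import numpy as np
import pandas as pd
import pytest

from alsflow import (
    ALSFRS_ITEMS,
    MappingConfig,
    alsfrs_to_mitos,
    apply_cohort_filters,
    build_event_log,
    cohort_table,
    encode_state_label,
    parse_state_label,
    state_activities,
)
from alsflow.errors import ConfigError, ConsistencyError, IncompleteAssessmentError
from alsflow.preprocessing import MiToSState


def full_scores(**overrides):
    scores = {item: 4 for item in ALSFRS_ITEMS}
    scores.update(overrides)
    return scores


def visit_row(pid, t, **overrides):
    return {"patient_id": pid, "visit_time": float(t), **full_scores(**overrides)}


class TestMapping:
    def test_full_scores_mean_no_impairment(self):
        assert alsfrs_to_mitos(full_scores()).label == "M_0000"

    def test_walking_item_low_flags_first_domain(self):
        assert alsfrs_to_mitos(full_scores(walking=1)).label == "M_1000"

    def test_swallowing_zero_flags_second_domain(self):
        assert alsfrs_to_mitos(full_scores(swallowing=0)).label == "M_0100"

    def test_communicating_needs_both_speech_and_handwriting(self):
        assert alsfrs_to_mitos(full_scores(speech=1)).label == "M_0000"
        assert alsfrs_to_mitos(full_scores(speech=1, handwriting=0)).label == "M_0010"

    def test_dressing_also_triggers_walking_selfcare(self):
        assert alsfrs_to_mitos(full_scores(dressing_hygiene=0)).label == "M_1000"

    def test_missing_item_names_the_domain(self):
        scores = full_scores()
        del scores["breathing"]
        with pytest.raises(IncompleteAssessmentError, match="breathing"):
            alsfrs_to_mitos(scores)

    def test_label_round_trip_over_all_16_states(self):
        for label in state_activities():
            assert encode_state_label(parse_state_label(label)) == label

    def test_named_states_from_flags(self):
        assert encode_state_label(MiToSState(0, 0, 0, 0)) == "M_0000"
        assert encode_state_label(MiToSState(0, 0, 1, 1)) == "M_0011"
        assert encode_state_label(MiToSState(1, 1, 1, 1)) == "M_1111"


@pytest.fixture
def toy_cohort():
    """Four patients probing each subject-level filter rule."""
    statics = pd.DataFrame(
        [
            {"patient_id": "no_onset", "onset_recorded": False, "trial_start_time": 100.0,
             "survival_event": "Censored", "survival_time": 500.0},
            {"patient_id": "late_onset", "onset_recorded": True, "trial_start_time": -50.0,
             "survival_event": "Censored", "survival_time": 500.0},
            {"patient_id": "no_alsfrs", "onset_recorded": True, "trial_start_time": 100.0,
             "survival_event": "Censored", "survival_time": 500.0},
            {"patient_id": "ok", "onset_recorded": True, "trial_start_time": 100.0,
             "onset_site": "Spinal", "age_at_onset": 55.0, "sex": "Male",
             "survival_event": "Dead", "survival_time": 500.0},
        ]
    )
    bare = {item: np.nan for item in ALSFRS_ITEMS}
    visits = pd.DataFrame(
        [
            visit_row("no_onset", 120),
            visit_row("late_onset", 120),
            {"patient_id": "no_alsfrs", "visit_time": 120.0, **bare},
            visit_row("ok", 50),          # pre-trial, dropped at visit level
            visit_row("ok", 150),
        ]
    )
    return visits, statics


class TestCohortFilters:
    def test_each_rule_removes_its_patient(self, toy_cohort):
        visits, statics = toy_cohort
        _, kept, report = apply_cohort_filters(visits, statics)
        assert list(kept["patient_id"]) == ["ok"]
        assert report.removed_subjects == {
            "missing_onset": 1,
            "onset_after_trial_start": 1,
            "no_functional_assessment": 1,
            "no_visit_in_window": 0,
        }
        assert report.check_conservation()

    def test_pre_trial_visit_dropped_post_trial_kept(self, toy_cohort):
        visits, statics = toy_cohort
        kept_visits, _, report = apply_cohort_filters(visits, statics)
        assert list(kept_visits["patient_id"]) == ["ok"]
        assert kept_visits["visit_time"].tolist() == [150.0]
        assert report.removed_visits["visit_before_trial_start"] == 1

    def test_registry_mode_skips_trial_rules(self, toy_cohort):
        visits, statics = toy_cohort
        _, kept, report = apply_cohort_filters(visits, statics, trial_mode=False)
        assert sorted(kept["patient_id"]) == ["late_onset", "ok"]
        assert "onset_after_trial_start" not in report.removed_subjects
        assert "no_visit_in_window" not in report.removed_subjects

    def test_window_outside_six_months_removes_patient(self):
        statics = pd.DataFrame([{"patient_id": "p", "onset_recorded": True,
                                 "trial_start_time": 100.0}])
        visits = pd.DataFrame([visit_row("p", 400)])  # 300 days after start
        _, kept, report = apply_cohort_filters(visits, statics, window_days=183)
        assert kept.empty
        assert report.removed_subjects["no_visit_in_window"] == 1

    def test_non_positive_window_rejected(self, toy_cohort):
        visits, statics = toy_cohort
        with pytest.raises(ConfigError):
            apply_cohort_filters(visits, statics, window_days=0)


class TestBuildEventLog:
    def statics_for(self, pid, event="Dead", time=300.0):
        return pd.DataFrame([{"patient_id": pid, "trial_start_time": 10.0,
                              "onset_site": "Spinal", "age_at_onset": 55.0, "sex": "Male",
                              "survival_event": event, "survival_time": time}])

    def test_state_change_emission(self):
        visits = pd.DataFrame([
            visit_row("p", 20), visit_row("p", 60),
            visit_row("p", 100, walking=1), visit_row("p", 140, walking=1),
        ])
        log = build_event_log(visits, self.statics_for("p"))
        assert log["p"].activities() == ["Onset", "TrialStart", "M_0000", "M_1000", "Dead"]
        assert [e.timestamp for e in log["p"].events] == [0.0, 10.0, 20.0, 100.0, 300.0]

    def test_single_visit_censored_gives_four_events(self):
        visits = pd.DataFrame([visit_row("p", 20, swallowing=0)])
        log = build_event_log(visits, self.statics_for("p", event="Censored"))
        assert log["p"].activities() == ["Onset", "TrialStart", "M_0100", "Censored"]

    def test_lock_monotone_suppresses_regression(self):
        visits = pd.DataFrame([visit_row("p", 20, walking=1), visit_row("p", 60)])
        log = build_event_log(visits, self.statics_for("p"),
                              config=MappingConfig.default(lock_monotone=True))
        assert log["p"].activities() == ["Onset", "TrialStart", "M_1000", "Dead"]

    def test_without_lock_regression_is_visible(self):
        visits = pd.DataFrame([visit_row("p", 20, walking=1), visit_row("p", 60)])
        log = build_event_log(visits, self.statics_for("p"))
        assert "M_0000" in log["p"].activities()

    def test_survival_before_last_visit_is_inconsistent(self):
        visits = pd.DataFrame([visit_row("p", 20), visit_row("p", 400)])
        with pytest.raises(ConsistencyError):
            build_event_log(visits, self.statics_for("p", time=300.0))

    def test_emission_is_idempotent(self):
        """Re-encoding an already change-compressed sequence emits the same events."""
        visits = pd.DataFrame([
            visit_row("p", 20), visit_row("p", 100, walking=1),
            visit_row("p", 200, walking=1, swallowing=1),
        ])
        statics = self.statics_for("p")
        first = build_event_log(visits, statics)["p"].activities()
        assert first == build_event_log(visits, statics)["p"].activities()
        assert first == ["Onset", "TrialStart", "M_0000", "M_1000", "M_1100", "Dead"]

    def test_lock_monotone_impairments_never_decrease(self):
        rng = np.random.default_rng(7)
        rows = []
        for t in range(10):
            scores = {item: int(rng.integers(0, 5)) for item in ALSFRS_ITEMS}
            rows.append({"patient_id": "p", "visit_time": float(10 * (t + 1)), **scores})
        log = build_event_log(pd.DataFrame(rows), self.statics_for("p", time=1000.0),
                              config=MappingConfig.default(lock_monotone=True))
        burdens = [parse_state_label(a).n_impaired for a in log["p"].activities()
                   if a.startswith("M_")]
        assert burdens == sorted(burdens)


class TestCohortTable:
    def test_identical_continuous_samples(self):
        a = pd.DataFrame({"age": [50.0, 55.0, 60.0]})
        table = cohort_table(a, a.copy(), {"age": "continuous"})
        row = table.iloc[0]
        assert row["statistic"] == 0.0 and row["p_value"] == 1.0

    def test_balanced_categorical_counts(self):
        a = pd.DataFrame({"sex": ["M"] * 10 + ["F"] * 10})
        table = cohort_table(a, a.copy(), {"sex": "categorical"})
        row = table[table["test"] == "chi2"].iloc[0]
        assert row["statistic"] == 0.0 and row["p_value"] == 1.0

    def test_shifted_samples_flagged_significant(self):
        a = pd.DataFrame({"x": np.arange(10.0)})
        b = pd.DataFrame({"x": np.arange(100.0, 110.0)})
        row = cohort_table(a, b, {"x": "continuous"}, alpha=0.01).iloc[0]
        assert row["p_value"] < 0.01 and row["significant"]

    def test_small_expected_counts_break_assumption(self):
        a = pd.DataFrame({"site": ["Spinal"] * 9 + ["Bulbar"]})
        b = pd.DataFrame({"site": ["Spinal"] * 2 + ["Bulbar"] * 2})
        row = cohort_table(a, b, {"site": "categorical"})
        assert not row[row["test"] == "chi2"].iloc[0]["assumption_ok"]

    def test_missing_variable_is_a_key_error(self):
        a = pd.DataFrame({"x": [1.0]})
        with pytest.raises(KeyError):
            cohort_table(a, pd.DataFrame({"y": [1.0]}), {"x": "continuous"})
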