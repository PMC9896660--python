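"""Cohort filtering, ALSFRS-to-MiToS conversion and event-log construction.

The ALS Functional Rating Scale (ALSFRS) scores ten daily/vital
abilities 0-4 each.  The Milano-Torino staging (MiToS) collapses the
scale into four binary functional domains -- Walking/Self-care,
Swallowing, Communicating, Breathing -- each flipping from intact (0) to
impaired (1) as the disease progresses.  A visit's overall impairment
state is written ``M_abcd`` with one digit per domain in that order.

The mapping from item scores to domain impairments is configurable
(:class:`MappingConfig`); the shipped default flags a domain as impaired
when its defining item(s) drop to a score of 1 or below:

* Walking/Self-care: walking <= 1  OR  dressing_hygiene <= 1
* Swallowing: swallowing <= 1
* Communicating: speech <= 1  AND  handwriting <= 1
* Breathing: breathing <= 1
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError, ConsistencyError, IncompleteAssessmentError
from .event_log import (
    CENSORED,
    DEAD,
    ONSET,
    TRIAL_START,
    Event,
    EventLog,
    Trace,
)

#: Canonical names of the ten ALSFRS items.
ALSFRS_ITEMS = (
    "speech",
    "salivation",
    "swallowing",
    "handwriting",
    "cutting_food",
    "dressing_hygiene",
    "turning_in_bed",
    "walking",
    "climbing_stairs",
    "breathing",
)

DOMAINS = ("walking_selfcare", "swallowing", "communicating", "breathing")


@dataclass(frozen=True)
class MiToSState:
    """Binary impairment flags for the four MiToS functional domains."""

    walking_selfcare: int
    swallowing: int
    communicating: int
    breathing: int

    @property
    def flags(self) -> tuple[int, int, int, int]:
        return (self.walking_selfcare, self.swallowing, self.communicating, self.breathing)

    @property
    def n_impaired(self) -> int:
        return sum(self.flags)

    @property
    def label(self) -> str:
        return encode_state_label(self)

    def union(self, other: "MiToSState") -> "MiToSState":
        """Domain-wise OR: once impaired, always impaired."""
        return MiToSState(*(max(a, b) for a, b in zip(self.flags, other.flags)))


def encode_state_label(state: MiToSState) -> str:
    """``M_abcd`` label in domain order walking, swallowing, communicating, breathing."""
    return "M_" + "".join(str(flag) for flag in state.flags)


def parse_state_label(label: str) -> MiToSState:
    if not (len(label) == 6 and label.startswith("M_") and set(label[2:]) <= {"0", "1"}):
        raise ValueError(f"not an M_abcd label: {label!r}")
    return MiToSState(*(int(c) for c in label[2:]))


@dataclass(frozen=True)
class DomainRule:
    """One domain's impairment rule over (item, max-score) pairs.

    The domain counts as impaired when the *combinator* ("any"/"all")
    holds over the conditions ``score(item) <= max_score``.
    """

    items: tuple[tuple[str, int], ...]
    combinator: str = "any"

    def __post_init__(self):
        if self.combinator not in ("any", "all"):
            raise ConfigError(f"combinator must be 'any' or 'all', got {self.combinator!r}")
        if not self.items:
            raise ConfigError("a domain rule needs at least one item condition")


@dataclass(frozen=True)
class MappingConfig:
    """Per-domain ALSFRS-to-MiToS rules plus the monotone-lock flag.

    With ``lock_monotone`` set, impairments are carried forward along a
    patient's visit sequence so a domain can never revert to intact; by
    default recorded regressions stay visible (they are useful for
    spotting data errors downstream).
    """

    rules: Mapping[str, DomainRule]
    lock_monotone: bool = False

    def __post_init__(self):
        missing = [d for d in DOMAINS if d not in self.rules]
        if missing:
            raise ConfigError(f"mapping lacks rules for domains {missing}")

    def referenced_items(self) -> set[str]:
        return {item for rule in self.rules.values() for item, _ in rule.items}

    @classmethod
    def default(cls, lock_monotone: bool = False) -> "MappingConfig":
        return cls(
            rules={
                "walking_selfcare": DomainRule(
                    (("walking", 1), ("dressing_hygiene", 1)), "any"
                ),
                "swallowing": DomainRule((("swallowing", 1),), "any"),
                "communicating": DomainRule(
                    (("speech", 1), ("handwriting", 1)), "all"
                ),
                "breathing": DomainRule((("breathing", 1),), "any"),
            },
            lock_monotone=lock_monotone,
        )

    @classmethod
    def from_yaml(cls, path) -> "MappingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = {
            domain: DomainRule(
                tuple((cond["item"], int(cond["max_score"])) for cond in spec["items"]),
                spec.get("combinator", "any"),
            )
            for domain, spec in raw["domains"].items()
        }
        return cls(rules=rules, lock_monotone=bool(raw.get("lock_monotone", False)))


def alsfrs_to_mitos(items: Mapping[str, object], config: MappingConfig | None = None) -> MiToSState:
    """Convert one visit's ALSFRS item scores into a MiToS state.

    *items* maps item name to integer score 0-4.  Every item a domain
    rule references must be present, otherwise that domain is
    undetermined and an :class:`IncompleteAssessmentError` is raised.
    """
    config = config or MappingConfig.default()
    flags = []
    for domain in DOMAINS:
        rule = config.rules[domain]
        conditions = []
        for item, max_score in rule.items:
            value = items.get(item)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise IncompleteAssessmentError(
                    f"item {item!r} needed for domain {domain!r} is missing"
                )
            conditions.append(int(value) <= max_score)
        hit = any(conditions) if rule.combinator == "any" else all(conditions)
        flags.append(int(hit))
    return MiToSState(*flags)


# ---------------------------------------------------------------------------
# Cohort filters

RULE_MISSING_ONSET = "missing_onset"
RULE_ONSET_AFTER_TRIAL_START = "onset_after_trial_start"
RULE_NO_FUNCTIONAL_ASSESSMENT = "no_functional_assessment"
RULE_NO_VISIT_IN_WINDOW = "no_visit_in_window"
VISIT_RULE_NO_ASSESSMENT = "visit_without_assessment"
VISIT_RULE_BEFORE_TRIAL = "visit_before_trial_start"


@dataclass
class FilterReport:
    """Tally of subjects and visits removed by each preprocessing rule."""

    subjects_before: int
    subjects_after: int
    visits_before: int
    visits_after: int
    removed_subjects: dict[str, int]
    removed_visits: dict[str, int]

    def check_conservation(self) -> bool:
        return self.subjects_before - sum(self.removed_subjects.values()) == self.subjects_after


def _has_assessment(row: pd.Series, items: Iterable[str]) -> bool:
    """A visit counts as a functional assessment when every mapped item is scored."""
    return all(pd.notna(row.get(item)) for item in items)


def apply_cohort_filters(
    visits: pd.DataFrame,
    statics: pd.DataFrame,
    window_days: float = 183.0,
    trial_mode: bool = True,
    config: MappingConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply the cohort-cleaning rules, in order, and tally removals.

    Subject-level rules: (1) unrecorded onset date; (2, trial mode)
    onset after trial start, i.e. ``trial_start_time < 0`` on the
    days-from-onset axis; (3) no visit carrying a functional assessment;
    (4, trial mode) no functional visit within *window_days* after
    trial start.  Visit-level rules then drop visits without a
    functional assessment and, in trial mode, visits before trial
    start.  A subject removed by an earlier rule is not counted under
    later rules.

    *visits* needs columns ``patient_id``, ``visit_time`` and the ALSFRS
    item columns referenced by *config* (default mapping if omitted);
    *statics* needs ``patient_id``, ``onset_recorded`` and, in trial
    mode, ``trial_start_time``.
    """
    if window_days <= 0:
        raise ConfigError(f"window_days must be positive, got {window_days}")
    config = config or MappingConfig.default()
    items = sorted(config.referenced_items())

    statics = statics.set_index("patient_id", drop=False)
    visits = visits.copy()
    subjects_before = len(statics)
    visits_before = len(visits)
    removed: dict[str, int] = {}
    alive = list(statics.index)

    def drop(rule: str, pids: set) -> None:
        nonlocal alive
        hit = [pid for pid in alive if pid in pids]
        removed[rule] = len(hit)
        alive = [pid for pid in alive if pid not in pids]

    drop(RULE_MISSING_ONSET, set(statics.index[~statics["onset_recorded"].astype(bool)]))

    if trial_mode:
        bad = set(statics.index[statics["trial_start_time"] < 0])
        bad |= set(statics.index[statics["trial_start_time"].isna()])
        drop(RULE_ONSET_AFTER_TRIAL_START, bad)

    has_assessment = visits.apply(lambda row: _has_assessment(row, items), axis=1)
    assessed = visits[has_assessment]
    with_assessment = set(assessed["patient_id"])
    drop(RULE_NO_FUNCTIONAL_ASSESSMENT, set(statics.index) - with_assessment)

    if trial_mode:
        start = statics["trial_start_time"]
        in_window: set = set()
        for pid, group in assessed.groupby("patient_id"):
            if pid not in start.index or pd.isna(start[pid]):
                continue
            lo, hi = start[pid], start[pid] + window_days
            if ((group["visit_time"] >= lo) & (group["visit_time"] <= hi)).any():
                in_window.add(pid)
        drop(RULE_NO_VISIT_IN_WINDOW, set(statics.index) - in_window)

    keep = visits["patient_id"].isin(alive)
    removed_visits = {
        VISIT_RULE_NO_ASSESSMENT: int((keep & ~has_assessment).sum()),
    }
    keep &= has_assessment
    if trial_mode:
        starts = visits["patient_id"].map(statics["trial_start_time"])
        pre_trial = keep & (visits["visit_time"] < starts)
        removed_visits[VISIT_RULE_BEFORE_TRIAL] = int(pre_trial.sum())
        keep &= ~pre_trial

    visits_out = visits[keep].reset_index(drop=True)
    statics_out = statics.loc[alive].reset_index(drop=True)
    report = FilterReport(
        subjects_before=subjects_before,
        subjects_after=len(statics_out),
        visits_before=visits_before,
        visits_after=len(visits_out),
        removed_subjects=removed,
        removed_visits=removed_visits,
    )
    return visits_out, statics_out, report


# ---------------------------------------------------------------------------
# Event-log construction

_ATTRIBUTE_COLUMNS = ("onset_site", "age_at_onset", "sex")


def build_event_log(
    visits: pd.DataFrame,
    statics: pd.DataFrame,
    config: MappingConfig | None = None,
    trial_mode: bool = True,
) -> EventLog:
    """Turn filtered visit and static tables into an event log.

    Per patient: ``Onset`` at day 0; ``TrialStart`` at its offset in
    trial mode; an ``M_abcd`` event at the first retained visit and at
    every later visit whose encoded state differs from the previously
    emitted one (with ``lock_monotone`` impairments are carried forward,
    so recorded regressions emit nothing); the terminal ``Dead`` or
    ``Censored`` event at ``survival_time``.  Static covariates become
    trace attributes.
    """
    config = config or MappingConfig.default()
    statics = statics.set_index("patient_id", drop=False)
    traces: list[Trace] = []
    for pid, group in visits.groupby("patient_id", sort=True):
        if pid not in statics.index:
            raise ConsistencyError(f"patient {pid!r} has visits but no static record")
        static = statics.loc[pid]
        group = group.sort_values("visit_time")

        events = [Event(ONSET, 0.0)]
        if trial_mode:
            events.append(Event(TRIAL_START, float(static["trial_start_time"])))

        previous: MiToSState | None = None
        for _, row in group.iterrows():
            state = alsfrs_to_mitos(row, config)
            if config.lock_monotone and previous is not None:
                state = previous.union(state)
            if previous is None or state != previous:
                events.append(Event(state.label, float(row["visit_time"])))
            previous = state

        survival_time = static.get("survival_time")
        if pd.isna(survival_time):
            if static.get("survival_event") == DEAD:
                raise ConsistencyError(f"patient {pid!r}: death without a survival_time")
            survival_time = float(group["visit_time"].max())
        survival_time = float(survival_time)
        # guard against statics contradicting the visit table, whether or
        # not the offending visit emitted a state change
        last = max(
            max(e.timestamp for e in events), float(group["visit_time"].max())
        )
        if survival_time < last:
            raise ConsistencyError(
                f"patient {pid!r}: survival_time {survival_time} precedes event at {last}"
            )
        terminal = DEAD if static.get("survival_event") == DEAD else CENSORED
        events.append(Event(terminal, survival_time))

        attributes = {
            name: static[name]
            for name in _ATTRIBUTE_COLUMNS
            if name in static.index and pd.notna(static[name])
        }
        traces.append(Trace(str(pid), events, attributes))
    return EventLog.from_traces(
        traces, trial_mode=trial_mode, lock_monotone=config.lock_monotone
    )


# ---------------------------------------------------------------------------
# Baseline cohort comparison


def cohort_table(
    cohort_a: pd.DataFrame,
    cohort_b: pd.DataFrame,
    variables: Mapping[str, str],
    alpha: float = 0.01,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Baseline comparison of two cohorts' static variables.

    *variables* maps column name to ``"continuous"`` or
    ``"categorical"``.  Continuous variables are summarized mean +/- SD
    per cohort and compared with a Kruskal-Wallis test; categorical ones
    as count (percent) per level with a chi-square test of independence
    (no continuity correction).  ``assumption_ok`` is False when any
    expected cell count falls below 5, mirroring the starred entries of
    baseline tables in the clinical literature.
    """
    rows = []
    for name, kind in variables.items():
        for frame in (cohort_a, cohort_b):
            if name not in frame.columns:
                raise KeyError(f"variable {name!r} absent from a cohort table")
        a = cohort_a[name].dropna()
        b = cohort_b[name].dropna()
        if kind == "continuous":
            pooled = np.concatenate([a.to_numpy(float), b.to_numpy(float)])
            if np.all(pooled == pooled[0]):
                stat, p = 0.0, 1.0  # a single tied value: H = 0 by construction
            else:
                stat, p = stats.kruskal(a, b)
            rows.append(
                {
                    "variable": name,
                    "level": "",
                    labels[0]: f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                    labels[1]: f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                    "test": "kruskal-wallis",
                    "statistic": float(stat),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                    "assumption_ok": True,
                }
            )
        elif kind == "categorical":
            levels = sorted(set(a) | set(b))
            counts = np.array(
                [[int((a == lv).sum()) for lv in levels], [int((b == lv).sum()) for lv in levels]]
            )
            if counts.sum() == 0:
                raise KeyError(f"variable {name!r} has no observations")
            stat, p, _, expected = stats.chi2_contingency(counts, correction=False)
            ok = bool((expected >= 5).all())
            for j, lv in enumerate(levels):
                rows.append(
                    {
                        "variable": name,
                        "level": str(lv),
                        labels[0]: f"{counts[0, j]} ({100 * counts[0, j] / max(len(a), 1):.1f})",
                        labels[1]: f"{counts[1, j]} ({100 * counts[1, j] / max(len(b), 1):.1f})",
                        "test": "chi2" if j == 0 else "",
                        "statistic": float(stat) if j == 0 else np.nan,
                        "p_value": float(p) if j == 0 else np.nan,
                        "significant": bool(p < alpha) if j == 0 else False,
                        "assumption_ok": ok if j == 0 else True,
                    }
                )
        else:
            raise ConfigError(f"variable kind must be continuous/categorical, got {kind!r}")
    return pd.DataFrame(rows)
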