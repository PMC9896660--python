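"""Synthetic ALS-like progression cohorts with known ground truth.

The generator follows a deliberately simple multistate model: each of
the four MiToS functional domains carries an independent exponential
clock (started at disease onset) whose rate is the product of a
baseline per-day hazard and an onset-site multiplier; impairments are
permanent.  Death follows a piecewise-exponential hazard that is
multiplied by a constant factor for every currently impaired domain
and scaled by an exponential age effect per decade above 55 years.
The latent trajectory is then observed through a visit schedule --
frequent and short for trial-like follow-up, sparse and long for
registry-like follow-up -- with impairments interval-censored to visit
dates and death times taken as exactly known.  The structure makes no
claim of biological fidelity; it exists so every pipeline stage has a
reproducible input whose qualitative behavior (site-specific first
impairment, age-death association, observation-granularity effects) is
known by construction.

Reproducibility: each patient draws from RNG substreams keyed by
``(seed, patient index, stage)``, so enlarging the cohort never
reshuffles existing patients and the emitted event-log CSV is
byte-identical for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .event_log import CENSORED, DEAD, ONSET, TRIAL_START, Event, EventLog, Trace
from .preprocessing import DOMAINS, MiToSState

#: Onset-site levels used by the generator.
SITES = ("Spinal", "Bulbar", "SpinalAndBulbar", "Other")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Rates are per-day hazards.  The defaults mimic a pooled-trial
    population: onset-site mix, age distribution and follow-up duration
    taken from the published cohort characterization of a large ALS
    trial repository (spinal-dominant mix, age 55.26 +/- 11.68 years,
    follow-up 407 +/- 175 days with roughly monthly visits); the
    registry preset stretches follow-up to 931 +/- 627 days with
    roughly quarterly-to-biannual visits.
    """

    n_patients: int
    seed: int
    # latent dynamics
    domain_hazards: dict[str, float] = field(
        default_factory=lambda: {
            "walking_selfcare": 8e-4,
            "swallowing": 4e-4,
            "communicating": 2.5e-4,
            "breathing": 3.5e-4,
        }
    )
    site_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Spinal": {"walking_selfcare": 2.0},
            "Bulbar": {"swallowing": 2.5, "communicating": 1.8, "walking_selfcare": 0.6},
            "SpinalAndBulbar": {"walking_selfcare": 1.5, "swallowing": 1.5},
            "Other": {},
        }
    )
    death_hazard: float = 3.5e-4
    death_domain_multiplier: float = 1.8
    death_age_effect: float = 0.3  # log-hazard per decade above 55
    # population
    site_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Spinal": 0.719,
            "Bulbar": 0.208,
            "SpinalAndBulbar": 0.011,
            "Other": 0.062,
        }
    )
    age_mean: float = 55.26
    age_sd: float = 11.68
    age_bounds: tuple[float, float] = (18.0, 95.0)
    sex_male_fraction: float = 0.626
    # observation schedule
    trial_mode: bool = True
    enrollment_delay_mean: float = 180.0
    enrollment_delay_sd: float = 90.0
    visit_interval_mean: float = 32.0
    visit_interval_sd: float = 5.0
    followup_mean: float = 407.0
    followup_sd: float = 175.0
    followup_min: float = 60.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if any(rate < 0 for rate in self.domain_hazards.values()) or self.death_hazard < 0:
            raise ConfigError("hazard rates must be non-negative")
        total = sum(self.site_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"site_mix fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.site_mix.values()):
            raise ConfigError("site_mix fractions must be non-negative")

    @classmethod
    def trial_like(cls, n_patients: int, seed: int, **overrides) -> "GeneratorConfig":
        """Trial-style follow-up: short, frequent, heavily censored."""
        return replace(cls(n_patients=n_patients, seed=seed), **overrides)

    @classmethod
    def registry_like(cls, n_patients: int, seed: int, **overrides) -> "GeneratorConfig":
        """Registry-style follow-up: long and sparse."""
        base = cls(
            n_patients=n_patients,
            seed=seed,
            trial_mode=False,
            visit_interval_mean=125.0,
            visit_interval_sd=25.0,
            followup_mean=931.0,
            followup_sd=627.0,
        )
        return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Latent per-patient state of a generated cohort.

    ``patients`` has one row per patient with covariates, the latent
    impairment time of each domain (``inf`` when never impaired), the
    latent death time, the enrollment offset and the administrative
    censoring time; ``visit_times`` holds the realized visit schedule
    once :func:`observe` has run.
    """

    patients: pd.DataFrame
    visit_times: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(config: GeneratorConfig, index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index, stage])


def sample_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw covariates for every patient: onset site, age at onset, sex.

    Ages follow a normal distribution truncated to ``age_bounds`` by
    resampling.  Deterministic for a fixed seed and independent of
    patients added later.
    """
    sites = list(config.site_mix)
    probs = np.array([config.site_mix[s] for s in sites])
    rows = []
    for i in range(config.n_patients):
        rng = _rng(config, i, 0)
        site = sites[int(rng.choice(len(sites), p=probs))]
        lo, hi = config.age_bounds
        age = float(rng.normal(config.age_mean, config.age_sd))
        while not lo <= age <= hi:
            age = float(rng.normal(config.age_mean, config.age_sd))
        sex = "Male" if rng.random() < config.sex_male_fraction else "Female"
        rows.append(
            {
                "patient_id": f"s{i:05d}",
                "onset_site": site,
                "age_at_onset": age,
                "sex": sex,
            }
        )
    return pd.DataFrame(rows)


def _death_time(
    rng: np.random.Generator,
    impairment_times: np.ndarray,
    config: GeneratorConfig,
    age: float,
) -> float:
    """Piecewise-exponential death time given the domain impairment times."""
    base = config.death_hazard * math.exp(
        config.death_age_effect * (age - 55.0) / 10.0
    )
    if base <= 0:
        return math.inf
    target = rng.exponential(1.0)
    boundaries = sorted(t for t in impairment_times if math.isfinite(t))
    t, acc, k = 0.0, 0.0, 0
    for b in [*boundaries, math.inf]:
        hazard = base * config.death_domain_multiplier**k
        span = b - t
        if math.isfinite(span) and acc + hazard * span < target:
            acc += hazard * span
            t = b
            k += 1
            continue
        return t + (target - acc) / hazard
    return math.inf


def simulate_progression(covariates: pd.DataFrame, config: GeneratorConfig) -> GroundTruth:
    """Sample latent impairment and death times for every patient.

    Each domain's impairment time is exponential with rate
    ``baseline x site multiplier`` (``inf`` for zero rates); death is
    piecewise-exponential with the hazard stepping up by the domain
    multiplier at every impairment and scaled by the age effect.
    """
    rows = []
    for i, cov in enumerate(covariates.itertuples(index=False)):
        rng = _rng(config, i, 1)
        multipliers = config.site_multipliers.get(cov.onset_site, {})
        times = np.empty(len(DOMAINS))
        for j, domain in enumerate(DOMAINS):
            rate = config.domain_hazards.get(domain, 0.0) * multipliers.get(domain, 1.0)
            times[j] = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        death = _death_time(rng, times, config, cov.age_at_onset)
        rows.append(
            {
                "patient_id": cov.patient_id,
                "onset_site": cov.onset_site,
                "age_at_onset": cov.age_at_onset,
                "sex": cov.sex,
                **{f"t_{domain}": times[j] for j, domain in enumerate(DOMAINS)},
                "death_time": death,
            }
        )
    return GroundTruth(patients=pd.DataFrame(rows))


def _state_at(row: pd.Series, time: float) -> MiToSState:
    return MiToSState(*(int(row[f"t_{domain}"] <= time) for domain in DOMAINS))


def observe(truth: GroundTruth, config: GeneratorConfig) -> EventLog:
    """Observe the latent cohort through the configured visit schedule.

    Visits start at the enrollment offset and recur at normally
    jittered intervals until death or administrative censoring at
    enrollment + follow-up.  The MiToS state is read at each visit and
    emitted on change (the first visit always emits); death is emitted
    at its exact time when it precedes censoring (registry-linkage
    assumption), otherwise the trace ends with ``Censored``.  In trial
    mode a ``TrialStart`` event marks the enrollment.  Fills
    ``truth.visit_times`` and per-patient ``enrollment``/``censor_time``
    columns as a side effect.
    """
    traces: list[Trace] = []
    enrollments, censor_times = [], []
    for i, row in truth.patients.iterrows():
        rng = _rng(config, int(i), 2)
        enrollment = max(
            0.0, float(rng.normal(config.enrollment_delay_mean, config.enrollment_delay_sd))
        )
        followup = float(rng.normal(config.followup_mean, config.followup_sd))
        followup = max(config.followup_min, followup)
        censor_time = enrollment + followup
        death = float(row["death_time"])
        end = min(censor_time, death)

        visits = []
        t = enrollment
        while t <= end:
            visits.append(t)
            t += max(1.0, float(rng.normal(config.visit_interval_mean, config.visit_interval_sd)))
        visit_arr = np.asarray(visits)
        truth.visit_times[row["patient_id"]] = visit_arr
        enrollments.append(enrollment)
        censor_times.append(censor_time)

        # patients dying before enrollment are never observed in follow-up:
        # their trace is Onset + Dead, with no TrialStart or visits
        events = [Event(ONSET, 0.0)]
        if config.trial_mode and death > enrollment:
            events.append(Event(TRIAL_START, enrollment))
        previous = None
        for v in visits:
            state = _state_at(row, v)
            if previous is None or state != previous:
                events.append(Event(state.label, float(v)))
            previous = state
        if death <= censor_time:
            events.append(Event(DEAD, death))
        else:
            events.append(Event(CENSORED, censor_time))
        traces.append(
            Trace(
                row["patient_id"],
                events,
                {
                    "onset_site": row["onset_site"],
                    "age_at_onset": float(row["age_at_onset"]),
                    "sex": row["sex"],
                },
            )
        )
    truth.patients = truth.patients.assign(enrollment=enrollments, censor_time=censor_times)
    return EventLog.from_traces(
        traces,
        source="synthetic",
        mode="trial" if config.trial_mode else "registry",
        seed=config.seed,
    )


def generate(config: GeneratorConfig) -> tuple[EventLog, GroundTruth]:
    """Sample covariates, latent trajectories and observations in one call."""
    covariates = sample_population(config)
    truth = simulate_progression(covariates, config)
    log = observe(truth, config)
    return log, truth


# ---------------------------------------------------------------------------
# Parameter-recovery utility


def estimate_first_impairment_rate(truth: GroundTruth, domain: str) -> float:
    """Exponential-rate estimate for one domain from interval-censored data.

    Uses the visit schedule realized by :func:`observe`: a patient
    whose impairment is first seen at visit ``v`` contributes the
    midpoint of the censoring interval (last unimpaired visit, or
    onset, to ``v``) as an event time; patients never observed impaired
    contribute their last visit as right-censored exposure.  The
    estimate is the maximum-likelihood ``events / total exposure``.
    """
    if not truth.visit_times:
        raise ValueError("observe() must run before rates can be recovered")
    events = 0
    exposure = 0.0
    col = f"t_{domain}"
    for _, row in truth.patients.iterrows():
        visits = truth.visit_times.get(row["patient_id"], np.empty(0))
        if len(visits) == 0:
            continue
        t_imp = float(row[col])
        detected = visits[visits >= t_imp]
        if len(detected) > 0:
            first_seen = float(detected[0])
            before = visits[visits < t_imp]
            left = float(before[-1]) if len(before) else 0.0
            exposure += (left + first_seen) / 2.0
            events += 1
        else:
            exposure += float(visits[-1])
    if events == 0:
        raise ValueError(f"no observed impairments for domain {domain!r}")
    return events / exposure
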