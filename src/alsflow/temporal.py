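"""Transition-time statistics between activities of an event log.

The "time to fly" from a source to a target activity is the
distribution of durations patients need to move between the two states,
either in one step (``consecutive_only``) or through an arbitrary
number of intermediate events.  Patients who reach the source but are
never observed in the target contribute right-censored durations up to
their last event.  On top of the collected durations the module offers
a Gaussian kernel-density estimate of the observed times, the
Kaplan-Meier product-limit curve honoring censoring, the two-group
log-rank test, and a Mann-Whitney comparison of observed durations that
falls back to qualitative inspection below a minimum sample size.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .errors import InsufficientDataError
from .event_log import EventLog


@dataclass
class TransitionTimes:
    """Observed and right-censored durations from a source to a target activity."""

    source: str
    target: str
    observed: np.ndarray
    censored: np.ndarray
    consecutive_only: bool = False

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_censored(self) -> int:
        return len(self.censored)

    def durations_events(self) -> tuple[np.ndarray, np.ndarray]:
        """All durations plus the 1/0 event indicator, observed first."""
        durations = np.concatenate([self.observed, self.censored])
        events = np.concatenate(
            [np.ones(len(self.observed), dtype=int), np.zeros(len(self.censored), dtype=int)]
        )
        return durations, events


def collect_transition_times(
    log: EventLog,
    source: str,
    target: str,
    consecutive_only: bool = False,
) -> TransitionTimes:
    """Collect per-patient durations from *source* to *target*.

    For every trace containing the source: the duration is the first
    target occurrence after the first source occurrence, minus the
    source time.  With ``consecutive_only`` the target must be the very
    next event after the source.  Traces reaching the source but not
    the target (under the chosen rule) contribute a censored duration
    up to their last event, which for well-formed traces is the
    terminal Dead/Censored event.
    """
    observed: list[float] = []
    censored: list[float] = []
    for trace in log:
        acts = trace.activities()
        if source not in acts:
            continue
        i = acts.index(source)
        t0 = trace.events[i].timestamp
        hit: float | None = None
        if consecutive_only:
            if i + 1 < len(acts) and acts[i + 1] == target:
                hit = trace.events[i + 1].timestamp
        else:
            for event in trace.events[i + 1:]:
                if event.activity == target:
                    hit = event.timestamp
                    break
        if hit is not None:
            observed.append(hit - t0)
        else:
            censored.append(trace.events[-1].timestamp - t0)
    return TransitionTimes(
        source=source,
        target=target,
        observed=np.asarray(observed, dtype=float),
        censored=np.asarray(censored, dtype=float),
        consecutive_only=consecutive_only,
    )


# ---------------------------------------------------------------------------
# Kernel density estimate ("time to fly")


@dataclass
class KDEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    median: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def time_to_fly_kde(
    tt: TransitionTimes,
    bandwidth: str | float = "silverman",
    fallback_bandwidth: float = 10.0,
    grid_size: int = 512,
) -> KDEstimate:
    """Gaussian KDE of the observed transition times.

    Censored durations are excluded.  The bandwidth follows Silverman's
    rule by default; for degenerate samples (a single observation, or
    zero spread) where Silverman collapses, *fallback_bandwidth* days
    is used instead.  The density is evaluated on a uniform grid from 0
    to 1.2x the largest duration, and ``median`` is the sample median
    of the raw observed durations (not a property of the smoothed
    curve).
    """
    x = np.asarray(tt.observed, dtype=float)
    if len(x) == 0:
        raise InsufficientDataError(
            f"no observed durations for {tt.source} -> {tt.target}"
        )
    kde = None
    if len(x) > 1 and float(np.std(x)) > 0:
        if bandwidth == "silverman":
            kde = stats.gaussian_kde(x, bw_method="silverman")
        elif isinstance(bandwidth, (int, float)):
            kde = stats.gaussian_kde(x, bw_method=float(bandwidth) / float(np.std(x, ddof=1)))
        else:
            kde = stats.gaussian_kde(x, bw_method=bandwidth)
        bw = float(kde.factor * np.std(x, ddof=1))
    else:
        bw = float(fallback_bandwidth)
    # grid reaches 1.2x the largest duration, extended if needed so the
    # upper kernel tail is integrable on the grid
    upper = max(1.2 * float(x.max()), float(x.max()) + 4.0 * bw)
    grid = np.linspace(0.0, upper, grid_size)
    if kde is not None:
        density = kde(grid)
    else:
        density = np.mean(
            stats.norm.pdf(grid[:, None], loc=x[None, :], scale=bw), axis=1
        )
    return KDEstimate(grid=grid, density=density, bandwidth=bw, median=float(np.median(x)))


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit estimate as a step function with risk-set bookkeeping."""

    rows: pd.DataFrame  # columns: time, survival, at_risk, events, censorings
    median: float

    def survival_at(self, time: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        eligible = self.rows[self.rows["time"] <= time]
        if eligible.empty:
            return 1.0
        return float(eligible["survival"].iloc[-1])


def km_fit(tt: TransitionTimes) -> KMCurve:
    """Kaplan-Meier curve of the source-to-target transition time.

    Censored durations reduce the risk set without an event step;
    death before a non-death target counts as right-censoring for that
    target (competing risks are not modeled).
    """
    durations, events = tt.durations_events()
    if len(durations) == 0:
        raise InsufficientDataError("cannot fit a survival curve on no durations")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    rows = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censorings": table["censored"].to_numpy(dtype=int),
        }
    )
    return KMCurve(rows=rows, median=float(kmf.median_survival_time_))


def logrank_test(tt_a: TransitionTimes, tt_b: TransitionTimes) -> tuple[float, float]:
    """Two-group log-rank test (1 df) on the pooled risk sets.

    Returns (chi-square statistic, two-sided p-value).  Undefined when
    neither group contains an event.
    """
    da, ea = tt_a.durations_events()
    db, eb = tt_b.durations_events()
    if ea.sum() + eb.sum() == 0:
        raise InsufficientDataError("log-rank test undefined without any event")
    result = _lifelines_logrank(da, db, event_observed_A=ea, event_observed_B=eb)
    return float(result.test_statistic), float(result.p_value)


# ---------------------------------------------------------------------------
# Mann-Whitney comparison with the small-sample rule


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with the package's exact/asymptotic switch.

    Exact null enumeration when both samples have at most 20
    observations and no ties straddle the groups; otherwise the normal
    approximation with midrank tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


@dataclass
class TransitionComparison:
    """Outcome of comparing observed transition times across two datasets."""

    p_value: float | None
    flag: str  # "tested" or "insufficient-for-test"
    median_a: float
    median_b: float
    n_a: int
    n_b: int

    @property
    def tested(self) -> bool:
        return self.flag == "tested"


def compare_transition_times(
    observed_a: Sequence[float],
    observed_b: Sequence[float],
    min_n: int = 5,
) -> TransitionComparison:
    """Compare two datasets' observed transition times for one edge.

    When both samples have at least *min_n* observations a two-sided
    Mann-Whitney p-value is returned with the medians; below that the
    result is flagged ``insufficient-for-test`` and only the medians
    are reported, for qualitative (visual) inspection of the densities.
    """
    a = np.asarray(observed_a, dtype=float)
    b = np.asarray(observed_b, dtype=float)
    if len(a) == 0 and len(b) == 0:
        raise InsufficientDataError("no observed durations in either dataset")
    median_a = float(np.median(a)) if len(a) else float("nan")
    median_b = float(np.median(b)) if len(b) else float("nan")
    if min(len(a), len(b)) >= min_n:
        _, p = mann_whitney(a, b)
        return TransitionComparison(p, "tested", median_a, median_b, len(a), len(b))
    return TransitionComparison(None, "insufficient-for-test", median_a, median_b, len(a), len(b))
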