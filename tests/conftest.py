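import numpy as np
import pytest

from alsflow import Event, EventLog, Trace


def make_trace(pid, pairs, **attributes):
    return Trace(pid, [Event(a, float(t)) for a, t in pairs], dict(attributes))


@pytest.fixture
def toy_log():
    """Three-trace worked example used throughout the DFG/CFM/temporal tests.

    p1: Onset 0, TrialStart 30, M_0000 60, M_1000 160, Dead 260
    p2: Onset 0, TrialStart 30, M_0000 60, M_1000 160, M_1100 260, Censored 360
    p3: Onset 0, TrialStart 30, M_0100 90, Censored 190
    """
    return EventLog.from_traces(
        [
            make_trace(
                "p1",
                [("Onset", 0), ("TrialStart", 30), ("M_0000", 60), ("M_1000", 160), ("Dead", 260)],
                onset_site="Spinal", age_at_onset=50.0,
            ),
            make_trace(
                "p2",
                [("Onset", 0), ("TrialStart", 30), ("M_0000", 60), ("M_1000", 160),
                 ("M_1100", 260), ("Censored", 360)],
                onset_site="Spinal", age_at_onset=60.0,
            ),
            make_trace(
                "p3",
                [("Onset", 0), ("TrialStart", 30), ("M_0100", 90), ("Censored", 190)],
                onset_site="Bulbar", age_at_onset=70.0,
            ),
        ]
    )


def random_toy_log(rng: np.random.Generator, max_traces=10, max_events=8, alphabet=None):
    """Small random log over a handful of state activities, for oracle checks."""
    alphabet = alphabet or ["M_0000", "M_1000", "M_1100", "M_1110", "M_1111"]
    n_traces = int(rng.integers(1, max_traces + 1))
    traces = []
    for i in range(n_traces):
        n_events = int(rng.integers(1, max_events + 1))
        times = np.sort(rng.uniform(0, 500, size=n_events))
        acts = [alphabet[int(k)] for k in rng.integers(0, len(alphabet), size=n_events)]
        traces.append(make_trace(f"r{i}", list(zip(acts, times)),
                                 group="a" if rng.random() < 0.5 else "b"))
    return EventLog.from_traces(traces)
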