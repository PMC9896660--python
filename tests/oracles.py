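"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the Fisher
oracle enumerates hypergeometric tables with integer arithmetic, the
DFG oracle counts consecutive pairs directly, and the Kaplan-Meier
oracle multiplies factors by hand.
"""

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for the table [[a, b], [c, d]].

    Evaluates the hypergeometric pmf over the whole support in floating
    point and sums the probabilities of tables no more likely than the
    observed one (1e-7 relative tolerance for near-ties) -- a different
    numerical route from the integer enumeration it cross-checks.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    observed = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= observed * (1 + 1e-7)].sum()))


def dfg_pair_counts(log):
    """Directly-follows pair counts by plain enumeration over all traces."""
    counts: dict[tuple[str, str], int] = {}
    for trace in log:
        acts = trace.activities()
        for i in range(len(acts) - 1):
            key = (acts[i], acts[i + 1])
            counts[key] = counts.get(key, 0) + 1
    return counts


def km_survival(observed, censored):
    """Product-limit S(t) at each event time, computed factor by factor."""
    times = sorted(set(observed))
    all_durations = sorted([(t, 1) for t in observed] + [(t, 0) for t in censored])
    survival = {}
    s = 1.0
    for t in times:
        at_risk = sum(1 for d, _ in all_durations if d >= t)
        events = observed.count(t)
        s *= 1.0 - events / at_risk
        survival[t] = s
    return survival
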