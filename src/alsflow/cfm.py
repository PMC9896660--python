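"""CareFlow-Miner prefix trees with node-level statistical inference.

Starting from a chosen root activity, every trace containing the root
contributes the suffix beginning at its first root occurrence as one
branch of an acyclic prefix tree.  Each node records the patients whose
pathway reaches that exact activity sequence and the times they needed
to get there from the root.  Trees can be pruned by minimum support,
annotated with per-edge percentages, and stratified on a binary
covariate with a node-by-node Fisher exact or chi-square test on the
reached/not-reached contingency plus a Wilcoxon-Mann-Whitney comparison
of root-to-node times.
"""

from __future__ import annotations

import copy
import statistics
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field
from math import comb, inf, nan

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .event_log import EventLog, Stratification, stratify
from .temporal import mann_whitney

#: Median-time color bins (days) used when rendering trees: <=100,
#: 101-200, 201-400, >400.
DEFAULT_COLOR_BINS = (100.0, 200.0, 400.0)
_BIN_COLORS = ("#deebf7", "#9ecae1", "#fd8d3c", "#de2d26")
_SIGNIFICANT_FILL = "yellow"


@dataclass
class CFMNode:
    """One node of the prefix tree: an exact root-anchored pathway."""

    node_id: int
    activity: str
    depth: int
    path: tuple[str, ...]
    patients: list[str] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    children: list["CFMNode"] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.patients)

    @property
    def min_time(self) -> float:
        return min(self.times)

    @property
    def median_time(self) -> float:
        return float(statistics.median(self.times))

    @property
    def max_time(self) -> float:
        return max(self.times)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def find(self, path: Sequence[str]) -> "CFMNode | None":
        """Locate the node for an exact activity path from the root."""
        path = tuple(path)
        for node in self.walk():
            if node.path == path:
                return node
        return None


@dataclass
class CFMTree:
    root: CFMNode
    population_size: int
    prune_threshold: int | None = None

    def nodes(self) -> list[CFMNode]:
        return list(self.root.walk())


def mine_cfm(log: EventLog, root_activity: str) -> CFMTree:
    """Build the CareFlow prefix tree of *log* anchored at *root_activity*.

    Each trace containing the root contributes the suffix starting at
    its first root occurrence; node times are event timestamps minus
    the root timestamp.  Traces without the root are excluded from the
    tree but still count in ``population_size``, the denominator of the
    whole-population edge percentages.
    """
    root = CFMNode(node_id=0, activity=root_activity, depth=0, path=(root_activity,))
    contributed = 0
    for trace in sorted(log, key=lambda t: t.patient_id):
        acts = trace.activities()
        if root_activity not in acts:
            continue
        contributed += 1
        start = acts.index(root_activity)
        t0 = trace.events[start].timestamp
        root.patients.append(trace.patient_id)
        root.times.append(0.0)
        node = root
        for event in trace.events[start + 1:]:
            child = next((c for c in node.children if c.activity == event.activity), None)
            if child is None:
                child = CFMNode(
                    node_id=-1,
                    activity=event.activity,
                    depth=node.depth + 1,
                    path=node.path + (event.activity,),
                )
                node.children.append(child)
            child.patients.append(trace.patient_id)
            child.times.append(event.timestamp - t0)
            node = child
    if contributed == 0:
        raise InsufficientDataError(f"root activity {root_activity!r} absent from every trace")
    _normalize(root)
    return CFMTree(root=root, population_size=len(log))


def _normalize(root: CFMNode) -> None:
    """Sort siblings (support desc, then activity) and assign DFS node ids."""
    counter = 0

    def visit(node: CFMNode) -> None:
        nonlocal counter
        node.node_id = counter
        counter += 1
        node.children.sort(key=lambda c: (-c.support, c.activity))
        for child in node.children:
            visit(child)

    visit(root)


def prune_cfm(tree: CFMTree, min_support: int) -> CFMTree:
    """Remove nodes (with their subtrees) supported by fewer than *min_support* patients.

    Parent supports are untouched, so after pruning the children
    percentages of a node may sum to less than one: the gap is the mass
    of the out-filtered infrequent pathways.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    root = copy.deepcopy(tree.root)

    def cut(node: CFMNode) -> None:
        node.children = [c for c in node.children if c.support >= min_support]
        for child in node.children:
            cut(child)

    cut(root)
    return CFMTree(root=root, population_size=tree.population_size,
                   prune_threshold=min_support)


def edge_percentages(tree: CFMTree) -> dict[int, tuple[float, float]]:
    """Per non-root node: (share of the parent's patients, share of the whole population)."""
    out: dict[int, tuple[float, float]] = {}

    def visit(node: CFMNode) -> None:
        for child in node.children:
            out[child.node_id] = (
                child.support / node.support,
                child.support / tree.population_size,
            )
            visit(child)

    visit(tree.root)
    return out


# ---------------------------------------------------------------------------
# Node-level inference


@dataclass(frozen=True)
class AssociationTest:
    test: str  # "fisher" or "chi2"
    p_value: float
    odds_ratio: float | None = None


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates the full hypergeometric support with exact integer
    weights over the common denominator C(n, a+c) and sums the tables
    whose probability does not exceed the observed one, using the
    conventional 1e-7 relative tolerance for near-ties.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise InsufficientDataError("Fisher test undefined on an all-zero table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    numer = sum(w for w in weights if w <= observed * (1 + 1e-7))
    return min(1.0, numer / comb(n, c1))


def node_association_test(
    a_through: int,
    a_not: int,
    b_through: int,
    b_not: int,
    expected_cutoff: float = 5.0,
) -> AssociationTest:
    """Test whether reaching a node is associated with stratum membership.

    Builds the 2x2 table stratum x {reaches node, does not} and applies
    Fisher's exact test (two-sided, hypergeometric) when any expected
    cell count falls below *expected_cutoff*, else the 1-df chi-square
    test without continuity correction.  Pass ``expected_cutoff=inf``
    to force the exact test.
    """
    table = np.array([[a_through, a_not], [b_through, b_not]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    n = table.sum()
    if n == 0:
        raise InsufficientDataError("association test undefined on an all-zero table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < expected_cutoff).any():
        p = fisher_exact_two_sided(a_through, a_not, b_through, b_not)
        if a_not * b_through > 0:
            odds = (a_through * b_not) / (a_not * b_through)
        else:
            odds = inf if a_through * b_not > 0 else nan
        return AssociationTest("fisher", p, odds)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return AssociationTest("chi2", float(p))


def node_time_comparison(
    times_a: Sequence[float], times_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test on root-to-node times.

    Returns (U statistic, p-value); midranks handle ties.  Raises
    :class:`InsufficientDataError` when either sample is empty.
    """
    if len(times_a) == 0 or len(times_b) == 0:
        raise InsufficientDataError("both samples must be non-empty")
    return mann_whitney(times_a, times_b)


@dataclass
class NodeStratum:
    """Per-node stratified statistics in a :class:`StratifiedCFM`."""

    node_id: int
    support_a: int
    support_b: int
    ratio: float | None
    test: str | None
    p_value: float | None
    significant: bool


@dataclass
class StratifiedCFM:
    """A combined CFM tree annotated with per-node two-stratum inference.

    The tree is mined on the union of both strata; for every node the
    2x2 table compares, within each stratum, the members containing the
    root against those among them whose pathway reaches the node.  The
    reported ratio is ``(support_a / root_a) / (support_b / root_b)``,
    i.e. the ratio of the per-stratum reach proportions relative to the
    initial (root-containing) populations.
    """

    tree: CFMTree
    level_a: str
    level_b: str
    root_a: int
    root_b: int
    alpha: float
    stats: dict[int, NodeStratum]


def stratify_cfm(
    log: EventLog,
    root_activity: str,
    attribute: str,
    splitter,
    alpha: float = 0.05,
    min_support: int = 1,
    expected_cutoff: float = 5.0,
) -> StratifiedCFM:
    """Mine a CFM on two strata of *log* and test every node's occupancy.

    *splitter* must yield exactly two levels (see
    :func:`alsflow.event_log.stratify`); levels are ordered
    alphabetically as (A, B).  Nodes supported by fewer than
    *min_support* patients are pruned before testing.  A node is flagged
    significant when its association p-value falls below *alpha*.
    """
    split: Stratification = stratify(log, attribute, splitter)
    levels = sorted(name for name, sub in split.items() if len(sub) > 0) or sorted(split)
    if len(levels) != 2:
        raise ValueError(f"stratification must yield exactly 2 levels, got {levels}")
    level_a, level_b = levels
    members_a = set(split[level_a].traces)
    members_b = set(split[level_b].traces)

    union = EventLog(
        traces={**split[level_a].traces, **split[level_b].traces},
        metadata={**log.metadata, "strata": (level_a, level_b)},
    )
    tree = mine_cfm(union, root_activity)
    if min_support > 1:
        tree = prune_cfm(tree, min_support)

    root_a = sum(1 for pid in tree.root.patients if pid in members_a)
    root_b = sum(1 for pid in tree.root.patients if pid in members_b)
    degenerate = root_a == 0 or root_b == 0
    if degenerate:
        warnings.warn(
            f"stratum without the root activity {root_activity!r}; node tests skipped",
            stacklevel=2,
        )

    node_stats: dict[int, NodeStratum] = {}
    for node in tree.nodes():
        sa = sum(1 for pid in node.patients if pid in members_a)
        sb = sum(1 for pid in node.patients if pid in members_b)
        if degenerate:
            node_stats[node.node_id] = NodeStratum(node.node_id, sa, sb, None, None, None, False)
            continue
        prop_a, prop_b = sa / root_a, sb / root_b
        ratio = prop_a / prop_b if prop_b > 0 else None
        test = node_association_test(sa, root_a - sa, sb, root_b - sb, expected_cutoff)
        node_stats[node.node_id] = NodeStratum(
            node.node_id, sa, sb, ratio, test.test, test.p_value,
            bool(test.p_value < alpha),
        )
    return StratifiedCFM(
        tree=tree, level_a=level_a, level_b=level_b,
        root_a=root_a, root_b=root_b, alpha=alpha, stats=node_stats,
    )


# ---------------------------------------------------------------------------
# DOT export


def _median_bin(median: float, bins: Sequence[float]) -> int:
    for i, edge in enumerate(bins):
        if median <= edge:
            return i
    return len(bins)


def _quote(text: str) -> str:
    return '"' + text.replace('"', r"\"") + '"'


def cfm_to_dot(
    tree: CFMTree | StratifiedCFM,
    color_bins: Sequence[float] = DEFAULT_COLOR_BINS,
    name: str = "CFM",
) -> str:
    """Render a (stratified) CareFlow tree as Graphviz DOT text.

    Plain trees color nodes by median root-to-node time bins and label
    edges with the percentage of the parent's patients (above) and of
    the entire population (below).  Stratified trees show per-stratum
    supports, the reach-proportion ratio and the node p-value, filling
    significant nodes yellow.  Output is byte-deterministic.
    """
    if isinstance(tree, StratifiedCFM):
        strat, tree_obj = tree, tree.tree
    else:
        strat, tree_obj = None, tree
    pct = edge_percentages(tree_obj)
    lines = [f"digraph {name} {{", "  rankdir=TB;", '  node [shape=box, style=filled];']
    for node in tree_obj.nodes():
        if strat is None:
            label = (
                f"{node.activity}\\n({node.support})\\n"
                f"{node.min_time:.0f}-{node.median_time:.0f}-{node.max_time:.0f}"
            )
            fill = _BIN_COLORS[_median_bin(node.median_time, color_bins)]
        else:
            ns = strat.stats[node.node_id]
            ratio = f"{ns.ratio:.2f}" if ns.ratio is not None else "NA"
            pval = f"p={ns.p_value:.3g}" if ns.p_value is not None else "p=NA"
            label = f"{node.activity}\\n{ns.support_a}/{ns.support_b} ({ratio})\\n{pval}"
            fill = _SIGNIFICANT_FILL if ns.significant else "white"
        lines.append(f'  n{node.node_id} [label="{label}", fillcolor={_quote(fill)}];')
    for node in tree_obj.nodes():
        for child in node.children:
            p_parent, p_pop = pct[child.node_id]
            lines.append(
                f"  n{node.node_id} -> n{child.node_id} "
                f'[label="{100 * p_parent:.0f}%\\n{100 * p_pop:.0f}%"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
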