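"""Directly-Follows Graphs and cohort deltaGraphs.

The DFG connects two activities with a directed edge whenever one
immediately follows the other in at least one trace.  Edges carry the
count of directly-follows pairs and a transition probability computed
against all pairs leaving the source activity, so outgoing
probabilities from every non-terminal node sum to one.  Two DFGs mined
on different cohorts can be overlaid into a deltaGraph that classifies
every edge by the difference of its transition probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .event_log import EventLog

#: deltaGraph edge classifications.
A_FAVORED = "A-favored"
B_FAVORED = "B-favored"
SIMILAR = "similar"
A_ONLY = "A-only"
B_ONLY = "B-only"


@dataclass
class DFGNode:
    activity: str
    patient_count: int = 0
    occurrence_count: int = 0


@dataclass
class DFGEdge:
    source: str
    target: str
    count: int = 0
    probability: float = 0.0


@dataclass
class DFGraph:
    """Directly-follows counts and transition probabilities of one log."""

    nodes: dict[str, DFGNode] = field(default_factory=dict)
    edges: dict[tuple[str, str], DFGEdge] = field(default_factory=dict)

    def probability(self, source: str, target: str) -> float:
        edge = self.edges.get((source, target))
        return edge.probability if edge else 0.0

    def out_probabilities(self, source: str) -> dict[str, float]:
        return {
            t: e.probability for (s, t), e in self.edges.items() if s == source
        }

    def to_json(self) -> str:
        """Deterministic JSON serialization (sorted nodes and edges)."""
        payload = {
            "nodes": [
                {
                    "activity": n.activity,
                    "patient_count": n.patient_count,
                    "occurrence_count": n.occurrence_count,
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.activity)
            ],
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "count": e.count,
                    "probability": e.probability,
                }
                for e in sorted(self.edges.values(), key=lambda e: (e.source, e.target))
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def mine_dfg(log: EventLog) -> DFGraph:
    """Mine the directly-follows graph of *log*.

    Edge count (A, B) is the number of consecutive event pairs A then B
    over all traces; the transition probability divides by the total
    number of directly-follows pairs leaving A.  Node ``patient_count``
    is the number of distinct patients whose trace contains the
    activity; ``occurrence_count`` the total number of occurrences.
    """
    if len(log) == 0:
        raise ValueError("cannot mine an empty event log")
    graph = DFGraph()
    out_totals: dict[str, int] = {}
    for trace in log:
        acts = trace.activities()
        for activity in set(acts):
            node = graph.nodes.setdefault(activity, DFGNode(activity))
            node.patient_count += 1
        for activity in acts:
            graph.nodes[activity].occurrence_count += 1
        for src, tgt in zip(acts, acts[1:]):
            edge = graph.edges.setdefault((src, tgt), DFGEdge(src, tgt))
            edge.count += 1
            out_totals[src] = out_totals.get(src, 0) + 1
    for (src, _), edge in graph.edges.items():
        edge.probability = edge.count / out_totals[src]
    return graph


def prune_dfg(graph: DFGraph, min_probability: float) -> DFGraph:
    """Drop edges whose probability is not strictly above *min_probability*.

    Display-level pruning: node counts are untouched and nodes orphaned
    by the removal are retained, so downstream statistics are unchanged.
    """
    if not 0.0 <= min_probability <= 1.0:
        raise ValueError("min_probability must lie in [0, 1]")
    return DFGraph(
        nodes={a: DFGNode(n.activity, n.patient_count, n.occurrence_count)
               for a, n in graph.nodes.items()},
        edges={
            key: DFGEdge(e.source, e.target, e.count, e.probability)
            for key, e in graph.edges.items()
            if e.probability > min_probability
        },
    )


@dataclass
class DeltaEdge:
    source: str
    target: str
    prob_a: float
    prob_b: float
    delta: float
    classification: str


@dataclass
class DeltaGraph:
    """Edge-wise overlay of two DFGs thresholded on probability differences."""

    edges: dict[tuple[str, str], DeltaEdge]
    threshold: float

    def to_json(self) -> str:
        payload = {
            "threshold": self.threshold,
            "edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "prob_a": e.prob_a,
                    "prob_b": e.prob_b,
                    "delta": e.delta,
                    "classification": e.classification,
                }
                for e in sorted(self.edges.values(), key=lambda e: (e.source, e.target))
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def delta_graph(graph_a: DFGraph, graph_b: DFGraph, threshold: float = 0.2) -> DeltaGraph:
    """Overlay two DFGs and classify every edge by its probability gap.

    For edges present in both graphs: ``delta = prob_a - prob_b``;
    ``|delta| > threshold`` marks the edge as favored by the cohort with
    the higher probability, otherwise it is ``similar``.  Edges found in
    only one graph are labeled one-sided (``A-only``/``B-only``) with
    the missing probability treated as zero, so absences driven by a
    small cohort stay visible rather than masquerading as differences.
    """
    edges: dict[tuple[str, str], DeltaEdge] = {}
    for key in sorted(set(graph_a.edges) | set(graph_b.edges)):
        in_a, in_b = key in graph_a.edges, key in graph_b.edges
        pa = graph_a.edges[key].probability if in_a else 0.0
        pb = graph_b.edges[key].probability if in_b else 0.0
        delta = pa - pb
        if in_a and in_b:
            if abs(delta) <= threshold:
                cls = SIMILAR
            else:
                cls = A_FAVORED if delta > 0 else B_FAVORED
        else:
            cls = A_ONLY if in_a else B_ONLY
        edges[key] = DeltaEdge(key[0], key[1], pa, pb, delta, cls)
    return DeltaGraph(edges=edges, threshold=threshold)


# ---------------------------------------------------------------------------
# DOT export

_DELTA_COLORS = {
    A_FAVORED: "red",
    B_FAVORED: "green",
    SIMILAR: "gray",
    A_ONLY: "red",
    B_ONLY: "green",
}


def _quote(name: str) -> str:
    return '"' + name.replace('"', r"\"") + '"'


def dfg_to_dot(graph: DFGraph | DeltaGraph, name: str = "DFG") -> str:
    """Render a DFG or deltaGraph as Graphviz DOT text.

    DFG nodes are labeled with their patient counts and edges with
    count and probability.  DeltaGraph edges follow the cohort-contrast
    color convention: red when the first cohort's transition probability
    is higher, green when the second's is, gray when similar; one-sided
    edges are dashed.  Output is byte-deterministic for a given graph.
    """
    lines = [f"digraph {name} {{", "  rankdir=TB;"]
    if isinstance(graph, DeltaGraph):
        nodes = sorted({e.source for e in graph.edges.values()}
                       | {e.target for e in graph.edges.values()})
        for node in nodes:
            lines.append(f"  {_quote(node)};")
        for key in sorted(graph.edges):
            e = graph.edges[key]
            color = _DELTA_COLORS[e.classification]
            style = ', style=dashed' if e.classification in (A_ONLY, B_ONLY) else ""
            label = f"{e.prob_a:.2f} | {e.prob_b:.2f} (d={e.delta:+.2f})"
            lines.append(
                f"  {_quote(e.source)} -> {_quote(e.target)} "
                f'[label="{label}", color={color}{style}];'
            )
    else:
        for activity in sorted(graph.nodes):
            node = graph.nodes[activity]
            lines.append(
                f"  {_quote(activity)} "
                f'[label="{activity}\\n(n={node.patient_count})"];'
            )
        for key in sorted(graph.edges):
            e = graph.edges[key]
            lines.append(
                f"  {_quote(e.source)} -> {_quote(e.target)} "
                f'[label="{e.probability:.2f} ({e.count})"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
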