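"""Weighted line graphs: deciding which in/out edge pairs belong together.

The line graph L(G) has one node per edge of the splicing graph G, weighted
by that edge's read coverage, and an edge for every incident pair (e_in
ends where e_out starts).  At each branching node of G a small quadratic
program distributes flow between in- and out-edges; pairs carrying enough
flow — or witnessed by a reliable subpath through the node — get L-edge
weight 1, the rest 0.  Transcripts are then paths through weight-1 edges.

The program at node v with in-edge weights w_i and out-edge weights w_j is

    min  sum_i (sum_j f_ij - w_i)^2 + sum_j (sum_i f_ij - w_j)^2
    s.t. f_ij >= 0, and
         f_ij >= eps_support * min(w_i, w_j)   for witnessed pairs (i, j)

solved by non-negative least squares after shifting out the lower bounds.
NNLS's active-set pivoting is deterministic for a fixed variable order
(pairs enumerated row-major over sorted in/out edges), so results are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import nnls

from .paired_subpaths import ReliableSubpathSet
from .splice_graph import SplicingGraph

log = logging.getLogger(__name__)

#: relative flow lower bound for witnessed pairs
EPS_SUPPORT = 0.05
#: binarization threshold (fraction of the node's maximum flow)
THETA = 0.1
#: absolute tolerance below which a flow counts as zero
FLOW_ZERO = 1e-9

LNode = tuple[int, int]  # an edge of G


@dataclass
class LineGraph:
    """L(G): nodes are G-edges; mutable node weights drive the assembly."""

    graph: SplicingGraph
    l: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def node_weight(self) -> dict[LNode, float]:
        return {n: self.l.nodes[n]["weight"] for n in self.l.nodes}

    def weight(self, n: LNode) -> float:
        return self.l.nodes[n]["weight"]

    def set_weight(self, n: LNode, w: float) -> None:
        self.l.nodes[n]["weight"] = w

    def edge_weight(self, a: LNode, b: LNode) -> float:
        return self.l.edges[a, b]["weight"]


def build_line_graph(graph: SplicingGraph) -> LineGraph:
    """Standard line-graph construction; L inherits acyclicity from G."""
    line = LineGraph(graph=graph)
    for u, v, data in graph.g.edges(data=True):
        line.l.add_node((u, v), weight=float(data["weight"]))
    for v in graph.g.nodes:
        for u in graph.g.predecessors(v):
            for w in graph.g.successors(v):
                line.l.add_edge((u, v), (v, w), weight=1.0)
    return line


def witnessed_pairs(
    graph: SplicingGraph, reliable: ReliableSubpathSet
) -> set[tuple[LNode, LNode]]:
    """Incident G-edge pairs supported by a reliable 3-window a -> v -> b."""
    pairs: set[tuple[LNode, LNode]] = set()
    for k, entries in reliable.by_length.items():
        if k < 3:
            continue
        for e in entries:
            for a, v, b in zip(e.nodes, e.nodes[1:], e.nodes[2:]):
                pairs.add(((a, v), (v, b)))
    return pairs


def solve_connection_qp(
    graph: SplicingGraph,
    v: int,
    reliable: ReliableSubpathSet,
    eps_support: float = EPS_SUPPORT,
    witnesses: set[tuple[LNode, LNode]] | None = None,
) -> dict[tuple[LNode, LNode], float]:
    """Distribute flow between the in- and out-edges of one G-node.

    Returns the flow matrix as a dict over (in-edge, out-edge) pairs.  When
    every incident weight is zero the objective is vacuous; flow is then
    spread uniformly over witnessed pairs (over all pairs if none).
    """
    ins = sorted(graph.g.predecessors(v))
    outs = sorted(graph.g.successors(v))
    if not ins or not outs:
        return {}
    w_in = np.array([graph.edge_weight(u, v) for u in ins], dtype=float)
    w_out = np.array([graph.edge_weight(v, w) for w in outs], dtype=float)
    if witnesses is None:
        witnesses = witnessed_pairs(graph, reliable)

    pairs = [((u, v), (v, w)) for u in ins for w in outs]
    ni, no = len(ins), len(outs)

    if w_in.sum() == 0 and w_out.sum() == 0:
        chosen = [p for p in pairs if p in witnesses] or pairs
        return {p: (1.0 if p in chosen else 0.0) for p in pairs}

    # rows: in-edge balance then out-edge balance; columns: pairs row-major
    a_mat = np.zeros((ni + no, ni * no))
    for idx, (i, j) in enumerate((i, j) for i in range(ni) for j in range(no)):
        a_mat[i, idx] = 1.0
        a_mat[ni + j, idx] = 1.0
    b = np.concatenate([w_in, w_out])

    lower = np.zeros(ni * no)
    for idx, pair in enumerate(pairs):
        if pair in witnesses:
            i, j = divmod(idx, no)
            lower[idx] = eps_support * min(w_in[i], w_out[j])
    g_sol, _ = nnls(a_mat, b - a_mat @ lower)
    f = g_sol + lower
    return {pair: float(f[idx]) for idx, pair in enumerate(pairs)}


def binarize_edge_weights(
    line: LineGraph,
    flows: dict[int, dict[tuple[LNode, LNode], float]],
    reliable: ReliableSubpathSet,
    theta: float = THETA,
) -> LineGraph:
    """Turn flows into 0/1 connection indicators on L's edges.

    An L-edge keeps weight 1 when its flow reaches ``theta`` times the
    node's maximum flow, when it carries its in-edge's largest positive
    flow (every expressed in-edge must continue somewhere), or when the
    pair is witnessed by a reliable subpath.  Non-branching incidences
    (one in, one out) are always 1.
    """
    witnesses = witnessed_pairs(line.graph, reliable)
    for v, f in flows.items():
        if not f:
            continue
        ins = sorted(line.graph.g.predecessors(v))
        outs = sorted(line.graph.g.successors(v))
        if len(ins) == 1 and len(outs) == 1:
            continue  # constructed with weight 1
        fmax = max(f.values())
        row_max = {
            u: max(f[((u, v), (v, w))] for w in outs) for u in ins
        }
        for (ein, eout), val in f.items():
            keep = (
                (fmax > FLOW_ZERO and val >= theta * fmax)
                or (val > FLOW_ZERO and val >= row_max[ein[0]])
                or (ein, eout) in witnesses
            )
            line.l.edges[ein, eout]["weight"] = 1.0 if keep else 0.0
    return line


def weight_line_graph(
    graph: SplicingGraph,
    reliable: ReliableSubpathSet,
    theta: float = THETA,
    eps_support: float = EPS_SUPPORT,
) -> LineGraph:
    """Build L(G), solve the connection program at every branching node,
    and binarize."""
    line = build_line_graph(graph)
    witnesses = witnessed_pairs(graph, reliable)
    flows = {
        v: solve_connection_qp(
            graph, v, reliable, eps_support=eps_support, witnesses=witnesses
        )
        for v in graph.g.nodes
        if graph.g.in_degree(v) >= 1 and graph.g.out_degree(v) >= 1
    }
    return binarize_edge_weights(line, flows, reliable, theta=theta)


def project_subpath(
    nodes: tuple[int, ...], graph: SplicingGraph
) -> tuple[LNode, ...]:
    """G-path of length n -> the unique L-path of length n - 1."""
    if len(nodes) < 2:
        raise ValueError("projection needs a path of length >= 2")
    out = []
    for u, v in zip(nodes, nodes[1:]):
        if not graph.g.has_edge(u, v):
            raise ValueError(f"({u}, {v}) is not an edge of the splicing graph")
        out.append((u, v))
    return tuple(out)


def project_reliable_set(
    reliable: ReliableSubpathSet, graph: SplicingGraph
) -> ReliableSubpathSet:
    """Project every reliable G-subpath to L; lengths shift down by one."""
    from .paired_subpaths import ScoredPath

    out = ReliableSubpathSet(provenance=reliable.provenance)
    for k, entries in reliable.by_length.items():
        if k < 2:
            continue
        projected = [
            ScoredPath(project_subpath(e.nodes, graph), e.score, e.provenance)
            for e in entries
        ]
        out.by_length[k - 1] = projected
    return out
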