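"""Hub detection on protein-protein interaction graphs.

Two complementary hub detectors operate on a simple undirected graph of
gene/TF identifiers:

* **MCC** (maximal clique centrality): ``MCC(v) = sum over maximal cliques C
  containing v of (|C| - 1)!``, counting cliques of size >= 2.  A node in no
  edge scores 0; in triangle-free neighborhoods MCC reduces to degree.
* **MCODE** (molecular complex detection): k-core-based vertex weighting,
  seeded greedy complex growth, and 2-core/haircut post-processing; each
  complex is scored by density x size.

Hub calls combine the two: the top-k MCC nodes intersected with the members
of high-scoring MCODE complexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class Complex:
    """One predicted complex: member nodes, density x size score, seed node."""

    nodes: tuple
    score: float
    seed: object

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class NodeScoreTable:
    scores: pd.Series
    method: str

    def top(self, k: int = 10) -> list:
        """The k best-scoring nodes, ties broken by node id for determinism."""
        ranked = sorted(self.scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
        return [node for node, _ in ranked[:k]]

    def to_tsv(self, path) -> None:
        self.scores.rename(self.method).to_csv(path, sep="\t", index_label="node")


def read_edges(path, score_threshold: float = 400.0) -> nx.Graph:
    """Load an interaction graph from a TSV edge list.

    Rows hold two node columns and an optional numeric confidence score
    (STRING-style 0-1000 scale); edges below ``score_threshold`` are
    dropped, as are self-loops and duplicates.  A single-column row adds a
    singleton node.  A non-numeric score on the first line is treated as a
    header.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                graph.add_node(fields[0].strip())
                continue
            if len(fields) not in (2, 3):
                raise ValueError(f"malformed row at line {lineno}: {line!r}")
            u, v = fields[0].strip(), fields[1].strip()
            score = None
            if len(fields) == 3 and fields[2].strip():
                try:
                    score = float(fields[2])
                except ValueError:
                    if lineno == 1:  # header line
                        continue
                    raise ValueError(
                        f"malformed score at line {lineno}: {fields[2]!r}"
                    ) from None
            if not u or not v:
                raise ValueError(f"empty node identifier at line {lineno}")
            if u == v:
                continue
            if score is not None and score < score_threshold:
                continue
            if score is None:
                graph.add_edge(u, v)
            else:
                graph.add_edge(u, v, score=score)
    return graph


def maximal_cliques(graph: nx.Graph) -> list[frozenset]:
    """All maximal cliques of size >= 2 (Bron-Kerbosch with pivoting)."""
    return [frozenset(c) for c in nx.find_cliques(graph) if len(c) >= 2]


def mcc_scores(graph: nx.Graph) -> NodeScoreTable:
    """Maximal clique centrality for every node of the graph."""
    scores = {v: 0.0 for v in graph.nodes}
    for clique in maximal_cliques(graph):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    series = pd.Series(scores, dtype=float).sort_index()
    return NodeScoreTable(scores=series, method="MCC")


def _mcode_weight(graph: nx.Graph, v, degree_cutoff: int) -> float:
    if graph.degree(v) < degree_cutoff:
        return 0.0
    nbhd = graph.subgraph(set(graph.neighbors(v)) | {v})
    core_num = nx.core_number(nbhd)
    k = max(core_num.values())
    if k == 0:
        return 0.0
    core_nodes = [n for n, c in core_num.items() if c >= k]
    core = nbhd.subgraph(core_nodes)
    n = core.number_of_nodes()
    if n < 2:
        return 0.0
    density = core.number_of_edges() / (n * (n - 1) / 2)
    return k * density


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return graph.number_of_edges() / (n * (n - 1) / 2)


def mcode_complexes(
    graph: nx.Graph,
    vwp: float = 0.2,
    degree_cutoff: int = 2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
    k_core: int = 2,
) -> list[Complex]:
    """Predict dense complexes with the three MCODE stages.

    1. weight each vertex by k x density of the highest k-core of its closed
       neighborhood (vertices below ``degree_cutoff`` weigh 0);
    2. grow complexes from the highest-weight unused seed, admitting
       neighbors with weight >= (1 - vwp) x seed weight, each vertex used
       once across complexes;
    3. discard complexes lacking a ``k_core``-core; haircut trims to the
       2-core; fluff optionally adds neighbors whose weight exceeds
       ``fluff_density`` (after scoring, without reserving them).

    Complexes are ranked by score = density x size (descending).
    """
    weights = {v: _mcode_weight(graph, v, degree_cutoff) for v in graph.nodes}
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    seen: set = set()
    raw: list[tuple[object, set]] = []
    for seed in order:
        if seed in seen or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        seen.add(seed)
        while frontier:
            nxt = []
            for u in frontier:
                for w in graph.neighbors(u):
                    if w in seen or weights[w] < threshold:
                        continue
                    seen.add(w)
                    members.add(w)
                    nxt.append(w)
            frontier = nxt
        raw.append((seed, members))

    out: list[Complex] = []
    for seed, members in raw:
        sub = graph.subgraph(members)
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            continue
        final = nx.k_core(sub, 2) if haircut else sub
        if seed not in final:
            continue
        if fluff:
            extra = {
                w
                for v in final.nodes
                for w in graph.neighbors(v)
                if w not in final and weights[w] > fluff_density
            }
            final = graph.subgraph(set(final.nodes) | extra)
        score = _density(final) * final.number_of_nodes()
        out.append(Complex(nodes=tuple(sorted(final.nodes, key=str)), score=score, seed=seed))
    out.sort(key=lambda c: (-c.score, -len(c), str(c.seed)))
    return out


def mcode_members(complexes: list[Complex], min_size: int = 4) -> set:
    """Union of members over complexes with at least ``min_size`` nodes."""
    out: set = set()
    for c in complexes:
        if len(c) >= min_size:
            out.update(c.nodes)
    return out


def hub_intersection(set_a, set_b) -> list:
    """Deterministic sorted intersection of two hub candidate sets."""
    return sorted(set(set_a) & set(set_b), key=str)
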