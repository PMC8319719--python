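"""Scored protein-interaction network analysis.

Builds an undirected graph from a STRING-style scored edge list
(thresholded on the combined confidence score, restricted to a node
whitelist), computes degree and unnormalized shortest-path betweenness
centrality, classifies hubs (degree >= 30), bottlenecks (betweenness
>= 300) and high hubs (both), and detects dense modules with the MCODE
procedure: vertices are weighted by the density of the highest k-core
of their closed neighborhood, complexes are grown outward from
high-weight seeds, and post-processing applies a k-core check and an
optional haircut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Module",
    "build_graph",
    "read_edges_tsv",
    "centrality",
    "classify_hubs",
    "mcode",
    "filter_modules",
    "write_centrality_tsv",
    "write_modules_tsv",
]

logger = logging.getLogger(__name__)

SCORE_THRESHOLD_DEFAULT = 700.0
DEGREE_CUT_DEFAULT = 30
BETWEENNESS_CUT_DEFAULT = 300.0
MIN_MODULE_SIZE_DEFAULT = 5


@dataclass
class Module:
    members: frozenset[str]
    seed: str
    score: float

    def __len__(self) -> int:
        return len(self.members)


def read_edges_tsv(path) -> pd.DataFrame:
    """Read a 3-column (protein1, protein2, combined_score) TSV."""
    return pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})


def build_graph(edges: pd.DataFrame,
                node_whitelist: Iterable[str] | None = None,
                score_threshold: float = SCORE_THRESHOLD_DEFAULT,
                inclusive: bool = False) -> nx.Graph:
    """Thresholded undirected graph from a scored edge list.

    Keeps edges whose score is strictly above ``score_threshold``
    (``inclusive=True`` switches to >=, the common STRING convention)
    and whose endpoints are both in the whitelist.  Self-loops are
    dropped; duplicate and reversed-duplicate pairs are merged keeping
    the maximum score.  Nodes are only those incident to a kept edge.
    """
    whitelist = set(node_whitelist) if node_whitelist is not None else None
    G = nx.Graph()
    skipped = 0
    for row in edges.itertuples(index=False):
        try:
            a, b = str(row.protein1), str(row.protein2)
            score = float(row.combined_score)
        except (AttributeError, TypeError, ValueError):
            skipped += 1
            continue
        if a == b or pd.isna(score):
            skipped += a == b
            continue
        if whitelist is not None and (a not in whitelist or b not in whitelist):
            continue
        ok = score >= score_threshold if inclusive else score > score_threshold
        if not ok:
            continue
        if G.has_edge(a, b):
            G[a][b]["score"] = max(G[a][b]["score"], score)
        else:
            G.add_edge(a, b, score=score)
    if skipped:
        logger.info("build_graph: skipped %d malformed/self-loop rows", skipped)
    return G


def centrality(graph: nx.Graph) -> pd.DataFrame:
    """Degree and unnormalized betweenness per node.

    Betweenness counts each unordered node pair once, excludes
    endpoints, and splits credit fractionally across equal-length
    shortest paths (Brandes accumulation on the unweighted graph), so a
    node's value is the expected number of pairs it mediates.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    btw = nx.betweenness_centrality(graph, normalized=False)
    rows = [
        {"node": v, "degree": graph.degree(v), "betweenness": btw[v]}
        for v in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows)


def classify_hubs(rows: pd.DataFrame,
                  degree_cut: int = DEGREE_CUT_DEFAULT,
                  betweenness_cut: float = BETWEENNESS_CUT_DEFAULT) -> pd.DataFrame:
    """Flag hubs / bottlenecks / high hubs with inclusive thresholds."""
    out = rows.copy()
    out["is_hub"] = out["degree"] >= degree_cut
    out["is_bottleneck"] = out["betweenness"] >= betweenness_cut
    out["is_high_hub"] = out["is_hub"] & out["is_bottleneck"]
    return out


# ---------------------------------------------------------------------------
# MCODE module detection
# ---------------------------------------------------------------------------

def _density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def _vertex_weights(G: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """MCODE stage 1: weight = (highest core number of the closed
    neighborhood) x (density of that highest k-core)."""
    weights: dict[str, float] = {}
    for v in G.nodes:
        if G.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = G.subgraph(set(G[v]) | {v})
        cores = nx.core_number(nbhd)
        k_max = max(cores.values())
        core_nodes = [u for u, c in cores.items() if c == k_max]
        weights[v] = k_max * _density(nbhd.subgraph(core_nodes))
    return weights


def mcode(graph: nx.Graph,
          degree_cutoff: int = 2,
          node_score_cutoff: float = 0.2,
          k_core: int = 2,
          haircut: bool = True,
          fluff: bool = False,
          max_depth: int = 100) -> list[Module]:
    """MCODE molecular-complex detection.

    Stage 1 weights vertices (see ``_vertex_weights``); stage 2 grows a
    complex from each unassigned seed in descending weight order
    (lexicographic tie-break), including unassigned neighbors whose
    weight is at least (1 - node_score_cutoff) times the seed weight,
    breadth-first to ``max_depth``; stage 3 discards complexes without
    a ``k_core``-core and, when ``haircut`` is on, trims members until
    every remaining member has at least two connections inside the
    complex.  Nodes belong to at most one complex.  The fluff expansion
    stage is not implemented (``fluff=True`` raises).

    Module score = density x size; modules are returned sorted by score
    descending with seed-name tie-break.
    """
    if fluff:
        raise NotImplementedError("fluff expansion is not supported")
    weights = _vertex_weights(graph, degree_cutoff)
    order = sorted(weights, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    modules: list[Module] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in graph[v]:
                    if u in members or u in assigned:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        sub = graph.subgraph(members).copy()
        core = nx.k_core(sub, k=k_core)
        if core.number_of_nodes() == 0:
            assigned |= members
            continue
        if haircut:
            # Iterated removal of singly-connected members == 2-core.
            sub = nx.k_core(sub, k=2)
            if sub.number_of_nodes() == 0:
                assigned |= members
                continue
        score = _density(sub) * sub.number_of_nodes()
        assigned |= members
        if score > 0:
            modules.append(
                Module(members=frozenset(sub.nodes), seed=seed, score=score)
            )
    modules.sort(key=lambda m: (-m.score, m.seed))
    return modules


def filter_modules(modules: Sequence[Module],
                   min_size: int = MIN_MODULE_SIZE_DEFAULT) -> list[Module]:
    """Keep modules with at least ``min_size`` members."""
    return [m for m in modules if len(m) >= min_size]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_centrality_tsv(rows: pd.DataFrame, path) -> None:
    out = rows.copy()
    if "is_high_hub" in out.columns:
        out["type"] = "-"
        out.loc[out["is_hub"], "type"] = "Hub"
        out.loc[out["is_bottleneck"], "type"] = "Bottleneck"
        out.loc[out["is_high_hub"], "type"] = "High hub"
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_modules_tsv(modules: Sequence[Module], path) -> None:
    rows = [
        {
            "module": i + 1,
            "score": round(m.score, 6),
            "size": len(m),
            "seed": m.seed,
            "members": ",".join(sorted(m.members)),
        }
        for i, m in enumerate(modules)
    ]
    pd.DataFrame(rows, columns=["module", "score", "size", "seed", "members"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
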