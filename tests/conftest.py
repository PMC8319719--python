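"""Shared fixtures: a small simulated cohort and independent oracles."""

import math
from itertools import combinations

import networkx as nx
import pytest

import crossdex as cx


@pytest.fixture(scope="session")
def sim_config():
    return cx.SimConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """One simulated cohort with everything downstream needs."""
    matrix, truth = cx.simulate_expression(sim_config)
    annotation = cx.simulate_annotation(sim_config)
    collection = cx.simulate_genesets(sim_config, truth)
    edges = cx.simulate_ppi(sim_config, truth)
    return {
        "config": sim_config,
        "matrix": matrix,
        "truth": truth,
        "annotation": annotation,
        "collection": collection,
        "edges": edges,
    }


@pytest.fixture(scope="session")
def contrast_results(cohort):
    matrix = cohort["matrix"]
    cfg = cohort["config"]
    return [
        cx.run_contrast(matrix, cfg.control_group, g) for g in cfg.disease_groups
    ]


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def hypergeom_enum(x: int, K: int, n: int, N: int) -> float:
    """P(X >= x) by direct summation of hypergeometric point masses."""
    denom = math.comb(N, n)
    total = 0
    for j in range(x, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def naive_betweenness(G: nx.Graph) -> dict:
    """All-pairs BFS path counting: for every unordered pair (s, t),
    each intermediate vertex of a shortest path gets credit equal to
    the fraction of shortest s-t paths passing through it."""
    btw = {v: 0.0 for v in G.nodes}
    for s, t in combinations(G.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw
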