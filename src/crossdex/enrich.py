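"""Gene-set over-representation meta-analysis across contrasts.

Per disease contrast, each gene set is scored by the upper tail of the
hypergeometric distribution (is the DEG list enriched for set
members?); the per-contrast p-values are then combined per set with
Fisher's method (-2 * sum(ln p) ~ chi-square on 2k degrees of freedom
for k contrasts) and Benjamini-Hochberg corrected across sets.  Sets
with corrected combined p below the cutoff are the consensus
dysregulated pathways.

Gene sets are exchanged in GMT (one set per line: name, description,
then tab-separated member symbols).  Collections are filtered to a
size window after restriction to the measured-gene universe, with an
optional name-pattern exclusion list.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dex import DEGSet, bh_adjust

__all__ = [
    "read_gmt",
    "filter_collection",
    "hypergeom_p",
    "fisher_combine",
    "consensus_pathways",
    "write_enrichment_tsv",
]

MIN_SET_SIZE = 5
MAX_SET_SIZE = 300
Q_CUT_DEFAULT = 0.05
_TINY = np.finfo(float).tiny


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: member symbols}."""
    collection: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >= 3 fields): {line[:80]!r}")
        name = fields[0]
        collection[name] = {m for m in fields[2:] if m}
    return collection


def filter_collection(collection: Mapping[str, set[str]],
                      universe: set[str],
                      min_size: int = MIN_SET_SIZE,
                      max_size: int = MAX_SET_SIZE,
                      exclude_patterns: Sequence[str] = ()) -> dict[str, set[str]]:
    """Restrict sets to the universe, drop out-of-window sizes and
    name-matched (e.g. disease/drug) sets.

    A set is kept iff min_size <= |set & universe| <= max_size and its
    name matches none of ``exclude_patterns`` (case-insensitive regex).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    patterns = [re.compile(p, re.IGNORECASE) for p in exclude_patterns]
    out: dict[str, set[str]] = {}
    for name, members in collection.items():
        if any(p.search(name) for p in patterns):
            continue
        restricted = set(members) & universe
        if min_size <= len(restricted) <= max_size:
            out[name] = restricted
    return out


def hypergeom_p(x: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    N genes in the universe, K of them in the set, n drawn (the DEG
    list), x of the drawn genes in the set.  Computed via scipy's
    log-space survival function; stable for large counts.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= x <= min(K, n)):
        raise ValueError(f"overlap x={x} outside [0, min(K={K}, n={n})]")
    if x == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(x - 1, N, K, n)))


def fisher_combine(p_list: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's combined probability test.

    Returns (X2, df, p_combined) with X2 = -2 * sum(ln p_i) and
    p_combined the upper chi-square tail on df = 2k.  Zero p-values are
    clamped to the smallest positive float with a warning rather than
    propagating infinities.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p=0 clamped to the smallest positive float before "
                      "Fisher combination", RuntimeWarning, stacklevel=2)
        p = np.maximum(p, _TINY)
    x2, p_comb = stats.combine_pvalues(p, method="fisher")
    return float(x2), 2 * p.size, float(p_comb)


def consensus_pathways(collection: Mapping[str, set[str]],
                       degsets: Sequence[DEGSet],
                       universe: set[str],
                       q_cut: float = Q_CUT_DEFAULT) -> pd.DataFrame:
    """Score every gene set across all contrasts and select consensus
    pathways.

    Per set and contrast the DEG list is the unsigned union of the up
    and down calls restricted to the universe.  Output columns:
    one ``p_<contrast>`` and ``x_<contrast>`` per contrast, set size K,
    ``fisher_stat``, ``df``, ``p_combined``, ``q_bh`` and a boolean
    ``selected`` (q_bh < q_cut, strict).  Rows are sorted by combined p
    ascending with set-name tie-break.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    if not degsets:
        raise ValueError("need at least one DEGSet")
    N = len(universe)
    deg_lists = {d.contrast_name: d.all & universe for d in degsets}
    names = sorted(collection)
    rows = []
    for name in names:
        members = set(collection[name]) & universe
        K = len(members)
        row: dict[str, object] = {"set_name": name, "K": K}
        ps = []
        for cname, degs in deg_lists.items():
            x = len(members & degs)
            p = hypergeom_p(x, K, len(degs), N)
            row[f"x_{cname}"] = x
            row[f"p_{cname}"] = p
            ps.append(p)
        x2, df, p_comb = fisher_combine(ps)
        row.update(fisher_stat=x2, df=df, p_combined=p_comb)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["q_bh"] = bh_adjust(table["p_combined"].to_numpy())
    table["selected"] = table["q_bh"] < q_cut
    table = table.sort_values(
        ["p_combined", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
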