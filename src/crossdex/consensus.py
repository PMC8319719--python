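"""Direction-consistent consensus of DEG sets across contrasts.

A consensus DEG (CDEG) is a gene called differentially expressed with
the same sign in every disease-vs-control contrast; genes missing from
any contrast's DEG list, or called with mixed signs, are excluded.
The module also annotates CDEGs with biotypes and computes the
composition breakdown (counts and one-decimal percentages).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dex import ContrastResult, DEGSet, call_degs

__all__ = [
    "ConsensusSet",
    "BiotypeBreakdown",
    "intersect_consistent",
    "consensus_from_contrasts",
    "biotype_breakdown",
    "percentage",
    "rank_top",
    "write_consensus_tsv",
]

UNANNOTATED_LABEL = "other annotated RNAs"


@dataclass
class ConsensusSet:
    up: set[str]
    down: set[str]
    mean_logfc: dict[str, float] = field(default_factory=dict)
    biotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("consensus up and down sets overlap")

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class BiotypeBreakdown:
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def intersect_consistent(degsets: Sequence[DEGSet],
                         logfc: Mapping[str, pd.Series] | None = None
                         ) -> ConsensusSet:
    """Intersect DEG sets keeping only genes consistent in sign.

    ``logfc`` optionally maps contrast name to a per-gene logFC series;
    when given, each consensus gene records its mean logFC across the
    contrasts.
    """
    if not degsets:
        raise ValueError("need at least one DEGSet")
    up = set.intersection(*(d.up for d in degsets))
    down = set.intersection(*(d.down for d in degsets))
    mean_logfc: dict[str, float] = {}
    if logfc:
        series = [logfc[d.contrast_name] for d in degsets if d.contrast_name in logfc]
        if series:
            stacked = pd.concat(series, axis=1)
            means = stacked.mean(axis=1)
            mean_logfc = {g: float(means[g]) for g in (up | down) if g in means.index}
    return ConsensusSet(up=up, down=down, mean_logfc=mean_logfc)


def consensus_from_contrasts(results: Sequence[ContrastResult],
                             p_cut: float = 0.01,
                             fc_cut: float = 1.5) -> ConsensusSet:
    """Call DEGs per contrast and intersect them consistently."""
    degsets = [call_degs(r, p_cut=p_cut, fc_cut=fc_cut) for r in results]
    logfc = {r.contrast_name: r.table["logfc"] for r in results}
    return intersect_consistent(degsets, logfc=logfc)


def percentage(count: int, total: int) -> float:
    """100 * count / total, rounded half-up to one decimal place."""
    if total == 0:
        return 0.0
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def biotype_breakdown(consensus: ConsensusSet,
                      annotation: Mapping[str, str]) -> BiotypeBreakdown:
    """Count consensus genes per biotype and compute percentages.

    Genes absent from the annotation table fall into the
    "other annotated RNAs" bucket rather than being dropped.
    """
    genes = sorted(consensus.genes)
    if not genes:
        warnings.warn("empty consensus set; breakdown is all zeros", stacklevel=2)
        return BiotypeBreakdown(counts={}, percentages={}, total=0)
    counts: dict[str, int] = {}
    for g in genes:
        label = annotation.get(g, UNANNOTATED_LABEL)
        counts[label] = counts.get(label, 0) + 1
        consensus.biotype[g] = label
    total = len(genes)
    percentages = {b: percentage(c, total) for b, c in counts.items()}
    return BiotypeBreakdown(counts=counts, percentages=percentages, total=total)


def rank_top(consensus: ConsensusSet, n: int, direction: str,
             alphabetical: bool = False) -> list[str]:
    """Top-n consensus genes of one direction.

    Default ranking is |mean logFC| descending with alphabetical
    tie-break; ``alphabetical=True`` returns a plain alphabetical list
    instead. If fewer than ``n`` genes exist the whole subset is
    returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    subset = sorted(consensus.up if direction == "up" else consensus.down)
    if alphabetical:
        return subset[:n]
    ranked = sorted(subset, key=lambda g: (-abs(consensus.mean_logfc.get(g, 0.0)), g))
    return ranked[:n]


def write_consensus_tsv(consensus: ConsensusSet, path) -> None:
    rows = []
    for direction, genes in (("up", consensus.up), ("down", consensus.down)):
        for g in sorted(genes):
            rows.append(
                {
                    "gene": g,
                    "direction": direction,
                    "mean_logFC": round(consensus.mean_logfc.get(g, float("nan")), 6),
                    "biotype": consensus.biotype.get(g, ""),
                }
            )
    pd.DataFrame(rows, columns=["gene", "direction", "mean_logFC", "biotype"]).to_csv(
        path, sep="\t", index=False
    )


def write_breakdown_json(breakdown: BiotypeBreakdown, path) -> None:
    payload = {
        "total": breakdown.total,
        "counts": dict(sorted(breakdown.counts.items())),
        "percentages": dict(sorted(breakdown.percentages.items())),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
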