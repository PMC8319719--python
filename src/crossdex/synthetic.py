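"""Synthetic cohort generator with planted ground truth.

Emulates the kind of data behind a cross-disease microarray study: a
log2 expression matrix for one shared control group and several disease
groups, a KEGG-style gene-set collection, a STRING-style scored
protein-interaction edge list, and a gene-biotype annotation table.
Every artifact carries a recoverable planted truth (which genes are
differentially expressed and in which direction, which gene sets are
enriched, which network modules exist) so the downstream statistics can
be validated end to end.

The noise model mirrors the hierarchical-variance assumptions of the
empirical-Bayes moderated t-test: per-gene variances are drawn from a
scaled inverse chi-square distribution with prior degrees of freedom
``d0_true`` and prior variance ``s0sq_true``, and observations are
Gaussian around a gene baseline plus a fixed log2 effect in affected
groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_expression",
    "simulate_annotation",
    "simulate_genesets",
    "simulate_ppi",
    "write_expression_tsv",
    "write_design_tsv",
    "write_annotation_tsv",
    "write_gmt",
    "write_edges_tsv",
    "write_truth_json",
]

# Default group layout: 11 shared controls and three disease groups of
# 6/4/4 samples, the shape of a small clinical microarray cohort.
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("control", 11),
    ("IPAH", 6),
    ("CTD", 4),
    ("CHD", 4),
)

# Biotype composition of an annotated array: overwhelmingly protein
# coding with small pseudogene / snoRNA / other fractions.
DEFAULT_BIOTYPE_PROBS: dict[str, float] = {
    "protein_coding": 0.93,
    "pseudogene": 0.04,
    "snoRNA": 0.02,
    "other": 0.01,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    All expression values are log2 scale; ``effect_logfc`` is the
    absolute log2 fold change planted for differentially expressed
    genes, and ``s0sq_true`` is in log2-units squared.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    d0_true: float = 4.0
    s0sq_true: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    frac_shared_de: float = 0.10
    frac_specific_de: float = 0.05
    frac_up: float = 0.80
    effect_logfc: float = 2.0
    n_null_sets: int = 50
    n_planted_sets: int = 3
    set_size_range: tuple[int, int] = (10, 80)
    planted_enrich_frac: float = 0.5
    n_modules: int = 3
    module_size: int = 8
    bg_edge_prob: float = 0.005
    score_planted: float = 950.0
    score_bg_mean: float = 500.0
    score_bg_sd: float = 150.0
    biotype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.groups) < 2:
            raise ValueError("need a control group and at least one disease group")
        for name, n in self.groups:
            if n < 1:
                raise ValueError(f"group {name!r} has non-positive sample count")
        if not (self.d0_true > 0):
            raise ValueError("d0_true must be > 0 (math.inf allowed)")
        if not (self.s0sq_true > 0):
            raise ValueError("s0sq_true must be > 0")
        for frac_name in ("frac_shared_de", "frac_specific_de", "frac_up",
                          "planted_enrich_frac", "bg_edge_prob"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{frac_name} must be in [0, 1]")
        if self.frac_shared_de + self.frac_specific_de > 1.0:
            raise ValueError("frac_shared_de + frac_specific_de must be <= 1")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("set_size_range must satisfy 1 <= lo <= hi <= n_genes")
        if not (0.0 <= self.score_planted <= 1000.0):
            raise ValueError("score_planted must be in [0, 1000]")
        if not (0.0 <= self.score_bg_mean <= 1000.0):
            raise ValueError("score_bg_mean must be in [0, 1000]")
        probs = dict(self.biotype_probs)
        if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_probs must be non-negative and sum to 1")

    @property
    def control_group(self) -> str:
        return self.groups[0][0]

    @property
    def disease_groups(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups[1:])

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:06d}" for i in range(self.n_genes)]


@dataclass
class SimTruth:
    """Planted ground truth accompanying one simulated cohort."""

    shared_up: set[str]
    shared_down: set[str]
    specific_de: dict[str, set[str]]
    planted_set_names: list[str]
    planted_module_members: list[set[str]]
    sigma_sq: pd.Series

    @property
    def shared_de(self) -> set[str]:
        return self.shared_up | self.shared_down


def _stream(config: SimConfig, key: int) -> np.random.Generator:
    """Independent child RNG stream; regenerating one artifact never
    perturbs the others."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig):
    """Draw the log2 expression matrix and its planted truth.

    Returns ``(matrix, truth)`` where ``matrix`` is an
    :class:`~crossdex.dex.ExpressionMatrix` and ``truth`` records the
    planted DE genes and the true per-gene variances.
    """
    from .dex import ExpressionMatrix  # local import to avoid a cycle

    rng = _stream(config, 0)
    genes = config.gene_ids
    n = config.n_genes
    diseases = config.disease_groups

    # Scaled inverse chi-square gene variances: s0^2 * d0 / chi2(d0).
    if math.isinf(config.d0_true):
        sigma_sq = np.full(n, config.s0sq_true)
    else:
        sigma_sq = (
            config.s0sq_true * config.d0_true / rng.chisquare(config.d0_true, size=n)
        )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    # Partition genes into shared-DE, group-specific-DE and null.
    n_shared = int(round(config.frac_shared_de * n))
    n_specific = int(round(config.frac_specific_de * n))
    order = rng.permutation(n)
    shared_idx = order[:n_shared]
    specific_idx = order[n_shared:n_shared + n_specific]

    n_shared_up = int(round(config.frac_up * n_shared))
    shared_signs = np.zeros(n, dtype=float)
    shared_signs[shared_idx[:n_shared_up]] = 1.0
    shared_signs[shared_idx[n_shared_up:]] = -1.0

    # Specific genes cycle over disease groups; sign up with frac_up.
    specific_group = {g: [] for g in diseases}
    specific_signs = np.zeros(n, dtype=float)
    specific_assign = np.empty(n, dtype=object)
    for j, gi in enumerate(specific_idx):
        grp = diseases[j % len(diseases)]
        sign = 1.0 if rng.random() < config.frac_up else -1.0
        specific_group[grp].append(genes[gi])
        specific_signs[gi] = sign
        specific_assign[gi] = grp

    # Assemble samples and effects.
    sample_ids: list[str] = []
    sample_groups: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for grp, n_samp in config.groups:
        affected = grp != config.control_group
        for k in range(n_samp):
            sid = f"{grp}_{k + 1:02d}"
            sample_ids.append(sid)
            sample_groups[sid] = grp
            effect = np.zeros(n)
            if affected:
                effect += shared_signs * config.effect_logfc
                mask = specific_assign == grp
                effect[mask] += specific_signs[mask] * config.effect_logfc
            noise = rng.normal(0.0, np.sqrt(sigma_sq))
            cols.append(baseline + effect + noise)

    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    matrix = ExpressionMatrix(values=values, sample_groups=sample_groups)

    truth = SimTruth(
        shared_up={genes[i] for i in shared_idx[:n_shared_up]},
        shared_down={genes[i] for i in shared_idx[n_shared_up:]},
        specific_de={g: set(members) for g, members in specific_group.items()},
        planted_set_names=[],
        planted_module_members=[],
        sigma_sq=pd.Series(sigma_sq, index=genes, name="sigma_sq"),
    )
    return matrix, truth


def simulate_annotation(config: SimConfig) -> pd.Series:
    """Per-gene biotype labels drawn i.i.d. from ``biotype_probs``."""
    rng = _stream(config, 3)
    labels = list(config.biotype_probs.keys())
    probs = np.array([config.biotype_probs[b] for b in labels], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(labels), size=config.n_genes, p=probs)
    return pd.Series(
        [labels[i] for i in draws],
        index=pd.Index(config.gene_ids, name="gene"),
        name="biotype",
    )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_genesets(config: SimConfig, truth: SimTruth) -> dict[str, set[str]]:
    """Null and planted gene sets over the simulated universe.

    Planted sets draw ``planted_enrich_frac`` of their members from the
    shared DE genes and the remainder uniformly from non-DE genes; null
    sets are uniform over all genes. Planted names are recorded in
    ``truth.planted_set_names`` only — nothing in the emitted collection
    marks them.
    """
    rng = _stream(config, 1)
    genes = config.gene_ids
    shared = sorted(truth.shared_de)
    all_de = truth.shared_de.union(*truth.specific_de.values()) if truth.specific_de else truth.shared_de
    non_de = sorted(set(genes) - all_de)
    lo, hi = config.set_size_range

    collection: dict[str, set[str]] = {}
    truth.planted_set_names = []
    for i in range(config.n_planted_sets):
        size = int(rng.integers(lo, hi + 1))
        n_from_de = int(round(config.planted_enrich_frac * size))
        if n_from_de > len(shared) or size - n_from_de > len(non_de):
            raise ValueError("requested set size exceeds available gene pool")
        members = set(rng.choice(shared, size=n_from_de, replace=False))
        members |= set(rng.choice(non_de, size=size - n_from_de, replace=False))
        name = f"SET_{i + 1:03d}"
        collection[name] = members
        truth.planted_set_names.append(name)
    for i in range(config.n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        if size > len(genes):
            raise ValueError("requested set size exceeds available gene pool")
        name = f"SET_{config.n_planted_sets + i + 1:03d}"
        collection[name] = set(rng.choice(genes, size=size, replace=False))
    return collection


# ---------------------------------------------------------------------------
# Scored interaction network
# ---------------------------------------------------------------------------

def simulate_ppi(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """STRING-style scored edge list with planted clique modules.

    Planted modules are cliques over disjoint subsets of the shared-up
    genes, all at confidence ``score_planted``; background edges are
    Bernoulli(``bg_edge_prob``) over every gene pair, with Gaussian
    scores centred at ``score_bg_mean`` and clipped to [0, 1000].
    """
    rng = _stream(config, 2)
    genes = config.gene_ids
    n = config.n_genes
    need = config.n_modules * config.module_size
    shared_up = sorted(truth.shared_up)
    if need > len(shared_up):
        raise ValueError(
            f"module_size * n_modules = {need} exceeds |shared_up| = {len(shared_up)}"
        )

    pool = list(rng.choice(shared_up, size=need, replace=False))
    truth.planted_module_members = [
        set(pool[i * config.module_size:(i + 1) * config.module_size])
        for i in range(config.n_modules)
    ]

    edges: dict[tuple[str, str], float] = {}
    for members in truth.planted_module_members:
        ms = sorted(members)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                edges[(ms[i], ms[j])] = config.score_planted

    # Background: draw the binomial edge count, then that many distinct
    # unordered pairs (planted pairs keep their planted score).
    n_pairs = n * (n - 1) // 2
    m = rng.binomial(n_pairs, config.bg_edge_prob)
    if m > 0:
        picked = rng.choice(n_pairs, size=m, replace=False)
        scores = np.clip(
            rng.normal(config.score_bg_mean, config.score_bg_sd, size=m), 0.0, 1000.0
        )
        # Map a linear pair index k to (i, j), i < j, row-major over the
        # strictly upper triangle: row i starts at offset i*(n-1) - i*(i-1)/2.
        picked = np.sort(picked)
        rows_ = np.arange(n, dtype=np.int64)
        offsets = rows_ * (n - 1) - rows_ * (rows_ - 1) // 2
        i_idx = np.searchsorted(offsets, picked, side="right") - 1
        j_idx = picked - offsets[i_idx] + i_idx + 1
        for i, j, s in zip(i_idx, j_idx, scores):
            key = (genes[int(i)], genes[int(j)])
            if key not in edges:
                edges[key] = float(s)

    rows = sorted(edges.items())
    return pd.DataFrame(
        {
            "protein1": [a for (a, _b), _s in rows],
            "protein2": [b for (_a, b), _s in rows],
            "combined_score": [round(s, 1) for _ab, s in rows],
        }
    )


# ---------------------------------------------------------------------------
# Writers (plain-text exchange formats)
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6g")


def write_design_tsv(matrix, path: str | Path) -> None:
    design = pd.DataFrame(
        {"sample_id": list(matrix.sample_groups), "group": list(matrix.sample_groups.values())}
    )
    design.to_csv(path, sep="\t", index=False)


def write_annotation_tsv(annotation: pd.Series, path: str | Path) -> None:
    annotation.rename("biotype").to_csv(path, sep="\t", header=True)


def write_gmt(collection: Mapping[str, Sequence[str] | set[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in collection:
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def write_edges_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "shared_up": sorted(truth.shared_up),
        "shared_down": sorted(truth.shared_down),
        "specific_de": {g: sorted(s) for g, s in truth.specific_de.items()},
        "planted_set_names": list(truth.planted_set_names),
        "planted_module_members": [sorted(s) for s in truth.planted_module_members],
        "sigma_sq": {g: float(v) for g, v in truth.sigma_sq.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
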