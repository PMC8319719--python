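"""Gene-set filtering, hypergeometric tail, Fisher combination,
consensus-pathway selection."""

import dataclasses
import math

import numpy as np
import pytest

import crossdex as cx
from crossdex import enrich, synthetic
from crossdex.dex import DEGSet

from conftest import hypergeom_enum


# -- GMT and filtering ------------------------------------------------------

def test_gmt_round_trip(tmp_path):
    coll = {"S1": {"G1", "G2", "G3"}, "S2": {"G2"}}
    path = tmp_path / "sets.gmt"
    synthetic.write_gmt(coll, path)
    assert cx.read_gmt(path) == coll


def test_gmt_rejects_malformed_line(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("ONLY_NAME\tdesc\n")
    with pytest.raises(ValueError, match="malformed"):
        cx.read_gmt(path)


def test_filter_size_window_boundaries():
    universe = {f"G{i}" for i in range(400)}
    coll = {
        "tiny": {f"G{i}" for i in range(4)},
        "min": {f"G{i}" for i in range(5)},
        "max": {f"G{i}" for i in range(300)},
        "big": {f"G{i}" for i in range(301)},
    }
    kept = cx.filter_collection(coll, universe)
    assert set(kept) == {"min", "max"}


def test_filter_applies_universe_restriction_first():
    universe = {"G1", "G2", "G3"}
    coll = {"S": {"G1", "G2", "G3", "X1", "X2", "X3", "X4", "X5", "X6", "X7"}}
    assert cx.filter_collection(coll, universe) == {}  # size 3 < 5 after restriction


def test_filter_name_pattern_exclusion():
    universe = {f"G{i}" for i in range(10)}
    coll = {"PATHWAYS_IN_CANCER": set(universe), "SPLICEOSOME": set(universe)}
    kept = cx.filter_collection(coll, universe, exclude_patterns=["cancer"])
    assert set(kept) == {"SPLICEOSOME"}


# -- hypergeometric tail ----------------------------------------------------

def test_hypergeom_zero_overlap_is_one():
    assert cx.hypergeom_p(0, 4, 5, 10) == 1.0


def test_hypergeom_hand_enumeration():
    assert cx.hypergeom_p(3, 4, 5, 10) == pytest.approx(66 / 252, rel=1e-12)


def test_hypergeom_saturated_draw_is_one():
    assert cx.hypergeom_p(3, 4, 10, 10) == pytest.approx(1.0)


def test_hypergeom_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        cx.hypergeom_p(5, 4, 5, 10)
    with pytest.raises(ValueError):
        cx.hypergeom_p(1, 4, 11, 10)


def test_hypergeom_full_enumeration_sweep():
    """Exact agreement with brute-force enumeration for every
    (N <= 12, K, n, x)."""
    for N in range(1, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                for x in range(min(K, n) + 1):
                    assert cx.hypergeom_p(x, K, n, N) == pytest.approx(
                        hypergeom_enum(x, K, n, N), rel=1e-9, abs=1e-12), \
                        (x, K, n, N)


def test_hypergeom_monotone_in_overlap():
    for K, n, N in [(10, 20, 100), (5, 5, 12), (50, 80, 200)]:
        ps = [cx.hypergeom_p(x, K, n, N) for x in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


# -- Fisher combination -----------------------------------------------------

def test_fisher_all_ones():
    x2, df, p = cx.fisher_combine([1.0, 1.0, 1.0])
    assert x2 == 0.0 and df == 6 and p == 1.0


def test_fisher_single_p_identity():
    _, df, p = cx.fisher_combine([0.2])
    assert df == 2 and p == pytest.approx(0.2, rel=1e-12)


def test_fisher_closed_form_chi2_six_df():
    """X2 = -6 ln 0.05; chi-square(6) tail = e^(-x/2)(1 + x/2 + (x/2)^2/2)."""
    x2, df, p = cx.fisher_combine([0.05, 0.05, 0.05])
    assert x2 == pytest.approx(-2 * 3 * math.log(0.05), rel=1e-12)
    h = x2 / 2
    assert p == pytest.approx(math.exp(-h) * (1 + h + h * h / 2), rel=1e-10)
    assert x2 == pytest.approx(17.974, abs=5e-4)
    assert p == pytest.approx(6.3e-3, abs=1e-4)


def test_fisher_clamps_zero_with_warning():
    with pytest.warns(RuntimeWarning, match="clamped"):
        x2, _, p = cx.fisher_combine([0.0, 0.5])
    assert math.isfinite(x2) and p > 0


def test_fisher_rejects_empty_and_out_of_range():
    with pytest.raises(ValueError):
        cx.fisher_combine([])
    with pytest.raises(ValueError):
        cx.fisher_combine([0.5, 1.5])


def test_fisher_null_type_one_error():
    """k = 3 independent uniforms: rejection rate at 0.05 within 3
    binomial SDs over 10,000 replicates."""
    rng = np.random.default_rng(41)
    u = rng.uniform(size=(10000, 3))
    x2 = -2 * np.log(u).sum(axis=1)
    from scipy import stats
    p = stats.chi2.sf(x2, 6)
    # spot-check the vectorized null against the package function
    for row, pc in zip(u[:5], p[:5]):
        assert cx.fisher_combine(row)[2] == pytest.approx(pc, rel=1e-10)
    rate = (p < 0.05).mean()
    sd = math.sqrt(0.05 * 0.95 / 10000)
    assert abs(rate - 0.05) <= 3 * sd


# -- consensus pathways -----------------------------------------------------

def _degsets(names, genes):
    return [DEGSet(contrast_name=n, up=set(genes), down=set()) for n in names]


def test_all_empty_degsets_select_nothing():
    universe = {f"G{i}" for i in range(50)}
    coll = {"S1": {f"G{i}" for i in range(10)}, "S2": {f"G{i}" for i in range(20, 30)}}
    degsets = [DEGSet(contrast_name=c, up=set(), down=set()) for c in "abc"]
    table = cx.consensus_pathways(coll, degsets, universe)
    assert (table["p_combined"] == 1.0).all()
    assert (table["q_bh"] == 1.0).all()
    assert not table["selected"].any()


def test_table_sorted_by_combined_p_and_q_dominates_p(cohort, contrast_results):
    coll = cx.filter_collection(cohort["collection"], set(cohort["matrix"].gene_ids))
    degsets = [cx.call_degs(r) for r in contrast_results]
    table = cx.consensus_pathways(coll, degsets, set(cohort["matrix"].gene_ids))
    assert table["p_combined"].is_monotonic_increasing
    assert (table["q_bh"] >= table["p_combined"] - 1e-15).all()
    assert (table["df"] == 2 * len(degsets)).all()


def test_planted_set_power_over_replicates():
    """A single planted set (half its members shared DE) among 50 null
    sets is selected in at least 90% of seeded replicates."""
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        cfg = cx.SimConfig(n_genes=1000, n_planted_sets=1, n_null_sets=50,
                           planted_enrich_frac=0.5, seed=seed)
        matrix, truth = cx.simulate_expression(cfg)
        coll = cx.simulate_genesets(cfg, truth)
        results = [cx.run_contrast(matrix, "control", g)
                   for g in cfg.disease_groups]
        degsets = [cx.call_degs(r) for r in results]
        universe = set(matrix.gene_ids)
        table = cx.consensus_pathways(
            cx.filter_collection(coll, universe), degsets, universe)
        selected = set(table.loc[table["selected"], "set_name"])
        hits += truth.planted_set_names[0] in selected
    assert hits / n_rep >= 0.90
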