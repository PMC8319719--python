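"""Moderated-t workflow: fits, prior, shrinkage, BH, DEG calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

import crossdex as cx
from crossdex.dex import FitResult

GROUPS = {"c1": "ctrl", "c2": "ctrl", "t1": "case", "t2": "case"}


def _matrix(rows, index, groups=GROUPS):
    values = pd.DataFrame(rows, index=index, columns=list(groups))
    return cx.ExpressionMatrix(values=values, sample_groups=dict(groups))


# -- collapse_probes --------------------------------------------------------

def test_collapse_unique_symbols_unchanged():
    values = pd.DataFrame(np.arange(8.0).reshape(2, 4), index=["A", "B"],
                          columns=list(GROUPS))
    m = cx.collapse_probes(values, dict(GROUPS))
    assert m.values.equals(values)


def test_collapse_keeps_largest_iqr_row():
    values = pd.DataFrame(
        [[0.0, 1.0, 2.0, 3.0],   # G1, IQR 1.5
         [0.0, 2.0, 4.0, 6.0],   # G1, IQR 3.0
         [1.0, 1.0, 1.0, 1.0]],  # G2
        index=["G1", "G1", "G2"], columns=list(GROUPS))
    m = cx.collapse_probes(values, dict(GROUPS))
    assert list(m.values.index) == ["G1", "G2"]
    assert list(m.values.loc["G1"]) == [0.0, 2.0, 4.0, 6.0]


def test_collapse_tie_keeps_first_occurrence():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]],
        index=["G1", "G1"], columns=list(GROUPS))
    m = cx.collapse_probes(values, dict(GROUPS))
    assert m.values.shape[0] == 1
    assert list(m.values.loc["G1"]) == [1.0, 2.0, 3.0, 4.0]


def test_collapse_empty_matrix_rejected():
    with pytest.raises(ValueError):
        cx.collapse_probes(pd.DataFrame(), {})


# -- fit_linear -------------------------------------------------------------

def test_fit_noiseless_means():
    m = _matrix([[1.0, 1.0, 2.0, 2.0]], ["G1"])
    fit = cx.fit_linear(m, "ctrl", "case")
    assert fit.logfc["G1"] == 1.0
    assert fit.s2["G1"] == 0.0
    assert fit.df_resid == 2
    assert fit.v_contrast == 1.0


def test_fit_equal_groups_zero_logfc():
    m = _matrix([[3.0, 3.0, 3.0, 3.0]], ["G1"])
    assert cx.fit_linear(m, "ctrl", "case").logfc["G1"] == 0.0


def test_fit_pooled_variance_hand_case():
    """ctrl (1,1,1), case (3,5): SS_case = 2, pooled s2 = 2/3, dg = 3."""
    groups = {"c1": "ctrl", "c2": "ctrl", "c3": "ctrl", "t1": "case", "t2": "case"}
    m = _matrix([[1.0, 1.0, 1.0, 3.0, 5.0]], ["G1"], groups)
    fit = cx.fit_linear(m, "ctrl", "case")
    assert fit.logfc["G1"] == pytest.approx(3.0)
    assert fit.s2["G1"] == pytest.approx(2.0 / 3.0)
    assert fit.df_resid == 3
    assert fit.v_contrast == pytest.approx(1 / 2 + 1 / 3)


def test_fit_rejects_missing_or_tiny_groups():
    m = _matrix([[1.0, 1.0, 2.0, 2.0]], ["G1"])
    with pytest.raises(ValueError, match="absent"):
        cx.fit_linear(m, "ctrl", "nope")
    groups = {"c1": "ctrl", "c2": "ctrl", "c3": "ctrl", "t1": "case"}
    m2 = _matrix([[1.0, 1.0, 1.0, 2.0]], ["G1"], groups)
    with pytest.raises(ValueError, match="fewer than 2"):
        cx.fit_linear(m2, "ctrl", "case")


# -- estimate_prior ---------------------------------------------------------

def test_prior_identical_variances_infinite_d0():
    prior = cx.estimate_prior(np.full(50, 0.3), dg=4)
    assert math.isinf(prior.d0)
    # with no dispersion, s0^2 is the common variance corrected for the
    # chi-square bias of a single draw at dg degrees of freedom
    expected = 0.3 * math.exp(-special.digamma(2.0) + math.log(2.0))
    assert prior.s0sq == pytest.approx(expected, rel=1e-9)


def test_prior_trigamma_symmetry_d0_equals_dg():
    """If Var(log s2) is exactly 2*trigamma(dg/2), the fitted d0 is dg."""
    dg = 6
    target_var = 2 * special.polygamma(1, dg / 2)
    # build z with sample variance exactly target_var
    z = np.tile([-1.0, 1.0], 20)
    z *= math.sqrt(target_var / np.var(z, ddof=1))
    prior = cx.estimate_prior(np.exp(z), dg=dg)
    assert prior.d0 == pytest.approx(dg, rel=1e-6)
    # plug back: the trigamma equation balances
    assert special.polygamma(1, prior.d0 / 2) == pytest.approx(
        np.var(z, ddof=1) - special.polygamma(1, dg / 2), rel=1e-9)


def test_prior_parameter_recovery_from_simulation():
    """Hierarchical simulation at 5000 genes, dg = 9: recover
    (d0, s0^2) = (4, 0.05) within 15%."""
    rng = np.random.default_rng(123)
    d0, s0sq, dg, n = 4.0, 0.05, 9, 5000
    sigma_sq = s0sq * d0 / rng.chisquare(d0, size=n)
    s2 = sigma_sq * rng.chisquare(dg, size=n) / dg
    prior = cx.estimate_prior(s2, dg=dg)
    assert prior.d0 == pytest.approx(d0, rel=0.15)
    assert prior.s0sq == pytest.approx(s0sq, rel=0.15)


def test_prior_refuses_too_few_variances():
    with pytest.raises(ValueError, match="at least 30"):
        cx.estimate_prior(np.full(10, 0.5), dg=4)
    # zero variances do not count toward the minimum
    with pytest.raises(ValueError, match="at least 30"):
        cx.estimate_prior(np.concatenate([np.zeros(40), np.full(20, 0.5)]), dg=4)


# -- moderated_t ------------------------------------------------------------

def _fit_from(logfc, s2, dg, v):
    idx = pd.RangeIndex(len(logfc)).astype(str)
    return FitResult("toy", pd.Series(logfc, index=idx),
                     pd.Series(s2, index=idx), dg, v)


def test_moderated_t_d0_zero_is_ordinary_t():
    """With no prior weight the statistic and p-value must match an
    independently coded pooled two-sample t-test."""
    rng = np.random.default_rng(7)
    yc = rng.normal(size=(40, 5))
    yt = rng.normal(size=(40, 4))
    groups = {f"c{i}": "ctrl" for i in range(5)} | {f"t{i}": "case" for i in range(4)}
    values = pd.DataFrame(np.hstack([yc, yt]), columns=list(groups),
                          index=[f"G{i}" for i in range(40)])
    m = cx.ExpressionMatrix(values=values, sample_groups=groups)
    fit = cx.fit_linear(m, "ctrl", "case")
    out = cx.moderated_t(fit, cx.PriorEstimate(d0=0.0, s0sq=1.0))
    t_ref, p_ref = stats.ttest_ind(yt, yc, axis=1, equal_var=True)
    np.testing.assert_allclose(out["t_mod"], t_ref, rtol=1e-10)
    np.testing.assert_allclose(out["p_raw"], p_ref, rtol=1e-10)


def test_moderated_t_zero_effect():
    out = cx.moderated_t(_fit_from([0.0], [0.5], 4, 0.5),
                         cx.PriorEstimate(d0=2.0, s0sq=0.1))
    assert out["t_mod"].iloc[0] == 0.0
    assert out["p_raw"].iloc[0] == 1.0


def test_moderated_t_hand_arithmetic():
    """b=1, posterior s2 = 0.25, v = 0.5, total df 10 => t = 2.8284."""
    # choose d0, s0sq, s2 so the posterior variance is exactly 0.25
    fit = _fit_from([1.0], [0.25], 5, 0.5)
    out = cx.moderated_t(fit, cx.PriorEstimate(d0=5.0, s0sq=0.25))
    t = 1.0 / (0.5 * math.sqrt(0.5))
    assert out["t_mod"].iloc[0] == pytest.approx(t)
    assert out["p_raw"].iloc[0] == pytest.approx(2 * stats.t.sf(t, 10), rel=1e-12)


def test_moderated_t_infinite_d0_uses_normal_tail():
    out = cx.moderated_t(_fit_from([1.0], [9.9], 4, 1.0),
                         cx.PriorEstimate(d0=math.inf, s0sq=1.0))
    assert out["t_mod"].iloc[0] == pytest.approx(1.0)
    assert out["p_raw"].iloc[0] == pytest.approx(2 * stats.norm.sf(1.0), rel=1e-12)


def test_moderated_t_degenerate_zero_variance_warns():
    fit = _fit_from([1.0], [0.0], 4, 1.0)
    with pytest.warns(RuntimeWarning, match="zero posterior variance"):
        out = cx.moderated_t(fit, cx.PriorEstimate(d0=0.0, s0sq=1.0))
    assert np.isinf(out["t_mod"].iloc[0])
    assert out["p_raw"].iloc[0] == np.finfo(float).tiny


# -- bh_adjust --------------------------------------------------------------

def test_bh_stepup_hand_case():
    np.testing.assert_allclose(cx.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_identity():
    assert cx.bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        cx.bh_adjust([0.5, 1.2])


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_dominance_and_monotonicity(p):
    q = cx.bh_adjust(p)
    assert np.all(q >= np.asarray(p) - 1e-15)
    assert np.all(q <= 1.0)
    # step-up preserves the ordering of the raw p-values (the cummin
    # enforcement is already applied, so sorted q follows sorted p)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-15)


# -- call_degs --------------------------------------------------------------

def _result(logfc, p_adj):
    idx = [f"G{i}" for i in range(len(logfc))]
    table = pd.DataFrame({"logfc": logfc, "s2": 1.0, "t_mod": 0.0,
                          "p_raw": p_adj, "p_adj": p_adj}, index=idx)
    return cx.ContrastResult("toy", table, cx.PriorEstimate(1.0, 1.0), 4, 0.5)


def test_deg_cutoffs_are_strict():
    res = _result([2.0, math.log2(1.5), -1.0], [0.01, 0.001, 0.001])
    degs = cx.call_degs(res)
    assert "G0" not in degs.all       # p_adj exactly at the cutoff
    assert "G1" not in degs.all       # FC exactly 1.5
    assert "G2" in degs.down          # clears both cutoffs, downregulated


def test_null_simulation_raw_p_uniform():
    """Global null: the raw moderated p-values reject at close to the
    nominal rate (within 3 binomial SDs at alpha = 0.05)."""
    cfg = cx.SimConfig(n_genes=5000, frac_shared_de=0.0, frac_specific_de=0.0,
                       seed=29)
    matrix, _ = cx.simulate_expression(cfg)
    res = cx.run_contrast(matrix, "control", "IPAH")
    alpha = 0.05
    frac = (res.table["p_raw"] < alpha).mean()
    sd = math.sqrt(alpha * (1 - alpha) / 5000)
    assert abs(frac - alpha) <= 3 * sd
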