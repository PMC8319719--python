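"""Moderated-t differential expression for two-group contrasts.

Implements the empirical-Bayes workflow used for small-sample
microarray cohorts: per-gene two-group linear fits on log2 expression,
a moment-matched scaled-inverse-chi-square prior on the gene variances,
variance shrinkage, moderated t-statistics with augmented degrees of
freedom, Benjamini-Hochberg adjustment, and DEG calling at a corrected
p-value cutoff combined with a linear fold-change cutoff.

Model. For gene g with estimated log2 fold change b_g, pooled residual
variance s_g^2 on d_g degrees of freedom and contrast variance factor
v_g = 1/n_case + 1/n_ctrl, the prior s_g^2 ~ s0^2 * d0 / chi2(d0)
yields the posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated statistic t~_g = b_g / (s~_g * sqrt(v_g)), referred
to a Student t distribution with d0 + d_g degrees of freedom (standard
normal in the limit d0 -> inf).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "PriorEstimate",
    "FitResult",
    "ContrastResult",
    "DEGSet",
    "collapse_probes",
    "fit_linear",
    "estimate_prior",
    "moderated_t",
    "bh_adjust",
    "call_degs",
    "run_contrast",
    "read_expression_tsv",
    "write_toptable_tsv",
]

P_CUT_DEFAULT = 0.01
FC_CUT_DEFAULT = 1.5
_TINY = np.finfo(float).tiny


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, with a group label per sample."""

    values: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("empty expression matrix")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]


@dataclass(frozen=True)
class PriorEstimate:
    """Empirical-Bayes variance prior: d0 degrees of freedom, s0^2 scale.

    d0 = 0 expresses the prior-free limit (ordinary pooled t);
    d0 = inf expresses complete shrinkage to the common variance s0^2.
    """

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (math.inf allowed)")
        if not (self.s0sq > 0):
            raise ValueError("s0sq must be > 0")


@dataclass
class FitResult:
    """Per-gene two-group fit for one disease-vs-control contrast."""

    contrast_name: str
    logfc: pd.Series
    s2: pd.Series
    df_resid: int
    v_contrast: float


@dataclass
class ContrastResult:
    contrast_name: str
    table: pd.DataFrame  # columns: logfc, s2, t_mod, p_raw, p_adj
    prior: PriorEstimate
    df_resid: int
    v_contrast: float


@dataclass
class DEGSet:
    contrast_name: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down DEG sets overlap")

    @property
    def all(self) -> set[str]:
        return self.up | self.down


def collapse_probes(values: pd.DataFrame,
                    sample_groups: dict[str, str]) -> ExpressionMatrix:
    """Collapse duplicate gene symbols, keeping the most variable row.

    Among rows sharing a symbol the one with the largest interquartile
    range across samples is retained; ties go to the first occurrence.
    """
    if values.empty:
        raise ValueError("empty expression matrix")
    if values.index.is_unique:
        return ExpressionMatrix(values=values, sample_groups=sample_groups)
    q75 = values.quantile(0.75, axis=1)
    q25 = values.quantile(0.25, axis=1)
    iqr = (q75 - q25).to_numpy()
    keep_pos: dict[str, int] = {}
    for pos, gene in enumerate(values.index):
        best = keep_pos.get(gene)
        if best is None or iqr[pos] > iqr[best]:
            keep_pos[gene] = pos
    rows = sorted(keep_pos.values())
    collapsed = values.iloc[rows]
    return ExpressionMatrix(values=collapsed, sample_groups=sample_groups)


def fit_linear(matrix: ExpressionMatrix, control_group: str,
               case_group: str) -> FitResult:
    """Two-group fit: difference of means with pooled within-group variance."""
    ctrl = matrix.samples_in(control_group)
    case = matrix.samples_in(case_group)
    for name, samples in ((control_group, ctrl), (case_group, case)):
        if not samples:
            raise ValueError(f"group {name!r} absent from matrix")
        if len(samples) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    yc = matrix.values[ctrl].to_numpy()
    yt = matrix.values[case].to_numpy()
    n_ctrl, n_case = yc.shape[1], yt.shape[1]
    logfc = yt.mean(axis=1) - yc.mean(axis=1)
    ss = ((yc - yc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((yt - yt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n_case + n_ctrl - 2
    idx = matrix.values.index
    return FitResult(
        contrast_name=f"{case_group}_vs_{control_group}",
        logfc=pd.Series(logfc, index=idx, name="logfc"),
        s2=pd.Series(ss / df, index=idx, name="s2"),
        df_resid=df,
        v_contrast=1.0 / n_case + 1.0 / n_ctrl,
    )


def estimate_prior(s2: pd.Series | np.ndarray, dg: int,
                   min_genes: int = 30) -> PriorEstimate:
    """Moment-match the variance prior on the log scale.

    Under the hierarchical model, s_g^2 / s0^2 is d_g/d0-scaled
    F(d_g, d0), so z = log s_g^2 has variance psi'(d_g/2) + psi'(d0/2)
    (psi' the trigamma function) and a mean that fixes s0^2 once d0 is
    known. d0 solves psi'(d0/2) = Var(z) - psi'(d_g/2) by monotone
    root-finding; when the right side is non-positive the variances are
    under-dispersed relative to chi-square sampling noise and d0 is
    infinite (complete shrinkage to a common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < min_genes:
        raise ValueError(
            f"need at least {min_genes} positive variances to fit the prior, "
            f"got {s2.size}"
        )
    z = np.log(s2)
    var_z = float(np.var(z, ddof=1))
    mean_z = float(np.mean(z))
    rhs = var_z - special.polygamma(1, dg / 2.0)
    if rhs <= 0:
        d0 = math.inf
        log_s0sq = mean_z - special.digamma(dg / 2.0) + math.log(dg / 2.0)
    else:
        f = lambda d0_: special.polygamma(1, d0_ / 2.0) - rhs
        lo, hi = 0.1, 1e6
        if f(lo) <= 0:       # extremely heavy-tailed variances
            d0 = lo
        elif f(hi) >= 0:     # indistinguishable from infinite d0
            d0 = math.inf
        else:
            d0 = float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
        if math.isinf(d0):
            log_s0sq = mean_z - special.digamma(dg / 2.0) + math.log(dg / 2.0)
        else:
            log_s0sq = (
                mean_z
                - special.digamma(dg / 2.0)
                + special.digamma(d0 / 2.0)
                - math.log(d0 / dg)
            )
    return PriorEstimate(d0=d0, s0sq=float(np.exp(log_s0sq)))


def moderated_t(fit: FitResult, prior: PriorEstimate) -> pd.DataFrame:
    """Shrink variances toward the prior and compute moderated t and p.

    With d0 = 0 the statistic reduces to the ordinary pooled two-sample
    t on d_g degrees of freedom; with d0 infinite all genes share the
    prior variance and the reference distribution is standard normal.
    """
    b = fit.logfc.to_numpy(dtype=float)
    s2 = fit.s2.to_numpy(dtype=float)
    dg, v = fit.df_resid, fit.v_contrast
    if math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0sq + dg * s2) / (prior.d0 + dg)
        df_total = prior.d0 + dg

    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(s2_post * v)
    t = np.where((b == 0), 0.0, t)
    degenerate = (s2_post == 0) & (b != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} genes have zero posterior variance with "
            "non-zero effect; reporting infinite statistics with minimal p",
            RuntimeWarning,
            stacklevel=2,
        )
        t = np.where(degenerate, np.sign(b) * np.inf, t)

    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, _TINY, 1.0)
    return pd.DataFrame({"t_mod": t, "p_raw": p}, index=fit.logfc.index)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(matrix: ExpressionMatrix, control_group: str, case_group: str,
                 prior: PriorEstimate | None = None) -> ContrastResult:
    """Fit, moderate and BH-adjust one disease-vs-control contrast."""
    fit = fit_linear(matrix, control_group, case_group)
    if prior is None:
        prior = estimate_prior(fit.s2, fit.df_resid)
    tp = moderated_t(fit, prior)
    table = pd.DataFrame(
        {
            "logfc": fit.logfc,
            "s2": fit.s2,
            "t_mod": tp["t_mod"],
            "p_raw": tp["p_raw"],
            "p_adj": bh_adjust(tp["p_raw"].to_numpy()),
        }
    )
    return ContrastResult(
        contrast_name=fit.contrast_name,
        table=table,
        prior=prior,
        df_resid=fit.df_resid,
        v_contrast=fit.v_contrast,
    )


def call_degs(result: ContrastResult, p_cut: float = P_CUT_DEFAULT,
              fc_cut: float = FC_CUT_DEFAULT) -> DEGSet:
    """DEG = adjusted p strictly below ``p_cut`` AND linear fold change
    strictly above ``fc_cut`` (i.e. |logfc| > log2(fc_cut))."""
    t = result.table
    lfc_cut = math.log2(fc_cut)
    sig = (t["p_adj"] < p_cut) & (t["logfc"].abs() > lfc_cut)
    up = set(t.index[sig & (t["logfc"] > 0)])
    down = set(t.index[sig & (t["logfc"] < 0)])
    return DEGSet(contrast_name=result.contrast_name, up=up, down=down)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(expression_path, design_path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene symbols, header sample
    ids) plus its (sample_id, group) design TSV, collapsing duplicate
    symbols by largest IQR."""
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    groups = dict(zip(design["sample_id"].astype(str), design["group"].astype(str)))
    return collapse_probes(values, groups)


def write_toptable_tsv(result: ContrastResult, path) -> None:
    """Write the conventional topTable layout:
    gene, logFC, FC, t, P.Value, adj.P.Val."""
    t = result.table
    out = pd.DataFrame(
        {
            "gene": t.index,
            "logFC": t["logfc"].to_numpy(),
            "FC": np.exp2(t["logfc"].to_numpy()),
            "t": t["t_mod"].to_numpy(),
            "P.Value": t["p_raw"].to_numpy(),
            "adj.P.Val": t["p_adj"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
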