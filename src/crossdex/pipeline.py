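"""End-to-end orchestration and command-line interface.

Runs the full consensus chain — simulate (or load) a cohort, moderated-t
differential expression per disease contrast, direction-consistent
consensus, pathway meta-enrichment, PPI centrality and MCODE modules —
writing per-stage tables and a run manifest.  Every tunable threshold
defaults to the study-style value (adjusted p < 0.01, FC > 1.5, set
sizes 5..300, combined q < 0.05, score > 700, degree >= 30,
betweenness >= 300, MCODE 2 / 0.2 / 2 / haircut / depth 100) so a
zero-flag run reproduces the reference analysis recipe.

Also houses the comparative-threshold-cycle (2^-ddCt) utility for
relative qPCR quantification.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import consensus as cns
from . import dex, enrich, network, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "ddct", "cli", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "dex", "consensus", "enrich", "network")
STAGE_EXIT_CODES = {name: i + 2 for i, name in enumerate(STAGES)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one run.

    Either all four input paths (expression + design, GMT, edges,
    annotation) are given, or ``sim`` holds a synthetic-cohort
    configuration for a self-contained run.
    """

    outdir: str = "crossdex_out"
    seed: int = 0
    log_level: str = "INFO"
    # input paths (file mode)
    expression: str | None = None
    design: str | None = None
    gmt: str | None = None
    edges: str | None = None
    annotation: str | None = None
    # synthetic mode
    sim: synthetic.SimConfig | None = None
    # thresholds (study-style defaults)
    p_cut: float = dex.P_CUT_DEFAULT
    fc_cut: float = dex.FC_CUT_DEFAULT
    min_set_size: int = enrich.MIN_SET_SIZE
    max_set_size: int = enrich.MAX_SET_SIZE
    q_cut: float = enrich.Q_CUT_DEFAULT
    score_threshold: float = network.SCORE_THRESHOLD_DEFAULT
    score_inclusive: bool = False
    degree_cut: int = network.DEGREE_CUT_DEFAULT
    betweenness_cut: float = network.BETWEENNESS_CUT_DEFAULT
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_haircut: bool = True
    mcode_max_depth: int = 100
    min_module_size: int = network.MIN_MODULE_SIZE_DEFAULT
    exclude_set_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        paths = (self.expression, self.design, self.gmt, self.edges, self.annotation)
        if self.sim is None and any(p is None for p in paths):
            raise ValueError(
                "config needs either all input paths or a synthetic 'sim' block"
            )
        for name in ("p_cut", "fc_cut", "q_cut", "score_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        sim = raw.pop("sim", None)
        if sim is not None:
            if "groups" in sim:
                sim["groups"] = tuple((str(g), int(n)) for g, n in sim["groups"])
            if "set_size_range" in sim:
                sim["set_size_range"] = tuple(sim["set_size_range"])
            sim = synthetic.SimConfig(**sim)
        if "exclude_set_patterns" in raw:
            raw["exclude_set_patterns"] = tuple(raw["exclude_set_patterns"])
        return cls(sim=sim, **raw)


def _stage(manifest: dict, name: str):
    manifest["stages"].append(name)
    logger.info("stage %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the run manifest.

    Per-stage tables are written under ``config.outdir``.  On failure a
    :class:`PipelineError` naming the failing stage is raised; outputs
    of completed stages are retained.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": [],
        "counts": {},
        "thresholds": {
            "p_cut": config.p_cut,
            "fc_cut": config.fc_cut,
            "set_size": [config.min_set_size, config.max_set_size],
            "q_cut": config.q_cut,
            "score_threshold": config.score_threshold,
            "degree_cut": config.degree_cut,
            "betweenness_cut": config.betweenness_cut,
            "mcode": [
                config.mcode_degree_cutoff,
                config.mcode_node_score_cutoff,
                config.mcode_k_core,
                config.mcode_haircut,
                config.mcode_max_depth,
            ],
            "min_module_size": config.min_module_size,
        },
    }

    # -- inputs -------------------------------------------------------
    try:
        _stage(manifest, "simulate")
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            matrix, truth = synthetic.simulate_expression(sim)
            annotation = synthetic.simulate_annotation(sim)
            collection = synthetic.simulate_genesets(sim, truth)
            edges = synthetic.simulate_ppi(sim, truth)
            synthetic.write_expression_tsv(matrix, outdir / "expression.tsv")
            synthetic.write_design_tsv(matrix, outdir / "design.tsv")
            synthetic.write_annotation_tsv(annotation, outdir / "annotation.tsv")
            synthetic.write_gmt(collection, outdir / "genesets.gmt")
            synthetic.write_edges_tsv(edges, outdir / "edges.tsv")
            synthetic.write_truth_json(truth, outdir / "truth.json")
            control = sim.control_group
            cases = list(sim.disease_groups)
            ann_map = annotation.to_dict()
        else:
            matrix = dex.read_expression_tsv(config.expression, config.design)
            collection = enrich.read_gmt(config.gmt)
            edges = network.read_edges_tsv(config.edges)
            ann = pd.read_csv(config.annotation, sep="\t", index_col=0)
            ann_map = ann.iloc[:, 0].to_dict()
            groups = list(dict.fromkeys(matrix.sample_groups.values()))
            control, cases = groups[0], groups[1:]
        manifest["counts"]["genes"] = len(matrix.gene_ids)
        manifest["counts"]["samples"] = matrix.values.shape[1]
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError("simulate", e) from e

    # -- differential expression --------------------------------------
    try:
        _stage(manifest, "dex")
        results = [dex.run_contrast(matrix, control, case) for case in cases]
        degsets = []
        for r in results:
            dex.write_toptable_tsv(r, outdir / f"dex_{r.contrast_name}.tsv")
            d = dex.call_degs(r, p_cut=config.p_cut, fc_cut=config.fc_cut)
            degsets.append(d)
            manifest["counts"][f"degs_{r.contrast_name}"] = len(d.all)
    except Exception as e:
        raise PipelineError("dex", e) from e

    # -- consensus -----------------------------------------------------
    try:
        _stage(manifest, "consensus")
        logfc = {r.contrast_name: r.table["logfc"] for r in results}
        consensus = cns.intersect_consistent(degsets, logfc=logfc)
        breakdown = cns.biotype_breakdown(consensus, ann_map)
        cns.write_consensus_tsv(consensus, outdir / "consensus.tsv")
        cns.write_breakdown_json(breakdown, outdir / "biotype_breakdown.json")
        manifest["counts"]["cdegs"] = len(consensus)
        manifest["counts"]["cdegs_up"] = len(consensus.up)
        manifest["counts"]["cdegs_down"] = len(consensus.down)
    except Exception as e:
        raise PipelineError("consensus", e) from e

    # -- enrichment ----------------------------------------------------
    try:
        _stage(manifest, "enrich")
        universe = set(matrix.gene_ids)
        filtered = enrich.filter_collection(
            collection, universe,
            min_size=config.min_set_size, max_size=config.max_set_size,
            exclude_patterns=config.exclude_set_patterns,
        )
        table = enrich.consensus_pathways(filtered, degsets, universe,
                                          q_cut=config.q_cut)
        enrich.write_enrichment_tsv(table, outdir / "enrichment.tsv")
        manifest["counts"]["gene_sets_filtered"] = len(filtered)
        manifest["counts"]["pathways_selected"] = int(table["selected"].sum())
    except Exception as e:
        raise PipelineError("enrich", e) from e

    # -- network -------------------------------------------------------
    try:
        _stage(manifest, "network")
        coding = {
            g for g in consensus.genes if ann_map.get(g) == "protein_coding"
        }
        graph = network.build_graph(
            edges, node_whitelist=coding,
            score_threshold=config.score_threshold,
            inclusive=config.score_inclusive,
        )
        manifest["counts"]["network_nodes"] = graph.number_of_nodes()
        manifest["counts"]["network_edges"] = graph.number_of_edges()
        if graph.number_of_nodes() > 0:
            rows = network.classify_hubs(
                network.centrality(graph),
                degree_cut=config.degree_cut,
                betweenness_cut=config.betweenness_cut,
            )
            network.write_centrality_tsv(rows, outdir / "centrality.tsv")
            manifest["counts"]["high_hubs"] = int(rows["is_high_hub"].sum())
            modules = network.filter_modules(
                network.mcode(
                    graph,
                    degree_cutoff=config.mcode_degree_cutoff,
                    node_score_cutoff=config.mcode_node_score_cutoff,
                    k_core=config.mcode_k_core,
                    haircut=config.mcode_haircut,
                    max_depth=config.mcode_max_depth,
                ),
                min_size=config.min_module_size,
            )
            network.write_modules_tsv(modules, outdir / "modules.tsv")
            manifest["counts"]["modules"] = len(modules)
        else:
            manifest["counts"]["high_hubs"] = 0
            manifest["counts"]["modules"] = 0
    except Exception as e:
        raise PipelineError("network", e) from e

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Comparative threshold cycle (2^-ddCt)
# ---------------------------------------------------------------------------

def ddct(table: pd.DataFrame) -> pd.DataFrame:
    """Relative expression by the comparative threshold cycle method.

    ``table`` needs columns sample, condition ('treated'/'control'),
    target_ct, reference_ct.  Per sample, dCt = target_ct -
    reference_ct; ddCt = dCt - mean(dCt over control samples); relative
    expression = 2^-ddCt, so the control group has geometric mean 1 by
    construction.
    """
    required = {"sample", "condition", "target_ct", "reference_ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["target_ct"] <= 0).any() or (table["reference_ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ctrl = table["condition"] == "control"
    if not ctrl.any():
        raise ValueError("Ct table has no control samples")
    out = table.copy()
    out["delta_ct"] = out["target_ct"] - out["reference_ct"]
    out["delta_delta_ct"] = out["delta_ct"] - out.loc[ctrl, "delta_ct"].mean()
    out["rel_expr"] = np.exp2(-out["delta_delta_ct"])
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Consensus differential expression, pathway meta-enrichment and
    PPI network analysis across disease contrasts."""


def _sim_from_options(seed: int, n_genes: int) -> synthetic.SimConfig:
    return synthetic.SimConfig(n_genes=n_genes, seed=seed)


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--n-genes", type=int, default=2000, show_default=True)
@click.option("--outdir", type=click.Path(), default="crossdex_sim", show_default=True)
def simulate(seed: int, n_genes: int, outdir: str) -> None:
    """Write a synthetic cohort (expression, design, GMT, edges,
    annotation, truth) to OUTDIR."""
    sim = _sim_from_options(seed, n_genes)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = synthetic.simulate_expression(sim)
    synthetic.write_expression_tsv(matrix, out / "expression.tsv")
    synthetic.write_design_tsv(matrix, out / "design.tsv")
    synthetic.write_annotation_tsv(synthetic.simulate_annotation(sim), out / "annotation.tsv")
    synthetic.write_gmt(synthetic.simulate_genesets(sim, truth), out / "genesets.gmt")
    synthetic.write_edges_tsv(synthetic.simulate_ppi(sim, truth), out / "edges.tsv")
    synthetic.write_truth_json(truth, out / "truth.json")
    click.echo(f"synthetic cohort written to {out}")


@cli.command(name="dex")
@click.option("--expression", required=True, type=click.Path(exists=True))
@click.option("--design", required=True, type=click.Path(exists=True))
@click.option("--control", required=True)
@click.option("--case", required=True)
@click.option("--out", required=True, type=click.Path())
def dex_cmd(expression: str, design: str, control: str, case: str, out: str) -> None:
    """One moderated-t contrast; writes a topTable-layout TSV."""
    matrix = dex.read_expression_tsv(expression, design)
    result = dex.run_contrast(matrix, control, case)
    dex.write_toptable_tsv(result, out)
    click.echo(f"{result.contrast_name}: prior d0={result.prior.d0:.4g} "
               f"s0sq={result.prior.s0sq:.4g}")


@cli.command(name="ddct")
@click.option("--table", "table_path", required=True, type=click.Path(exists=True),
              help="TSV with sample, condition, target_ct, reference_ct")
@click.option("--out", required=True, type=click.Path())
def ddct_cmd(table_path: str, out: str) -> None:
    """Relative qPCR expression by the 2^-ddCt method."""
    table = pd.read_csv(table_path, sep="\t")
    ddct(table).to_csv(out, sep="\t", index=False, float_format="%.6g")
    click.echo(f"relative expression written to {out}")


@cli.command(name="run")
@click.option("--config", "config_path", type=click.Path(exists=True),
              help="JSON/YAML pipeline config; omit for a synthetic run")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--outdir", type=click.Path(), default="crossdex_out", show_default=True)
@click.option("--log-level", default="INFO", show_default=True)
def run_cmd(config_path: str | None, seed: int, outdir: str, log_level: str) -> None:
    """Run the full pipeline (simulate -> dex -> consensus -> enrich ->
    network); exit code identifies the failing stage."""
    if config_path:
        config = PipelineConfig.from_file(config_path)
        config = dataclasses.replace(config, seed=seed, outdir=outdir,
                                     log_level=log_level)
    else:
        config = PipelineConfig(sim=synthetic.SimConfig(seed=seed), seed=seed,
                                outdir=outdir, log_level=log_level)
    try:
        manifest = run_pipeline(config)
    except PipelineError as e:
        click.echo(str(e), err=True)
        sys.exit(STAGE_EXIT_CODES.get(e.stage, 1))
    click.echo(json.dumps(manifest["counts"], indent=1, sort_keys=True))


@cli.command(name="consensus")
@click.argument("deg_tables", nargs=-1, required=True,
                type=click.Path(exists=True))
@click.option("--annotation", type=click.Path(exists=True))
@click.option("--p-cut", type=float, default=dex.P_CUT_DEFAULT, show_default=True)
@click.option("--fc-cut", type=float, default=dex.FC_CUT_DEFAULT, show_default=True)
@click.option("--out", required=True, type=click.Path())
def consensus_cmd(deg_tables, annotation, p_cut, fc_cut, out) -> None:
    """Intersect topTable TSVs into direction-consistent consensus DEGs."""
    degsets, logfc = [], {}
    for path in deg_tables:
        t = pd.read_csv(path, sep="\t", index_col="gene")
        sig = (t["adj.P.Val"] < p_cut) & (t["logFC"].abs() > np.log2(fc_cut))
        name = Path(path).stem
        degsets.append(dex.DEGSet(
            contrast_name=name,
            up=set(t.index[sig & (t["logFC"] > 0)]),
            down=set(t.index[sig & (t["logFC"] < 0)]),
        ))
        logfc[name] = t["logFC"]
    result = cns.intersect_consistent(degsets, logfc=logfc)
    if annotation:
        ann = pd.read_csv(annotation, sep="\t", index_col=0)
        cns.biotype_breakdown(result, ann.iloc[:, 0].to_dict())
    cns.write_consensus_tsv(result, out)
    click.echo(f"{len(result)} consensus genes "
               f"({len(result.up)} up, {len(result.down)} down)")


@cli.command(name="enrich")
@click.option("--gmt", required=True, type=click.Path(exists=True))
@click.option("--consensus-tsv", "consensus_path", type=click.Path(exists=True),
              help="unused genes column accepted for universe restriction")
@click.argument("deg_tables", nargs=-1, required=True, type=click.Path(exists=True))
@click.option("--universe-tsv", required=True, type=click.Path(exists=True),
              help="expression TSV whose gene column defines the universe")
@click.option("--out", required=True, type=click.Path())
def enrich_cmd(gmt, consensus_path, deg_tables, universe_tsv, out) -> None:
    """Hypergeometric + Fisher-combined + BH pathway meta-enrichment."""
    universe = set(pd.read_csv(universe_tsv, sep="\t", usecols=[0]).iloc[:, 0])
    degsets = []
    for path in deg_tables:
        t = pd.read_csv(path, sep="\t", index_col="gene")
        sig = (t["adj.P.Val"] < dex.P_CUT_DEFAULT) & (
            t["logFC"].abs() > np.log2(dex.FC_CUT_DEFAULT))
        degsets.append(dex.DEGSet(
            contrast_name=Path(path).stem,
            up=set(t.index[sig & (t["logFC"] > 0)]),
            down=set(t.index[sig & (t["logFC"] < 0)]),
        ))
    filtered = enrich.filter_collection(enrich.read_gmt(gmt), universe)
    table = enrich.consensus_pathways(filtered, degsets, universe)
    enrich.write_enrichment_tsv(table, out)
    click.echo(f"{int(table['selected'].sum())} of {len(table)} sets selected")


@cli.command(name="network")
@click.option("--edges", required=True, type=click.Path(exists=True))
@click.option("--consensus-tsv", required=True, type=click.Path(exists=True))
@click.option("--outdir", required=True, type=click.Path())
@click.option("--score-threshold", type=float,
              default=network.SCORE_THRESHOLD_DEFAULT, show_default=True)
def network_cmd(edges, consensus_tsv, outdir, score_threshold) -> None:
    """PPI centrality and MCODE modules over protein-coding consensus genes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ctab = pd.read_csv(consensus_tsv, sep="\t")
    coding = set(ctab.loc[ctab["biotype"] == "protein_coding", "gene"])
    if not coding:  # biotype column may be empty in hand-made tables
        coding = set(ctab["gene"])
    graph = network.build_graph(network.read_edges_tsv(edges),
                                node_whitelist=coding,
                                score_threshold=score_threshold)
    if graph.number_of_nodes() == 0:
        click.echo("no network edges above threshold", err=True)
        sys.exit(STAGE_EXIT_CODES["network"])
    rows = network.classify_hubs(network.centrality(graph))
    network.write_centrality_tsv(rows, out / "centrality.tsv")
    modules = network.filter_modules(network.mcode(graph))
    network.write_modules_tsv(modules, out / "modules.tsv")
    click.echo(f"{graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges, "
               f"{len(modules)} modules with >= {network.MIN_MODULE_SIZE_DEFAULT} genes")


if __name__ == "__main__":
    cli()
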