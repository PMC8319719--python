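# crossdex

Consensus transcriptomic analysis across disease contrasts: which genes
and pathways are dysregulated *in the same direction* in several
diseases that share a phenotype?

The motivating setting is pulmonary arterial hypertension (PAH), which
can arise idiopathically or secondary to congenital heart disease or
connective tissue disease. Given one expression cohort with a shared
healthy control group and several disease groups, `crossdex` runs the
full comparative chain:

1. **Moderated-t differential expression** per disease-vs-control
   contrast. For gene *g* with log2 fold change *b\_g*, pooled residual
   variance *s\_g²* on *d\_g* degrees of freedom and contrast variance
   factor *v\_g = 1/n₁ + 1/n₂*, an empirical-Bayes prior
   *s\_g² ∼ s₀²·d₀/χ²(d₀)* is moment-matched on log *s\_g²* (trigamma
   equation), giving the posterior variance
   *s̃\_g² = (d₀s₀² + d\_g s\_g²)/(d₀ + d\_g)* and the statistic
   *t̃\_g = b\_g / (s̃\_g √v\_g)* on *d₀ + d\_g* df. DEGs are called at
   BH-adjusted *p* < 0.01 and |FC| > 1.5.
2. **Consensus DEGs (CDEGs)**: genes significant with the same sign in
   every contrast, with biotype composition and top-gene ranking.
3. **Pathway meta-enrichment**: per contrast a hypergeometric
   upper-tail test of DEG/gene-set overlap; per set, Fisher's combined
   probability *X² = −2Σln pᵢ ∼ χ²(2k)* across the *k* contrasts; BH
   correction across sets; selection at combined *q* < 0.05. Sets are
   pre-filtered to 5–300 genes within the measured universe.
4. **PPI network analysis**: STRING-style scored edges thresholded at
   score > 700 between protein-coding CDEGs; degree and unnormalized
   betweenness centrality; hubs (degree ≥ 30), bottlenecks
   (betweenness ≥ 300), high hubs (both); MCODE module detection
   (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut, depth
   100) keeping modules of ≥ 5 genes.

A synthetic-cohort generator (`crossdex.synthetic`) emulates the
11-control / 6+4+4-disease microarray design with hierarchical gene
variances and planted shared/specific DE genes, enriched gene sets and
clique modules, so the entire chain is testable against known truth.
A small `2^-ΔΔCt` utility for relative qPCR quantification is included.

## Worked example

```python
import crossdex as cx

cfg = cx.SimConfig(seed=1)                       # 2000 genes, 25 samples
matrix, truth = cx.simulate_expression(cfg)
res = cx.run_contrast(matrix, "control", "IPAH")
print(res.prior)
# PriorEstimate(d0=3.844884190976348, s0sq=0.05007730421150769)

results = [cx.run_contrast(matrix, "control", g) for g in cfg.disease_groups]
cons = cx.consensus_from_contrasts(results)
print(len(cons), len(cons.up), len(cons.down))
# 198 159 39
```

The recovered prior (d₀ ≈ 3.84, s₀² ≈ 0.0501) matches the generating
values (4, 0.05); of the 200 planted consensus DE genes, 198 are
recovered with the planted signs (159 up, 39 down) and no
disease-specific gene leaks into the consensus.

The same run from a shell:

```bash
crossdex run --seed 1 --outdir out/
```

writes per-contrast topTable-style TSVs, the consensus table, the
biotype breakdown, the enrichment table, centrality and module tables,
and a `manifest.json` with per-stage counts. Two runs from one seed
are byte-identical.

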