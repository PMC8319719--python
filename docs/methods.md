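# Methods

## Statistical model

### Two-group fits and the variance prior

Each disease contrast is fit as its own two-group model against the
shared controls: b_g = mean(case) − mean(control), pooled within-group
variance s_g² on d_g = n_case + n_control − 2 degrees of freedom, and
contrast variance factor v_g = 1/n_case + 1/n_control. An alternative —
one four-group model with a residual variance shared across contrasts —
would give each contrast more residual df, but couples the contrasts;
the per-contrast fit keeps them exchangeable and matches the framing
of each disease being compared to the controls on its own.

The empirical-Bayes layer assumes s_g² | σ_g² ∼ σ_g²·χ²(d_g)/d_g with
σ_g² ∼ s₀²·d₀/χ²(d₀). Then s_g²/s₀² is a scaled F(d_g, d₀) variate, so
z = log s_g² satisfies

    Var(z)  = ψ′(d_g/2) + ψ′(d₀/2)
    E(z)    = log s₀² + ψ(d_g/2) − ψ(d₀/2) + log(d₀/d_g)

with ψ, ψ′ the digamma and trigamma functions. `estimate_prior` solves
the first equation for d₀ by monotone root-finding (brentq on
d₀ ∈ (0.1, 10⁶); ψ′ is strictly decreasing) and back-substitutes into
the second for s₀². If Var(z) ≤ ψ′(d_g/2) the observed dispersion is
no larger than pure chi-square sampling noise and d₀ = ∞ (all genes
share s₀²; the moderated statistic becomes a z-score). Genes with zero
pooled variance are excluded from the moment fit (they carry no
information about the prior) but are still scored through the
posterior variance. Fewer than 30 positive variances is refused — the
two-moment fit is not meaningfully identifiable below that.

The posterior variance is s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g) and
t̃_g = b_g/(s̃_g √v_g) is referred to Student t with d₀ + d_g df
(standard normal at d₀ = ∞; at d₀ = 0 the ordinary pooled t is
recovered exactly). p-values are two-sided and clamped below at the
smallest positive double before any log transform; a zero posterior
variance with a non-zero effect yields an infinite statistic, the
clamped p, and a warning.

### DEG calling and consensus

DEG: BH-adjusted p strictly below 0.01 AND linear fold change strictly
above 1.5, i.e. |logFC| > log2(1.5) ≈ 0.585 — the fold-change cutoff is
interpreted on the linear scale. Consensus DEGs are genes called with
the same sign in every contrast; mixed-sign or partially-missing genes
are excluded. "Top" consensus genes are ranked by |mean logFC| with
alphabetical tie-break (no ranking metric is canonical for this; a
plain alphabetical mode is also exposed). Genes missing from the
annotation are reported as "other annotated RNAs" rather than dropped.
Composition percentages are 100·count/total rounded half-up to one
decimal.

### Pathway meta-enrichment

The universe is the set of genes measured on the (collapsed) array,
not all annotated genes. Per contrast the DEG list is the unsigned
union of up and down calls. Per set, enrichment is the inclusive upper
tail P(X ≥ x) of Hypergeometric(N, K, n); per-contrast p-values are
combined with Fisher's method (X² = −2Σ ln p ∼ χ²(2k)) and BH is
applied across sets to the combined p — combine first, correct last.
Zero p-values are clamped to the smallest positive double with a
warning rather than propagating infinities. Collections are filtered
to 5–300 members after universe restriction, with an optional
case-insensitive name-pattern exclusion list (disease/drug sets).

### Network analysis

Edges are kept when the combined confidence score is strictly greater
than 700 (a `inclusive=True` switch provides the ≥ 700 convention)
and both endpoints are protein-coding consensus genes; duplicate and
reversed pairs merge keeping the maximum score. Betweenness is
unnormalized, unweighted and undirected — each unordered pair counted
once with fractional credit across tied shortest paths — because the
hub/bottleneck thresholds (degree ≥ 30, betweenness ≥ 300, both
inclusive) are on raw pair counts; the betweenness threshold is
configurable in case normalized values are wanted.

MCODE follows the canonical three stages. (1) Every vertex with degree
≥ 2 is weighted by k·density of the highest k-core of its closed
neighborhood; lower-degree vertices weigh 0. (2) Complexes grow
breadth-first from the highest-weight unassigned seed, admitting
unassigned neighbors with weight ≥ 0.8× the seed weight (node score
cutoff 0.2), to depth 100; vertices belong to at most one complex
(stricter than MCODE variants that allow multi-membership, and
deterministic given the lexicographic tie-breaks on equal weights).
(3) Complexes without a 2-core are discarded; the haircut removes
members until all have ≥ 2 internal connections (iterated, i.e. the
2-core). Fluff expansion is not implemented. Module score is
density × size; modules below 5 members are filtered.

## Synthetic cohort generator

The generator emulates a small clinical microarray cohort: 11 shared
controls and disease groups of 6/4/4 samples, 2,000 genes by default
(a desk-scale stand-in for a ~20k-gene array; planted fractions keep
the DEG rate near the ~12% seen in such studies). Expression is log2
throughout. Gene baselines are N(8, 2²); true variances are scaled
inverse chi-square with d₀ = 4, s₀² = 0.05 (log2-units², typical of
moderately noisy arrays); 10% of genes carry a shared ±2 log2 effect
in all disease groups (80% up, matching the observed up-skew) and 5%
carry a disease-specific effect. Gene sets: 3 planted sets drawing
half their members from shared DE genes plus 50 null sets, sizes
10–80. Network: 3 planted 8-cliques over shared-up genes at score 950,
background edges Bernoulli(0.005) with N(500, 150²) scores clipped to
[0, 1000] — most background falls below the 700 threshold, leaving
realistic noise edges. Biotypes are i.i.d. (93% protein coding, 4%
pseudogene, 2% snoRNA, 1% other). One global seed drives independent
spawn-keyed RNG streams per artifact (expression, sets, network,
annotation), so regenerating one artifact never perturbs another, and
all outputs are byte-deterministic given the config.

What the generator does **not** emulate: probe-level structure,
normalization artifacts, batch effects, correlated gene blocks outside
the planted modules, and realistic gene-set overlap structure. Passing
tests therefore demonstrate correctness of the statistical machinery
under the model's own assumptions, not robustness to real-array
pathologies.

## Calibration experiments and their problem sizes

Problem sizes are chosen so each experiment is informative at desk
scale: BH false-discovery calibration uses 200 replicates of 500-gene
cohorts (realized FDR ≈ 0.003 ≪ 0.01, the fold-change filter removes
most borderline nulls); Fisher null calibration uses 10,000 triples of
independent uniforms; prior recovery uses 5,000 genes at d_g = 9.

The null-enrichment uniformity check needs care: the combined p of a
null set is only approximately Uniform(0,1) when (a) overlap counts
are large enough that the inclusive hypergeometric tail is effectively
continuous, and (b) the per-contrast p-values are independent. With
small sets (10–80 genes) the discrete p-values are super-uniform
(conservative) — Monte Carlo with fully independent contrasts gives
KS D ≈ 0.22 — and with shared-consensus DE the three contrasts' DEG
lists nearly coincide, making the combined p strongly non-uniform
(D ≈ 0.3). Neither deviation is anti-conservative, so pathway
selection remains valid; but the uniformity *oracle* is only meaningful
where its premises hold. The calibration test therefore uses
disease-specific planted DE (disjoint ~200-gene DEG lists per
contrast) and 150–300-gene sets on the 2,000-gene universe. Even
there a small conservative bias remains (point masses ≈ 0.08 at the
overlap mode), so the chain yields KS D ≈ 0.08–0.10 stably while the
KS p-value fluctuates widely across seeds (0.0002–0.19 observed); the
distance, not the p-value, is the robust summary of how close to
uniform the null combined p gets.

## Known limitations

- A single background edge above the score threshold can bridge two
  planted cliques, and the MCODE growth stage then (correctly) merges
  them into one module; per-clique recovery Jaccard drops to 0.5 in
  that event (~8% of seeds under default noise).
- The prior moment fit uses all genes, including truly DE ones; with
  mean-shift effects the within-group variances are unaffected, so
  this is exact under the generator but approximate for real data with
  variance outliers (no robust/trended prior variants).
- BH control is guaranteed for independent or positively dependent
  tests; moderated t-statistics share the estimated prior, a weak
  dependence ignored here as in standard practice.
- Fisher's combination treats the disease contrasts as independent
  although they share the control samples; the shared-control
  correlation is mild at these group sizes but makes combined p-values
  slightly liberal in principle.
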