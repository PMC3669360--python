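# Methods

This note records the models, the synthetic study conditions, and the
numerical and design choices behind `cernet`, in the order the pipeline
runs them.

## Study design

The pipeline targets a two-condition, replicated expression study: a
parental and a drug-resistant cell line, each profiled in triplicate on
three platforms (mRNA, lncRNA, miRNA). All intensities are treated as
summarized, log2-scale probe values; raw array processing (background
correction, probe summarization) is upstream of this package.

## Normalization

Quantile normalization forces every sample onto the common distribution
defined by the across-sample mean of rank-ordered values. It is exact and
idempotent as implemented (ties broken by stable sort order). One policy
choice matters at desk scale: QN estimates the common distribution *from
the probes*, so on a matrix with very few probes rank collisions flatten
genuine effects (a probe that keeps the same rank in every sample becomes
exactly constant). The pipeline therefore applies QN only to matrices
with at least 100 probes and leaves smaller ones (e.g. a down-scaled
miRNA panel) on their original scale, logging the decision.

## Moderated differential expression (random variance model)

With n1 = n2 = 3 the per-gene pooled variance s² (d = n1 + n2 − 2 = 4 df)
is far too noisy for a plain t-test. The random variance model treats the
per-gene precision as exchangeable across genes:

    1/σ²_g ~ Gamma(shape a, scale b)  ⇒  s²_g · a · b ~ F(d, 2a).

* **Fitting.** (a, b) maximize the likelihood of the observed s² under the
  marginal F law; genes with s² = 0 are excluded from the fit (they carry
  no likelihood information) but are still scored afterwards. Optimization
  is Nelder–Mead on (log a, log b) from a moment-based start (a from the
  squared coefficient of variation of s², b from the mean). The shape is
  bounded above at 10³: with (near-)homogeneous variances the likelihood
  increases monotonically in a (the prior degenerates to a point), and the
  capped fit then approaches the correct pooled large-df test instead of
  diverging. Exactly identical variances are rejected as non-convergent.
  At least 50 positive variances are required.
* **Testing.** s̃² = (d·s² + 2/b)/(d + 2a) shrinks s² toward the prior
  point 1/(a·b); t = (x̄₁ − x̄₂)/√(s̃²(1/n₁ + 1/n₂)) is referred to a t
  distribution with d + 2a df, two-sided. The log2 fold change is the
  group-mean difference on log2 data.
* **Calibration.** On model-consistent null data (10,000 genes, 3 vs 3,
  prior fitted on the same data) the empirical type-I error at p < 0.05
  lands within a few thousandths of 0.05, and (a, b) are recovered within
  a few percent from 5,000 simulated variances (the test suite asserts
  15%).
* **Multiplicity and calling.** Benjamini–Hochberg step-up q-values are
  reported alongside p. Headline DE calling uses p < 0.05 by default
  (the conventional screen for this design); q-based calling and a fold-
  change cut are configuration switches.
* **Class-specific priors.** The variance prior is an array-wide nuisance
  parameter and is fitted per platform. A platform matrix with too few
  probes to support its own fit borrows the mRNA-array prior — defensible
  when, as in the synthetic data, the platforms share the same intensity
  model; with real data from heterogeneous platforms, supply a prior
  explicitly instead.

Hierarchical clustering of the DE matrix uses 1 − Pearson correlation
distance with average linkage (the usual expression-heatmap convention);
the sample tree is exported in nested-parenthesis form.

qPCR validation panels are supported by the 2^−ΔΔCt fold change:
ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target − Ct_ref)_control.

## miRNA target prediction

Canonical seed sites on a 3'UTR (5'→3'), for a mature miRNA (5'→3'):
8mer = exact Watson–Crick complement of miRNA positions 2–8 followed by an
A opposite position 1; 7mer-m8 = the 2–8 complement alone; 7mer-A1 = the
2–7 complement plus the A1. The A1 must literally be an adenosine on the
UTR (it need not pair with position 1), and no G:U wobble is accepted in
the seed. Every maximal occurrence is reported with 1-based inclusive
coordinates; an 8mer suppresses the 7mer classifications contained in its
span. T and U are interchangeable on input.

A non-default mode reports 3'-compensatory sites (seed 2–7 with exactly
one mismatch rescued by ≥ 4 consecutive Watson–Crick pairs to miRNA
positions 13–17). The class is biologically recognized but its thresholds
are not standardized, so the mode is off by default and the chosen
thresholds are this package's own.

Candidate relations (any pair with ≥ 1 site) pass two screens: both
partners must be differentially expressed, and the pair's Pearson
correlation across all samples must fall below r_max (default 0) with
opposite DE directions required — a repression signature. Conservation
scoring and context-style regression efficacy scores are out of scope;
the scanner is validated instead by exact agreement with a naive
window-scan oracle.

## Pathway over-representation

For a gene set with Nf members on the array (N genes total) and a
differential list of n genes, nf of them in the set:

    Re = (nf/n) / (Nf/N)

with one-sided Fisher exact p computed as the explicit hypergeometric
tail sum P(X ≥ nf), X ~ Hypergeom(N, Nf, n), a Pearson chi-square p on
the same 2×2 table (no continuity correction; NaN when a margin is zero)
as a cross-check, and BH q across the sets of one run. The universe is
the array, not the genome. Up- and down-regulated lists are tested in
separate runs. Set membership is intersected with the universe first;
sets disjoint from it are dropped with a warning.

## Co-expression networks

Node universe: differentially expressed probes only, coloured by DE
direction. Edge types are mechanism-specific and exclusive:

* lncRNA–mRNA: correlation edges, weight |r|;
* miRNA–mRNA: filtered target relations, weight 1;
* mRNA–mRNA: shared gene-set membership AND a passing correlation
  (default; a pathway-only mode exists) — the AND keeps an expression
  network expression-driven;
* lncRNA–lncRNA, miRNA–miRNA and lncRNA–miRNA edges are never drawn.

One network is built per condition, with correlations computed over that
condition's replicates; at n = 3 the correlation p-value is unstable, so
the magnitude screen |r| ≥ r_min (default 0.99; an extreme 0.99999 preset
mirrors published neighbour listings) is the primary filter and the
p ≤ 0.05 test is applied only when n ≥ 4. This per-condition screen at
n = 3 is intentionally faithful to the published procedure and is noisy —
it finds many spurious high-|r| pairs; the pooled six-sample correlation
is what the anticorrelation filter uses. Zero-variance probes are skipped
with a warning.

Topology per node: degree, clustering coefficient
(2·triangles/(deg·(deg−1)), 0 for deg < 2; a subnetwork-average variant
is also exposed), and k-core number (maximal subgraph with all internal
degrees ≥ k, by iterative pruning). Candidate core regulatory factors are
ranked by |degree(A) − degree(B)| across the two condition networks, with
absent nodes counting degree 0 and lexicographic tie-breaks. Networks are
exported as SIF, GraphML (with node attributes), a node-metrics TSV and a
JSON summary of per-class node counts and per-type edge counts.

## Dose–response

Viabilities are normalized to the untreated-control mean when a
zero-concentration row is present. IC50 defaults to log2-linear
interpolation between the two doses bracketing viability 0.5 —
assumption-free and exactly testable; a 4-parameter logistic fit
(bottom + (top − bottom)/(1 + (c/ec50)^hill), least squares, IC50 = the
fitted midpoint concentration) serves smooth curves. The two estimators
agree within 15% on clean logistic curves sampled at ≥ 6 doses, and both
are unit-equivariant. The fold-resistance index is
IC50(resistant)/IC50(parental), reported to one decimal. A non-monotone
mean response beyond 0.05 raises a warning, not an error.

## Synthetic study conditions

The generator emulates the design above at desk scale. Defaults, chosen
once: 600 mRNA / 400 lncRNA / 30 miRNA probes, 3 replicates per
condition, 10% DE per class with |log2 fold change| = 2.0 (a 4-fold
change, typical of validated array hits), residual scale noise_sd = 0.5,
four lncRNA–mRNA co-expression blocks of 8 probes at within-block
correlation 0.9, 30 planted miRNA→mRNA repression pairs, 200-nt UTRs and
22-nt miRNAs, 10 gene sets of ~30 genes. One `numpy` Generator seeded by
a single integer drives everything; identical configs are bit-identical.

Construction details that matter:

* Intensities are additive Gaussian on the log2 scale: baseline N(9, 2²)
  + condition effect (DE probes, both directions) + block latent factor +
  noise. Per-probe residual variances are drawn from an inverse-gamma
  (shape 3, scaled so the mean variance is noise_sd²) — the family the
  RVM assumes and the heterogeneity real arrays show; constant variances
  would make the prior fit degenerate by construction.
* Block members share a per-sample latent factor with loading
  λ = σ·√(ρ/(1−ρ)), which hits the target correlation ρ in expectation
  regardless of each member's own noise level. Blocks are placed on
  non-DE probes so the DE ground truth stays clean.
* Every planted repression pair has its miRNA and mRNA differentially
  expressed in opposite directions (so the pooled-sample anticorrelation
  holds by construction) and a literal 8mer site for that miRNA spliced
  into the target's UTR at a recorded position. Random UTRs also contain
  occasional chance seed matches — deliberately left in, since a real
  screen faces them; at the default sizes they cost a few points of
  funnel precision.
* One gene set is deliberately enriched for planted DE mRNAs (20 DE + 10
  background members); the rest are uniform draws.

What the generator does **not** emulate: array-specific intensity biases
and batch effects (QN is therefore a near no-op on synthetic data),
probe-level noise and cross-hybridization, realistic UTR length and
composition (200 nt keeps chance seed matches rare; human UTRs are longer
and compositionally biased), miRNA family structure (shared seeds), and
indirect regulatory correlation. Passing recovery tests on this generator
shows the pipeline's statistics and plumbing are correct under the
assumed model — not that the biological error rates on real arrays match.

## Verification strategy and problem sizes

Component oracles are independent re-implementations: a per-nucleotide
window scan for the seed scanner (exact agreement on 200 random
miRNA/UTR pairs), the hypergeometric survival function for the Fisher
tail sum (exhaustive over all 2×2 tables with N ≤ 30), brute-force
triangle counting and iterative pruning for clustering/k-core (50 random
20-node graphs). Statistical behaviour is checked by simulation: type-I
error of the moderated test on 10,000 null genes across 5 seeds, prior
recovery at 5,000 genes, planted-structure recovery over three full
pipeline runs at the default conditions (recall of planted DE mRNAs at
q < 0.05, empirical FDR, funnel survival of planted pairs, rank of the
planted pathway). These sizes keep the whole suite and the acceptance
script each under a minute on a laptop-class core while leaving the
Monte-Carlo error well inside the asserted margins.

## Known limitations

* The RVM prior assumes exchangeable inverse-gamma variances; strong
  mean–variance trends would call for an intensity-dependent prior.
* Seed matching ignores conservation, site context and 3' supplementary
  pairing (beyond the optional compensatory mode); predicted relations
  are candidates, not validated targets.
* Correlation networks at n = 3 per condition are exploratory; the
  degree-difference ranking inherits that noise.
* The 2×2 chi-square is undefined (NaN) for degenerate margins; use the
  Fisher p there.
* Probe-to-gene mapping is identity; duplicate probe ids are rejected
  rather than collapsed.
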