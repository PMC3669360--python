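# cernet

Integrative lncRNA / miRNA / mRNA expression analysis for two-condition
chemoresistance screens — the kind of study that profiles a parental and a
drug-resistant cancer cell line on mRNA, lncRNA and miRNA arrays in
triplicate and asks which coding and noncoding RNAs drive the resistant
phenotype.

`cernet` implements the full desk-top pipeline as a tested library plus CLI:

* **Moderated differential expression.** A random-variance-model t-test:
  per-gene inverse variances are modelled as 1/σ² ~ Gamma(a, b), fitted by
  maximum likelihood across all genes via the marginal law s²·a·b ~ F(d, 2a).
  Each gene's variance is shrunk to s̃² = (d·s² + 2/b)/(d + 2a) and the
  moderated t is referred to d + 2a degrees of freedom — crucial power at
  n = 3 vs 3. Benjamini–Hochberg FDR, direction calling, quantile
  normalization and hierarchical clustering included.
* **Seed-based miRNA target prediction.** Exhaustive scan of 3'UTRs for
  canonical 8mer, 7mer-m8 and 7mer-A1 sites (Watson–Crick complement of the
  miRNA seed, positions 2–8, no G:U wobble), intersected with the DE lists
  and screened for expression anticorrelation (Pearson r < 0 with opposite
  DE directions) — the classic repression funnel
  *predicted → DE-intersected → anticorrelated*.
* **Pathway over-representation.** Enrichment ratio
  Re = (nf/n)/(Nf/N) with one-sided Fisher exact p (hypergeometric tail),
  chi-square cross-check and BH FDR across sets, GMT input.
* **Condition-specific co-expression networks.** Typed edges over DE probes
  only: lncRNA–mRNA by correlation, miRNA–mRNA by target prediction,
  mRNA–mRNA by shared pathway membership; per-node degree, clustering
  coefficient and k-core; candidate core regulatory factors ranked by the
  degree difference between the two condition networks.
* **Dose–response.** IC50 from relative survival curves (log2-linear
  interpolation or 4-parameter logistic fit) and the fold-resistance index
  IC50(resistant)/IC50(parental).
* **Synthetic data.** A generator that plants differential expression,
  lncRNA–mRNA co-expression blocks, miRNA→target repression pairs (with
  real seed sites spliced into the UTRs) and an enriched pathway, with the
  ground truth returned alongside — every stage is testable without any
  download.

## Worked example

```python
from cernet import SynthConfig, generate_dataset, write_fixtures
from cernet.pipeline import PipelineConfig, run_pipeline

ds = generate_dataset(SynthConfig(seed=1))   # 600 mRNA / 400 lncRNA / 30 miRNA probes
write_fixtures(ds, "fixtures")

config = PipelineConfig(
    mrna_matrix="fixtures/mrna.tsv", lncrna_matrix="fixtures/lncrna.tsv",
    mirna_matrix="fixtures/mirna.tsv", design="fixtures/design.tsv",
    mirna_fasta="fixtures/mirna.fasta", utr_fasta="fixtures/utr.fasta",
    gene_sets_gmt="fixtures/gene_sets.gmt", outdir="results", seed=1,
)
report = run_pipeline(config)

de = report["de_counts"]["mRNA"]
print(f"DE mRNAs: {de['up']} up / {de['down']} down of {de['total']}")
f = report["target_funnel"]
print(f"target funnel: {f['predicted']} predicted -> "
      f"{f['de_intersected']} DE-intersected -> {f['anticorrelated']} anticorrelated")
top = report["enrichment"]["up"][0]
print(f"top enriched set (up): {top['set_id']}  Re={top['Re']:.2f}  p={top['p_fisher']:.2e}")
```

prints

```
DE mRNAs: 46 up / 36 down of 600
target funnel: 383 predicted -> 37 DE-intersected -> 31 anticorrelated
top enriched set (up): PATHWAY_PLANTED  Re=6.52  p=1.22e-10
```

With a 10% planted DE fraction, 82 of 600 mRNA probes are called at
p < 0.05 (60 are truly differential); 383 candidate miRNA–mRNA relations
shrink to 31 once both partners must be differential and anticorrelated —
most of the survivors are the generator's planted repression pairs — and
the pathway deliberately stuffed with DE mRNAs dominates the enrichment
ranking. The `results/` directory holds all intermediate tables, the
per-condition networks (SIF/GraphML), the ranked core factors and a
`report.json` / `report.md` summary.

The same stages are exposed as subcommands of the `cernet` console script
(`synth`, `run`, `de`, `targets`, `enrich`, `ic50`), e.g.

```bash
cernet synth --outdir fixtures --seed 1
cernet ic50 --csv viability.csv --method four_param_logistic --out ic50.json
```

For two survival curves with half-inhibition at 17.06 and 4.36 mg/L the
`ic50` command reports a fold-resistance index of 3.9.

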