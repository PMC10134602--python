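# reboundomics

Rebound analysis of longitudinal multi-omics T-cell cohorts.

Pregnancy transiently reshapes the maternal immune system: DNA methylation
and gene expression in CD4⁺/CD8⁺ T cells drift through the trimesters,
peak around the 3rd trimester, and largely reverse after delivery. This
package identifies those **rebound features** — CpGs and genes that change
significantly in the 3rd-vs-1st-trimester window and reverse direction in
the post-partum-vs-3rd window — in a two-group design (e.g. a disease
cohort and healthy controls), expands the genes shared by both groups into
protein–protein-interaction (PPI) network modules, and quantifies their
enrichment for disease-associated gene sets. It is aimed at
epigenomics/transcriptomics analysts working with paired methylation-array
and RNA-seq data from small longitudinal cohorts.

## The model

Every feature (CpG M-value `M = log2(β/(1−β))`, or gene log-CPM after TMM
normalization and voom-style precision weighting) is fitted to

```
y = β₀ + β_{d,t}·s + β_a·age + β_m·memory + β_c·viability
```

where `s` indexes the combined (group `d`, timepoint `t`) cell, so that
`β_{d,t}` measures the effect of time within each group. Repeated samples
of the same donor are handled by a consensus intra-donor correlation ρ
used in a generalized-least-squares fit with block-equicorrelated errors.
Residual variances are shrunk by empirical-Bayes moderation
(`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)`, prior estimated by matching the
moments of `log s²_g` to a scaled F distribution) and contrasts
`β_{d,3rd} − β_{d,1st}` and `β_{d,PP} − β_{d,3rd}` are tested with
moderated t-statistics.

Calling rules: a DMP requires nominal `p ≤ 0.05` **and** `|Δβ| > 0.05`; a
DEG requires `p ≤ 0.05`. A feature rebounds when significant in both
windows with opposite directions; the **shared rebound** set additionally
requires the identical direction pattern in both groups. Shared rebound
genes (DEGs, and DMGs = genes annotated to ≥1 shared rebound DMP) seed
**DIAMOnD** expansion in the score-filtered (≥700) PPI network: at each
step the node with the most significant hypergeometric excess of links
into the module joins it, up to 200 additions. The intersection of the
methylation- and expression-derived modules is the *rebound pregnancy
module*, tested for enrichment with Fisher's exact test against the
measured-plus-network gene universe.

A first-class synthetic-data generator produces cohorts with planted
ground truth (rebound fraction, effect sizes, intra-donor correlation,
count overdispersion, 4-fold library-size variation, PPI graph with a
planted dense neighborhood, gene sets with a controlled disease-set
overlap), so every stage is testable by parameter recovery.

## Worked example

```python
import reboundomics as rb
from reboundomics.synthetic import gene_ids

config = rb.CohortConfig(
    n_donors_per_group={"MS": 8, "HC": 8},
    timepoints=("T1", "T2", "T3", "PP"),
    n_cpgs=3000, n_genes=2000, frac_rebound=0.02,
    effect_m=2.0, effect_lfc=2.0, rho_donor=0.5,
    missing_pattern={}, seed=11,
)
beta, counts, samples, annotation, truth = rb.generate_cohort(config)
ppi = rb.generate_ppi(2000, truth.planted_module_genes, extra_density=0.3, seed=12)
gene_sets = rb.generate_gene_sets(gene_ids(2000), truth.planted_module_genes,
                                  overlap_frac=0.5, seed=13)

result = rb.run_analysis(beta, counts, samples, annotation,
                         ppi=ppi, gene_sets=gene_sets)

print("shared rebound DMPs:", len(result.shared_meth.shared_ids))
print("shared rebound DEGs:", len(result.shared_expr.shared_ids))
print("rebound module size:", len(result.rebound_module))
de = result.disease_enrichment
print(f"disease enrichment: OR={de.odds_ratio:.1f}, p={de.p:.2e}")
```

prints

```
shared rebound DMPs: 60
shared rebound DEGs: 40
rebound module size: 240
disease enrichment: OR=7.4, p=1.87e-10
```

All 60 planted rebound CpGs and all 40 planted genes are recovered as
shared rebound features; the module built from them (40 seeds from each
omic plus 200 DIAMOnD additions, intersected across omics) overlaps the
planted disease set about 7-fold more than chance. The during- vs
after-pregnancy contrast estimates correlate at r ≈ −0.89 (methylation),
the signature of a genuine rebound.

The same analysis runs from the shell on TSV/GMT inputs:

```
reboundomics simulate --out sim/ --seed 11
reboundomics run --config config.yaml
reboundomics diamond --ppi sim/ppi.tsv --seeds seeds.txt --n 200
```

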