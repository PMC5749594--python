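# radiogenomap

Radiogenomic association mapping for non–small cell lung cancer–style studies:
given a tumor gene-expression matrix and a table of radiologist-assigned
semantic CT features (binary presence/absence plus ordinal scales such as
nodule margin or ground-glass proportion), the package produces

1. **validated metagenes** — clusters of coexpressed genes scored per sample,
   ranked by their cross-cohort *homogeneity* and annotated by hypergeometric
   gene-set enrichment,
2. **a prognosis table** — per-cohort univariate Cox *z* statistics combined
   into a Stouffer meta-*z* per histology group, and
3. **a radiogenomic map** — an FDR-controlled matrix of feature–metagene
   associations ordered by hierarchical clustering.

A synthetic-data module generates every input with planted ground truth
(coexpression blocks, feature–metagene effects, hazard coefficients), so the
whole pipeline is testable end to end without any external download.

## The statistics at the core

* **Homogeneity** of metagene *M* in a cohort:
  `H(M) = mean over gene pairs (i,j) in M of Pearson r(x_i, x_j)`.
  Metagenes are ranked by the average of `H` over validation cohorts, and the
  top 10 with average ≥ 0.45 are carried forward.
* **Enrichment**: for overlap *k* between a metagene (size *K*) and a gene set
  (size *m*) in a universe of *N* analyzed genes, the upper tail
  `P(X ≥ k)` of the Hypergeometric(*N*, *m*, *K*) law, Benjamini–Hochberg
  corrected jointly; significant iff `P < .001` and `Q < 0.05`.
* **Prognosis**: per cohort, member genes are standardized (mean 0,
  variance 1), averaged into a metagene score, and fit by univariate Cox
  proportional hazards (Breslow ties, Newton–Raphson to 1e-9). The Wald
  `z = β̂ / SE(β̂)` statistics combine as `meta_z = Σ z_c / √k`; a metagene is
  poor-prognosis if `meta_z > 2`, good-prognosis if `meta_z < −2`.
* **The map**: binary features use the pooled-variance two-sample *t*
  (positive *t* = higher metagene activity when the feature is present);
  ordinal features use Spearman rank correlation over the codebook's level
  order. BH FDR runs jointly over all feature × metagene pairs; a pair is
  significant iff `P < .05` and `FDR < 0.01`. Features are screened first by
  occurrence rate (minor-class frequency > 10%).
* **Preprocessing**: transcripts kept with ≥ 5 reads in ≥ 70% of samples;
  FPKM log2-transformed with zeros marked missing; missing entries imputed
  from the 15 nearest gene rows; genes standardized per row.

## Worked example

```sh
radiogenomap demo demo_bundle --seed 0
radiogenomap run --config demo_bundle/config.yaml --outdir demo_out
```

or, in Python:

```python
from radiogenomap import (AssociationMap, SemanticFeatureTable,
                          load_metagenes, metagene_scores)
from radiogenomap import io as rio
from radiogenomap.pipeline import PipelineConfig, make_demo, run_pipeline

cfg = make_demo("demo_bundle", seed=0)
report = run_pipeline(cfg, "demo_out")

expr   = rio.read_expression_tsv("demo_out/expression_log_imputed.tsv")
mgs    = load_metagenes("demo_out/metagenes_selected.gmt")
book   = rio.read_codebook_csv(cfg.path(cfg.codebook))
feats  = SemanticFeatureTable(rio.read_features_csv(cfg.path(cfg.features), book), book)
res    = AssociationMap(metagene_scores(expr, mgs), feats).fit().order_map()
print(res.summary())
```

prints

```
Radiogenomic association map
  patients: 113   features retained: 35 (removed 52)   metagenes: 10
  pairs tested: 350   significant (P<0.05, FDR<0.01): 6
      metagene_1 ~ solid_attenuation               t= +7.416  p=2.57e-11  fdr=3e-09
      metagene_2 ~ poorly_defined_margin           t= -6.625  p=1.29e-09  fdr=9.06e-08
      metagene_3 ~ ggo_proportion           spearman= +0.810  p=1.85e-27  fdr=3.24e-25
      metagene_4 ~ margin_type              spearman= +0.853  p=3.99e-33  fdr=1.4e-30
      metagene_5 ~ emphysema_present               t= +6.832  p=4.7e-10  fdr=4.12e-08
      metagene_6 ~ reticulation                    t= -6.460  p=2.86e-09  fdr=1.67e-07
```

Of 87 simulated semantic features, 52 fall at or below the 10% occurrence
cutoff and are removed; the 350 remaining pairs yield exactly the six planted
associations (and no false positives), with signs matching the planted effect
directions. The run report (`demo_out/run_report.json`) reconciles every
stage's counts, and `demo_out/prognosis.csv` shows the planted hazard
coefficients called poor-prognosis (`meta_z ≈ +16`) and good-prognosis
(`meta_z ≈ −14`) in the right histology groups.

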