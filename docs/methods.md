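# Methods

This note records the models, parameter choices and numerical conventions
behind `radiogenomap`, and what the synthetic benchmarks do and do not
establish about real data.

## Pipeline model

The analysis treats a tumor cohort as three linked data objects: a gene ×
sample expression matrix, a patient × semantic-feature table with a codebook,
and a collection of external survival cohorts with matched expression. The
chain is

```
counts ──filter──▶ FPKM ──log2──▶ (missing) ──kNN──▶ complete ──standardize──▶ Z
Z ──metagene scores──▶ per-patient activities ──t / Spearman──▶ association map
metagenes ──hypergeometric──▶ functional annotation
cohort expression ──Cox z──▶ Stouffer meta-z ──▶ prognosis calls
```

### Preprocessing

* **Low-count filter.** A transcript is kept when it has ≥ `min_count` (5)
  reads in at least `ceil(min_fraction × n_samples)` samples
  (`min_fraction` = 0.7). `ceil` implements "at least 70%" strictly; 7 of 10
  samples pass, 6 of 10 do not.
* **Log transform.** Base 2. Zero FPKM values are marked missing rather than
  shifted by a pseudocount, because imputation follows the transform in this
  pipeline; a `pseudocount` mode (log2(x+c), no missingness) is available
  when zeros should be kept as data.
* **k-NN imputation** (k = 15, Troyanskaya-style over gene rows). Distance
  between rows is the Euclidean distance over jointly observed samples
  divided by √(number shared) — so rows with different missingness patterns
  are comparable — and weights are 1/(d + 1e-12), which makes an exact
  duplicate row dominate. A missing entry uses only the neighbors observed at
  that sample and falls back to the gene's own row mean when none is. This is
  implemented in-package because library imputers use a column-mean fallback
  and unnormalized weights, which breaks the duplicate-row contract the tests
  pin down.
* **Standardization.** Per gene row, mean 0 and unit variance with the n−1
  denominator. Constant rows cannot be standardized and are dropped with a
  warning rather than aborting, since a constant gene carries no signal for
  any downstream stage.

### Metagenes

A metagene is a named set of ≥ 2 genes. Its per-sample **score** is the
unweighted mean of its standardized member rows — the simplest summary that
makes a single-gene metagene the identity and is the common convention for
metagene activity (a first-principal-component variant would differ only by
member weighting; the mean was chosen for transparency and determinism).

The **homogeneity** of a metagene in one cohort is the mean of all pairwise
Pearson correlations between member rows; pairs involving a constant row are
excluded. Selection averages homogeneity over *validation* cohorts only (the
primary cohort's value is reported but not averaged), ranks decreasing with
lexicographic tie-break, and takes the top `top_n` (10) among those with
average ≥ `min_avg` (0.45).

De-novo construction uses k-means on standardized rows (20 restarts, fixed
seed). For standardized rows ‖x−y‖² = 2(n−1)(1−r), so this is a Pearson
correlation-distance clustering; the identity is asserted in the tests.
Loading predefined memberships from GMT is the first-class path.

### Enrichment

One-sided upper-tail hypergeometric probability P(X ≥ k) (enrichment only),
exact via the survival function. The **universe** is the set of genes in the
analyzed expression matrix after filtering — the genes actually eligible to
be drawn — not the database's union. BH FDR is applied jointly across all
metagene × set pairs; zero-overlap pairs are excluded from the family by
default (configurable), trading a conservative family for power. Significance
requires both P < 0.001 and Q < 0.05.

### Survival meta-analysis

Univariate Cox proportional hazards per cohort, Breslow tie handling,
Newton–Raphson from β = 0 with steps clipped to ±5, converged when the score
gradient falls below 1e-9 (max 100 iterations; non-convergence raises with
diagnostics). The covariate is centered first — Cox is invariant to shifts —
for numerical stability. The Wald z = β̂·√I(β̂) is cross-checked in the tests
against brute-force maximization of the written-out partial likelihood and
against an independent survival library on tie-free data.

Cohort z's combine by the unweighted Stouffer rule Σz/√k. Cohorts whose fit
is undefined (constant score, < 2 events, non-convergence) contribute neither
to the sum nor to k — missing, not zero. meta-p is the two-sided standard
normal tail of meta-z; BH FDR runs within each histology group (the reported
family); calls use the strict |meta-z| > 2 rule. A √n-weighted Stouffer
variant was considered and not made the default, since cohort weighting
conventions vary; the unweighted form is the reproducible baseline.

### Association map

Binary features: pooled-variance two-sample Student t (Welch is a flag, not
the default — the pooled form is the canonical "t statistic" and the
synthetic generator produces near-equal variances). Ordinal features:
Spearman with average ranks over the codebook's declared level order, p from
the t approximation; |ρ| = 1 up to float error yields p = 0. Missing patient
values drop pairwise per test, not listwise.

The occurrence filter reads "> 10%" as **minor-class frequency** for binary
features — a feature present in 95% of patients is as uninformative as one
present in 5% — and as the non-modal fraction for ordinal ones. The cutoff is
strict: exactly 10% is removed.

BH FDR runs jointly over all retained feature × metagene pairs; undefined
tests are recorded as untested and excluded from the family (its size is
logged). Significance requires P < .05 *and* FDR < 0.01. Map ordering is
agglomerative average-linkage clustering on Euclidean distances between
−log10(p) profiles (untested cells imputed with 0), rows and columns
independently; leaf order is deterministic given input order.

The default ordinal margin scale is smooth < lobulated < irregular <
spiculated < poorly-defined; it is a configurable codebook convention, not a
fact about anatomy.

## Synthetic data: what it emulates and what it does not

* **Expression**: one shared standard-normal factor per block; gene g in
  block b is √ρ·f_b + √(1−ρ)·ε_g, giving expected pairwise within-block
  correlation exactly ρ. This captures coexpression structure but not
  count noise, library-size effects, batch structure or heavy tails.
* **Counts**: expressed rows are 5 + Poisson(50) (always ≥ 5), unexpressed
  rows are Poisson(1) clipped at 4 (never ≥ 5) — a deliberately separable
  construction so the filter's kept set is known exactly.
* **Features**: planted binary features are Bernoulli(logistic(d·score));
  planted ordinal features quantile-bin d·score + N(0, σ²) onto the declared
  levels; nulls are independent Bernoulli with configurable marginals. One
  interpretable effect-size knob d per pair; no radiologist disagreement or
  feature-feature correlation is modeled.
* **Survival**: exponential event times with hazard h₀·exp(Σ β_m f_m) in the
  block factors, independent Uniform(0, τ) censoring with τ calibrated by
  bisection so the expected censored fraction of the drawn event times equals
  the requested rate. No non-proportional hazards, no covariate-dependent
  censoring.
* **Gene sets**: planted sets share an exact overlap count with their target
  metagene; random sets are uniform draws.

Passing the planted-recovery benchmarks therefore shows the machinery is
correct and calibrated under its own assumptions (Gaussian blocks, logistic
feature links, proportional hazards); it does not certify performance under
real RNA-seq noise, annotation variability, or confounded cohorts.

## Study conditions and problem sizes

The bundled demo mirrors the target study's shape: 113 patients, 87 semantic
features of which ~35 survive the 10% filter (52 rare nulls are planted below
the cutoff), 14 candidate metagenes of 20 genes (10 tight blocks at ρ = 0.7,
4 loose at ρ = 0.2 that fail the 0.45 homogeneity bar), 5 validation cohorts
of 200 samples, and 11 survival cohorts (6 adenocarcinoma, 5 squamous,
n = 150, 30% censoring) with planted log-hazards ±0.8. Planted
feature–metagene effects use d = 2, the effect size at which the dual
threshold attains ≥ 0.9 sensitivity at n = 150. Monte-Carlo checks in the
test suite use 500 replicates for null false-discovery calibration, 10⁴ for
the Stouffer null, and 40–50 seeds for recovery rates — sizes chosen so each
band is several Monte-Carlo standard errors wide.

## Numerical conventions and edge cases

* Sample standard deviations use ddof = 1 everywhere except where a
  population sd is explicitly irrelevant (Pearson r is scale-free).
* BH q-values are computed by the standard step-up and verified against a
  brute-force suffix-minimum oracle; p-values must lie in (0, 1].
* Rank-sum p is exact by enumeration for n₁+n₂ ≤ 12 without ties, otherwise
  the tie-corrected normal approximation with continuity correction; the two
  branches agree within 0.02 at n₁ = n₂ = 6.
* Homogeneity ties in ranking break lexicographically by metagene id.
* Run outputs are plain text with full-precision floats; re-running a config
  is byte-identical. Output directories are caller-named rather than
  timestamped so that byte-level reproducibility is directly checkable.

## Known limitations

* The de-novo clustering is a documented stand-in for externally defined
  metagene memberships; loading a GMT is the supported path for replication.
* The metagene score is the mean of standardized members; signatures whose
  activity is better captured by a principal component will be attenuated.
* The Cox solver is univariate by design; no multivariable adjustment or
  proportional-hazards diagnostics are provided.
* FDR control is exercised under independence-like simulation; strongly
  correlated feature panels can make BH conservative or (under unusual
  dependence) anti-conservative.
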