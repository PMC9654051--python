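# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical conventions a user should know before trusting a green test.

## Synthetic data: the stated world

`generate_counts` simulates a 2-diet × T-tissue design (default four
tissues, 5 samples per diet × tissue cell, n = 40). Counts for gene g in
sample s are negative binomial with

    mu(g, s) = B_g · t_{g,τ(s)} · (L_g / 1000) · f_{g,τ(s)}^{[diet(s)=CR]} · c_s
    Var      = mu + φ · mu²

- **Baselines** `B_g` are log-normal, median 50 with sd 1.0 on the natural-log
  scale (`mean_log_baseline = ln 50`, `sd_log_baseline = 1`). This is meant
  as a *post-filter* mRNA-seq expression distribution — most genes
  comfortably above the FPKM-5 filter, a small left tail below it. With these
  defaults a planted gene is filtered out with probability ≈ 2·10⁻⁴.
- **Tissue offsets** `t_{g,τ}` are log-normal with sd 0.5 per gene × tissue
  (`sd_log_tissue`): typical between-tissue expression ratios of ~1.5–3,
  deliberately comparable to the planted diet effect so that tissue
  heterogeneity is a real confounder rather than decoration.
- **Gene lengths** `L_g` are uniform on 500–5000 bp and enter the mean, so
  FPKM is not a monotone function of counts.
- **Library-size factors** `c_s` are log-normal(0, 0.1), so size-factor
  estimation is non-trivially exercised.
- **Dispersion** φ defaults to 0.3 (Var = mu + 0.3 mu²), a typical bulk
  RNA-seq value at small n; scalar or per-gene.
- **Planted effects**: a fraction `frac_signature` of genes receives a
  diet fold `f` (or 1/f, sign drawn per gene) *identical in every tissue*;
  a fraction `frac_tissue_dep` receives an independent fold direction per
  tissue (the up-in-one-tissue / down-in-others pattern seen in real
  per-tissue DE tables); the rest are null (fold 1 everywhere). The exact
  per-gene class and per-tissue fold are returned as `SyntheticTruth`.

The generator does **not** emulate read-level artefacts (no FASTQ, mapping
bias, GC effects), batch structure beyond size factors, gene–gene
correlation, or compositional effects. A green recovery test therefore
establishes that the pipeline finds planted mean-shift effects under NB
noise, tissue heterogeneity and library-size variation — not that it is
robust to correlated or compositional artefacts.

`generate_posterior_draws` returns seeded normal draws and exists purely to
exercise the SEXIT reporting layer; fitting the Bayesian models that would
produce real posteriors is out of scope.

## FPKM and filtering

FPKM(g, s) = counts · 10⁹ / (library size · gene length), with library size
the per-sample total of assigned counts and the plain annotated length in
the denominator (no effective-length correction — none is well defined
without fragment-length information). The low-expression filter removes a
gene iff its arithmetic mean FPKM over *all* samples (pooled across tissues)
is strictly below the threshold (default 5): a gene sitting exactly at the
threshold is kept. The mined table is samples × (kept genes, sorted by id) +
one categorical `tissue` column, with `diet` as the class label.

## Differential expression

Per tissue, CR vs control:

- **Size factors**: median-of-ratios against a geometric-mean
  pseudo-reference over genes with no zero counts; upper-quartile
  normalisation (rescaled to geometric mean 1) as fallback when no such
  gene exists.
- **Dispersion**: method of moments per group, φ_g = (s² − m)/m² on
  normalised counts, pooled with (n_g − 1) weights, floored at 0. Pooling
  within groups keeps the estimate valid when the two group means differ.
  No shrinkage is applied; at n = 5/group the estimate is noisy and biased
  low, which makes p-values based on *estimated* φ anticonservative
  (measured type-I ≈ 0.09 at α = 0.05 in the null simulation). A
  `shared_dispersion` option pools the median φ across genes as a rough
  stabiliser. With the true φ supplied, the Wald machinery itself is
  calibrated (measured type-I 0.058, inside [0.03, 0.07]).
- **Wald test**: the statistic is log(m_CR/m_ctl) of normalised group means
  over its delta-method NB standard error; for constant size factors this
  coincides exactly with the expected-information Wald test of a two-group
  NB GLM with log link (the statsmodels GLM cross-check in the tests
  confirms the point estimate to 1e-6). Reference distribution: standard
  normal. A group whose mean is zero gets a 0.5/n pseudo-count on both
  group means. Genes with zero counts across all samples of a tissue are
  reported `not_expressed` and excluded from testing and FDR.
- **FDR**: hand-rolled Benjamini–Hochberg step-up with monotonicity
  enforcement, applied within tissue over tested genes only.
- **Signed fold change**: r ≥ 1 → r, r < 1 → −1/r, so |signed FC| ≥ 1 and
  the sign encodes direction under CR.

## Attribute weighting

Seven models score every feature (gene FPKM columns + categorical tissue)
against the binary diet class.

**Discretisation.** The five contingency-based models and the rule model
need binned features. Two methods are provided:

- `entropy` (default): supervised Fayyad–Irani minimal-entropy partitioning
  with the MDL stopping criterion. A feature whose best split does not pay
  its MDL cost stays in a single bin, which maps all five contingency
  weights to exactly 0 — null features are silenced rather than scored on
  binning noise.
- `equal_frequency`: unsupervised quantile bins (default 5), right-closed,
  duplicate edges collapsed.

Equal-frequency binning was the original design but demonstrably degrades
planted-signature recovery in this design (7–9/10 planted genes in the top
20 across seeds, versus 8–10/10 with supervised partitioning): pooled
quantile bins split on tissue heterogeneity as readily as on the diet
effect. Supervised entropy partitioning is also what the RapidMiner-style
weighting operators these models descend from apply to numeric attributes,
so it is the default; the choice is a config key.

**The models** (raw weights): info gain I(bins; class) in bits; gain ratio
I/H(bins); symmetric uncertainty 2I/(H(class)+H(bins)); Gini impurity
reduction; the raw Pearson chi-square statistic (not its p-value); OneR rule
weight = majority-class-per-bin training accuracy minus the majority-class
baseline, floored at 0; and ReliefF. ReliefF uses Manhattan distance on
min-max-scaled numerics (0/1 mismatch for categoricals), k = 5 nearest hits
and misses, and a full deterministic pass over all samples by default
(seeded subsampling available). With 5 samples per diet × tissue cell only
4 same-cell hits exist, so at k = 5 every reference sample borrows one
cross-tissue hit; a structural consequence is that the tissue attribute's
relief weight is the minimum in any balanced design, and the tissue
attribute lands at the very bottom of the ranking whether or not the diet
effects are tissue-dependent. The tissue-independence diagnostic is
therefore reported as a rank plus a bottom-decile flag, not inferred from
relief alone.

**Normalisation and ranking.** Each model's raw weights are min-max mapped
to [0, 1] over all features (constant vectors map to all-0 with a warning);
the per-feature sum of the seven normalised weights (0–7) ranks features,
ties broken lexicographically by feature id for determinism. Report tables
print 1-decimal weights while sums are computed from unrounded values, so a
printed row may disagree with the digit-sum by up to 0.1.

## SEXIT reporting

From a posterior draw vector: E_M is the sample median; the HDI is the
shortest window containing ⌈mass·n⌉ sorted draws (default mass 0.95,
leftmost window on ties); D_p = max(fraction > 0, fraction < 0) computed
from integer counts (exact zeros split evenly); the ROPE is ±0.05·SD(y) and
ROPE_p is the fraction of the *full* posterior inside the closed interval
(bounds count as inside — conservative for the decision); the effect is
"not practically equivalent to zero" iff ROPE_p < 0.025. A
`rope_within_hdi` flag restricts the ROPE denominator to HDI members for
the alternative convention. A minimum of 100 draws is required for a
summary.

## Multivariate views

PCA is an eigendecomposition of the correlation matrix of the tissue
columns of the signed fold-change matrix (eigenvector signs fixed so the
largest-magnitude loading is positive); explained-variance fractions are
eigenvalues over their sum. Clustering is agglomerative on Euclidean
distances between tissue columns (complete linkage by default; single and
average available) with each merge reported as percent similarity
100·(1 − d/d_max), d_max the final merge distance — so identical columns
merge at 100% and the final merge is exactly 0%. Gene-wise clustering is
available by transposition. The printed similarity of any particular
dataset depends on which genes enter the matrix; only the conventions, not
reference values, are fixed here.

## Pipeline and determinism

Stages run in dependency order; each stage derives its own RNG seed from
the master seed by hashing `"{seed}:{stage}"` (kept below 2³¹), so toggling
one stage never changes another's stream. Every run writes a resolved
config, plain-text/TSV/JSON artifacts only, and a manifest of SHA-256
checksums; identical config + seed reproduces identical checksums.

## Known limitations

- Dispersion estimation at n = 5/group is noisy and unshrunk; q-values from
  estimated dispersions are optimistic at this sample size (see above).
- ReliefF in high dimensions measures neighbourhoods dominated by noise
  features; its weights separate planted effects less sharply as the
  feature count grows.
- The OneR "rule" weight and the exact ReliefF variant are reasonable,
  documented interpretations of loosely specified commercial operators;
  numeric agreement with any particular commercial implementation is not
  claimed — only the aggregation arithmetic and qualitative behaviour.
- Single-factor design only: no covariates, no interaction tests, no
  multi-class labels.
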