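# Methods

`ibcnet` re-implements, as a tested pipeline over log2 expression matrices, a
comparative transcriptional analysis of inflammatory (IBC) versus
non-inflammatory (nIBC) breast cancer models: expression merging across
batches, unsupervised clustering, a penalized-logistic IBC signature
classifier, moderated and percentile-based differential expression, signed
weighted co-expression network analysis with module preservation,
minimum-spanning-tree module prioritization, connectivity-map-style
regulator/drug screening, and a nested MYC ~ ER-stratum × phenotype
regression. This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic data do and do not emulate.

## Synthetic data

All inputs are generated; nothing is downloaded.

**Cell-line compendium.** Genes × samples log2 matrix for
`n_cell_lines_ibc + n_cell_lines_nibc` lines profiled in
`replicates_per_line` replicates (default 3, the customary minimum for
array profiling of cell lines; defaults 10 IBC + 22 nIBC lines mirror a
124-profile, 32-model compendium). Each planted module m has a latent
per-line factor f_{m,c}; gene g in m reads

    x_gs = baseline_g + l_g · f_{m,line(s)} + ε_gs,  ε ~ N(0, noise_sd²).

Loadings are a *shifted* half-normal, `l_g = effect_sd · (0.3 + |N(0,1)|)`:
graded (so gene–module-membership scores span a realistic range) but bounded
away from zero, since a loading below ≈0.3·effect_sd is statistically
invisible at 10 cell lines and would make the planted truth unrecoverable in
principle. Factors are standardized across lines (mean 0, sd 1 in-sample)
and successively decorrelated across modules, so `effect_sd/noise_sd` is
exactly the planted signal-to-noise ratio and the planted partition is
identifiable; without this, the 10-line factor draw varies its sd by ±35%
across seeds and occasionally collapses two modules onto one axis.
Phenotype-linked modules place the linked phenotype's factor at
+`phenotype_shift` and the other at −`phenotype_shift` (default 1; values ≳3
make the phenotypes linearly separable on module genes). Batch effects are
per-(batch, gene) multiplicative factors on the linear scale (additive log2
shifts, sd `batch_shift_sd`) plus residual-scale distortions
(`batch_scale_sd`); replicates of a line are spread across batches so batch
is crossed with line. One seed per generator is split into named
`SeedSequence` substreams (documented in each docstring), so adding a
randomness consumer never perturbs existing output.

What this does *not* emulate: probe-level array artifacts, intensity-
dependent variance, correlated noise between modules, or stromal admixture.
A passing recovery test therefore demonstrates the algorithm under the
assumed generative model, not performance on arbitrary real data.

**Perturbation catalog.** Ranked differential-expression vectors. For a
planted regulator of module m with strength s: overexpression
`s·profile_m + (1−s)·noise`, knockdown `−s·profile_m + (1−s)·noise`
(exact negation at s = 1); planted drugs mimic knockdown of their declared
target's module; fillers are independent noise.

**Patient cohort.** 146 IBC + 252 nIBC samples (the study scale). ESR1 is
continuous; ER strata are exact tertiles of ESR1 *within* phenotype, so the
six design cells are balanced to within one sample. MYC is the nIBC/ER-low
reference mean plus five offsets (defaults −0.754, −0.931, −0.832, +0.599,
+1.414 expression units, the IBC ER-moderate/high values coded as increments
over IBC/ER-low) plus N(0, noise_sd²). Proximal-MYC-network (PMN) members
are drawn through a Gaussian copula against the standardized MYC score with
latent correlation 2·sin(π·ρ_s/6), which hits a requested Spearman ρ_s in
population. Stage and subtype frequencies depend on ER stratum (higher ER →
more luminal, lower stage). MYC "activity" tracks standardized MYC with
independent noise.

## Preprocessing

Fixed chain: expression filter → batch correction → quantile normalization →
probe collapsing → replicate averaging. Inputs are assumed log2-summarized;
missing values are rejected, not imputed.

* **Filter**: keep genes with > log2(100) intensity in ≥ 2 samples (both
  configurable).
* **Batch correction**: parametric empirical-Bayes location/scale
  adjustment (ComBat), delegated to `scanpy.pp.combat` with protected
  covariates encoded as numeric drop-first indicators; we pre-validate the
  design and raise a named error when batch is confounded with a protected
  factor. Note a property of EB shrinkage worth knowing: a constant
  between-batch shift is removed *exactly* only when per-gene variances are
  equal (then every per-gene batch effect coincides with the across-gene
  prior mean); with heterogeneous variances a small shrinkage residual
  remains by design. Protected covariates default to the replicate group
  (line identity); phenotype is not protected by default.
* **Quantile normalization**: rank-wise column means, ties averaged.
* **Probe collapsing**: per gene, the probe with maximal sample SD;
  ties go to the lexicographically smallest probe id.
* **Averaging**: arithmetic mean per replicate group, first-appearance
  column order.

## Clustering and cluster-number voting

Samples are clustered on the 500 most variable genes (SD on the input
scale, then per-gene center/scale), Manhattan distance, Ward linkage. The
number of clusters k ∈ 2..10 is chosen by majority vote over eight named
internal validity indices — silhouette, Calinski–Harabasz, Dunn,
Davies–Bouldin, C-index, point-biserial, McClain–Rao, and a within-
dispersion-drop (elbow) index — each voting for its optimal k; ties go to
the smallest k. The panel replaces a much larger published index battery:
the voting mechanism, not the exact panel, carries the method, and the
panel is pluggable. Cluster–annotation association uses Fisher's exact test
for 2×2 tables, a seeded Monte-Carlo chi-square for small r×c tables, and
the asymptotic chi-square otherwise. Competing predictors of the cluster
pattern are compared by multinomial logistic regression (statsmodels
MNLogit) via AIC = 2k − 2logL and likelihood-ratio tests; separation falls
back to a ridge-stabilized fit and is flagged.

## IBC classifier

Elastic-net logistic regression over a supplied signature gene list
(a 79-gene signature in the motivating application). Objective

    (1/n) Σ logloss + λ[(1−α)/2‖β‖² + α‖β‖₁],

fit with scikit-learn's saga solver via C = 1/(n·λ). Stratified 3/1
train/validation split; per-gene standardization from the training split
only; grid α ∈ {0,…,1 step 0.1} × λ ∈ {0.001,…,0.1 step 0.001} scored by
mean AUROC under repeated stratified 10-fold CV (5 repeats by default — the
repeat count is otherwise unstated in the motivating design); ties prefer
larger λ then larger α. Replicate-level posteriors are aggregated per model
by the median; the binary IBC call is median ≥ 0.5 (ties call IBC).
Confusion statistics use exact rational arithmetic. McNemar's test is
(b−c)²/(b+c) on discordant pairs, continuity correction off by default,
exact two-sided binomial below 25 discordant pairs. A generic
nearest-centroid caller (Spearman by default, ties to file order) is
provided as plumbing for user-supplied subtype centroids; no published
centroid values ship with the package.

## Differential expression

**Moderated t.** Per-gene two-group model with empirical-Bayes variance
shrinkage. The prior (d₀, s₀²) is estimated by closed-form moment matching
of log sample variances: with residual df d_g,
e_g = log s_g² − ψ(d_g/2) + log(d_g/2) has variance ψ′(d₀/2) + ψ′(d_g/2),
so d₀ comes from inverting the trigamma function and s₀² from the mean of
e_g; the posterior variance is s̃² = (d₀s₀² + d_g s_g²)/(d₀+d_g) and the
moderated t is referred to t with d₀+d_g df (normal in the pooled d₀ → ∞
limit, triggered when log-variances show no excess dispersion). This moment
estimator is a deliberate simplification of iterative ML fitting of the
scaled-F marginal — closed-form, testable, and adequate at desk scale.
BH step-up adjustment (statsmodels) controls FDR at 10% by convention.

**Paired percentile comparison.** For one sample pair (e.g. a cell line vs
its source tumor): per-gene differences on genes above the expression
threshold in both profiles; genes strictly above the 97.5th (strictly below
the 2.5th) empirical percentile (type-7) form the two sets. Strict
inequalities make the identity comparison yield empty sets, and the
operation is exactly antisymmetric under swapping the profiles.

## Co-expression network

Signed weighted network over genes:

* **bicor**: biweight midcorrelation, u = (x − median)/(9·MAD), weights
  (1−u²)² on |u| < 1; zero-MAD genes fall back to Pearson with a log entry.
* **Soft threshold**: signed adjacency a_ij = ((1+cor_ij)/2)^β (the signed
  convention is deliberate: unsigned |cor|^β would conflate anti-correlated
  genes into modules). β is the smallest integer in 1..20 whose
  connectivity distribution fits scale-free topology with sign-adjusted
  R² ≥ 0.8 over ten equal-width log-binned connectivity bins *and* whose
  mean connectivity has decayed to ≤ 1% of the gene count — the standard
  companion check, since a network can look scale-free while far too dense
  for modules to be resolvable. (Equal-count bins would make the binned
  frequency constant by construction, so equal-width bins are used.)
* **TOM**: topological overlap
  TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), dissimilarity
  1 − TOM.
* **Module detection** (minimum size 100 by default): Ward tree on the TOM
  dissimilarity; an adaptive branch carve keeps dendrogram nodes of
  ≥ min_size leaves whose mean within-branch overlap exceeds the matrix
  background by the factor `cohesion_ratio` (1.5) — overlap *ratios*, unlike
  dissimilarity gaps, are comparable across powers; a cohesive node is
  descended only when both children are large, cohesive and mutually
  separated by the same ratio (i.e. it lumps two modules). A recovery pass
  re-carves the unassigned residual so a module shredded by an unlucky
  top-level split is found. A PAM-style stage then reassigns every gene to
  its closest core by mean dissimilarity to core members, within a radius
  interpolated 70% of the way from the members' mean distance to the
  unassigned background's mean distance (admits weak peripheral members,
  keeps background genes out), iterated twice; modules below min_size
  dissolve to the unassigned label 0; finally modules whose eigengenes
  correlate above 1 − merge_cut (0.75) merge iteratively. This carve/PAM
  design collapses the many tunables of published branch-pruning codes to
  min_size, merge_cut and cohesion_ratio, all exposed.
* **Eigengenes and GMM**: eigengene = first principal component of the
  standardized module submatrix, oriented so the mean member correlation is
  positive, unit norm; GMM (kME) = Pearson correlation of every gene with
  every eigengene.
* **Preservation**: per module, a density statistic (mean within-module
  signed adjacency in the test data) and a connectivity statistic (Spearman
  correlation of intramodular connectivity between reference and test),
  each Z-scored against random same-size gene sets (200 permutations by
  default); Zsummary is their mean, banded < 2 poor / 2–10 moderate / > 10
  good.

## Prioritization

Module–module eigengene correlations and per-line module eigengene values
are dichotomized at zero (strictly positive → edge; exact zeros → no edge,
logged) into a binary modules ∪ cell-lines graph. On an unweighted graph
the minimum spanning tree is not unique, so a canonical Kruskal over
lexicographically sorted node pairs is imposed — the single convention this
procedure needs to be reproducible. The prioritized modules are the module
nodes on the unique tree paths joining the target cell lines (the Steiner
subtree of the MST); disconnected targets raise an error naming the lines
outside the main component.

## Connectivity screening

A module query is the 150 highest- plus 150 lowest-GMM genes (ties broken
by gene id). Against a ranked signature, the connectivity score is the
two-sided weighted Kolmogorov–Smirnov statistic: hits advance the running
sum by |value|/Σ|hit values| (exponent 1; a rank-only variant is a flag),
misses retreat it by 1/(N−n); ES is the running sum at maximal |deviation|;
CS = 100·(ES_up − ES_down)/2 when the two ES have opposite signs, else 0.
Positive CS means congruence. CS(q, −s) = −CS(q, s) holds exactly for
signatures with distinct values (tie blocks can reorder under reversal;
practical signatures are continuous). No touchstone/tau normalization is
applied — the score is the raw scaled weighted-KS statistic, and the
decision thresholds operate on it: regulators need CS ≥ +75 on
overexpression *and* ≤ −75 on knockdown (difference ≥ 150 with both bounds
met); drug/target pairs need the drug strictly < −75 and the declared
target's overexpression strictly > +75.

## Enrichment and activity

Preranked GSEA uses the same weighted-KS kernel; significance comes from
gene-label permutations (vectorized over the piecewise-linear breakpoints
of the running sum), NES = ES / mean |ES| of same-sign permutation scores,
p = same-sign tail with a +1 pseudocount, BH across sets. ORA is the
hypergeometric upper tail P(X ≥ overlap) with a Haldane-corrected 2×2 odds
ratio; degenerate margins (module or hit set spanning the whole universe,
or empty) are defined as OR = 1, p = 1. Single-sample activity is a
rank-sum z per sample,

    z = (meanrank_S − (G+1)/2) / sqrt((G+1)(G−|S|)/(12|S|)),

monotone-invariant per sample with a closed-form standard-normal null —
a deliberate substitution for kernel-CDF single-sample enrichment; analyses
built on it are comparable in direction and ordering, not in absolute score.

## Interaction model

OLS (identity link, Gaussian errors — appropriate for log2 expression) on
five indicators over the six phenotype × ER-stratum cells with nIBC/ER-low
as reference: nIBC·ER-moderate, nIBC·ER-high, IBC (the IBC/ER-low shift),
IBC·ER-moderate and IBC·ER-high as *increments over IBC/ER-low* — matching
the narrative "MYC increased by 0.599 and 1.414 units" within IBC; the
alternative coding (increments vs same-stratum nIBC) is rejected. HC3
robust SEs are available, off by default. Blocking factors (stage, subtype)
enter as indicator columns; aliased columns are dropped with a warning and
the blocked model is compared to the unblocked by LRT. ER tertiles for a
real cohort default to pooled stratification (`stratify_tertiles` with
quantiles 1/3 and 2/3, type-7, boundary ties to the lower stratum); the
synthetic cohort stratifies within phenotype to keep all six cells
populated. PMN analysis reports Spearman ρ and p per member vs MYC and vs
activity scores, plus a Ward-ordered pairwise matrix; constant members
yield missing correlations. Outlier flagging marks samples whose candidate
gene expression strictly exceeds its empirical 90th percentile and overlays
the flags on residuals of activity ~ MYC.

## Problem sizes and benchmarks

The benchmark scenarios in `ibcnet.evaluation` (also used by
`scripts/acceptance.py`) run at desk scale as the package's own choice:
1000 genes with three planted 150-gene modules at signal-to-noise 2 for
module recovery; 500 genes / 150-gene module / 200 permutations × 100 seeds
for preservation; 1000-gene signatures for connectivity; the full 398-sample
cohort × 100 seeds for interaction recovery; a 96-profile separable
compendium for classifier accuracy plus 300 independent profiles × 100
seeds for the permuted-label no-leakage check (replicate near-duplicates
shrink the effective sample size of a null AUROC to the number of lines, so
the null band is checked on single-replicate profiles at an n where the
chance AUROC spread supports it). Benchmark classifier runs use a compact
tuning grid (3×3 or 2×2); the full default grid remains the package
default.

## Known limitations

* Module detection quality degrades when the soft threshold lands at the
  extremes of the candidate range; the mean-connectivity cap mitigates but
  does not remove this.
* The preservation Z uses 2 statistics and a random-gene-set null, not the
  full published battery; bands (2/10) are unchanged.
* The connectivity score is not tau-normalized against a reference catalog;
  thresholds are honored on the raw scaled score, so absolute values are
  not interchangeable with clue.io scores.
* GSVA-style analyses are reproduced in direction/ordering only (rank-sum z
  substitution).
* No blockwise/out-of-core path: gene counts are assumed ≤ ~10k.
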