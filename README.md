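# ibcnet

A tested pipeline for comparative transcriptomics of inflammatory breast
cancer (IBC) versus non-inflammatory breast cancer (nIBC) preclinical
models and patient cohorts, built for analysts who need the full chain —
from multi-batch expression merging to network-level drug screening — to be
reproducible on synthetic data before touching real accessions.

The pipeline covers:

* **Preprocessing** — background filtering (log2(100) in ≥ 2 samples),
  empirical-Bayes batch correction (ComBat) with protected covariates,
  quantile normalization, max-SD probe collapsing, replicate averaging.
* **Unsupervised analysis** — Manhattan/Ward clustering of samples with a
  majority vote over eight validity indices for the cluster number
  (k ∈ 2..10), Fisher/chi-square association tests, multinomial AIC/LRT
  model comparison.
* **IBC classification** — an elastic-net logistic model over a signature
  gene list: objective (1/n)Σlogloss + λ[(1−α)/2‖β‖² + α‖β‖₁], tuned by
  repeated stratified 10-fold CV AUROC over α ∈ {0,…,1} × λ ∈ {0.001,…,0.1},
  3/1 train/validation split, median-posterior calling per model.
* **Differential expression** — moderated t with closed-form
  empirical-Bayes variance shrinkage (s̃² = (d₀s₀²+d_g s_g²)/(d₀+d_g)),
  BH control at 10 % FDR, and a 97.5/2.5-percentile paired comparison.
* **Co-expression networks** — signed biweight-midcorrelation networks
  a_ij = ((1+bicor_ij)/2)^β with β chosen for scale-free topology,
  topological overlap, adaptive branch-carve module detection (minimum
  100 genes) with PAM refinement and eigengene merging, gene–module
  membership (kME), and permutation Zsummary module preservation
  (bands 2/10).
* **Prioritization** — dichotomized module/cell-line graph, canonical
  minimum spanning tree, and the minimal module set connecting target
  cell lines.
* **Connectivity screening** — 150-up/150-down GMM marker queries scored
  against a perturbation catalog by weighted-KS connectivity
  CS ∈ [−100, 100]; regulators at CS ≥ 75 (overexpression) and ≤ −75
  (knockdown), drug/target pairs at < −75 / > +75.
* **Enrichment & activity** — preranked GSEA (permutation NES/p),
  hypergeometric ORA, rank-sum single-sample activity scores.
* **Interaction model** — nested MYC ~ ER-stratum × phenotype regression
  (five coefficients against the nIBC/ER-low reference), blocking-variable
  sensitivity via LRT, proximal-MYC-network Spearman reports, and
  90th-percentile outlier flagging.

Synthetic generators (`ibcnet.synthetic`) produce every input the pipeline
consumes — a multi-batch cell-line compendium with planted co-expression
modules, an L1000-like perturbation catalog with planted regulators, and a
146 + 252-sample patient cohort with ESR1-tertile-dependent MYC effects —
so every stage is testable end to end without downloads. See
`docs/methods.md` for models, conventions and limitations.

## Worked example

```python
import ibcnet as ib

spec = ib.CompendiumSpec(seed=0, n_genes=1000,
    modules=(ib.ModuleSpec(150, 2.0, "IBC"),
             ib.ModuleSpec(150, 2.0, "none"),
             ib.ModuleSpec(150, 2.0, "none")),
    n_cell_lines_ibc=5, n_cell_lines_nibc=5)
comp = ib.generate_cell_line_compendium(spec)

params, modules, gmm = ib.build_network(comp.values, min_size=100)
print("soft threshold beta:", params.beta)
print("module sizes:", modules.sizes.to_dict())

eig_lines = ib.average_replicates(gmm.eigengenes.T,
                                  comp.annotation["replicate_group"])
adj = ib.build_bipartite_adjacency(gmm.eigengenes.corr(), eig_lines)
ibc_lines = [l for l in eig_lines.columns if l.startswith("IBC")]
edges, prioritized = ib.minimal_connecting_modules(adj, ibc_lines)
print("modules connecting all IBC lines:", prioritized)

cohort = ib.generate_patient_cohort(ib.CohortSpec(seed=0))
fit = ib.fit_nested_interaction(cohort.data["MYC"],
                                cohort.data["phenotype"],
                                cohort.data["er_stratum"])
print(fit.params.round(3))
```

prints

```
soft threshold beta: 18
module sizes: {1: 144, 2: 142, 3: 140}
modules connecting all IBC lines: ('M1', 'M2', 'M3')
Intercept           10.042
nIBC:ER-moderate    -0.654
nIBC:ER-high        -0.753
IBC:ER-low          -0.665
IBC:ER-moderate      0.505
IBC:ER-high          0.916
```

The network recovers the three planted 150-gene modules (a few weak-loading
genes stay unassigned), the minimal spanning tree reports which modules
connect every IBC line, and the nested regression estimates how MYC shifts
across ER strata within each phenotype relative to nIBC/ER-low — negative
in nIBC as ER rises, increasing again within IBC (here at one noisy draw of
the default cohort; the generator's true offsets are −0.754, −0.931,
−0.832, +0.599, +1.414).

A thin CLI mirrors the library: `ibcnet simulate|preprocess|cluster|
classify|de|de-paired|network|prioritize|cs-screen|enrich|ora|activity|
interaction --help`.

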