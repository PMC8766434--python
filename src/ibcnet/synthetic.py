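"""Synthetic-data generators for every pipeline input.

Three generators emulate the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any external download:

* a multi-batch cell-line expression compendium with planted co-expression
  modules (latent-factor model) and optional phenotype-linked signal;
* an L1000-like perturbation catalog with planted regulator pairs
  (overexpression aligned with a module profile, knockdown its negation)
  and planted drug/target pairs;
* a two-phenotype patient cohort in which MYC expression follows a nested
  ER-stratum x phenotype cell-mean structure and proximal-MYC-network (PMN)
  genes track MYC with requested Spearman correlations.

Determinism: each spec carries a single integer seed which is split into
named substreams via ``numpy.random.SeedSequence.spawn``; the substream
order is fixed and documented per generator, so extending a generator with
a new randomness consumer appends a stream and never perturbs existing
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionCompendium, PatientCohort, PerturbationCatalog

# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``phenotype_shift`` sets how far apart (in latent-factor units, +/-
    shift around zero) the linked phenotype's line factors sit from the
    other phenotype's; the within-phenotype factor spread is 1, so shifts
    well above 1 make the phenotypes linearly separable on module genes.
    """

    size: int
    effect_sd: float = 2.0
    phenotype_link: str = "none"  # {"IBC", "nIBC", "none"}
    phenotype_shift: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("module size must be >= 1")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        if self.phenotype_link not in ("IBC", "nIBC", "none"):
            raise ValueError(f"bad phenotype_link {self.phenotype_link!r}")


@dataclass
class CompendiumSpec:
    n_genes: int = 2000
    modules: Sequence[ModuleSpec] = field(
        default_factory=lambda: (
            ModuleSpec(150, 2.0, "IBC"),
            ModuleSpec(150, 2.0, "none"),
            ModuleSpec(150, 2.0, "none"),
        )
    )
    n_cell_lines_ibc: int = 10
    n_cell_lines_nibc: int = 22
    replicates_per_line: int = 3  # "at least in triplicate"
    n_batches: int = 5
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.modules = tuple(
            m if isinstance(m, ModuleSpec) else ModuleSpec(*m) for m in self.modules
        )
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")
        for name in ("n_genes", "n_cell_lines_ibc", "n_cell_lines_nibc",
                     "replicates_per_line", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CatalogSpec:
    n_signature_genes: int = 1000
    n_perturbagens: int = 30
    planted_regulators: Sequence[tuple] = field(default_factory=tuple)  # (module_id, strength)
    planted_drug_pairs: Sequence[tuple] = field(default_factory=tuple)  # (target_id, drug_id, strength)
    seed: int = 0

    def __post_init__(self) -> None:
        for _, s in self.planted_regulators:
            if not 0.0 <= s <= 1.0:
                raise ValueError("regulator strength must lie in [0, 1]")
        for _, _, s in self.planted_drug_pairs:
            if not 0.0 <= s <= 1.0:
                raise ValueError("drug strength must lie in [0, 1]")
        drug_ids = [d for _, d, _ in self.planted_drug_pairs]
        if len(set(drug_ids)) != len(drug_ids):
            raise ValueError("planted drug ids must be unique")
        mod_ids = [m for m, _ in self.planted_regulators]
        if len(set(mod_ids)) != len(mod_ids):
            raise ValueError("planted regulator module ids must be unique")


# Study-scale defaults: 146 IBC / 252 nIBC samples; MYC cell-mean offsets
# relative to the nIBC / ER-low reference, with the IBC ER-moderate/high
# coefficients coded as increments over IBC / ER-low.
@dataclass
class CohortSpec:
    n_ibc: int = 146
    n_nibc: int = 252
    coef_nibc_er_mod: float = -0.754
    coef_nibc_er_high: float = -0.931
    coef_ibc_er_low: float = -0.832
    coef_ibc_er_mod: float = 0.599
    coef_ibc_er_high: float = 1.414
    reference_mean: float = 10.0
    noise_sd: float = 1.0
    pmn_cor_targets: dict = field(
        default_factory=lambda: {"MAX": 0.5, "MLX": 0.4, "MXD3": -0.5, "MYCN": -0.3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ibc, self.n_nibc) < 9:
            raise ValueError("need >= 3 samples per ER stratum in each phenotype")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


# ---------------------------------------------------------------------------
# cell-line compendium
# ---------------------------------------------------------------------------


def generate_cell_line_compendium(spec: CompendiumSpec) -> ExpressionCompendium:
    """Simulate a multi-batch, replicated cell-line expression compendium.

    Genes in a planted module share a latent per-cell-line factor: gene g in
    module m has loading ``l_g = effect_sd * (0.3 + |N(0, 1)|)`` (a shifted
    half-normal, graded but bounded away from zero) and every replicate
    of line c reads ``baseline_g + l_g * f_{m,c} + noise``. Phenotype-linked
    modules draw the line factor around +1 for the linked phenotype and -1
    for the other, so module eigengenes separate phenotypes. Batch effects
    are per-(batch, gene) location shifts (multiplicative on the linear
    scale, hence additive in log2) and residual-scale distortions.

    Substream order: 0 baseline, 1 loadings, 2 factors, 3 noise, 4 batch,
    5 receptor labels.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(6)
    rng_base, rng_load, rng_fact, rng_noise, rng_batch, rng_label = (
        np.random.default_rng(s) for s in ss
    )

    n_lines = spec.n_cell_lines_ibc + spec.n_cell_lines_nibc
    lines = [f"IBC{i + 1:02d}" for i in range(spec.n_cell_lines_ibc)] + [
        f"NIBC{i + 1:02d}" for i in range(spec.n_cell_lines_nibc)
    ]
    phenos = ["IBC"] * spec.n_cell_lines_ibc + ["nIBC"] * spec.n_cell_lines_nibc
    genes = pd.Index([f"G{i + 1:05d}" for i in range(spec.n_genes)], name="gene_id")

    baseline = rng_base.normal(8.0, 1.5, size=spec.n_genes)

    # module membership: contiguous blocks from the top of the gene list
    truth = np.zeros(spec.n_genes, dtype=int)
    loadings = np.zeros(spec.n_genes)
    start = 0
    for m_idx, mod in enumerate(spec.modules, start=1):
        sl = slice(start, start + mod.size)
        truth[sl] = m_idx
        # shifted half-normal: graded memberships, but bounded away from zero
        # so every planted gene carries signal detectable at cohort scale
        loadings[sl] = mod.effect_sd * (
            0.3 + np.abs(rng_load.standard_normal(mod.size))
        )
        start += mod.size

    # per-(module, line) latent factors
    factors = np.zeros((len(spec.modules), n_lines))
    for m_idx, mod in enumerate(spec.modules):
        mean = np.zeros(n_lines)
        if mod.phenotype_link != "none":
            mean = np.where(
                np.array(phenos) == mod.phenotype_link,
                mod.phenotype_shift, -mod.phenotype_shift,
            )
        f = mean + rng_fact.normal(0.0, 1.0, size=n_lines)
        # decorrelate from earlier module factors (planted modules are
        # distinct by construction), then standardize across lines so
        # effect_sd is exactly the per-unit-loading signal scale
        for prev in range(m_idx):
            g = factors[prev]
            f = f - (f @ g) / (g @ g) * g
        factors[m_idx] = (f - f.mean()) / f.std(ddof=0)
        if mod.phenotype_link != "none":
            # keep the linked phenotype on the high side after standardizing
            linked = np.array(phenos) == mod.phenotype_link
            if factors[m_idx][linked].mean() < factors[m_idx][~linked].mean():
                factors[m_idx] *= -1.0

    n_samples = n_lines * spec.replicates_per_line
    sample_ids, batch, group, pheno_col = [], [], [], []
    values = np.empty((spec.n_genes, n_samples))
    col = 0
    for li, line in enumerate(lines):
        for r in range(spec.replicates_per_line):
            sid = f"{line}_r{r + 1}"
            sample_ids.append(sid)
            group.append(line)
            pheno_col.append(phenos[li])
            # replicates spread across batches so batch is crossed with line
            batch.append(f"B{(li + r) % spec.n_batches + 1}")
            signal = baseline.copy()
            for m_idx, mod in enumerate(spec.modules):
                mask = truth == (m_idx + 1)
                signal[mask] += loadings[mask] * factors[m_idx, li]
            values[:, col] = signal + rng_noise.normal(0.0, spec.noise_sd, spec.n_genes)
            col += 1

    # batch distortion: per-(batch, gene) multiplicative factor on the linear
    # scale (= additive log2 shift) plus a residual-scale distortion
    batches = sorted(set(batch))
    shift = {b: rng_batch.normal(0.0, spec.batch_shift_sd, spec.n_genes) for b in batches}
    scale = {
        b: np.exp(rng_batch.normal(0.0, spec.batch_scale_sd, spec.n_genes)) for b in batches
    }
    gene_means = values.mean(axis=1)
    for j, b in enumerate(batch):
        values[:, j] = (values[:, j] - gene_means) * scale[b] + gene_means + shift[b]

    er, her2 = [], []
    for ph in phenos:
        er.append("neg" if rng_label.random() < (0.9 if ph == "IBC" else 0.5) else "pos")
        her2.append("pos" if rng_label.random() < 0.3 else "neg")
    per_line = dict(zip(lines, zip(er, her2)))

    annotation = pd.DataFrame(
        {
            "batch": batch,
            "replicate_group": group,
            "phenotype": pheno_col,
            "ER": [per_line[g][0] for g in group],
            "PR": [per_line[g][0] for g in group],  # PR tracks ER in this generator
            "HER2": [per_line[g][1] for g in group],
            "subtype": ["unknown"] * n_samples,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=genes, columns=annotation.index)
    comp = ExpressionCompendium(df, annotation)
    comp.module_truth = pd.Series(truth, index=genes, name="module")
    comp.module_loadings = pd.Series(loadings, index=genes, name="loading")
    return comp


# ---------------------------------------------------------------------------
# perturbation catalog
# ---------------------------------------------------------------------------


def generate_perturbation_catalog(
    spec: CatalogSpec, module_profiles: pd.DataFrame
) -> PerturbationCatalog:
    """Simulate an L1000-like catalog of ranked differential-expression vectors.

    ``module_profiles`` is a genes x modules DataFrame giving each module's
    characteristic profile over the catalog's gene universe (e.g. a GMM
    column, or planted loadings). For a planted regulator of strength s the
    overexpression signature is ``s * profile + (1 - s) * noise`` and the
    knockdown signature ``-s * profile + (1 - s) * noise``; at strength 1 the
    knockdown is exactly the negated overexpression. Filler perturbagens and
    unplanted entries are independent standard-normal noise.

    Substream order: 0 planted noise, 1 filler.
    """
    planted_modules = [m for m, _ in spec.planted_regulators]
    for m in planted_modules:
        if m not in module_profiles.columns:
            raise KeyError(f"unknown module id {m!r} in planted_regulators")

    ss = np.random.SeedSequence(spec.seed).spawn(2)
    rng_plant, rng_fill = (np.random.default_rng(s) for s in ss)

    genes = module_profiles.index[: spec.n_signature_genes]
    if len(genes) < spec.n_signature_genes:
        raise ValueError("module_profiles has fewer genes than n_signature_genes")
    profiles = module_profiles.loc[genes]
    # standardize each profile so strength is comparable across modules
    profiles = (profiles - profiles.mean()) / profiles.std(ddof=0).replace(0.0, 1.0)

    cols, types, targets = {}, {}, {}
    for mod_id, strength in spec.planted_regulators:
        prof = profiles[mod_id].to_numpy()
        oe = strength * prof + (1 - strength) * rng_plant.standard_normal(len(genes))
        kd = -strength * prof + (1 - strength) * rng_plant.standard_normal(len(genes))
        reg = f"REG_{mod_id}"
        cols[f"{reg}_OE"] = oe
        cols[f"{reg}_KD"] = kd
        types[f"{reg}_OE"] = "overexpression"
        types[f"{reg}_KD"] = "knockdown"
        targets[f"{reg}_OE"] = targets[f"{reg}_KD"] = ""

    reg_module = {f"REG_{m}_OE": m for m, _ in spec.planted_regulators}
    for target_id, drug_id, strength in spec.planted_drug_pairs:
        if target_id not in reg_module:
            raise KeyError(f"planted drug target {target_id!r} is not a planted OE entry")
        prof = profiles[reg_module[target_id]].to_numpy()
        cols[drug_id] = -strength * prof + (1 - strength) * rng_plant.standard_normal(len(genes))
        types[drug_id] = "drug"
        targets[drug_id] = target_id

    n_fill = spec.n_perturbagens - len(cols)
    if n_fill < 0:
        raise ValueError("n_perturbagens smaller than number of planted entries")
    for i in range(n_fill):
        pid = f"FILL{i + 1:03d}"
        cols[pid] = rng_fill.standard_normal(len(genes))
        types[pid] = "drug" if i % 3 == 0 else ("overexpression" if i % 3 == 1 else "knockdown")
        targets[pid] = ""

    signatures = pd.DataFrame(cols, index=genes)
    meta = pd.DataFrame(
        {"type": pd.Series(types), "target": pd.Series(targets)}
    ).loc[signatures.columns]
    meta.index.name = "perturbagen"
    return PerturbationCatalog(signatures, meta)


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

_STAGE_P = {"low": (0.5, 0.4, 0.1), "moderate": (0.4, 0.4, 0.2), "high": (0.3, 0.4, 0.3)}
_SUBTYPE_P = {
    "low": (0.1, 0.3, 0.6),   # (LumA, Her2, Basal)
    "moderate": (0.4, 0.3, 0.3),
    "high": (0.7, 0.2, 0.1),
}


def generate_patient_cohort(spec: CohortSpec) -> PatientCohort:
    """Simulate a two-phenotype patient cohort with nested MYC~ER structure.

    ESR1 is continuous; ER strata are exact tertiles of ESR1 *within* each
    phenotype, so the six phenotype x stratum cells are populated and
    balanced to within one sample. MYC is the nIBC/ER-low reference mean
    plus the five spec coefficients per cell plus Gaussian noise. Each PMN
    member is generated via a Gaussian copula against the standardized MYC
    residual scale so its population Spearman correlation with MYC matches
    the requested target. Stage and subtype are drawn with ER-stratum-
    dependent frequencies (higher ER leans luminal and lower stage).

    Substream order: 0 ESR1, 1 MYC noise, 2 PMN, 3 labels, 4 activity.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(5)
    rng_esr, rng_myc, rng_pmn, rng_lab, rng_act = (np.random.default_rng(s) for s in ss)

    n = spec.n_ibc + spec.n_nibc
    phenotype = np.array(["IBC"] * spec.n_ibc + ["nIBC"] * spec.n_nibc)
    esr1 = np.where(phenotype == "IBC",
                    rng_esr.normal(5.5, 1.5, n),
                    rng_esr.normal(6.5, 1.5, n))

    from .classifier import stratify_tertiles  # local import avoids cycle

    stratum = np.empty(n, dtype=object)
    for ph in ("IBC", "nIBC"):
        mask = phenotype == ph
        stratum[mask] = stratify_tertiles(pd.Series(esr1[mask])).to_numpy()
    for ph in ("IBC", "nIBC"):
        for s in ("low", "moderate", "high"):
            if not np.any((phenotype == ph) & (stratum == s)):
                raise ValueError(f"empty stratum {ph}/{s} after assignment")

    offset = {
        ("nIBC", "low"): 0.0,
        ("nIBC", "moderate"): spec.coef_nibc_er_mod,
        ("nIBC", "high"): spec.coef_nibc_er_high,
        ("IBC", "low"): spec.coef_ibc_er_low,
        ("IBC", "moderate"): spec.coef_ibc_er_low + spec.coef_ibc_er_mod,
        ("IBC", "high"): spec.coef_ibc_er_low + spec.coef_ibc_er_high,
    }
    mu = np.array([spec.reference_mean + offset[(p, s)] for p, s in zip(phenotype, stratum)])
    z_myc = rng_myc.standard_normal(n)
    myc = mu + spec.noise_sd * z_myc

    # PMN members: Gaussian copula against z_myc; the Pearson correlation of
    # the latent normals that yields a Spearman rho_s is 2 sin(pi rho_s / 6)
    pmn = {}
    for gene, rho_s in spec.pmn_cor_targets.items():
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        z = r * z_myc + np.sqrt(1.0 - r * r) * rng_pmn.standard_normal(n)
        pmn[gene] = 7.0 + z  # arbitrary log2 location

    stage = np.array([
        rng_lab.choice(["I-II", "III", "IV"], p=_STAGE_P[s]) for s in stratum
    ])
    subtype = np.array([
        rng_lab.choice(["LumA", "Her2", "Basal"], p=_SUBTYPE_P[s]) for s in stratum
    ])

    # MYC transcriptional activity tracks expression with independent noise
    activity = 0.7 * (myc - myc.mean()) / myc.std(ddof=0) + 0.5 * rng_act.standard_normal(n)

    data = pd.DataFrame(
        {
            "ESR1": esr1,
            "MYC": myc,
            **pmn,
            "activity_myc": activity,
            "phenotype": phenotype,
            "er_stratum": stratum,
            "stage": stage,
            "subtype": subtype,
        },
        index=pd.Index([f"P{i + 1:04d}" for i in range(n)], name="sample_id"),
    )
    return PatientCohort(data, pmn_members=tuple(spec.pmn_cor_targets))
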