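"""End-to-end benchmark scenarios exercising the whole pipeline.

Each function builds its inputs with the synthetic generators at the stated
study conditions, runs the relevant pipeline stage(s), and returns summary
quantities. Problem sizes are desk scale: gene counts in the hundreds to a
thousand and cell-line counts matching the study design (10 IBC + 22 nIBC
lines, triplicate profiles), which keeps every scenario tractable on a
single CPU while preserving the statistical structure the methods assume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import adjusted_rand_score

from . import (
    CatalogSpec,
    CohortSpec,
    CompendiumSpec,
    ModuleSpec,
    QuerySignature,
    bh_adjust,
    build_bipartite_adjacency,
    build_network,
    connectivity_score,
    correct_batch,
    fit_nested_interaction,
    generate_cell_line_compendium,
    generate_patient_cohort,
    minimal_connecting_modules,
    moderated_t_test,
    module_preservation,
    ora_hypergeometric,
    preranked_gsea,
    quantile_normalize,
    train_elastic_net,
)
from ._ks import enrichment_score, order_by_value
from .interaction import COEF_NAMES
from .network import ModuleAssignment


def _sub(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# module recovery
# ---------------------------------------------------------------------------


def module_recovery(seed: int = 0) -> dict:
    """ARI of the bicor -> power -> TOM -> detect chain on planted modules.

    Conditions: 3 modules x 150 genes among 1000, effect_sd/noise_sd = 2,
    10 lines x 3 replicates.
    """
    spec = CompendiumSpec(
        seed=_sub(seed, 1), n_genes=1000,
        modules=(ModuleSpec(150, 2.0, "IBC"), ModuleSpec(150, 2.0, "none"),
                 ModuleSpec(150, 2.0, "none")),
        n_cell_lines_ibc=5, n_cell_lines_nibc=5,
        replicates_per_line=3, noise_sd=1.0,
    )
    comp = generate_cell_line_compendium(spec)
    params, assignment, _ = build_network(comp.values, min_size=100)
    ari = adjusted_rand_score(comp.module_truth, assignment.labels)
    return {"ari": float(ari), "beta": params.beta,
            "n_modules": int(len(assignment.sizes)), "n_genes": 1000}


# ---------------------------------------------------------------------------
# preservation discrimination
# ---------------------------------------------------------------------------


def preservation_discrimination(seed: int = 0, n_seeds: int = 100,
                                n_perm: int = 200) -> dict:
    """Zsummary for a module planted in both data sets vs permuted test data."""
    planted, permuted = [], []
    for i in range(n_seeds):
        spec = CompendiumSpec(
            seed=_sub(seed, 100 + i), n_genes=500,
            modules=(ModuleSpec(150, 2.0, "none"),),
            n_cell_lines_ibc=5, n_cell_lines_nibc=11,
            replicates_per_line=3, noise_sd=1.0,
        )
        comp = generate_cell_line_compendium(spec)
        ann = comp.annotation
        ref = comp.values[ann.index[ann.phenotype == "IBC"]]
        test = comp.values[ann.index[ann.phenotype == "nIBC"]]
        assignment = ModuleAssignment(labels=pd.Series(comp.module_truth))
        rep = module_preservation(assignment, ref, test, beta=12,
                                  n_perm=n_perm, seed=_sub(seed, 300 + i))
        planted.append(float(rep.table.loc[1, "Zsummary"]))
        rng = np.random.default_rng(_sub(seed, 500 + i))
        test_perm = test.copy()
        test_perm.index = rng.permutation(test.index)
        rep2 = module_preservation(assignment, ref, test_perm, beta=12,
                                   n_perm=n_perm, seed=_sub(seed, 700 + i))
        permuted.append(float(rep2.table.loc[1, "Zsummary"]))
    planted = np.asarray(planted)
    permuted = np.asarray(permuted)
    return {
        "planted_rate": float((planted >= 10).mean()),
        "permuted_rate": float((permuted < 2).mean()),
        "planted_median_z": float(np.median(planted)),
        "permuted_median_z": float(np.median(permuted)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# connectivity exactness
# ---------------------------------------------------------------------------


def connectivity_exactness(seed: int = 0, n_signatures: int = 50,
                           n_null: int = 1000) -> dict:
    rng = np.random.default_rng(_sub(seed, 11))
    genes = [f"g{i:04d}" for i in range(1000)]
    self_scores, neg_scores = [], []
    for _ in range(n_signatures):
        sig = pd.Series(rng.standard_normal(1000), index=genes)
        order = order_by_value(sig)
        q = QuerySignature(up=tuple(order[:150]), down=tuple(order[-150:]),
                           module="Q")
        self_scores.append(connectivity_score(q, sig))
        neg_scores.append(connectivity_score(q, -sig))
    base = pd.Series(rng.standard_normal(1000), index=genes)
    order = order_by_value(base)
    q = QuerySignature(up=tuple(order[:150]), down=tuple(order[-150:]), module="Q")
    null = [connectivity_score(q, pd.Series(rng.standard_normal(1000), index=genes))
            for _ in range(n_null)]
    return {
        "self_min": float(min(self_scores)),
        "self_max": float(max(self_scores)),
        "negated_min": float(min(neg_scores)),
        "negated_max": float(max(neg_scores)),
        "null_mean": float(np.mean(null)),
        "n_null": n_null,
    }


# ---------------------------------------------------------------------------
# prioritization oracle agreement
# ---------------------------------------------------------------------------


def prioritization_agreement(seed: int = 0, n_graphs: int = 100) -> dict:
    import networkx as nx

    from .prioritize import _canonical_mst

    rng = np.random.default_rng(_sub(seed, 17))
    total = agree = 0
    while total < n_graphs:
        nm, nc = int(rng.integers(2, 6)), int(rng.integers(2, 4))
        mods = [f"M{i}" for i in range(nm)]
        lines = [f"C{i}" for i in range(nc)]
        corr = pd.DataFrame(rng.uniform(-1, 1, (nm, nm)), index=mods, columns=mods)
        corr = (corr + corr.T) / 2
        expr = pd.DataFrame(rng.uniform(-1, 1, (nm, nc)), index=mods, columns=lines)
        adjacency = build_bipartite_adjacency(corr, expr)
        try:
            _, modules = minimal_connecting_modules(adjacency, lines)
        except ValueError:
            continue
        total += 1
        tree = _canonical_mst(adjacency.graph)
        nodes = set(lines)
        for i in range(len(lines)):
            for j in range(i + 1, len(lines)):
                nodes.update(nx.shortest_path(tree, lines[i], lines[j]))
        oracle = tuple(sorted(
            n for n in nodes if adjacency.graph.nodes[n]["kind"] == "module"
        ))
        agree += oracle == modules
    return {"agreement": float(agree / total), "n_graphs": total}


# ---------------------------------------------------------------------------
# statistical oracles
# ---------------------------------------------------------------------------


def statistical_oracles(seed: int = 0, n_fdr_seeds: int = 100) -> dict:
    """Brute-force cross-checks of the elementary statistics, plus a null
    FDR simulation for the BH-controlled moderated test."""
    rng = np.random.default_rng(_sub(seed, 23))

    # moderated t vs literal posterior-variance formula on a 20-gene fixture
    values = pd.DataFrame(rng.normal(8, 1, size=(20, 10)),
                          index=[f"g{i}" for i in range(20)])
    groups = pd.Series(["IBC"] * 5 + ["nIBC"] * 5, index=values.columns)
    res = moderated_t_test(values, groups)
    g1 = values.loc[:, groups == "IBC"].to_numpy()
    g2 = values.loc[:, groups == "nIBC"].to_numpy()
    dg = 8
    s2 = (((g1 - g1.mean(1, keepdims=True)) ** 2).sum(1)
          + ((g2 - g2.mean(1, keepdims=True)) ** 2).sum(1)) / dg
    e = np.log(s2) - special.digamma(dg / 2) + np.log(dg / 2)
    excess = e.var(ddof=1) - special.polygamma(1, dg / 2)
    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > excess:
            lo = mid
        else:
            hi = mid
    d0 = 2 * lo if excess > 0 else np.inf
    s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2)) \
        if np.isfinite(d0) else np.exp(e.mean())
    post = (d0 * s0 + dg * s2) / (d0 + dg) if np.isfinite(d0) else np.full_like(s2, s0)
    t_bf = (g1.mean(1) - g2.mean(1)) / np.sqrt(post * (1 / 5 + 1 / 5))
    t_err = float(np.max(np.abs(res.table["t_moderated"].to_numpy() - t_bf)))

    # BH vs step-up definition
    bh_err = 0.0
    for _ in range(50):
        p = rng.random(int(rng.integers(2, 40)))
        adj = bh_adjust(pd.Series(p)).to_numpy()
        m = len(p)
        order = np.argsort(p)
        raw = p[order] * m / np.arange(1, m + 1)
        mono = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(mono, 1.0)
        bh_err = max(bh_err, float(np.max(np.abs(adj - expected))))

    # hypergeometric ORA vs direct pmf summation
    universe = [f"u{i}" for i in range(60)]
    ora_err = 0.0
    for _ in range(20):
        module = list(rng.choice(universe, 15, replace=False))
        hits = list(rng.choice(universe, 12, replace=False))
        _, p = ora_hypergeometric(hits, module, universe)
        a = len(set(hits) & set(module))
        direct = float(sum(stats.hypergeom.pmf(k, 60, 15, 12) for k in range(a, 13)))
        ora_err = max(ora_err, abs(p - direct))

    # GSEA ES vs literal running sum on 50-gene fixtures
    es_err = 0.0
    for _ in range(20):
        vals = pd.Series(rng.standard_normal(50), index=[f"g{i}" for i in range(50)])
        ranked = vals.loc[order_by_value(vals)]
        hit = set(rng.choice(vals.index, 8, replace=False))
        running, best, tot = 0.0, 0.0, sum(abs(ranked[g]) for g in hit)
        for g, v in ranked.items():
            running += abs(v) / tot if g in hit else -1.0 / 42
            if abs(running) > abs(best):
                best = running
        es_err = max(es_err, abs(enrichment_score(ranked, hit) - best))

    # null FDR simulation: 200 genes, no effect, BH at 10%
    fracs = []
    for i in range(n_fdr_seeds):
        r = np.random.default_rng(_sub(seed, 900 + i))
        vals = pd.DataFrame(r.normal(size=(200, 10)),
                            index=[f"g{i}" for i in range(200)])
        grp = pd.Series(["A"] * 5 + ["B"] * 5, index=vals.columns)
        out = moderated_t_test(vals, grp)
        fracs.append(float((out.table["p_adj"] < 0.10).mean()))

    return {
        "moderated_t_max_err": t_err,
        "bh_max_err": bh_err,
        "ora_max_err": ora_err,
        "gsea_es_max_err": es_err,
        "null_fdr_mean": float(np.mean(fracs)),
        "n_fdr_seeds": n_fdr_seeds,
    }


# ---------------------------------------------------------------------------
# interaction-model recovery
# ---------------------------------------------------------------------------


def interaction_recovery(seed: int = 0, n_seeds: int = 100) -> dict:
    truth = np.array([-0.754, -0.931, -0.832, 0.599, 1.414])

    cohort0 = generate_patient_cohort(CohortSpec(seed=_sub(seed, 31), noise_sd=1e-12))
    d0 = cohort0.data
    fit0 = fit_nested_interaction(d0["MYC"], d0["phenotype"], d0["er_stratum"])
    zero_noise_err = float(np.max(np.abs(
        fit0.params[list(COEF_NAMES)].to_numpy() - truth
    )))

    within = np.zeros(5)
    estimates = []
    for i in range(n_seeds):
        cohort = generate_patient_cohort(CohortSpec(seed=_sub(seed, 1300 + i)))
        d = cohort.data
        fit = fit_nested_interaction(d["MYC"], d["phenotype"], d["er_stratum"])
        est = fit.params[list(COEF_NAMES)].to_numpy()
        se = fit.bse[list(COEF_NAMES)].to_numpy()
        within += (np.abs(est - truth) <= 2 * se)
        estimates.append(est)
    mean_est = np.mean(estimates, axis=0)
    out = {
        "zero_noise_max_err": zero_noise_err,
        "min_within_2se_rate": float(within.min() / n_seeds),
        "n_seeds": n_seeds,
        "n_cohort": 398,
    }
    for name, val in zip(COEF_NAMES, mean_est):
        key = name.lower().replace(":", "_").replace("-", "_")
        out[f"coef_{key}"] = float(val)
    return out


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


def classifier_metrics(seed: int = 0, n_perm_seeds: int = 100) -> dict:
    spec = CompendiumSpec(
        seed=_sub(seed, 41), n_genes=120,
        modules=(ModuleSpec(40, 2.0, "IBC", phenotype_shift=3.0),),
        n_cell_lines_ibc=10, n_cell_lines_nibc=22,
        replicates_per_line=3, noise_sd=0.2,
    )
    comp = generate_cell_line_compendium(spec)
    sig = list(comp.module_truth.index[comp.module_truth == 1])
    model = train_elastic_net(
        comp.values, comp.annotation["phenotype"], sig,
        alpha_grid=(0.0, 0.5, 1.0), lambda_grid=(0.001, 0.01, 0.1),
        repeats=1, seed=_sub(seed, 43),
    )

    in_band = 0
    for i in range(n_perm_seeds):
        s = _sub(seed, 2100 + i)
        pspec = CompendiumSpec(
            seed=s, n_genes=60,
            modules=(ModuleSpec(20, 2.0, "IBC", phenotype_shift=3.0),),
            n_cell_lines_ibc=150, n_cell_lines_nibc=150,
            replicates_per_line=1, noise_sd=0.5,
        )
        pcomp = generate_cell_line_compendium(pspec)
        rng = np.random.default_rng(s)
        y = pd.Series(rng.permutation(pcomp.annotation["phenotype"].to_numpy()),
                      index=pcomp.annotation.index)
        psig = list(pcomp.module_truth.index[pcomp.module_truth == 1])
        m = train_elastic_net(pcomp.values, y, psig, alpha_grid=(0.0, 1.0),
                              lambda_grid=(0.01, 0.1), repeats=2, seed=s)
        auc = float(m.cv_auroc.loc[m.alpha, m.lam])
        in_band += 0.4 <= auc <= 0.6
    return {
        "validation_accuracy": float(model.validation_accuracy),
        "permuted_auroc_in_band_rate": float(in_band / n_perm_seeds),
        "n_perm_seeds": n_perm_seeds,
    }


# ---------------------------------------------------------------------------
# preprocessing contracts
# ---------------------------------------------------------------------------


def preprocess_contracts(seed: int = 0) -> dict:
    rng = np.random.default_rng(_sub(seed, 53))
    vals = pd.DataFrame(rng.normal(8, 2, size=(200, 12)),
                        index=[f"g{i}" for i in range(200)],
                        columns=[f"s{i}" for i in range(12)])
    qn = quantile_normalize(vals).to_numpy()
    ref = np.sort(qn[:, 0])
    qn_gap = max(float(np.max(np.abs(np.sort(qn[:, j]) - ref)))
                 for j in range(1, qn.shape[1]))

    spec = CompendiumSpec(
        seed=_sub(seed, 59), n_genes=300,
        modules=(ModuleSpec(80, 2.0, "IBC"),),
        n_cell_lines_ibc=8, n_cell_lines_nibc=8,
        n_batches=2, batch_shift_sd=1.0,
    )
    comp = generate_cell_line_compendium(spec)
    adj = correct_batch(comp.values, comp.annotation["batch"],
                        comp.annotation[["replicate_group"]])
    b = pd.get_dummies(comp.annotation["batch"]).to_numpy(dtype=float)
    fracs = []
    for g in range(adj.shape[0]):
        y = adj.iloc[g].to_numpy()
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(b, yc, rcond=None)
        fracs.append(1 - ((yc - b @ beta) ** 2).sum() / (yc ** 2).sum())

    # planted phenotype effect on module genes: sign before vs after
    pheno = (comp.annotation["phenotype"] == "IBC").to_numpy()
    module = (comp.module_truth == 1).to_numpy()
    before = comp.values.loc[module].T.groupby(pheno).mean()
    after = adj.loc[module].T.groupby(pheno).mean()
    sign_before = np.sign(before.loc[True] - before.loc[False])
    sign_after = np.sign(after.loc[True] - after.loc[False])
    return {
        "quantile_max_gap": qn_gap,
        "batch_variance_fraction": float(np.mean(fracs)),
        "effect_sign_preserved_fraction": float((sign_before == sign_after).mean()),
        "n_genes": 300,
    }
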