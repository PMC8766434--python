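"""Connectivity-map-style screening of module queries against a perturbation
catalog.

Each module query is 150 up + 150 down marker genes taken from the extremes
of its GMM column. The connectivity score against a ranked perturbation
signature is the weighted-KS two-sided statistic scaled to [-100, 100]:
CS = 100 (ES_up - ES_down) / 2 when the two enrichment scores have opposite
signs, else 0. Positive CS means the perturbation's response is congruent
with the module profile. Regulators are genes scoring >= +75 on
overexpression and <= -75 on knockdown (difference >= 150 with both bounds
met); drug/target pairs need the drug strictly below -75 and its declared
target's overexpression strictly above +75.

The score here is the raw scaled weighted-KS connectivity; no reference
(touchstone) tau-normalization is applied, and the 75/150 decision
thresholds operate on this score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ks import enrichment_score, order_by_value
from .containers import PerturbationCatalog

logger = logging.getLogger(__name__)


@dataclass
class QuerySignature:
    up: tuple
    down: tuple
    module: str

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down sets must be disjoint")


def make_query(gmm_column: pd.Series, module: str = "", n_each: int = 150,
               allow_small: bool = False) -> QuerySignature:
    """Top/bottom ``n_each`` genes of a GMM column as the module query.

    Ties at the boundary break by gene id (lexicographically smaller id
    ranks higher). With fewer than ``2 * n_each`` finite genes, errors
    unless ``allow_small``, in which case proportional halves are used.
    """
    col = gmm_column.dropna()
    if len(col) < 2 * n_each:
        if not allow_small:
            raise ValueError(
                f"need >= {2 * n_each} genes with finite GMM, got {len(col)}"
            )
        n_each = len(col) // 2
        logger.warning("small universe: using %d genes per side", n_each)
    order = order_by_value(col)
    up = tuple(order[:n_each])
    down = tuple(order[len(order) - n_each:][::-1])
    return QuerySignature(up=up, down=down, module=module or str(gmm_column.name))


def connectivity_score(query: QuerySignature, signature: pd.Series,
                       weight_exponent: float = 1.0) -> float:
    """Connectivity score of a query against one ranked signature."""
    missing = [g for g in (*query.up, *query.down) if g not in signature.index]
    if missing:
        raise KeyError(f"query genes missing from signature: {missing[:10]}")
    ranked = signature.loc[order_by_value(signature)]
    es_up = enrichment_score(ranked, query.up, weight_exponent)
    es_down = enrichment_score(ranked, query.down, weight_exponent)
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    cs = 100.0 * (es_up - es_down) / 2.0
    # the running sums are exactly +/-1 at the extremes; clip accumulated
    # floating-point excess so the bounds are exact
    return float(np.clip(cs, -100.0, 100.0))


def screen_catalog(
    queries: list, catalog: PerturbationCatalog, weight_exponent: float = 1.0
) -> pd.DataFrame:
    """All (query, perturbagen) connectivity records as a tidy table."""
    rows = []
    for q in queries:
        for pid in catalog.signatures.columns:
            cs = connectivity_score(q, catalog.signatures[pid], weight_exponent)
            rows.append({
                "query": q.module, "perturbagen": pid,
                "type": catalog.meta.loc[pid, "type"],
                "target": catalog.meta.loc[pid, "target"],
                "cs": cs,
            })
    return pd.DataFrame(rows)


def _base_gene(pid: str) -> str:
    """Strip the _OE/_KD suffix used to pair genetic perturbagens."""
    for suf in ("_OE", "_KD"):
        if pid.endswith(suf):
            return pid[: -len(suf)]
    return pid


def find_regulators(records: pd.DataFrame, oe_cut: float = 75.0,
                    kd_cut: float = -75.0) -> pd.DataFrame:
    """Genes with CS >= oe_cut on overexpression and CS <= kd_cut on knockdown.

    Candidates without both an overexpression and a knockdown record for a
    query are skipped with a warning. Deterministic: pure filtering.
    """
    out = []
    gen = records[records["type"].isin(["overexpression", "knockdown"])].copy()
    gen["gene"] = gen["perturbagen"].map(_base_gene)
    for (query, gene), sub in gen.groupby(["query", "gene"], sort=True):
        oe = sub.loc[sub["type"] == "overexpression", "cs"]
        kd = sub.loc[sub["type"] == "knockdown", "cs"]
        if oe.empty or kd.empty:
            logger.warning("unpaired candidate %s for query %s skipped", gene, query)
            continue
        cs_oe, cs_kd = float(oe.iloc[0]), float(kd.iloc[0])
        if cs_oe >= oe_cut and cs_kd <= kd_cut:
            out.append({"query": query, "gene": gene, "cs_oe": cs_oe,
                        "cs_kd": cs_kd, "difference": cs_oe - cs_kd})
    return pd.DataFrame(out, columns=["query", "gene", "cs_oe", "cs_kd", "difference"])


def find_drug_target_pairs(records: pd.DataFrame, drug_cut: float = -75.0,
                           target_cut: float = 75.0) -> pd.DataFrame:
    """Drug/target pairs: drug CS strictly below drug_cut, declared target's
    overexpression CS strictly above target_cut, per query."""
    out = []
    drugs = records[records["type"] == "drug"]
    oes = records[records["type"] == "overexpression"].set_index(
        ["query", "perturbagen"]
    )["cs"]
    for _, row in drugs.iterrows():
        target = row["target"]
        if not target:
            continue
        key = (row["query"], target)
        if key not in oes.index:
            logger.warning("drug %s declares unknown target %s; skipped",
                           row["perturbagen"], target)
            continue
        cs_t = float(oes.loc[key])
        if row["cs"] < drug_cut and cs_t > target_cut:
            out.append({"query": row["query"], "drug": row["perturbagen"],
                        "target": target, "cs_drug": float(row["cs"]),
                        "cs_target_oe": cs_t})
    return pd.DataFrame(out, columns=["query", "drug", "target", "cs_drug",
                                      "cs_target_oe"])
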