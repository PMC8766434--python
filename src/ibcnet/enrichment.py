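"""Preranked gene-set enrichment, hypergeometric over-representation, and
single-sample activity scoring.

The activity score replaces kernel-density single-sample enrichment with a
rank-sum z statistic: per sample, genes are ranked and the set's mean rank
is standardized by its exact null moments,

    z = (meanrank_S - (G+1)/2) / sqrt((G+1)(G-|S|) / (12 |S|)),

which is monotone-invariant per sample and has a closed-form standard-normal
null for iid genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ks import enrichment_score, enrichment_scores_at, order_by_value
from .diffexpr import bh_adjust


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: size, es, nes, p, p_adj, leading_edge
    n_perm: int


def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: list of gene ids}."""
    from gseapy.parser import read_gmt as _read

    return _read(str(path))


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + [str(g) for g in genes]) + "\n")


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: dict,
    n_perm: int = 1000,
    min_overlap: int = 5,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted-KS preranked GSEA with gene-label permutation.

    NES = ES / mean |ES| over same-sign permutation scores; p is the
    same-sign permutation tail with a +1 pseudocount; BH across sets.
    """
    rng = np.random.default_rng(seed)
    ranked = ranking.loc[order_by_value(ranking)]
    universe = set(ranked.index)
    genes_arr = ranked.index.to_numpy()

    rows = []
    for name, genes in gene_sets.items():
        hit = [g for g in set(genes) if g in universe]
        if len(hit) == 0:
            raise ValueError(f"gene set {name!r} is disjoint from the ranking")
        if len(hit) < min_overlap:
            continue
        es = enrichment_score(ranked, hit, weight_exponent)
        perm_pos = np.stack([
            rng.choice(len(genes_arr), size=len(hit), replace=False)
            for _ in range(n_perm)
        ])
        perm_es = enrichment_scores_at(
            ranked.to_numpy(dtype=float), perm_pos, weight_exponent
        )
        same = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        denom = np.abs(same).mean() if len(same) else np.abs(perm_es).mean()
        nes = es / denom if denom > 0 else 0.0
        n_ge = int((np.abs(same) >= abs(es)).sum()) if len(same) else n_perm
        p = (n_ge + 1) / (len(same) + 1) if len(same) else 1.0
        # leading edge: hits at or before the ES extremum
        hits_mask = ranked.index.isin(set(hit))
        lead = _leading_edge_size(ranked, hit, es, weight_exponent, hits_mask)
        rows.append({"set": name, "size": len(hit), "es": es, "nes": nes,
                     "p": p, "leading_edge": lead})
    table = pd.DataFrame(rows).set_index("set")
    if len(table):
        table["p_adj"] = bh_adjust(table["p"])
    return EnrichmentResult(table=table, n_perm=n_perm)


def _leading_edge_size(ranked, hit, es, weight_exponent, hits_mask) -> int:
    vals = ranked.to_numpy(dtype=float)
    w = np.abs(vals) ** weight_exponent
    wh = np.where(hits_mask, w, 0.0)
    tot = wh.sum() or float(hits_mask.sum())
    inc = (wh / tot) if wh.sum() else hits_mask / tot
    dec = np.where(hits_mask, 0.0, 1.0 / (len(vals) - hits_mask.sum()))
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    if es >= 0:
        return int(hits_mask[: i + 1].sum())
    return int(hits_mask[i:].sum())


def ora_hypergeometric(hits, module_genes, universe) -> tuple[float, float]:
    """Over-representation of ``hits`` in ``module_genes`` within ``universe``.

    Returns (odds ratio, upper-tail hypergeometric p = P(X >= overlap)).
    The 2x2 odds ratio uses the Haldane 0.5 correction when a cell is zero;
    degenerate margins (module or hits spanning the whole universe, or
    empty) are defined as OR = 1, p = 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    module = set(module_genes) & universe
    G, H, M = len(universe), len(hits), len(module)
    a = len(hits & module)
    if M in (0, G) or H in (0, G):
        return 1.0, 1.0
    p = float(stats.hypergeom.sf(a - 1, G, M, H))
    b = M - a
    c = H - a
    d = G - M - c
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return float(a2 * d2 / (b2 * c2)), p


def activity_score(values: pd.DataFrame, gene_set, min_overlap: int = 5) -> pd.Series:
    """Rank-sum z activity of a gene set per sample (higher = more active)."""
    genes = [g for g in set(gene_set) if g in values.index]
    if len(genes) < min_overlap:
        raise ValueError(
            f"only {len(genes)} set genes present in the matrix (need >= {min_overlap})"
        )
    G = values.shape[0]
    S = len(genes)
    ranks = values.rank(axis=0, method="average")
    mean_rank = ranks.loc[genes].mean(axis=0)
    null_mean = (G + 1) / 2.0
    null_sd = np.sqrt((G + 1) * (G - S) / (12.0 * S))
    return ((mean_rank - null_mean) / null_sd).rename("activity")
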