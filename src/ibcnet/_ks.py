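"""Weighted Kolmogorov-Smirnov running-sum enrichment kernel.

Shared by connectivity scoring and preranked GSEA. Genes are ordered by
signature/ranking value (descending, ties broken by gene id); walking down
the list, a hit adds its weight |value|^w / sum(hit weights) and a miss
subtracts 1 / (N - n). The enrichment score is the running sum at the point
of maximal absolute deviation (the first such point on exact ties).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def order_by_value(values: pd.Series) -> pd.Index:
    """Descending value order with deterministic gene-id tie-break."""
    df = pd.DataFrame({"v": values})
    df["g"] = df.index.astype(str)
    return df.sort_values(["v", "g"], ascending=[False, True]).index


def enrichment_score(
    ranked_values: pd.Series, hit_genes, weight_exponent: float = 1.0
) -> float:
    """Signed weighted-KS enrichment score of ``hit_genes`` in a ranking.

    ``ranked_values`` must already be in walk order (use
    :func:`order_by_value`). ``weight_exponent`` 0 gives the unweighted
    (classic KS) statistic.
    """
    vals = ranked_values.to_numpy(dtype=float)
    hits = ranked_values.index.isin(set(hit_genes))
    n, nh = len(vals), int(hits.sum())
    if nh == 0 or nh == n:
        raise ValueError("hit set must be a proper non-empty subset of the ranking")
    w = np.abs(vals) ** weight_exponent
    wh = np.where(hits, w, 0.0)
    tot = wh.sum()
    if tot == 0:  # all hit weights zero: fall back to uniform increments
        wh = hits.astype(float)
        tot = float(nh)
    inc = wh / tot
    dec = np.where(hits, 0.0, 1.0 / (n - nh))
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def enrichment_scores_at(
    weights: np.ndarray, positions: np.ndarray, weight_exponent: float = 1.0
) -> np.ndarray:
    """Vectorized enrichment scores for many hit-position sets at once.

    ``weights`` are the ranking values in walk order; ``positions`` is an
    (n_sets x h) integer array of 0-based hit positions per set. The running
    deviation is piecewise linear with breakpoints just before and just
    after each hit, so the extremum over the full walk equals the extremum
    over those 2h candidates; this reproduces the cumsum kernel exactly.
    """
    w = np.abs(np.asarray(weights, dtype=float)) ** weight_exponent
    n = len(w)
    pos = np.sort(np.asarray(positions, dtype=int), axis=1)
    h = pos.shape[1]
    wh = w[pos]
    cum = np.cumsum(wh, axis=1)
    tot = cum[:, -1:]
    degenerate = (tot == 0).ravel()
    if degenerate.any():  # all-zero hit weights: uniform increments
        cum[degenerate] = np.arange(1, h + 1)[None, :]
        tot = np.where(tot == 0, float(h), tot)
    k = np.arange(h)[None, :]
    miss = 1.0 / (n - h)
    after = cum / tot - (pos - k) * miss          # just after the k-th hit
    before = (cum - wh) / tot - (pos - k) * miss  # just before the k-th hit
    cand = np.empty((pos.shape[0], 2 * h))
    cand[:, 0::2] = before
    cand[:, 1::2] = after
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(pos.shape[0]), idx]
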