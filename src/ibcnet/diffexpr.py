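"""Moderated two-group differential expression and percentile-based paired
comparison.

The moderated test shrinks per-gene residual variances toward a common prior
estimated by moment-matching the marginal distribution of log sample
variances (the scaled-F marginal of the hierarchical normal/inverse-gamma
model): with residual df d_g, e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)
has variance trigamma(d0/2) + trigamma(d_g/2), giving d0 by inverting the
trigamma function and s0^2 from the mean of e_g. The posterior variance is
s~^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g) and the moderated t is referred to
a t distribution with d0 + d_g degrees of freedom. This closed-form moment
estimator is a deliberate simplification of the full empirical-Bayes
machinery and is exact in the two extremes (d0 -> 0 and d0 -> infinity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import DEFAULT_EXPRESSION_THRESHOLD


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame  # logFC, t_ordinary, t_moderated, p, p_adj per gene
    d0: float
    s0_sq: float


@dataclass
class PairedPercentileResult:
    differences: pd.Series
    upper_cut: float
    lower_cut: float
    high_in_a: tuple  # genes strictly above the upper cut (higher in profile_a)
    high_in_b: tuple  # genes strictly below the lower cut


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderated_t_test(values: pd.DataFrame, groups: pd.Series) -> ModeratedTestResult:
    """Empirical-Bayes moderated two-group t-test per gene.

    ``groups`` must contain exactly two levels; the reported log fold change
    is first level IBC minus nIBC when those labels are present, otherwise
    the lexicographically larger level minus the smaller.
    """
    groups = groups.loc[values.columns]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if "IBC" in levels and "nIBC" in levels:
        g1, g2 = "IBC", "nIBC"
    else:
        g2, g1 = levels
    X1 = values.loc[:, groups == g1].to_numpy()
    X2 = values.loc[:, groups == g2].to_numpy()
    n1, n2 = X1.shape[1], X2.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")
    dg = n1 + n2 - 2
    if dg <= 0:
        raise ValueError("zero residual degrees of freedom")

    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / dg
    logfc = m1 - m2
    sed = np.sqrt(1.0 / n1 + 1.0 / n2)

    pos = s2 > 0
    if not pos.any():
        raise ValueError("all residual variances are zero")
    e = np.log(s2[pos]) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    var_e = float(np.var(e, ddof=1)) if pos.sum() > 1 else 0.0
    excess = var_e - float(special.polygamma(1, dg / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:  # no excess variability in log s^2: pooled-variance limit
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = logfc / (np.sqrt(s2) * sed)
        t_mod = logfc / (np.sqrt(s2_post) * sed)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = bh_adjust(pd.Series(p, index=values.index))

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "p": p,
            "p_adj": p_adj,
        },
        index=values.index,
    )
    return ModeratedTestResult(table=table, d0=float(d0), s0_sq=s0_sq)


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = pd.Series(p)
    arr = p.to_numpy(dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    return pd.Series(adj, index=p.index, name="p_adj")


def percentile_de(
    profile_a: pd.Series,
    profile_b: pd.Series,
    upper: float = 0.975,
    lower: float = 0.025,
    expressed_mask: pd.Series | None = None,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
) -> PairedPercentileResult:
    """Percentile comparison of one profile against a paired profile.

    Differences d_g = profile_a - profile_b on genes expressed above
    ``threshold`` in both profiles (or on an explicit mask); genes strictly
    above the empirical ``upper`` percentile of the differences form the
    a-high set, genes strictly below the ``lower`` percentile the b-high
    set. With identical profiles both sets are empty.
    """
    common = profile_a.index.intersection(profile_b.index)
    a, b = profile_a.loc[common], profile_b.loc[common]
    if expressed_mask is None:
        mask = (a > threshold) & (b > threshold)
    else:
        mask = expressed_mask.loc[common].astype(bool)
    if not mask.any():
        raise ValueError("expressed mask is empty")
    d = (a - b)[mask]
    up_cut = float(np.quantile(d.to_numpy(), upper))  # type-7
    lo_cut = float(np.quantile(d.to_numpy(), lower))
    high_a = tuple(d.index[d > up_cut])
    high_b = tuple(d.index[d < lo_cut])
    return PairedPercentileResult(
        differences=d, upper_cut=up_cut, lower_cut=lo_cut,
        high_in_a=high_a, high_in_b=high_b,
    )
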