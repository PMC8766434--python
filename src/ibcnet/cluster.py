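"""Unsupervised clustering with cluster-number voting and annotation tests.

Samples are clustered on the most variable genes with Manhattan distance and
Ward linkage; the number of clusters is chosen by majority vote over a fixed
panel of eight internal validity indices; cluster labels are then tested for
association with categorical annotations (Fisher/chi-square) and compared
across candidate predictors with multinomial regression (AIC, LRT).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: pd.Series
    k: int
    votes: dict = field(default_factory=dict)


@dataclass
class ModelComparison:
    aic: dict
    loglik: dict
    lrt: dict = field(default_factory=dict)  # (full, reduced) -> (stat, df, p)
    notes: dict = field(default_factory=dict)


def _prepare_features(values: pd.DataFrame, top_n_genes: int) -> np.ndarray:
    """Top-SD gene selection on the input scale, then per-gene center/scale."""
    sd = values.std(axis=1, ddof=1)
    top = sd.sort_values(ascending=False, kind="stable").index[:top_n_genes]
    sub = values.loc[top]
    sd_sub = sub.std(axis=1, ddof=1)
    constant = sd_sub == 0
    if constant.any():
        logger.warning("dropping %d constant genes after selection", int(constant.sum()))
        sub = sub.loc[~constant]
        sd_sub = sd_sub[~constant]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd_sub, axis=0)
    return z.to_numpy().T  # samples x genes


def hierarchical_cluster(values: pd.DataFrame, top_n_genes: int = 500) -> np.ndarray:
    """Ward linkage over Manhattan distances on standardized top-SD genes."""
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    X = _prepare_features(values, top_n_genes)
    d = pdist(X, metric="cityblock")
    return hierarchy.linkage(d, method="ward")


# --- validity indices -------------------------------------------------------


def _dunn(dmat: np.ndarray, labels: np.ndarray) -> float:
    ks = np.unique(labels)
    intra = max(dmat[np.ix_(labels == k, labels == k)].max() for k in ks)
    inter = min(
        dmat[np.ix_(labels == a, labels == b)].min()
        for a, b in itertools.combinations(ks, 2)
    )
    return inter / intra if intra > 0 else np.inf


def _c_index(dmat: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(dmat, k=1)
    d = dmat[iu]
    within = labels[iu[0]] == labels[iu[1]]
    nw = int(within.sum())
    if nw == 0 or nw == len(d):
        return np.nan
    sw = d[within].sum()
    ds = np.sort(d)
    smin, smax = ds[:nw].sum(), ds[-nw:].sum()
    return (sw - smin) / (smax - smin) if smax > smin else np.nan


def _point_biserial(dmat: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(dmat, k=1)
    d = dmat[iu]
    same = (labels[iu[0]] == labels[iu[1]]).astype(float)
    if same.std() == 0 or d.std() == 0:
        return np.nan
    # correlation of distance with "different cluster" indicator
    return float(np.corrcoef(d, 1.0 - same)[0, 1])


def _mcclain_rao(dmat: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices_from(dmat, k=1)
    d = dmat[iu]
    within = labels[iu[0]] == labels[iu[1]]
    if within.sum() == 0 or (~within).sum() == 0:
        return np.nan
    return float(d[within].mean() / d[~within].mean())


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    return sum(
        ((X[labels == k] - X[labels == k].mean(axis=0)) ** 2).sum()
        for k in np.unique(labels)
    )


INDEX_DIRECTIONS = {
    "silhouette": "max",
    "calinski_harabasz": "max",
    "dunn": "max",
    "davies_bouldin": "min",
    "c_index": "min",
    "point_biserial": "max",
    "mcclain_rao": "min",
    "wss_drop": "max",
}


def select_k(
    values: pd.DataFrame,
    linkage: np.ndarray,
    k_range: range = range(2, 11),
    top_n_genes: int = 500,
) -> ClusteringResult:
    """Majority vote over eight internal validity indices on tree cuts.

    Each index votes for its preferred k (its own direction of optimality);
    the modal k wins, ties resolved to the smallest k. Cuts that produce a
    singleton-only partition (every cluster of size 1) are excluded.
    """
    n = values.shape[1]
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range out of bounds for the sample count")
    X = _prepare_features(values, top_n_genes)
    dmat = squareform(pdist(X, metric="cityblock"))

    cuts, scores = {}, {name: {} for name in INDEX_DIRECTIONS}
    wss = {}
    for k in ks:
        lab = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        if len(np.unique(lab)) != k:
            continue  # degenerate cut
        sizes = np.bincount(lab)[1:]
        if (sizes <= 1).all():
            continue
        cuts[k] = lab
        wss[k] = _wss(X, lab)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores["silhouette"][k] = silhouette_score(dmat, lab, metric="precomputed")
            scores["calinski_harabasz"][k] = calinski_harabasz_score(X, lab)
            scores["davies_bouldin"][k] = davies_bouldin_score(X, lab)
        scores["dunn"][k] = _dunn(dmat, lab)
        scores["c_index"][k] = _c_index(dmat, lab)
        scores["point_biserial"][k] = _point_biserial(dmat, lab)
        scores["mcclain_rao"][k] = _mcclain_rao(dmat, lab)
    # gap-like: relative drop in within-cluster dispersion going k-1 -> k
    for k in cuts:
        prev = wss.get(k - 1)
        scores["wss_drop"][k] = (prev - wss[k]) / prev if prev else np.nan

    votes = {}
    for name, direction in INDEX_DIRECTIONS.items():
        vals = {k: v for k, v in scores[name].items() if np.isfinite(v)}
        if not vals:
            continue
        best = (min if direction == "min" else max)(vals, key=lambda k: (vals[k], -k))
        votes[name] = best
    if not votes:
        raise ValueError("no index produced a valid vote")
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    k = int(top)
    labels = pd.Series(cuts[k], index=values.columns, name="cluster")
    return ClusteringResult(linkage=linkage, labels=labels, k=k, votes=votes)


# --- association tests ------------------------------------------------------


def associate_clusters(
    labels: pd.Series,
    annotation: pd.Series,
    max_exact_n: int = 200,
    n_mc: int = 20000,
    seed: int = 0,
):
    """Test association between cluster labels and a categorical annotation.

    Uses Fisher's exact test for 2x2 tables, a Monte-Carlo permutation
    version of the chi-square test for small non-2x2 tables (total count
    <= ``max_exact_n``), and the asymptotic chi-square test otherwise.
    Returns (table, statistic, p, method).
    """
    annotation = annotation.loc[labels.index]
    if annotation.nunique() < 2:
        raise ValueError("annotation has a single level")
    table = pd.crosstab(labels, annotation)
    arr = table.to_numpy()
    if arr.shape == (2, 2):
        stat, p = stats.fisher_exact(arr)
        return table, float(stat), float(p), "fisher"
    if arr.sum() <= max_exact_n:
        chi2_obs = stats.chi2_contingency(arr, correction=False)[0]
        rng = np.random.default_rng(seed)
        lab = labels.to_numpy()
        ann = annotation.to_numpy()
        count = 0
        for _ in range(n_mc):
            perm = rng.permutation(ann)
            chi2 = stats.chi2_contingency(pd.crosstab(lab, perm).to_numpy(),
                                          correction=False)[0]
            if chi2 >= chi2_obs - 1e-12:
                count += 1
        return table, float(chi2_obs), (count + 1) / (n_mc + 1), "chi2-mc"
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return table, float(chi2), float(p), "chi2"


def likelihood_ratio_test(loglik_full: float, loglik_reduced: float, df: int):
    """LRT statistic, df and p for a nested model pair (df 0 -> stat 0, p 1)."""
    stat = max(2.0 * (loglik_full - loglik_reduced), 0.0)
    if df <= 0:
        return 0.0, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def compare_predictors(
    labels: pd.Series,
    predictors: pd.DataFrame,
    combinations: tuple = (),
) -> ModelComparison:
    """Multinomial logistic fits of cluster labels on candidate predictors.

    Fits one model per predictor column (plus a null intercept model and any
    requested multivariate ``combinations``), reporting AIC = 2k - 2 logL and
    likelihood-ratio tests for nested pairs (each single predictor vs null,
    each combination vs its components). Perfect separation is flagged in
    ``notes``; the AIC at the converged point is still reported.
    """
    import statsmodels.api as sm

    predictors = predictors.loc[labels.index]
    y = pd.Categorical(labels)
    models = {"null": []}
    for col in predictors.columns:
        if predictors[col].nunique() < 2:
            raise ValueError(f"predictor {col!r} has an empty/constant level")
        models[col] = [col]
    for combo in combinations:
        models["+".join(combo)] = list(combo)

    aic, loglik, nparams, notes = {}, {}, {}, {}
    for name, cols in models.items():
        if cols:
            X = pd.get_dummies(predictors[cols].astype(str), drop_first=True, dtype=float)
        else:
            X = pd.DataFrame(index=predictors.index)
        X = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MNLogit(y.codes, X.to_numpy())
            try:
                fit = model.fit(method="newton", maxiter=200, disp=0)
                if not fit.mle_retvals.get("converged", True):
                    notes[name] = "not converged (possible separation)"
            except Exception:  # separation: fall back to ridge-stabilized BFGS
                fit = model.fit_regularized(alpha=1e-8, disp=0)
                notes[name] = "separation; ridge-stabilized fit"
        k = X.shape[1] * (len(y.categories) - 1)
        loglik[name] = float(fit.llf)
        nparams[name] = k
        aic[name] = 2 * k - 2 * float(fit.llf)

    lrt = {}
    for name, cols in models.items():
        if name == "null":
            continue
        pairs = [("null", name)]
        if len(cols) > 1:
            pairs += [(c, name) for c in cols if c in models]
        for reduced, full in pairs:
            stat = 2.0 * (loglik[full] - loglik[reduced])
            df = nparams[full] - nparams[reduced]
            p = float(stats.chi2.sf(max(stat, 0.0), df)) if df > 0 else 1.0
            lrt[(full, reduced)] = (max(stat, 0.0), df, p)
    return ModelComparison(aic=aic, loglik=loglik, lrt=lrt, notes=notes)
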