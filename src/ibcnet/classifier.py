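"""Elastic-net IBC signature classifier with replicate-median calling.

The classifier retrains a penalized logistic model over a supplied signature
gene list. The objective, in the glmnet-style parameterization, is

    (1/n) sum_i logloss_i  +  lambda * [ (1-alpha)/2 ||b||_2^2 + alpha ||b||_1 ]

fit via scikit-learn's saga solver with C = 1 / (n * lambda), which makes the
two objectives identical up to the factor n. The tuning grid defaults to
alpha in {0, 0.1, ..., 1} and lambda in {0.001, ..., 0.1 step 0.001}; the
grid point with the highest mean cross-validated AUROC wins, ties resolved
to the larger lambda then the larger alpha (the sparser/smoother model).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.001, 0.1001, 0.001), 10))


def stratify_tertiles(values: pd.Series) -> pd.Series:
    """Split a continuous vector into low / moderate / high tertiles.

    Cuts at the 33rd/66th (exact-tertile) quantiles with type-7
    interpolation; values equal to a cut fall into the lower stratum.
    Labels are rank-invariant under monotone transforms.
    """
    values = pd.Series(values)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if values.nunique() == 1:
        raise ValueError("all values equal: no strata")
    q1, q2 = np.quantile(values.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])  # type-7
    labels = np.where(values <= q1, "low", np.where(values <= q2, "moderate", "high"))
    return pd.Series(labels, index=values.index, name="stratum")


@dataclass
class ClassifierModel:
    signature: tuple
    mean: pd.Series
    sd: pd.Series
    alpha: float
    lam: float
    coef: pd.Series
    intercept: float
    cv_auroc: pd.DataFrame  # alpha x lambda mean CV AUROC
    validation_accuracy: float
    folds: int
    repeats: int
    seed: int

    def posterior(self, X: pd.DataFrame) -> pd.Series:
        """Posterior probability of IBC for each profile (rows = genes)."""
        missing = [g for g in self.signature if g not in X.index]
        if missing:
            raise KeyError(f"signature genes missing from matrix: {missing[:10]}")
        Z = X.loc[list(self.signature)].sub(self.mean, axis=0).div(self.sd, axis=0)
        eta = self.intercept + Z.T.to_numpy() @ self.coef.to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.columns, name="posterior")


@dataclass
class PredictionSet:
    posterior: pd.Series          # per profile
    median_posterior: pd.Series   # per replicate group
    call: pd.Series               # per group: "IBC"/"nIBC", IBC iff median >= 0.5


def _fit_enet(X: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> LogisticRegression:
    C = 1.0 / (X.shape[0] * lam)
    clf = LogisticRegression(
        penalty="elasticnet", l1_ratio=alpha, C=C, solver="saga",
        max_iter=3000, tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return clf


def train_elastic_net(
    X: pd.DataFrame,
    y: pd.Series,
    signature: tuple | list,
    split_ratio: float = 0.75,
    folds: int = 10,
    repeats: int = 5,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> ClassifierModel:
    """Tune and fit the elastic-net logistic classifier on signature genes.

    ``X`` is genes x samples; ``y`` holds "IBC"/"nIBC" per sample. The data
    are split 3/1 (stratified) into training and validation; per-gene
    center/scale parameters come from the training split only. The grid is
    searched with repeated stratified ``folds``-fold CV scored by AUROC; the
    winning point is refit on the whole training split and the held-out
    accuracy on the validation quarter reported.
    """
    signature = tuple(signature)
    missing = [g for g in signature if g not in X.index]
    if missing:
        raise KeyError(f"signature genes missing from X: {missing[:10]}")
    y = y.loc[X.columns]
    ybin = (y == "IBC").astype(int).to_numpy()
    if ybin.min() == ybin.max():
        raise ValueError("both classes must be present")

    idx = np.arange(X.shape[1])
    tr, va = train_test_split(
        idx, train_size=split_ratio, stratify=ybin, random_state=seed
    )
    Xs = X.loc[list(signature)]
    mean = Xs.iloc[:, tr].mean(axis=1)
    sd = Xs.iloc[:, tr].std(axis=1, ddof=1).replace(0.0, 1.0)
    Z = Xs.sub(mean, axis=0).div(sd, axis=0).to_numpy().T  # samples x genes
    Ztr, ytr = Z[tr], ybin[tr]
    Zva, yva = Z[va], ybin[va]

    # CV folds: retry with a fresh seed if a fold loses a class
    for attempt in range(10):
        cv = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=repeats, random_state=seed + attempt
        )
        splits = list(cv.split(Ztr, ytr))
        if all(len(np.unique(ytr[tr_i])) == 2 and len(np.unique(ytr[te_i])) == 2
               for tr_i, te_i in splits):
            break
    else:
        raise ValueError("could not build CV folds with both classes present")

    mean_auc = pd.DataFrame(
        np.zeros((len(alpha_grid), len(lambda_grid))),
        index=list(alpha_grid), columns=list(lambda_grid),
    )
    for tr_i, te_i in splits:
        for a in alpha_grid:
            for lam in lambda_grid:
                clf = _fit_enet(Ztr[tr_i], ytr[tr_i], a, lam)
                prob = clf.predict_proba(Ztr[te_i])[:, 1]
                mean_auc.loc[a, lam] += roc_auc_score(ytr[te_i], prob)
    mean_auc /= len(splits)

    # best mean AUROC; ties -> larger lambda, then larger alpha
    best = max(
        ((a, lam) for a in mean_auc.index for lam in mean_auc.columns),
        key=lambda al: (mean_auc.loc[al[0], al[1]], al[1], al[0]),
    )
    alpha, lam = float(best[0]), float(best[1])
    final = _fit_enet(Ztr, ytr, alpha, lam)
    val_acc = float((final.predict(Zva) == yva).mean())

    return ClassifierModel(
        signature=signature, mean=mean, sd=sd, alpha=alpha, lam=lam,
        coef=pd.Series(final.coef_.ravel(), index=list(signature)),
        intercept=float(final.intercept_[0]),
        cv_auroc=mean_auc, validation_accuracy=val_acc,
        folds=folds, repeats=repeats, seed=seed,
    )


def call_models(
    model: ClassifierModel, X: pd.DataFrame, replicate_group: pd.Series
) -> PredictionSet:
    """Per-replicate posteriors, per-model median, binary call at >= 0.5."""
    post = model.posterior(X)
    groups = replicate_group.loc[X.columns]
    if groups.isna().any():
        raise ValueError("every profile needs a replicate group")
    med = post.groupby(groups, sort=False).median()
    call = pd.Series(np.where(med >= 0.5, "IBC", "nIBC"), index=med.index, name="call")
    return PredictionSet(posterior=post, median_posterior=med, call=call)


def confusion_stats(calls: pd.Series, truth: pd.Series) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV from binary IBC calls.

    Computed in exact rational arithmetic before conversion to float.
    """
    truth = truth.loc[calls.index]
    if len(calls) == 0:
        raise ValueError("empty input")
    pos = calls == "IBC"
    tpos = truth == "IBC"
    tp = int((pos & tpos).sum()); fp = int((pos & ~tpos).sum())
    fn = int((~pos & tpos).sum()); tn = int((~pos & ~tpos).sum())

    def frac(a, b):
        return float(Fraction(a, b)) if b else float("nan")

    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": frac(tp + tn, tp + tn + fp + fn),
        "sensitivity": frac(tp, tp + fn),
        "specificity": frac(tn, tn + fp),
        "ppv": frac(tp, tp + fp),
        "npv": frac(tn, tn + fn),
    }


def mcnemar_test(a: pd.Series, b: pd.Series, correction: bool = False,
                 exact_below: int = 25) -> tuple:
    """McNemar test on paired binary outcomes.

    Chi-square (b-c)^2/(b+c) on the discordant counts, continuity correction
    off by default; exact two-sided binomial when the discordant total is
    below ``exact_below``. Returns (statistic, p, method).
    """
    a = np.asarray(a).astype(bool)
    bb = np.asarray(b).astype(bool)
    if a.shape != bb.shape:
        raise ValueError("paired outcomes must have equal length")
    n01 = int((a & ~bb).sum())
    n10 = int((~a & bb).sum())
    disc = n01 + n10
    if disc == 0:
        return 0.0, 1.0, "degenerate (no discordant pairs)"
    if disc < exact_below:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(n01, n10), disc, 0.5)))
        return float(min(n01, n10)), p, "exact-binomial"
    num = (abs(n01 - n10) - (1.0 if correction else 0.0)) ** 2
    chi2 = num / disc
    return float(chi2), float(stats.chi2.sf(chi2, 1)), "chi2"


def classify_nearest_centroid(
    values: pd.DataFrame, centroids: pd.DataFrame, method: str = "spearman"
) -> pd.Series:
    """Label each sample with its maximally correlated centroid.

    Generic plumbing for user-supplied centroid tables (genes x centroids);
    ties go to the first centroid in file order; requires >= 5 overlapping
    genes.
    """
    common = values.index.intersection(centroids.index)
    if len(common) < 5:
        raise ValueError(f"only {len(common)} genes overlap the centroids (need >= 5)")
    V = values.loc[common]
    C = centroids.loc[common]
    if method == "spearman":
        V = V.rank(axis=0)
        C = C.rank(axis=0)
    corr = np.corrcoef(V.to_numpy().T, C.to_numpy().T)[: V.shape[1], V.shape[1]:]
    best = corr.argmax(axis=1)  # argmax takes the first maximum -> file order
    return pd.Series(C.columns[best], index=values.columns, name="subtype")
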