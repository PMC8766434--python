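"""Nested ER-stratum x phenotype interaction regression and proximal-MYC-
network (PMN) analysis.

The nested model for a response (MYC expression or an activity score) over
the six phenotype x ER-stratum cells uses the nIBC / ER-low cell as
reference and five indicator columns:

    x1 = 1[nIBC & ER moderate]      (shift vs reference)
    x2 = 1[nIBC & ER high]          (shift vs reference)
    x3 = 1[IBC]                     (IBC / ER-low shift vs reference)
    x4 = 1[IBC & ER moderate]       (increment over IBC / ER-low)
    x5 = 1[IBC & ER high]           (increment over IBC / ER-low)

so the IBC ER-moderate/high coefficients read as increments relative to
IBC / ER-low. The response is modeled with identity link and Gaussian
errors (ordinary least squares on log2-scale data); HC3 robust standard
errors are available but off by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats

from .cluster import likelihood_ratio_test

logger = logging.getLogger(__name__)

COEF_NAMES = (
    "nIBC:ER-moderate",
    "nIBC:ER-high",
    "IBC:ER-low",
    "IBC:ER-moderate",
    "IBC:ER-high",
)


@dataclass
class NestedFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    nparams: int
    dropped: tuple = ()
    result: object = field(default=None, repr=False)


def _design(phenotype: pd.Series, stratum: pd.Series) -> pd.DataFrame:
    ph = phenotype.astype(str)
    st = stratum.astype(str)
    bad = set(st) - {"low", "moderate", "high"}
    if bad:
        raise ValueError(f"unknown ER strata: {bad}")
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            COEF_NAMES[0]: ((ph == "nIBC") & (st == "moderate")).astype(float),
            COEF_NAMES[1]: ((ph == "nIBC") & (st == "high")).astype(float),
            COEF_NAMES[2]: (ph == "IBC").astype(float),
            COEF_NAMES[3]: ((ph == "IBC") & (st == "moderate")).astype(float),
            COEF_NAMES[4]: ((ph == "IBC") & (st == "high")).astype(float),
        },
        index=phenotype.index,
    )
    for p in ("IBC", "nIBC"):
        for s in ("low", "moderate", "high"):
            if not (((ph == p) & (st == s)).any()):
                raise ValueError(f"empty design cell: {p}/ER-{s}")
    return X


def fit_nested_interaction(
    response: pd.Series,
    phenotype: pd.Series,
    stratum: pd.Series,
    robust: bool = False,
) -> NestedFit:
    """OLS fit of the five-indicator nested interaction design."""
    import statsmodels.api as sm

    X = _design(phenotype.loc[response.index], stratum.loc[response.index])
    res = sm.OLS(response.to_numpy(dtype=float), X.to_numpy()).fit(
        cov_type="HC3" if robust else "nonrobust"
    )
    return NestedFit(
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        loglik=float(res.llf),
        aic=float(res.aic),
        nparams=X.shape[1],
        result=res,
    )


def fit_with_blocking(
    response: pd.Series,
    phenotype: pd.Series,
    stratum: pd.Series,
    blocking: pd.Series,
    robust: bool = False,
) -> tuple[NestedFit, dict]:
    """Nested fit with a categorical blocking factor, plus an LRT vs unblocked.

    Blocking indicator columns aliased with the phenotype x stratum cells
    are dropped with a warning; the comparison dict reports the LRT
    statistic/df/p and the shift of each interaction coefficient.
    """
    import statsmodels.api as sm

    blocking = blocking.loc[response.index]
    if blocking.nunique() < 2:
        raise ValueError("blocking factor is constant")
    base = fit_nested_interaction(response, phenotype, stratum, robust=robust)
    X = _design(phenotype.loc[response.index], stratum.loc[response.index])
    B = pd.get_dummies(blocking.astype(str), drop_first=True, dtype=float)
    B.columns = [f"block:{c}" for c in B.columns]
    Xb = pd.concat([X, B], axis=1)

    dropped = []
    arr = Xb.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    while rank < Xb.shape[1]:
        # drop trailing blocking columns until full rank
        for col in reversed(B.columns):
            if col in Xb.columns:
                trial = Xb.drop(columns=[col])
                if np.linalg.matrix_rank(trial.to_numpy()) == trial.shape[1]:
                    dropped.append(col)
                    Xb = trial
                    break
        else:
            break
        rank = np.linalg.matrix_rank(Xb.to_numpy())
    if dropped:
        logger.warning("aliased blocking columns dropped: %s", dropped)

    res = sm.OLS(response.to_numpy(dtype=float), Xb.to_numpy()).fit(
        cov_type="HC3" if robust else "nonrobust"
    )
    blocked = NestedFit(
        params=pd.Series(res.params, index=Xb.columns),
        bse=pd.Series(res.bse, index=Xb.columns),
        pvalues=pd.Series(res.pvalues, index=Xb.columns),
        loglik=float(res.llf),
        aic=float(res.aic),
        nparams=Xb.shape[1],
        dropped=tuple(dropped),
        result=res,
    )
    stat, df, p = likelihood_ratio_test(
        blocked.loglik, base.loglik, blocked.nparams - base.nparams
    )
    shifts = {c: float(blocked.params[c] - base.params[c]) for c in COEF_NAMES}
    comparison = {"lrt_stat": stat, "lrt_df": df, "lrt_p": p,
                  "coefficient_shifts": shifts, "dropped": tuple(dropped)}
    return blocked, comparison


@dataclass
class PMNReport:
    vs_myc: pd.DataFrame          # member: rho, p (vs MYC)
    vs_activity: pd.DataFrame     # member: rho, p (vs activity), per score column
    pairwise: pd.DataFrame        # member x member Spearman rho, Ward-ordered
    order: tuple


def pmn_correlations(
    expression: pd.DataFrame,
    myc: pd.Series,
    activity: pd.DataFrame | pd.Series | None = None,
) -> PMNReport:
    """Spearman correlations of PMN members vs MYC and vs activity scores.

    ``expression`` is members x samples. Constant member vectors yield
    missing correlations. The pairwise matrix is ordered by Ward clustering
    of 1 - rho.
    """
    if expression.shape[1] < 4:
        raise ValueError("need at least 4 observations")
    myc = myc.loc[expression.columns]

    def spear(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return np.nan, np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)

    rows = {m: spear(expression.loc[m], myc) for m in expression.index}
    vs_myc = pd.DataFrame(rows, index=["rho", "p"]).T

    if activity is None:
        vs_activity = pd.DataFrame(columns=["score", "member", "rho", "p"])
    else:
        if isinstance(activity, pd.Series):
            activity = activity.to_frame()
        recs = []
        for col in activity.columns:
            act = activity[col].loc[expression.columns]
            for m in expression.index:
                rho, p = spear(expression.loc[m], act)
                recs.append({"score": col, "member": m, "rho": rho, "p": p})
        vs_activity = pd.DataFrame(recs)

    members = list(expression.index)
    P = np.eye(len(members))
    for i, a in enumerate(members):
        for j in range(i + 1, len(members)):
            rho, _ = spear(expression.loc[a], expression.loc[members[j]])
            P[i, j] = P[j, i] = rho if np.isfinite(rho) else 0.0
    if len(members) > 2:
        link = hierarchy.linkage(squareform(1.0 - P, checks=False), method="ward")
        order = hierarchy.leaves_list(link)
    else:
        order = np.arange(len(members))
    ordered = [members[i] for i in order]
    pairwise = pd.DataFrame(P, index=members, columns=members).loc[ordered, ordered]
    return PMNReport(vs_myc=vs_myc, vs_activity=vs_activity, pairwise=pairwise,
                     order=tuple(ordered))


def flag_activity_outliers(
    myc: pd.Series,
    activity: pd.Series,
    candidates: pd.DataFrame,
    percentile: float = 0.90,
) -> pd.DataFrame:
    """Flag samples whose candidate-gene expression exceeds its 90th percentile.

    ``candidates`` is genes x samples. Flags are strict (> empirical
    percentile, type-7), so constant candidates flag nothing. The returned
    table also carries the residual of activity regressed on MYC so flags
    can be read against the activity-vs-MYC relationship.
    """
    samples = myc.index
    if len(samples) < 10:
        logger.warning("fewer than 10 samples: the percentile flag is unstable")
    activity = activity.loc[samples]
    X = np.column_stack([np.ones(len(samples)), myc.to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(X, activity.to_numpy(dtype=float), rcond=None)
    resid = activity.to_numpy() - X @ coef

    out = pd.DataFrame({"myc": myc, "activity": activity, "residual": resid},
                       index=samples)
    for gene in candidates.index:
        v = candidates.loc[gene, samples]
        cut = float(np.quantile(v.to_numpy(dtype=float), percentile))
        out[f"flag_{gene}"] = (v > cut).to_numpy()
    return out


def run_interaction_analysis(cohort, response: str = "MYC",
                             blocking: str | None = None, seed: int = 0) -> dict:
    """One deterministic pipeline call: nested fit, optional blocked fit,
    PMN correlation report and outlier flags for a :class:`PatientCohort`."""
    data = cohort.data
    resp = data[response] if response in data.columns else data["MYC"]
    fit = fit_nested_interaction(resp, data["phenotype"], data["er_stratum"])
    out = {"fit": fit}
    if blocking:
        out["blocked_fit"], out["blocking_comparison"] = fit_with_blocking(
            resp, data["phenotype"], data["er_stratum"], data[blocking]
        )
    members = [m for m in cohort.pmn_members if m in data.columns]
    if members:
        expr = data[members].T
        act_cols = [c for c in data.columns if c.startswith("activity_")]
        out["pmn"] = pmn_correlations(expr, data["MYC"],
                                      data[act_cols] if act_cols else None)
        if act_cols:
            out["outliers"] = flag_activity_outliers(
                data["MYC"], data[act_cols[0]], expr
            )
    return out
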