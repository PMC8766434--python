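"""Multi-batch expression merging: filter, batch-correct, quantile-normalize,
collapse probes, average replicates.

The chain order is fixed and enforced by :func:`run_preprocess`:
filter -> batch correction -> quantile normalization -> probe collapsing ->
replicate averaging. Inputs are assumed to be log2-summarized already;
missing values are rejected, never imputed.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EXPRESSION_THRESHOLD = math.log2(100.0)


def filter_expressed(
    values: pd.DataFrame,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    min_samples: int = 2,
) -> pd.DataFrame:
    """Keep rows with at least ``min_samples`` entries strictly above ``threshold``.

    Default threshold log2(100) matches the background-fluorescence cutoff
    customary for log2-summarized microarray intensities.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > values.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples {values.shape[1]}"
        )
    keep = (values.to_numpy() > threshold).sum(axis=1) >= min_samples
    return values.loc[keep]


def correct_batch(
    values: pd.DataFrame,
    batch: pd.Series,
    protected: pd.DataFrame | pd.Series | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch adjustment (parametric ComBat).

    Per gene, protected-covariate effects are fit and preserved; per-batch
    residual means and variances are shrunk toward across-gene normal /
    inverse-gamma priors and removed. Delegates the adjustment to
    ``scanpy.pp.combat`` after validating the design: with a single batch
    the matrix is returned unchanged, and a batch perfectly confounded with
    a protected covariate raises a rank-deficiency error naming the pair.
    """
    batch = batch.loc[values.columns]
    if batch.nunique() < 2:
        return values.copy()

    if protected is not None:
        if isinstance(protected, pd.Series):
            protected = protected.to_frame()
        protected = protected.loc[values.columns]
        bd = pd.get_dummies(batch.astype(str), dtype=float)
        cov = pd.get_dummies(protected.astype(str), dtype=float)
        design = pd.concat([bd, cov], axis=1)
        full = bd.shape[1] + cov.shape[1] - 1 - (protected.shape[1] - 1)
        if np.linalg.matrix_rank(design.to_numpy()) < full:
            for col in protected.columns:
                tab = pd.crosstab(batch, protected[col])
                if ((tab > 0).sum(axis=1) == 1).all() or ((tab > 0).sum(axis=0) == 1).all():
                    raise ValueError(
                        f"batch is confounded with protected covariate {col!r}: "
                        "the location/scale model is rank deficient"
                    )
            raise ValueError("batch/protected design is rank deficient")

    import anndata

    obs = pd.DataFrame({"batch": batch.astype(str).to_numpy()}, index=values.columns)
    cov_cols = []
    if protected is not None:
        # encode each protected factor as numeric drop-first indicators with
        # formula-safe names: the downstream design concatenates them with a
        # full batch one-hot, so full categorical dummies would be collinear
        dummies = pd.get_dummies(protected.astype(str), drop_first=True, dtype=float)
        for i, col in enumerate(dummies.columns):
            name = f"cov_{i}"
            obs[name] = dummies[col].to_numpy()
            cov_cols.append(name)
    adata = anndata.AnnData(
        X=values.to_numpy(dtype=float).T.copy(), obs=obs
    )
    import scanpy as sc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = sc.pp.combat(adata, key="batch", covariates=cov_cols or None,
                                 inplace=False)
    return pd.DataFrame(np.asarray(corrected).T, index=values.index, columns=values.columns)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the rank-wise mean distribution (ties averaged)."""
    if values.isna().any().any():
        raise ValueError("quantile_normalize requires complete data")
    arr = values.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    ranks = values.rank(method="average").to_numpy()  # 1-based, .5 on ties
    # interpolate mean_sorted at (rank - 1); half-ranks average two entries
    out = np.interp(ranks - 1.0, np.arange(arr.shape[0]), mean_sorted)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_probes(values: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """One row per gene: the probe with maximal sample standard deviation.

    ``probe_map`` maps probe id -> gene id (many-to-one). Ties break to the
    lexicographically smallest probe id. Rows are returned indexed by gene,
    in first-appearance order of genes over the sorted probe list.
    """
    unmapped = values.index.difference(probe_map.index)
    if len(unmapped):
        raise KeyError(f"unmapped probes: {list(unmapped)[:10]}")
    sd = values.std(axis=1, ddof=1)
    pick = (
        pd.DataFrame({"gene": probe_map.loc[values.index], "sd": sd})
        .reset_index(names="probe")
        .sort_values(["gene", "sd", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    out = values.loc[pick["probe"]]
    out.index = pd.Index(pick["gene"].to_numpy(), name="gene_id")
    return out


def average_replicates(values: pd.DataFrame, replicate_group: pd.Series) -> pd.DataFrame:
    """Arithmetic per-gene mean within replicate groups.

    Output column order is the first-appearance order of groups.
    """
    groups = replicate_group.loc[values.columns]
    if groups.isna().any() or (groups.astype(str) == "").any():
        raise ValueError("empty replicate group label")
    order = groups.drop_duplicates().tolist()
    out = values.T.groupby(groups, sort=False).mean().T
    return out[order]


def run_preprocess(
    compendium,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    min_samples: int = 2,
    probe_map: pd.Series | None = None,
    protect_cols: tuple = ("replicate_group",),
) -> pd.DataFrame:
    """Run the fixed chain on an :class:`ExpressionCompendium`.

    Returns the gene x replicate-group averaged matrix. The order
    filter -> batch-correct -> quantile-normalize -> collapse -> average is
    not configurable.
    """
    ann = compendium.annotation
    mat = filter_expressed(compendium.values, threshold, min_samples)
    mat = correct_batch(mat, ann["batch"], ann[list(protect_cols)])
    mat = quantile_normalize(mat)
    if probe_map is not None:
        mat = collapse_probes(mat, probe_map)
    return average_replicates(mat, ann["replicate_group"])
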