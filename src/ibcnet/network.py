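"""Signed weighted co-expression network analysis.

Robust pairwise correlation (biweight midcorrelation), soft-threshold
selection against scale-free topology, topological overlap, hierarchical
module detection with medoid refinement and eigengene merging, gene-module
membership (GMM/kME), and permutation-based module preservation statistics.

Conventions
-----------
* Signed adjacency: a_ij = ((1 + cor_ij) / 2) ** beta, so anti-correlated
  genes get near-zero adjacency rather than high adjacency.
* Eigengene: first principal component of the per-gene standardized module
  submatrix, oriented so the mean gene-eigengene correlation is >= 0.
* Preservation bands: Zsummary < 2 poor, 2-10 moderate, > 10 good.
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

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    beta: int
    candidates: tuple
    fit_table: pd.DataFrame  # per-beta scale-free fit R^2 (sign-adjusted) and mean k
    r2_threshold: float = 0.8
    signed: bool = True


@dataclass
class ModuleAssignment:
    labels: pd.Series                 # gene -> module id, 0 = unassigned
    merge_history: list = field(default_factory=list)

    @property
    def sizes(self) -> pd.Series:
        return self.labels[self.labels > 0].value_counts().sort_index()

    def genes_in(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]


@dataclass
class GMMMatrix:
    gmm: pd.DataFrame         # genes x modules Pearson correlations
    eigengenes: pd.DataFrame  # samples x modules


@dataclass
class PreservationReport:
    table: pd.DataFrame  # per module: Zdensity, Zconnectivity, Zsummary, band
    n_perm: int
    skipped: tuple = ()


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------


def bicor(values: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene biweight midcorrelation matrix.

    For each gene x: u_i = (x_i - median) / (9 MAD), weights
    w_i = (1 - u_i^2)^2 on |u_i| < 1, correlation of the weighted, median-
    centered vectors. Genes with zero MAD fall back to Pearson (standardized
    mean-centered rows), logged.
    """
    if values.shape[1] < 4:
        raise ValueError("bicor requires at least 4 samples")
    X = values.to_numpy(dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero = (mad.ravel() == 0)
    if zero.any():
        logger.warning("%d genes have zero MAD; Pearson fallback", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    T = (X - med) * w
    if zero.any():  # Pearson rows for degenerate genes
        Xi = X[zero]
        T[zero] = Xi - Xi.mean(axis=1, keepdims=True)
    norm = np.sqrt((T ** 2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    Tn = T / norm
    C = Tn @ Tn.T
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=values.index, columns=values.index)


# ---------------------------------------------------------------------------
# soft threshold and topological overlap
# ---------------------------------------------------------------------------


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: int) -> np.ndarray:
    A = ((1.0 + np.asarray(cor, dtype=float)) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Sign-adjusted R^2 of log10 freq(k) vs log10 k over equal-width bins."""
    k = k[k > 0]
    if len(k) < n_bins or np.allclose(k, k[0]):
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-9
    counts, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (k >= lo) & (k < hi)
        if m.sum() > 0:
            counts.append(m.sum())
            means.append(k[m].mean())
    if len(counts) < 3:
        return np.nan
    x = np.log10(np.asarray(means))
    y = np.log10(np.asarray(counts) / len(k))
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_threshold(
    cor: pd.DataFrame,
    candidates=tuple(range(1, 21)),
    r2_threshold: float = 0.8,
    mean_k_cap: float | None = None,
) -> NetworkParams:
    """Smallest power giving scale-free fit R^2 >= threshold.

    R^2 is sign-adjusted (negative slopes count positively) so increasing
    degree distributions never satisfy the criterion. Alongside the fit, the
    mean connectivity must have decayed to at most ``mean_k_cap`` (default
    1% of the gene count) — the standard companion check: a network can look
    scale-free while still far too dense for module structure to be
    resolvable. Fallbacks, in order:
    smallest power meeting the R^2 threshold alone, then argmax R^2, each
    with a warning.
    """
    rows = []
    for beta in candidates:
        A = signed_adjacency(cor, beta)
        if not A.any():
            raise ValueError("all-zero adjacency")
        k = A.sum(axis=1) - 1.0
        rows.append({"beta": beta, "r2": _scale_free_fit(k), "mean_k": float(k.mean())})
    fit = pd.DataFrame(rows).set_index("beta")
    if mean_k_cap is None:
        mean_k_cap = 0.01 * cor.shape[0]
    ok = fit.index[(fit["r2"] >= r2_threshold) & (fit["mean_k"] <= mean_k_cap)]
    if len(ok):
        beta = int(ok[0])
    else:
        ok = fit.index[fit["r2"] >= r2_threshold]
        if len(ok):
            beta = int(ok[0])
            logger.warning(
                "no power reaches R^2 >= %.2f with mean k <= %g; using beta=%d",
                r2_threshold, mean_k_cap, beta,
            )
        elif fit["r2"].notna().any():
            beta = int(fit["r2"].idxmax(skipna=True))
            logger.warning(
                "no power reaches scale-free R^2 >= %.2f; falling back to "
                "argmax beta=%d", r2_threshold, beta,
            )
        else:  # constant connectivity everywhere: degenerate fit
            beta = int(candidates[0])
            logger.warning(
                "scale-free fit is degenerate for every power; using beta=%d",
                beta,
            )
    return NetworkParams(beta=beta, candidates=tuple(candidates), fit_table=fit,
                         r2_threshold=r2_threshold)


def tom(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Topological overlap matrix and its dissimilarity (1 - TOM).

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k the connectivity (row sum minus diagonal); diagonal TOM = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if np.abs(A - A.T).max() > 1e-10:
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1.0 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = A.sum(axis=1) - np.diag(A)
    shared = A @ A - np.diag(A)[:, None] * A - A * np.diag(A)[None, :]
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(T, 1.0)
    T = np.clip((T + T.T) / 2.0, 0.0, 1.0)
    return T, 1.0 - T


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------


def _eigengene(sub: pd.DataFrame) -> np.ndarray:
    """First PC (per sample) of the standardized module submatrix, oriented."""
    Z = sub.sub(sub.mean(axis=1), axis=0)
    sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
    Z = Z.div(sd, axis=0).to_numpy()
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    e = vt[0]
    corr_sign = np.sign(np.mean(Z @ e))
    if corr_sign < 0:
        e = -e
    n = np.linalg.norm(e)
    return e / n if n > 0 else e


def detect_modules(
    dissim: np.ndarray,
    values: pd.DataFrame,
    min_size: int = 100,
    merge_cut: float = 0.25,
    cohesion_ratio: float = 1.5,
) -> ModuleAssignment:
    """Assign genes to co-expression modules from a TOM dissimilarity.

    Procedure: Ward tree on the dissimilarity; an adaptive branch carve
    selects the deepest dendrogram nodes that have >= ``min_size`` leaves
    and whose mean within-branch topological overlap exceeds the matrix-
    wide background overlap by the factor ``cohesion_ratio`` (overlap
    ratios, unlike dissimilarity gaps, are comparable across soft-threshold
    powers; branches failing the gate are pruned to module 0); a cohesive
    node is split further only when both children are large, cohesive and
    mutually separated by the same ratio — i.e. when it lumps two distinct
    modules. A PAM-style stage then reassigns every gene to its closest
    module core by mean dissimilarity to the core's members, within an
    adaptive radius — iterated twice so cores stabilize; finally modules
    whose eigengenes correlate above 1 - ``merge_cut`` are merged
    iteratively.
    """
    D = np.asarray(dissim, dtype=float)
    n = D.shape[0]
    if min_size > n:
        raise ValueError("min_size exceeds the number of genes")
    link = hierarchy.linkage(squareform(D, checks=False), method="ward")
    S = 1.0 - D  # topological overlap (similarity)
    bg_sim = float(S[np.triu_indices(n, 1)].mean())

    def within_sim(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return 0.0
        sub = S[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(len(idx), 1)].mean())

    def cohesive(idx: np.ndarray) -> bool:
        if len(idx) < 2 or bg_sim <= 0:
            return False
        return within_sim(idx) >= cohesion_ratio * bg_sim

    root = hierarchy.to_tree(link)

    def carve(node) -> list:
        if node.is_leaf() or node.get_count() < min_size:
            return []
        idx = np.asarray(node.pre_order())
        if not cohesive(idx):
            return carve(node.get_left()) + carve(node.get_right())
        li = np.asarray(node.get_left().pre_order())
        ri = np.asarray(node.get_right().pre_order())
        if (
            len(li) >= min_size and len(ri) >= min_size
            and cohesive(li) and cohesive(ri)
        ):
            between = float(S[np.ix_(li, ri)].mean())
            if min(within_sim(li), within_sim(ri)) >= cohesion_ratio * max(between, 1e-12):
                return carve(node.get_left()) + carve(node.get_right())
        return [idx]

    cores = carve(root)
    labels = np.zeros(n, dtype=int)
    for j, idx in enumerate(cores, start=1):
        labels[idx] = j

    # recovery pass: a module can be shredded by an unlucky top-level split;
    # re-carve the unassigned residual until no cohesive branch of min_size
    # remains there
    while True:
        rest = np.where(labels == 0)[0]
        if len(rest) < min_size:
            break
        sub_link = hierarchy.linkage(
            squareform(D[np.ix_(rest, rest)], checks=False), method="ward"
        )
        sub_root = hierarchy.to_tree(sub_link)

        def carve_sub(node) -> list:
            if node.is_leaf() or node.get_count() < min_size:
                return []
            idx = rest[np.asarray(node.pre_order())]
            if not cohesive(idx):
                return carve_sub(node.get_left()) + carve_sub(node.get_right())
            return [idx]

        found = carve_sub(sub_root)
        if not found:
            break
        for idx in found:
            labels[idx] = labels.max() + 1

    # PAM-style reassignment against core aggregates, iterated so the cores
    # absorb stragglers and shed genes no closer than the core radius
    for _ in range(2):
        mods = [m for m in np.unique(labels) if m > 0]
        if not mods:
            break
        dm = np.stack([D[:, labels == m].mean(axis=1) for m in mods], axis=1)
        # acceptance radius per module: interpolate between the members'
        # mean distance and the unassigned background's mean distance; 0.7
        # admits weak peripheral members while background genes stay out
        # (falls back to the maximal member distance with no background)
        unassigned = labels == 0
        radii = []
        for j, m in enumerate(mods):
            mu_in = dm[labels == m, j].mean()
            if unassigned.any():
                radii.append(mu_in + 0.7 * (dm[unassigned, j].mean() - mu_in))
            else:
                radii.append(dm[labels == m, j].max())
        radii = np.asarray(radii)
        nearest = dm.argmin(axis=1)
        within = dm[np.arange(n), nearest] <= radii[nearest]
        labels = np.where(within, np.array(mods)[nearest], 0)
        for m, size in zip(*np.unique(labels[labels > 0], return_counts=True)):
            if size < min_size:
                labels[labels == m] = 0
    labels = _relabel(labels)

    # iterative eigengene merging
    history = []
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eig = {m: _eigengene(values.iloc[labels == m]) for m in mods}
        best_pair, best_cor = None, -np.inf
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                c = float(np.corrcoef(eig[a], eig[b])[0, 1])
                if c > best_cor:
                    best_cor, best_pair = c, (a, b)
        if best_cor <= 1.0 - merge_cut:
            break
        a, b = best_pair
        labels[labels == b] = a
        history.append((a, b, best_cor))
        labels = _relabel(labels)

    return ModuleAssignment(
        labels=pd.Series(labels, index=values.index, name="module"),
        merge_history=history,
    )


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber non-zero modules 1..M in decreasing size order."""
    out = np.zeros_like(labels)
    mods, counts = np.unique(labels[labels > 0], return_counts=True)
    order = mods[np.argsort(-counts, kind="stable")]
    for new, m in enumerate(order, start=1):
        out[labels == m] = new
    return out


# ---------------------------------------------------------------------------
# eigengenes, GMM, preservation
# ---------------------------------------------------------------------------


def module_eigengene(values: pd.DataFrame, assignment: ModuleAssignment) -> GMMMatrix:
    """Module eigengenes and the genes x modules GMM (kME) matrix."""
    labels = assignment.labels.loc[values.index]
    mods = sorted(set(labels) - {0})
    eig = {}
    for m in mods:
        sub = values.loc[labels == m]
        if sub.shape[0] < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        if (sub.std(axis=1, ddof=0) == 0).all():
            raise ValueError(f"module {m} consists of constant genes")
        eig[m] = _eigengene(sub)
    eigengenes = pd.DataFrame(eig, index=values.columns)
    eigengenes.columns = [f"M{m}" for m in mods]

    X = values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = Xc / np.where(
        (s := np.sqrt((Xc ** 2).sum(axis=1, keepdims=True))) == 0, 1.0, s
    )
    E = eigengenes.to_numpy()
    Ec = E - E.mean(axis=0, keepdims=True)
    En = Ec / np.where(
        (se := np.sqrt((Ec ** 2).sum(axis=0, keepdims=True))) == 0, 1.0, se
    )
    gmm = pd.DataFrame(Xn @ En, index=values.index, columns=eigengenes.columns)
    return GMMMatrix(gmm=gmm.clip(-1.0, 1.0), eigengenes=eigengenes)


_BANDS = ((2.0, "poor"), (10.0, "moderate"), (np.inf, "good"))


def preservation_band(z: float) -> str:
    for cut, name in _BANDS:
        if z < cut or cut == np.inf:
            return name
    return "good"


def module_preservation(
    reference_assignment: ModuleAssignment,
    reference_values: pd.DataFrame,
    test_values: pd.DataFrame,
    beta: int,
    n_perm: int = 200,
    seed: int = 0,
) -> PreservationReport:
    """Permutation Z-scores for module density and connectivity preservation.

    Density statistic: mean off-diagonal within-module signed adjacency in
    the test data. Connectivity statistic: Spearman correlation of
    intramodular connectivity between reference and test. Each is compared
    with random same-size gene sets drawn from the test data; Zsummary is
    the mean of the two Z-scores, banded at 2 and 10.
    """
    rng = np.random.default_rng(seed)
    labels = reference_assignment.labels
    mods = sorted(set(labels) - {0})
    cor_test = bicor(test_values).to_numpy()
    A_test = signed_adjacency(cor_test, beta)
    cor_ref = bicor(reference_values).to_numpy()
    A_ref = signed_adjacency(cor_ref, beta)
    test_pos = {g: i for i, g in enumerate(test_values.index)}
    ref_pos = {g: i for i, g in enumerate(reference_values.index)}

    rows, skipped = [], []
    for m in mods:
        genes = list(labels.index[labels == m])
        missing = [g for g in genes if g not in test_pos]
        if missing:
            logger.warning("module %s: %d genes missing from test data; skipped",
                           m, len(missing))
            skipped.append(m)
            continue
        ti = np.array([test_pos[g] for g in genes])
        ri = np.array([ref_pos[g] for g in genes])
        size = len(genes)

        def mod_stats(idx_test):
            sub = A_test[np.ix_(idx_test, idx_test)]
            dens = float((sub.sum() - np.trace(sub)) / (size * (size - 1)))
            k_test = sub.sum(axis=0) - np.diag(sub)
            return dens, k_test

        sub_ref = A_ref[np.ix_(ri, ri)]
        k_ref = sub_ref.sum(axis=0) - np.diag(sub_ref)
        dens_obs, k_test_obs = mod_stats(ti)
        conn_obs = float(stats.spearmanr(k_ref, k_test_obs)[0])

        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        n_test = A_test.shape[0]
        for p in range(n_perm):
            ridx = rng.choice(n_test, size=size, replace=False)
            d, kt = mod_stats(ridx)
            null_d[p] = d
            null_c[p] = stats.spearmanr(k_ref, kt)[0]
        zd = (dens_obs - null_d.mean()) / max(null_d.std(ddof=1), 1e-12)
        zc = (conn_obs - null_c.mean()) / max(null_c.std(ddof=1), 1e-12)
        zs = (zd + zc) / 2.0
        rows.append({
            "module": m, "size": size,
            "density": dens_obs, "connectivity": conn_obs,
            "Zdensity": zd, "Zconnectivity": zc, "Zsummary": zs,
            "band": preservation_band(zs),
        })
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    return PreservationReport(table=table, n_perm=n_perm, skipped=tuple(skipped))


def build_network(
    values: pd.DataFrame,
    beta: int | None = None,
    min_size: int = 100,
    merge_cut: float = 0.25,
):
    """Convenience chain: bicor -> power -> TOM -> modules -> eigengenes.

    Returns (NetworkParams, ModuleAssignment, GMMMatrix).
    """
    cor = bicor(values)
    if beta is None:
        params = pick_soft_threshold(cor)
    else:
        params = NetworkParams(beta=beta, candidates=(beta,),
                               fit_table=pd.DataFrame())
    A = signed_adjacency(cor, params.beta)
    _, dissim = tom(A)
    assignment = detect_modules(dissim, values, min_size=min_size, merge_cut=merge_cut)
    gmm = module_eigengene(values, assignment) if (assignment.labels > 0).any() else None
    return params, assignment, gmm
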