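"""Signed weighted co-expression network construction and module detection.

The network is built from Pearson correlations mapped through the signed
soft-threshold transform a_ij = ((1 + cor_ij)/2)^beta, so perfectly
anticorrelated genes receive adjacency 0 and the exponent beta suppresses
weak correlations.  beta is chosen as the smallest candidate whose
connectivity distribution fits scale-free topology with signed R^2 above a
target (default 0.9).  Topological overlap smooths the adjacency by shared
neighbours; modules are branches of the average-linkage dendrogram of
1 - TOM, cut by a recursive static-height rule, then merged when their
eigengenes are close and pruned by module-membership (kME) thresholds.

Module labels are assigned by decreasing size as "mod1", "mod2", ...; the
reserved label for genes outside any module is "unassigned".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"


class CoexpressionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Correlation, adjacency, TOM
# ---------------------------------------------------------------------------


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation across samples."""
    if expr.shape[1] < 3:
        raise CoexpressionError("correlation requires at least 3 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise CoexpressionError(f"gene {expr.index[zero[0]]!r} has zero variance")
    cor = np.corrcoef(values)
    np.clip(cor, -1.0, 1.0, out=cor)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Signed soft-threshold adjacency ((1 + cor)/2)^beta."""
    if beta < 1:
        raise CoexpressionError("beta must be >= 1")
    adj = ((1.0 + cor.to_numpy(dtype=float)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=cor.index, columns=cor.columns)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbour smoothing of the adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with connectivity k_i = sum_{u != i} a_iu; the diagonal is 1.
    Since k_i >= a_ij the denominator is always >= 1.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# Soft-threshold selection
# ---------------------------------------------------------------------------


@dataclass
class SoftThresholdReport:
    """Scale-free fit per candidate power and the chosen power (if any)."""

    table: pd.DataFrame  # columns: power, r_squared, mean_connectivity
    chosen: int | None
    target_r2: float


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    """Signed scale-free fit index of a connectivity distribution.

    Connectivities are binned into equal-width bins on k, the bin frequency
    is regressed on the mean bin connectivity on log-log axes, and R^2 is
    signed by -sign(slope) so an increasing (anti-scale-free) distribution
    cannot pass a positive target.
    """
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - (resid**2).sum() / ss_tot
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: list[int] | None = None,
    *,
    target_r2: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdReport:
    """Scan candidate powers; choose the smallest with signed R^2 > target."""
    if powers is None:
        powers = list(range(1, 21))
    if not powers:
        raise CoexpressionError("powers must be non-empty")
    cor = pearson_matrix(expr).to_numpy()
    rows = []
    for beta in sorted(powers):
        adj = ((1.0 + cor) / 2.0) ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=0)
        if not np.any(k > 0):
            raise CoexpressionError("all connectivities are zero")
        rows.append(
            {
                "power": beta,
                "r_squared": _scale_free_fit(k, n_bins),
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows)
    passing = table.loc[table["r_squared"] > target_r2, "power"]
    chosen = int(passing.iloc[0]) if len(passing) else None
    if chosen is None:
        warnings.warn(
            f"no candidate power reached scale-free fit R^2 > {target_r2}",
            stacklevel=2,
        )
    return SoftThresholdReport(table=table, chosen=chosen, target_r2=target_r2)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------


def _cut_recursive(
    dissim: np.ndarray,
    indices: np.ndarray,
    min_module_size: int,
    cut_quantile: float,
    deep_split: int,
) -> list[np.ndarray]:
    """Static-height cut at a merge-height quantile with recursive sub-splits.

    A cluster is re-examined only when deep_split >= 2 and it is large
    enough to hold two modules; a sub-split is accepted when it yields at
    least two children of minimum module size.
    """
    if indices.size < 2:
        return [indices]
    sub = dissim[np.ix_(indices, indices)]
    Z = linkage(squareform(sub, checks=False), method="average")
    height = np.quantile(Z[:, 2], cut_quantile)
    labels = fcluster(Z, t=height, criterion="distance")
    clusters = [indices[labels == lab] for lab in np.unique(labels)]
    if len(clusters) == 1:
        return clusters
    result: list[np.ndarray] = []
    for cluster in clusters:
        if deep_split >= 2 and cluster.size >= 2 * min_module_size:
            children = _cut_recursive(
                dissim, cluster, min_module_size, cut_quantile, deep_split
            )
            if sum(child.size >= min_module_size for child in children) >= 2:
                result.extend(children)
                continue
        result.append(cluster)
    return result


def _relabel_by_size(partition: pd.Series) -> pd.Series:
    """Rename modules to mod1, mod2, ... by decreasing size (stable ties)."""
    sizes = partition[partition != UNASSIGNED].value_counts()
    first_seen = {lab: i for i, lab in enumerate(pd.unique(partition))}
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], first_seen[lab]))
    mapping = {lab: f"mod{i + 1}" for i, lab in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return partition.map(mapping)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    *,
    cut_quantile: float = 0.99,
) -> pd.Series:
    """Branches of the average-linkage dendrogram of 1 - TOM.

    Clusters below ``min_module_size`` are assigned the reserved label;
    module labels run by decreasing size.
    """
    if min_module_size < 2:
        raise CoexpressionError("min_module_size must be >= 2")
    genes = tom.index
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    clusters = _cut_recursive(
        dissim, np.arange(len(genes)), min_module_size, cut_quantile, deep_split
    )
    labels = np.array([UNASSIGNED] * len(genes), dtype=object)
    for i, cluster in enumerate(clusters):
        if cluster.size >= min_module_size:
            labels[cluster] = f"raw{i}"
    return _relabel_by_size(pd.Series(labels, index=genes, name="module"))


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise CoexpressionError("module contains a zero-variance gene")
    return (values - mean) / sd


def module_eigengenes(expr: pd.DataFrame, partition: pd.Series) -> pd.DataFrame:
    """First principal component per module, oriented and standardized.

    Member genes are standardized across samples; the eigengene is the
    leading right singular vector of the module matrix, scaled to unit
    variance and oriented to correlate positively with the module's mean
    standardized profile.
    """
    modules = [m for m in pd.unique(partition) if m != UNASSIGNED]
    profiles = {}
    for module in modules:
        genes = partition.index[partition == module]
        if len(genes) < 2:
            raise CoexpressionError(f"module {module!r} has fewer than 2 genes")
        X = _standardize_rows(expr.loc[genes].to_numpy(dtype=float))
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        score = vt[0]
        mean_profile = X.mean(axis=0)
        if np.dot(score - score.mean(), mean_profile) < 0:
            score = -score
        score = (score - score.mean()) / score.std()
        profiles[module] = score
    me = pd.DataFrame(profiles, index=expr.columns).T
    me.index.name = "module"
    return me.loc[sorted(profiles, key=_module_sort_key)]


def _module_sort_key(label: str):
    digits = "".join(c for c in label if c.isdigit())
    return (int(digits) if digits else 0, label)


def eigengene_correlation(gene_profile: np.ndarray, eigengene: np.ndarray) -> float:
    gp = gene_profile - gene_profile.mean()
    eg = eigengene - eigengene.mean()
    denom = np.sqrt((gp**2).sum() * (eg**2).sum())
    return float(gp @ eg / denom) if denom > 0 else 0.0


# ---------------------------------------------------------------------------
# Module merging and kME pruning
# ---------------------------------------------------------------------------


def merge_close_modules(
    expr: pd.DataFrame,
    partition: pd.Series,
    *,
    cut_height: float = 0.25,
) -> pd.Series:
    """Merge modules whose eigengenes are closer than ``cut_height``.

    Eigengene dissimilarity is 1 - cor; the closest pair is merged first and
    eigengenes are recomputed after every merge until no pair remains below
    the cut.
    """
    partition = partition.copy()
    if cut_height <= 0:
        return _relabel_by_size(partition)
    while True:
        modules = [m for m in pd.unique(partition) if m != UNASSIGNED]
        if len(modules) < 2:
            break
        me = module_eigengenes(expr, partition)
        cor = np.corrcoef(me.to_numpy())
        dissim = 1.0 - cor
        np.fill_diagonal(dissim, np.inf)
        i, j = np.unravel_index(np.argmin(dissim), dissim.shape)
        if dissim[i, j] >= cut_height:
            break
        keep, absorb = me.index[i], me.index[j]
        partition[partition == absorb] = keep
    return _relabel_by_size(partition)


def module_membership(
    expr: pd.DataFrame, partition: pd.Series, eigengenes: pd.DataFrame
) -> pd.Series:
    """kME: correlation of each assigned gene with its own module eigengene."""
    kme = {}
    values = expr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    for module in eigengenes.index:
        eg = eigengenes.loc[module].to_numpy()
        for gene in partition.index[partition == module]:
            kme[gene] = eigengene_correlation(values[gene_pos[gene]], eg)
    return pd.Series(kme, name="kme")


def apply_kme_filters(
    expr: pd.DataFrame,
    partition: pd.Series,
    eigengenes: pd.DataFrame,
    *,
    min_kme_to_stay: float = 0.3,
    min_core_kme: float = 0.5,
    min_core_size: int = 10,
) -> pd.Series:
    """Prune weakly connected members and dissolve coreless modules.

    A member whose kME falls below ``min_kme_to_stay`` is unassigned; a
    module without at least ``min_core_size`` members at kME >=
    ``min_core_kme`` is dissolved entirely.
    """
    partition = partition.copy()
    kme = module_membership(expr, partition, eigengenes)
    for module in eigengenes.index:
        members = partition.index[partition == module]
        member_kme = kme.loc[members]
        core = int((member_kme >= min_core_kme).sum())
        if core < min_core_size:
            partition[members] = UNASSIGNED
            continue
        weak = member_kme.index[member_kme < min_kme_to_stay]
        partition[weak] = UNASSIGNED
    return _relabel_by_size(partition)
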