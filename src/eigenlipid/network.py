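"""Weighted correlation network analysis of the CLR lipid matrix.

From the CLR view of one ocean region this module builds a soft-thresholded
correlation network over lipids, converts it to topological overlap,
detects co-occurring lipid clusters (eigenlipid clusters, ELs) by
average-linkage clustering of 1−TOM with a tree-variant dynamic cut,
summarizes each cluster by its eigenlipid (first principal component of
the member profiles), scores cluster membership by Spearman correlation,
projects held-out regions onto the reference eigenlipids, and quantifies
cluster reproducibility with an in-group proportion (IGP) permutation test.

The network correlation is Pearson on CLR values (CLR already removes
per-sample scale); membership scores are Spearman. The network is signed
by default: a_ij = ((1+cor_ij)/2)^β, preserving the sign of co-occurrence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .containers import ConfigurationError, DegenerateDataError, FeatureTable


# --- adjacency and topological overlap ------------------------------------


@dataclass
class NetworkMatrices:
    """Correlation, adjacency and derived network quantities over lipids."""

    correlation: pd.DataFrame
    adjacency: pd.DataFrame
    beta: float
    mode: str  # "signed" | "unsigned"

    @property
    def connectivity(self) -> pd.Series:
        a = self.adjacency.to_numpy().copy()
        np.fill_diagonal(a, 0.0)
        return pd.Series(a.sum(axis=1), index=self.adjacency.index, name="k")


def _clr_matrix(clr: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(clr, FeatureTable):
        if clr.view != "clr":
            raise DegenerateDataError("network analysis expects the clr view")
        return clr.data
    return clr


def lipid_correlation(clr: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between lipids across samples."""
    data = _clr_matrix(clr)
    values = data.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(data.index[sd == 0][:5])
        raise DegenerateDataError(f"constant lipid profiles, correlation undefined: {bad}")
    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=data.index, columns=data.index)


def adjacency(
    clr: FeatureTable | pd.DataFrame,
    beta: float = 6.0,
    mode: str = "signed",
    correlation: Optional[pd.DataFrame] = None,
) -> NetworkMatrices:
    """Soft-thresholded adjacency: |cor|^β (unsigned) or ((1+cor)/2)^β (signed)."""
    if beta < 1:
        raise ConfigurationError("soft power β must be ≥ 1")
    if mode not in ("signed", "unsigned"):
        raise ConfigurationError(f"unknown network mode {mode!r}")
    cor = correlation if correlation is not None else lipid_correlation(clr)
    c = cor.to_numpy(dtype=float)
    if mode == "unsigned":
        a = np.abs(c) ** beta
    else:
        a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return NetworkMatrices(
        correlation=cor,
        adjacency=pd.DataFrame(a, index=cor.index, columns=cor.columns),
        beta=float(beta),
        mode=mode,
    )


def tom_similarity(net: NetworkMatrices) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 − a_ij)."""
    a = net.adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # Σ_u a_iu a_uj ; zero diagonal excludes u=i and u=j
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=net.adjacency.index, columns=net.adjacency.columns)


# --- soft threshold selection ----------------------------------------------


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity distribution.

    Bins k, regresses log10 p(k) on log10 mean-k per bin; returns
    (signed R², slope). R² is negated when the slope is positive.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 4:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(k[mask].mean())
        ys.append(mask.mean())
    xs = np.log10(np.asarray(xs))
    ys = np.log10(np.asarray(ys))
    if len(xs) < 3 or np.allclose(xs.std(), 0) or np.allclose(ys.std(), 0):
        return 0.0, 0.0
    slope, _ = np.polyfit(xs, ys, 1)
    r2 = float(np.corrcoef(xs, ys)[0, 1] ** 2)
    return (-r2 if slope > 0 else r2), float(slope)


def pick_soft_threshold(
    clr: FeatureTable | pd.DataFrame,
    powers: Sequence[float] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    target_fit: float = 0.8,
    mode: str = "signed",
) -> tuple[float, pd.DataFrame]:
    """Smallest soft power whose signed scale-free fit R² reaches the target.

    Returns (β, diagnostics table). If no candidate reaches the target, the
    power with the highest fit is returned with a warning.
    """
    if len(powers) < 2:
        raise ConfigurationError("need at least two candidate powers")
    cor = lipid_correlation(clr)
    rows = []
    for p in powers:
        net = adjacency(clr, beta=p, mode=mode, correlation=cor)
        k = net.connectivity.to_numpy()
        fit, slope = scale_free_fit(k)
        rows.append({"power": p, "fit_r2": fit, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    adequate = table[table["fit_r2"] >= target_fit]
    if len(adequate):
        beta = float(adequate["power"].iloc[0])
    else:
        beta = float(table.loc[table["fit_r2"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reached scale-free fit {target_fit}; "
            f"using β={beta} (fit {table['fit_r2'].max():.2f})"
        )
    return beta, table


# --- module detection (tree-variant dynamic cut) ---------------------------


def _size(node) -> int:
    return node.get_count()


def _carve(node, attach: float, min_size: int, join_ratio: float, split_ratio: float, out: list) -> None:
    """Recursive branch identification by merge-height ratios.

    A subtree is a *distinct branch* when its top internal merge is
    markedly lower than the height at which it attaches to the rest of the
    tree (``dist ≤ join_ratio × attach``); otherwise the recursion
    descends, which strips straggler leaves and loose noise subtrees one
    merge at a time. A distinct branch is still split when its own top
    merge is a decisive boundary between two sizable tight sub-branches
    (both children ≥ ``min_size`` leaves and every child's internal merge
    ≤ ``split_ratio`` × the branch height).
    """
    if node.is_leaf():
        return
    if node.dist > join_ratio * attach:
        _carve(node.left, node.dist, min_size, join_ratio, split_ratio, out)
        _carve(node.right, node.dist, min_size, join_ratio, split_ratio, out)
        return
    left, right = node.left, node.right
    decisive = (
        _size(left) >= min_size
        and _size(right) >= min_size
        and max(left.dist, right.dist) <= split_ratio * node.dist
    )
    if decisive:
        _carve(left, node.dist, min_size, join_ratio, split_ratio, out)
        _carve(right, node.dist, min_size, join_ratio, split_ratio, out)
        return
    out.append(node)


@dataclass
class EigenlipidSet:
    """Cluster labels, eigenlipid profiles and membership for one analysis."""

    labels: pd.Series  # per lipid; 0 = EL0 (unassigned)
    profiles: Optional[pd.DataFrame] = None  # samples × EL
    loadings: dict[int, pd.Series] = field(default_factory=dict)
    singular_values: dict[int, float] = field(default_factory=dict)
    explained_variance: dict[int, float] = field(default_factory=dict)
    membership: Optional[pd.DataFrame] = None

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in set(self.labels) if m > 0)

    @property
    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels > 0].value_counts().sort_index()
        counts.index = [int(i) for i in counts.index]
        return counts

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 10,
    cut_fraction: float = 0.99,
    join_ratio: float = 0.75,
    split_ratio: float = 0.7,
) -> EigenlipidSet:
    """Average-linkage clustering of 1−TOM with a tree-variant dynamic cut.

    The dendrogram of 1−TOM is traversed top-down (the root is always cut;
    ``cut_fraction`` sets its nominal attach height). Branches are
    identified by merge-height fluctuation: a subtree counts as a branch
    only when its internal merges sit clearly below its attachment height
    (ratio ≤ ``join_ratio``), so straggler leaves and loose noise subtrees
    that join high on a branch are stripped instead of absorbed; a branch
    is split further at decisive internal boundaries (see :func:`_carve`).
    Branches smaller than ``min_module_size`` become EL0, and modules are
    relabeled EL1, EL2, … by decreasing size.
    """
    if min_module_size < 2:
        raise ConfigurationError("min_module_size must be ≥ 2")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = average(squareform(diss, checks=False))
    tree = to_tree(z)
    max_h = float(z[:, 2].max()) if len(z) else 0.0
    labels = pd.Series(0, index=tom.index, dtype=int)
    if max_h <= 0:
        # all lipids identical: one module containing everything
        if len(tom.index) >= min_module_size:
            labels[:] = 1
        return EigenlipidSet(labels=labels)

    candidates: list = []
    _carve(tree, max_h / cut_fraction, min_module_size, join_ratio, split_ratio, candidates)
    modules = []
    for node in candidates:
        leaves = node.pre_order(lambda n: n.id)
        if len(leaves) >= min_module_size:
            modules.append(leaves)

    modules.sort(key=lambda lv: (-len(lv), min(lv)))
    for m, leaves in enumerate(modules, start=1):
        labels.iloc[leaves] = m
    return EigenlipidSet(labels=labels)


# --- eigenlipids, membership, projection -----------------------------------


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def compute_eigenlipids(clr: FeatureTable | pd.DataFrame, labels: pd.Series) -> EigenlipidSet:
    """First principal component of each module's member CLR profiles.

    Member profiles are standardized across samples; the eigenlipid is the
    unit-norm first right singular vector (a profile over samples), with its
    sign oriented to correlate positively with the mean member profile. A
    single-member module degenerates to that lipid's standardized profile.
    """
    data = _clr_matrix(clr)
    modules = sorted(int(m) for m in set(labels) if m > 0)
    if not modules:
        raise DegenerateDataError("no modules to summarize")
    profiles = {}
    loadings: dict[int, pd.Series] = {}
    svs: dict[int, float] = {}
    expl: dict[int, float] = {}
    n_samples = data.shape[1]
    for m in modules:
        member_ids = [i for i in labels.index[labels == m] if i in data.index]
        if not member_ids:
            continue
        x = _standardize_rows(data.loc[member_ids].to_numpy(dtype=float))
        if x.shape[0] == 1:
            v = x[0] / np.linalg.norm(x[0])
            u = np.array([1.0])
            s1 = float(np.linalg.norm(x[0]))
            expl[m] = 1.0
        else:
            u_all, s_all, vt = np.linalg.svd(x, full_matrices=False)
            v = vt[0]
            u = u_all[:, 0]
            s1 = float(s_all[0])
            expl[m] = float(s_all[0] ** 2 / (s_all**2).sum())
        mean_profile = x.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
            u = -u
        profiles[f"EL{m}"] = v
        loadings[m] = pd.Series(u, index=member_ids)
        svs[m] = s1
    return EigenlipidSet(
        labels=labels.copy(),
        profiles=pd.DataFrame(profiles, index=data.columns),
        loadings=loadings,
        singular_values=svs,
        explained_variance=expl,
    )


def membership_scores(clr: FeatureTable | pd.DataFrame, elset: EigenlipidSet) -> pd.DataFrame:
    """Spearman ρ of every lipid with every eigenlipid profile over samples."""
    if elset.profiles is None:
        raise DegenerateDataError("eigenlipid profiles not computed")
    data = _clr_matrix(clr)
    x = np.apply_along_axis(rankdata, 1, data.to_numpy(dtype=float))
    e = np.apply_along_axis(rankdata, 0, elset.profiles.to_numpy(dtype=float))
    x_sd = x.std(axis=1)
    e_sd = e.std(axis=0)
    xc = x - x.mean(axis=1, keepdims=True)
    ec = e - e.mean(axis=0, keepdims=True)
    num = xc @ ec / x.shape[1]
    denom = np.outer(x_sd, e_sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / denom
    rho[~np.isfinite(rho)] = np.nan
    return pd.DataFrame(rho, index=data.index, columns=elset.profiles.columns)


def project_region(
    clr_other: FeatureTable | pd.DataFrame,
    reference: EigenlipidSet,
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigenlipid values for new samples from the reference PC loadings.

    Member lipids missing from the new data are dropped and the loading
    vector renormalized; returns (profiles, overlap fraction per EL).
    Projecting the training data reproduces :func:`compute_eigenlipids`.
    """
    data = _clr_matrix(clr_other)
    if reference.profiles is None:
        raise DegenerateDataError("reference eigenlipids not computed")
    out = {}
    overlap = {}
    for m, u in reference.loadings.items():
        present = [i for i in u.index if i in data.index]
        overlap[f"EL{m}"] = len(present) / len(u)
        if not present:
            warnings.warn(f"EL{m}: no member lipids present in projected data")
            out[f"EL{m}"] = np.full(data.shape[1], np.nan)
            continue
        x = _standardize_rows(data.loc[present].to_numpy(dtype=float))
        w = u.loc[present].to_numpy(dtype=float)
        if len(present) < len(u):
            w = w / np.linalg.norm(w)
            out[f"EL{m}"] = x.T @ w
        else:
            out[f"EL{m}"] = x.T @ w / reference.singular_values[m]
    profiles = pd.DataFrame(out, index=data.columns)
    return profiles, pd.Series(overlap, name="overlap")


# --- in-group proportion reproducibility -----------------------------------


@dataclass
class IGPResult:
    """In-group proportion score and permutation p-value per EL."""

    igp: pd.Series
    p_value: pd.Series
    n_permutations: int
    seed: int
    null_mean: pd.Series
    null_sd: pd.Series


def _igp_scores(x_std: np.ndarray, labels: np.ndarray, modules: np.ndarray) -> np.ndarray:
    """IGP per module for standardized lipid profiles and integer labels.

    Each lipid's correlation to its *own* module centroid is computed
    leave-one-out (the lipid is removed from the centroid first), so that
    under random relabeling every module is exchangeable and the expected
    IGP is exactly 1/k. Rows of ``x_std`` are standardized (mean 0, sd 1),
    hence zero-mean dot products give Pearson correlations directly.
    """
    n = x_std.shape[1]
    sums = np.vstack([x_std[labels == m].sum(axis=0) for m in modules])  # k × samples
    dots = x_std @ sums.T  # lipid × module: x_i · S_m
    norm_s = (sums**2).sum(axis=1)  # ||S_m||²
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = dots / (np.sqrt(n) * np.sqrt(norm_s)[None, :])
    sizes = np.array([(labels == m).sum() for m in modules])
    for j, m in enumerate(modules):
        members = labels == m
        if sizes[j] < 2:
            cor[members, j] = 1.0  # leave-one-out undefined for singletons
            continue
        d = dots[members, j]
        loo_norm = norm_s[j] - 2.0 * d + n  # ||S_m − x_i||²
        with np.errstate(invalid="ignore", divide="ignore"):
            cor[members, j] = (d - n) / (np.sqrt(n) * np.sqrt(np.maximum(loo_norm, 1e-12)))
    nearest = modules[np.argmax(cor, axis=1)]
    return np.array([(nearest[labels == m] == m).mean() for m in modules])


def igp_reproducibility(
    clr_validation: FeatureTable | pd.DataFrame,
    reference: EigenlipidSet,
    n_perm: int = 999,
    seed: int = 0,
) -> IGPResult:
    """Permutation test of cluster reproducibility via in-group proportion.

    Each reference member lipid present in the validation data is assigned
    to the nearest EL centroid by correlation distance (its own centroid is
    computed leave-one-out, which makes the shuffle null exactly uniform);
    the IGP of an EL is the fraction of its members whose nearest centroid
    is their own EL. The null permutes the lipid→EL assignment ``n_perm``
    times (centroids recomputed each time);
    p = (1 + #{null ≥ observed}) / (n_perm + 1).
    """
    data = _clr_matrix(clr_validation)
    if data.shape[1] < 3:
        raise DegenerateDataError("need ≥ 3 validation samples")
    if n_perm < 99:
        raise ConfigurationError("n_perm must be ≥ 99")
    members = [i for i in reference.labels.index if reference.labels[i] > 0 and i in data.index]
    labels = reference.labels.loc[members].to_numpy(dtype=int)
    modules = np.array(sorted(set(labels)))
    skipped = [m for m in reference.module_ids if m not in modules]
    if skipped:
        warnings.warn(f"ELs absent from validation data, skipped: {skipped}")
    x = _standardize_rows(data.loc[members].to_numpy(dtype=float))
    sd0 = data.loc[members].to_numpy(dtype=float).std(axis=1)
    if (sd0 == 0).any():
        raise DegenerateDataError("constant lipid profiles in validation data")
    observed = _igp_scores(x, labels, modules)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(modules))
    null_scores = np.empty((n_perm, len(modules)))
    for i in range(n_perm):
        perm = rng.permutation(labels)
        null = _igp_scores(x, perm, modules)
        exceed += null >= observed
        null_scores[i] = null
    names = [f"EL{m}" for m in modules]
    return IGPResult(
        igp=pd.Series(observed, index=names, name="igp"),
        p_value=pd.Series((1.0 + exceed) / (n_perm + 1.0), index=names, name="p"),
        n_permutations=n_perm,
        seed=seed,
        null_mean=pd.Series(null_scores.mean(axis=0), index=names, name="null_mean"),
        null_sd=pd.Series(null_scores.std(axis=0, ddof=1), index=names, name="null_sd"),
    )
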