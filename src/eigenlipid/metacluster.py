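"""Meta-clustering of ELs across distributional, geographic and depth views.

Three EL × EL distance matrices — distributional (1 − Pearson correlation
of eigenlipid sample profiles), province (correlation distance between
per-province mean relative intensities in the mixed layer) and depth
(Euclidean distance between standardized per-depth-bin mean profiles) —
are min-max normalized and combined as a weighted mean. The integrated
matrix is clustered by average linkage; internal nodes are tested by a
Monte Carlo Gaussian null on a 2-group cluster index, and consistency is
reported as the cophenetic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, cut_tree, fcluster, to_tree
from scipy.spatial.distance import pdist, squareform

from .containers import ConfigurationError, DegenerateDataError
from .spatial import mixed_layer_samples

#: depth bins (m) used to align stations with different sampling depths
DEFAULT_DEPTH_BINS = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0)


@dataclass
class ELDistanceSet:
    """The three component distances, their weights and the integrated matrix."""

    distributional: pd.DataFrame
    province: pd.DataFrame
    depth: pd.DataFrame
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        idx = self.distributional.index
        for name in ("province", "depth"):
            other = getattr(self, name)
            if not other.index.equals(idx) or not other.columns.equals(idx):
                missing = idx.difference(other.index)
                raise DegenerateDataError(
                    f"{name} distance does not cover all ELs (missing: {list(missing)})"
                )

    @property
    def integrated(self) -> pd.DataFrame:
        w = np.asarray(self.weights, dtype=float)
        if w.sum() <= 0:
            raise ConfigurationError("distance weights must have positive sum")
        w = w / w.sum()
        total = (
            w[0] * self.distributional.to_numpy()
            + w[1] * self.province.to_numpy()
            + w[2] * self.depth.to_numpy()
        )
        np.fill_diagonal(total, 0.0)
        return pd.DataFrame(total, index=self.distributional.index, columns=self.distributional.columns)


def _minmax(d: np.ndarray) -> np.ndarray:
    off = ~np.eye(d.shape[0], dtype=bool)
    lo, hi = d[off].min(), d[off].max()
    if hi > lo:
        d = (d - lo) / (hi - lo)
    elif hi > 0:
        d = d / hi
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """1 − Pearson between rows (constant rows → distance 1 to everything)."""
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        cor = np.zeros((len(profiles), len(profiles)))
        ok = sd > 0
        if ok.sum() >= 2:
            cor[np.ix_(ok, ok)] = np.corrcoef(profiles[ok])
        np.fill_diagonal(cor, 1.0)
    else:
        cor = np.corrcoef(profiles)
    return 1.0 - np.clip(cor, -1.0, 1.0)


def build_distances(
    el_profiles: pd.DataFrame,
    el_table: pd.DataFrame,
    metadata: pd.DataFrame,
    depth_bins: Sequence[float] = DEFAULT_DEPTH_BINS,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ELDistanceSet:
    """The three EL × EL distances, each min-max normalized to [0, 1].

    ``el_profiles``: samples × EL eigenlipid profiles (distributional view);
    ``el_table``: samples × EL relative intensities (province/depth views).
    """
    els = [c for c in el_profiles.columns if c != "EL0"]
    if len(els) < 3:
        raise DegenerateDataError("need ≥ 3 ELs for meta-clustering")
    missing = [c for c in els if c not in el_table.columns]
    if missing:
        raise DegenerateDataError(f"ELs missing from the intensity table: {missing}")

    distributional = _correlation_distance(el_profiles[els].to_numpy(dtype=float).T)

    ml = mixed_layer_samples(metadata).intersection(el_table.index)
    prov_means = (
        el_table.loc[ml, els].groupby(metadata.loc[ml, "province"]).mean()
    )  # provinces × ELs
    province = _correlation_distance(prov_means.to_numpy(dtype=float).T)

    bins = np.asarray(depth_bins, dtype=float)
    bin_idx = pd.cut(metadata.loc[el_table.index, "depth"], bins=bins, include_lowest=True)
    depth_means = el_table[els].groupby(bin_idx, observed=True).mean()  # bins × ELs
    z = depth_means.to_numpy(dtype=float).T  # ELs × bins
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (z - z.mean(axis=1, keepdims=True)) / sd
    depth = squareform(pdist(z, metric="euclidean"))

    return ELDistanceSet(
        distributional=pd.DataFrame(_minmax(distributional), index=els, columns=els),
        province=pd.DataFrame(_minmax(province), index=els, columns=els),
        depth=pd.DataFrame(_minmax(depth), index=els, columns=els),
        weights=weights,
    )


@dataclass
class MetaDendrogram:
    """Average-linkage tree over ELs with meta-cluster labels."""

    linkage: np.ndarray
    leaves: list[str]
    meta_labels: pd.Series  # MC1..MCk per EL
    k: int
    cophenetic: float
    node_p: Optional[pd.DataFrame] = None


def meta_dendrogram(distances: ELDistanceSet, k: int = 3) -> MetaDendrogram:
    """Cluster the integrated distance and cut into k meta-clusters.

    Meta-cluster labels are stable under EL input order: clusters are
    numbered by the smallest EL index they contain.
    """
    d = distances.integrated
    n = d.shape[0]
    if not (2 <= k <= n - 1):
        raise ConfigurationError(f"k={k} out of range for {n} ELs")
    order = np.argsort([_el_number(e) for e in d.index])
    leaves = [d.index[i] for i in order]
    dm = d.to_numpy()[np.ix_(order, order)]
    z = average(squareform(dm, checks=False))
    flat = cut_tree(z, n_clusters=k).ravel() + 1
    coph = cophenetic_correlation(z, dm)
    relabel: dict[int, int] = {}
    labels = []
    for c in flat:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels.append(f"MC{relabel[c]}")
    return MetaDendrogram(
        linkage=z,
        leaves=list(leaves),
        meta_labels=pd.Series(labels, index=leaves, name="meta_cluster"),
        k=k,
        cophenetic=coph,
    )


def _el_number(name: str) -> int:
    digits = "".join(ch for ch in str(name) if ch.isdigit())
    return int(digits) if digits else hash(name) % 10_000


def cophenetic_correlation(linkage: np.ndarray, distance: np.ndarray | pd.DataFrame) -> float:
    """Pearson correlation between original and cophenetic (merge-height) distances."""
    if isinstance(distance, pd.DataFrame):
        distance = distance.to_numpy()
    if distance.shape[0] < 3:
        raise DegenerateDataError("cophenetic correlation undefined for < 3 leaves")
    coph = cophenet(linkage)
    orig = squareform(distance, checks=False)
    if orig.std() == 0 or coph.std() == 0:
        return 1.0 if np.allclose(orig, coph) else np.nan
    return float(np.corrcoef(orig, coph)[0, 1])


# --- Monte Carlo node significance -----------------------------------------


def _two_group_index(x: np.ndarray, split: np.ndarray) -> float:
    """Within-cluster sum of squares of a 2-way split over total WSS."""
    total = ((x - x.mean(axis=0)) ** 2).sum()
    if total == 0:
        return 1.0
    within = 0.0
    for g in (0, 1):
        sub = x[split == g]
        if len(sub):
            within += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(within / total)


def _best_two_split(x: np.ndarray) -> np.ndarray:
    z = average(pdist(x, metric="euclidean"))
    return (cut_tree(z, n_clusters=2).ravel()).astype(int)


def node_significance(
    el_features: pd.DataFrame,
    dendrogram: MetaDendrogram,
    n_sim: int = 499,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo Gaussian test of each internal node of the meta-dendrogram.

    For a node's ELs the observed statistic is the 2-group cluster index of
    the node's split (within-cluster sum of squares ratio). The null draws
    ``n_sim`` datasets from a single Gaussian fitted to the node's feature
    vectors (mean and diagonal-inflated covariance), re-clusters each, and
    computes p = (1 + #{simulated index ≤ observed}) / (n_sim + 1). The
    tree is descended sequentially: children are only tested below
    significant nodes (family-wise control by the sequential rule).
    """
    if n_sim < 99:
        raise ConfigurationError("n_sim must be ≥ 99")
    rng = np.random.default_rng(seed)
    x_all = el_features.loc[dendrogram.leaves].to_numpy(dtype=float)
    tree = to_tree(dendrogram.linkage)
    rows: list[dict] = []

    def leaf_ids(node) -> list[int]:
        return node.pre_order(lambda n: n.id)

    def test(node, gate_open: bool) -> None:
        if node.is_leaf():
            return
        ids = leaf_ids(node)
        if len(ids) < 3:
            rows.append({"node": node.id, "n_leaves": len(ids), "p": np.nan,
                         "tested": False, "note": "fewer than 3 leaves"})
            return
        if not gate_open:
            rows.append({"node": node.id, "n_leaves": len(ids), "p": np.nan,
                         "tested": False, "note": "parent not significant"})
            test(node.left, False)
            test(node.right, False)
            return
        x = x_all[ids]
        left = set(leaf_ids(node.left))
        split = np.array([0 if i in left else 1 for i in ids])
        observed = _two_group_index(x, split)
        mu = x.mean(axis=0)
        var = x.var(axis=0, ddof=1)
        var = var + 0.05 * var.mean() + 1e-12  # diagonal inflation
        count = 0
        for _ in range(n_sim):
            sim = rng.normal(mu, np.sqrt(var), size=x.shape)
            sim_split = _best_two_split(sim)
            count += _two_group_index(sim, sim_split) <= observed
        p = (1.0 + count) / (n_sim + 1.0)
        significant = p <= alpha
        rows.append({"node": node.id, "n_leaves": len(ids), "p": p,
                     "tested": True, "note": "", "significant": significant})
        test(node.left, significant)
        test(node.right, significant)

    test(tree, True)
    out = pd.DataFrame(rows).set_index("node")
    return out
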