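"""Structural composition of ELs and structural-vs-distributional comparison.

Each EL gets an intensity-weighted structural profile (headgroup
composition, mean chain length, unsaturation, saturation-class and
phosphorus-free fractions); profiles are compared by a Gower-type distance
and clustered; per-sample structural properties are tested with a
random-intercept mixed model (EL fixed, sample random); and the structural
dendrogram is compared with the distributional meta-dendrogram via
tanglegram entanglement after two-sided stepwise untangling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform

from .containers import DegenerateDataError, FeatureTable
from .lipids import LipidSpecies, classify_saturation
from .stats import bh_adjust

#: ELs need at least this many headgroup-annotated species to enter the analysis
MIN_ANNOTATED_SPECIES = 5


# --- structural profiles ----------------------------------------------------


def structural_profiles(
    labels: pd.Series,
    species: dict[str, LipidSpecies],
    features: FeatureTable,
    min_annotated: int = MIN_ANNOTATED_SPECIES,
) -> pd.DataFrame:
    """Intensity-weighted structural profile per EL.

    Weights are each member's mean relative intensity across samples. ELs
    with fewer than ``min_annotated`` species carrying a recognized
    headgroup are excluded; the excluded list is recorded in
    ``result.attrs["excluded"]``.
    """
    if features.view == "raw":
        rel = features.data.div(features.data.sum(axis=0), axis=1)
    elif features.view == "relative":
        rel = features.data
    else:
        raise DegenerateDataError("structural_profiles expects raw or relative intensities")
    mean_rel = rel.mean(axis=1)
    rows = {}
    excluded = []
    for m in sorted(set(labels[labels > 0])):
        member_ids = [i for i in labels.index[labels == m] if i in species and i in mean_rel.index]
        annotated = [i for i in member_ids if species[i].headgroup != "other"]
        if len(annotated) < min_annotated:
            excluded.append(f"EL{m}")
            continue
        w = mean_rel.loc[annotated].to_numpy(dtype=float)
        if w.sum() == 0:
            excluded.append(f"EL{m}")
            continue
        w = w / w.sum()
        sp = [species[i] for i in annotated]
        hg_comp: dict[str, float] = {}
        for wi, s in zip(w, sp):
            hg_comp[s.headgroup] = hg_comp.get(s.headgroup, 0.0) + wi
        pufa = np.array([classify_saturation(s).species_class == "PUFA-containing" for s in sp])
        odd = np.array([s.total_carbons % 2 == 1 for s in sp])
        no_p = np.array([not s.has_phosphorus for s in sp])
        cpf = np.array([s.carbons_per_chain for s in sp])
        dbpc = np.array([s.total_double_bonds / s.n_chains for s in sp])
        row = {f"hg_{h}": v for h, v in hg_comp.items()}
        row.update(
            {
                "mean_chain_length": float(w @ cpf),
                "mean_double_bonds": float(w @ dbpc),
                "frac_pufa": float(w @ pufa),
                "frac_phosphorus_free": float(w @ no_p),
                "frac_odd_chain": float(w @ odd),
                "n_species": len(annotated),
            }
        )
        rows[f"EL{m}"] = row
    if not rows:
        raise DegenerateDataError("no EL retains enough annotated species")
    out = pd.DataFrame(rows).T.fillna(0.0)
    out.attrs["excluded"] = excluded
    return out


# --- mixed-effects structural model -----------------------------------------


def property_mixed_model(values: pd.DataFrame, fdr_level: float = 0.05) -> pd.DataFrame:
    """Random-intercept model of a structural property across ELs.

    ``values`` is long-format with columns ``sample``, ``el``, ``value``.
    Fits value ~ EL (reference-coded fixed effect) with a per-sample random
    intercept by REML; coefficients are tested with z statistics and
    BH-adjusted across EL contrasts. On non-convergence the model falls
    back to OLS with cluster-robust (by sample) standard errors, flagged in
    the ``method`` column.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"sample", "el", "value"}
    if not required.issubset(values.columns):
        raise DegenerateDataError(f"values must have columns {sorted(required)}")
    data = values.dropna(subset=["value"]).copy()
    if data["sample"].nunique() < 10:
        raise DegenerateDataError("need ≥ 10 samples for the mixed model")
    method = "mixed_reml"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("value ~ C(el)", data=data, groups=data["sample"])
            fit = model.fit(reml=True)
        if not np.all(np.isfinite(fit.bse[:-1])):
            raise ValueError("non-finite standard errors")
        params, bse = fit.params, fit.bse
        group_var = float(fit.cov_re.iloc[0, 0])
    except Exception:
        method = "ols_cluster_robust"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols("value ~ C(el)", data=data).fit(
                cov_type="cluster", cov_kwds={"groups": data["sample"]}
            )
        params, bse = ols.params, ols.bse
        group_var = np.nan
    rows = []
    for name in params.index:
        if not name.startswith("C(el)"):
            continue
        coef = float(params[name])
        se = float(bse[name])
        z = coef / se if se > 0 else np.nan
        p = 2 * (1 - _norm_cdf(abs(z))) if np.isfinite(z) else np.nan
        rows.append({"term": name, "coef": coef, "se": se, "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"])
    out["significant"] = out["p_adjusted"] < fdr_level
    out["method"] = method
    out["group_variance"] = group_var
    return out


def _norm_cdf(z: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf(z))


# --- structural dendrogram ---------------------------------------------------


@dataclass
class Dendrogram:
    """A hierarchical clustering over named leaves."""

    linkage: np.ndarray
    leaves: list[str]

    def to_newick(self) -> str:
        tree = to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def gower_distance(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Gower-type distance over structural profiles.

    Headgroup composition columns (``hg_*``) form one compositional field
    compared by total-variation distance; the numeric fields are compared
    by range-normalized absolute difference; the distance is the equal
    weight mean over valid fields. Constant numeric fields are dropped
    (returned in the notes list).
    """
    hg_cols = [c for c in profiles.columns if c.startswith("hg_")]
    numeric = [
        c
        for c in ("mean_chain_length", "mean_double_bonds", "frac_pufa",
                  "frac_phosphorus_free", "frac_odd_chain")
        if c in profiles.columns
    ]
    n = len(profiles)
    parts = []
    dropped = []
    if hg_cols:
        comp = profiles[hg_cols].to_numpy(dtype=float)
        tv = 0.5 * np.abs(comp[:, None, :] - comp[None, :, :]).sum(axis=2)
        parts.append(tv)
    for c in numeric:
        v = profiles[c].to_numpy(dtype=float)
        rng = v.max() - v.min()
        if rng == 0:
            dropped.append(c)
            continue
        parts.append(np.abs(v[:, None] - v[None, :]) / rng)
    if not parts:
        raise DegenerateDataError("no informative structural fields")
    d = np.mean(parts, axis=0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index), dropped


def structural_dendrogram(profiles: pd.DataFrame) -> tuple[Dendrogram, pd.DataFrame]:
    """Average-linkage clustering of the Gower structural distance."""
    if len(profiles) < 3:
        raise DegenerateDataError("need ≥ 3 ELs for a structural dendrogram")
    dist, dropped = gower_distance(profiles)
    if dropped:
        warnings.warn(f"constant structural fields dropped: {dropped}")
    z = average(squareform(dist.to_numpy(), checks=False))
    return Dendrogram(linkage=z, leaves=list(profiles.index)), dist


# --- tanglegram entanglement -------------------------------------------------


class _Node:
    __slots__ = ("label", "left", "right")

    def __init__(self, label=None, left=None, right=None):
        self.label = label
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def clone(self) -> "_Node":
        if self.is_leaf:
            return _Node(label=self.label)
        return _Node(left=self.left.clone(), right=self.right.clone())

    def order(self, out: list) -> None:
        if self.is_leaf:
            out.append(self.label)
        else:
            self.left.order(out)
            self.right.order(out)

    def internal_nodes(self, out: list) -> None:
        if not self.is_leaf:
            out.append(self)
            self.left.internal_nodes(out)
            self.right.internal_nodes(out)


def _build(dendro: Dendrogram) -> _Node:
    tree = to_tree(dendro.linkage)

    def rec(node) -> _Node:
        if node.is_leaf():
            return _Node(label=dendro.leaves[node.id])
        return _Node(left=rec(node.left), right=rec(node.right))

    return rec(tree)


def _leaf_order(root: _Node) -> list[str]:
    out: list[str] = []
    root.order(out)
    return out


def _score(left_order: Sequence[str], right_order: Sequence[str], exponent: float) -> float:
    n = len(left_order)
    rank_right = {lbl: i + 1 for i, lbl in enumerate(right_order)}
    num = sum(abs((i + 1) - rank_right[lbl]) ** exponent for i, lbl in enumerate(left_order))
    denom = sum(abs((i + 1) - (n - i)) ** exponent for i in range(n))
    if denom == 0:
        return 0.0
    return num / denom


@dataclass
class TanglegramResult:
    """Entanglement between two dendrograms over the same leaves."""

    entanglement: float
    entanglement_before: float
    left_order: list[str]
    right_order: list[str]
    exponent: float


def entanglement(
    left: Dendrogram,
    right: Dendrogram,
    exponent: float = 1.5,
    untangle: bool = True,
) -> TanglegramResult:
    """Normalized leaf-rank discrepancy between two dendrograms.

    Entanglement = Σ_i |r_left(i) − r_right(i)|^L normalized by the fully
    reversed configuration; 0 means identical leaf orders. With
    ``untangle`` a two-sided stepwise search flips internal-node children
    (alternating sides until no flip improves the score); untangling can
    only lower the score.
    """
    if set(left.leaves) != set(right.leaves):
        diff = set(left.leaves) ^ set(right.leaves)
        raise DegenerateDataError(f"leaf sets differ: {sorted(diff)}")
    lroot, rroot = _build(left), _build(right)
    before = _score(_leaf_order(lroot), _leaf_order(rroot), exponent)
    best = before
    best_orders = (_leaf_order(lroot), _leaf_order(rroot))
    if untangle:
        # the stepwise search is path-dependent; running it from both
        # starting sides and keeping the better optimum makes the result
        # symmetric in its two arguments
        for first in (0, 1):
            l_work, r_work = lroot.clone(), rroot.clone()
            sides = (l_work, r_work) if first == 0 else (r_work, l_work)
            current = before
            improved = True
            while improved:
                improved = False
                for root in sides:
                    nodes: list[_Node] = []
                    root.internal_nodes(nodes)
                    for node in nodes:
                        node.left, node.right = node.right, node.left
                        s = _score(_leaf_order(l_work), _leaf_order(r_work), exponent)
                        if s < current - 1e-12:
                            current = s
                            improved = True
                        else:
                            node.left, node.right = node.right, node.left
            if current < best:
                best = current
                best_orders = (_leaf_order(l_work), _leaf_order(r_work))
    return TanglegramResult(
        entanglement=best,
        entanglement_before=before,
        left_order=best_orders[0],
        right_order=best_orders[1],
        exponent=exponent,
    )
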