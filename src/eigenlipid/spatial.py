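"""EL relative intensities, vertical structure and geographic enrichment.

Relative EL intensities are computed against the total annotated-lipid
intensity of each sample; vertical structure is summarized by the depth at
which each EL peaks per station (EL maximum depth) and by the deep
chlorophyll maximum (DCM) inferred from fluorescence profiles. Contrasts
use Mann-Whitney U with Cliff's Delta effect sizes (two-sided for depth
comparisons, one-sided for province enrichment) with Benjamini-Hochberg
FDR per analysis family, and headgroup enrichment per EL uses a chi-square
goodness-of-fit against a uniform allocation across ELs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import DegenerateDataError, FeatureTable
from .lipids import LipidSpecies
from .stats import bh_adjust, cliffs_delta, mann_whitney


def el_relative_intensity(features: FeatureTable, labels: pd.Series) -> pd.DataFrame:
    """Per sample and EL: Σ member raw intensities / Σ all annotated intensities.

    EL0 (unassigned lipids) is reported as its own column so the shares
    partition each sample's total.
    """
    if features.view != "raw":
        raise DegenerateDataError("el_relative_intensity expects the raw view")
    totals = features.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateDataError(f"samples with zero total intensity: {list(zero.index[:5])}")
    labels = labels.reindex(features.data.index).fillna(0).astype(int)
    out = {}
    for m in sorted(set(labels)):
        member_ids = labels.index[labels == m]
        out[f"EL{m}"] = features.data.loc[member_ids].sum(axis=0) / totals
    return pd.DataFrame(out, index=features.data.columns)


def el_maximum_depth(el_table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per station and EL, the sampled depth of maximum relative intensity.

    Ties resolve to the shallowest depth. Stations with a single sampled
    depth are excluded (column ``n_depths`` in the attrs records coverage).
    """
    meta = metadata.loc[el_table.index]
    rows = {}
    excluded = []
    for station, idx in meta.groupby("station").groups.items():
        depths = meta.loc[idx, "depth"]
        if depths.nunique() < 2:
            excluded.append(station)
            continue
        sub = el_table.loc[idx]
        order = depths.sort_values(kind="stable")
        sub = sub.loc[order.index]
        # first occurrence of the max along the shallow→deep order = shallowest tie
        pos = sub.to_numpy().argmax(axis=0)
        rows[station] = pd.Series(order.to_numpy()[pos], index=el_table.columns)
    out = pd.DataFrame(rows).T
    out.index.name = "station"
    out.attrs["excluded_stations"] = excluded
    return out


def dcm_depth(metadata: pd.DataFrame, smooth: bool = False) -> pd.DataFrame:
    """Depth of maximum chlorophyll-a fluorescence per station.

    An optional 3-point median smoothing can be applied along depth first
    (useful for dense, noisy CTD traces; on coarse bottle-depth grids it
    erodes single-sample maxima, so it is off by default). Ties resolve
    shallowest; a monotone-decreasing profile yields the surface depth
    flagged ``no subsurface maximum``; a flat profile yields a missing DCM.
    """
    if "fluorescence" not in metadata.columns:
        raise DegenerateDataError("metadata has no fluorescence column")
    rows = []
    for station, sub in metadata.groupby("station"):
        sub = sub.sort_values("depth", kind="stable")
        f = sub["fluorescence"].to_numpy(dtype=float)
        depths = sub["depth"].to_numpy(dtype=float)
        if smooth and len(f) >= 3:
            from scipy.signal import medfilt

            f = medfilt(f, kernel_size=3)
        note = ""
        if np.all(f == f[0]):
            rows.append({"station": station, "dcm_depth": np.nan, "note": "flat profile"})
            continue
        pos = int(f.argmax())
        if pos == 0 and len(f) > 1 and not np.any(f[1:] > f[0]):
            note = "no subsurface maximum"
        rows.append({"station": station, "dcm_depth": depths[pos], "note": note})
    return pd.DataFrame(rows).set_index("station")


def depth_comparisons(
    el_max_depths: pd.DataFrame,
    dcm_depths: Optional[pd.DataFrame] = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """All EL-pair and EL-vs-DCM depth contrasts across stations.

    Two-sided Mann-Whitney U with Cliff's Delta; positive Delta means the
    y entity (first column) sits deeper than the x entity. BH adjustment
    spans the full comparison family. With < 3 stations per side the
    contrast is reported as underpowered without a p-value.
    """
    columns = {el: el_max_depths[el].dropna() for el in el_max_depths.columns}
    if dcm_depths is not None:
        columns["DCM"] = dcm_depths["dcm_depth"].dropna()
    names = list(columns)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x, y = columns[a], columns[b]
            row = {"y": a, "x": b, "n_y": len(x), "n_x": len(y)}
            if len(x) < 3 or len(y) < 3:
                row.update({"cliffs_delta": np.nan, "p": np.nan, "note": "underpowered"})
            else:
                delta = cliffs_delta(x, y)
                _, p = mann_whitney(x, y, alternative="two-sided")
                row.update({"cliffs_delta": delta, "p": p, "note": ""})
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"])
    out["significant"] = out["p_adjusted"] < fdr_level
    return out


def mixed_layer_samples(metadata: pd.DataFrame) -> pd.Index:
    """Samples whose depth is at or above the station mixed-layer depth."""
    return metadata.index[metadata["depth"] <= metadata["mixed_layer_depth"]]


def province_enrichment(
    el_table: pd.DataFrame,
    metadata: pd.DataFrame,
    min_samples: int = 3,
    fdr_level: float = 0.05,
    mixed_layer_only: bool = True,
) -> pd.DataFrame:
    """One-sided province-vs-rest enrichment per EL in the mixed layer.

    For every EL and province with enough mixed-layer samples: one-sided
    Mann-Whitney U (province greater), Cliff's Delta, BH over the full
    EL × province family.
    """
    idx = mixed_layer_samples(metadata) if mixed_layer_only else metadata.index
    idx = idx.intersection(el_table.index)
    meta = metadata.loc[idx]
    table = el_table.loc[idx]
    counts = meta["province"].value_counts()
    provinces = [p for p in counts.index if counts[p] >= min_samples]
    if len(provinces) < 2:
        raise DegenerateDataError("need ≥ 2 provinces with enough mixed-layer samples")
    rows = []
    for el in table.columns:
        for prov in provinces:
            in_p = table.loc[meta["province"] == prov, el]
            rest = table.loc[meta["province"] != prov, el]
            if len(rest) < min_samples:
                continue
            delta = cliffs_delta(in_p, rest)
            _, p = mann_whitney(in_p, rest, alternative="greater")
            rows.append({"el": el, "province": prov, "cliffs_delta": delta, "p": p,
                         "n_province": len(in_p), "n_rest": len(rest)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"])
    out["significant"] = out["p_adjusted"] < fdr_level
    return out


def headgroup_enrichment(
    labels: pd.Series,
    species: dict[str, LipidSpecies],
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Chi-square goodness-of-fit of headgroup counts per EL vs uniform.

    For each EL and headgroup the observed member count is compared with
    the expectation total-count-of-headgroup / number-of-ELs; χ² is summed
    over ELs per headgroup with df = #ELs − 1, BH-adjusted.
    """
    assigned = labels[labels > 0]
    modules = sorted(set(assigned))
    if len(modules) < 2:
        raise DegenerateDataError("need ≥ 2 ELs for headgroup enrichment")
    hg = pd.Series({fid: species[fid].headgroup for fid in assigned.index if fid in species})
    counts = pd.crosstab(hg, assigned.loc[hg.index])
    counts = counts.reindex(columns=modules, fill_value=0)
    rows = []
    for headgroup, obs in counts.iterrows():
        total = obs.sum()
        expected = total / len(modules)
        if expected == 0:
            rows.append({"headgroup": headgroup, "chi2": np.nan, "p": np.nan,
                         "note": "zero expected count, dropped"})
            continue
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        p = float(sps.chi2.sf(chi2, df=len(modules) - 1))
        top = int(obs.idxmax())
        rows.append({"headgroup": headgroup, "chi2": chi2, "p": p,
                     "df": len(modules) - 1, "max_el": f"EL{top}", "note": ""})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"])
    out["significant"] = out["p_adjusted"] < fdr_level
    return out


def correlate_el_with_pigment(
    el_table: pd.DataFrame,
    metadata: pd.DataFrame,
    pigment: str = "fluorescence",
    method: str = "spearman",
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Correlation of each EL's relative intensity with a pigment covariate."""
    if pigment not in metadata.columns:
        raise DegenerateDataError(f"metadata has no column {pigment!r}")
    pig = metadata.loc[el_table.index, pigment].astype(float)
    if pig.std() == 0:
        raise DegenerateDataError(f"pigment {pigment!r} is constant")
    rows = []
    for el in el_table.columns:
        x = el_table[el].astype(float)
        if method == "spearman":
            rho, p = sps.spearmanr(x, pig)
        else:
            rho, p = sps.pearsonr(x, pig)
        rows.append({"el": el, "rho": float(rho), "p": float(p), "n": len(x)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"])
    out["significant"] = out["p_adjusted"] < fdr_level
    return out
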