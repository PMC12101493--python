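"""Environmental drivers of lipid remodeling.

Homeoviscous adaptation is quantified by regressing the per-sample
intensity-weighted mean carbon number per fatty acid of membrane
glycerolipids on in-situ temperature (mixed-layer samples, separately for
SFA/MUFA- and PUFA-containing species). Relationships between EL
intensities and the environment are summarized by PCA with supplementary
covariate vectors, and driver attribution (temperature vs phosphate) uses
Random Forest regression with a 70:30 train-test split, R²-scaled
importances and individual conditional expectation (ICE) curves. Layer
contrasts compare the deep chlorophyll maximum against the mixed layer
(EL8/EL16-style ratio shifts, PUFA enrichment per class, EPA peak depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .containers import DegenerateDataError, FeatureTable
from .lipids import (
    MEMBRANE_GLYCEROLIPID_CLASSES,
    LipidSpecies,
    classify_saturation,
    contains_epa,
    select_species,
    weighted_mean_chain_length,
)
from .spatial import mixed_layer_samples
from .stats import bh_adjust, cohens_d


# --- chain length vs temperature -------------------------------------------


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    slope_ci: tuple[float, float]
    n: int


def chain_length_vs_temperature(
    features: FeatureTable,
    species: dict[str, LipidSpecies],
    metadata: pd.DataFrame,
    saturation: str = "SFA",
    headgroups: Sequence[str] = MEMBRANE_GLYCEROLIPID_CLASSES,
    mixed_layer_only: bool = True,
) -> RegressionResult:
    """OLS of per-sample weighted mean C/FA on in-situ temperature."""
    selection = select_species(species, headgroups=headgroups, saturation=saturation)
    selection = [s for s in selection if s in features.data.index]
    if not selection:
        raise DegenerateDataError(f"no {saturation} species among the selected headgroups")
    samples = features.data.columns
    if mixed_layer_only:
        samples = samples.intersection(mixed_layer_samples(metadata))
    if len(samples) < 3:
        raise DegenerateDataError("need ≥ 3 samples for the regression")
    sub = features.subset_samples(samples)
    y = weighted_mean_chain_length(sub, species, selection)
    x = metadata.loc[samples, "temperature"].astype(float)
    mask = y.notna()
    x, y = x[mask], y[mask]
    import statsmodels.api as sm

    # heteroskedasticity-robust (HC3) errors: the intensity-weighted mean is
    # a share-based statistic whose noise varies along the temperature range
    fit = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit(cov_type="HC3")
    slope, intercept = float(fit.params[1]), float(fit.params[0])
    se = float(fit.bse[1])
    tcrit = sps.t.ppf(0.975, df=len(x) - 2)
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=float(fit.rsquared),
        slope_se=se,
        slope_ci=(slope - tcrit * se, slope + tcrit * se),
        n=int(len(x)),
    )


# --- PCA of ELs vs environment ---------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × PCs
    loadings: pd.DataFrame  # ELs × PCs
    covariate_vectors: pd.DataFrame  # covariates × PCs (correlation with scores)
    projections: pd.DataFrame  # ELs × covariates (projection lengths)
    explained_variance_ratio: np.ndarray
    dropped_covariates: list[str]


def pca_el_environment(
    el_table: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: Sequence[str] = ("temperature", "po4", "depth", "fluorescence"),
    n_components: int = 2,
) -> PCAResult:
    """PCA of standardized EL intensities with supplementary covariate vectors.

    Covariates are projected as correlation vectors with the sample scores;
    each EL's projection length onto each covariate vector measures their
    association in the biplot.
    """
    x = el_table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise DegenerateDataError("constant EL intensity column")
    xs = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    k = min(n_components, vt.shape[0])
    scores = u[:, :k] * s[:k]
    # correlation-scaled loadings (biplot convention): loading_ij = cor(EL_i, PC_j)
    n_obs = xs.shape[0]
    with np.errstate(invalid="ignore"):
        loadings = vt[:k].T * s[:k] / np.sqrt(n_obs)
    loadings = np.clip(loadings, -1.0, 1.0)
    evr = (s**2) / (s**2).sum()
    dropped = []
    vec_rows = {}
    for cov in covariates:
        if cov not in metadata.columns:
            dropped.append(cov)
            continue
        v = metadata.loc[el_table.index, cov].astype(float).to_numpy()
        if v.std() == 0:
            dropped.append(cov)
            continue
        vec_rows[cov] = [float(np.corrcoef(v, scores[:, j])[0, 1]) for j in range(k)]
    if not vec_rows:
        raise DegenerateDataError("no usable covariates")
    cov_vecs = pd.DataFrame(vec_rows, index=[f"PC{j + 1}" for j in range(k)]).T
    load_df = pd.DataFrame(loadings, index=el_table.columns, columns=[f"PC{j + 1}" for j in range(k)])
    proj = {}
    for cov in cov_vecs.index:
        vec = cov_vecs.loc[cov].to_numpy()
        norm = np.linalg.norm(vec)
        proj[cov] = load_df.to_numpy() @ vec / (norm if norm > 0 else 1.0)
    projections = pd.DataFrame(proj, index=el_table.columns)
    return PCAResult(
        scores=pd.DataFrame(scores, index=el_table.index, columns=[f"PC{j + 1}" for j in range(k)]),
        loadings=load_df,
        covariate_vectors=cov_vecs,
        projections=projections,
        explained_variance_ratio=evr[:k],
        dropped_covariates=dropped,
    )


# --- Random Forest attribution ----------------------------------------------


@dataclass
class RFAttribution:
    response: str
    r_squared: float
    importance: pd.Series  # raw impurity importance (sums to 1)
    scaled_importance: pd.Series  # importance × max(R², 0)
    ice_curves: pd.DataFrame  # long format: predictor, sample, grid_value, prediction
    seed: int


def rf_attribution(
    X: pd.DataFrame,
    y: pd.Series,
    response: str = "response",
    test_size: float = 0.3,
    n_trees: int = 500,
    seed: int = 0,
    ice_grid_points: int = 50,
    ice_max_samples: int = 50,
) -> RFAttribution:
    """Random Forest driver attribution with R²-scaled importances and ICE curves."""
    if len(X) < 30:
        raise DegenerateDataError("need ≥ 30 samples for Random Forest attribution")
    mask = y.notna()
    X, y = X.loc[mask], y.loc[mask]
    x_train, x_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, random_state=seed
    )
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x_train, y_train)
    r2 = float(forest.score(x_test, y_test))
    importance = pd.Series(forest.feature_importances_, index=X.columns, name="importance")
    scale = max(r2, 0.0)
    if r2 < 0:
        import warnings

        warnings.warn(f"{response}: held-out R² < 0; scaled importances set to 0")
    ice_rows = []
    sample_idx = X.index[: min(ice_max_samples, len(X))]
    for predictor in X.columns:
        grid = np.linspace(X[predictor].min(), X[predictor].max(), ice_grid_points)
        base = X.loc[sample_idx]
        for g in grid:
            mod = base.copy()
            mod[predictor] = g
            preds = forest.predict(mod)
            for sid, pred in zip(sample_idx, preds):
                ice_rows.append(
                    {"predictor": predictor, "sample": sid, "grid_value": float(g),
                     "prediction": float(pred)}
                )
    return RFAttribution(
        response=response,
        r_squared=r2,
        importance=importance,
        scaled_importance=importance * scale,
        ice_curves=pd.DataFrame(ice_rows),
        seed=seed,
    )


# --- saturation-class intensities and layer contrasts ------------------------


def sfa_mufa_class_intensity(
    features: FeatureTable,
    species: dict[str, LipidSpecies],
) -> pd.DataFrame:
    """Per-sample share of each lipid class among SFA/MUFA-chain lipids.

    Class intensity is normalized to the total intensity of all lipids
    whose species class is SFA/MUFA, so shares sum to 1 per sample;
    samples without any SFA/MUFA intensity come back missing.
    """
    sel = [f for f in select_species(species, saturation="SFA/MUFA") if f in features.data.index]
    if not sel:
        raise DegenerateDataError("no SFA/MUFA species in the table")
    classes = pd.Series({f: species[f].headgroup for f in sel})
    sub = features.data.loc[sel]
    total = sub.sum(axis=0)
    out = {}
    for cls in sorted(classes.unique()):
        ids = classes.index[classes == cls]
        out[cls] = sub.loc[ids].sum(axis=0) / total
    shares = pd.DataFrame(out, index=features.data.columns)
    shares[total <= 0] = np.nan
    return shares


def assign_layers(metadata: pd.DataFrame, dcm_depths: pd.DataFrame) -> pd.Series:
    """Label samples as ``mixed`` (depth ≤ mixed-layer depth), ``dcm`` or ``other``.

    The DCM sample of a station is the one taken at the station's inferred
    DCM depth; mixed-layer membership wins when the DCM sits inside the
    mixed layer.
    """
    layers = pd.Series("other", index=metadata.index, name="layer")
    dcm = dcm_depths["dcm_depth"]
    for sid, row in metadata.iterrows():
        if row["depth"] <= row["mixed_layer_depth"]:
            layers[sid] = "mixed"
        elif row["station"] in dcm.index and row["depth"] == dcm[row["station"]]:
            layers[sid] = "dcm"
    return layers


@dataclass
class RatioBin:
    sst_low: float
    sst_high: float
    layer: str
    mean_ratio: float
    ci_low: float
    ci_high: float
    n: int


def el_ratio_by_sst(
    el_table: pd.DataFrame,
    metadata: pd.DataFrame,
    el_a: str,
    el_b: str,
    layers: pd.Series,
    bin_width: float = 2.0,
    n_boot: int = 1000,
    seed: int = 0,
    fdr_level: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ratio el_a / (el_a + el_b) across sea-surface temperature bins and layers.

    SST per station is the temperature of its shallowest sample. Within
    each SST bin and layer the mean ratio gets a seeded bootstrap 95% CI;
    per-bin layer differences use a two-sided Welch t-test with BH
    adjustment; bins where the DCM mean exceeds the mixed-layer mean and
    the difference is significant are flagged.
    """
    for el in (el_a, el_b):
        if el not in el_table.columns:
            raise DegenerateDataError(f"{el} not in the EL table")
    rng = np.random.default_rng(seed)
    surf = metadata.sort_values("depth", kind="stable").groupby("station")["temperature"].first()
    sst = metadata["station"].map(surf)
    denom = el_table[el_a] + el_table[el_b]
    ratio = el_table[el_a] / denom.replace(0, np.nan)
    frame = pd.DataFrame({"ratio": ratio, "sst": sst.loc[el_table.index],
                          "layer": layers.loc[el_table.index]})
    frame = frame[frame["layer"].isin(["mixed", "dcm"])].dropna()
    lo = np.floor(frame["sst"].min() / bin_width) * bin_width
    hi = np.ceil(frame["sst"].max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    frame["bin"] = pd.cut(frame["sst"], bins=edges, include_lowest=True)
    curve_rows = []
    test_rows = []
    for b, sub in frame.groupby("bin", observed=True):
        groups = {}
        for layer in ("mixed", "dcm"):
            vals = sub.loc[sub["layer"] == layer, "ratio"].to_numpy()
            groups[layer] = vals
            if len(vals) >= 3:
                boots = rng.choice(vals, size=(n_boot, len(vals)), replace=True).mean(axis=1)
                ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
            else:
                ci_low = ci_high = np.nan
            curve_rows.append(
                {"sst_low": b.left, "sst_high": b.right, "layer": layer,
                 "mean_ratio": vals.mean() if len(vals) else np.nan,
                 "ci_low": ci_low, "ci_high": ci_high, "n": len(vals)}
            )
        if len(groups["mixed"]) >= 3 and len(groups["dcm"]) >= 3:
            t, p = sps.ttest_ind(groups["dcm"], groups["mixed"], equal_var=False)
            test_rows.append(
                {"sst_low": b.left, "sst_high": b.right, "t": float(t), "p": float(p),
                 "dcm_minus_mixed": float(groups["dcm"].mean() - groups["mixed"].mean()),
                 "n_mixed": len(groups["mixed"]), "n_dcm": len(groups["dcm"])}
            )
    tests = pd.DataFrame(test_rows)
    if len(tests):
        tests["p_adjusted"] = bh_adjust(tests["p"])
        tests["dcm_higher_significant"] = (tests["p_adjusted"] < fdr_level) & (
            tests["dcm_minus_mixed"] > 0
        )
    return pd.DataFrame(curve_rows), tests


def pufa_layer_contrast(
    features: FeatureTable,
    species: dict[str, LipidSpecies],
    layers: pd.Series,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-class PUFA relative intensity: DCM vs mixed layer.

    The per-sample relative intensity of PUFA-containing species of each
    headgroup class (vs total annotated intensity) is compared between the
    two layers with a two-sided Welch t-test and Cohen's d (positive d ⇒
    higher in the DCM), BH-adjusted across classes.
    """
    total = features.data.sum(axis=0)
    pufa_ids = [
        f for f in features.data.index
        if f in species and classify_saturation(species[f]).species_class == "PUFA-containing"
    ]
    if not pufa_ids:
        raise DegenerateDataError("no PUFA-containing species")
    cls = pd.Series({f: species[f].headgroup for f in pufa_ids})
    dcm_samples = layers.index[layers == "dcm"].intersection(features.data.columns)
    mixed_samples = layers.index[layers == "mixed"].intersection(features.data.columns)
    if len(dcm_samples) < 2 or len(mixed_samples) < 2:
        raise DegenerateDataError("both layers need ≥ 2 samples")
    rows = []
    for c in sorted(cls.unique()):
        ids = cls.index[cls == c]
        rel = features.data.loc[ids].sum(axis=0) / total
        x = rel[dcm_samples].to_numpy()
        y = rel[mixed_samples].to_numpy()
        if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
            d, p = 0.0, 1.0
        else:
            d = cohens_d(x, y)
            _, p = sps.ttest_ind(x, y, equal_var=False)
        rows.append({"lipid_class": c, "cohens_d": float(d), "p": float(p),
                     "n_dcm": len(x), "n_mixed": len(y)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"])
    out["significant"] = out["p_adjusted"] < fdr_level
    return out


def epa_depth_vs_dcm(
    features: FeatureTable,
    species: dict[str, LipidSpecies],
    metadata: pd.DataFrame,
    dcm_depths: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Depth of peak EPA (20:5 chain) intensity per station vs the DCM depth.

    Returns the per-station table (epa_depth, dcm_depth, difference; ties
    resolve shallowest and flat profiles are flagged) and a summary with a
    Wilcoxon signed-rank test of the differences against zero.
    """
    epa_ids = [f for f in features.data.index if f in species and contains_epa(species[f])]
    if not epa_ids:
        raise DegenerateDataError("no EPA-containing species with chain annotations")
    epa_total = features.data.loc[epa_ids].sum(axis=0)
    rows = []
    for station, sub in metadata.loc[features.data.columns].groupby("station"):
        sub = sub.sort_values("depth", kind="stable")
        vals = epa_total[sub.index].to_numpy()
        if len(vals) < 2:
            continue
        note = "flat profile" if np.all(vals == vals[0]) else ""
        depth = float(sub["depth"].to_numpy()[int(vals.argmax())])
        dcm = float(dcm_depths.loc[station, "dcm_depth"]) if station in dcm_depths.index else np.nan
        rows.append({"station": station, "epa_depth": depth, "dcm_depth": dcm,
                     "difference": depth - dcm, "note": note})
    table = pd.DataFrame(rows).set_index("station")
    diffs = table["difference"].dropna()
    if len(diffs) >= 5 and not np.all(diffs == 0):
        stat, p = sps.wilcoxon(diffs, zero_method="wilcox")
    else:
        stat, p = np.nan, 1.0 if np.all(diffs == 0) else np.nan
    summary = {
        "n_stations": int(len(diffs)),
        "median_difference": float(diffs.median()) if len(diffs) else np.nan,
        "median_abs_difference": float(diffs.abs().median()) if len(diffs) else np.nan,
        "wilcoxon_statistic": float(stat) if np.isfinite(stat) else None,
        "p": float(p) if p is not None and np.isfinite(p) else None,
    }
    return table, summary
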