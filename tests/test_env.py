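"""Environmental drivers: chain-length slopes, PCA, RF attribution, layers."""

import numpy as np
import pandas as pd
import pytest

from eigenlipid.containers import DegenerateDataError, FeatureTable
from eigenlipid.environment import (
    assign_layers,
    chain_length_vs_temperature,
    el_ratio_by_sst,
    epa_depth_vs_dcm,
    pca_el_environment,
    pufa_layer_contrast,
    rf_attribution,
    sfa_mufa_class_intensity,
)
from eigenlipid.lipids import parse_annotation_table, parse_lipid_name
from eigenlipid.spatial import dcm_depth, el_relative_intensity
from eigenlipid.synthetic import OceanConfig, generate_dataset, generate_metadata


def test_chain_length_regression_exact_toy_points():
    """(T, y) = (0,14), (10,14.4), (20,14.8) → slope 0.04, R² = 1."""
    temps = [0.0, 10.0, 20.0]
    shares = [(y - 14.0) / 2.0 for y in (14.0, 14.4, 14.8)]  # PC 28:0 vs PC 32:0
    data = pd.DataFrame(
        {f"s{i}": [1 - s, s] for i, s in enumerate(shares)},
        index=["f0", "f1"],
    )
    ft = FeatureTable(data=data)
    species = {
        "f0": parse_lipid_name("PC 28:0", species_id="f0"),
        "f1": parse_lipid_name("PC 32:0", species_id="f1"),
    }
    meta = pd.DataFrame(
        {"temperature": temps, "depth": 5.0, "mixed_layer_depth": 30.0},
        index=[f"s{i}" for i in range(3)],
    )
    res = chain_length_vs_temperature(ft, species, meta, saturation="SFA")
    assert res.slope == pytest.approx(0.04, abs=1e-12)
    assert res.intercept == pytest.approx(14.0, abs=1e-9)
    assert res.r_squared == pytest.approx(1.0)


def test_chain_length_recovery_on_default_generator():
    cfg = OceanConfig(noise_sd=0.1, stations_per_province=8, seed=21)
    _, features, _, truth = generate_dataset(cfg)
    species = parse_annotation_table(features.annotations)
    meta = features.metadata
    for sat in ("SFA", "PUFA"):
        res = chain_length_vs_temperature(features, species, meta, saturation=sat)
        # recovered within 2 SE, or within 1% of the planted value at large n
        # (where 2 SE shrinks below the construction's share-noise floor)
        tol = max(2 * res.slope_se, 0.01 * truth.chain_length_slope)
        assert abs(res.slope - truth.chain_length_slope) <= tol
        assert res.r_squared > 0.99


def test_pca_temperature_tracking_el_has_longest_projection():
    rng = np.random.default_rng(0)
    meta = generate_metadata(OceanConfig(seed=3))
    n = len(meta)
    t = meta["temperature"].to_numpy()
    table = pd.DataFrame(
        {
            "EL1": (t - t.mean()) / t.std() + rng.normal(0, 0.05, n),
            "EL2": rng.normal(size=n),
            "EL3": rng.normal(size=n),
        },
        index=meta.index,
    )
    res = pca_el_environment(table, meta, covariates=("temperature", "po4"))
    proj = res.projections["temperature"].abs()
    assert proj.idxmax() == "EL1"
    # in the full-rank projection an orthogonal noise EL sits near zero
    full = pca_el_environment(table, meta, covariates=("temperature",), n_components=3)
    fproj = full.projections["temperature"].abs()
    assert fproj.idxmax() == "EL1"
    assert fproj["EL1"] > 0.9
    assert fproj["EL2"] < 0.2 and fproj["EL3"] < 0.2
    total_scores = (full.scores.to_numpy() ** 2).sum()
    x = table.to_numpy()
    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    assert total_scores == pytest.approx((xs**2).sum())


def test_rf_attribution_identifies_planted_driver_and_monotone_ice():
    meta = generate_metadata(OceanConfig(seed=4))
    ml = meta[meta["depth"] <= meta["mixed_layer_depth"]]
    X = ml[["po4", "temperature"]]
    y = pd.Series(1 / (1 + np.exp(-(ml["temperature"] - 14) / 6)), index=ml.index)
    rf = rf_attribution(X, y, n_trees=300, seed=0, ice_grid_points=25, ice_max_samples=10)
    assert rf.importance["temperature"] > rf.importance["po4"]
    assert rf.importance.sum() == pytest.approx(1.0)
    assert rf.r_squared > 0.8
    ice = rf.ice_curves[rf.ice_curves["predictor"] == "temperature"]
    mean_curve = ice.groupby("grid_value")["prediction"].mean()
    increments = np.diff(mean_curve.to_numpy())
    assert increments.min() >= -0.01  # monotone within forest step noise
    assert mean_curve.iloc[-1] > mean_curve.iloc[0]


def test_rf_attribution_null_response_scaled_to_zero():
    meta = generate_metadata(OceanConfig(seed=5))
    ml = meta[meta["depth"] <= meta["mixed_layer_depth"]]
    X = ml[["po4", "temperature"]]
    rng = np.random.default_rng(1)
    y = pd.Series(rng.normal(size=len(ml)), index=ml.index)
    with pytest.warns(UserWarning):
        rf = rf_attribution(X, y, n_trees=100, seed=0, ice_grid_points=5, ice_max_samples=2)
    assert rf.r_squared < 0.1
    assert rf.scaled_importance.sum() <= max(rf.r_squared, 0.0) + 1e-12


def test_sfa_mufa_class_shares_sum_to_one():
    names = ["MGDG 34:1", "SQDG 30:0", "PC 32:0", "PC 36:5"]
    data = pd.DataFrame(
        {"s0": [30.0, 10.0, 60.0, 500.0], "s1": [1.0, 1.0, 2.0, 9.0]},
        index=[f"f{i}" for i in range(4)],
    )
    ft = FeatureTable(data=data)
    species = {f"f{i}": parse_lipid_name(n, species_id=f"f{i}") for i, n in enumerate(names)}
    species["f3"] = parse_lipid_name("PC 16:0/20:5", species_id="f3")  # PUFA, excluded
    shares = sfa_mufa_class_intensity(ft, species)
    assert shares.loc["s0"].tolist() == pytest.approx([0.3, 0.6, 0.1])
    assert np.allclose(shares.sum(axis=1), 1.0)


def test_el_ratio_by_sst_trivial_equality():
    meta = generate_metadata(OceanConfig(seed=6))
    dcm = dcm_depth(meta)
    layers = assign_layers(meta, dcm)
    table = pd.DataFrame({"EL8": 0.2, "EL16": 0.2}, index=meta.index)
    curves, tests = el_ratio_by_sst(table, meta, "EL8", "EL16", layers, seed=0)
    observed = curves.dropna(subset=["mean_ratio"])
    assert np.allclose(observed["mean_ratio"], 0.5)
    if len(tests):
        assert not tests["dcm_higher_significant"].any()


def test_el_ratio_flags_planted_warm_dcm_enrichment():
    meta = generate_metadata(OceanConfig(stations_per_province=10, seed=7))
    dcm = dcm_depth(meta)
    layers = assign_layers(meta, dcm)
    rng = np.random.default_rng(2)
    warm = meta["surface_temperature"] > 20
    is_dcm = layers == "dcm"
    el8 = pd.Series(0.1, index=meta.index) + rng.normal(0, 0.005, len(meta))
    el8[warm & is_dcm] *= 2.0  # DCM-only doubling in warm provinces
    table = pd.DataFrame({"EL8": el8.clip(0.01), "EL16": 0.1}, index=meta.index)
    curves, tests = el_ratio_by_sst(table, meta, "EL8", "EL16", layers, seed=0)
    flagged = tests[tests["dcm_higher_significant"]]
    assert len(flagged) > 0
    assert flagged["sst_low"].min() >= 18.0  # only warm bins flagged
    assert (table["EL8"] / (table["EL8"] + table["EL16"])).between(0, 1).all()


def test_pufa_layer_contrast_identities(dataset, species_map):
    _, metadata, features, _, truth = dataset
    dcm = dcm_depth(metadata)
    layers = assign_layers(metadata, dcm)
    out = pufa_layer_contrast(features, species_map, layers)
    assert set(out.columns) >= {"lipid_class", "cohens_d", "p", "p_adjusted"}
    assert out["p_adjusted"].dropna().ge(out["p"].dropna()).all()


def test_epa_peaks_near_dcm_for_planted_chlorophyll_module(dataset, species_map):
    _, metadata, features, _, truth = dataset
    dcm = dcm_depth(metadata)
    table, summary = epa_depth_vs_dcm(features, species_map, metadata, dcm)
    grid = np.sort(metadata["depth"].unique())
    step = np.diff(grid).max()
    assert summary["median_abs_difference"] <= step
    assert summary["n_stations"] == metadata["station"].nunique()


def test_assign_layers_partition():
    meta = generate_metadata(OceanConfig(seed=8))
    layers = assign_layers(meta, dcm_depth(meta))
    assert set(layers.unique()) <= {"mixed", "dcm", "other"}
    mixed = meta[layers == "mixed"]
    assert (mixed["depth"] <= mixed["mixed_layer_depth"]).all()
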