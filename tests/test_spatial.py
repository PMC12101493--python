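"""EL intensities, vertical structure, province and headgroup enrichment."""

import numpy as np
import pandas as pd
import pytest

from eigenlipid.containers import DegenerateDataError, FeatureTable
from eigenlipid.lipids import parse_lipid_name
from eigenlipid.spatial import (
    correlate_el_with_pigment,
    dcm_depth,
    depth_comparisons,
    el_maximum_depth,
    el_relative_intensity,
    headgroup_enrichment,
    province_enrichment,
)
from eigenlipid.synthetic import OceanConfig, generate_lipidome, generate_metadata


def _features(matrix, samples=None):
    matrix = np.asarray(matrix, dtype=float)
    return FeatureTable(
        data=pd.DataFrame(matrix, index=[f"f{i}" for i in range(matrix.shape[0])],
                          columns=samples or [f"s{j}" for j in range(matrix.shape[1])])
    )


def test_el_relative_intensity_partitions_totals():
    ft = _features([[30, 10], [60, 20], [30, 70]])
    labels = pd.Series([1, 2, 0], index=ft.feature_ids)
    table = el_relative_intensity(ft, labels)
    assert table.loc["s0", "EL1"] == pytest.approx(0.25)  # 30 of 120
    assert np.allclose(table.sum(axis=1), 1.0)
    single = el_relative_intensity(ft, pd.Series([1, 1, 1], index=ft.feature_ids))
    assert np.allclose(single["EL1"], 1.0)


def test_el_relative_intensity_zero_sample_raises():
    ft = _features([[0, 1], [0, 1]])
    with pytest.raises(DegenerateDataError):
        el_relative_intensity(ft, pd.Series([1, 1], index=ft.feature_ids))


def _station_meta(depths, station="st1"):
    return pd.DataFrame(
        {"station": station, "depth": depths},
        index=[f"{station}-{int(d)}" for d in depths],
    )


def test_el_maximum_depth_and_tie_rule():
    meta = _station_meta([5, 50, 100])
    el = pd.DataFrame({"EL1": [0.1, 0.3, 0.2], "EL2": [0.3, 0.1, 0.3]}, index=meta.index)
    out = el_maximum_depth(el, meta)
    assert out.loc["st1", "EL1"] == 50.0
    assert out.loc["st1", "EL2"] == 5.0  # tie → shallowest


def test_el_maximum_depth_excludes_single_depth_stations():
    meta = pd.concat([_station_meta([5, 50]), _station_meta([10], station="st2")])
    el = pd.DataFrame({"EL1": [0.1, 0.2, 0.9]}, index=meta.index)
    out = el_maximum_depth(el, meta)
    assert "st2" not in out.index
    assert out.attrs["excluded_stations"] == ["st2"]


def test_dcm_depth_recovers_planted_maximum(dataset):
    _, metadata, _, _, _ = dataset
    dcm = dcm_depth(metadata)
    planted = metadata.groupby("station")["dcm_depth"].first()
    assert (dcm["dcm_depth"] == planted.loc[dcm.index]).all()


def test_dcm_flags_monotone_and_flat_profiles():
    meta = _station_meta([5, 50, 100, 200])
    meta["fluorescence"] = [1.0, 0.6, 0.3, 0.1]
    out = dcm_depth(meta, smooth=False)
    assert out.loc["st1", "dcm_depth"] == 5.0
    assert out.loc["st1", "note"] == "no subsurface maximum"
    meta["fluorescence"] = 0.5
    out = dcm_depth(meta)
    assert np.isnan(out.loc["st1", "dcm_depth"])


def test_dcm_smoothing_neutral_on_clean_single_peak():
    # single-peaked profile; the shallow-tie rule keeps the argmax in place
    meta = _station_meta([5.0, 25, 50, 85, 120])
    meta["fluorescence"] = [0.2, 0.5, 1.0, 0.8, 0.3]
    a = dcm_depth(meta, smooth=True)
    b = dcm_depth(meta, smooth=False)
    assert a.loc["st1", "dcm_depth"] == b.loc["st1", "dcm_depth"] == 50.0


def test_depth_comparisons_identities_and_sign():
    el_max = pd.DataFrame(
        {"EL1": [10, 20, 30, 40], "EL2": [10, 20, 30, 40], "EL3": [100, 110, 120, 130]},
        index=[f"st{i}" for i in range(4)],
    )
    out = depth_comparisons(el_max)
    same = out[(out["y"] == "EL1") & (out["x"] == "EL2")].iloc[0]
    assert same["cliffs_delta"] == 0.0 and same["p"] == pytest.approx(1.0)
    deeper = out[(out["y"] == "EL1") & (out["x"] == "EL3")].iloc[0]
    assert deeper["cliffs_delta"] == -1.0  # EL3 (x) deeper than EL1 (y)


def test_depth_comparisons_underpowered_without_stations():
    el_max = pd.DataFrame({"EL1": [10, 20], "EL2": [30, 40]}, index=["a", "b"])
    out = depth_comparisons(el_max)
    assert (out["note"] == "underpowered").all()
    assert out["p"].isna().all()


@pytest.fixture(scope="module")
def province_dataset():
    """Larger mixed-layer design (~100 ML samples in the reference region)."""
    cfg = OceanConfig(stations_per_province=15, seed=11)
    meta = generate_metadata(cfg)
    features, truth = generate_lipidome(cfg, meta)
    table = el_relative_intensity(features, truth.module_label)
    return cfg, meta, truth, table


def test_province_enrichment_finds_planted_province(province_dataset):
    cfg, meta, truth, table = province_dataset
    atlantic = meta[meta["region"] == "atlantic"]
    ml = atlantic[atlantic["depth"] <= atlantic["mixed_layer_depth"]]
    assert len(ml) >= 100
    out = province_enrichment(table.loc[atlantic.index].drop(columns="EL0"), atlantic)
    for m, prov in truth.province_enriched.items():
        if prov is None:
            continue
        sub = out[out["el"] == f"EL{m}"].set_index("province")
        assert sub["cliffs_delta"].idxmax() == prov
        assert sub.loc[prov, "p_adjusted"] < 0.05


def test_province_enrichment_null_el_makes_no_discoveries(province_dataset):
    cfg, meta, truth, table = province_dataset
    atlantic = meta[meta["region"] == "atlantic"]
    rng = np.random.default_rng(0)
    null = pd.DataFrame({"ELX": rng.uniform(0, 1, len(atlantic))}, index=atlantic.index)
    out = province_enrichment(null, atlantic)
    assert not out["significant"].any()


def test_headgroup_enrichment_closed_forms():
    # 2 ELs, one headgroup with counts [10, 20]: χ² = 3.333, p ≈ 0.0679
    labels = pd.Series([1] * 10 + [2] * 20 + [1] * 5 + [2] * 5,
                       index=[f"f{i}" for i in range(40)])
    species = {}
    for i in range(30):
        species[f"f{i}"] = parse_lipid_name("PC 34:1", species_id=f"f{i}")
    for i in range(30, 40):
        species[f"f{i}"] = parse_lipid_name("SQDG 30:0", species_id=f"f{i}")
    out = headgroup_enrichment(labels, species).set_index("headgroup")
    assert out.loc["PC", "chi2"] == pytest.approx(10 / 3)
    assert out.loc["PC", "p"] == pytest.approx(0.0679, abs=2e-4)
    assert out.loc["SQDG", "chi2"] == pytest.approx(0.0)
    assert out.loc["SQDG", "p"] == pytest.approx(1.0)


def test_headgroup_enrichment_concentrated_counts():
    # all 30 species of one headgroup in one of 3 ELs → χ² = 60
    labels = pd.Series([1] * 30 + [2, 3], index=[f"f{i}" for i in range(32)])
    species = {f"f{i}": parse_lipid_name("MGDG 34:2", species_id=f"f{i}") for i in range(30)}
    species["f30"] = parse_lipid_name("PC 34:1", species_id="f30")
    species["f31"] = parse_lipid_name("PC 34:1", species_id="f31")
    out = headgroup_enrichment(labels, species).set_index("headgroup")
    assert out.loc["MGDG", "chi2"] == pytest.approx(60.0)


def test_pigment_correlation_identity_and_planted_tracker(dataset):
    _, metadata, features, _, truth = dataset
    table = el_relative_intensity(features, truth.module_label)
    out = correlate_el_with_pigment(table.drop(columns="EL0"), metadata).set_index("el")
    chl_modules = [m for m, kind in truth.peak_depth.items()]
    # the chlorophyll-tracking module correlates positively and significantly
    tracking = truth.latent_profiles.corrwith(metadata["fluorescence"]).idxmax()
    row = out.loc[f"EL{tracking}"]
    assert row["rho"] > 0.5 and row["p_adjusted"] < 0.05
    # an EL equal to the pigment itself has ρ = 1
    table2 = table.copy()
    table2["ELpig"] = metadata.loc[table2.index, "fluorescence"]
    out2 = correlate_el_with_pigment(table2, metadata).set_index("el")
    assert out2.loc["ELpig", "rho"] == pytest.approx(1.0)
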