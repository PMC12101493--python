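"""Seeded synthetic-ocean generator with planted ground truth.

Emulates a multi-cruise, depth-resolved marine lipidome at the annotated
feature-table level: stations grouped into biogeochemical provinces across
ocean regions, an environmental field (temperature, phosphate, chlorophyll
fluorescence, mixed-layer depth) with a planted deep chlorophyll maximum
per station, and a lipidome whose co-occurrence structure is planted as
latent-response modules (province indicator, Gaussian depth peak, monotone
temperature response, or chlorophyll tracking).

Member lipids of a module share a structural signature: a headgroup
distribution, a saturation-class mix, and — for membrane glycerolipids —
a chain-length composition whose per-sample intensity-weighted mean carbon
number per fatty acid is linear in in-situ temperature with a configurable
slope. The linearity is obtained by pairing each membrane member with a
baseline-matched partner of different chain length and splitting the pair's
intensity with temperature-linear weights, so the planted slope is exactly
recoverable by ordinary least squares in expectation.

Contaminant features are appended with high blank intensities so the
20-fold blank rule removes exactly the flagged set. Everything is
deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import ConfigurationError, AlignmentError, FeatureTable

#: province pools per region: (code, typical surface temperature °C)
_PROVINCE_POOLS = {
    "atlantic": [("ARCT", 1.0), ("NADR", 12.0), ("WTRA", 28.0), ("NASW", 22.0), ("SATL", 18.0)],
    "pacific": [("PSAE", 6.0), ("NPTG", 27.0), ("NPPF", 14.0), ("PEQD", 24.0), ("SPSG", 20.0)],
    "antarctic": [("APLR", -1.0), ("ANTA", 0.5), ("SANT", 4.0), ("SSTC", 9.0), ("FKLD", 6.0)],
}
_REGION_NAMES = ["atlantic", "pacific", "antarctic"]
_REGION_LON = {"atlantic": -30.0, "pacific": -150.0, "antarctic": 0.0}

#: reference temperature at which the membrane chain-length mean equals its base
CHAIN_T_REF = 14.0
#: base mean carbons per fatty acid for the two saturation pools
CHAIN_BASE = {"SFA/MUFA": 15.0, "PUFA-containing": 19.0}
#: short/long carbons-per-chain for the paired construction
_CHAIN_PAIR_CPF = {"SFA/MUFA": (14, 16), "PUFA-containing": (18, 20)}


@dataclass
class OceanConfig:
    """Sampling design and lipidome parameters of the synthetic ocean."""

    n_regions: int = 3
    provinces_per_region: int = 3
    stations_per_province: int = 5
    depth_grid: tuple[float, ...] = (5.0, 25.0, 50.0, 85.0, 120.0, 200.0)
    n_modules: int = 5
    lipids_per_module: int = 60
    n_unassigned_lipids: int = 40
    n_contaminants: int = 8
    noise_sd: float = 0.15
    unassigned_noise_sd: float = 1.0  # private variability of non-module lipids
    chain_length_slope: float = 0.04  # carbons per fatty acid per °C
    module_loading: float = 1.5
    n_blanks: int = 4
    blank_margin: float = 10.0  # clean blank medians sit margin-fold below the 20× line
    seed: int = 0

    def validate(self) -> None:
        grid = np.asarray(self.depth_grid, dtype=float)
        if grid.size < 1 or not np.all(np.diff(grid) > 0):
            raise ConfigurationError("depth_grid must be non-empty and strictly increasing")
        for name in (
            "n_regions", "provinces_per_region", "stations_per_province",
            "n_modules", "lipids_per_module", "n_unassigned_lipids",
            "n_contaminants", "n_blanks",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be ≥ 0")
        if self.n_regions < 1 or self.provinces_per_region < 1 or self.stations_per_province < 1:
            raise ConfigurationError("need at least one region, province and station")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be ≥ 0")
        if not (0 < self.blank_margin):
            raise ConfigurationError("blank_margin must be positive")

    @property
    def reference_region(self) -> str:
        return _region_name(0)


def _region_name(i: int) -> str:
    return _REGION_NAMES[i] if i < len(_REGION_NAMES) else f"region{i + 1}"


def _provinces_for_region(region: str, n: int) -> list[tuple[str, float]]:
    pool = _PROVINCE_POOLS.get(region, [])
    out = list(pool[:n])
    k = len(out)
    while len(out) < n:
        out.append((f"{region[:3].upper()}{k + 1}", 10.0 + 4.0 * k))
        k += 1
    return out


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator."""

    module_label: pd.Series  # per feature id, 0 = unassigned/contaminant
    latent_profiles: pd.DataFrame  # samples × modules (standardized)
    province_enriched: dict[int, Optional[str]]
    peak_depth: dict[int, Optional[float]]
    contaminant_flag: pd.Series
    chain_length_slope: float

    def to_json(self) -> str:
        payload = {
            "module_label": {str(k): int(v) for k, v in self.module_label.items()},
            "latent_profiles": {
                str(c): [float(v) for v in self.latent_profiles[c]] for c in self.latent_profiles.columns
            },
            "latent_samples": [str(s) for s in self.latent_profiles.index],
            "province_enriched": {str(k): v for k, v in self.province_enriched.items()},
            "peak_depth": {str(k): (None if v is None else float(v)) for k, v in self.peak_depth.items()},
            "contaminant_flag": {str(k): bool(v) for k, v in self.contaminant_flag.items()},
            "chain_length_slope": float(self.chain_length_slope),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        latents = pd.DataFrame(
            {int(k): v for k, v in d["latent_profiles"].items()}, index=d["latent_samples"]
        )
        return cls(
            module_label=pd.Series({k: int(v) for k, v in d["module_label"].items()}),
            latent_profiles=latents,
            province_enriched={int(k): v for k, v in d["province_enriched"].items()},
            peak_depth={int(k): v for k, v in d["peak_depth"].items()},
            contaminant_flag=pd.Series({k: bool(v) for k, v in d["contaminant_flag"].items()}),
            chain_length_slope=float(d["chain_length_slope"]),
        )


def generate_metadata(cfg: OceanConfig) -> pd.DataFrame:
    """One metadata row per (station, depth), deterministic given the seed.

    Temperature decreases with the province's latitude band and with depth;
    phosphate is depleted where the surface is warm; chlorophyll
    fluorescence is a single-peaked profile whose planted maximum (the DCM)
    sits deeper in warm provinces; each station records a mixed-layer depth.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    grid = np.asarray(cfg.depth_grid, dtype=float)
    rows = []
    for r in range(cfg.n_regions):
        region = _region_name(r)
        lon0 = _REGION_LON.get(region, -60.0 + 40.0 * r)
        for code, t_base in _provinces_for_region(region, cfg.provinces_per_region):
            # provinces carry an independent nutrient baseline (upwelling vs
            # oligotrophic) on top of the broad warm-surface depletion trend
            po4_offset = rng.uniform(-0.7, 0.7)
            for s in range(cfg.stations_per_province):
                t_surf = float(np.clip(t_base + rng.uniform(-0.8, 0.8), -1.9, 31.5))
                station = f"{region[:3]}-{code}-{s + 1:02d}"
                lat = 65.0 - 2.1 * t_surf + rng.uniform(-1.5, 1.5)
                if region == "antarctic":
                    lat = -abs(lat)
                lon = lon0 + rng.uniform(-10.0, 10.0)
                mld = float(np.clip(70.0 - 1.6 * t_surf + rng.uniform(-5.0, 5.0), 15.0, 100.0))
                dcm_raw = 30.0 + 3.2 * t_surf
                dcm = float(grid[np.argmin(np.abs(grid - dcm_raw))])
                sigma = 0.3 * dcm + 12.0
                t_deep = min(4.0, t_surf)
                for z in grid:
                    temp = t_deep + (t_surf - t_deep) * np.exp(-z / 120.0) - 0.002 * z
                    po4 = float(
                        np.clip(
                            2.1 - 0.045 * temp + 0.004 * z + po4_offset + rng.normal(0, 0.18),
                            0.01,
                            3.6,
                        )
                    )
                    fluor = (0.05 + 1.5 * np.exp(-((z - dcm) ** 2) / (2 * sigma**2))) * np.exp(
                        rng.normal(0, 0.02)
                    )
                    rows.append(
                        {
                            "sample_id": f"{station}-{int(z):03d}m",
                            "station": station,
                            "region": region,
                            "province": code,
                            "latitude": round(lat, 3),
                            "longitude": round(lon, 3),
                            "depth": float(z),
                            "temperature": round(float(temp), 4),
                            "po4": round(po4, 4),
                            "fluorescence": round(float(fluor), 5),
                            "mixed_layer_depth": round(mld, 1),
                            "dcm_depth": dcm,
                            "surface_temperature": round(t_surf, 3),
                        }
                    )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta


# --- module latent design -------------------------------------------------

_MODULE_STYLES = {
    # headgroup distribution, module saturation class (True = PUFA-containing)
    "province_cold": ({"PC": 0.25, "PG": 0.2, "TAG": 0.3, "DGDG": 0.15, "PE": 0.1}, True),
    "depth": ({"PE": 0.4, "PC": 0.4, "PG": 0.2}, False),
    "temperature": ({"MGDG": 0.3, "SQDG": 0.3, "DGTS/A": 0.2, "DGCC": 0.2}, False),
    "chlorophyll": ({"MGDG": 0.3, "SQDG": 0.3, "DGDG": 0.2, "PG": 0.2}, True),
    "province_warm": ({"SQDG": 0.4, "MGDG": 0.4, "DGDG": 0.2}, False),
}
_KIND_CYCLE = ["province_cold", "depth", "temperature", "chlorophyll", "province_warm"]
_NON_MEMBRANE = {"TAG", "DAG", "WE", "other", "OL"}

_TAG_CHAINS = [
    [(16, 0), (18, 1), (16, 1)],
    [(18, 1), (16, 0), (18, 2)],
    [(16, 0), (16, 0), (18, 1)],
]
_TAG_CHAINS_PUFA = [
    [(16, 0), (20, 5), (18, 1)],
    [(20, 5), (18, 1), (16, 0)],
]
_UNASSIGNED_POOL = [
    ("TAG", [(16, 0), (18, 1), (16, 1)]),
    ("DAG", [(16, 0), (18, 1)]),
    ("WE", [(16, 0), (18, 1)]),
    ("other", None),
    ("OL", None),
]


def _module_design(cfg: OceanConfig, metadata: pd.DataFrame):
    """Latent kind, profile, and structural style per module (1-based)."""
    ref_provs = _provinces_for_region(cfg.reference_region, cfg.provinces_per_region)
    by_temp = sorted(ref_provs, key=lambda pt: pt[1])
    cold_cycle = [pt[0] for pt in by_temp]
    warm_cycle = [pt[0] for pt in by_temp[::-1]]
    grid = list(cfg.depth_grid)
    peak_cycle = [min(grid, key=lambda z: abs(z - target)) for target in (50.0, 120.0, 85.0, 25.0, 200.0)]

    designs = []
    counters = {"province_cold": 0, "province_warm": 0, "depth": 0}
    for m in range(cfg.n_modules):
        kind = _KIND_CYCLE[m % len(_KIND_CYCLE)]
        province = None
        peak = None
        if kind == "province_cold":
            province = cold_cycle[counters[kind] % len(cold_cycle)]
            counters[kind] += 1
            raw = (metadata["province"] == province).astype(float)
        elif kind == "province_warm":
            province = warm_cycle[counters[kind] % len(warm_cycle)]
            counters[kind] += 1
            raw = (metadata["province"] == province).astype(float)
        elif kind == "depth":
            peak = peak_cycle[counters[kind] % len(peak_cycle)]
            counters[kind] += 1
            raw = np.exp(-((metadata["depth"] - peak) ** 2) / (2 * 25.0**2))
        elif kind == "temperature":
            raw = metadata["temperature"].astype(float)
        else:  # chlorophyll
            raw = metadata["fluorescence"].astype(float)
        raw = np.asarray(raw, dtype=float)
        sd = raw.std()
        if sd == 0:
            raise ConfigurationError(f"latent for module {m + 1} ({kind}) is constant under this design")
        latent = (raw - raw.mean()) / sd
        headgroups, is_pufa = _MODULE_STYLES[kind]
        designs.append(
            {
                "module": m + 1,
                "kind": kind,
                "latent": latent,
                "province": province,
                "peak_depth": peak,
                "headgroups": headgroups,
                "is_pufa": is_pufa,
            }
        )
    return designs


def _chain_share(temperature: np.ndarray, slope: float, pool: str) -> np.ndarray:
    """Temperature-linear share of the long member of a chain pair."""
    c_short, c_long = _CHAIN_PAIR_CPF[pool]
    target = CHAIN_BASE[pool] + slope * (temperature - CHAIN_T_REF)
    return np.clip((target - c_short) / (c_long - c_short), 0.02, 0.98)


def generate_lipidome(cfg: OceanConfig, metadata: pd.DataFrame) -> tuple[FeatureTable, PlantedTruth]:
    """Generate the synthetic lipid feature table and its planted truth."""
    cfg.validate()
    if metadata.empty:
        raise AlignmentError("metadata is empty")
    rng = np.random.default_rng([cfg.seed, 23])
    samples = metadata.index
    n_s = len(samples)
    temperature = metadata["temperature"].to_numpy(dtype=float)
    designs = _module_design(cfg, metadata)

    ids: list[str] = []
    names: list[str] = []
    tiers: list[str] = []
    chain_strs: list[Optional[str]] = []
    labels: list[int] = []
    log_rows: list[np.ndarray] = []

    share_long = {
        pool: _chain_share(temperature, cfg.chain_length_slope, pool) for pool in _CHAIN_PAIR_CPF
    }

    def add_feature(name: str, chains, tier: str, label: int, log_intensity: np.ndarray) -> None:
        fid = f"feat_{len(ids) + 1:04d}"
        ids.append(fid)
        names.append(name)
        tiers.append(tier)
        chain_strs.append("/".join(f"{c}:{d}" for c, d in chains) if chains else None)
        labels.append(label)
        log_rows.append(log_intensity)

    for design in designs:
        m = design["module"]
        latent = design["latent"]
        hg_dist = design["headgroups"]
        membrane_classes = [h for h in hg_dist if h not in _NON_MEMBRANE]
        other_classes = [h for h in hg_dist if h in _NON_MEMBRANE]
        n_other = int(round(sum(hg_dist[h] for h in other_classes) * cfg.lipids_per_module))
        n_membrane = cfg.lipids_per_module - n_other
        if n_membrane % 2 == 1:  # pairing requires an even membrane count
            n_membrane -= 1
            n_other += 1
        n_pairs = n_membrane // 2
        if membrane_classes:
            probs = np.array([hg_dist[h] for h in membrane_classes], dtype=float)
            probs /= probs.sum()
        signal = cfg.module_loading * latent

        for _ in range(n_pairs):
            hg = str(rng.choice(membrane_classes, p=probs))
            if design["is_pufa"]:
                pool = "PUFA-containing"
                chains_a = [(16, 0), (20, 5)]
                chains_b = [(20, 5), (20, 5)]
            else:
                pool = "SFA/MUFA"
                if rng.random() < 0.5:
                    chains_a = [(14, 0), (14, 0)]
                    chains_b = [(16, 0), (16, 0)]
                else:
                    chains_a = [(14, 0), (14, 1)]
                    chains_b = [(16, 0), (16, 1)]
            baseline = rng.normal(11.5, 0.8)
            g = share_long[pool]
            for chains, weight in ((chains_a, 1.0 - g), (chains_b, g)):
                tot_c = sum(c for c, _ in chains)
                tot_d = sum(d for _, d in chains)
                noise = rng.normal(0.0, cfg.noise_sd, n_s) if cfg.noise_sd > 0 else 0.0
                log_i = baseline + signal + np.log(weight) + noise
                add_feature(f"{hg} {tot_c}:{tot_d}", chains, "Ann.1", m, log_i)

        for j in range(n_other):
            if design["is_pufa"]:
                chains = _TAG_CHAINS_PUFA[j % len(_TAG_CHAINS_PUFA)]
            else:
                chains = _TAG_CHAINS[j % len(_TAG_CHAINS)]
            tot_c = sum(c for c, _ in chains)
            tot_d = sum(d for _, d in chains)
            baseline = rng.normal(11.5, 0.8)
            noise = rng.normal(0.0, cfg.noise_sd, n_s) if cfg.noise_sd > 0 else 0.0
            add_feature(f"TAG {tot_c}:{tot_d}", chains, "Ann.1", m, baseline + signal + noise)

    # non-module lipids vary independently of the planted latents; their
    # private variability is kept comparable to the module signal so the
    # compositional (CLR) common mode does not dominate their profiles
    sd_free = max(cfg.noise_sd, cfg.unassigned_noise_sd) if cfg.noise_sd > 0 else cfg.noise_sd
    for j in range(cfg.n_unassigned_lipids):
        hg, chains = _UNASSIGNED_POOL[j % len(_UNASSIGNED_POOL)]
        if chains is not None:
            tot_c = sum(c for c, _ in chains)
            tot_d = sum(d for _, d in chains)
        else:
            tot_c, tot_d = 30 + (j % 6), 1 + (j % 3)
        baseline = rng.normal(11.0, 1.0)
        noise = rng.normal(0.0, sd_free, n_s) if sd_free > 0 else 0.0
        tier = "Ann.2" if j % 2 == 0 else "Ann.3"
        add_feature(f"{hg} {tot_c}:{tot_d}", chains, tier, 0, baseline + noise)

    for j in range(cfg.n_contaminants):
        baseline = rng.normal(12.0, 0.5)
        noise = rng.normal(0.0, cfg.noise_sd, n_s) if cfg.noise_sd > 0 else 0.0
        add_feature(f"other {24 + j}:0", None, "Ann.3", 0, baseline + noise)

    log_matrix = np.vstack([np.broadcast_to(r, (n_s,)) for r in log_rows])
    data = pd.DataFrame(np.exp(log_matrix), index=pd.Index(ids, name="feature_id"), columns=samples)
    annotations = pd.DataFrame(
        {"name": names, "annotation_tier": tiers, "chains": chain_strs},
        index=pd.Index(ids, name="feature_id"),
    )
    features = FeatureTable(data=data, view="raw", annotations=annotations, metadata=metadata)

    contaminant_flag = pd.Series(False, index=data.index)
    if cfg.n_contaminants:
        contaminant_flag.iloc[-cfg.n_contaminants :] = True
    truth = PlantedTruth(
        module_label=pd.Series(labels, index=data.index),
        latent_profiles=pd.DataFrame(
            {d["module"]: d["latent"] for d in designs}, index=samples
        ),
        province_enriched={d["module"]: d["province"] for d in designs},
        peak_depth={d["module"]: d["peak_depth"] for d in designs},
        contaminant_flag=contaminant_flag,
        chain_length_slope=cfg.chain_length_slope,
    )
    return features, truth


def generate_blanks(features: FeatureTable, truth: PlantedTruth, cfg: OceanConfig) -> pd.DataFrame:
    """Blank-run intensities: contaminants sit above the 20-fold line, the rest below.

    Contaminant-flagged features get blank medians around sample_median / 5
    (so they fail the 20× retention rule); all other features get blank
    medians around sample_median / (20 · blank_margin). An infinite margin
    degenerates to all-zero clean blanks.
    """
    cfg.validate()
    if not features.data.index.equals(truth.contaminant_flag.index):
        raise AlignmentError("truth is not aligned to the feature table")
    rng = np.random.default_rng([cfg.seed, 37])
    sample_median = features.data.median(axis=1).to_numpy()
    flags = truth.contaminant_flag.to_numpy()
    target = np.where(
        flags,
        sample_median / 5.0,
        0.0 if np.isinf(cfg.blank_margin) else sample_median / (20.0 * cfg.blank_margin),
    )
    noise = np.exp(rng.normal(0.0, 0.1, size=(features.n_features, cfg.n_blanks)))
    values = target[:, None] * noise
    return pd.DataFrame(
        values,
        index=features.data.index,
        columns=[f"blank_{b + 1}" for b in range(cfg.n_blanks)],
    )


def generate_dataset(cfg: OceanConfig):
    """Convenience: metadata, feature table, blanks and truth in one call."""
    metadata = generate_metadata(cfg)
    features, truth = generate_lipidome(cfg, metadata)
    blanks = generate_blanks(features, truth, cfg)
    return metadata, features, blanks, truth


# --- on-disk format -------------------------------------------------------

_FLOAT_FMT = "%.10g"


def write_dataset(
    outdir: str | Path,
    cfg: OceanConfig,
    metadata: pd.DataFrame,
    features: FeatureTable,
    blanks: pd.DataFrame,
    truth: PlantedTruth,
) -> None:
    """Write features/blanks/metadata/annotations as TSV, truth as JSON, config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features.data.to_csv(outdir / "features.tsv", sep="\t", float_format=_FLOAT_FMT)
    blanks.to_csv(outdir / "blanks.tsv", sep="\t", float_format=_FLOAT_FMT)
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", float_format=_FLOAT_FMT)
    assert features.annotations is not None
    features.annotations.to_csv(outdir / "annotations.tsv", sep="\t")
    (outdir / "truth.json").write_text(truth.to_json())
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def load_dataset(indir: str | Path):
    """Load a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    with open(indir / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["depth_grid"] = tuple(raw["depth_grid"])
    cfg = OceanConfig(**raw)
    metadata = pd.read_csv(indir / "metadata.tsv", sep="\t", index_col=0)
    data = pd.read_csv(indir / "features.tsv", sep="\t", index_col=0)
    annotations = pd.read_csv(indir / "annotations.tsv", sep="\t", index_col=0)
    blanks = pd.read_csv(indir / "blanks.tsv", sep="\t", index_col=0)
    truth = PlantedTruth.from_json((indir / "truth.json").read_text())
    features = FeatureTable(data=data, view="raw", annotations=annotations, metadata=metadata)
    return cfg, metadata, features, blanks, truth
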