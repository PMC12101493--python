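"""End-to-end orchestration: preprocess → network → projection → statistics.

A single :class:`RunConfig` carries every parameter and seed. The pipeline
derives ELs from the designated reference region, projects the remaining
regions onto them, and runs the spatial, meta-clustering, structural and
environmental analyses, writing tidy TSV/JSON/Newick outputs plus a
manifest (parameters, seeds, input hashes, stage counts) that makes a run
bit-identical reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ConfigurationError, DegenerateDataError, FeatureTable
from .lipids import CHLOROPLAST_CLASSES, parse_annotation_table, weighted_mean_chain_length
from .metacluster import (
    DEFAULT_DEPTH_BINS,
    build_distances,
    meta_dendrogram,
    node_significance,
)
from .network import (
    adjacency,
    compute_eigenlipids,
    detect_modules,
    igp_reproducibility,
    membership_scores,
    pick_soft_threshold,
    project_region,
    tom_similarity,
)
from .preprocess import blank_subtract, clr_transform, normalize_total
from .spatial import (
    correlate_el_with_pigment,
    dcm_depth,
    depth_comparisons,
    el_maximum_depth,
    el_relative_intensity,
    headgroup_enrichment,
    province_enrichment,
)
from .structure import (
    Dendrogram,
    entanglement,
    property_mixed_model,
    structural_dendrogram,
    structural_profiles,
)
from .environment import (
    assign_layers,
    chain_length_vs_temperature,
    el_ratio_by_sst,
    epa_depth_vs_dcm,
    pca_el_environment,
    pufa_layer_contrast,
    rf_attribution,
    sfa_mufa_class_intensity,
)
from .synthetic import OceanConfig, generate_dataset, load_dataset

log = logging.getLogger("eigenlipid")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """All parameters of an end-to-end run."""

    input_dir: Optional[str] = None  # dataset directory; None → generate synthetic
    ocean: OceanConfig = field(default_factory=OceanConfig)
    reference_region: Optional[str] = None  # None → first region in the metadata
    blank_fold: float = 20.0
    beta: Optional[float] = 6.0  # None → pick by scale-free fit
    beta_target_fit: float = 0.8
    network_mode: str = "signed"
    min_module_size: int = 10
    fdr_level: float = 0.05
    igp_permutations: int = 499
    node_simulations: int = 199
    meta_k: Optional[int] = None  # None → significant top-level splits + 1
    distance_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    depth_bins: tuple[float, ...] = DEFAULT_DEPTH_BINS
    rf_trees: int = 500
    seed: int = 0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if not (0 < self.fdr_level < 1):
            raise ConfigurationError(f"fdr_level must be in (0, 1), got {self.fdr_level}")
        if self.blank_fold <= 0:
            raise ConfigurationError("blank_fold must be positive")
        if self.min_module_size < 2:
            raise ConfigurationError("min_module_size must be ≥ 2")
        if self.igp_permutations < 99 or self.node_simulations < 99:
            raise ConfigurationError("permutation/simulation counts must be ≥ 99")
        if self.network_mode not in ("signed", "unsigned"):
            raise ConfigurationError(f"unknown network mode {self.network_mode!r}")
        self.ocean.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ocean = OceanConfig(**{k: tuple(v) if k == "depth_grid" else v
                               for k, v in (raw.pop("ocean", {}) or {}).items()})
        for key in ("distance_weights", "depth_bins"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(ocean=ocean, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ocean"]["depth_grid"] = list(d["ocean"]["depth_grid"])
        d["distance_weights"] = list(d["distance_weights"])
        d["depth_bins"] = list(d["depth_bins"])
        return d


@dataclass
class PipelineResult:
    """Everything one run computes, plus the manifest."""

    config: RunConfig
    metadata: pd.DataFrame
    features: FeatureTable  # blank-filtered raw view
    clr: FeatureTable
    beta: float
    elset: object
    el_profiles: pd.DataFrame  # all samples × EL (reference + projected)
    el_table: pd.DataFrame  # relative intensities, all samples
    igp: Optional[object]
    removal_report: Optional[pd.DataFrame]
    el_max_depths: pd.DataFrame
    dcm: pd.DataFrame
    depth_tests: pd.DataFrame
    province_tests: pd.DataFrame
    headgroup_tests: pd.DataFrame
    pigment_tests: pd.DataFrame
    distances: Optional[object]
    meta: Optional[object]
    node_p: Optional[pd.DataFrame]
    struct_profiles: Optional[pd.DataFrame]
    struct_dendro: Optional[Dendrogram]
    tangle: Optional[object]
    mixed_model: Optional[pd.DataFrame]
    chain_regressions: dict
    pca: Optional[object]
    rf_results: list
    ratio_curves: Optional[pd.DataFrame]
    ratio_tests: Optional[pd.DataFrame]
    pufa_tests: Optional[pd.DataFrame]
    epa_table: Optional[pd.DataFrame]
    epa_summary: Optional[dict]
    manifest: dict


def _hash_frame(df: pd.DataFrame) -> str:
    payload = df.to_csv(float_format="%.12g").encode()
    return hashlib.sha256(payload).hexdigest()


def _load_inputs(config: RunConfig):
    if config.input_dir is not None:
        _, metadata, features, blanks, truth = load_dataset(config.input_dir)
        return metadata, features, blanks, truth
    metadata, features, blanks, truth = generate_dataset(config.ocean)
    return metadata, features, blanks, truth


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    config.validate()
    stage = "load"
    try:
        metadata, features, blanks, truth = _load_inputs(config)
        input_hashes = {
            "features": _hash_frame(features.data),
            "blanks": _hash_frame(blanks),
            "metadata": _hash_frame(metadata),
        }
        species = parse_annotation_table(features.annotations)

        stage = "preprocess"
        n_in = features.n_features
        features, removal_report = blank_subtract(features, blanks, fold=config.blank_fold)
        log.info("blank filter: %d → %d features", n_in, features.n_features)
        rel = normalize_total(features)
        clr = clr_transform(rel)

        stage = "network"
        regions = list(dict.fromkeys(metadata["region"]))
        reference = config.reference_region or regions[0]
        if reference not in regions:
            raise ConfigurationError(f"reference region {reference!r} not in metadata")
        ref_samples = metadata.index[metadata["region"] == reference]
        clr_ref = clr.subset_samples(ref_samples)
        if config.beta is None:
            beta, _ = pick_soft_threshold(
                clr_ref, target_fit=config.beta_target_fit, mode=config.network_mode
            )
        else:
            beta = float(config.beta)
        net = adjacency(clr_ref, beta=beta, mode=config.network_mode)
        tom = tom_similarity(net)
        elset = detect_modules(tom, min_module_size=config.min_module_size)
        n_modules = len(elset.module_ids)
        log.info("detected %d ELs (β=%.1f)", n_modules, beta)
        if n_modules == 0:
            raise DegenerateDataError("no modules detected; nothing to analyze")
        elset = compute_eigenlipids(clr_ref, elset.labels)
        elset.membership = membership_scores(clr_ref, elset)

        stage = "projection"
        profile_parts = [elset.profiles]
        for region in regions:
            if region == reference:
                continue
            other = clr.subset_samples(metadata.index[metadata["region"] == region])
            proj, _ = project_region(other, elset)
            profile_parts.append(proj)
        el_profiles = pd.concat(profile_parts).loc[clr.sample_ids]

        stage = "reproducibility"
        other_samples = metadata.index[metadata["region"] != reference]
        igp = None
        if len(other_samples) >= 3:
            igp = igp_reproducibility(
                clr.subset_samples(other_samples),
                elset,
                n_perm=config.igp_permutations,
                seed=config.seed,
            )

        stage = "spatial"
        el_table = el_relative_intensity(features, elset.labels)
        el_cols = [c for c in el_table.columns if c != "EL0"]
        el_max = el_maximum_depth(el_table[el_cols], metadata)
        dcm = dcm_depth(metadata)
        depth_tests = depth_comparisons(el_max, dcm, fdr_level=config.fdr_level)
        province_tests = province_enrichment(
            el_table[el_cols], metadata, fdr_level=config.fdr_level
        )
        headgroup_tests = headgroup_enrichment(elset.labels, species, fdr_level=config.fdr_level)
        pigment_tests = correlate_el_with_pigment(
            el_table[el_cols], metadata, fdr_level=config.fdr_level
        )

        stage = "meta_clustering"
        distances = meta = node_p = None
        if n_modules >= 3:
            distances = build_distances(
                el_profiles, el_table, metadata,
                depth_bins=config.depth_bins, weights=config.distance_weights,
            )
            meta0 = meta_dendrogram(distances, k=min(2, n_modules - 1) if n_modules < 4 else 3)
            node_p = node_significance(
                el_profiles[el_cols].T,
                meta0,
                n_sim=config.node_simulations,
                alpha=config.fdr_level,
                seed=config.seed,
            )
            if config.meta_k is None:
                if "significant" in node_p.columns:
                    n_sig = int((node_p["significant"] == True).sum())  # noqa: E712
                else:
                    n_sig = 0
                k = int(np.clip(n_sig + 1, 2, n_modules - 1))
            else:
                k = int(np.clip(config.meta_k, 2, n_modules - 1))
            meta = meta_dendrogram(distances, k=k)

        stage = "structure"
        struct_profiles = struct_dendro = tangle = mixed_model = None
        try:
            struct_profiles = structural_profiles(elset.labels, species, features)
        except DegenerateDataError as err:
            log.info("structural profiles skipped: %s", err)
        if struct_profiles is not None and len(struct_profiles) >= 3 and meta is not None:
            struct_dendro, _ = structural_dendrogram(struct_profiles)
            shared = [e for e in meta.leaves if e in struct_profiles.index]
            if len(shared) >= 3:
                dist_dendro = _restrict_dendrogram(distances, shared)
                struct_sub, _ = structural_dendrogram(struct_profiles.loc[shared])
                tangle = entanglement(dist_dendro, struct_sub)
            long_rows = []
            for m in elset.module_ids:
                el_name = f"EL{m}"
                if el_name not in struct_profiles.index:
                    continue
                members = elset.members(m)
                members = [i for i in members if i in species and species[i].headgroup != "other"]
                if not members:
                    continue
                wml = weighted_mean_chain_length(features, species, members)
                for sid, v in wml.items():
                    long_rows.append({"sample": sid, "el": el_name, "value": v})
            long_df = pd.DataFrame(long_rows)
            if len(long_df) and long_df["el"].nunique() >= 2:
                mixed_model = property_mixed_model(long_df, fdr_level=config.fdr_level)

        stage = "environment"
        chain_regressions = {}
        for sat in ("SFA", "PUFA"):
            try:
                chain_regressions[sat] = chain_length_vs_temperature(
                    features, species, metadata, saturation=sat
                )
            except DegenerateDataError as err:
                log.info("chain-length regression (%s) skipped: %s", sat, err)
        pca = None
        try:
            pca = pca_el_environment(el_table[el_cols], metadata)
        except DegenerateDataError as err:
            log.info("PCA skipped: %s", err)
        ml = metadata.index[metadata["depth"] <= metadata["mixed_layer_depth"]]
        rf_results = []
        try:
            shares = sfa_mufa_class_intensity(features, species)
            X = metadata.loc[ml, ["po4", "temperature"]].astype(float)
            for cls in shares.columns:
                y = shares.loc[ml, cls]
                if y.notna().sum() < 30 or y.std() == 0:
                    continue
                rf_results.append(
                    rf_attribution(X, y, response=cls, n_trees=config.rf_trees, seed=config.seed)
                )
        except DegenerateDataError as err:
            log.info("RF attribution skipped: %s", err)

        layers = assign_layers(metadata, dcm)
        ratio_curves = ratio_tests = None
        pair = _chloroplast_ratio_pair(struct_profiles)
        if pair is not None:
            ratio_curves, ratio_tests = el_ratio_by_sst(
                el_table, metadata, pair[0], pair[1], layers,
                seed=config.seed, fdr_level=config.fdr_level,
            )
        pufa_tests = None
        try:
            pufa_tests = pufa_layer_contrast(features, species, layers, fdr_level=config.fdr_level)
        except DegenerateDataError as err:
            log.info("PUFA layer contrast skipped: %s", err)
        epa_table = epa_summary = None
        try:
            epa_table, epa_summary = epa_depth_vs_dcm(features, species, metadata, dcm)
        except DegenerateDataError as err:
            log.info("EPA analysis skipped: %s", err)

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "parameters": config.to_dict(),
            "input_hashes": input_hashes,
            "reference_region": reference,
            "beta": beta,
            "counts": {
                "features_in": int(n_in),
                "features_kept": int(features.n_features),
                "n_samples": int(features.n_samples),
                "n_modules": int(n_modules),
                "module_sizes": {f"EL{m}": int(s) for m, s in elset.sizes.items()},
                "depth_tests": int(len(depth_tests)),
                "depth_discoveries": int(depth_tests["significant"].sum()),
                "province_tests": int(len(province_tests)),
                "province_discoveries": int(province_tests["significant"].sum()),
                "meta_clusters": int(meta.k) if meta is not None else None,
            },
        }
        result = PipelineResult(
            config=config, metadata=metadata, features=features, clr=clr, beta=beta,
            elset=elset, el_profiles=el_profiles, el_table=el_table, igp=igp,
            removal_report=removal_report, el_max_depths=el_max, dcm=dcm,
            depth_tests=depth_tests, province_tests=province_tests,
            headgroup_tests=headgroup_tests, pigment_tests=pigment_tests,
            distances=distances, meta=meta, node_p=node_p,
            struct_profiles=struct_profiles, struct_dendro=struct_dendro,
            tangle=tangle, mixed_model=mixed_model,
            chain_regressions=chain_regressions, pca=pca, rf_results=rf_results,
            ratio_curves=ratio_curves, ratio_tests=ratio_tests,
            pufa_tests=pufa_tests, epa_table=epa_table, epa_summary=epa_summary,
            manifest=manifest,
        )
        if config.out_dir is not None:
            write_results(result, config.out_dir)
        return result
    except Exception as err:
        try:
            wrapped = type(err)(f"[stage: {stage}] {err}")
        except Exception:
            wrapped = RuntimeError(f"[stage: {stage}] {err}")
        raise wrapped from err


def _restrict_dendrogram(distances, leaves: list[str]) -> Dendrogram:
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    d = distances.integrated.loc[leaves, leaves].to_numpy()
    return Dendrogram(linkage=average(squareform(d, checks=False)), leaves=list(leaves))


def _chloroplast_ratio_pair(struct_profiles: Optional[pd.DataFrame]) -> Optional[tuple[str, str]]:
    """Pick the PUFA-rich and PUFA-poor chloroplast-dominated ELs for the
    layer ratio analysis; None when fewer than two qualify."""
    if struct_profiles is None:
        return None
    chloro_cols = [f"hg_{c}" for c in CHLOROPLAST_CLASSES if f"hg_{c}" in struct_profiles.columns]
    if not chloro_cols:
        return None
    chloro_frac = struct_profiles[chloro_cols].sum(axis=1)
    candidates = struct_profiles[chloro_frac > 0.5]
    if len(candidates) < 2:
        return None
    ranked = candidates["frac_pufa"].sort_values()
    return str(ranked.index[-1]), str(ranked.index[0])  # (PUFA-rich, PUFA-poor)


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write all result tables; file bytes are deterministic for a fixed config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", float_format=_FLOAT_FMT)

    elset = result.elset
    labels = pd.DataFrame({"el": ["EL%d" % m for m in elset.labels]}, index=elset.labels.index)
    tsv(labels, "labels.tsv")
    tsv(result.el_profiles, "eigenlipid_profiles.tsv")
    if elset.membership is not None:
        tsv(elset.membership, "membership.tsv")
    tsv(result.el_table, "el_relative_intensity.tsv")
    tsv(result.el_max_depths, "el_max_depth.tsv")
    tsv(result.dcm, "dcm_depth.tsv")
    tsv(result.depth_tests, "depth_comparisons.tsv")
    tsv(result.province_tests, "province_enrichment.tsv")
    tsv(result.headgroup_tests, "headgroup_enrichment.tsv")
    tsv(result.pigment_tests, "pigment_correlation.tsv")
    if result.removal_report is not None:
        tsv(result.removal_report, "blank_removal.tsv")
    if result.igp is not None:
        tsv(pd.DataFrame({"igp": result.igp.igp, "p": result.igp.p_value}), "igp.tsv")
    if result.distances is not None:
        tsv(result.distances.integrated, "meta_distance_integrated.tsv")
        tsv(result.distances.distributional, "meta_distance_distributional.tsv")
        tsv(result.distances.province, "meta_distance_province.tsv")
        tsv(result.distances.depth, "meta_distance_depth.tsv")
    if result.meta is not None:
        (out / "meta_dendrogram.nwk").write_text(
            Dendrogram(result.meta.linkage, result.meta.leaves).to_newick() + "\n"
        )
        tsv(result.meta.meta_labels.to_frame(), "meta_clusters.tsv")
    if result.node_p is not None:
        (out / "node_significance.json").write_text(
            json.dumps(json.loads(result.node_p.to_json(orient="index")), indent=1, sort_keys=True)
        )
    if result.struct_profiles is not None:
        tsv(result.struct_profiles, "structural_profiles.tsv")
    if result.struct_dendro is not None:
        (out / "structural_dendrogram.nwk").write_text(result.struct_dendro.to_newick() + "\n")
    if result.tangle is not None:
        (out / "entanglement.json").write_text(
            json.dumps(
                {
                    "entanglement": result.tangle.entanglement,
                    "entanglement_before_untangling": result.tangle.entanglement_before,
                    "exponent": result.tangle.exponent,
                    "left_order": result.tangle.left_order,
                    "right_order": result.tangle.right_order,
                },
                indent=1,
            )
        )
    if result.mixed_model is not None:
        tsv(result.mixed_model, "structural_mixed_model.tsv")
    if result.chain_regressions:
        (out / "chain_length_regression.json").write_text(
            json.dumps(
                {k: dataclasses.asdict(v) for k, v in result.chain_regressions.items()},
                indent=1, sort_keys=True,
            )
        )
    if result.pca is not None:
        tsv(result.pca.projections, "pca_projections.tsv")
    if result.rf_results:
        rows = []
        ice_frames = []
        for rf in result.rf_results:
            for predictor, raw in rf.importance.items():
                rows.append(
                    {"response": rf.response, "predictor": predictor, "importance": raw,
                     "scaled_importance": rf.scaled_importance[predictor], "r2": rf.r_squared}
                )
            ice = rf.ice_curves.copy()
            ice.insert(0, "response", rf.response)
            ice_frames.append(ice)
        pd.DataFrame(rows).to_csv(out / "rf_attribution.tsv", sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
        pd.concat(ice_frames).to_csv(out / "ice_curves.tsv", sep="\t", index=False,
                                     float_format=_FLOAT_FMT)
    if result.ratio_curves is not None:
        result.ratio_curves.to_csv(out / "el_ratio_curves.tsv", sep="\t", index=False,
                                   float_format=_FLOAT_FMT)
        if result.ratio_tests is not None and len(result.ratio_tests):
            result.ratio_tests.to_csv(out / "el_ratio_tests.tsv", sep="\t", index=False,
                                      float_format=_FLOAT_FMT)
    if result.pufa_tests is not None:
        result.pufa_tests.to_csv(out / "pufa_layer_contrast.tsv", sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    if result.epa_table is not None:
        tsv(result.epa_table, "epa_depth.tsv")
        (out / "epa_summary.json").write_text(json.dumps(result.epa_summary, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))


# --- subset runs ------------------------------------------------------------


def subset_run(config: RunConfig, subset: dict) -> tuple[PipelineResult, pd.DataFrame]:
    """Re-run the pipeline on a sample subset and report module overlap.

    ``subset`` is one of ``{"kind": "mixed_layer"}``, ``{"kind": "region",
    "region": name}`` or ``{"kind": "depth_range", "min": a, "max": b}``.
    Returns the subset result and a table of Jaccard overlaps between
    subset and full-run module member sets (best match per subset EL).
    """
    full = run_pipeline(dataclasses.replace(config, out_dir=None))
    metadata = full.metadata
    kind = subset.get("kind")
    if kind == "mixed_layer":
        keep = metadata.index[metadata["depth"] <= metadata["mixed_layer_depth"]]
    elif kind == "region":
        keep = metadata.index[metadata["region"] == subset["region"]]
    elif kind == "depth_range":
        keep = metadata.index[
            (metadata["depth"] >= subset["min"]) & (metadata["depth"] <= subset["max"])
        ]
    else:
        raise ConfigurationError(f"unknown subset kind {kind!r}")
    if len(keep) == 0:
        raise ConfigurationError("subset selects no samples")
    sub_result = _run_on_samples(config, keep)
    overlap = module_overlap(sub_result.elset.labels, full.elset.labels)
    return sub_result, overlap


def _run_on_samples(config: RunConfig, samples) -> PipelineResult:
    """Run the pipeline with the input restricted to the given samples."""
    metadata, features, blanks, truth = _load_inputs(config)
    samples = [s for s in metadata.index if s in set(samples)]
    import tempfile

    from .synthetic import write_dataset

    with tempfile.TemporaryDirectory() as tmp:
        write_dataset(
            tmp,
            config.ocean,
            metadata.loc[samples],
            features.subset_samples(samples),
            blanks,
            truth,
        )
        sub_cfg = dataclasses.replace(config, input_dir=tmp)
        return run_pipeline(sub_cfg)


def module_overlap(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Best-match Jaccard overlap of module member sets between two labelings."""
    rows = []
    for ma in sorted(set(labels_a[labels_a > 0])):
        set_a = set(labels_a.index[labels_a == ma])
        best, best_j = None, 0.0
        for mb in sorted(set(labels_b[labels_b > 0])):
            set_b = set(labels_b.index[labels_b == mb])
            j = len(set_a & set_b) / len(set_a | set_b)
            if j > best_j:
                best, best_j = mb, j
        rows.append({"el_subset": f"EL{ma}", "el_full": f"EL{best}" if best else None,
                     "jaccard": best_j, "size": len(set_a)})
    return pd.DataFrame(rows)
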