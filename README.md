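# eigenlipid

Weighted correlation network analysis of ocean lipidomes.

Marine plankton remodel their membrane lipids along environmental
gradients — shortening and desaturating acyl chains in cold water,
substituting phosphorus-free glycolipids and betaine lipids where
phosphate is scarce, accumulating polyunsaturated chloroplast lipids in
the dim light of the deep chlorophyll maximum (DCM). Untargeted LC-MS
surveys measure thousands of lipid species across stations and depths,
but individual species are noisy and hard to interpret. `eigenlipid`
groups species whose relative intensities co-vary across samples into
**eigenlipid clusters (ELs)** and characterizes each cluster's vertical,
geographic, structural and environmental signature.

The pipeline, for a lipid feature table with blanks and station metadata:

1. **Preprocess** — remove features whose sample median is < 20× their
   blank median; normalize each sample to total annotated intensity;
   centered log-ratio (CLR) transform.
2. **Network** — Pearson correlation of CLR profiles in a reference ocean
   region, signed soft-threshold adjacency `a_ij = ((1+r_ij)/2)^β`,
   topological overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1
   − a_ij)`, average-linkage clustering of 1−TOM with a deterministic
   dynamic tree cut. Each cluster is summarized by its *eigenlipid*, the
   first principal component of the member CLR profiles; other regions
   are projected onto the reference loadings, and cluster reproducibility
   is scored by an in-group proportion (IGP) permutation test.
3. **Spatial statistics** — EL relative intensities, per-station EL
   maximum depth vs the DCM (Mann-Whitney U, Cliff's Delta,
   Benjamini-Hochberg FDR), one-sided province enrichment in the mixed
   layer, headgroup enrichment (chi-square goodness-of-fit), pigment
   correlations.
4. **Meta-clustering** — an integrated EL × EL distance (distributional +
   province + depth views), average-linkage meta-dendrogram, Monte Carlo
   Gaussian node significance, cophenetic correlation.
5. **Structure** — intensity-weighted structural profiles per EL, a
   random-intercept mixed model of structural properties, and a
   tanglegram entanglement score (0 = identical, 1 = fully reversed)
   between the distributional and structural dendrograms.
6. **Environment** — weighted mean carbons per fatty acid vs in-situ
   temperature (OLS with robust errors), PCA biplot of ELs vs
   environmental covariates, Random-Forest attribution of lipid-class
   shares to temperature vs phosphate (R²-scaled importances, ICE
   curves), DCM-vs-mixed-layer contrasts of PUFA lipids and the EL ratio
   across sea-surface temperature, and EPA (20:5) peak depth vs the DCM.

Because the underlying study data are not shipped, the package includes a
first-class **synthetic ocean generator**: seeded cruises with provinces,
depth profiles, environmental fields and a lipidome with planted
co-occurrence modules, province/depth/temperature/chlorophyll responses, a
planted chain-length–temperature slope, and contaminant features high in
blanks. Every downstream stage is tested against this recoverable ground
truth; `docs/methods.md` describes the models and the generator in detail.

## Worked example

```python
from eigenlipid.pipeline import RunConfig, run_pipeline
from eigenlipid.synthetic import OceanConfig

result = run_pipeline(RunConfig(ocean=OceanConfig(seed=1), seed=1))
counts = result.manifest["counts"]
print("features kept:", counts["features_kept"], "of", counts["features_in"])
print("module sizes:", counts["module_sizes"])
print("IGP (validation basins):", {k: float(v) for k, v in result.igp.igp.round(2).items()})
print("meta-clusters:", result.meta.k, "| cophenetic:", round(result.meta.cophenetic, 3))
print("entanglement:", round(result.tangle.entanglement, 3))
r = result.chain_regressions["SFA"]
print(f"SFA chain length ~ T: slope={r.slope:.4f} C/degC  R2={r.r_squared:.3f}  n={r.n}")
```

prints

```
features kept: 340 of 348
module sizes: {'EL1': 60, 'EL2': 60, 'EL3': 60, 'EL4': 60, 'EL5': 60}
IGP (validation basins): {'EL1': 0.65, 'EL2': 1.0, 'EL3': 1.0, 'EL4': 1.0, 'EL5': 0.5}
meta-clusters: 3 | cophenetic: 0.947
entanglement: 0.092
SFA chain length ~ T: slope=0.0400 C/degC  R2=0.997  n=115
```

Reading this: the blank filter removed exactly the 8 planted contaminants;
all five planted co-occurrence modules were recovered at their true sizes
(the 40 unassigned lipids land in EL0); the two basin-spanning responses
(depth peak, temperature) and the chlorophyll tracker reproduce perfectly
in the held-out Pacific/Antarctic samples (IGP = 1), while the two
Atlantic-province clusters score low there — their provinces do not exist
in the other basins, so low IGP is itself informative. The meta-dendrogram
groups the five ELs into three meta-clusters, the structural and
distributional trees entangle at 0.092 (strong agreement), and the OLS
slope of mean chain length on temperature recovers the planted
0.04 carbons per fatty acid per °C.

The same run from a shell:

```sh
eigenlipid run --out results/ --seed 1
eigenlipid report results/
eigenlipid simulate --out data/         # write the synthetic dataset as TSV/JSON
eigenlipid subset --out sub/ --filter mixed-layer --seed 1
```

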