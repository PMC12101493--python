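# Methods

`eigenlipid` re-implements, as a tested pipeline with synthetic ground
truth, a weighted-correlation-network analysis of ocean lipidomes: lipid
species whose relative intensities co-vary across stations and depths are
grouped into *eigenlipid clusters* (ELs), and the clusters' vertical,
geographic and structural signatures are related to environmental drivers
(temperature, phosphate, depth/light). This note records the models, the
numerical choices, and what the synthetic benchmark does and does not
demonstrate.

## Preprocessing

Feature intensities from untargeted LC-MS lipidomics carry contaminant
signals and are compositional. The pipeline:

1. **Blank filter.** A feature is retained iff its median intensity across
   samples is at least `fold` (default 20) times its median across
   procedural blanks. The boundary case (exactly 20-fold) is retained; a
   zero blank median always retains. Medians are computed globally across
   all samples and blanks (a per-group option exists; the choice between
   global and per-cruise medians is a judgment call with no clear
   convention).
2. **Total normalization.** Each sample is divided by its total annotated
   lipid intensity, giving relative intensities that sum to 1.
3. **CLR.** Centered log-ratio transform per sample, after multiplicative
   zero replacement with δ = half the smallest nonzero relative intensity
   of that sample (standard compositional practice). CLR rows are
   scale-invariant and each sample's CLR values sum to 0 (tolerance 1e−9).

## Network and cluster detection

* **Correlation.** Pearson on CLR values for the network (CLR already
  removes per-sample scale); Spearman for the membership scores.
* **Adjacency.** Signed by default: `a_ij = ((1 + cor_ij)/2)^β`.
  Anticorrelation of lipid intensities is ecologically meaningful, so the
  sign is preserved; an unsigned mode (`|cor|^β`) is available.
* **Soft power.** Default β = 6 with minimum module size 10. A scale-free
  fit criterion (smallest power whose signed R² of log p(k) vs log k
  reaches 0.8) is implemented and configurable, but block-structured
  co-occurrence — exactly what planted modules produce — is not scale-free,
  so the fixed default is used for benchmark runs.
* **Topological overlap.**
  `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
  with unit diagonal; clustering dissimilarity is 1 − TOM.
* **Tree cut.** Average linkage on 1 − TOM, followed by a tree-variant
  dynamic cut implemented as a top-down traversal driven by merge-height
  ratios: a subtree is a *distinct branch* only when its top internal
  merge sits at ≤ 0.75 of its attachment height; otherwise the traversal
  descends, which strips straggler leaves and loose noise subtrees that
  attach high on a branch (with fractional topological overlap such
  stragglers always attach *below* any fixed cut height, so a plain static
  cut cannot separate them). A distinct branch is split further when its
  top merge is a decisive boundary (both children with at least
  `min_module_size` leaves and internal merges ≤ 0.7 of the branch
  height). Branches below the minimum size become EL0 (unassigned), and
  modules are relabeled EL1, EL2, … by decreasing size. The hybrid
  PAM-assignment stage of the reference dynamic-cut method is deliberately
  not implemented; this variant is fully deterministic.
* **Eigenlipids.** Per module, member CLR profiles are standardized across
  samples and the eigenlipid is the unit-norm first right singular vector
  (a profile over samples), sign-oriented to correlate positively with the
  mean member profile. Explained-variance fractions are reported; a
  single-member module degenerates to that member's standardized profile.
* **Projection.** Held-out regions are standardized within themselves and
  projected onto the reference PC loadings; member lipids missing from the
  new data are dropped and the loading vector renormalized. Projecting the
  training region reproduces the training eigenlipids exactly.
* **Reproducibility (IGP).** Each reference member lipid is assigned, in
  validation data, to the nearest EL centroid by correlation distance;
  the in-group proportion of an EL is the fraction of members landing on
  their own centroid. A lipid's own centroid is computed leave-one-out:
  without this, self-inclusion biases the permutation null upward, whereas
  with it the expected IGP under random relabeling is exactly 1/k by
  exchangeability. The null relabels lipids `n_perm` times (centroids
  recomputed), and p = (1 + #{null ≥ observed}) / (n_perm + 1). Province-
  specific ELs legitimately score low when the validation basin does not
  contain their province — low IGP there is a finding, not a failure.

## Spatial statistics

EL relative intensity is the member intensity sum over the total annotated
intensity per sample (EL0 reported so shares partition each sample). Per
station, the *EL maximum depth* is the sampled depth of highest relative
intensity (ties resolve shallowest — conservative toward the surface); the
DCM is the fluorescence argmax per station (optional 3-point median
smoothing is off by default because on coarse bottle grids it erodes
single-sample maxima). Depth contrasts use two-sided Mann-Whitney U with
Cliff's Delta (positive ⇒ the y entity is deeper); province enrichment is
one-sided (province greater than the rest) over mixed-layer samples
(sample depth ≤ station mixed-layer depth). Mann-Whitney is exact for
n+m ≤ 12 without ties and a tie-corrected, continuity-corrected normal
approximation otherwise (worst-case gap from exact at n+m = 12 is ≈ 0.015,
in the mid-p range). Benjamini-Hochberg FDR is applied within one family
per analysis (all depth contrasts; all EL × province tests; all
EL–pigment correlations). Headgroup enrichment per EL is a chi-square
goodness-of-fit against uniform allocation of each headgroup's species
across ELs (df = #ELs − 1).

## Meta-clustering

Three EL × EL distances — 1 − Pearson between eigenlipid sample profiles;
correlation distance between per-province mean mixed-layer intensities;
Euclidean distance between standardized per-depth-bin mean profiles (bins
0–25, 25–50, 50–100, 100–200, 200–400 m, chosen to align stations with
different sampling depths) — are min-max normalized to [0, 1] and combined
as an equal-weight mean (weights configurable). Average linkage gives the
meta-dendrogram; `cut_tree` (not `fcluster`, which can return fewer groups
under tied heights) yields exactly k meta-clusters. k defaults to the
number of significant internal nodes + 1 (clipped to [2, n−1]); fixed k is
a config preset.

**Node significance** is a simplified Monte Carlo Gaussian test, not a
re-implementation of any external package's internals: per node, the
observed statistic is the 2-group cluster index (within-cluster sum of
squares of the node's split over the node's total), and the null draws
`n_sim` datasets from a single Gaussian with the node's mean and
diagonal-inflated variance (diagonal because the EL feature matrices have
far more features than ELs), re-clusters each (average linkage,
Euclidean), and counts simulated indices ≤ observed. Descent is
sequential: children are tested only below significant nodes. Calibration
on single-Gaussian data rejects at ≈ the nominal rate (the acceptance
suite checks ≤ 7% at α = 0.05 over 200 replicates with n_sim = 99).

## Structural analysis

Per EL, an intensity-weighted structural profile (weights = mean relative
intensity across samples): headgroup composition, mean carbons per fatty
acid, mean double bonds per chain, PUFA-containing fraction,
phosphorus-free fraction, odd-chain fraction. ELs with fewer than 5
headgroup-annotated species are excluded (configurable; mirrors the
exclusion of sparsely annotated clusters in practice). Saturation calls
are exact with chain-level data (PUFA-containing iff any chain has ≥ 2
double bonds); for sum compositions a minimal-assumption heuristic is used
(PUFA-containing iff total double bonds exceed the chain count) and
flagged as such.

Profiles are compared by a Gower-type distance: the headgroup composition
contributes a total-variation distance, each numeric field a
range-normalized absolute difference, all fields equally weighted
(constant fields dropped with a warning). Average linkage gives the
structural dendrogram.

The **mixed-effects structural model** treats the per-sample, per-EL
intensity-weighted property (e.g. mean chain length) as the response with
EL as a reference-coded fixed effect and a per-sample random intercept,
fit by REML; coefficients are tested with z statistics and BH-adjusted.
This is the only reading under which "sample-specific variation" is a
coherent random effect, and it is recorded here as an interpretation. On
non-convergence the model falls back to OLS with cluster-robust (by
sample) errors, flagged in the output.

**Tanglegram entanglement** between the distributional and structural
dendrograms: after two-sided stepwise untangling (flipping internal-node
children, alternating sides until no flip improves), the score is
Σ|r_left − r_right|^L over the fully-reversed-order normalizer, L = 1.5 by
default. The stepwise search is path-dependent, so it is run from both
starting sides and the better optimum kept, making the score symmetric in
its arguments; untangling can only lower it.

## Environmental response

* **Chain length vs temperature.** Per mixed-layer sample, the
  intensity-weighted mean carbons per fatty acid over membrane
  glycerolipids (PC, PG, PE, SQDG, MGDG, DGDG, GADG, DGTS/A, DGCC) of one
  saturation class, regressed on in-situ temperature by OLS. Standard
  errors are HC3 (heteroskedasticity-robust): the response is a share
  statistic whose variance differs across provinces, and classical errors
  undercover slightly. Slope, intercept, R² and a 95% CI are reported.
* **PCA biplot.** PCA of standardized EL intensities; loadings are
  correlation-scaled (biplot convention), covariates enter as
  supplementary vectors (correlations with the scores), and each EL's
  projection length onto each covariate vector is reported. With few,
  mutually uncorrelated ELs the 2-PC biplot is nearly degenerate after
  standardization; full-rank projections recover exact associations.
* **Random-Forest attribution.** Per response (e.g. each lipid class's
  share of total SFA/MUFA intensity), a forest (500 trees, unlimited
  depth, seeded) on {PO4, temperature} with a 70:30 train-test split; R²
  on the held-out 30%; impurity importances (sum 1) scaled by max(R², 0);
  ICE curves on a 50-point grid per predictor with the other held at
  observed values.
* **Layer contrasts.** Sea-surface temperature per station = temperature
  of the shallowest sample. The EL ratio (PUFA-chloroplast EL over the sum
  with its SFA/MUFA counterpart) is summarized in 2 °C SST bins per layer
  with seeded bootstrap (1000 resamples) 95% CIs of the mean, Welch
  t-tests per bin (BH-adjusted), and flags where the DCM exceeds the mixed
  layer. PUFA enrichment per class uses Welch t with Cohen's d (pooled SD;
  positive ⇒ higher in the DCM). EPA (20:5 chains) peak depth is compared
  to the DCM per station with a Wilcoxon signed-rank summary.

## The synthetic ocean

The generator is the benchmark's ground truth, not a fixture. It emulates
a multi-cruise sampling design: 3 regions (Atlantic as the reference for
network derivation, Pacific, Antarctic) × 3 provinces × 5 stations × 6
depths (5–200 m) = 270 samples by default, 90 in the reference region.
Provinces carry fixed surface temperatures (−1 to 28 °C); temperature
decays with depth toward a deep value; phosphate follows a broad
warm-surface depletion trend plus an independent province-level baseline
(upwelling vs oligotrophic provinces differ at equal temperature), giving
a realistic but separable temperature–phosphate correlation (r ≈ −0.6);
fluorescence is a single-peaked profile whose maximum (the planted DCM,
snapped to the depth grid) deepens with surface temperature; the mixed
layer shoals as the surface warms.

The lipidome plants 5 modules × 60 lipids plus 40 unassigned lipids and 8
contaminants. Each module has one latent response over samples
(standardized to unit variance so the log-scale noise SD, default 0.15, is
interpretable as relative noise): a cold-province indicator, a 50-m
Gaussian depth peak, a monotone temperature response, chlorophyll
tracking, and a warm-province indicator. Member log-intensities are
baseline + loading (default 1.5) × latent + Gaussian noise; intensities
are exponentiated (log-normal, matching multiplicative mass-spec error).
Modules carry structural signatures — headgroup distributions (the polar
module TAG/phospholipid-rich; the warm-water and chlorophyll modules
glycolipid/betaine- and chloroplast-dominated) and a module-level
saturation class (the polar and chlorophyll modules PUFA-containing with
20:5 chains, the rest SFA/MUFA).

Two generator choices double as identifiability requirements:

* **Chain-length field.** Within each module, membrane members come in
  baseline-matched short/long pairs (14 vs 16 carbons per chain for
  SFA/MUFA, 18 vs 20 for PUFA, the latter via 16:0/20:5 and 20:5/20:5) and
  the pair's intensity is split with weights linear in in-situ
  temperature, so the per-sample weighted mean C/FA is *exactly* linear in
  T with the configured slope (default 0.04 C/°C) regardless of which
  modules dominate where. A species-level multiplicative tilt was
  considered and rejected: its tanh-like saturation biases the recovered
  slope detectably at the benchmark's noise level.
* **Unassigned lipids** receive private log-scale variability (default
  1.0) comparable to the module signal. Without it, the CLR common mode —
  every lipid shares the subtraction of the per-sample mean log intensity
  — dominates low-variance features and makes nominally independent lipids
  almost perfectly mutually correlated.

Blanks place contaminants at ≈ sample-median/5 (failing the 20-fold rule)
and clean features a configurable margin below sample-median/20; an
infinite margin degenerates to all-zero clean blanks.

What passing the benchmark does **not** show about real data: annotations
here are complete and exact (no Ann.2/Ann.3 ambiguity), noise is
homoscedastic log-normal without missingness or censoring at the detection
limit, module memberships are disjoint and latents low-dimensional, and
provinces are sampled in a balanced design. Recovery statistics on this
generator are upper bounds on what field data would yield.

## Benchmark problem sizes

The shipped test and acceptance runs use the default conditions above
(348 features × 270 samples; 99–499 permutations/simulations for the
resampling tests; 100 seeded replicates for the regression-coverage and
Random-Forest-ranking experiments; 200 replicates for the
node-significance null calibration). These sizes keep every planted
effect comfortably identifiable while a full run completes in about a
minute on one core.

One confounding is inherent to the design rather than configured: in a
mixed-layer-only analysis the monotone-temperature response and the
warm-province indicator are collinear (the warm province *is* the warm
surface water), so the corresponding modules merge in that subset — a
faithful analog of what restricted sampling does to real co-occurrence
structure.

## Known limitations

* The dynamic tree cut is the deterministic tree variant; very close
  modules that the hybrid PAM stage would merge or refine may split or
  stay merged here (module merging by eigenlipid correlation at 0.25 is
  implemented but off by default).
* The node-significance test fits a diagonal-covariance Gaussian; strongly
  correlated EL features make it conservative.
* The entanglement optimizer is a greedy stepwise search; it guarantees no
  global optimum, only monotone improvement and argument symmetry.
* `project_region` assumes the validation regions share the reference
  lipidome's annotation space; systematic batch effects between regions
  are not modeled or corrected.
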