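"""Network construction, module detection, eigenlipids and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from eigenlipid.containers import ConfigurationError, DegenerateDataError, FeatureTable
from eigenlipid.network import (
    NetworkMatrices,
    adjacency,
    compute_eigenlipids,
    detect_modules,
    igp_reproducibility,
    lipid_correlation,
    membership_scores,
    pick_soft_threshold,
    project_region,
    scale_free_fit,
    tom_similarity,
)
from eigenlipid.preprocess import clr_transform, normalize_total
from eigenlipid.synthetic import OceanConfig, generate_lipidome, generate_metadata


def _net_from_adjacency(a: np.ndarray) -> NetworkMatrices:
    idx = [f"f{i}" for i in range(a.shape[0])]
    df = pd.DataFrame(a, index=idx, columns=idx)
    return NetworkMatrices(correlation=df, adjacency=df, beta=1.0, mode="unsigned")


def _clr_from_latents(members_per_latent, latents, noise=0.0, seed=0):
    """Lipid × sample CLR-like matrix built from latent profiles."""
    rng = np.random.default_rng(seed)
    rows, ids = [], []
    for m, latent in enumerate(latents):
        for j in range(members_per_latent):
            rows.append(latent + rng.normal(0, noise, len(latent)))
            ids.append(f"m{m}_l{j}")
    return pd.DataFrame(rows, index=ids, columns=[f"s{k}" for k in range(len(latents[0]))])


# --- adjacency & TOM --------------------------------------------------------


def test_adjacency_modes_and_examples():
    latent = np.sin(np.arange(30))
    clr = pd.DataFrame([latent, latent, -latent], index=list("abc"),
                       columns=[f"s{i}" for i in range(30)])
    signed = adjacency(clr, beta=6, mode="signed")
    unsigned = adjacency(clr, beta=6, mode="unsigned")
    assert signed.adjacency.loc["a", "b"] == pytest.approx(1.0)
    assert signed.adjacency.loc["a", "c"] == pytest.approx(0.0)
    assert unsigned.adjacency.loc["a", "c"] == pytest.approx(1.0)
    # cor 0.5, unsigned, β=6 → 0.5^6
    a = adjacency(clr, beta=6, mode="unsigned",
                  correlation=pd.DataFrame(np.array([[1, 0.5], [0.5, 1]])))
    assert a.adjacency.iloc[0, 1] == pytest.approx(0.015625)
    with pytest.raises(ConfigurationError):
        adjacency(clr, beta=0.5)


def test_tom_two_node_closed_form():
    for a12 in (0.2, 0.5, 0.9):
        tom = tom_similarity(_net_from_adjacency(np.array([[1, a12], [a12, 1]])))
        assert tom.iloc[0, 1] == pytest.approx(a12)
        assert tom.iloc[0, 0] == 1.0


@pytest.mark.parametrize("n", [3, 5, 10])
def test_tom_complete_and_empty_graph(n):
    tom = tom_similarity(_net_from_adjacency(np.ones((n, n))))
    assert np.allclose(tom.to_numpy(), 1.0)
    tom0 = tom_similarity(_net_from_adjacency(np.eye(n)))
    off = ~np.eye(n, dtype=bool)
    assert np.allclose(tom0.to_numpy()[off], 0.0)


def test_tom_bounds_symmetry_and_duplicate_identity():
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 1, (12, 12))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    tom = tom_similarity(_net_from_adjacency(a)).to_numpy()
    assert np.allclose(tom, tom.T)
    assert tom.min() >= 0 and tom.max() <= 1
    # binary adjacency: duplicated nodes have TOM 1 (1−TOM = 0)
    b = np.array(
        [[1, 1, 1, 0], [1, 1, 1, 0], [1, 1, 1, 0], [0, 0, 0, 1]], dtype=float
    )
    tom_b = tom_similarity(_net_from_adjacency(b))
    assert tom_b.iloc[0, 1] == pytest.approx(1.0)


# --- soft threshold ---------------------------------------------------------


def test_scale_free_fit_on_exact_power_law():
    # p(k) ∝ k^-2 sampled exactly by frequencies
    ks = np.concatenate([np.full(int(1e5 / k**2), k) for k in range(2, 30)])
    fit, slope = scale_free_fit(ks, n_bins=10)
    assert fit > 0.9
    assert slope < 0


def test_pick_soft_threshold_contracts():
    cfg = OceanConfig(seed=3)
    meta = generate_metadata(cfg)
    features, _ = generate_lipidome(cfg, meta)
    clr = clr_transform(normalize_total(features))
    with pytest.warns(UserWarning):
        beta1, table = pick_soft_threshold(clr, powers=(2, 4, 6), target_fit=0.99)
    beta2, _ = pick_soft_threshold(clr, powers=(2, 4, 6), target_fit=-1.0)
    assert beta2 == 2  # every power adequate → smallest returned
    with pytest.warns(UserWarning):
        beta3, _ = pick_soft_threshold(clr, powers=(2, 4, 6), target_fit=0.99)
    assert beta1 == beta3  # deterministic
    with pytest.raises(ConfigurationError):
        pick_soft_threshold(clr, powers=(6,))


def test_constant_lipid_rows_raise():
    clr = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["a", "b"])
    with pytest.raises(DegenerateDataError):
        lipid_correlation(clr)


# --- module detection -------------------------------------------------------


def test_two_perfect_blocks_recovered_exactly():
    rng = np.random.default_rng(1)
    l1, l2 = rng.normal(size=40), rng.normal(size=40)
    clr = _clr_from_latents(50, [l1, l2], noise=0.0)
    net = adjacency(clr, beta=6, mode="unsigned")
    tom = tom_similarity(net)
    els = detect_modules(tom, min_module_size=5)
    labels = els.labels
    truth = np.repeat([1, 2], 50)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, labels) == 1.0
    assert len(els.module_ids) == 2


def test_all_noise_yields_only_el0():
    rng = np.random.default_rng(2)
    clr = pd.DataFrame(rng.normal(size=(60, 50)),
                       index=[f"f{i}" for i in range(60)])
    net = adjacency(clr, beta=6)
    tom = tom_similarity(net)
    els = detect_modules(tom, min_module_size=31)  # > n/2
    assert (els.labels == 0).all()


def test_detect_modules_parameter_and_ordering():
    rng = np.random.default_rng(3)
    latents = [rng.normal(size=60) for _ in range(3)]
    clr = pd.concat(
        [
            _clr_from_latents(30, [latents[0]], noise=0.05, seed=1),
            _clr_from_latents(20, [latents[1]], noise=0.05, seed=2),
            _clr_from_latents(10, [latents[2]], noise=0.05, seed=3),
        ]
    )
    clr.index = [f"f{i}" for i in range(len(clr))]
    tom = tom_similarity(adjacency(clr, beta=6))
    els = detect_modules(tom, min_module_size=5)
    sizes = els.sizes
    assert list(sizes) == sorted(sizes, reverse=True)  # EL1 largest
    assert sizes.iloc[0] == 30 and sizes.iloc[-1] == 10
    with pytest.raises(ConfigurationError):
        detect_modules(tom, min_module_size=1)


def test_planted_module_recovery_on_default_regime(dataset, reference):
    from sklearn.metrics import adjusted_rand_score

    _, _, _, _, truth = dataset
    clr_ref, elset = reference
    planted = truth.module_label.reindex(clr_ref.feature_ids)
    assert adjusted_rand_score(planted, elset.labels) >= 0.9


# --- eigenlipids ------------------------------------------------------------


def test_eigenlipid_of_identical_profiles():
    latent = np.cos(np.arange(40) / 3.0)
    clr = _clr_from_latents(10, [latent], noise=0.0)
    labels = pd.Series(1, index=clr.index)
    els = compute_eigenlipids(clr, labels)
    e = els.profiles["EL1"]
    assert abs(np.corrcoef(e, latent)[0, 1]) == pytest.approx(1.0)
    assert els.explained_variance[1] == pytest.approx(1.0)


def test_eigenlipid_sign_oriented_to_mean_profile():
    rng = np.random.default_rng(4)
    latent = rng.normal(size=50)
    clr = _clr_from_latents(8, [latent], noise=0.1, seed=5)
    labels = pd.Series(1, index=clr.index)
    e1 = compute_eigenlipids(clr, labels).profiles["EL1"]
    e2 = compute_eigenlipids(-clr, labels).profiles["EL1"]
    mean1 = ((clr - clr.mean(axis=1).values[:, None])).mean(axis=0)
    assert np.corrcoef(e1, mean1)[0, 1] > 0
    assert np.corrcoef(e2, -mean1)[0, 1] > 0
    # flipping every member flips the eigenlipid with the mean profile
    assert np.corrcoef(e1, e2)[0, 1] == pytest.approx(-1.0, abs=1e-9)


def test_noiseless_planted_eigenlipid_matches_latent():
    cfg = OceanConfig(n_modules=1, n_unassigned_lipids=40, n_contaminants=0,
                      noise_sd=0.0, chain_length_slope=0.0, seed=6)
    meta = generate_metadata(cfg)
    features, truth = generate_lipidome(cfg, meta)
    clr = clr_transform(normalize_total(features))
    els = compute_eigenlipids(clr, truth.module_label)
    rho = np.corrcoef(els.profiles["EL1"], truth.latent_profiles[1])[0, 1]
    assert rho >= 0.999


def test_eigenlipid_first_pc_explains_most():
    rng = np.random.default_rng(7)
    latent = rng.normal(size=60)
    clr = _clr_from_latents(15, [latent], noise=0.5, seed=8)
    labels = pd.Series(1, index=clr.index)
    els = compute_eigenlipids(clr, labels)
    x = clr.to_numpy()
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    total = (x**2).sum()
    for i in range(x.shape[0]):
        axis = x[i] / np.linalg.norm(x[i])
        member_explained = ((x @ axis) ** 2).sum() / total
        assert els.explained_variance[1] >= member_explained - 1e-12


def test_membership_scores_identities():
    rng = np.random.default_rng(9)
    latent = rng.normal(size=100)
    clr = _clr_from_latents(6, [latent], noise=0.05, seed=10)
    labels = pd.Series(1, index=clr.index)
    els = compute_eigenlipids(clr, labels)
    extra = pd.DataFrame(
        {
            "equal": els.profiles["EL1"].to_numpy(),
            "reversed": -np.exp(els.profiles["EL1"].to_numpy()),
            "independent": rng.normal(size=100),
        }
    ).T
    extra.columns = clr.columns
    rho = membership_scores(pd.concat([clr, extra]), els)
    assert rho.loc["equal", "EL1"] == pytest.approx(1.0)
    assert rho.loc["reversed", "EL1"] == pytest.approx(-1.0)
    assert abs(rho.loc["independent", "EL1"]) < 0.3


# --- projection -------------------------------------------------------------


def test_projection_self_consistency(reference):
    clr_ref, elset = reference
    proj, overlap = project_region(clr_ref, elset)
    assert (overlap == 1.0).all()
    pd.testing.assert_frame_equal(proj, elset.profiles, atol=1e-9, rtol=0)


def test_projection_robust_to_missing_lipids():
    rng = np.random.default_rng(11)
    latent = rng.normal(size=80)
    clr = _clr_from_latents(30, [latent], noise=0.0, seed=12)
    labels = pd.Series(1, index=clr.index)
    els = compute_eigenlipids(clr, labels)
    dropped = clr.drop(index=rng.choice(clr.index, size=3, replace=False))
    proj, overlap = project_region(dropped, els)
    assert overlap["EL1"] == pytest.approx(27 / 30)
    assert np.corrcoef(proj["EL1"], els.profiles["EL1"])[0, 1] >= 0.99


def test_projection_disjoint_lipids_missing():
    rng = np.random.default_rng(13)
    latent = rng.normal(size=30)
    clr = _clr_from_latents(5, [latent], noise=0.0, seed=14)
    labels = pd.Series(1, index=clr.index)
    els = compute_eigenlipids(clr, labels)
    other = clr.copy()
    other.index = [f"x{i}" for i in range(len(other))]
    with pytest.warns(UserWarning):
        proj, overlap = project_region(other, els)
    assert overlap["EL1"] == 0.0
    assert proj["EL1"].isna().all()


# --- in-group proportion ----------------------------------------------------


def _block_clr(k=4, size=20, n_samples=60, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    latents = [rng.normal(size=n_samples) for _ in range(k)]
    clr = _clr_from_latents(size, latents, noise=noise, seed=seed + 1)
    labels = pd.Series(np.repeat(np.arange(1, k + 1), size), index=clr.index)
    return clr, labels


def test_igp_perfect_on_separated_blocks():
    clr, labels = _block_clr()
    els = compute_eigenlipids(clr, labels)
    res = igp_reproducibility(clr, els, n_perm=99, seed=0)
    assert (res.igp == 1.0).all()
    assert (res.p_value >= 1 / 100).all()
    assert (res.p_value <= 0.05).all()


def test_igp_p_lower_bound_and_preconditions():
    clr, labels = _block_clr()
    els = compute_eigenlipids(clr, labels)
    res = igp_reproducibility(clr, els, n_perm=199, seed=1)
    assert res.p_value.min() >= 1 / 200 - 1e-12
    with pytest.raises(ConfigurationError):
        igp_reproducibility(clr, els, n_perm=10)
    with pytest.raises(DegenerateDataError):
        igp_reproducibility(clr.iloc[:, :2], els, n_perm=99)


def test_igp_null_mean_near_one_over_k():
    clr, labels = _block_clr(k=4, size=25)
    els = compute_eigenlipids(clr, labels)
    res = igp_reproducibility(clr, els, n_perm=200, seed=2)
    se = res.null_sd / np.sqrt(res.n_permutations)
    assert (np.abs(res.null_mean - 0.25) <= 3 * se).all()
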