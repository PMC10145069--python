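"""Generator contracts: precision construction, determinism, moments, truth."""
import numpy as np
import pytest

from metnetmap import CohortConfig, generate_cohort, make_precision_matrix


def _partial_corrs(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    return -theta / np.outer(d, d)


def test_independence_case_gives_identity():
    cfg = CohortConfig(seed=1, n_metabolites=6, community_sizes=(6,),
                       edge_density_within=0.0, n_cross_edges=0)
    theta, support = make_precision_matrix(cfg)
    assert not support.to_numpy().any()
    assert np.allclose(theta.to_numpy(), np.eye(6))


def test_two_full_triangles_are_block_independent():
    cfg = CohortConfig(seed=2, n_metabolites=6, community_sizes=(3, 3),
                       edge_density_within=1.0, n_cross_edges=0)
    theta, support = make_precision_matrix(cfg)
    s = support.to_numpy()
    assert s[:3, :3].sum() == 6 and s[3:, 3:].sum() == 6
    assert not s[:3, 3:].any()
    # zero cross-block precision implies block-diagonal covariance
    sigma = np.linalg.inv(theta.to_numpy())
    assert np.abs(sigma[:3, 3:]).max() < 1e-12


def test_partial_correlations_near_requested_strength():
    cfg = CohortConfig(seed=3, n_metabolites=16, community_sizes=(8, 8),
                       within_partial_corr=0.3, edge_density_within=0.25,
                       n_cross_edges=2)
    theta, support = make_precision_matrix(cfg)
    pc = _partial_corrs(theta.to_numpy())
    edges = support.to_numpy() & np.triu(np.ones(16, dtype=bool), 1)
    assert edges.any()
    assert np.all(np.abs(np.abs(pc[edges]) - 0.3) < 0.05)


def test_infeasible_strength_raises_naming_eigenvalue():
    cfg = CohortConfig(seed=4, n_metabolites=20, community_sizes=(20,),
                       within_partial_corr=0.9, edge_density_within=1.0,
                       n_cross_edges=0)
    with pytest.raises(ValueError, match="eigenvalue"):
        make_precision_matrix(cfg)


def test_same_seed_bit_identical(small_cfg, small_cohort):
    cov, fasting, one_hour, qc, outcomes, truth = small_cohort
    cov2, f2, h2, qc2, out2, truth2 = generate_cohort(small_cfg)
    assert cov.equals(cov2)
    assert fasting.values.equals(f2.values)
    assert one_hour.values.equals(h2.values)
    assert qc.values.equals(qc2.values)
    assert outcomes.equals(out2)
    assert truth.true_precision.equals(truth2.true_precision)


def test_seed_is_mandatory():
    with pytest.raises((TypeError, ValueError)):
        CohortConfig(seed=None)


def test_community_sizes_must_sum():
    with pytest.raises(ValueError, match="community_sizes"):
        CohortConfig(seed=1, n_metabolites=10, community_sizes=(4, 4))


def test_birthweight_moments_match_configured_population():
    cfg = CohortConfig(seed=5, n_samples=4000, n_metabolites=12,
                       community_sizes=(12,))
    *_, outcomes, _ = generate_cohort(cfg)
    bw = outcomes["birthweight"]
    n = len(bw)
    se_mean = 485.0 / np.sqrt(n)
    assert abs(bw.mean() - 3391.5) < 3 * se_mean
    se_sd = 485.0 / np.sqrt(2 * n)
    assert abs(bw.std(ddof=1) - 485.0) < 3 * se_sd


def test_null_effects_give_unbiased_zero_betas():
    cfg = CohortConfig(seed=6, n_samples=4000, n_metabolites=8,
                       community_sizes=(8,), edge_density_within=0.0,
                       n_cross_edges=0, outcome_effects={},
                       covariate_loadings={}, outcome_covariate_effects={},
                       censor_fraction=0.0, n_batches=1, batch_shift_sd=0.0)
    _, fasting, _, _, outcomes, _ = generate_cohort(cfg)
    y = outcomes["birthweight"].to_numpy()
    y = (y - y.mean()) / y.std(ddof=1)
    X = fasting.values.to_numpy()
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    betas = X.T @ y / len(y) * 485.0  # outcome units per SD
    mc_se = 485.0 / np.sqrt(len(y))
    assert abs(betas.mean()) < 2 * mc_se


def test_noise_covariance_converges_to_truth():
    errs = {}
    for n in (500, 5000):
        cfg = CohortConfig(seed=7, n_samples=n, n_metabolites=10,
                           community_sizes=(5, 5), edge_density_within=0.4,
                           n_cross_edges=1, censor_fraction=0.0, n_batches=1,
                           batch_shift_sd=0.0, run_order_drift=0.0,
                           covariate_loadings={}, outcome_effects={})
        _, fasting, _, _, _, truth = generate_cohort(cfg)
        vals = np.log2(fasting.values.to_numpy()) if (
            fasting.assay_of == "gcms").all() else fasting.values.to_numpy()
        # normalize per-metabolite scale before comparing with unit-variance truth
        vals = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=1)
        sigma_true = np.linalg.inv(truth.true_precision.to_numpy())
        d = np.sqrt(np.diag(sigma_true))
        corr_true = sigma_true / np.outer(d, d)
        errs[n] = np.linalg.norm(np.corrcoef(vals, rowvar=False) - corr_true)
    assert errs[5000] < errs[500]


def test_censoring_is_left_tailed(small_cohort):
    _, fasting, _, _, _, truth = small_cohort
    vals = fasting.masked()
    for met in fasting.metabolite_ids:
        lim = truth.censor_limits[met]
        if np.isnan(lim) or not fasting.missing[met].any():
            continue
        observed = np.log2(vals[met].dropna())  # gcms metabolites censor
        assert observed.min() >= lim - 1e-9


def test_qc_batch_means_reflect_planted_shifts(small_cohort):
    cfg_seed = 11
    cov, fasting, _, qc, _, truth = small_cohort
    rec = qc.records
    mask = rec["sample_time"] == "fasting"
    shifts = truth.batch_shifts.loc["fasting"]
    for met in fasting.metabolite_ids[:6]:
        qv = np.asarray(qc.values.loc[mask.to_numpy(), met], dtype=float)
        if fasting.assay_of[met] == "gcms":
            qv = np.log2(qv)
        elif fasting.class_of[met] == "AC":
            qv = np.log(qv)
        batches = rec.loc[mask, "batch"].to_numpy()
        means = {b: qv[batches == b].mean() for b in np.unique(batches)}
        for b1 in means:
            for b2 in means:
                planted = shifts.loc[b1, met] - shifts.loc[b2, met]
                assert abs((means[b1] - means[b2]) - planted) < 0.15


def test_planted_outliers_recorded_and_applied():
    cfg = CohortConfig(seed=8, n_samples=200, n_metabolites=8,
                       community_sizes=(8,), outlier_plants=((5, "met_004", 8.0),),
                       censor_fraction=0.0)
    _, fasting, _, _, _, truth = generate_cohort(cfg)
    assert truth.planted_outliers == (("S00006", "met_004", 8.0),)
    col = fasting.values["met_004"]
    if fasting.assay_of["met_004"] == "gcms":
        col = np.log2(col)
    z = (col - col.mean()) / col.std(ddof=1)
    assert z.loc["S00006"] > 5
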