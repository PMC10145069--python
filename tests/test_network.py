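"""Residualization, spin-glass communities, and network assembly/export."""
import numpy as np
import pandas as pd
import pytest

from metnetmap import AnnealSchedule, CohortConfig, ModelSpec, generate_cohort
from metnetmap.network import (
    NetworkError,
    build_network,
    exhaustive_minimum,
    fit_network,
    residualize,
    spin_glass_communities,
    spinglass_hamiltonian,
    write_graphml,
)
from metnetmap.preprocess import preprocess_matrix


def _two_cliques(k=4):
    n = 2 * k
    A = np.zeros((n, n))
    for blk in (range(k), range(k, n)):
        for i in blk:
            for j in blk:
                if i != j:
                    A[i, j] = 1.0
    return A


def test_residual_structure_matches_ggm_truth():
    cfg = CohortConfig(seed=21, n_samples=5000, n_metabolites=10,
                       community_sizes=(5, 5), edge_density_within=0.4,
                       n_cross_edges=1, censor_fraction=0.0,
                       outcome_effects={},
                       covariate_loadings={"met_001": {"bmi": 2.0}})
    cov, fasting, _, qc, outcomes, truth = generate_cohort(cfg)
    mat, _ = preprocess_matrix(fasting, qc)
    spec = ModelSpec(model=2, outcome="birthweight", sample_time="fasting")
    resid, dropped = residualize(mat, cov, spec)
    assert not dropped
    # BMI signal removed from the loaded metabolite
    bmi = cov.loc[resid.index, "bmi"].to_numpy()
    r = np.corrcoef(resid["met_001"], bmi)[0, 1]
    assert abs(r) < 1e-8
    # residual correlations track the generating GGM covariance
    S = np.corrcoef(resid.to_numpy(), rowvar=False)
    sigma = np.linalg.inv(truth.true_precision.to_numpy())
    d = np.sqrt(np.diag(sigma))
    assert np.abs(S - sigma / np.outer(d, d)).max() < 0.08


def test_intercept_only_residuals_are_centered_metabolites(small_cohort):
    cov, fasting, _, qc, _, _ = small_cohort
    mat, _ = preprocess_matrix(fasting, qc)

    class FreeSpec:
        covariates: tuple = ()
    resid, _ = residualize(mat, cov, FreeSpec())
    vals = mat.masked().loc[resid.index]
    met = resid.columns[0]
    centered = vals[met].fillna(vals[met].mean()) - vals[met].mean()
    expected = centered / centered.std(ddof=1)
    assert np.allclose(resid[met], expected, atol=1e-9)


def test_linear_combination_of_covariates_is_dropped(small_cohort):
    cov, fasting, _, qc, _, _ = small_cohort
    mat, _ = preprocess_matrix(fasting, qc)
    mat.values["met_001"] = 2.0 * cov.loc[mat.values.index, "bmi"]
    spec = ModelSpec(model=2, outcome="birthweight", sample_time="fasting")
    resid, dropped = residualize(mat, cov, spec)
    assert "met_001" in dropped
    assert "met_001" not in resid.columns


def test_two_cliques_split_exactly():
    A = _two_cliques()
    labels = spin_glass_communities(A, AnnealSchedule(seed=5))
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert labels[0] != labels[4]
    h = spinglass_hamiltonian(A, labels)
    h_star, _ = exhaustive_minimum(A)
    assert h == pytest.approx(h_star)


def test_single_clique_single_community():
    A = 1.0 - np.eye(6)
    labels = spin_glass_communities(A, AnnealSchedule(seed=1))
    assert len(set(labels)) == 1
    h_star, _ = exhaustive_minimum(A)
    assert spinglass_hamiltonian(A, labels) == pytest.approx(h_star)


def test_edgeless_graph_all_singletons():
    labels = spin_glass_communities(np.zeros((5, 5)), AnnealSchedule(seed=1))
    assert sorted(labels) == [0, 1, 2, 3, 4]


def test_community_labels_deterministic():
    rng = np.random.default_rng(3)
    A = (rng.random((12, 12)) < 0.3).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    l1 = spin_glass_communities(A, AnnealSchedule(seed=9))
    l2 = spin_glass_communities(A, AnnealSchedule(seed=9))
    assert np.array_equal(l1, l2)


def test_asymmetric_adjacency_rejected():
    A = np.zeros((3, 3))
    A[0, 1] = 1.0
    with pytest.raises(NetworkError):
        spin_glass_communities(A)


def _toy_fit(p=3, edges=((0, 1),)):
    from metnetmap.containers import GlassoFit
    theta = np.eye(p) * 2.0
    for i, j in edges:
        theta[i, j] = theta[j, i] = -0.5
    support = (theta != 0) & ~np.eye(p, dtype=bool)
    return GlassoFit(S=np.linalg.inv(theta), lam=0.1, precision=theta,
                     covariance=np.linalg.inv(theta), support=support,
                     iterations=1, converged=True, max_kkt_violation=0.0,
                     metabolite_ids=tuple(f"m{i}" for i in range(p)))


def test_node_sizes_from_nominal_p():
    fit = _toy_fit()
    classes = pd.Series(["AA", "AC", "CHO"], index=["m0", "m1", "m2"])
    comms = np.array([0, 0, 1])
    with pytest.warns(UserWarning):
        net = build_network(fit, comms, {"m0": 0.01, "m1": 1.0, "m2": 0.0},
                            classes, "fasting", "birthweight")
    sizes = net.nodes["node_size"]
    assert sizes["m0"] == pytest.approx(2.0)
    assert sizes["m1"] == pytest.approx(0.0)
    assert sizes["m2"] == pytest.approx(50.0)  # p=0 capped


def test_missing_pvalue_warns_and_zeroes():
    fit = _toy_fit()
    classes = pd.Series(["AA", "AC", "CHO"], index=["m0", "m1", "m2"])
    with pytest.warns(UserWarning, match="no p-value"):
        net = build_network(fit, np.zeros(3, dtype=int),
                            {"m0": 0.5, "m1": 0.5}, classes, "fasting", "ssf")
    assert net.nodes.loc["m2", "node_size"] == 0.0


def test_single_community_has_no_between_edges():
    fit = _toy_fit(p=3, edges=((0, 1), (1, 2)))
    classes = pd.Series(["AA"] * 3, index=["m0", "m1", "m2"])
    net = build_network(fit, np.zeros(3, dtype=int),
                        {f"m{i}": 0.5 for i in range(3)},
                        classes, "fasting", "birthweight")
    assert net.edges["within_community"].all()


def test_planted_bridge_is_the_only_between_community_edge():
    # an acylcarnitine-like and an amino-acid-like community joined by a
    # single bridge edge: the exported network flags exactly that edge as
    # between-community
    cfg = CohortConfig(seed=31, n_samples=3000, n_metabolites=16,
                       community_sizes=(8, 8), edge_density_within=0.4,
                       n_cross_edges=1, censor_fraction=0.0,
                       outcome_effects={}, covariate_loadings={})
    cov, fasting, _, qc, outcomes, truth = generate_cohort(cfg)
    mat, _ = preprocess_matrix(fasting, qc)
    spec = ModelSpec(model=2, outcome="birthweight", sample_time="fasting")
    resid, _ = residualize(mat, cov, spec)
    fit = fit_network(resid, seed=31)
    labels = spin_glass_communities(fit.support.astype(float),
                                    AnnealSchedule(seed=31))
    classes = mat.class_of
    net = build_network(fit, labels, {m: 0.5 for m in resid.columns},
                        classes, "fasting", "birthweight")
    ids = list(resid.columns)
    tru = truth.true_support.to_numpy()
    bridge = [(ids[i], ids[j]) for i, j in zip(*np.nonzero(np.triu(tru, 1)))
              if truth.true_communities.iloc[i] != truth.true_communities.iloc[j]]
    assert len(bridge) == 1
    between = net.edges.loc[~net.edges["within_community"],
                            ["source", "target"]].apply(tuple, axis=1).tolist()
    assert between == bridge


def test_graphml_round_trip(tmp_path):
    import networkx as nx
    fit = _toy_fit(p=3, edges=((0, 1),))
    classes = pd.Series(["AA", "AC", "CHO"], index=["m0", "m1", "m2"])
    net = build_network(fit, np.array([0, 0, 1]),
                        {f"m{i}": 0.05 for i in range(3)},
                        classes, "fasting", "birthweight")
    path = tmp_path / "net.graphml"
    write_graphml(net, path)
    g = nx.read_graphml(path)
    assert g.nodes["m0"]["class"] == "AA"
    assert g.nodes["m0"]["community"] == 0
    assert g.edges["m0", "m1"]["partial_correlation"] == pytest.approx(0.25)
    assert g.graph["selected_lambda"] == pytest.approx(0.1)
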