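"""Metabolite network estimation and community structure.

Residualizes the low-missingness metabolite set on Model 2 covariates,
estimates a sparse Gaussian graphical model with the graphical lasso at a
rotation-information-criterion penalty, converts the precision matrix to
partial-correlation edges, partitions nodes with Reichardt-Bornholdt
spin-glass annealing, and exports node-sized (-log10 p) networks to
GraphML / CSV.
"""
from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .association import _design_matrix
from .config import AnnealSchedule, ModelSpec
from .containers import GlassoFit, MetaboliteMatrix, MetaboliteNetwork
from .glasso import glasso_fit, partial_correlations, select_lambda_ric

#: node size assigned when p underflows to 0
MAX_NODE_SIZE = 50.0
#: residual columns with variance below this fraction of 1 are degenerate
RESIDUAL_VAR_FLOOR = 1e-10


class NetworkError(ValueError):
    pass


def residualize(m: MetaboliteMatrix, cov: pd.DataFrame, spec: ModelSpec,
                ) -> tuple[pd.DataFrame, list[str]]:
    """Residuals of each metabolite on the model covariates.

    Rows are restricted to samples complete on all covariates; remaining
    missing metabolite cells (below 1% by construction of the network set)
    are mean-imputed per metabolite before the OLS. Residual columns are
    standardized to unit variance; columns with (near-)zero residual
    variance are flagged and excluded. Returns ``(residuals, dropped)``.
    """
    missing_cov = [c for c in spec.covariates if c not in cov.columns]
    if missing_cov:
        raise NetworkError(f"covariate table lacks required columns: {missing_cov}")
    samples = m.values.index.intersection(cov.index)
    cov = cov.loc[samples]
    numeric = [c for c in spec.covariates if c != "field_center"]
    ok = cov[numeric].notna().all(axis=1)
    cov = cov.loc[ok]
    vals = m.masked().loc[cov.index]

    X = _design_matrix(cov, spec.covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient covariate design: dropping aliased columns")
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) > len(kept):
                kept.append(j)
        X = X[:, kept]
    # hat-matrix-free residual projector via least squares
    Y = vals.to_numpy(dtype=float)
    col_means = np.nanmean(Y, axis=0)
    nan_mask = np.isnan(Y)
    Y = np.where(nan_mask, col_means[None, :], Y)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ coef

    ids = list(m.metabolite_ids)
    var = R.var(axis=0, ddof=1)
    dropped = [ids[j] for j in range(len(ids)) if var[j] <= RESIDUAL_VAR_FLOOR]
    keep = [j for j in range(len(ids)) if var[j] > RESIDUAL_VAR_FLOOR]
    R = R[:, keep] / np.sqrt(var[keep])[None, :]
    out = pd.DataFrame(R, index=cov.index, columns=[ids[j] for j in keep])
    return out, dropped


def spinglass_hamiltonian(adjacency: np.ndarray, labels: np.ndarray,
                          gamma: float = 1.0) -> float:
    """Reichardt-Bornholdt Hamiltonian with the configuration null model,
    H = -sum_{i<j} [A_ij - gamma k_i k_j / (2m)] delta(s_i, s_j), evaluated
    per connected component (each with its own m) and summed."""
    A = np.asarray(adjacency, dtype=float)
    n_comp, comp = connected_components(A, directed=False)
    H = 0.0
    for c in range(n_comp):
        nodes = np.flatnonzero(comp == c)
        if len(nodes) < 2:
            continue
        Ac = A[np.ix_(nodes, nodes)]
        k = Ac.sum(axis=1)
        two_m = k.sum()
        if two_m == 0:
            continue
        lab = labels[nodes]
        same = lab[:, None] == lab[None, :]
        mod = Ac - gamma * np.outer(k, k) / two_m
        H -= float((mod * same)[np.triu_indices(len(nodes), k=1)].sum())
    return H


def _anneal_component(A: np.ndarray, sched: AnnealSchedule,
                      rng: np.random.Generator) -> np.ndarray:
    """Seeded single-spin Metropolis annealing on one connected component."""
    n = A.shape[0]
    k = A.sum(axis=1).astype(float)
    two_m = float(k.sum())
    gamma = sched.gamma
    q = min(n, sched.max_communities)
    if n > sched.max_communities:
        warnings.warn(f"component of {n} nodes capped at "
                      f"{sched.max_communities} communities")
    neighbors = [np.flatnonzero(A[i]) for i in range(n)]

    labels = rng.integers(0, q, size=n) if n > q else np.arange(n) % q
    K = np.zeros(q)  # community degree sums
    for i in range(n):
        K[labels[i]] += k[i]

    def delta_h(u: int, c_new: int) -> float:
        c_old = labels[u]
        if c_new == c_old:
            return 0.0
        nb = labels[neighbors[u]]
        links_new = float((nb == c_new).sum())
        links_old = float((nb == c_old).sum())
        null_new = gamma * k[u] * K[c_new] / two_m
        null_old = gamma * k[u] * (K[c_old] - k[u]) / two_m
        return -(links_new - null_new) + (links_old - null_old)

    sweeps = sched.sweeps_per_temp if sched.sweeps_per_temp is not None else n
    T = sched.start_temp
    while T > sched.stop_temp:
        for _ in range(sweeps * n):
            u = int(rng.integers(n))
            c = int(rng.integers(q))
            dh = delta_h(u, c)
            if dh <= 0 or rng.random() < np.exp(-dh / T):
                K[labels[u]] -= k[u]
                labels[u] = c
                K[c] += k[u]
        T *= sched.cooling_factor

    # zero-temperature polish: greedy best-move until a local minimum
    improved = True
    while improved:
        improved = False
        for u in range(n):
            best_c, best_dh = labels[u], 0.0
            for c in range(q):
                dh = delta_h(u, c)
                if dh < best_dh - 1e-12:
                    best_c, best_dh = c, dh
            if best_c != labels[u]:
                K[labels[u]] -= k[u]
                labels[u] = best_c
                K[best_c] += k[u]
                improved = True
    return labels


def spin_glass_communities(adjacency, sched: AnnealSchedule | None = None,
                           ) -> np.ndarray:
    """Community labels for a symmetric adjacency matrix.

    Each connected component with >= 2 nodes is annealed separately;
    isolated nodes get singleton labels. Labels are relabeled to
    consecutive integers in order of first appearance; the result is
    deterministic given ``sched.seed``.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise NetworkError("adjacency must be symmetric")
    if np.diag(A).any():
        raise NetworkError("adjacency diagonal must be zero")
    sched = sched or AnnealSchedule()
    n = A.shape[0]
    labels = np.full(n, -1, dtype=int)
    n_comp, comp = connected_components(A, directed=False)
    next_label = 0
    ss = np.random.SeedSequence([int(sched.seed)])
    children = ss.spawn(n_comp)
    for c in range(n_comp):
        nodes = np.flatnonzero(comp == c)
        if len(nodes) == 1:
            labels[nodes[0]] = next_label
            next_label += 1
            continue
        rng = np.random.default_rng(children[c])
        sub = _anneal_component(A[np.ix_(nodes, nodes)], sched, rng)
        for raw in pd.unique(sub):
            labels[nodes[sub == raw]] = next_label
            next_label += 1
    # relabel consecutively by first appearance over node order
    mapping: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def exhaustive_minimum(adjacency: np.ndarray, gamma: float = 1.0,
                       ) -> tuple[float, np.ndarray]:
    """Brute-force Hamiltonian minimum over all set partitions (n <= 12).

    Enumeration is by restricted growth strings; intended as an oracle for
    small graphs, not for production use.
    """
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    if n > 12:
        raise NetworkError("exhaustive search is for small graphs only")

    best_h, best_lab = np.inf, None

    def grow(prefix: list[int]):
        nonlocal best_h, best_lab
        if len(prefix) == n:
            lab = np.array(prefix)
            h = spinglass_hamiltonian(A, lab, gamma)
            if h < best_h:
                best_h, best_lab = h, lab
            return
        top = max(prefix) if prefix else -1
        for v in range(top + 2):
            grow(prefix + [v])

    grow([])
    return float(best_h), best_lab


def fit_network(residuals: pd.DataFrame, lam: float | None = None,
                ric_rotations: int = 20, seed: int = 0,
                n_points: int = 30, ratio: float = 0.05,
                tol: float = 1e-4) -> GlassoFit:
    """Correlation matrix of the standardized residuals -> glasso fit at
    the RIC-selected penalty (or a caller-fixed one)."""
    S = np.corrcoef(residuals.to_numpy(), rowvar=False)
    if lam is None:
        lam = select_lambda_ric(residuals.to_numpy(), n_rotations=ric_rotations,
                                seed=seed, n_points=n_points, ratio=ratio)
    return glasso_fit(S, lam, tol=tol,
                      metabolite_ids=tuple(residuals.columns))


def build_network(fit: GlassoFit, communities: np.ndarray,
                  per_metabolite_p: dict[str, float],
                  class_of: pd.Series, sample_time: str,
                  outcome: str) -> MetaboliteNetwork:
    """Assemble the exportable network: nodes sized by -log10(nominal p)
    from the matching Model 2 analysis, partial-correlation edges, and a
    within/between-community flag per edge."""
    ids = list(fit.metabolite_ids)
    rho = partial_correlations(fit)
    sizes = []
    for met in ids:
        p = per_metabolite_p.get(met)
        if p is None:
            warnings.warn(f"no p-value for {met}; node size set to 0")
            sizes.append(0.0)
        elif p <= 0:
            warnings.warn(f"p=0 for {met}; node size capped at {MAX_NODE_SIZE}")
            sizes.append(MAX_NODE_SIZE)
        else:
            sizes.append(min(-np.log10(p), MAX_NODE_SIZE))
    nodes = pd.DataFrame({
        "class": class_of.loc[ids].to_numpy(),
        "node_size": sizes,
        "community": communities.astype(int),
    }, index=pd.Index(ids, name="metabolite"))

    rows = []
    for i, j in zip(*np.nonzero(np.triu(fit.support, k=1))):
        rows.append({
            "source": ids[i], "target": ids[j],
            "partial_correlation": float(rho[i, j]),
            "within_community": bool(communities[i] == communities[j]),
        })
    edges = pd.DataFrame(rows, columns=["source", "target",
                                        "partial_correlation", "within_community"])
    return MetaboliteNetwork(nodes=nodes, edges=edges, selected_lambda=fit.lam,
                             sample_time=sample_time, outcome=outcome)


def to_graph(net: MetaboliteNetwork) -> nx.Graph:
    g = nx.Graph(selected_lambda=net.selected_lambda,
                 sample_time=net.sample_time, outcome=net.outcome)
    for met, row in net.nodes.iterrows():
        g.add_node(met, **{"class": row["class"],
                           "node_size": float(row["node_size"]),
                           "community": int(row["community"])})
    for _, e in net.edges.iterrows():
        g.add_edge(e["source"], e["target"],
                   partial_correlation=float(e["partial_correlation"]),
                   within_community=bool(e["within_community"]))
    return g


def write_graphml(net: MetaboliteNetwork, path) -> None:
    nx.write_graphml(to_graph(net), path)
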