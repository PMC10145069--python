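"""Graphical lasso: L1-penalized sparse precision estimation.

Maximizes ``log det(Theta) - trace(S Theta) - lambda * sum_{i!=j} |Theta_ij|``
over positive-definite matrices (diagonal unpenalized, so the lambda -> 0
limit is the unpenalized MLE ``inv(S)`` and the off-diagonal entries keep
their partial-correlation interpretation). Solved by block coordinate
descent on the working covariance W with a coordinate-wise soft-threshold
lasso for each column, the classic approach for this objective.

Stationarity of the objective gives the KKT certificate reported on every
fit: with W = inv(Theta), ``W_ij - S_ij = lambda * sign(Theta_ij)`` on the
support and ``|W_ij - S_ij| <= lambda`` off it.
"""
from __future__ import annotations

import warnings

import numpy as np

from .containers import GlassoFit

#: relative zero threshold for the edge support
SUPPORT_RTOL = 1e-6


class GlassoError(ValueError):
    pass


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _lasso_cd(V: np.ndarray, s: np.ndarray, lam: float, beta: np.ndarray,
              tol: float, max_iter: int = 500) -> np.ndarray:
    """Coordinate descent for min 0.5 b'Vb - s'b + lam*|b|_1, warm-started."""
    p = len(s)
    Vb = V @ beta
    for _ in range(max_iter):
        delta = 0.0
        for k in range(p):
            old = beta[k]
            # partial residual: s_k - sum_{l != k} V_kl b_l
            g = s[k] - (Vb[k] - V[k, k] * old)
            new = _soft(g, lam) / V[k, k]
            if new != old:
                beta[k] = new
                Vb += V[:, k] * (new - old)
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return beta


def glasso_fit(S: np.ndarray, lam: float, tol: float = 1e-4,
               max_iter: int = 200,
               metabolite_ids: tuple[str, ...] = ()) -> GlassoFit:
    """Fit the graphical lasso at one penalty value.

    ``S`` must be symmetric positive semidefinite; ``lam >= 0``.
    Convergence: mean absolute change of the off-diagonal of W across a
    full sweep below ``tol`` times the mean absolute off-diagonal of S.
    At ``lam == 0`` the closed-form MLE ``inv(S)`` is returned directly.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise GlassoError("S must be a symmetric matrix")
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin < -1e-8 * max(1.0, np.abs(S).max()):
        raise GlassoError(f"S is not positive semidefinite (min eig {eigmin:.3g})")
    if lam < 0:
        raise GlassoError("lambda must be non-negative")

    off = ~np.eye(p, dtype=bool)
    if lam == 0.0:
        theta = np.linalg.inv(S)
        support = (np.abs(theta) > SUPPORT_RTOL * np.abs(np.diag(theta)).max()) & off
        return GlassoFit(S=S, lam=0.0, precision=theta, covariance=S.copy(),
                         support=support, iterations=0, converged=True,
                         max_kkt_violation=0.0, metabolite_ids=tuple(metabolite_ids))

    W = S.copy()
    B = np.zeros((p, p))  # column-wise lasso coefficients, warm-started
    s_off_mean = float(np.abs(S[off]).mean()) if p > 1 else 0.0
    thresh = tol * max(s_off_mean, 1e-12)
    inner_tol = thresh / 10.0

    converged = False
    iterations = 0
    idx_cache = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    for it in range(1, max_iter + 1):
        iterations = it
        W_old_off = W[off].copy()
        for j in range(p):
            idx = idx_cache[j]
            V = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            beta = _lasso_cd(V, s12, lam, B[idx, j].copy(), inner_tol)
            B[idx, j] = beta
            w12 = V @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if float(np.abs(W[off] - W_old_off).mean()) < thresh:
            converged = True
            break
    if not converged:
        warnings.warn(f"glasso did not converge in {max_iter} sweeps at lambda={lam}")

    # recover Theta from the final (W, B) pair
    theta = np.zeros((p, p))
    for j in range(p):
        idx = idx_cache[j]
        beta = B[idx, j]
        denom = W[j, j] - float(W[idx, j] @ beta)
        theta[j, j] = 1.0 / denom
        theta[idx, j] = -beta * theta[j, j]
    theta = 0.5 * (theta + theta.T)

    support = (np.abs(theta) > SUPPORT_RTOL * np.abs(np.diag(theta)).max()) & off
    theta_inv = np.linalg.inv(theta)
    diff = theta_inv - S
    grad_on = np.abs(diff - lam * np.sign(theta))[support & off]
    grad_off = np.maximum(np.abs(diff) - lam, 0.0)[off & ~support]
    kkt = 0.0
    if grad_on.size:
        kkt = max(kkt, float(grad_on.max()))
    if grad_off.size:
        kkt = max(kkt, float(grad_off.max()))
    return GlassoFit(S=S, lam=float(lam), precision=theta, covariance=theta_inv,
                     support=support, iterations=iterations, converged=converged,
                     max_kkt_violation=kkt, metabolite_ids=tuple(metabolite_ids))


def lambda_path(S: np.ndarray, n_points: int = 30, ratio: float = 0.05) -> np.ndarray:
    """Descending log-spaced penalty path from lambda_max (= max off-diagonal
    |S_ij|, the smallest penalty giving the empty graph) down to
    ratio * lambda_max."""
    if n_points < 2:
        raise GlassoError("n_points must be >= 2")
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    lam_max = float(np.abs(S[off]).max()) if p > 1 else 0.0
    if lam_max == 0.0:
        warnings.warn("all off-diagonal entries of S are zero; single lambda=0 path")
        return np.array([0.0])
    return np.exp(np.linspace(np.log(lam_max), np.log(ratio * lam_max), n_points))


def partial_correlations(fit: GlassoFit) -> np.ndarray:
    """Partial-correlation matrix rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj),
    unit diagonal, exactly zero off the edge support."""
    theta = fit.precision
    d = np.diag(theta)
    if (d <= 0).any():
        raise GlassoError("precision matrix has non-positive diagonal")
    rho = -theta / np.sqrt(np.outer(d, d))
    np.fill_diagonal(rho, 1.0)
    off = ~np.eye(len(d), dtype=bool)
    rho[off & ~fit.support] = 0.0
    return rho


def select_lambda_ric(residuals: np.ndarray, n_rotations: int = 20,
                      seed: int = 0, n_points: int = 30,
                      ratio: float = 0.05) -> float:
    """Rotation-information-criterion penalty selection.

    Each rotation independently permutes the sample indices within every
    column (destroying all cross-column dependence while preserving
    margins), computes the permuted sample correlation matrix, and records
    its largest absolute off-diagonal entry. The selected penalty is the
    maximum over rotations, snapped up to the nearest value of the penalty
    path of the observed data — calibrated so truly independent data yield
    an (almost) empty graph.
    """
    if n_rotations < 1:
        raise GlassoError("n_rotations must be >= 1")
    R = np.asarray(residuals, dtype=float)
    n, p = R.shape
    if n <= 3:
        raise GlassoError("need more than 3 samples")
    rng = np.random.default_rng(seed)
    lam_star = 0.0
    for _ in range(n_rotations):
        perm = np.column_stack([rng.permutation(R[:, j]) for j in range(p)])
        C = np.corrcoef(perm, rowvar=False)
        off = ~np.eye(p, dtype=bool)
        lam_star = max(lam_star, float(np.abs(C[off]).max()))
    S = np.corrcoef(R, rowvar=False)
    path = lambda_path(S, n_points=n_points, ratio=ratio)
    at_least = path[path >= lam_star - 1e-12]
    if at_least.size == 0:
        # null level exceeds every observed correlation: empty graph
        return float(path[0])
    return float(at_least.min())
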