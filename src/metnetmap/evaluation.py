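"""Recovery metrics and benchmark drivers used by the analysis scripts.

These functions regenerate cohorts under known truth and score the
estimators against it: edge-support F1 for the graphical lasso, adjusted
Rand index for spin-glass communities, bias of planted per-SD effects,
empirical false-discovery proportion under the global null, and pooled-QC
batch-shift recovery error.
"""
from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .association import associate
from .config import AnnealSchedule, CohortConfig, ModelSpec
from .network import fit_network, residualize, spin_glass_communities
from .preprocess import preprocess_matrix
from .synthetic import generate_cohort


def edge_f1(estimated: np.ndarray, truth: np.ndarray) -> float:
    """F1 of the estimated edge set against the true support (upper
    triangles of symmetric boolean matrices)."""
    iu = np.triu_indices(truth.shape[0], k=1)
    est, tru = np.asarray(estimated)[iu], np.asarray(truth)[iu]
    tp = int((est & tru).sum())
    fp = int((est & ~tru).sum())
    fn = int((~est & tru).sum())
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def recovery_config(seed: int, n: int = 2000, p: int = 40) -> CohortConfig:
    """Graph-recovery study conditions: 4 equal communities, requested
    within partial correlation 0.3, a few cross-community bridges;
    censoring and batch artifacts disabled so the measurement isolates the
    graph estimators. Within-block density 0.4 keeps each community a
    single cohesive connected subgraph (sparser blocks fragment and have
    no community structure to recover)."""
    return CohortConfig(
        seed=seed, n_samples=n, n_metabolites=p,
        community_sizes=(p // 4,) * 4,
        within_partial_corr=0.3, edge_density_within=0.4, n_cross_edges=4,
        censor_fraction=0.0, n_batches=1, batch_shift_sd=0.0,
        outcome_effects={}, covariate_loadings={},
    )


def graph_recovery_once(seed: int, n: int = 2000, p: int = 40,
                        ric_rotations: int = 20) -> tuple[float, float]:
    """Simulate -> residualize -> RIC-selected glasso -> spin-glass; return
    (edge-support F1 vs truth, ARI of communities vs planted labels)."""
    cfg = recovery_config(seed, n=n, p=p)
    cov, fasting, _, qc, outcomes, truth = generate_cohort(cfg)
    mat, _ = preprocess_matrix(fasting, qc)
    spec = ModelSpec(model=2, outcome="birthweight", sample_time="fasting")
    resid, _ = residualize(mat, cov, spec)
    fit = fit_network(resid, ric_rotations=ric_rotations, seed=seed)
    cols = list(resid.columns)
    f1 = edge_f1(fit.support, truth.true_support.loc[cols, cols].to_numpy())
    sched = AnnealSchedule(seed=seed)
    labels = spin_glass_communities(fit.support.astype(float), sched)
    true_labels = truth.true_communities.loc[list(resid.columns)].to_numpy()
    return f1, float(adjusted_rand_score(true_labels, labels))


def null_fdr_once(seed: int, n: int = 300, p: int = 500,
                  q: float = 0.05) -> tuple[int, int]:
    """One global-null cohort: no planted effects anywhere. Returns
    (number FDR-significant at q, number tested)."""
    cfg = CohortConfig(
        seed=seed, n_samples=n, n_metabolites=p,
        community_sizes=(p,), edge_density_within=0.0, n_cross_edges=0,
        outcome_effects={}, covariate_loadings={},
        outcome_covariate_effects={}, censor_fraction=0.0, n_batches=1,
        batch_shift_sd=0.0,
    )
    cov, fasting, _, qc, outcomes, _ = generate_cohort(cfg)
    mat, _ = preprocess_matrix(fasting, qc)
    spec = ModelSpec(model=2, outcome="birthweight", sample_time="fasting")
    results = associate(mat, cov, outcomes, spec)
    n_sig = sum(r.fdr_p < q for r in results)
    return n_sig, len(results)


def effect_recovery_once(seed: int, n: int = 2000, effect: float = 40.0,
                         ) -> tuple[float, bool, bool]:
    """One cohort with a planted direct effect and a fully BMI-mediated
    metabolite. Returns (estimated beta for the planted metabolite,
    mediated metabolite Model-1 significant, mediated Model-2 null) at
    nominal p < 0.05."""
    cfg = CohortConfig(
        seed=seed, n_samples=n, n_metabolites=8, community_sizes=(8,),
        edge_density_within=0.0, n_cross_edges=0,
        outcome_effects={("met_005", "birthweight"): effect},
        covariate_loadings={"met_002": {"bmi": 0.6}},
        censor_fraction=0.0,
    )
    cov, fasting, _, qc, outcomes, _ = generate_cohort(cfg)
    mat, _ = preprocess_matrix(fasting, qc)
    res = {}
    for model in (1, 2):
        spec = ModelSpec(model=model, outcome="birthweight", sample_time="fasting")
        res[model] = {r.metabolite: r
                      for r in associate(mat, cov, outcomes, spec)}
    beta = res[2]["met_005"].beta
    m1_sig = res[1]["met_002"].p < 0.05
    m2_null = res[2]["met_002"].p >= 0.05
    return beta, m1_sig, m2_null


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Direct-formula Benjamini-Hochberg used as an independent check of
    :func:`metnetmap.association.adjust_fdr`: for the i-th smallest p,
    min over j >= i of p_(j) * m / j, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for rank_idx, i in enumerate(order):
        j = np.arange(rank_idx + 1, m + 1)
        out[i] = min(1.0, float((p[order][rank_idx:] * m / j).min()))
    return out
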