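"""Metabolome-wide association of maternal metabolites with newborn outcomes.

Each metabolite is standardized to mean 0 / SD 1 within an ancestry stratum
and regressed against the outcome by ordinary least squares together with
the model's covariates (field center entering as indicator contrasts).
Stratum estimates are pooled by fixed-effect inverse-variance weighting,
p-values are Benjamini-Hochberg adjusted within (sample time x outcome x
model) families, and results are laid out one row per metabolite with
Model 1 and Model 2 side by side.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelSpec
from .containers import AssociationResult, MetaboliteMatrix

MIN_STRATUM_MARGIN = 5  # stratum must satisfy n > n_params + this margin


class AssociationError(ValueError):
    pass


def _design_matrix(cov: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Intercept + covariates; field center expands to indicator contrasts
    (first level dropped; levels constant within the stratum drop out)."""
    cols = [np.ones(len(cov))]
    for c in covariates:
        if c == "field_center":
            levels = sorted(cov[c].unique())
            for lev in levels[1:]:
                cols.append((cov[c] == lev).to_numpy(dtype=float))
        else:
            cols.append(cov[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def ols_beta_se(y: np.ndarray, X: np.ndarray) -> tuple[float, float, int]:
    """OLS of y on X; returns (beta_1, se_1, dof) for the first column of X
    (the standardized metabolite). Aliased covariate columns are dropped
    with a warning."""
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design: dropping aliased columns",
                      stacklevel=2)
        # greedy forward pass keeping independent columns; column 0 (the
        # metabolite) is kept first so its coefficient stays interpretable
        kept = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
        X = X[:, kept]
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise AssociationError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * XtX_inv[0, 0]))
    return float(beta[0]), se, dof


def fit_per_metabolite(m: MetaboliteMatrix, cov: pd.DataFrame,
                       out: pd.DataFrame, spec: ModelSpec,
                       metabolites: list[str] | None = None,
                       ) -> dict[str, dict[str, tuple[float, float, int]]]:
    """Within-ancestry OLS for every metabolite.

    Returns ``{metabolite: {ancestry: (beta, se, n)}}`` with beta in outcome
    units per 1 within-stratum SD of the metabolite, complete-case per
    metabolite. Strata too small for the design are omitted (recorded by
    their absence).
    """
    missing_cov = [c for c in spec.covariates if c not in cov.columns]
    if missing_cov:
        raise AssociationError(f"covariate table lacks required columns: {missing_cov}")
    if spec.outcome not in out.columns:
        raise AssociationError(f"outcome table lacks {spec.outcome!r}")
    metabolites = metabolites or m.metabolite_ids

    y_all = out[spec.outcome]
    if spec.outcome == "cord_c_peptide" and spec.cpeptide_scale == "log":
        y_all = np.log(y_all)

    samples = m.values.index.intersection(cov.index).intersection(out.index)
    cov = cov.loc[samples]
    y_all = y_all.loc[samples]
    vals = m.masked().loc[samples]

    results: dict[str, dict[str, tuple[float, float, int]]] = {met: {} for met in metabolites}
    n_aliased = 0
    numeric_cov = [c for c in spec.covariates if c != "field_center"]
    for ancestry, idx in cov.groupby("ancestry").groups.items():
        sub_cov = cov.loc[idx]
        base_ok = sub_cov[numeric_cov].notna().all(axis=1) & y_all.loc[idx].notna()
        sub_cov = sub_cov.loc[base_ok[base_ok].index]
        if sub_cov.empty:
            continue
        Z = _design_matrix(sub_cov, spec.covariates)
        y_s = y_all.loc[sub_cov.index].to_numpy(dtype=float)
        v_s = vals.loc[sub_cov.index, metabolites].to_numpy(dtype=float)
        for k, met in enumerate(metabolites):
            x = v_s[:, k]
            ok = ~np.isnan(x)
            n_ok = int(ok.sum())
            if n_ok <= Z.shape[1] + 1 + MIN_STRATUM_MARGIN:
                continue
            xs = x[ok]
            sd = xs.std(ddof=1)
            if sd == 0:
                continue
            z = (xs - xs.mean()) / sd
            X = np.column_stack([z, Z[ok]])
            # complete-case row subsetting can alias a center indicator with
            # the intercept; collect those warnings and emit one summary
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                beta, se, _ = ols_beta_se(y_s[ok], X)
            n_aliased += sum("aliased" in str(w.message) for w in caught)
            results[met][str(ancestry)] = (beta, se, n_ok)
    if n_aliased:
        warnings.warn(f"{n_aliased} metabolite fits dropped aliased design columns")
    return results


def pool_ancestries(strata: dict[str, tuple[float, float, int]]
                    ) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance pooling across ancestry strata.

    Returns (beta, se, two-sided normal p). With one stratum this is the
    identity.
    """
    if not strata:
        raise AssociationError("no strata to pool")
    betas = np.array([b for b, _, _ in strata.values()])
    ses = np.array([s for _, s, _ in strata.values()])
    if (ses <= 0).any():
        raise AssociationError("non-positive stratum standard error")
    w = 1.0 / ses ** 2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return beta, se, p


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up within one family.

    Order-preserving: adjusted[i] corresponds to pvals[i]. Implements
    p*(m/rank) with a cumulative-minimum monotonicity pass, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise AssociationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def associate(m: MetaboliteMatrix, cov: pd.DataFrame, out: pd.DataFrame,
              spec: ModelSpec, metabolites: list[str] | None = None,
              ) -> list[AssociationResult]:
    """Fit, pool and FDR-adjust one (outcome, model, sample time) family."""
    per_met = fit_per_metabolite(m, cov, out, spec, metabolites=metabolites)
    results = []
    for met, strata in per_met.items():
        if not strata:
            continue
        beta, se, p = pool_ancestries(strata)
        results.append(AssociationResult(
            metabolite=met, model=spec.model, outcome=spec.outcome,
            sample_time=spec.sample_time, strata=strata,
            beta=beta, se=se, ci_lo=beta - 1.96 * se, ci_hi=beta + 1.96 * se,
            p=p))
    fdr = adjust_fdr([r.p for r in results])
    for r, q in zip(results, fdr):
        r.fdr_p = float(q)
    return results


def format_estimate(beta: float, ci_lo: float, ci_hi: float, p: float) -> str:
    """Render "beta (lo-hi, p)" in the journal style, e.g.
    ``44.80 (27.58-62.03, 2.43 x 10^-5)`` with an en dash and typographic
    multiplication sign."""
    if p < 0.01:
        exp = int(np.floor(np.log10(p)))
        mant = p / 10 ** exp
        p_str = f"{mant:.2f} × 10^−{-exp}"
    else:
        p_str = f"{p:.2f}"
    return f"{beta:.2f} ({ci_lo:.2f}–{ci_hi:.2f}, {p_str})"


def association_table(results: list[AssociationResult],
                      fdr_q: float = 0.05) -> pd.DataFrame:
    """Long-format table with Model 1 and Model 2 side by side.

    One row per metabolite x outcome x sample_time; significance boolean is
    ``fdr_p < fdr_q`` per model. Both models must cover the same metabolite
    set within each (outcome, sample_time) family.
    """
    if not results:
        return pd.DataFrame()
    frames = {}
    for r in results:
        frames.setdefault((r.outcome, r.sample_time, r.model), {})[r.metabolite] = r
    rows = []
    for outcome in sorted({r.outcome for r in results}):
        for time in sorted({r.sample_time for r in results if r.outcome == outcome}):
            m1 = frames.get((outcome, time, 1), {})
            m2 = frames.get((outcome, time, 2), {})
            if m1 and m2 and set(m1) != set(m2):
                raise AssociationError(
                    f"Model 1/2 metabolite sets differ for ({outcome}, {time})")
            for met in sorted(set(m1) | set(m2)):
                row = {"outcome": outcome, "sample_time": time, "metabolite": met}
                for model, fam in ((1, m1), (2, m2)):
                    r = fam.get(met)
                    if r is None:
                        continue
                    row.update({
                        f"model{model}_beta": r.beta,
                        f"model{model}_se": r.se,
                        f"model{model}_ci_lo": r.ci_lo,
                        f"model{model}_ci_hi": r.ci_hi,
                        f"model{model}_p": r.p,
                        f"model{model}_fdr_p": r.fdr_p,
                        f"model{model}_n": r.n_total,
                        f"model{model}_significant": bool(r.fdr_p < fdr_q),
                        f"model{model}_formatted": format_estimate(
                            r.beta, r.ci_lo, r.ci_hi, r.p),
                    })
                rows.append(row)
    return pd.DataFrame(rows)
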