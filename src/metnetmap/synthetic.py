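"""Seeded synthetic mother-newborn cohort generator with known truth.

Emulates the statistical structure the downstream analyses assume: maternal
covariates with ancestry nested unevenly within field centers, two
samples-by-metabolites panels (fasting / 1-h) whose noise component follows
a block-structured Gaussian graphical model, pooled-QC batches with additive
batch shifts and linear run-order drift, detection-limit (left-censored)
missingness on the untargeted assay, planted gross outliers, and newborn
outcomes built from known per-SD metabolite coefficients plus covariate
effects. Every draw flows from one integer seed; identical seeds give
bit-identical outputs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .containers import (
    MetaboliteMatrix,
    QCPoolSeries,
    SyntheticTruth,
)

# minimum eigenvalue enforced on the assembled precision matrix
_MIN_EIG = 0.1
# community -> metabolite class, mirroring class-coherent clusters
_COMMUNITY_CLASS_CYCLE = ("AC", "AA", "LIPIDS", "CHO", "FA", "GC/TCA", "OA", "MISC", "PUR/PYR")

_LOGNORMAL_OUTCOMES = ("cord_c_peptide",)


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage substream of the cohort seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


def make_precision_matrix(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble a block-structured precision matrix and its edge support.

    Within each community, pairs are connected independently with
    probability ``edge_density_within`` and given partial correlation
    ``within_partial_corr``; ``n_cross_edges`` extra edges join distinct
    communities. The matrix is made positive definite by diagonal loading
    to a minimum eigenvalue of 0.1 and then rescaled so the implied
    covariance has unit diagonal (partial correlations are invariant to
    this rescaling).

    Raises ``ValueError`` when the requested density/strength combination
    requires so much loading that edge strength collapses below half the
    requested value.
    """
    rng = _rng(cfg.seed, 0)
    p = cfg.n_metabolites
    ids = cfg.metabolite_ids
    rho = cfg.within_partial_corr

    labels = np.repeat(np.arange(len(cfg.community_sizes)), cfg.community_sizes)
    theta = np.eye(p)
    for c in range(len(cfg.community_sizes)):
        members = np.flatnonzero(labels == c)
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                if cfg.edge_density_within >= 1.0 or rng.random() < cfg.edge_density_within:
                    i, j = members[a_i], members[b_i]
                    theta[i, j] = theta[j, i] = -rho

    # cross-community bridges
    cross_pairs: list[tuple[int, int]] = []
    if len(cfg.community_sizes) > 1 and cfg.n_cross_edges > 0:
        candidates = [
            (i, j) for i in range(p) for j in range(i + 1, p)
            if labels[i] != labels[j]
        ]
        take = rng.choice(len(candidates), size=min(cfg.n_cross_edges, len(candidates)),
                          replace=False)
        for k in sorted(take):
            i, j = candidates[k]
            theta[i, j] = theta[j, i] = -rho
            cross_pairs.append((i, j))

    eigmin = float(np.linalg.eigvalsh(theta).min())
    load = max(0.0, _MIN_EIG - eigmin)
    theta[np.diag_indices(p)] += load
    realized = rho / (1.0 + load)
    if realized < 0.5 * rho:
        raise ValueError(
            "infeasible density/strength combination: minimum eigenvalue "
            f"{eigmin:.3f} < {_MIN_EIG} requires diagonal loading {load:.3f}, "
            f"collapsing partial correlations from {rho} to {realized:.3f}")

    # rescale so the implied covariance has unit diagonal
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    theta = theta * d[:, None] * d[None, :]

    support = (theta != 0.0) & ~np.eye(p, dtype=bool)
    return (
        pd.DataFrame(theta, index=ids, columns=ids),
        pd.DataFrame(support, index=ids, columns=ids),
    )


def default_transforms(class_of: pd.Series, assay_of: pd.Series,
                       extra_ln: tuple[str, ...] = ()) -> pd.Series:
    """Per-metabolite analysis transform: GC-MS peak areas on log2,
    acylcarnitines (and any explicitly listed metabolite, e.g. a
    3-hydroxybutyrate panel member) on natural log, all else untransformed."""
    out = pd.Series("none", index=class_of.index, dtype=object)
    out[assay_of == "gcms"] = "log2"
    out[class_of == "AC"] = "ln"
    for m in extra_ln:
        out[m] = "ln"
    return out


def _community_labels(cfg: CohortConfig) -> pd.Series:
    labels = np.repeat(np.arange(len(cfg.community_sizes)), cfg.community_sizes)
    return pd.Series(labels, index=cfg.metabolite_ids, name="community")


def _annotations(cfg: CohortConfig) -> tuple[pd.Series, pd.Series]:
    """Class per community (AC / AA / LIPIDS / CHO / ...) and assay per class:
    amino acids and acylcarnitines on the targeted panel, a small set of
    lipid-class conventional assays, everything else GC-MS."""
    comm = _community_labels(cfg)
    classes = pd.Series(
        [_COMMUNITY_CLASS_CYCLE[c % len(_COMMUNITY_CLASS_CYCLE)] for c in comm],
        index=comm.index, dtype=object)
    assays = pd.Series("gcms", index=comm.index, dtype=object)
    assays[classes.isin(["AC", "AA"])] = "targeted"
    lipid_ids = classes.index[classes == "LIPIDS"]
    assays[lipid_ids[:5]] = "conventional"
    return classes, assays


def _draw_covariates(cfg: CohortConfig) -> pd.DataFrame:
    rng = _rng(cfg.seed, 1)
    n = cfg.n_samples
    levels = list(cfg.ancestry_levels)

    center_idx = rng.integers(0, cfg.n_centers, size=n)
    centers = np.array([f"C{c + 1:02d}" for c in center_idx])

    # ancestry nested in centers: each center is dominated by one ancestry
    # (field centers are ancestrally skewed), mimicking confounding between
    # center and ancestry that the stratified regressions must absorb.
    k = len(levels)
    probs = np.full((cfg.n_centers, k), 0.4 / max(k - 1, 1))
    for c in range(cfg.n_centers):
        probs[c, c % k] = 0.6
    ancestry = np.array([
        levels[rng.choice(k, p=probs[c])] for c in center_idx
    ])

    # genetic PCs track ancestry
    pc_means = {lab: 2.0 * np.array([
        np.cos(2 * np.pi * i / k), np.sin(2 * np.pi * i / k), (i - k / 2) / k,
    ]) for i, lab in enumerate(levels)}
    pcs = np.vstack([pc_means[a] for a in ancestry]) + rng.normal(size=(n, 3))

    mom = cfg.covariate_moments
    z_bmi = rng.normal(size=n)
    z_map = 0.3 * z_bmi + np.sqrt(1 - 0.09) * rng.normal(size=n)
    z_fg = 0.3 * z_bmi + np.sqrt(1 - 0.09) * rng.normal(size=n)
    z_1h = 0.5 * z_fg + np.sqrt(1 - 0.25) * rng.normal(size=n)

    def nat(name: str, z: np.ndarray) -> np.ndarray:
        mu, sd = mom[name]
        return mu + sd * z

    df = pd.DataFrame({
        "field_center": centers,
        "ancestry": ancestry,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2],
        "age": nat("age", rng.normal(size=n)),
        "height": nat("height", rng.normal(size=n)),
        "bmi": nat("bmi", z_bmi),
        "map": nat("map", z_map),
        "fasting_glucose": nat("fasting_glucose", z_fg),
        "one_hour_glucose": nat("one_hour_glucose", z_1h),
        "gestational_age": nat("gestational_age", rng.normal(size=n)),
        "storage_time": nat("storage_time", rng.normal(size=n)),
        "smoking": (rng.random(n) < cfg.binary_rates["smoking"]).astype(int),
        "alcohol": (rng.random(n) < cfg.binary_rates["alcohol"]).astype(int),
        "parity": (rng.random(n) < cfg.binary_rates["parity"]).astype(int),
        "newborn_sex": (rng.random(n) < cfg.binary_rates["newborn_sex"]).astype(int),
    }, index=[f"S{i + 1:05d}" for i in range(n)])
    df.index.name = "sample_id"
    # glucose is a concentration; clip far-left tails to a positive floor
    for col in ("fasting_glucose", "one_hour_glucose"):
        df[col] = df[col].clip(lower=0.5)
    return df


def _batch_layout(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray, dict[int, list[tuple[int, str]]]]:
    """Assign samples to batches (contiguous chunks) and run positions.

    Within a batch of B experimental injections the pooled QC occupies the
    first, middle, and last injection slots; experimental samples fill the
    remainder in order. Returns (batch_of, run_order_of, qc_slots) where
    qc_slots maps batch -> [(position, role), ...].
    """
    n, nb = cfg.n_samples, cfg.n_batches
    sizes = [n // nb + (1 if i < n % nb else 0) for i in range(nb)]
    batch_of = np.repeat(np.arange(nb), sizes)
    run_pos = np.empty(n, dtype=int)
    qc_slots: dict[int, list[tuple[int, str]]] = {}
    start = 0
    for b, B in enumerate(sizes):
        total = B + 3
        mid = total // 2
        qc_slots[b] = [(0, "first"), (mid, "middle"), (total - 1, "last")]
        exp_positions = [p for p in range(total) if p not in (0, mid, total - 1)]
        run_pos[start:start + B] = exp_positions[:B]
        start += B
    return batch_of, run_pos, qc_slots


def _apply_raw_scale(analysis: pd.DataFrame, transforms: pd.Series) -> pd.DataFrame:
    raw = analysis.copy()
    for m in analysis.columns:
        t = transforms[m]
        if t == "log2":
            raw[m] = np.exp2(analysis[m])
        elif t == "ln":
            raw[m] = np.exp(analysis[m])
    return raw


def generate_cohort(cfg: CohortConfig):
    """Generate one cohort.

    Returns ``(covariates, fasting, one_hour, qc, outcomes, truth)`` where
    the two :class:`MetaboliteMatrix` objects are on the raw instrument
    scale (GC-MS peak areas, acylcarnitine concentrations), ``qc`` carries
    pooled-QC injections for both sample times, and ``truth`` records the
    generating precision matrix, support, community labels, outcome
    coefficients, batch shifts, censor limits and planted outliers.
    """
    theta_df, support_df = make_precision_matrix(cfg)
    comm = _community_labels(cfg)
    classes, assays = _annotations(cfg)
    transforms = default_transforms(classes, assays)
    cov = _draw_covariates(cfg)
    ids = cfg.metabolite_ids
    n, p = cfg.n_samples, cfg.n_metabolites

    sigma = np.linalg.inv(theta_df.to_numpy())
    chol = np.linalg.cholesky(sigma)

    rng_noise = _rng(cfg.seed, 2)
    eps_f = rng_noise.normal(size=(n, p)) @ chol.T
    fresh = rng_noise.normal(size=(n, p)) @ chol.T
    sc = cfg.state_correlation
    eps_h = sc * eps_f + np.sqrt(1.0 - sc ** 2) * fresh

    # covariate loadings shift the latent analysis-scale signal
    load = np.zeros((n, p))
    for m, terms in cfg.covariate_loadings.items():
        if m not in ids:
            continue
        j = ids.index(m)
        for c, a in terms.items():
            mu_c, sd_c = cfg.covariate_moments[c]
            load[:, j] += a * (cov[c].to_numpy() - mu_c) / sd_c

    # per-metabolite location/scale on the analysis (log) scale
    rng_scale = _rng(cfg.seed, 3)
    mu_m = np.where(transforms.to_numpy() == "log2",
                    rng_scale.uniform(12.0, 18.0, size=p),
                    np.where(transforms.to_numpy() == "ln",
                             rng_scale.uniform(-3.0, 0.0, size=p),
                             rng_scale.uniform(0.8, 2.5, size=p)))
    s_m = rng_scale.uniform(0.5, 1.0, size=p)

    latent_f = mu_m + s_m * (load + eps_f)
    latent_h = mu_m + s_m * (load + eps_h)

    # batch structure: shifts and run-order drift per sample time
    batch_of, run_pos, qc_slots = _batch_layout(cfg)
    rng_batch = _rng(cfg.seed, 4)
    shifts = {
        t: rng_batch.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_batches, p))
        for t in ("fasting", "one_hour")
    }
    drift = cfg.run_order_drift

    def measured(latent: np.ndarray, time: str) -> np.ndarray:
        return latent + shifts[time][batch_of] + drift * run_pos[:, None]

    meas = {"fasting": measured(latent_f, "fasting"),
            "one_hour": measured(latent_h, "one_hour")}

    # detection-limit left-censoring: GC-MS metabolites only, half of them
    # fully detected, the rest censored at a fixed quantile up to
    # cfg.censor_fraction
    rng_cens = _rng(cfg.seed, 5)
    frac = np.maximum(0.0, rng_cens.uniform(-cfg.censor_fraction, cfg.censor_fraction, size=p))
    frac[transforms.to_numpy() != "log2"] = 0.0
    limits = np.full(p, np.nan)
    missing = {t: np.zeros((n, p), dtype=bool) for t in meas}
    for j in range(p):
        if frac[j] <= 0:
            continue
        limits[j] = float(np.quantile(meas["fasting"][:, j], frac[j]))
        for t in meas:
            missing[t][:, j] = meas[t][:, j] < limits[j]

    # planted gross outliers (added after generation, on the analysis scale)
    sample_ids = list(cov.index)
    planted = []
    for s_idx, m_id, z_off in cfg.outlier_plants:
        j = ids.index(m_id)
        sd_obs = float(meas["fasting"][:, j].std(ddof=1))
        meas["fasting"][s_idx, j] += z_off * sd_obs
        planted.append((sample_ids[s_idx], m_id, float(z_off)))

    # pooled-QC injections: pool mean + batch shift + drift + injection noise
    rng_qc = _rng(cfg.seed, 6)
    qc_rows, qc_vals = [], []
    for t in ("fasting", "one_hour"):
        for b in range(cfg.n_batches):
            for pos, role in qc_slots[b]:
                qc_rows.append({"sample_time": t, "batch": b, "position": pos, "role": role})
                qc_vals.append(mu_m + shifts[t][b] + drift * pos
                               + rng_qc.normal(0.0, cfg.qc_noise_sd, size=p))
    qc_records = pd.DataFrame(qc_rows)
    # QC intensities leave the instrument on the same raw scale as samples
    qc_values = _apply_raw_scale(pd.DataFrame(qc_vals, columns=ids), transforms)
    qc = QCPoolSeries(records=qc_records, values=qc_values,
                      missing=pd.DataFrame(False, index=qc_values.index, columns=ids))

    # newborn outcomes from standardized fasting latents + covariate effects
    rng_out = _rng(cfg.seed, 7)
    z_lat = (latent_f - latent_f.mean(axis=0)) / latent_f.std(axis=0, ddof=1)
    outcome_cols = {}
    r2 = {}
    for outcome, (target_mu, target_sd) in cfg.outcome_moments.items():
        signal = np.zeros(n)
        for (m, o), coef in cfg.outcome_effects.items():
            if o == outcome and m in ids:
                signal += coef * z_lat[:, ids.index(m)]
        for c, eff in cfg.outcome_covariate_effects.get(outcome, {}).items():
            if c in cfg.covariate_moments:
                mu_c, sd_c = cfg.covariate_moments[c]
                signal += eff * (cov[c].to_numpy() - mu_c) / sd_c
            else:  # binary covariate: effect per unit, centered at prevalence
                signal += eff * (cov[c].to_numpy() - cfg.binary_rates[c])
        if outcome in _LOGNORMAL_OUTCOMES:
            # match (mean, sd) on the natural scale via log-normal moments
            log_sd2 = np.log1p((target_sd / target_mu) ** 2)
            log_mu = np.log(target_mu) - log_sd2 / 2.0
            scale_sd2 = log_sd2
        else:
            log_mu, scale_sd2 = target_mu, target_sd ** 2
        var_sig = float(signal.var(ddof=1))
        if var_sig >= scale_sd2:
            raise ValueError(
                f"outcome {outcome!r}: planted signal variance {var_sig:.3g} exceeds "
                f"the configured total variance {scale_sd2:.3g}")
        noise_sd = float(np.sqrt(scale_sd2 - var_sig))
        y = log_mu + signal + rng_out.normal(0.0, noise_sd, size=n)
        if outcome in _LOGNORMAL_OUTCOMES:
            y = np.exp(y)
        outcome_cols[outcome] = y
        r2[outcome] = var_sig / scale_sd2
    outcomes = pd.DataFrame(outcome_cols, index=cov.index)
    outcomes.index.name = "sample_id"

    def build_matrix(time: str) -> MetaboliteMatrix:
        analysis = pd.DataFrame(meas[time], index=cov.index, columns=ids)
        return MetaboliteMatrix(
            values=_apply_raw_scale(analysis, transforms),
            missing=pd.DataFrame(missing[time], index=cov.index, columns=ids),
            sample_time=time,
            class_of=classes.copy(),
            assay_of=assays.copy(),
            batch_of=pd.Series(batch_of, index=cov.index, name="batch"),
            run_order_of=pd.Series(run_pos, index=cov.index, name="run_order"),
        )

    shift_frames = [
        pd.DataFrame(shifts[t], columns=ids,
                     index=pd.MultiIndex.from_product([[t], range(cfg.n_batches)],
                                                      names=["sample_time", "batch"]))
        for t in ("fasting", "one_hour")
    ]
    truth = SyntheticTruth(
        true_precision=theta_df,
        true_support=support_df,
        true_communities=comm,
        true_outcome_coefs=dict(cfg.outcome_effects),
        batch_shifts=pd.concat(shift_frames),
        censor_limits=pd.Series(limits, index=ids, name="censor_limit"),
        planted_outliers=tuple(planted),
        outcome_r2=r2,
    )
    return cov, build_matrix("fasting"), build_matrix("one_hour"), qc, outcomes, truth
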