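"""Data conditioning for the metabolite panels.

Order of operations mirrors the analysis plan: per-metabolite analysis
transforms (log2 for GC-MS peak areas, natural log for acylcarnitines and
3-hydroxybutyrate), pooled-QC batch/run-order normalization, the >=5-SD
outlier rule with per-sample exclusion at >10 outlying metabolites, and
strict missingness filters (<10% for association, <1% for networks).
Missing values are never imputed here; complete-case handling is the
downstream modules' job.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .containers import MetaboliteMatrix, QCPoolSeries
from .synthetic import default_transforms


class PreprocessError(ValueError):
    pass


def transform_metabolites(m: MetaboliteMatrix,
                          extra_ln: tuple[str, ...] = ()) -> MetaboliteMatrix:
    """Put raw-scale values on the analysis scale.

    GC-MS metabolites -> log2(peak area); acylcarnitine-class metabolites
    and any metabolite listed in ``extra_ln`` (e.g. 3-hydroxybutyrate) ->
    natural log; everything else unchanged. The transform applied to each
    metabolite is recorded on the returned matrix. Non-positive values
    under a log transform are an error naming the offending cells.
    """
    transforms = default_transforms(m.class_of, m.assay_of, extra_ln=extra_ln)
    values = m.values.copy()
    bad: list[tuple[str, str]] = []
    for met in m.metabolite_ids:
        t = transforms[met]
        if t == "none":
            continue
        col = values[met]
        obs = ~m.missing[met]
        nonpos = obs & (col <= 0)
        if nonpos.any():
            bad.extend((s, met) for s in values.index[nonpos])
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            values[met] = np.log2(col) if t == "log2" else np.log(col)
    if bad:
        head = ", ".join(f"({s}, {met})" for s, met in bad[:10])
        raise PreprocessError(
            f"non-positive values under a log transform in {len(bad)} cells: {head}")
    return dataclasses.replace(m, values=values, transform_of=transforms)


def apply_recorded_transform(values: pd.DataFrame, transforms: pd.Series) -> pd.DataFrame:
    """Apply an already-decided per-metabolite transform to another table
    on the same metabolite set (used for the QC pool intensities)."""
    out = values.copy()
    for met in values.columns:
        t = transforms.get(met, "none")
        if t == "log2":
            out[met] = np.log2(out[met])
        elif t == "ln":
            out[met] = np.log(out[met])
    return out


def _fit_qc_model(y: np.ndarray, obs: np.ndarray, batch_idx: np.ndarray,
                  position: np.ndarray, n_batches: int):
    """Factorized ML fit of the two-part QC model for one metabolite.

    Detection indicator ~ Bernoulli(logit^-1(gamma_0 + gamma_batch)) and
    observed intensity ~ Normal(mu + b_batch + r*position, sigma^2) with a
    sum-to-zero constraint on {b_batch}. The two likelihoods factorize, so
    the Bernoulli part reduces to per-batch detection rates and the Normal
    part to least squares on batch indicators plus the run position.

    Returns (b_batch, r, sigma_hat, detect_rate).
    """
    detect_rate = np.array([
        obs[batch_idx == b].mean() if (batch_idx == b).any() else np.nan
        for b in range(n_batches)
    ])
    yo, bo, po = y[obs], batch_idx[obs], position[obs]
    # design: intercept + sum-to-zero batch contrasts + position
    X = np.zeros((len(yo), 1 + (n_batches - 1) + 1))
    X[:, 0] = 1.0
    for b in range(n_batches - 1):
        X[:, 1 + b] = (bo == b).astype(float) - (bo == n_batches - 1).astype(float)
    X[:, -1] = po
    coef, _, rank, _ = np.linalg.lstsq(X, yo, rcond=None)
    if rank < X.shape[1]:
        # drift not identifiable (e.g. single position per batch): refit
        # without the position term
        coef2, *_ = np.linalg.lstsq(X[:, :-1], yo, rcond=None)
        coef = np.concatenate([coef2, [0.0]])
    b_free = coef[1:n_batches]
    b_batch = np.concatenate([b_free, [-b_free.sum()]])
    r = float(coef[-1])
    resid = yo - X @ coef
    dof = max(len(yo) - X.shape[1], 1)
    sigma = float(np.sqrt((resid ** 2).sum() / dof))
    return b_batch, r, sigma, detect_rate


def qc_normalize(m: MetaboliteMatrix, qc: QCPoolSeries) -> MetaboliteMatrix:
    """Remove batch shifts and run-order drift estimated from pooled QCs.

    For each metabolite a two-part Bernoulli-Normal model is fit on the QC
    injections of this sample time; the fitted ``b_batch + r*position`` is
    subtracted from every experimental sample according to its own batch
    and run position. Metabolites whose QC record is entirely missing in
    some batch are returned unnormalized and flagged. A QC series missing
    an entire batch present in the data is an error.
    """
    if m.transform_of is None:
        raise PreprocessError("qc_normalize expects a transformed matrix "
                              "(run transform_metabolites first)")
    rec = qc.records
    keep = np.ones(len(rec), dtype=bool)
    if "sample_time" in rec.columns:
        keep = (rec["sample_time"] == m.sample_time).to_numpy()
    rec = rec.loc[keep]
    qvals = apply_recorded_transform(qc.values.loc[keep], m.transform_of)
    qmiss = qc.missing.loc[keep]

    data_batches = sorted(pd.unique(m.batch_of))
    qc_batches = set(rec["batch"].tolist())
    absent = [b for b in data_batches if b not in qc_batches]
    if absent:
        raise PreprocessError(f"QC series missing batches present in data: {absent}")

    batch_code = {b: i for i, b in enumerate(data_batches)}
    qb = rec["batch"].map(batch_code).to_numpy()
    qpos = rec["position"].to_numpy(dtype=float)
    sample_b = m.batch_of.map(batch_code).to_numpy()
    sample_pos = m.run_order_of.to_numpy(dtype=float)
    nb = len(data_batches)

    values = m.values.copy()
    flagged: list[str] = []
    audit: dict[str, dict] = {}
    for met in m.metabolite_ids:
        y = qvals[met].to_numpy(dtype=float)
        obs = ~qmiss[met].to_numpy(dtype=bool)
        per_batch_obs = np.array([(obs & (qb == bi)).sum() for bi in range(nb)])
        if (per_batch_obs == 0).any():
            flagged.append(met)
            audit[met] = {"normalized": False}
            continue
        b_batch, r, sigma, detect = _fit_qc_model(y, obs, qb, qpos, nb)
        if sigma == 0.0:
            warnings.warn(f"constant QC intensities for {met}; "
                          "normalizing by batch-mean offsets only")
            r = 0.0
        values[met] = values[met] - b_batch[sample_b] - r * sample_pos
        audit[met] = {
            "normalized": True,
            "b_batch": {str(b): float(b_batch[batch_code[b]]) for b in data_batches},
            "drift": r, "sigma": sigma,
            "detect_rate": {str(b): float(detect[batch_code[b]]) for b in data_batches},
        }
    return dataclasses.replace(m, values=values, normalized=True,
                               unnormalized_flags=tuple(flagged),
                               qc_audit=audit)


def flag_outliers(m: MetaboliteMatrix, sd_threshold: float = 5.0) -> pd.DataFrame:
    """Flag cells >= sd_threshold SDs from the per-metabolite mean.

    Mean and SD are computed once over non-missing cells (single pass, not
    iteratively re-estimated); the boundary is inclusive; constant
    metabolites (SD = 0) produce no flags.
    """
    vals = m.masked()
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        dev = (vals - mu).abs()
        flags = dev.ge(sd_threshold * sd) & (sd > 0)
    return flags.fillna(False) & ~m.missing


def apply_exclusions(m: MetaboliteMatrix, flags: pd.DataFrame,
                     max_outliers_per_sample: int = 10):
    """Blank flagged cells; drop samples with strictly more than
    ``max_outliers_per_sample`` flags in this sample time.

    Returns ``(matrix, report)`` where report lists every sample's flag
    count and whether it was excluded.
    """
    if not flags.shape == m.values.shape:
        raise PreprocessError("flags not conformable with matrix")
    counts = flags.sum(axis=1)
    excluded = counts > max_outliers_per_sample
    report = pd.DataFrame({
        "n_outliers": counts.astype(int),
        "excluded": excluded,
    })
    report.index.name = "sample_id"
    missing = m.missing | flags
    out = dataclasses.replace(m, missing=missing)
    keep = [s for s in m.sample_ids if not excluded[s]]
    return out.subset_samples(keep), report


def filter_missingness(m: MetaboliteMatrix, max_missing_frac: float) -> MetaboliteMatrix:
    """Keep metabolites with missing fraction strictly below the threshold."""
    if not (0.0 < max_missing_frac <= 1.0):
        raise PreprocessError("max_missing_frac must lie in (0, 1]")
    frac = m.missing_fraction()
    keep = [met for met in m.metabolite_ids if frac[met] < max_missing_frac]
    if not keep:
        raise PreprocessError(
            f"no metabolite has missingness below {max_missing_frac:.2%}; "
            "raise the threshold")
    return m.subset_metabolites(keep)


def preprocess_matrix(m: MetaboliteMatrix, qc: QCPoolSeries,
                      sd_threshold: float = 5.0,
                      max_outliers_per_sample: int = 10,
                      extra_ln: tuple[str, ...] = ()):
    """Full conditioning chain: transform -> QC-normalize -> outlier rule.

    Returns ``(matrix, exclusion_report)``.
    """
    t = transform_metabolites(m, extra_ln=extra_ln)
    n = qc_normalize(t, qc)
    flags = flag_outliers(n, sd_threshold=sd_threshold)
    return apply_exclusions(n, flags, max_outliers_per_sample=max_outliers_per_sample)
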