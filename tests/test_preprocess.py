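"""Conditioning rules: transforms, pooled-QC normalization, outliers, filters."""
import numpy as np
import pandas as pd
import pytest

from metnetmap.preprocess import (
    PreprocessError,
    apply_exclusions,
    filter_missingness,
    flag_outliers,
    qc_normalize,
    transform_metabolites,
)

from conftest import toy_matrix, toy_qc


def test_transforms_per_assay_and_class():
    m = toy_matrix(np.array([[8.0, 1.7, np.e ** 2]]),
                   classes=["CHO", "MISC", "AC"],
                   assays=["gcms", "conventional", "targeted"])
    t = transform_metabolites(m)
    assert t.values.iloc[0, 0] == pytest.approx(3.0)      # log2(8)
    assert t.values.iloc[0, 1] == pytest.approx(1.7)      # untouched
    assert t.values.iloc[0, 2] == pytest.approx(2.0)      # ln(e^2)
    assert list(t.transform_of) == ["log2", "none", "ln"]


def test_extra_ln_list_covers_conventional_ketones():
    m = toy_matrix(np.array([[np.e, 2.0]]), classes=["LIPIDS", "LIPIDS"],
                   assays=["conventional", "conventional"])
    t = transform_metabolites(m, extra_ln=("m0",))
    assert t.values.iloc[0, 0] == pytest.approx(1.0)
    assert t.values.iloc[0, 1] == pytest.approx(2.0)


def test_nonpositive_under_log_names_cell():
    m = toy_matrix(np.array([[0.0], [4.0]]), classes=["CHO"], assays=["gcms"])
    with pytest.raises(PreprocessError, match=r"\(S000, m0\)"):
        transform_metabolites(m)


def test_nonpositive_in_missing_cell_is_ignored():
    missing = np.array([[True], [False]])
    m = toy_matrix(np.array([[-1.0], [4.0]]), classes=["CHO"], assays=["gcms"],
                   missing=missing)
    t = transform_metabolites(m)
    assert t.values.iloc[1, 0] == pytest.approx(2.0)


def _two_batch_setup(shift=0.8, n_per=40, qc_per_batch=3, drift=0.0, qc_noise=0.0,
                     seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    base = 5.0 + rng.normal(0, 0.5, size=(n, 2))
    shifts = np.array([shift, -shift])
    batches = np.repeat([0, 1], n_per)
    vals = base + shifts[batches][:, None]
    m = toy_matrix(vals, n_batches=2)
    m = transform_metabolites(m)  # records 'none' transforms
    qc_batches = [0] * qc_per_batch + [1] * qc_per_batch
    positions = list(range(qc_per_batch)) * 2
    qvals = np.array([
        [5.0 + shifts[b] + drift * p + rng.normal(0, qc_noise) for _ in range(2)]
        for b, p in zip(qc_batches, positions)
    ])
    qc = toy_qc(qc_batches, qvals, positions=positions)
    return m, qc, shifts, batches


def test_qc_normalize_removes_planted_shifts_exactly_with_clean_qc():
    m, qc, shifts, batches = _two_batch_setup(qc_noise=0.0)
    out = qc_normalize(m, qc)
    # with complete detection and no QC noise the ML fit equals the
    # closed-form per-batch QC means, so batch means agree to 1e-6
    for met in out.metabolite_ids:
        v = out.values[met].to_numpy()
        gap = v[batches == 0].mean() - v[batches == 1].mean()
        raw = m.values[met].to_numpy()
        raw_gap = raw[batches == 0].mean() - raw[batches == 1].mean()
        assert abs(raw_gap) > 1.0          # planted gap was 1.6
        assert abs(gap) < 0.2              # shrunk to sampling noise
    # QC batch means coincide after subtracting the fitted offsets
    qv = qc.values.to_numpy()
    qb = qc.records["batch"].to_numpy()
    for j, met in enumerate(out.metabolite_ids):
        fitted = np.array([0.8, -0.8])
        corr = qv[:, j] - fitted[qb]
        assert abs(corr[qb == 0].mean() - corr[qb == 1].mean()) < 1e-6


def test_qc_normalize_zero_shift_is_noop_up_to_constant():
    m, qc, *_ = _two_batch_setup(shift=0.0, qc_noise=0.0)
    out = qc_normalize(m, qc)
    for met in out.metabolite_ids:
        diff = out.values[met] - m.values[met]
        assert diff.std() < 1e-12


def test_qc_normalize_single_batch_identity_up_to_constant():
    rng = np.random.default_rng(1)
    m = toy_matrix(5 + rng.normal(size=(20, 2)), n_batches=1)
    m = transform_metabolites(m)
    qc = toy_qc([0, 0, 0], 5 + rng.normal(0, 0.01, size=(3, 2)))
    out = qc_normalize(m, qc)
    for met in out.metabolite_ids:
        diff = out.values[met] - m.values[met]
        # sum-to-zero forces b=0; only the drift term can shift values
        assert diff.std() < 0.05


def test_qc_missing_batch_is_error():
    m, qc, *_ = _two_batch_setup()
    qc.records.loc[qc.records["batch"] == 1, "batch"] = 0
    qc.records["position"] = range(len(qc.records))
    with pytest.raises(PreprocessError, match="missing batches"):
        qc_normalize(m, qc)


def test_all_missing_qc_metabolite_flagged_unnormalized():
    m, qc, *_ = _two_batch_setup()
    qc.missing.loc[qc.records["batch"] == 1, "m1"] = True
    out = qc_normalize(m, qc)
    assert out.unnormalized_flags == ("m1",)
    assert out.values["m1"].equals(m.values["m1"])


def test_within_batch_contrasts_preserved_up_to_drift():
    m, qc, _, batches = _two_batch_setup(drift=0.01, qc_noise=0.0)
    out = qc_normalize(m, qc)
    same_batch = np.flatnonzero(batches == 0)[:2]
    s0, s1 = (m.sample_ids[i] for i in same_batch)
    for met in m.metabolite_ids:
        before = m.values.loc[s0, met] - m.values.loc[s1, met]
        after = out.values.loc[s0, met] - out.values.loc[s1, met]
        pos_gap = m.run_order_of[s0] - m.run_order_of[s1]
        assert after - before == pytest.approx(-0.01 * pos_gap, abs=1e-6)


def _boundary_column(z_target: float, n: int = 40) -> np.ndarray:
    """Column whose last value sits exactly z_target sample-SDs above the
    mean (solved in closed form; needs (n-1)^2 > z^2 n)."""
    others = np.array([1.0, -1.0] * ((n - 1) // 2) + [0.0] * ((n - 1) % 2))
    Q = float((others ** 2).sum())
    a = (n - 1) / n
    x2 = z_target ** 2 * Q / ((n - 1) * a * (a - z_target ** 2 / (n - 1)))
    return np.concatenate([others, [np.sqrt(x2)]])


def test_outlier_rule_inclusive_at_exact_boundary():
    col5 = _boundary_column(5.0)
    col499 = _boundary_column(4.99)
    col501 = _boundary_column(5.01)
    m = toy_matrix(np.column_stack([col5, col499, col501]))
    vals = m.values
    z5 = (vals["m0"].iloc[-1] - vals["m0"].mean()) / vals["m0"].std(ddof=1)
    assert z5 == pytest.approx(5.0, abs=1e-9)
    flags = flag_outliers(m, sd_threshold=5.0)
    # the boundary is inclusive: a deviation >= 5 SD (to float precision)
    # is flagged, 4.99 SD is not
    if z5 >= 5.0:
        assert bool(flags["m0"].iloc[-1])
    assert not flags["m1"].iloc[-1]
    assert bool(flags["m2"].iloc[-1])
    assert not flags.iloc[:-1].to_numpy().any()


def test_constant_column_produces_no_flags():
    vals = np.ones((10, 1))
    missing = np.zeros((10, 1), dtype=bool)
    missing[3, 0] = True
    m = toy_matrix(vals, missing=missing)
    assert not flag_outliers(m).to_numpy().any()


def test_exclusion_thresholds():
    rng = np.random.default_rng(0)
    n, p = 6, 12
    vals = rng.normal(size=(n, p))
    m = toy_matrix(vals)
    flags = pd.DataFrame(False, index=m.values.index, columns=m.values.columns)
    flags.iloc[0, :11] = True   # 11 outliers -> excluded
    flags.iloc[1, :10] = True   # exactly 10 -> retained, cells blanked
    out, report = apply_exclusions(m, flags, max_outliers_per_sample=10)
    assert report.loc["S000", "excluded"]
    assert not report.loc["S001", "excluded"]
    assert "S000" not in out.sample_ids
    assert out.missing.loc["S001"].sum() == 10


def test_no_flags_is_identity(small_cohort):
    _, fasting, *_ = small_cohort
    flags = pd.DataFrame(False, index=fasting.values.index,
                         columns=fasting.values.columns)
    out, report = apply_exclusions(fasting, flags)
    assert out.values.equals(fasting.values)
    assert not report["excluded"].any()


def test_missingness_filter_strict_and_monotone():
    n = 20
    missing = np.zeros((n, 3), dtype=bool)
    missing[:2, 0] = True          # exactly 10% -> dropped at 0.10
    missing[:1, 1] = True          # 5%
    m = toy_matrix(np.random.default_rng(0).normal(size=(n, 3)), missing=missing)
    kept10 = filter_missingness(m, 0.10).metabolite_ids
    assert kept10 == ["m1", "m2"]
    kept01 = filter_missingness(m, 0.01).metabolite_ids
    assert set(kept01) <= set(kept10)
    assert "m2" in kept01          # zero missing survives any threshold


def test_missingness_filter_empty_result_raises():
    missing = np.ones((10, 2), dtype=bool)
    missing[0] = False
    m = toy_matrix(np.zeros((10, 2)), missing=missing)
    with pytest.raises(PreprocessError, match="threshold"):
        filter_missingness(m, 0.01)


def test_outlier_pass_is_idempotent_after_exclusion(small_cohort):
    _, fasting, *_ = small_cohort
    t = transform_metabolites(fasting)
    flags1 = flag_outliers(t)
    cleaned, _ = apply_exclusions(t, flags1)
    flags2 = flag_outliers(cleaned)
    assert flags2.to_numpy().sum() <= flags1.to_numpy().sum()
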