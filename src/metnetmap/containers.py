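"""In-memory containers shared across pipeline stages.

Tables are pandas objects keyed by string sample ids; the metabolite panel
for one OGTT sample time travels as a :class:`MetaboliteMatrix` carrying
the value matrix, a missingness mask, per-metabolite class/assay/transform
annotations, and per-sample batch / run-order records.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

METABOLITE_CLASSES: tuple[str, ...] = (
    "AA", "AC", "CHO", "FA", "GC/TCA", "LIPIDS", "MISC", "OA", "PUR/PYR",
)
ASSAYS: tuple[str, ...] = ("conventional", "targeted", "gcms")
QC_ROLES: tuple[str, ...] = ("first", "middle", "last", "extra")


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites panel for one sample time.

    ``values`` holds numbers on whatever scale the stage produced (raw
    instrument scale out of the generator, analysis scale after
    :func:`metnetmap.preprocess.transform_metabolites`); cells where
    ``missing`` is True are ignored by every downstream statistic.
    """

    values: pd.DataFrame            # index: sample ids, columns: metabolite ids
    missing: pd.DataFrame           # boolean, same shape
    sample_time: str                # "fasting" | "one_hour"
    class_of: pd.Series             # metabolite -> class label
    assay_of: pd.Series             # metabolite -> assay
    batch_of: pd.Series             # sample -> batch id (int)
    run_order_of: pd.Series         # sample -> run position within batch
    transform_of: pd.Series | None = None   # metabolite -> {none, log2, ln}
    normalized: bool = False
    #: metabolites returned unnormalized because QC was entirely missing
    #: in some batch
    unnormalized_flags: tuple[str, ...] = ()
    #: per-metabolite fitted batch offsets / drift from qc_normalize
    qc_audit: dict | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask are not conformable")
        if not self.values.index.equals(self.missing.index):
            raise ValueError("values/missing sample ids differ")
        if not self.values.columns.equals(self.missing.columns):
            raise ValueError("values/missing metabolite ids differ")
        for ann in (self.class_of, self.assay_of):
            missing_ann = set(self.values.columns) - set(ann.index)
            if missing_ann:
                raise ValueError(f"annotation missing for metabolites: {sorted(missing_ann)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    def masked(self) -> pd.DataFrame:
        """Values with missing cells as NaN."""
        return self.values.mask(self.missing)

    def missing_fraction(self) -> pd.Series:
        return self.missing.mean(axis=0)

    def subset_metabolites(self, keep: list[str]) -> "MetaboliteMatrix":
        return replace(
            self,
            values=self.values[keep],
            missing=self.missing[keep],
            class_of=self.class_of.loc[keep],
            assay_of=self.assay_of.loc[keep],
            transform_of=None if self.transform_of is None else self.transform_of.loc[keep],
        )

    def subset_samples(self, keep: list[str]) -> "MetaboliteMatrix":
        return replace(
            self,
            values=self.values.loc[keep],
            missing=self.missing.loc[keep],
            batch_of=self.batch_of.loc[keep],
            run_order_of=self.run_order_of.loc[keep],
        )


@dataclass
class QCPoolSeries:
    """Pooled-QC injection records for one sample time.

    One row per injection: batch id, run position (unique within batch),
    a role label (first/middle/last per daily run, 'extra' for additional
    injections), per-metabolite intensities and missing flags.
    """

    records: pd.DataFrame           # columns: batch, position, role
    values: pd.DataFrame            # per-metabolite intensities, rows align with records
    missing: pd.DataFrame           # boolean, same shape as values

    def __post_init__(self) -> None:
        for col in ("batch", "position", "role"):
            if col not in self.records.columns:
                raise ValueError(f"QC records lack column {col!r}")
        key = ["batch", "position"]
        if "sample_time" in self.records.columns:
            key = ["sample_time"] + key
        if self.records.duplicated(subset=key).any():
            raise ValueError("QC run positions are not unique within batch")
        if len(self.records) != len(self.values):
            raise ValueError("QC records/values length mismatch")

    @property
    def batches(self) -> list:
        return sorted(self.records["batch"].unique().tolist())


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    true_precision: pd.DataFrame            # p x p, metabolite ids on both axes
    true_support: pd.DataFrame              # boolean p x p, zero diagonal
    true_communities: pd.Series             # metabolite -> community label
    true_outcome_coefs: dict[tuple[str, str], float]
    batch_shifts: pd.DataFrame              # batch x metabolite offsets (analysis scale)
    censor_limits: pd.Series                # metabolite -> analysis-scale limit (NaN if none)
    planted_outliers: tuple[tuple[str, str, float], ...]
    outcome_r2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        P = self.true_precision.to_numpy()
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("true_precision must be symmetric")
        w = np.linalg.eigvalsh(P)
        if w.min() <= 0:
            raise ValueError(f"true_precision must be positive definite (min eig {w.min():.3g})")
        S = self.true_support.to_numpy()
        if np.diag(S).any():
            raise ValueError("true_support diagonal must be zero")
        off = ~np.eye(len(P), dtype=bool)
        if not np.array_equal(S[off], (P != 0)[off]):
            raise ValueError("true_support must equal the off-diagonal nonzero pattern")


@dataclass
class AssociationResult:
    """Pooled per-metabolite association for one (outcome, model, time)."""

    metabolite: str
    model: int
    outcome: str
    sample_time: str
    strata: dict[str, tuple[float, float, int]]   # ancestry -> (beta, se, n)
    beta: float
    se: float
    ci_lo: float
    ci_hi: float
    p: float
    fdr_p: float = float("nan")

    @property
    def n_total(self) -> int:
        return int(sum(n for _, _, n in self.strata.values()))


@dataclass
class GlassoFit:
    """One graphical-lasso solution on a residual covariance."""

    S: np.ndarray
    lam: float
    precision: np.ndarray
    covariance: np.ndarray
    support: np.ndarray             # boolean, zero diagonal
    iterations: int
    converged: bool
    max_kkt_violation: float
    metabolite_ids: tuple[str, ...] = ()

    @property
    def n_edges(self) -> int:
        return int(self.support.sum()) // 2


@dataclass
class MetaboliteNetwork:
    """Exported partial-correlation network for one (sample time, outcome)."""

    nodes: pd.DataFrame             # index metabolite; columns class, node_size, community
    edges: pd.DataFrame             # columns: source, target, partial_correlation, within_community
    selected_lambda: float
    sample_time: str
    outcome: str

    def __post_init__(self) -> None:
        pc = self.edges["partial_correlation"]
        if len(pc) and (pc.abs() > 1.0 + 1e-12).any():
            raise ValueError("partial correlations must lie in [-1, 1]")
        if (self.nodes["node_size"] < 0).any():
            raise ValueError("node sizes must be non-negative")
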