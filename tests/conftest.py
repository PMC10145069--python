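import numpy as np
import pandas as pd
import pytest

from metnetmap import CohortConfig
from metnetmap.containers import MetaboliteMatrix, QCPoolSeries
from metnetmap.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> CohortConfig:
    return CohortConfig(seed=11, n_samples=400, n_metabolites=24,
                        community_sizes=(8, 8, 8), n_batches=3)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """One modest cohort shared by read-only tests."""
    return generate_cohort(small_cfg)


def toy_matrix(values: np.ndarray, classes=None, assays=None,
               missing=None, n_batches: int = 1,
               sample_time: str = "fasting") -> MetaboliteMatrix:
    """Hand-built MetaboliteMatrix around a plain array."""
    n, p = values.shape
    samples = [f"S{i:03d}" for i in range(n)]
    mets = [f"m{j}" for j in range(p)]
    vals = pd.DataFrame(values, index=samples, columns=mets)
    if missing is None:
        missing = np.zeros((n, p), dtype=bool)
    classes = classes or ["MISC"] * p
    assays = assays or ["conventional"] * p
    batches = np.repeat(np.arange(n_batches), -(-n // n_batches))[:n]
    return MetaboliteMatrix(
        values=vals,
        missing=pd.DataFrame(missing, index=samples, columns=mets),
        sample_time=sample_time,
        class_of=pd.Series(classes, index=mets),
        assay_of=pd.Series(assays, index=mets),
        batch_of=pd.Series(batches, index=samples),
        run_order_of=pd.Series(np.arange(n) + 1, index=samples),
    )


def toy_qc(batches, values, positions=None, roles=None,
           sample_time: str = "fasting") -> QCPoolSeries:
    """QC series from per-record batch labels and intensity rows."""
    values = np.asarray(values, dtype=float)
    k, p = values.shape
    if positions is None:
        positions = []
        seen: dict = {}
        for b in batches:
            seen[b] = seen.get(b, -1) + 1
            positions.append(seen[b] * 10)
    if roles is None:
        roles = ["extra"] * k
    records = pd.DataFrame({
        "sample_time": [sample_time] * k,
        "batch": batches,
        "position": positions,
        "role": roles,
    })
    mets = [f"m{j}" for j in range(p)]
    vals = pd.DataFrame(values, columns=mets)
    return QCPoolSeries(records=records, values=vals,
                        missing=pd.DataFrame(False, index=vals.index, columns=mets))
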