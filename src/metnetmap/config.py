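"""Configuration objects for the simulate -> preprocess -> associate -> network pipeline.

Every object round-trips losslessly through ``to_dict``/``from_dict`` (plain
JSON-compatible dictionaries), so a pipeline run is fully described by one
JSON document plus a seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

#: Maternal/newborn covariate moments (mean, sd) in natural units for a
#: HAPO-like pregnancy cohort: age in years, height in cm, BMI in kg/m^2,
#: mean arterial pressure in mmHg, glucose in mmol/L, gestational age at
#: delivery in weeks, sample storage time in years.
DEFAULT_COVARIATE_MOMENTS: dict[str, tuple[float, float]] = {
    "age": (29.2, 5.8),
    "height": (161.0, 7.1),
    "bmi": (27.9, 5.1),
    "map": (80.7, 7.8),
    "fasting_glucose": (4.5, 0.4),
    "one_hour_glucose": (7.5, 1.7),
    "gestational_age": (39.8, 1.2),
    "storage_time": (10.0, 2.0),
}

#: Newborn outcome moments in natural units: birthweight in grams, sum of
#: skinfolds in mm, cord C-peptide in nmol/L (log-normal on the natural scale).
DEFAULT_OUTCOME_MOMENTS: dict[str, tuple[float, float]] = {
    "birthweight": (3391.5, 485.0),
    "ssf": (12.5, 2.7),
    "cord_c_peptide": (0.3, 0.2),
}

#: Binary covariate prevalences.
DEFAULT_BINARY_RATES: dict[str, float] = {
    "smoking": 0.026,
    "alcohol": 0.044,
    "parity": 0.467,       # 1 = parous (1+), 0 = nulliparous
    "newborn_sex": 0.503,  # 1 = male
}

DEFAULT_ANCESTRY_LEVELS: tuple[str, ...] = (
    "Black", "East Asian", "Hispanic", "South Asian", "White",
)

#: Per-SD effects of maternal covariates on each outcome (outcome units per
#: 1 SD of the covariate; binary covariates per unit). BMI and glycemia are
#: the dominant anthropometric drivers; gestational age dominates birthweight.
DEFAULT_OUTCOME_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "birthweight": {
        "bmi": 110.0, "fasting_glucose": 60.0, "one_hour_glucose": 40.0,
        "gestational_age": 160.0, "height": 45.0, "parity": 60.0,
        "newborn_sex": 120.0, "smoking": -150.0, "age": 10.0,
    },
    "ssf": {
        "bmi": 0.65, "fasting_glucose": 0.30, "one_hour_glucose": 0.25,
        "gestational_age": 0.35, "newborn_sex": -0.25,
    },
    # cord C-peptide effects act on the log scale
    "cord_c_peptide": {
        "bmi": 0.14, "fasting_glucose": 0.10, "one_hour_glucose": 0.12,
    },
}

#: Default planted direct metabolite effects: outcome units per 1 SD of the
#: (fasting) metabolite. met_001 mimics triglycerides (positive on size
#: outcomes), met_021 a long-chain acylcarnitine (negative), met_003 a BCAA
#: with a cord C-peptide effect on the log scale.
DEFAULT_OUTCOME_EFFECTS: dict[tuple[str, str], float] = {
    ("met_001", "birthweight"): 45.0,
    ("met_001", "ssf"): 0.21,
    ("met_021", "birthweight"): -30.0,
    ("met_021", "ssf"): -0.17,
    ("met_003", "cord_c_peptide"): 0.04,
}

#: Default covariate loadings on metabolite analysis-scale values (per SD of
#: the covariate, in units of the metabolite's noise SD). met_002 is a pure
#: BMI marker with no direct outcome effect: its outcome association exists
#: only through BMI, the mediated/confounded case the two adjustment models
#: are designed to separate.
DEFAULT_COVARIATE_LOADINGS: dict[str, dict[str, float]] = {
    "met_002": {"bmi": 0.6},
    "met_001": {"bmi": 0.15, "fasting_glucose": 0.10},
    "met_003": {"bmi": 0.20},
    "met_004": {"age": 0.10},
}


def _effects_to_json(effects: Mapping[tuple[str, str], float]) -> dict[str, float]:
    return {f"{m}|{o}": v for (m, o), v in effects.items()}


def _effects_from_json(d: Mapping[str, float]) -> dict[tuple[str, str], float]:
    out = {}
    for k, v in d.items():
        m, o = k.split("|")
        out[(m, o)] = float(v)
    return out


@dataclass
class CohortConfig:
    """Parameters of the synthetic mother-newborn cohort generator.

    The defaults describe the emulated study: 11 field centers, five
    ancestry groups nested unevenly within centers, covariate moments in
    natural units, a block-structured Gaussian graphical model for the
    metabolite panel, pooled-QC batches with additive shifts and run-order
    drift, left-censored detection-limit missingness, and newborn outcomes
    driven by covariates plus a small set of planted per-SD metabolite
    effects.
    """

    seed: int
    n_samples: int = 1000
    n_centers: int = 11
    ancestry_levels: tuple[str, ...] = DEFAULT_ANCESTRY_LEVELS
    covariate_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MOMENTS))
    outcome_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MOMENTS))
    binary_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_RATES))
    n_metabolites: int = 60
    community_sizes: tuple[int, ...] = (10, 10, 10, 10, 10, 10)
    within_partial_corr: float = 0.3
    # dense enough that each community is one cohesive connected subgraph,
    # sparse enough that the requested strength stays attainable: a
    # unit-diagonal precision with off-diagonals -rho on a support A is
    # positive definite only while rho < 1/lambda_max(A)
    edge_density_within: float = 0.4
    n_cross_edges: int = 6
    outcome_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_EFFECTS))
    outcome_covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_COVARIATE_EFFECTS.items()})
    covariate_loadings: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_LOADINGS.items()})
    #: temporal stability of a metabolite between the fasting and 1-h draw
    state_correlation: float = 0.5
    #: fraction of the panel assayed by GC-MS (the rest conventional/targeted)
    gcms_fraction: float = 0.55
    censor_fraction: float = 0.08
    outlier_plants: tuple[tuple[int, str, float], ...] = ()
    n_batches: int = 8
    batch_shift_sd: float = 0.4
    run_order_drift: float = 0.001
    qc_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory: cohort generation must be reproducible")
        if sum(self.community_sizes) != self.n_metabolites:
            raise ValueError(
                f"community_sizes sum to {sum(self.community_sizes)}, "
                f"expected n_metabolites={self.n_metabolites}")
        if not (0.0 < self.within_partial_corr < 1.0):
            raise ValueError("within_partial_corr must lie in (0, 1)")
        # 0 is permitted as the degenerate independence case
        if not (0.0 <= self.edge_density_within <= 1.0):
            raise ValueError("edge_density_within must lie in [0, 1]")
        if not (0.0 <= self.censor_fraction < 0.5):
            raise ValueError("censor_fraction must lie in [0, 0.5)")
        for name, (_, sd) in self.covariate_moments.items():
            if sd <= 0:
                raise ValueError(f"sd for covariate {name!r} must be positive")

    @property
    def metabolite_ids(self) -> list[str]:
        return [f"met_{i + 1:03d}" for i in range(self.n_metabolites)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcome_effects"] = _effects_to_json(self.outcome_effects)
        d["ancestry_levels"] = list(self.ancestry_levels)
        d["community_sizes"] = list(self.community_sizes)
        d["outlier_plants"] = [list(t) for t in self.outlier_plants]
        d["covariate_moments"] = {k: list(v) for k, v in self.covariate_moments.items()}
        d["outcome_moments"] = {k: list(v) for k, v in self.outcome_moments.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        d["outcome_effects"] = _effects_from_json(d.get("outcome_effects", {}))
        d["ancestry_levels"] = tuple(d.get("ancestry_levels", DEFAULT_ANCESTRY_LEVELS))
        d["community_sizes"] = tuple(d["community_sizes"])
        d["outlier_plants"] = tuple(
            (int(s), str(m), float(z)) for s, m, z in d.get("outlier_plants", ()))
        d["covariate_moments"] = {
            k: (float(v[0]), float(v[1])) for k, v in d["covariate_moments"].items()}
        d["outcome_moments"] = {
            k: (float(v[0]), float(v[1])) for k, v in d["outcome_moments"].items()}
        return cls(**d)


MODEL1_COVARIATES: tuple[str, ...] = (
    "field_center", "pc1", "pc2", "pc3", "map", "age", "parity", "height",
    "smoking", "alcohol", "newborn_sex", "gestational_age", "storage_time",
)

OUTCOMES: tuple[str, ...] = ("birthweight", "ssf", "cord_c_peptide")
SAMPLE_TIMES: tuple[str, ...] = ("fasting", "one_hour")

MATCHED_GLUCOSE: dict[str, str] = {
    "fasting": "fasting_glucose",
    "one_hour": "one_hour_glucose",
}


@dataclass(frozen=True)
class ModelSpec:
    """One regression specification: model 1 (baseline covariates) or
    model 2 (baseline plus maternal BMI and the glucose measurement matched
    to the metabolite sample time)."""

    model: int
    outcome: str
    sample_time: str
    cpeptide_scale: str = "log"

    def __post_init__(self) -> None:
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.sample_time not in SAMPLE_TIMES:
            raise ValueError(f"unknown sample_time {self.sample_time!r}")
        if self.cpeptide_scale not in ("log", "raw"):
            raise ValueError("cpeptide_scale must be 'log' or 'raw'")

    @property
    def covariates(self) -> tuple[str, ...]:
        if self.model == 1:
            return MODEL1_COVARIATES
        return MODEL1_COVARIATES + ("bmi", MATCHED_GLUCOSE[self.sample_time])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(**d)


@dataclass
class AnnealSchedule:
    """Simulated-annealing schedule for spin-glass community detection.

    gamma is the resolution of the Reichardt-Bornholdt null-model term;
    temperatures cool geometrically from start_temp to stop_temp, with
    ``sweeps_per_temp`` full single-spin-update sweeps at each temperature
    (default: one sweep visits every node once; None means "use node count"
    sweeps per temperature).
    """

    gamma: float = 1.0
    start_temp: float = 1.0
    stop_temp: float = 0.01
    cooling_factor: float = 0.99
    sweeps_per_temp: int | None = None
    max_communities: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.start_temp > self.stop_temp > 0):
            raise ValueError("require start_temp > stop_temp > 0")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnnealSchedule":
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Either ``simulate`` is True and ``cohort`` drives the generator, or
    ``input_dir`` points at a directory of CSV tables in the package's
    layout. Thresholds collect the filtering constants of the analysis:
    the >=5 SD outlier rule, the >10-outliers-per-sample exclusion, the
    <10% (association) and <1% (network) missingness cuts, and the FDR
    significance level q.
    """

    seed: int
    simulate: bool = True
    cohort: CohortConfig | None = None
    input_dir: str | None = None
    sd_threshold: float = 5.0
    max_outliers_per_sample: int = 10
    association_missing_frac: float = 0.10
    network_missing_frac: float = 0.01
    fdr_q: float = 0.05
    cpeptide_scale: str = "log"
    ric_rotations: int = 20
    lambda_path_points: int = 30
    lambda_path_ratio: float = 0.05
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.simulate and self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if not self.simulate and not self.input_dir:
            raise ValueError("input_dir is required when simulate is False")
        for name in ("sd_threshold", "association_missing_frac", "network_missing_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": self.simulate,
            "cohort": self.cohort.to_dict() if self.cohort is not None else None,
            "input_dir": self.input_dir,
            "sd_threshold": self.sd_threshold,
            "max_outliers_per_sample": self.max_outliers_per_sample,
            "association_missing_frac": self.association_missing_frac,
            "network_missing_frac": self.network_missing_frac,
            "fdr_q": self.fdr_q,
            "cpeptide_scale": self.cpeptide_scale,
            "ric_rotations": self.ric_rotations,
            "lambda_path_points": self.lambda_path_points,
            "lambda_path_ratio": self.lambda_path_ratio,
            "anneal": self.anneal.to_dict(),
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if d.get("anneal") is not None:
            d["anneal"] = AnnealSchedule.from_dict(d["anneal"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
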