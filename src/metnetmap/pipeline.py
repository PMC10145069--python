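"""End-to-end driver: simulate (or ingest) -> preprocess -> associate -> network.

All artifacts are delimited text (CSV) plus JSON; a run manifest records the
configuration, seed fan-out, stage timings and a SHA-256 checksum of every
file written, so two runs with the same config and seed are verifiably
bit-identical (timings aside).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import associate, association_table
from .config import OUTCOMES, SAMPLE_TIMES, ModelSpec, PipelineConfig
from .containers import MetaboliteMatrix, QCPoolSeries
from .network import (
    build_network,
    fit_network,
    residualize,
    spin_glass_communities,
    to_graph,
)
from .preprocess import filter_missingness, preprocess_matrix
from .synthetic import generate_cohort

import networkx as nx

log = logging.getLogger("metnetmap")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    pass


def _stage_seed(seed: int, stage: int) -> int:
    """Fan one global seed out to a per-stage 31-bit integer."""
    return int(np.random.SeedSequence([int(seed), int(stage)]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# CSV layout


def write_cohort(out_dir, cov: pd.DataFrame, fasting: MetaboliteMatrix,
                 one_hour: MetaboliteMatrix, qc: QCPoolSeries,
                 outcomes: pd.DataFrame, truth=None) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, float_format=_FLOAT_FMT, **kw)
        written.append(path)

    save(cov, "covariates.csv")
    save(outcomes, "outcomes.csv")
    for m in (fasting, one_hour):
        t = m.sample_time
        save(m.masked(), f"metabolites_{t}.csv")
        ann = pd.DataFrame({"class": m.class_of, "assay": m.assay_of})
        ann.index.name = "metabolite"
        save(ann, f"metabolite_annotations_{t}.csv")
        run = pd.DataFrame({"batch": m.batch_of, "run_order": m.run_order_of})
        run.index.name = "sample_id"
        save(run, f"sample_runinfo_{t}.csv")
    qc_table = pd.concat(
        [qc.records.reset_index(drop=True),
         qc.values.mask(qc.missing).reset_index(drop=True)], axis=1)
    save(qc_table, "qc_records.csv", index=False)
    if truth is not None:
        save(truth.true_precision, "truth_precision.csv")
        truth_json = {
            "true_outcome_coefs": {f"{m}|{o}": v
                                   for (m, o), v in truth.true_outcome_coefs.items()},
            "communities": {m: int(c) for m, c in truth.true_communities.items()},
            "censor_limits": {m: (None if np.isnan(v) else float(v))
                              for m, v in truth.censor_limits.items()},
            "planted_outliers": [list(t) for t in truth.planted_outliers],
            "outcome_r2": truth.outcome_r2,
        }
        path = out / "truth.json"
        path.write_text(json.dumps(truth_json, indent=2, sort_keys=True))
        written.append(path)
        save(truth.batch_shifts, "truth_batch_shifts.csv")
    return written


def _read_matrix(in_dir: Path, time: str) -> MetaboliteMatrix:
    vals = pd.read_csv(in_dir / f"metabolites_{time}.csv", index_col=0)
    vals.index = vals.index.astype(str)
    ann = pd.read_csv(in_dir / f"metabolite_annotations_{time}.csv", index_col=0)
    run = pd.read_csv(in_dir / f"sample_runinfo_{time}.csv", index_col=0)
    run.index = run.index.astype(str)
    orphans = sorted(set(vals.index) ^ set(run.index))
    if orphans:
        raise PipelineError(f"run-info/matrix sample id mismatch for {time}: {orphans[:5]}")
    missing = vals.isna()
    # a harmless positive placeholder keeps later log transforms defined;
    # the mask makes the value irrelevant to every statistic
    return MetaboliteMatrix(
        values=vals.where(~missing, other=1.0),
        missing=missing,
        sample_time=time,
        class_of=ann["class"],
        assay_of=ann["assay"],
        batch_of=run.loc[vals.index, "batch"],
        run_order_of=run.loc[vals.index, "run_order"],
    )


def read_tables(in_dir):
    """Load a cohort directory back into typed tables, with validation."""
    in_dir = Path(in_dir)
    cov = pd.read_csv(in_dir / "covariates.csv", index_col=0)
    cov.index = cov.index.astype(str)
    outcomes = pd.read_csv(in_dir / "outcomes.csv", index_col=0)
    outcomes.index = outcomes.index.astype(str)
    orphans = sorted(set(cov.index) ^ set(outcomes.index))
    if orphans:
        raise PipelineError(f"covariate/outcome sample id mismatch: {orphans[:5]}")
    for col in ("fasting_glucose", "one_hour_glucose"):
        if col in cov.columns and (cov[col] <= 0).any():
            bad = cov.index[cov[col] <= 0][0]
            raise PipelineError(f"non-positive {col} for sample {bad}")
    if "parity" in cov.columns and not cov["parity"].isin([0, 1]).all():
        raise PipelineError("parity must be coded 0/1")
    fasting = _read_matrix(in_dir, "fasting")
    one_hour = _read_matrix(in_dir, "one_hour")
    for m in (fasting, one_hour):
        orphans = sorted(set(m.values.index) ^ set(cov.index))
        if orphans:
            raise PipelineError(
                f"{m.sample_time} matrix sample ids do not match covariates: {orphans[:5]}")
    qc_table = pd.read_csv(in_dir / "qc_records.csv")
    meta_cols = [c for c in ("sample_time", "batch", "position", "role")
                 if c in qc_table.columns]
    qc = QCPoolSeries(
        records=qc_table[meta_cols],
        values=qc_table.drop(columns=meta_cols),
        missing=qc_table.drop(columns=meta_cols).isna(),
    )
    return cov, fasting, one_hour, qc, outcomes


# ---------------------------------------------------------------------------
# orchestration


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage for both sample times and all three outcomes.

    Writes all artifacts beneath ``cfg.out_dir`` and returns the manifest
    (also written as ``manifest.json``). Any stage failure aborts with the
    stage name; partial outputs are preserved under a FAILED marker.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "metnetmap", "version": __version__,
                      "seed": cfg.seed, "config": cfg.to_dict(),
                      "stages": {}, "files": {}}
    written: list[Path] = []
    stage = "setup"
    try:
        # -- simulate / ingest ---------------------------------------------
        stage = "simulate" if cfg.simulate else "ingest"
        t0 = time.perf_counter()
        if cfg.simulate:
            cov, fasting, one_hour, qc, outcomes, truth = generate_cohort(cfg.cohort)
            written += write_cohort(out_dir / "cohort", cov, fasting, one_hour,
                                    qc, outcomes, truth)
        else:
            cov, fasting, one_hour, qc, outcomes = read_tables(cfg.input_dir)
        log.info("stage=%s n_samples=%d", stage, len(cov))
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        # -- preprocess ----------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        cleaned: dict[str, MetaboliteMatrix] = {}
        pre_dir = out_dir / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        for m in (fasting, one_hour):
            mat, report = preprocess_matrix(
                m, qc, sd_threshold=cfg.sd_threshold,
                max_outliers_per_sample=cfg.max_outliers_per_sample)
            cleaned[m.sample_time] = mat
            path = pre_dir / f"normalized_{m.sample_time}.csv"
            mat.masked().to_csv(path, float_format=_FLOAT_FMT)
            written.append(path)
            path = pre_dir / f"exclusions_{m.sample_time}.csv"
            report.to_csv(path)
            written.append(path)
            audit = {"unnormalized": list(mat.unnormalized_flags),
                     "transforms": mat.transform_of.to_dict()}
            path = pre_dir / f"audit_{m.sample_time}.json"
            path.write_text(json.dumps(audit, indent=2, sort_keys=True))
            written.append(path)
            log.info("stage=preprocess time=%s excluded=%d", m.sample_time,
                     int(report["excluded"].sum()))
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        # -- association ---------------------------------------------------
        stage = "association"
        t0 = time.perf_counter()
        assoc_dir = out_dir / "association"
        assoc_dir.mkdir(exist_ok=True)
        nominal_p: dict[tuple[str, str], dict[str, float]] = {}
        for time_key in SAMPLE_TIMES:
            assoc_set = filter_missingness(cleaned[time_key],
                                           cfg.association_missing_frac)
            for outcome in OUTCOMES:
                results = []
                for model in (1, 2):
                    spec = ModelSpec(model=model, outcome=outcome,
                                     sample_time=time_key,
                                     cpeptide_scale=cfg.cpeptide_scale)
                    res = associate(assoc_set, cov, outcomes, spec)
                    results.extend(res)
                    if model == 2:
                        nominal_p[(time_key, outcome)] = {r.metabolite: r.p for r in res}
                table = association_table(results, fdr_q=cfg.fdr_q)
                path = assoc_dir / f"association_{outcome}_{time_key}.csv"
                table.to_csv(path, index=False, float_format=_FLOAT_FMT)
                written.append(path)
                n_sig = int(table.get("model2_significant", pd.Series(dtype=bool)).sum())
                log.info("stage=association time=%s outcome=%s significant_m2=%d",
                         time_key, outcome, n_sig)
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}

        # -- network -------------------------------------------------------
        stage = "network"
        t0 = time.perf_counter()
        net_dir = out_dir / "network"
        net_dir.mkdir(exist_ok=True)
        for t_idx, time_key in enumerate(SAMPLE_TIMES):
            net_set = filter_missingness(cleaned[time_key], cfg.network_missing_frac)
            spec = ModelSpec(model=2, outcome="birthweight", sample_time=time_key,
                             cpeptide_scale=cfg.cpeptide_scale)
            resid, dropped = residualize(net_set, cov, spec)
            fit = fit_network(resid, ric_rotations=cfg.ric_rotations,
                              seed=_stage_seed(cfg.seed, 100 + t_idx),
                              n_points=cfg.lambda_path_points,
                              ratio=cfg.lambda_path_ratio)
            sched = cfg.anneal
            sched.seed = _stage_seed(cfg.seed, 200 + t_idx)
            comms = spin_glass_communities(fit.support.astype(float), sched)
            nets = {
                outcome: build_network(
                    fit, comms, nominal_p[(time_key, outcome)],
                    net_set.class_of, time_key, outcome)
                for outcome in OUTCOMES
            }
            # one GraphML per sample time: shared edge structure, one
            # node-size attribute per outcome
            g = to_graph(nets["birthweight"])
            for outcome in OUTCOMES:
                for met, row in nets[outcome].nodes.iterrows():
                    g.nodes[met][f"node_size_{outcome}"] = float(row["node_size"])
            path = net_dir / f"network_{time_key}.graphml"
            nx.write_graphml(g, path)
            written.append(path)
            edges = nets["birthweight"].edges.copy()
            path = net_dir / f"edges_{time_key}.csv"
            edges.to_csv(path, index=False, float_format=_FLOAT_FMT)
            written.append(path)
            log.info("stage=network time=%s lambda=%.4f edges=%d communities=%d dropped=%d",
                     time_key, fit.lam, fit.n_edges, len(set(comms)), len(dropped))
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["files"] = {
        str(p.relative_to(out_dir)): _sha256(p) for p in sorted(written)
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
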