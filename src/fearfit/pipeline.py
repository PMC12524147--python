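"""End-to-end orchestration: simulate-or-ingest through risk models.

Stages run in a fixed order — simulate (or ingest) -> score -> metrics ->
assemble -> fit -> compare -> associate — writing plain-CSV/JSON outputs
into a run directory, with a manifest recording the configuration verbatim,
per-stage wall times and a SHA-256 checksum of every output file.  Reruns
with an identical configuration reproduce identical derived CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, cohort, inference, metrics, scoring, simulate
from .rw import RWModelSpec
from .task import TaskDesign

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs; serialized into the manifest."""

    out_dir: str = "fearfit_run"
    # simulation (ignored when trials_csv is given)
    n_subjects: int = 40
    sim_seed: int = 1
    design: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    sim_model: str = "M4"
    # ingestion
    trials_csv: str | None = None
    subjects_csv: str | None = None
    # scoring / metrics toggles
    validate_window: bool = True
    extinction_metric: str = "percent"
    # fitting
    models: list[str] = field(default_factory=lambda: ["M1", "M4"])
    fit_method: str = "map"
    fit_seed: int = 2
    n_draws: int = 400
    outer_iters: int = 8
    priors: dict = field(default_factory=dict)
    # association
    standardize_disc: bool = True
    status_model_sequence: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": [],
        "files": {},
    }

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.perf_counter() - t0, 3)}
        )
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)
        _write_manifest(out, manifest)

    try:
        # 1. simulate or ingest -------------------------------------------
        t0 = time.perf_counter()
        if config.trials_csv:
            trials = simulate.read_trials(config.trials_csv)
            subjects = (
                simulate.read_subjects(config.subjects_csv)
                if config.subjects_csv
                else pd.DataFrame(
                    {"subject_id": trials["subject_id"].unique()}
                )
            )
        else:
            coh = simulate.simulate_cohort(
                n_subjects=config.n_subjects,
                design=TaskDesign(**config.design),
                effects=simulate.CohortEffects(**config.effects),
                population=simulate.PopulationTruth(**config.population),
                model=RWModelSpec.from_id(config.sim_model),
                seed=config.sim_seed,
            )
            trials, subjects = coh.trials, coh.subjects
        trials_path = out / "trials.csv"
        subjects_path = out / "subjects.csv"
        trials.to_csv(trials_path, index=False)
        subjects.to_csv(subjects_path, index=False)
        record("simulate_or_ingest", t0, [trials_path, subjects_path])

        # 2. score ---------------------------------------------------------
        t0 = time.perf_counter()
        if config.validate_window:
            trials = scoring.apply_response_window(trials)
        trials, qc = scoring.impute_artifacts(trials)
        scored_path = out / "trials_scored.csv"
        qc_path = out / "qc.json"
        trials.to_csv(scored_path, index=False)
        qc_path.write_text(json.dumps(qc.to_dict(), indent=2))
        record("score", t0, [scored_path, qc_path])

        # 3. metrics -------------------------------------------------------
        t0 = time.perf_counter()
        met = metrics.subject_metrics(
            trials, extinction_metric=config.extinction_metric
        )
        metrics_path = out / "metrics.csv"
        met.to_csv(metrics_path, index=False)
        record("metrics", t0, [metrics_path])

        # 4. assemble ------------------------------------------------------
        t0 = time.perf_counter()
        subjects = subjects.copy()
        subjects["drri_composite"] = cohort.drri_composite(subjects)
        flow = cohort.apply_exclusion_flow(
            subjects, met, unusable_subjects=qc.unusable_subjects
        )
        assign_path = out / "assignments.csv"
        flow_path = out / "flow.json"
        flow.assignments.to_csv(assign_path, index=False)
        flow_path.write_text(json.dumps(flow.flow, indent=2))
        record("assemble", t0, [assign_path, flow_path])

        # 5. fit -----------------------------------------------------------
        t0 = time.perf_counter()
        primary_ids = flow.primary["subject_id"]
        fit_trials = trials[trials["subject_id"].isin(primary_ids)]
        fits = []
        fit_files: list[Path] = []
        for model_id in config.models:
            fit = inference.fit_model(
                fit_trials,
                RWModelSpec.from_id(model_id),
                priors=inference.PriorConfig(**config.priors),
                method=config.fit_method,
                seed=config.fit_seed,
                n_draws=config.n_draws,
                outer_iters=config.outer_iters,
            )
            fit_dir = out / f"fit_{model_id}"
            fit.save(fit_dir)
            fits.append(fit)
            fit_files.extend(p for p in fit_dir.iterdir() if p.is_file())
        record("fit", t0, fit_files)

        # 6. compare -------------------------------------------------------
        if len(fits) >= 2 and fits[0].loglik is not None:
            t0 = time.perf_counter()
            comparison = inference.compare_models(fits)
            cmp_path = out / "comparison.csv"
            comparison.table.to_csv(cmp_path, index=False)
            pw_path = out / "comparison_pairwise.csv"
            comparison.pairwise.to_csv(pw_path, index=False)
            record("compare", t0, [cmp_path, pw_path])

        # 7. associate -----------------------------------------------------
        t0 = time.perf_counter()
        best = fits[-1]
        lrs = inference.extract_learning_rates(best)
        table = (
            met.merge(lrs, on="subject_id", how="inner")
            .merge(subjects, on="subject_id", how="left")
            .merge(flow.assignments, on="subject_id", how="left")
        )
        table = table[table["label"].isin([cohort.LABEL_HEALTHY,
                                           cohort.LABEL_PTSD])]
        table["outcome_status"] = table["label"]
        assoc_files = []
        status = association.fit_status_model(
            table,
            standardize_disc=config.standardize_disc,
            model_sequence=config.status_model_sequence,
        )
        p = out / "status_model.csv"
        status.params.to_csv(p, index=False)
        assoc_files.append(p)
        severity = association.fit_severity_model(table)
        p = out / "severity_model.csv"
        severity.params.to_csv(p, index=False)
        assoc_files.append(p)
        if severity.partial_residuals is not None:
            p = out / "severity_partial_residuals.csv"
            severity.partial_residuals.to_csv(p, index=False)
            assoc_files.append(p)
        record("associate", t0, assoc_files)
    except Exception as exc:
        manifest["failed_stage"] = {
            "after_stages": [s["stage"] for s in manifest["stages"]],
            "error": f"{type(exc).__name__}: {exc}",
        }
        _write_manifest(out, manifest)
        raise

    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
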