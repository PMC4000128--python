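"""Run configuration and end-to-end orchestration.

``run_pipeline`` chains simulate/load -> score -> calibrate -> evaluate
-> report, writing every artifact as TSV/JSON plus a machine-readable
run-metadata record (config hash, seed, library versions, per-stage
timing). Each stage is also independently callable from the CLI.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .agreement import agreement_report
from .calibration import assign_groups, percentile_cutoffs
from .clinical import read_clinical
from .evaluate import (
    MULTIVARIATE_SETS,
    SignatureSurvivalModel,
    multivariate_effects,
)
from .matrix import read_expression
from .scoring import ScoreTable, score_all
from .signatures import load_signature_dir
from .simulate import SimulationConfig, simulate_cohort
from .survival import aalen_cumulative, km_estimate, logrank


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    expression: Optional[str] = None
    clinical: Optional[str] = None
    signatures: Optional[str] = None
    outdir: str = "progsig_out"


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    intervals: list[float] = Field(default_factory=lambda: [5.0, 10.0])
    strata: Optional[str] = "er_status"
    score_correlation: Literal["pearson", "spearman"] = "pearson"
    ties: Literal["efron", "breslow"] = "efron"
    ph_transform: Literal["km", "identity", "rank", "log"] = "km"
    min_coverage: float = 0.5
    seed: int = 0
    bootstrap_b: int = 0
    cohort_adjust: bool = False
    simulate_n: Optional[int] = None  # when set, simulate instead of reading inputs

    @field_validator("intervals")
    @classmethod
    def _intervals_ascending(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])) or (v and v[0] <= 0):
            raise ValueError(f"interval cut points must be positive and ascending, got {v}")
        return v

    @field_validator("min_coverage")
    @classmethod
    def _coverage_range(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError(f"min_coverage must be in [0, 1], got {v}")
        return v


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    paths: PathsConfig = Field(default_factory=PathsConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)

    @property
    def interval_bounds(self) -> tuple[tuple[float, float], ...]:
        cuts = [0.0, *self.analysis.intervals, math.inf]
        return tuple(zip(cuts[:-1], cuts[1:]))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Pydantic reports every schema violation at once, not just the first.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(doc)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and return the paths of every artifact.

    Stages: (1) load or simulate inputs, (2) score all signatures,
    (3) population-based risk groups + KM curves per group, (4)
    cross-signature agreement, (5) survival evaluation (C-index/PVE,
    interval x stratum HRs, PH diagnostics, Aalen curves, multivariate
    models). A signature failing coverage is reported and skipped; any
    stage-level failure aborts with the stage name.
    """
    outdir = Path(config.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "load"
    t0 = time.time()
    try:
        if config.analysis.simulate_n is not None:
            sim = simulate_cohort(
                SimulationConfig(seed=config.analysis.seed, n_samples=config.analysis.simulate_n)
            )
            expr, clinical, signatures = sim.expression, sim.clinical, sim.signatures
            truth_path = outdir / "ground_truth.tsv"
            sim.truth.write(truth_path)
            artifacts["ground_truth"] = truth_path
        else:
            if not (config.paths.expression and config.paths.clinical and config.paths.signatures):
                raise ValueError("expression, clinical and signatures paths are all required")
            expr = read_expression(config.paths.expression)
            clinical = read_clinical(config.paths.clinical)
            signatures = load_signature_dir(config.paths.signatures)
        timings[stage] = time.time() - t0

        stage = "score"
        t0 = time.time()
        table: ScoreTable = score_all(
            expr, signatures, clinical, min_coverage=config.analysis.min_coverage
        )
        table.write(outdir / "scores.tsv")
        artifacts["scores"] = outdir / "scores.tsv"
        timings[stage] = time.time() - t0

        stage = "calibrate"
        t0 = time.time()
        artifacts["risk_groups"] = _calibrate_stage(table, signatures, clinical, outdir)
        timings[stage] = time.time() - t0

        stage = "agreement"
        t0 = time.time()
        calls = table.subtype_calls
        kwargs = {}
        if calls.shape[1] >= 2:
            first, second = calls.columns[:2]
            order = next(
                s.class_order for s in signatures if s.name == first
            )
            kwargs = dict(calls_a=calls[first], calls_b=calls[second], class_order=order)
        report = agreement_report(table.scores, method=config.analysis.score_correlation, **kwargs)
        report.write(outdir)
        artifacts["score_correlations"] = outdir / "score_correlations.tsv"
        timings[stage] = time.time() - t0

        stage = "evaluate"
        t0 = time.time()
        model = SignatureSurvivalModel(
            table.scores,
            clinical,
            intervals=config.interval_bounds,
            stratify_by=config.analysis.strata,
            cohort_adjust=config.analysis.cohort_adjust,
            ph_transform=config.analysis.ph_transform,
        )
        results = model.fit()
        results.write(outdir)
        artifacts["performance"] = outdir / "performance.tsv"
        artifacts["interval_effects"] = outdir / "interval_effects.tsv"
        (outdir / "summary.txt").write_text(results.summary() + "\n")
        artifacts["summary"] = outdir / "summary.txt"
        _aalen_stage(table, clinical, config, outdir)
        artifacts["aalen_curves"] = outdir / "aalen_curves.tsv"
        artifacts["multivariate"] = _multivariate_stage(table, clinical, config, outdir)
        timings[stage] = time.time() - t0
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    meta = {
        "config_hash": config.content_hash(),
        "seed": config.analysis.seed,
        "progsig_version": __version__,
        "versions": _library_versions(),
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
        "signature_status": table.status,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1) + "\n")
    artifacts["run_metadata"] = outdir / "run_metadata.json"
    return artifacts


def _calibrate_stage(table, signatures, clinical, outdir: Path) -> Path:
    cdf = clinical.indexed()
    rows = []
    km_rows = []
    logrank_rows = []
    for sig in signatures:
        if not sig.calibration or sig.name not in table.scores.columns:
            continue
        scores = table.scores[sig.name]
        stratified = set(sig.calibration) != {"all"}
        strat = cdf["er_status"].reindex(scores.index) if stratified else None
        cal = next(iter(sig.calibration.values()))
        cuts = percentile_cutoffs(scores, cal.proportions, strat)
        if stratified:
            # per-stratum proportions may differ: recompute each context
            cuts = {}
            for ctx, spec in sig.calibration.items():
                sub = scores[strat == ctx]
                cuts[ctx] = percentile_cutoffs(sub, spec.proportions)["__all__"]
        assignment = assign_groups(scores, cuts, cal.labels, strat)
        for sid, label in assignment.labels.items():
            rows.append({"sample_id": sid, "signature": sig.name, "risk_group": label})
        merged = cdf.join(assignment.labels.rename("group"))
        groups = {}
        for grp, sub in merged.dropna(subset=["group"]).groupby("group"):
            curve = km_estimate(sub["time_years"], sub["event"], label=f"{sig.name}:{grp}")
            km_rows.append(curve.as_frame())
            groups[grp] = (sub["time_years"].to_numpy(), sub["event"].to_numpy())
        if len(groups) >= 2:
            try:
                stat, p = logrank(groups)
                logrank_rows.append(
                    {"signature": sig.name, "chi2": stat, "df": len(groups) - 1, "p": p}
                )
            except ValueError:
                pass
    path = outdir / "risk_groups.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
    if km_rows:
        pd.concat(km_rows, ignore_index=True).to_csv(
            outdir / "km_curves.tsv", sep="\t", index=False
        )
    if logrank_rows:
        pd.DataFrame(logrank_rows).to_csv(
            outdir / "risk_group_logrank.tsv", sep="\t", index=False
        )
    return path


def _aalen_stage(table, clinical, config: RunConfig, outdir: Path) -> None:
    cdf = clinical.indexed()
    frames = []
    strata = ["positive", "negative"] if config.analysis.strata == "er_status" else [None]
    for sig in table.scores.columns:
        for st in strata:
            sub = cdf if st is None else cdf[cdf["er_status"] == st]
            s = table.scores[sig].reindex(sub.index).dropna()
            sub = sub.loc[s.index]
            if sub["event"].sum() < 2 or s.nunique() < 2:
                continue
            res = aalen_cumulative(s.to_numpy(), sub["time_years"], sub["event"])
            frame = res.as_frame("covariate")
            frame.insert(0, "signature", sig)
            frame.insert(1, "stratum", st or "all")
            frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(
        outdir / "aalen_curves.tsv", sep="\t", index=False
    )


def _multivariate_stage(table, clinical, config: RunConfig, outdir: Path) -> Path:
    rows = []
    for sig in table.scores.columns:
        try:
            fits = multivariate_effects(
                table.scores[sig],
                clinical,
                MULTIVARIATE_SETS,
                stratify_by=config.analysis.strata,
                stratum_value="positive" if config.analysis.strata == "er_status" else None,
                signature_name=sig,
                cohort_adjust=config.analysis.cohort_adjust,
            )
        except ValueError:
            continue
        for model_name, fit in fits.items():
            for cov, r in fit.summary.iterrows():
                rows.append(
                    {
                        "signature": sig,
                        "model": model_name,
                        "covariate": cov,
                        "hr": r["hr"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p": r["p"],
                        "n": fit.n,
                        "n_event": fit.n_events,
                    }
                )
    path = outdir / "multivariate_models.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def _library_versions() -> dict[str, str]:
    import lifelines
    import numpy
    import pandas as pd_
    import scipy

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd_.__version__,
        "lifelines": lifelines.__version__,
    }
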