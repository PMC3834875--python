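"""End-to-end study pipeline.

Generates (or loads) a cohort, produces the descriptive tables, fits every
configured model under 5-fold cross-validation, evaluates discrimination,
calibration and decision curves, optionally applies a Partin-style lookup
table, and writes everything plus a manifest (config echo, derived seeds,
library versions, per-output SHA-256 hashes) to an output directory. A
second run with the same config reproduces every numeric output exactly:
all randomness fans out deterministically from the single master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import DegeneratePredictionsError, loess_calibration
from .cohort import GeneratorParams, default_params, read_cohort, sample_cohort, write_cohort
from .decision import decision_curve
from .descriptives import gleason_transition, summarize_cohort
from .discrimination import discrimination_report
from .modelling import (
    ALL_PREDICTORS,
    ModelSpec,
    assign_folds,
    cross_validated_predictions,
    univariate_predictions,
    write_predictions,
)
from .partin import load_partin_table, partin_predict

__all__ = ["RunConfig", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_GEN_FIELDS = {
    "n",
    "noc_prevalence",
    "noc_split",
    "psa_clip",
    "age_mean_oc",
    "age_mean_noc",
    "age_sd",
    "age_range",
    "clinical_stage_probs",
    "family_history_probs",
}


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of generator / cohort_path."""

    out_dir: str
    seed: int = 0
    generator: dict | None = None
    cohort_path: str | None = None
    k_folds: int = 5
    families: tuple[str, ...] = ("LOGISTIC", "RANDOM_FOREST", "KNN")
    univariate: tuple[str, ...] = ALL_PREDICTORS
    hyperparameters: dict = field(default_factory=dict)
    threshold_rule: str = "youden"
    fixed_threshold: float = 0.5
    loess_span: float = 0.75
    loess_degree: int = 2
    n_bins: int = 10
    partin_table: str | None = None
    partin_outcome: str = "ECE"
    plots: bool = True

    def __post_init__(self):
        if (self.generator is None) == (self.cohort_path is None):
            raise ValueError("supply exactly one of generator params or cohort_path")


def load_config(path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    models = raw.get("models", {})
    evaluation = raw.get("evaluation", {})
    partin = raw.get("partin", {}) or {}
    return RunConfig(
        out_dir=raw.get("out_dir", "stagebench_run"),
        seed=int(raw.get("seed", 0)),
        generator=raw.get("generator"),
        cohort_path=raw.get("cohort_path"),
        k_folds=int(raw.get("k_folds", 5)),
        families=tuple(models.get("families", ("LOGISTIC", "RANDOM_FOREST", "KNN"))),
        univariate=tuple(models.get("univariate", ALL_PREDICTORS)),
        hyperparameters=models.get("hyperparameters", {}),
        threshold_rule=evaluation.get("threshold_rule", "youden"),
        fixed_threshold=float(evaluation.get("fixed_threshold", 0.5)),
        loess_span=float(evaluation.get("loess_span", 0.75)),
        loess_degree=int(evaluation.get("loess_degree", 2)),
        n_bins=int(evaluation.get("n_bins", 10)),
        partin_table=partin.get("table_path"),
        partin_outcome=partin.get("outcome", "ECE"),
        plots=bool(raw.get("plots", True)),
    )


def _generator_params(config: RunConfig) -> GeneratorParams:
    overrides = dict(config.generator or {})
    n = int(overrides.pop("n", 603))
    # master-seed fan-out: generator gets the master seed itself
    params = default_params(n=n, seed=config.seed)
    overrides = {
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    }
    unknown = set(overrides) - _GEN_FIELDS
    if unknown:
        raise ValueError(f"unknown generator overrides {sorted(unknown)}")
    if overrides:
        params = params.with_(**overrides)
        params.validate()
    return params


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study; returns the manifest dictionary.

    Any stage failure aborts with the stage name and cause; stages skipped
    by configuration (e.g. no Partin table) are recorded in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "derived_seeds": {"generator": config.seed, "folds": (config.seed * 7919 + 1) % 2**31},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "versions": _versions(),
        "stages": {},
        "outputs": {},
    }
    stage = "setup"
    try:
        stage = "cohort"
        t0 = time.perf_counter()
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            params = _generator_params(config)
            cohort = sample_cohort(params)
            write_cohort(cohort, out / "cohort.csv")
        _log_stage(manifest, stage, t0)

        stage = "descriptives"
        t0 = time.perf_counter()
        summary = summarize_cohort(cohort)
        (out / "cohort_summary.json").write_text(summary.to_json())
        for var, frame in summary.to_frames().items():
            frame.to_csv(out / f"summary_{var}.csv", index=False)
        transition = gleason_transition(cohort)
        transition.to_frame().to_csv(out / "gleason_transition.csv")
        (out / "gleason_transition.json").write_text(transition.to_json())
        pd.DataFrame([transition.overall_percentages()]).assign(
            discordance=transition.discordance_percentage(), n_excluded=transition.n_excluded
        ).to_csv(out / "gleason_transition_overall.csv", index=False)
        _log_stage(manifest, stage, t0)

        stage = "cross_validation"
        t0 = time.perf_counter()
        folds = assign_folds(cohort, k=config.k_folds, seed=manifest["derived_seeds"]["folds"])
        prediction_sets = []
        for family in config.families:
            spec = ModelSpec(
                family=family, hyperparameters=config.hyperparameters.get(family, {})
            )
            prediction_sets.append(cross_validated_predictions(cohort, spec, folds))
        for predictor in config.univariate:
            prediction_sets.append(univariate_predictions(cohort, predictor, folds))
        for preds in prediction_sets:
            write_predictions(preds, out / f"predictions_{preds.model}.csv")
        _log_stage(manifest, stage, t0)

        stage = "discrimination"
        t0 = time.perf_counter()
        reports = [
            discrimination_report(p, config.threshold_rule, config.fixed_threshold)
            for p in prediction_sets
        ]
        table3 = pd.DataFrame({r.model: r.as_dict() for r in reports})
        table3.to_csv(out / "discrimination.csv")
        _log_stage(manifest, stage, t0)

        stage = "calibration"
        t0 = time.perf_counter()
        curves = {}
        omitted = {}
        for preds in prediction_sets:
            try:
                curve = loess_calibration(
                    preds,
                    span=config.loess_span,
                    degree=config.loess_degree,
                    n_bins=config.n_bins,
                )
            except DegeneratePredictionsError as exc:
                omitted[preds.model] = str(exc)
                continue
            curves[preds.model] = curve
            curve.to_frame().to_csv(out / f"calibration_curve_{preds.model}.csv", index=False)
            curve.bins.to_csv(out / f"calibration_bins_{preds.model}.csv", index=False)
        manifest["stages"].setdefault("calibration_omitted", omitted)
        _log_stage(manifest, stage, t0)

        stage = "decision_curves"
        t0 = time.perf_counter()
        dcurves = [decision_curve(p) for p in prediction_sets]
        pd.concat(
            [c.to_frame().assign(panel=c.model) for c in dcurves], ignore_index=True
        ).to_csv(out / "decision_curves.csv", index=False)
        _log_stage(manifest, stage, t0)

        stage = "partin"
        if config.partin_table:
            t0 = time.perf_counter()
            table = load_partin_table(config.partin_table)
            rows = {}
            excluded = {}
            for cstage in table.stages:
                sub = cohort[cohort["clinical_stage"] == cstage]
                if len(sub) == 0:
                    continue
                preds, n_exc = partin_predict(sub, table, outcome=config.partin_outcome)
                excluded[cstage] = n_exc
                if len(np.unique(preds.label)) == 2:
                    rep = discrimination_report(preds, config.threshold_rule)
                    rows[f"partin_{cstage}"] = rep.as_dict()
            n_uncovered = int((~cohort["clinical_stage"].isin(table.stages)).sum())
            if rows:
                pd.DataFrame(rows).to_csv(out / "partin_discrimination.csv")
            manifest["stages"]["partin_excluded"] = {"uncovered_stage": n_uncovered, **excluded}
            _log_stage(manifest, "partin", t0)
        else:
            manifest["stages"]["partin"] = "skipped (no table configured)"

        if config.plots:
            stage = "plots"
            t0 = time.perf_counter()
            _render_plots(out, curves, dcurves, config)
            _log_stage(manifest, stage, t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _log_stage(manifest: dict, stage: str, t0: float) -> None:
    elapsed = time.perf_counter() - t0
    manifest["stages"][stage] = f"{elapsed:.2f}s"
    logger.info("stage %s finished in %.2fs", stage, elapsed)


def _versions() -> dict:
    import matplotlib
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _render_plots(out: Path, curves: dict, dcurves: list, config: RunConfig) -> None:
    """Best-effort figures; numeric CSVs remain the contract surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if curves:
        ncol = min(3, len(curves))
        nrow = -(-len(curves) // ncol)
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.5 * nrow), squeeze=False)
        for ax, (model, curve) in zip(axes.flat, curves.items()):
            ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
            ax.plot(curve.grid, curve.smoothed, color="tab:blue", label="loess")
            b = curve.bins
            ax.errorbar(
                b["mean_predicted"],
                b["observed_fraction"],
                yerr=np.maximum(
                    [
                        b["observed_fraction"] - b["ci_low"],
                        b["ci_high"] - b["observed_fraction"],
                    ],
                    0.0,
                ),
                fmt="o",
                ms=3,
                color="tab:red",
                lw=0.8,
            )
            ax.set(title=model, xlabel="predicted probability", ylabel="observed probability")
            ax.set_xlim(0, 1)
            ax.set_ylim(0, 1)
        for ax in axes.flat[len(curves):]:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(out / "calibration.png", dpi=120)
        plt.close(fig)

    if dcurves:
        multi = [c for c in dcurves if not c.model.startswith("univariate")]
        uni = [c for c in dcurves if c.model.startswith("univariate")]
        panels = [p for p in (("models", multi), ("univariate", uni)) if p[1]]
        fig, axes = plt.subplots(1, len(panels), figsize=(6 * len(panels), 4), squeeze=False)
        for ax, (title, group) in zip(axes.flat, panels):
            ref = group[0]
            ax.plot(ref.grid, ref.treat_all, color="grey", label="treat all")
            ax.axhline(0.0, color="black", lw=0.8, label="treat none")
            for c in group:
                ax.plot(c.grid, c.model_nb, label=c.model)
            ax.set(
                title=title, xlabel="threshold probability", ylabel="net benefit"
            )
            ax.set_ylim(-0.05, max(0.35, ref.treat_all.max() + 0.05))
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "decision_curves.png", dpi=120)
        plt.close(fig)
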