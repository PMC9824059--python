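"""End-to-end experiment runner.

Chains the stages: simulate (or read) recordings -> axis mapping and
ankle-anchored stride segmentation -> per-location feature matrices ->
optional sensor-location comparison (ANOVA / Tukey) -> ENET and mRMR
selection profiling under LOSO -> incremental feature curves and Kneedle
subset choice -> selector comparison (best AUC at fewest features) -> LOSO
evaluation of the top classifiers -> sliding-window post-processing curve.
All numeric tables are written as CSV together with the generating config
and seed, and a rerun with the same config reproduces them bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .errors import InvalidConfigError
from .features import FeatureMatrix, build_feature_matrix
from .location import location_auc_distributions, location_comparison_tables
from .modeling import (
    ModelSpec,
    default_model_specs,
    run_loso_evaluation,
)
from .postprocess import postprocess_curve, report_to_per_subject
from .segmentation import detect_heel_strikes, map_axes, segment_strides
from .selection import (
    ENETConfig,
    KneeCurve,
    incremental_feature_curve,
    kneedle_knee,
    loso_selection_profile,
)
from .simulate import (
    ANKLE,
    LOCATIONS,
    default_cohort_config,
    simulate_cohort,
)

log = logging.getLogger("gaitsurface")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "gaitsurface_run"
    seed: int = 0
    n_subjects: int = 12
    input_dir: str | None = None  # read recording CSVs instead of simulating
    compare_locations: bool = True
    select_features: bool = True
    train_models: bool = True
    postprocess: bool = True
    models: tuple[str, ...] = ("SVM", "RF", "LR", "ADA", "XGB")
    n_top_models: int = 3
    n_search_iterations: int = 20
    cv_folds: int = 5
    cv_repeats: int = 5
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    kneedle_sensitivity: float = 1.0
    # elastic-net search grids (None = module defaults); exposed so reduced
    # runs can trade grid resolution for speed
    enet_alpha_grid: tuple[float, ...] | None = None
    enet_lambda_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidConfigError("n_subjects must be >= 2")
        if any(k < 1 for k in self.k_values):
            raise InvalidConfigError("k_values must be >= 1")
        if self.cv_folds < 2 or self.cv_repeats < 1:
            raise InvalidConfigError("invalid CV configuration")
        from .modeling import MODEL_NAMES

        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise InvalidConfigError(f"unknown models {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise InvalidConfigError(f"unknown config keys {sorted(unknown)}")
        raw = dict(raw)
        for key in ("models", "k_values", "enet_alpha_grid", "enet_lambda_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InvalidConfigError("config file must hold a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        d["k_values"] = list(self.k_values)
        for key in ("enet_alpha_grid", "enet_lambda_grid"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def enet_config(self) -> ENETConfig:
        kw = {"seed": self.seed}
        if self.enet_alpha_grid is not None:
            kw["alpha_grid"] = self.enet_alpha_grid
        if self.enet_lambda_grid is not None:
            kw["lambda_grid"] = self.enet_lambda_grid
        return ENETConfig(**kw)


@dataclass
class RunReport:
    """Artifacts of a pipeline run (also written under ``outdir``)."""

    config: RunConfig
    features_by_location: dict[str, FeatureMatrix]
    anova_table: pd.DataFrame | None = None
    tukey_table: pd.DataFrame | None = None
    profiles: dict[str, dict[str, int]] = field(default_factory=dict)
    knee_curves: dict[str, dict[str, KneeCurve]] = field(default_factory=dict)
    chosen_subsets: dict[str, list[str]] = field(default_factory=dict)
    winning_method: str | None = None
    final_features: list[str] | None = None
    loso_reports: dict[str, object] = field(default_factory=dict)
    postprocess_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _timed(name: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.1f s", name, time.perf_counter() - self.t0)

    return _T()


def load_or_simulate(config: RunConfig):
    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.csv"))
        recs = [gio.read_recording_csv(p) for p in paths]
        if not recs:
            raise InvalidConfigError(f"no recording CSVs in {config.input_dir}")
        return recs
    cohort_cfg = default_cohort_config(config.n_subjects, config.seed)
    return simulate_cohort(cohort_cfg)


def extract_cohort_features(recordings) -> dict[str, FeatureMatrix]:
    """Per-location feature matrices, segmented from each subject's ankle AP."""
    by_subject: dict[str, dict[str, object]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, {})[rec.location] = rec
    strides_by_location: dict[str, list] = {loc: [] for loc in LOCATIONS}
    present_locations = set()
    for subject in sorted(by_subject):
        recs = by_subject[subject]
        if ANKLE not in recs:
            raise InvalidConfigError(
                f"subject {subject}: ankle recording required for segmentation"
            )
        ankle_signal = map_axes(recs[ANKLE])
        heel_strikes = detect_heel_strikes(ankle_signal)
        for loc, rec in recs.items():
            present_locations.add(loc)
            strides = segment_strides(map_axes(rec), heel_strikes)
            strides_by_location[loc].extend(strides)
    return {
        loc: build_feature_matrix(strides_by_location[loc])
        for loc in LOCATIONS
        if loc in present_locations
    }


def choose_subset(
    curves: dict[str, KneeCurve], profile_order: list[str]
) -> tuple[list[str], str, float]:
    """Knee on the best-performing model's curve -> feature subset."""
    best_model = max(curves, key=lambda m: float(np.max(curves[m].y)))
    curve = curves[best_model]
    knee = kneedle_knee(curve) if len(curve.x) >= 3 else None
    n_features = int(knee) if knee is not None else int(curve.x[-1])
    auc_at = float(curve.y[np.searchsorted(curve.x, n_features)])
    return profile_order[:n_features], best_model, auc_at


def run_pipeline(config: RunConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config, features_by_location={})

    with _timed("ingest+features"):
        recordings = load_or_simulate(config)
        feats = extract_cohort_features(recordings)
        report.features_by_location = feats
        for loc, fm in feats.items():
            gio.write_feature_table(fm, outdir / f"features_{loc}.csv")
    ankle = feats[ANKLE]
    specs = [
        ModelSpec(
            name=m,
            n_search_iterations=config.n_search_iterations,
            seed=config.seed,
        )
        for m in config.models
    ]

    if config.compare_locations and len(feats) > 1:
        with _timed("location-comparison"):
            metrics = location_auc_distributions(
                feats,
                specs,
                cv_folds=config.cv_folds,
                cv_repeats=config.cv_repeats,
                seed=config.seed,
            )
            anova, tukey = location_comparison_tables(metrics)
            report.anova_table, report.tukey_table = anova, tukey
            metrics.to_frame().to_csv(outdir / "location_metrics.csv", index=False)
            anova.to_csv(outdir / "location_anova.csv", index=False)
            tukey.to_csv(outdir / "location_tukey.csv", index=False)

    final_features = None
    if config.select_features:
        with _timed("feature-selection"):
            results = {}
            for method in ("enet", "mrmr"):
                profile, _ = loso_selection_profile(
                    ankle, method, config.enet_config()
                )
                curves = incremental_feature_curve(
                    profile,
                    ankle,
                    specs,
                    cv_folds=config.cv_folds,
                    cv_repeats=config.cv_repeats,
                    seed=config.seed,
                    sensitivity=config.kneedle_sensitivity,
                )
                subset, best_model, best_auc = choose_subset(
                    curves, profile.order
                )
                results[method] = (subset, best_model, best_auc)
                report.profiles[method] = profile.counts
                report.knee_curves[method] = curves
                report.chosen_subsets[method] = subset
                pd.DataFrame(
                    sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0])),
                    columns=["feature", "count"],
                ).to_csv(outdir / f"profile_{method}.csv", index=False)
                pd.concat(
                    {
                        m: pd.DataFrame({"n_features": c.x, "auc": c.y})
                        for m, c in curves.items()
                    },
                    names=["model"],
                ).reset_index(level=0).to_csv(
                    outdir / f"curve_{method}.csv", index=False
                )
            # best metric at the fewest features wins
            report.winning_method = min(
                results, key=lambda m: (-results[m][2], len(results[m][0]))
            )
            final_features = results[report.winning_method][0]
            report.final_features = final_features
            (outdir / "selected_features.json").write_text(
                json.dumps(
                    {
                        "method": report.winning_method,
                        "features": final_features,
                    },
                    indent=1,
                )
            )

    if config.train_models:
        with _timed("loso-training"):
            ranked = _rank_models_for_final(report, config)
            for name in ranked[: config.n_top_models]:
                spec = next(s for s in specs if s.name == name)
                loso = run_loso_evaluation(ankle, spec, final_features)
                report.loso_reports[name] = loso
                pd.DataFrame(
                    [
                        {"subject": s, "auc": a}
                        for s, a in loso.per_subject_auc.items()
                    ]
                    + [
                        {"subject": "mean", "auc": loso.mean_auc},
                        {"subject": "sd", "auc": loso.sd_auc},
                    ]
                ).to_csv(outdir / f"loso_{name}.csv", index=False)
                loso.predictions.to_csv(
                    outdir / f"predictions_{name}.csv", index=False
                )

    if config.postprocess and report.loso_reports:
        with _timed("postprocess"):
            for name, loso in report.loso_reports.items():
                table = postprocess_curve(
                    report_to_per_subject(loso), config.k_values
                )
                report.postprocess_tables[name] = table
                table.to_csv(outdir / f"postprocess_{name}.csv", index=False)

    provenance = {"config": config.to_dict(), "seed": config.seed}
    (outdir / "run.json").write_text(json.dumps(provenance, indent=1))
    return report


def _rank_models_for_final(report: RunReport, config: RunConfig) -> list[str]:
    """Order models by their best incremental-curve AUC (winning method)."""
    if report.winning_method and report.knee_curves:
        curves = report.knee_curves[report.winning_method]
        return sorted(
            curves, key=lambda m: -float(np.max(curves[m].y))
        )
    return list(config.models)
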