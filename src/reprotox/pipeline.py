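"""End-to-end orchestration: generate/ingest → filter → tune → repeated CV
→ confidence → LOAEL stratification → external validation → applicability
domain, with every artifact written to a run directory and a manifest
recording seeds, thresholds and the probability-model deviations that the
package documents (MCC denominator, LDA posterior, absolute-value
confidence, consensus N⁺=3 boundary).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from reprotox import __version__
from reprotox.chemspace import compare_distance_distributions, distance_report, fit_pc_model
from reprotox.confidence import bin_by_confidence, confidence_accuracy_trend, confidence_records
from reprotox.dataio import (
    join_dataset,
    read_descriptor_table,
    read_label_table,
    write_descriptor_table,
    write_label_table,
    write_metrics_report,
    write_predictions,
)
from reprotox.evaluation import (
    MODEL_ORDER,
    external_validate,
    loael_stratified_sensitivity,
    run_repeated_cv,
)
from reprotox.feature_filter import filter_descriptors
from reprotox.learners import DEFAULT_GRIDS, QUICK_GRIDS
from reprotox.synthetic_data import default_study_config, generate_study
from reprotox.tuning import tune_all

__all__ = ["RunConfig", "run_pipeline"]

EQUATION_NOTES = [
    "MCC uses the standard Matthews denominator sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).",
    "LDA probability is the two-class posterior (sigmoid of the discriminant).",
    "Prediction confidence is |prob-0.5|/0.5 so both classes map into [0,1].",
    "Consensus N+=3 yields label negative with probability 0.5 (confidence 0).",
]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run.

    File inputs (descriptor/label paths) and the synthetic generator are
    alternatives: when paths are absent, a synthetic study is generated.
    """

    descriptors: Optional[str] = None
    labels: Optional[str] = None
    external_descriptors: Optional[str] = None
    external_labels: Optional[str] = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    zero_fraction: float = 0.90
    entropy_threshold: float = 2.5
    bins: int = 20
    importance_threshold: float = 0.2
    importance_iterations: int = 500
    folds: int = 5
    iterations: int = 500
    tuning_repeats: int = 5
    tuning_fraction: float = 0.8
    quick_grids: bool = False
    loael_cutoff: float = 100.0
    variance_target: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.importance_iterations < 1:
            raise ValueError("iteration counts must be at least 1")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not (0.0 < self.zero_fraction < 1.0):
            raise ValueError("zero_fraction must lie in (0, 1)")
        if self.bins < 2:
            raise ValueError("bins must be at least 2")
        if not (0.0 < self.variance_target <= 1.0):
            raise ValueError("variance_target must lie in (0, 1]")
        if self.loael_cutoff <= 0:
            raise ValueError("loael_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_or_generate(config: RunConfig):
    if config.descriptors and config.labels:
        train = join_dataset(
            read_descriptor_table(config.descriptors), read_label_table(config.labels)
        )
        external = None
        if config.external_descriptors and config.external_labels:
            external = join_dataset(
                read_descriptor_table(config.external_descriptors),
                read_label_table(config.external_labels),
            )
        return train, external, None
    study = generate_study(default_study_config(seed=config.seed, **config.synthetic))
    return study.train, study.external, study


def run_pipeline(config: RunConfig, out_dir: str | Path, log=print) -> Path:
    """Execute every stage and write all reports under ``out_dir``.

    Any stage error aborts with the stage name; partial outputs are kept
    next to a FAILED marker naming the stage and cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "equation_notes": EQUATION_NOTES,
        "stages": {},
    }
    stage = "setup"
    t_start = time.time()

    def done(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}
        log(f"[{name}] done in {manifest['stages'][name]['seconds']}s")

    try:
        stage, t0 = "ingest", time.time()
        train, external, study = _load_or_generate(config)
        write_descriptor_table(train.table, out / "train_descriptors.csv")
        write_label_table(train.label_table(), out / "train_labels.csv")
        if external is not None:
            write_descriptor_table(external.table, out / "external_descriptors.csv")
            write_label_table(external.label_table(), out / "external_labels.csv")
        done(stage, t0, n_train=train.n_chemicals, n_positive=train.n_positive,
             n_external=external.n_chemicals if external is not None else 0)

        stage, t0 = "filter", time.time()
        filtered, report, profile = filter_descriptors(
            train,
            zero_fraction_threshold=config.zero_fraction,
            entropy_threshold=config.entropy_threshold,
            n_bins=config.bins,
            importance_threshold=config.importance_threshold,
            iterations=config.importance_iterations,
            folds=config.folds,
            seed=config.seed,
        )
        (out / "filter_report.json").write_text(json.dumps({
            "kept": list(report.kept),
            "removed": report.removed,
            "thresholds": report.thresholds,
        }, indent=2) + "\n")
        done(stage, t0, n_kept=len(report.kept), n_removed=len(report.removed))

        stage, t0 = "tune", time.time()
        grids = QUICK_GRIDS if config.quick_grids else DEFAULT_GRIDS
        specs, tuning = tune_all(
            filtered, grids=grids, seed=config.seed,
            fraction=config.tuning_fraction, repeats=config.tuning_repeats, folds=config.folds,
        )
        (out / "tuning.json").write_text(json.dumps({
            alg: {
                "chosen": res.chosen, "mean_mccs": list(res.mean_mccs),
                "settings": [dict(s) for s in res.settings],
                "tied_indices": list(res.tied_indices),
            } for alg, res in tuning.items()
        }, indent=2, default=str) + "\n")
        done(stage, t0)

        stage, t0 = "crossval", time.time()
        cv = run_repeated_cv(
            filtered, specs, iterations=config.iterations, folds=config.folds, seed=config.seed
        )
        agg = cv.aggregate()
        write_metrics_report({
            "seed": config.seed,
            "config_hash": manifest["config_hash"],
            "iterations": config.iterations,
            "aggregate": {
                model: {f"{m}_{s}": agg.loc[model, (s, m)] for s in ("mean", "sd")
                        for m in agg["mean"].columns}
                for model in agg.index
            },
            "per_iteration": cv.per_iteration,
        }, out / "cv_metrics.json")
        write_predictions(cv.predictions, out / "cv_predictions.csv")
        done(stage, t0)

        stage, t0 = "confidence", time.time()
        conf_payload = {}
        for model in MODEL_ORDER:
            profile_c = bin_by_confidence(confidence_records(cv, model))
            entry = {"bins": profile_c.table}
            try:
                trend = confidence_accuracy_trend(profile_c)
                entry["weighted_rank_correlation"] = trend.weighted_rank_correlation
                entry["sparse_bins"] = list(trend.sparse_bins)
            except ValueError:
                # all predictions in one confidence bin: trend undefined
                entry["weighted_rank_correlation"] = None
                entry["sparse_bins"] = []
            conf_payload[model] = entry
        write_metrics_report(conf_payload, out / "confidence.json")
        done(stage, t0)

        stage, t0 = "loael", time.time()
        strat = loael_stratified_sensitivity(cv, filtered, cutoff=config.loael_cutoff)
        write_predictions(strat, out / "loael_sensitivity.csv")
        done(stage, t0)

        if external is not None:
            stage, t0 = "extval", time.time()
            ext_filtered = external.select_descriptors(filtered.table.descriptor_names)
            ext = external_validate(filtered, ext_filtered, specs)
            write_metrics_report({"metrics": ext.metrics}, out / "external_metrics.json")
            write_predictions(ext.predictions, out / "external_predictions.csv")
            done(stage, t0)

            stage, t0 = "adomain", time.time()
            pc = fit_pc_model(filtered.table, variance_target=config.variance_target)
            rep = distance_report(pc, filtered.table, ext_filtered.table)
            cmp_res = compare_distance_distributions(rep)
            write_predictions(rep.table, out / "centroid_distances.csv")
            (out / "adomain.json").write_text(json.dumps({
                "n_components": pc.n_components,
                "cumulative_variance": pc.cumulative_variance,
                "median_train": cmp_res.median_train,
                "median_external": cmp_res.median_external,
                "p_value": cmp_res.p_value,
                "external_farther": bool(cmp_res.external_farther),
            }, indent=2) + "\n")
            done(stage, t0, n_components=pc.n_components)

        manifest["total_seconds"] = round(time.time() - t_start, 2)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc!r}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
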