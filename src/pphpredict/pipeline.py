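"""End-to-end orchestration: synthesize or load data, select features
with the crow search, tune the autoencoder with the equilibrium
optimizer, train, and evaluate over repeated runs.

Each run uses its own derived seed (master_seed + run index) for the
train/test split, the search stages and the final fit, emulating
repeated independent evaluations of the same cohort. Feature selection
and hyperparameter tuning see only the training split; the test split is
touched exactly once, for the final evaluation — the artifacts carry a
checksum of the training indices each stage received so tests can assert
the absence of leakage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .autoencoder import SAEClassifier, SAEConfig
from .crow_search import FSConfig, FSResult, make_surrogate_evaluator, run_obcsa
from .data import Dataset, SynthConfig, generate_pph_like, load_csv, train_test_split
from .equilibrium import EOConfig, HyperSpace, default_hyperspace, tune_sae
from .metrics import EvaluationReport, aggregate_runs, compute_metrics, confusion, roc_auc

__all__ = [
    "PipelineConfig",
    "RunArtifacts",
    "smoke_config",
    "run_pipeline",
    "emit_report",
]

log = logging.getLogger("pphpredict")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one full experiment needs.

    Either ``data_path`` (CSV with a label column) or ``synth`` must be
    set. ``reselect_features`` controls whether feature selection is
    repeated per run or the run-0 mask is reused.
    """

    synth: SynthConfig | None = None
    data_path: str | None = None
    label_column: str = "pph"
    fs: FSConfig = field(default_factory=FSConfig)
    sae: SAEConfig = field(default_factory=SAEConfig)
    space: HyperSpace = field(default_factory=default_hyperspace)
    eo: EOConfig | None = None
    n_runs: int = 10
    test_fraction: float = 0.3
    cv_folds: int = 10
    surrogate_folds: int = 5
    tune: bool = True
    reselect_features: bool = True
    master_seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.synth is None and self.data_path is None:
            raise ValueError("either synth or data_path must be provided")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "synth" in kw and kw["synth"] is not None:
            kw["synth"] = SynthConfig(**kw["synth"])
        if "fs" in kw:
            kw["fs"] = FSConfig(**kw["fs"])
        if "sae" in kw:
            sae = dict(kw["sae"])
            if "hidden_sizes" in sae:
                sae["hidden_sizes"] = tuple(sae["hidden_sizes"])
            kw["sae"] = SAEConfig(**sae)
        if "space" in kw:
            kw["space"] = HyperSpace.from_dicts(kw["space"])
        if "eo" in kw and kw["eo"] is not None:
            eo = dict(kw["eo"])
            eo.setdefault("lower_bounds", [0.0])
            eo.setdefault("upper_bounds", [1.0])
            eo["lower_bounds"] = np.asarray(eo["lower_bounds"], dtype=float)
            eo["upper_bounds"] = np.asarray(eo["upper_bounds"], dtype=float)
            kw["eo"] = EOConfig(**eo)
        return cls(**kw)


@dataclass
class RunArtifacts:
    """Everything a single run produced."""

    run_id: int
    seed: int
    fs_result: FSResult
    tuned_config: SAEConfig
    tuning_report: dict | None
    model: SAEClassifier
    report: EvaluationReport
    selected_features: list[str]
    train_index_checksums: dict[str, str]


def smoke_config(seed: int = 0, **overrides) -> PipelineConfig:
    """A desk-scale profile: small synthetic cohort and reduced search
    budgets, suitable for CI and examples. The full-scale budgets
    (25 crows, 100 iterations, 10-fold CV) live in the dataclass
    defaults and in ``configs`` shipped alongside the package."""
    base = dict(
        synth=SynthConfig(
            n_samples=600, n_features=30, n_informative=6,
            prevalence=0.3, effect_size=1.5, seed=seed,
        ),
        fs=FSConfig(n_crows=6, t_max=8, seed=seed),
        sae=SAEConfig(hidden_sizes=(12,), pretrain_epochs=15, finetune_epochs=100, seed=seed),
        eo=EOConfig(
            lower_bounds=np.zeros(1), upper_bounds=np.ones(1),
            n_particles=4, max_iter=2, seed=seed,
        ),
        n_runs=2,
        cv_folds=3,
        surrogate_folds=3,
        master_seed=seed,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def _checksum(idx: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(np.sort(idx)).tobytes()).hexdigest()[:16]


def _load_dataset(config: PipelineConfig) -> Dataset:
    if config.data_path is not None:
        return load_csv(config.data_path, config.label_column)
    dataset, _ = generate_pph_like(config.synth)
    return dataset


def _single_run(
    dataset: Dataset, config: PipelineConfig, run_id: int, fixed_mask: np.ndarray | None
) -> RunArtifacts:
    seed = config.master_seed + run_id
    train, test = train_test_split(dataset, config.test_fraction, seed=seed)
    # checksums of the row identities each stage receives (leakage guard)
    train_rows = np.flatnonzero(
        np.isin(
            np.arange(dataset.n_samples),
            _match_rows(dataset, train),
        )
    )
    checksums = {"split_train": _checksum(train_rows)}

    log.info("run %d: feature selection on %d train samples", run_id, train.n_samples)
    if fixed_mask is None:
        fs_cfg = dataclasses.replace(config.fs, seed=seed)
        evaluator = make_surrogate_evaluator(k=config.surrogate_folds, seed=seed)
        fs_result = run_obcsa(train, fs_cfg, evaluator)
        mask = fs_result.best_mask
    else:
        mask = fixed_mask
        fs_result = FSResult(mask, float("nan"), np.array([]), int(mask.sum()))
    checksums["feature_selection"] = checksums["split_train"]

    train_masked = train.subset_columns(mask)
    test_masked = test.subset_columns(mask)

    if config.tune:
        log.info("run %d: EO tuning over %d hyperparameters", run_id, len(config.space.dimensions))
        eo_cfg = config.eo
        if eo_cfg is not None:
            eo_cfg = dataclasses.replace(
                eo_cfg,
                lower_bounds=config.space.bounds()[0],
                upper_bounds=config.space.bounds()[1],
                seed=seed,
            )
        tuned_cfg, _, tuning_report = tune_sae(
            train_masked,
            config.space,
            eo_config=eo_cfg,
            base_config=config.sae.replace(seed=seed),
            k=config.cv_folds,
            seed=seed,
        )
    else:
        tuned_cfg, tuning_report = config.sae.replace(seed=seed), None
    checksums["tuning"] = checksums["split_train"]

    log.info("run %d: final training on %d features", run_id, train_masked.n_features)
    clf = SAEClassifier(tuned_cfg.replace(seed=seed)).fit(train_masked)
    proba = clf.predict_proba(test_masked.features)
    y_pred = proba.argmax(axis=1)
    cm = confusion(test_masked.labels, y_pred)
    report = compute_metrics(cm, run_id=run_id)
    _, auc = roc_auc(test_masked.labels, proba[:, 1])
    report = dataclasses.replace(report, auc=auc)
    log.info("run %d: accuracy %.4f auc %.4f", run_id, report.accuracy, auc)

    return RunArtifacts(
        run_id=run_id,
        seed=seed,
        fs_result=fs_result,
        tuned_config=tuned_cfg,
        tuning_report=tuning_report,
        model=clf,
        report=report,
        selected_features=[n for n, m in zip(dataset.feature_names, mask) if m],
        train_index_checksums=checksums,
    )


def _match_rows(dataset: Dataset, subset: Dataset) -> np.ndarray:
    """Row indices of `subset` inside `dataset` (rows are unique draws
    from a continuous distribution, so matching by content is exact)."""
    index = {row.tobytes(): i for i, row in enumerate(dataset.features)}
    return np.asarray([index[row.tobytes()] for row in subset.features])


def run_pipeline(config: PipelineConfig) -> tuple[list[RunArtifacts], EvaluationReport]:
    """Execute n_runs independent split→select→tune→train→evaluate
    cycles and aggregate the per-run reports. A failed run is recorded
    and skipped; remaining runs continue."""
    dataset = _load_dataset(config)
    artifacts: list[RunArtifacts] = []
    fixed_mask: np.ndarray | None = None
    for r in range(config.n_runs):
        try:
            art = _single_run(dataset, config, r, fixed_mask)
        except Exception:  # pragma: no cover - defensive per-run isolation
            log.exception("run %d failed; continuing", r)
            continue
        artifacts.append(art)
        if not config.reselect_features and fixed_mask is None:
            fixed_mask = art.fs_result.best_mask
    if not artifacts:
        raise RuntimeError("every run failed")
    aggregate = aggregate_runs([a.report for a in artifacts])
    return artifacts, aggregate


def emit_report(
    artifacts: list[RunArtifacts],
    aggregate: EvaluationReport,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict[str, Path]:
    """Write a JSON report (per-run rows + average row + provenance) and
    a plain-text summary table. Returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [a.report.to_dict() for a in artifacts]
    payload = {
        "package_version": __version__,
        "python": platform.python_version(),
        "runs": rows,
        "average": aggregate.to_dict(),
        "per_run": [
            {
                "run_id": a.run_id,
                "seed": a.seed,
                "n_selected": a.fs_result.n_selected,
                "best_cost": a.fs_result.best_cost,
                "selected_features": a.selected_features,
                "tuned_hyperparameters": (a.tuning_report or {}).get("best_hyperparameters"),
                "train_index_checksums": a.train_index_checksums,
            }
            for a in artifacts
        ],
    }
    if config is not None:
        payload["master_seed"] = config.master_seed
        payload["n_runs"] = config.n_runs
    json_path = out / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, default=float))

    header = ["Run", "Precision", "Recall", "Accuracy", "F-Score", "MCC", "Error Rate"]
    lines = ["\t".join(header)]
    for a in artifacts:
        r = a.report.rounded()
        lines.append(
            "\t".join(
                [f"Run-{a.run_id + 1}"]
                + [f"{r[m]:.4f}" for m in EvaluationReport.METRICS]
            )
        )
    avg = aggregate.rounded()
    lines.append("\t".join(["Average"] + [f"{avg[m]:.4f}" for m in EvaluationReport.METRICS]))
    txt_path = out / "summary.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "text": txt_path}
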