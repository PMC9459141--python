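"""End-to-end orchestration: data -> selection -> models -> fusion -> reports.

One global seed fans out to per-stage seeds through a fixed offset scheme
(documented in :data:`STAGE_SEED_OFFSETS`), so any stage can be rerun in
isolation with unchanged randomness. A run directory receives the feature
table, the selection report, both trained models, the per-case fusion CSV
and one evaluation report per arm (SVM, RF, reader-JR, reader-SR,
SVM+RF+JR, SVM+RF+SR), plus a manifest with the config hash and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import predict_proba, split_cohort, train_rf, train_svm
from .evaluate import compare_auc, evaluate_arm
from .fusion import fuse_cohort
from .selection import select_features
from .synthetic import (
    JUNIOR_READER,
    SENIOR_READER,
    CohortConfig,
    ReaderProfile,
    gen_feature_table,
    gen_reader_calls,
)
from .tables import read_feature_table, write_feature_table

STAGE_SEED_OFFSETS = {
    "data": 1, "readers": 2, "split": 3, "select": 4, "svm": 5, "rf": 6,
}

ARMS = ("svm", "rf", "reader_jr", "reader_sr", "svm_rf_jr", "svm_rf_sr")


@dataclass
class PipelineConfig:
    """Everything a full run needs; validates eagerly.

    ``table_path`` loads an existing feature-table CSV (with ``label`` and
    optional reader columns); otherwise a synthetic cohort is generated
    from ``cohort``. Reader verdict columns absent from the input are
    simulated from the reader profiles.
    """

    seed: int = 0
    table_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    junior_reader: ReaderProfile = JUNIOR_READER
    senior_reader: ReaderProfile = SENIOR_READER
    test_fraction: float = 0.25
    val_fraction: float = 0.2
    icc_threshold: float = 0.8
    screen_alpha: float = 0.05
    screen_require_both: bool = False
    n_lambda: int = 60
    lasso_repeats: int = 10
    lasso_folds: int = 10
    c_grid: tuple = tuple(10.0**k for k in range(-2, 4))
    gamma_grid: tuple = tuple(10.0**k for k in range(-4, 2))
    n_estimators_grid: tuple = (10, 100, 1000)
    cv_folds: int = 10
    scoring: str = "accuracy"
    fusion_threshold: float = 0.5
    ci_method: str = "exact"

    def __post_init__(self) -> None:
        if self.table_path is not None and not Path(self.table_path).exists():
            raise FileNotFoundError(f"input table not found: {self.table_path}")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer")

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) * 10 + STAGE_SEED_OFFSETS[stage]

    def content_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        for key in ("junior_reader", "senior_reader"):
            if key in raw:
                raw[key] = ReaderProfile(**raw[key])
        for key in ("c_grid", "gamma_grid", "n_estimators_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return PipelineConfig(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _load_or_generate(config: PipelineConfig) -> pd.DataFrame:
    if config.table_path is not None:
        table = read_feature_table(config.table_path)
    else:
        table, _ = gen_feature_table(
            CohortConfig(**{**asdict(config.cohort),
                            "seed": config.stage_seed("data")})
        )
    labels = table["label"].to_numpy()
    rseed = config.stage_seed("readers")
    if "reader_jr" not in table.columns:
        table["reader_jr"] = gen_reader_calls(labels, config.junior_reader, rseed)
    if "reader_sr" not in table.columns:
        table["reader_sr"] = gen_reader_calls(labels, config.senior_reader, rseed + 1)
    return table


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write all artifacts to ``outdir``.

    Returns the manifest dict. Stages run in the fixed order
    data -> split -> selection -> training -> fusion -> evaluation; any
    stage failure is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": int(config.seed),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGE_SEED_OFFSETS},
        "version": __version__,
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)

    try:
        stage("data")
        table = _load_or_generate(config)
        write_feature_table(table, outdir / "feature_table.csv")

        stage("split")
        reader_cols = ["reader_jr", "reader_sr"]
        model_table = table.drop(columns=reader_cols)
        train, val, test = split_cohort(
            model_table, config.test_fraction, config.val_fraction,
            seed=config.stage_seed("split"),
        )

        stage("select")
        # selection on the train+validation pool, never the test rows
        pool = pd.concat([train, val])
        report = select_features(
            pool,
            alpha=config.screen_alpha,
            require_both=config.screen_require_both,
            n_folds=config.lasso_folds,
            n_repeats=config.lasso_repeats,
            n_lambda=config.n_lambda,
            seed=config.stage_seed("select"),
        )
        with open(outdir / "selection.json", "w") as fh:
            json.dump(_jsonable(report.to_dict()), fh, indent=1)
        selected = list(report.selected)
        if not selected:
            raise RuntimeError("selection retained no features")
        cols = selected + ["label"]

        stage("train")
        svm = train_svm(
            train[cols], C_grid=config.c_grid, gamma_grid=config.gamma_grid,
            n_folds=config.cv_folds, seed=config.stage_seed("svm"),
            scoring=config.scoring,
        )
        rf = train_rf(
            train[cols], n_estimators_grid=config.n_estimators_grid,
            n_folds=config.cv_folds, seed=config.stage_seed("rf"),
            scoring=config.scoring,
        )
        svm.save(outdir / "model_svm.joblib")
        rf.save(outdir / "model_rf.joblib")

        stage("fuse")
        results = {}
        for split_name, part in (("validation", val), ("test", test)):
            if len(part) == 0:
                continue
            idx = part.index
            labels = part["label"].to_numpy()
            p_svm = predict_proba(svm, part[cols])
            p_rf = predict_proba(rf, part[cols])
            v_jr = table.loc[idx, "reader_jr"].to_numpy()
            v_sr = table.loc[idx, "reader_sr"].to_numpy()
            fj = fuse_cohort(p_svm, p_rf, v_jr, config.fusion_threshold)
            fs = fuse_cohort(p_svm, p_rf, v_sr, config.fusion_threshold)
            pd.DataFrame({
                "p_svm": p_svm, "p_rf": p_rf,
                "reader_jr": v_jr, "reader_sr": v_sr,
                "s_mlad_jr": fj["s_mlad"], "s_mlad_sr": fs["s_mlad"],
                "call_jr": fj["call"], "call_sr": fs["call"],
                "label": labels,
            }).to_csv(outdir / f"fusion_{split_name}.csv", index=False,
                      float_format="%.17g")
            results[split_name] = {
                "labels": labels,
                "scores": {
                    "svm": p_svm, "rf": p_rf,
                    "reader_jr": v_jr.astype(float),
                    "reader_sr": v_sr.astype(float),
                    "svm_rf_jr": fj["s_mlad"], "svm_rf_sr": fs["s_mlad"],
                },
                "calls": {
                    "reader_jr": v_jr, "reader_sr": v_sr,
                    "svm_rf_jr": fj["call"], "svm_rf_sr": fs["call"],
                },
            }

        stage("evaluate")
        evaluation: dict = {}
        for split_name, r in results.items():
            labels = r["labels"]
            split_eval = {}
            for arm in ARMS:
                rep = evaluate_arm(
                    r["scores"][arm], labels,
                    threshold=config.fusion_threshold,
                    calls=r["calls"].get(arm),
                    ci_method=config.ci_method,
                )
                rep.comparisons = {
                    f"vs_{other}": compare_auc(
                        r["scores"][arm], r["scores"][other], labels
                    )
                    for other in ARMS if other != arm
                }
                split_eval[arm] = rep.to_dict()
            evaluation[split_name] = split_eval
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(_jsonable(evaluation), fh, indent=1)

        manifest["selected_features"] = selected
        manifest["lasso_lambda"] = report.lasso_lambda
        manifest["svm_hyperparameters"] = svm.hyperparameters
        manifest["rf_hyperparameters"] = rf.hyperparameters
        manifest["arms"] = list(ARMS)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=1, sort_keys=True)
        return manifest
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "init"
        raise RuntimeError(f"pipeline failed at stage '{failed}': {exc}") from exc
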