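"""End-to-end orchestration: ingest -> ledger commit -> normalize -> feature
selection -> tuned classifier -> macro metric report.

The pipeline is a pure function of (data, config, seed) apart from
timestamps: one global seed fans out to per-stage seeds via stable hashing
of stage names, so each stage is individually reproducible.  Normalization
statistics, feature selection and hyperparameter tuning only ever see the
training and validation splits — test rows are touched exactly once, for the
final report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from . import abigru, mcoa, shoa
from .ledger import Ledger, append_record, verify_chain
from .metrics import ClassMetricsReport, macro_report
from .preprocessing import apply_zscore, fit_normalizer
from .synthdata import SynthSpec, generate_hd_like
from .table import FeatureMask, FeatureTable

logger = logging.getLogger("swarmdx.pipeline")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "StageError",
    "derive_seed",
    "stratified_split",
    "run_pipeline",
]


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed below 2**31, stable across runs and platforms."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Everything a run needs; ``synth`` is used unless ``data_path`` is set."""

    synth: SynthSpec = field(default_factory=SynthSpec)
    data_path: str | None = None
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    # feature selection
    fs_pop_size: int = 24
    fs_max_iter: int = 100
    fs_alpha: float = 0.99
    # hyperparameter tuning
    tune_pop_size: int = 6
    tune_max_iter: int = 4
    tune_epochs: int = 15
    tuning_metric: str = "precision"
    dol_enabled: bool = True
    # final training
    train_epochs: int = 200
    dropout: float = 0.5
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        synth = doc.pop("synth", None)
        cfg = cls(**{**doc, "fractions": tuple(doc.get("fractions", (0.6, 0.2, 0.2)))})
        if synth:
            cfg.synth = SynthSpec(**{**synth, "informative_idx": tuple(synth.get("informative_idx", (0, 2, 7, 9))), "effect_sizes": tuple(synth.get("effect_sizes", (3.0, -2.5, 2.0, 2.5)))})
        return cfg


@dataclass
class RunReport:
    selected_features: list[str]
    tuned_hyperparams: dict
    metrics: ClassMetricsReport
    ledger_verified: bool
    n_train: int
    n_val: int
    n_test: int
    config_echo: dict
    timings: dict = field(default_factory=dict)

    def to_json(self, include_timings: bool = False) -> str:
        doc = {
            "selected_features": self.selected_features,
            "tuned_hyperparams": {
                k: (round(v, 10) if isinstance(v, float) else v)
                for k, v in self.tuned_hyperparams.items()
            },
            "metrics": json.loads(self.metrics.to_json()),
            "ledger_verified": self.ledger_verified,
            "splits": {"train": self.n_train, "val": self.n_val, "test": self.n_test},
            "config": self.config_echo,
        }
        if include_timings:
            doc["timings"] = self.timings
        return json.dumps(doc, indent=2, sort_keys=True)


def stratified_split(
    table: FeatureTable, fractions: tuple[float, float, float], seed: int
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Disjoint, exhaustive train/val/test split preserving class
    proportions within one sample per split."""
    from sklearn.model_selection import train_test_split

    f_tr, f_val, f_te = fractions
    counts = {v: int(np.sum(table.y == v)) for v in np.unique(table.y)}
    if any(c < 3 for c in counts.values()) and 0 < f_te:
        raise ValueError(f"each class needs >= 3 members for a 3-way split, got {counts}")
    idx = np.arange(table.n_rows)
    if f_val + f_te == 0:
        return table, table.subset_rows(idx[:0]), table.subset_rows(idx[:0])
    idx_tr, idx_rest = train_test_split(
        idx, test_size=f_val + f_te, stratify=table.y, random_state=seed
    )
    if f_te == 0:
        idx_val, idx_te = idx_rest, idx[:0]
    elif f_val == 0:
        idx_val, idx_te = idx[:0], idx_rest
    else:
        idx_val, idx_te = train_test_split(
            idx_rest,
            test_size=f_te / (f_val + f_te),
            stratify=table.y[idx_rest],
            random_state=seed,
        )
    return table.subset_rows(idx_tr), table.subset_rows(idx_val), table.subset_rows(idx_te)


def _table_digest_bytes(table: FeatureTable) -> bytes:
    df = table.X.copy()
    df["__label__"] = table.y
    return df.to_csv(index=False, lineterminator="\n").encode("utf-8")


def _with_columns(table: FeatureTable, Xnew: np.ndarray) -> FeatureTable:
    import pandas as pd

    return FeatureTable(
        pd.DataFrame(Xnew, columns=table.feature_names), table.y.copy(), table.positive
    )


def _concat(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    import pandas as pd

    return FeatureTable(
        pd.concat([a.X, b.X], ignore_index=True),
        np.concatenate([a.y, b.y]),
        a.positive,
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage in order and return the reproducible run report."""
    timings: dict[str, float] = {}
    ledger = Ledger()

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.3fs", name, timings[name])

        return _Timer()

    with stage("ingest"):
        if config.data_path:
            table = FeatureTable.from_csv(config.data_path)
        else:
            table = generate_hd_like(config.synth).table

    with stage("ledger-commit-input"):
        append_record(ledger, _table_digest_bytes(table))

    with stage("split"):
        train_t, val_t, test_t = stratified_split(
            table, config.fractions, derive_seed(config.seed, "split")
        )

    with stage("normalize"):
        stats = fit_normalizer(train_t.values(), feature_names=train_t.feature_names)
        train_n = _with_columns(train_t, apply_zscore(train_t.values(), stats))
        val_n = _with_columns(val_t, apply_zscore(val_t.values(), stats))
        test_n = _with_columns(test_t, apply_zscore(test_t.values(), stats))

    with stage("select-features"):
        d = train_n.n_features
        fs_cfg = shoa.SHOAConfig(
            bounds=[(-4.0, 4.0)] * d,
            pop_size=config.fs_pop_size,
            max_iter=config.fs_max_iter,
            seed=derive_seed(config.seed, "shoa-fs"),
        )
        fs_spec = shoa.FSFitnessSpec(
            error_estimator=shoa.knn_cv_error(train_n, seed=derive_seed(config.seed, "fs-cv")),
            n_total=d,
            alpha=config.fs_alpha,
            beta=1.0 - config.fs_alpha,
        )
        fs_result = shoa.select_features(train_n, fs_cfg, fs_spec)
        mask = fs_result.mask
        logger.info("selected %d/%d features: %s", mask.selected_count, d, mask.selected_names())

    with stage("tune"):
        coa_cfg = mcoa.COAConfig(
            bounds=[(0.0, 1.0)],
            pop_size=config.tune_pop_size,
            max_iter=config.tune_max_iter,
            seed=derive_seed(config.seed, "mcoa-tune"),
            dol_enabled=config.dol_enabled,
        )
        tune = mcoa.tune_abigru(
            mcoa.default_space(),
            train_n.select_columns(mask),
            val_n.select_columns(mask),
            coa_cfg,
            metric=config.tuning_metric,
            epochs=config.tune_epochs,
            train_seed=derive_seed(config.seed, "tune-train"),
        )

    with stage("final-train"):
        fit_table = _concat(train_n, val_n).select_columns(mask)
        train_cfg = abigru.TrainConfig(
            learning_rate=tune.best_params["learning_rate"],
            epochs=config.train_epochs,
            dropout=tune.best_params.get("dropout", config.dropout),
            batch_size=int(tune.best_params["batch_size"]),
            seed=derive_seed(config.seed, "final-train"),
        )
        model = abigru.ABiGRUModel.initialize(
            n_features=mask.selected_count,
            hidden_size=int(tune.best_params["hidden_size"]),
            seed=derive_seed(config.seed, "final-init"),
        )
        abigru.train(model, fit_table, train_cfg)

    with stage("evaluate"):
        _, predicted = abigru.predict(model, test_n.select_columns(mask))
        report_metrics = macro_report(test_t.y, predicted)

    with stage("ledger-commit-report"):
        append_record(ledger, report_metrics.to_json().encode("utf-8"))
        verified, _ = verify_chain(ledger)

    report = RunReport(
        selected_features=mask.selected_names(),
        tuned_hyperparams=tune.best_params,
        metrics=report_metrics,
        ledger_verified=verified,
        n_train=train_t.n_rows,
        n_val=val_t.n_rows,
        n_test=test_t.n_rows,
        config_echo={
            "seed": config.seed,
            "fractions": list(config.fractions),
            "tuning_metric": config.tuning_metric,
            "dol_enabled": config.dol_enabled,
        },
        timings=timings,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json(include_timings=True), encoding="utf-8")
        (out / "report.txt").write_text(report_metrics.to_text() + "\n", encoding="utf-8")
        ledger.save(out / "ledger.jsonl")
        model.save_json(out / "model.json")
    return report
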