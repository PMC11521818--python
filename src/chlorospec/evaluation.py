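"""Evaluation statistics, train/validation splits and pipeline orchestration.

The five statistics reported for every model and stage are

    R2   = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RMSE = sqrt( sum (y_i - yhat_i)^2 / n )          [ug/g]
    MAE  = (1/n) sum |yhat_i - y_i|                  [ug/g]
    MBD  = (1/n) sum (y_i - yhat_i)                  [ug/g, positive = under-prediction]
    MSPE = (1/n) sum (y_i - yhat_i)^2                [(ug/g)^2]

so MSPE = RMSE^2 identically and RMSE >= MAE >= |MBD| for any input.

Two split schemes are provided: the deterministic "every third record to
validation" rule used for the single-index calibrations (540 records give
exactly 180 validation samples) and a seeded random split used for the
machine-learning models.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.random import default_rng
from scipy.stats import linregress

from . import __version__
from .band_selection import CollinearityReport, collinearity
from .errors import ConfigurationError, FitError, InputError, SplitError, ZeroVarianceError
from .indices import FeatureTable, IndexCatalog, compute_feature_table
from .models import ModelSpec, fit_model, predict
from .mrmr import DiscretizationConfig, MRMRRanking, mrmr_rank
from .synthetic import GeneratorConfig, SpectraSet, generate_dataset

__all__ = [
    "MetricsBundle",
    "SplitSpec",
    "RunReport",
    "metrics",
    "split_every_third",
    "split_random",
    "simple_linear_calibration",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsBundle:
    """R2, RMSE, MAE, MBD and MSPE for one model and stage."""

    r2: float
    rmse: float
    mae: float
    mbd: float
    mspe: float

    def to_dict(self) -> dict:
        return asdict(self)


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsBundle:
    """The five evaluation statistics for measured vs estimated chlorophyll.

    Raises ZeroVarianceError when the measured values have no variance; the
    exception carries the other four statistics in ``.partial``.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise InputError("y_true and y_pred must have equal length")
    n = y_true.size
    if n < 2:
        raise InputError("need n >= 2")
    diff = y_true - y_pred
    mspe = float((diff**2).mean())
    rmse = math.sqrt(mspe)
    mae = float(np.abs(diff).mean())
    mbd = float(diff.mean())
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    if sst == 0:
        raise ZeroVarianceError(
            "R2 undefined: zero variance in reference values",
            partial={"rmse": rmse, "mae": mae, "mbd": mbd, "mspe": mspe},
        )
    r2 = 1.0 - float((diff**2).sum()) / sst
    return MetricsBundle(r2=r2, rmse=rmse, mae=mae, mbd=mbd, mspe=mspe)


def split_every_third(dataset: Sequence) -> tuple[list, list]:
    """Every third record (positions 3, 6, 9, ...) goes to validation.

    Order is preserved within each part; the two parts are disjoint and
    exhaustive, and validation size is exactly floor(n/3).
    """
    items = list(dataset)
    if len(items) < 3:
        raise SplitError("need at least 3 records")
    validation = items[2::3]
    training = [x for i, x in enumerate(items) if (i + 1) % 3 != 0]
    return training, validation


@dataclass(frozen=True)
class SplitSpec:
    """Validation-split scheme: deterministic every-third or seeded random."""

    scheme: str = "random"
    fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("every_third", "random"):
            raise ConfigurationError("scheme must be 'every_third' or 'random'")
        if self.scheme == "random" and not (0.0 < self.fraction < 1.0):
            raise ConfigurationError("fraction must be in (0, 1)")


def split_random(dataset: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Seeded shuffle, then split at the configured validation fraction.

    Validation size is floor(n * fraction), clipped so both parts keep at
    least one record.
    """
    if spec.scheme != "random":
        raise ConfigurationError("split_random requires a random SplitSpec")
    items = list(dataset)
    n = len(items)
    if n < 2:
        raise SplitError("need at least 2 records")
    n_val = int(math.floor(n * spec.fraction))
    n_val = min(max(n_val, 1), n - 1)
    order = default_rng(spec.seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    training = [items[i] for i in range(n) if i not in val_idx]
    validation = [items[i] for i in sorted(val_idx)]
    return training, validation


def split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Train/validation row indices under either scheme."""
    train, val = (
        split_every_third(range(n)) if spec.scheme == "every_third" else split_random(range(n), spec)
    )
    return np.array(train, dtype=int), np.array(val, dtype=int)


def simple_linear_calibration(index_values: np.ndarray, chlorophyll: np.ndarray):
    """Least-squares line of chlorophyll on one index.

    Returns (slope, intercept, r) with the Pearson correlation signed, as
    single-index calibrations are conventionally reported.
    """
    x = np.asarray(index_values, dtype=float).ravel()
    y = np.asarray(chlorophyll, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise InputError("need equal-length vectors with n >= 3")
    if np.std(x) == 0:
        raise FitError("zero variance in index values")
    res = linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunReport:
    """End-to-end pipeline output: per-model metrics and the supporting reports."""

    config: dict
    seed: int
    software_version: str
    model_metrics: dict          # model -> {"training": {...}, "testing": {...}}
    mrmr: dict                   # feature -> importance, in rank order
    collinearity: dict           # feature -> {tolerance, vif, flagged}
    index_calibrations: dict     # index -> {slope, intercept, r, validation: metrics}
    selected_features: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "software_version": self.software_version,
            "seed": self.seed,
            "config": self.config,
            "selected_features": self.selected_features,
            "mrmr": self.mrmr,
            "collinearity": self.collinearity,
            "index_calibrations": self.index_calibrations,
            "model_metrics": self.model_metrics,
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    def metrics_frame(self) -> pd.DataFrame:
        """Model x stage table of the five statistics (report layout)."""
        rows = []
        for model, stages in self.model_metrics.items():
            for stage in ("training", "testing"):
                rows.append({"model": model, "stage": stage, **stages[stage]})
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.metrics_frame().to_csv(path, index=False, encoding="utf-8")


DEFAULT_PIPELINE_CONFIG: dict = {
    "schema_version": 1,
    "seed": 42,
    "generator": {},             # GeneratorConfig overrides, or {"spectra_csv": path}
    "ml_split": {"scheme": "random", "fraction": 1.0 / 3.0},
    "index_split": {"scheme": "every_third"},
    "models": list(
        ("robust_linear", "stepwise_linear", "svm_quadratic", "svm_fine_gaussian", "gpr_matern52", "trilayer_nn")
    ),
    "mrmr": {"n_bins": 10, "scheme": "quotient"},
    "drop_zero_importance": True,
}


def _load_config(config) -> dict:
    if isinstance(config, dict):
        user = dict(config)
    else:
        with open(config, "r", encoding="utf-8") as fh:
            text = fh.read()
        user = yaml.safe_load(text) or {}
    merged = {**DEFAULT_PIPELINE_CONFIG, **user}
    for key in ("generator", "ml_split", "index_split", "mrmr"):
        merged[key] = {**DEFAULT_PIPELINE_CONFIG.get(key, {}), **(user.get(key) or {})}
    return merged


def _spectra_from_config(cfg: dict, seed: int) -> SpectraSet:
    gen = dict(cfg.get("generator") or {})
    path = gen.pop("spectra_csv", None)
    if path:
        return SpectraSet.from_csv(path)
    gen.setdefault("seed", seed)
    return generate_dataset(GeneratorConfig(**gen))


def run_pipeline(config=None) -> RunReport:
    """Execute the full workflow and return a reproducible RunReport.

    Stages: generate or load spectra -> compute the eleven-index feature
    table -> collinearity screen -> MRMR ranking (zero-importance features
    dropped by default) -> single-index calibrations on the every-third
    split -> seeded random train/test split -> fit every configured model ->
    five statistics per model and stage.  Identical config (and seed) gives
    a byte-identical JSON report.
    """
    cfg = _load_config(config or {})
    seed = int(cfg["seed"])

    spectra = _spectra_from_config(cfg, seed)
    table = compute_feature_table(spectra, IndexCatalog())
    if table.target is None or np.isnan(table.target).any():
        raise InputError("pipeline requires labelled spectra")

    col_report: CollinearityReport = collinearity(table)
    ranking: MRMRRanking = mrmr_rank(
        table,
        config=DiscretizationConfig(n_bins=int(cfg["mrmr"].get("n_bins", 10))),
        scheme=cfg["mrmr"].get("scheme", "quotient"),
    )

    if cfg.get("drop_zero_importance", True):
        keep = [f for f, imp in zip(ranking.ordered_features, ranking.importance) if imp > 0]
    else:
        keep = list(ranking.ordered_features)
    if not keep:
        raise FitError("MRMR left no informative features")
    ml_table = table.select(keep)

    # Single-index calibrations on the deterministic every-third split.
    index_split = SplitSpec(**{"seed": seed, **cfg["index_split"]})
    tr_idx, va_idx = split_indices(table.n_samples, index_split)
    index_cal = {}
    for name in table.feature_names:
        x = table.column(name)
        slope, intercept, r = simple_linear_calibration(x[tr_idx], table.target[tr_idx])
        val_pred = slope * x[va_idx] + intercept
        index_cal[name] = {
            "slope": slope,
            "intercept": intercept,
            "r": r,
            "validation": metrics(table.target[va_idx], val_pred).to_dict(),
        }

    # ML models on the seeded random split.
    ml_split = SplitSpec(**{"seed": seed, **cfg["ml_split"]})
    tr_idx, te_idx = split_indices(ml_table.n_samples, ml_split)
    X_tr, X_te = ml_table.values[tr_idx], ml_table.values[te_idx]
    y_tr, y_te = ml_table.target[tr_idx], ml_table.target[te_idx]

    model_metrics = {}
    for preset in cfg["models"]:
        spec = ModelSpec(preset, seed=seed)
        logger.info("fitting %s on %d training samples", preset, len(tr_idx))
        model = fit_model(X_tr, y_tr, spec)
        model_metrics[preset] = {
            "training": metrics(y_tr, predict(model, X_tr)).to_dict(),
            "testing": metrics(y_te, predict(model, X_te)).to_dict(),
        }

    return RunReport(
        config=cfg,
        seed=seed,
        software_version=__version__,
        model_metrics=model_metrics,
        mrmr={f: float(i) for f, i in zip(ranking.ordered_features, ranking.importance)},
        collinearity={
            name: {"tolerance": float(t), "vif": float(v), "flagged": bool(fl)}
            for name, t, v, fl in zip(
                col_report.feature_names, col_report.tolerance, col_report.vif, col_report.flags
            )
        },
        index_calibrations=index_cal,
        selected_features=keep,
    )
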