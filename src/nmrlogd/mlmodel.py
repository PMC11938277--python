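"""Gradient-Boosting logD regression with 10-fold cross-validation.

The estimator is scikit-learn's ``GradientBoostingRegressor``; this module
owns the evaluation protocol around it: seeded shuffled 10-fold CV with
out-of-fold predictions collected for every compound exactly once, pooled
and per-fold RMSE, the three normalized-RMSE variants

    NRMSE(mean)  = RMSE / ȳ
    NRMSE(range) = RMSE / (y_max − y_min)
    NRMSE(sd)    = RMSE / σ

absolute-error summaries mirroring boxplot statistics, and an
information-free negative control built by replacing every feature vector
with a deterministic hash of its compound id (a shortcut-learning /
leakage check: a model trained on such vectors can do no better than
predicting the label mean).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .chemio import DataError

logger = logging.getLogger("nmrlogd")

N_FOLDS = 10

#: Gradient-Boosting defaults; every run records the params it used.
DEFAULT_GB_PARAMS: dict = {}


@dataclass
class Dataset:
    """Feature matrix + one (parameter, pH) slice of logD labels."""

    X: np.ndarray
    y: np.ndarray
    compound_ids: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise DataError("feature matrix must be 2-D")
        if len(self.X) != len(self.y) or len(self.y) != len(self.compound_ids):
            raise DataError(
                f"row mismatch: {len(self.X)} features, {len(self.y)} labels, "
                f"{len(self.compound_ids)} ids")
        if not np.all(np.isfinite(self.X)):
            raise DataError("missing/non-finite feature values")

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_frames(cls, features: pd.DataFrame, labels: pd.Series,
                    source: str = "") -> "Dataset":
        """Join an id-indexed feature frame with an id-indexed label slice."""
        common = [cid for cid in features.index if cid in labels.index]
        if not common:
            raise DataError("no compound ids shared between features and labels")
        return cls(X=features.loc[common].to_numpy(),
                   y=labels.loc[common].to_numpy(dtype=float),
                   compound_ids=list(common), source=source)


@dataclass
class LabelStats:
    """Summary statistics of a label vector (the NRMSE denominators)."""

    mean: float
    range: float
    sd: float

    @classmethod
    def of(cls, y) -> "LabelStats":
        y = np.asarray(y, dtype=float)
        return cls(mean=float(y.mean()), range=float(y.max() - y.min()),
                   sd=float(y.std(ddof=0)))


@dataclass
class EvalReport:
    """Cross-validation results for one model configuration."""

    source: str
    rmse: float                       # pooled over out-of-fold predictions
    fold_rmse: list[float]
    nrmse_mean: float
    nrmse_range: float
    nrmse_sd: float
    mae_mean: float
    mae_median: float
    abs_error_quartiles: tuple[float, float, float]
    n_outliers: int                   # |error| beyond Q3 + 1.5 IQR
    label_stats: LabelStats
    seed: int
    gb_params: dict
    predictions: pd.DataFrame = field(repr=False)  # compound_id, y_true, y_pred, fold

    def to_json(self, path: str) -> None:
        d = asdict(self)
        d["predictions"] = self.predictions.to_dict(orient="list")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, default=float)


def rmse(y, yhat) -> float:
    """Root-mean-square error √(mean((ŷ_i − y_i)²))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) == 0 or len(y) != len(yhat):
        raise DataError(f"rmse: bad lengths {len(y)} vs {len(yhat)}")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def nrmse(rmse_value: float, stats: LabelStats, mode: str = "sd") -> float:
    """Normalized RMSE: divide by the label mean, range, or SD.

    Normalization makes models trained on differently scaled label sets
    comparable — e.g. Chrom logD labels span roughly twice the range of
    CHI logD, so raw RMSEs differ about two-fold while NRMSEs align.
    """
    # |mean| for the mean variant: a label scale is sign-free
    denom = {"mean": abs(stats.mean), "range": stats.range,
             "sd": stats.sd}.get(mode)
    if denom is None:
        raise ValueError(f"unknown NRMSE mode {mode!r}")
    if denom <= 0:
        raise DataError(f"degenerate label set: NRMSE({mode}) denominator {denom}")
    return float(rmse_value / denom)


def train_gb(train: Dataset, params: dict | None = None,
             seed: int = 0) -> GradientBoostingRegressor:
    """Fit a Gradient-Boosting regressor; deterministic under ``seed``."""
    if len(train) < 2:
        raise DataError("need at least 2 training rows")
    if np.ptp(train.y) == 0:
        logger.warning("train_gb: constant labels; model will predict the constant")
    model = GradientBoostingRegressor(random_state=int(seed),
                                      **(params or DEFAULT_GB_PARAMS))
    model.fit(train.X, train.y)
    return model


def cross_validate_10cv(data: Dataset, params: dict | None = None,
                        seed: int = 0, n_folds: int = N_FOLDS) -> EvalReport:
    """Seeded shuffled k-fold CV (k = 10) with pooled out-of-fold metrics.

    Every compound is predicted exactly once, by the model that did not
    see it; the headline RMSE pools those out-of-fold predictions (the
    per-fold RMSEs are also reported).
    """
    if len(data) < n_folds:
        raise DataError(
            f"{len(data)} rows < {n_folds} folds; reduce n_folds for tiny sets")
    params = dict(params or DEFAULT_GB_PARAMS)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    oof = np.full(len(data), np.nan)
    fold_of = np.full(len(data), -1)
    fold_rmses = []
    for fold, (tr, te) in enumerate(kf.split(data.X)):
        model = GradientBoostingRegressor(random_state=int(seed), **params)
        model.fit(data.X[tr], data.y[tr])
        pred = model.predict(data.X[te])
        oof[te] = pred
        fold_of[te] = fold
        fold_rmses.append(rmse(data.y[te], pred))
    assert not np.any(np.isnan(oof))
    pooled = rmse(data.y, oof)
    stats = LabelStats.of(data.y)
    abs_err = np.abs(oof - data.y)
    q1, q2, q3 = np.percentile(abs_err, [25, 50, 75])
    preds = pd.DataFrame({"compound_id": data.compound_ids, "y_true": data.y,
                          "y_pred": oof, "fold": fold_of})
    return EvalReport(
        source=data.source,
        rmse=pooled,
        fold_rmse=fold_rmses,
        nrmse_mean=nrmse(pooled, stats, "mean"),
        nrmse_range=nrmse(pooled, stats, "range"),
        nrmse_sd=nrmse(pooled, stats, "sd"),
        mae_mean=float(abs_err.mean()),
        mae_median=float(q2),
        abs_error_quartiles=(float(q1), float(q2), float(q3)),
        n_outliers=int(np.sum(abs_err > q3 + 1.5 * (q3 - q1))),
        label_stats=stats,
        seed=int(seed),
        gb_params=params,
        predictions=preds,
    )


def save_model(model: GradientBoostingRegressor, path: str,
               params: dict | None = None, seed: int = 0) -> None:
    """Persist a fitted model with the params and seed that produced it."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"model": model, "params": dict(params or DEFAULT_GB_PARAMS),
                     "seed": int(seed)}, fh)


def load_model(path: str) -> tuple[GradientBoostingRegressor, dict, int]:
    import pickle

    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    return blob["model"], blob["params"], blob["seed"]


def _hash_vector(compound_id: str, seed: int, n: int) -> np.ndarray:
    """Deterministic pseudo-random unit-interval vector from an id hash."""
    digest = hashlib.blake2b(f"{compound_id}|{seed}".encode(),
                             digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big"))
    return rng.random(n)


def hashed_label_control(data: Dataset, seed: int = 0) -> Dataset:
    """Information-free negative control: features replaced by id hashes.

    Each compound's feature vector becomes a deterministic pseudo-random
    vector derived from hashing its compound id with the seed, rescaled
    to the original matrix's value range; labels are untouched.  By
    construction the features carry no information about the labels, so
    cross-validated RMSE should approach the label standard deviation.
    The input dataset is not modified.
    """
    lo, hi = float(data.X.min()), float(data.X.max())
    span = hi - lo if hi > lo else 1.0
    n_feat = data.X.shape[1]
    Xc = np.vstack([lo + span * _hash_vector(cid, seed, n_feat)
                    for cid in data.compound_ids])
    return Dataset(X=Xc, y=data.y.copy(), compound_ids=list(data.compound_ids),
                   source="hashed_control")
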