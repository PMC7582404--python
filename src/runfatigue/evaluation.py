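"""Cross-validated performance, sensor-ablation importance, per-joint models.

Metrics follow the study convention: coefficient of determination (R²) and
root mean squared error (RMSE) of the final integer RPE predictions, five
folds, reported as mean (sd) across folds.

Two fold schemes are provided. ``shuffled`` (default) draws random folds
stratified by RPE level; because neighbouring strides land in train and test
it measures within-session interpolation, which is the regime the study's
very high scores correspond to. ``blocked`` holds out contiguous time blocks
and is the honest extrapolation benchmark; expect visibly lower scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .features import FeatureMatrix
from .signal_io import GarmentConfig
from . import stacked_model

__all__ = [
    "UndefinedMetricError",
    "EvalResult",
    "ImportanceReport",
    "r_squared",
    "rmse",
    "cross_validate",
    "sensor_importance",
    "joint_ablation",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given inputs (e.g. R² of a constant target)."""


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 elements")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R² is undefined for a constant target")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class EvalResult:
    """Per-fold and aggregate metrics of one cross-validation run.

    Folds whose test labels are constant have NaN R² and are excluded from
    the R² aggregates (with a warning at compute time); RMSE is always
    defined.
    """

    per_fold_r2: list[float]
    per_fold_rmse: list[float]

    @property
    def n_folds(self) -> int:
        return len(self.per_fold_rmse)

    @property
    def mean_r2(self) -> float:
        return float(np.nanmean(self.per_fold_r2))

    @property
    def sd_r2(self) -> float:
        return float(np.nanstd(self.per_fold_r2, ddof=1))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.per_fold_rmse))

    @property
    def sd_rmse(self) -> float:
        return float(np.std(self.per_fold_rmse, ddof=1))

    def summary(self) -> str:
        return (
            f"R² {self.mean_r2:.2f} ({self.sd_r2:.2f}), "
            f"RMSE {self.mean_rmse:.2f} ({self.sd_rmse:.2f}) "
            f"over {self.n_folds} folds"
        )


def _fold_indices(
    labels: np.ndarray, folds: int, scheme: str, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    n = len(labels)
    idx = np.arange(n)
    if scheme == "shuffled":
        classes, counts = np.unique(labels, return_counts=True)
        if counts.min() >= folds and len(classes) > 1:
            kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            return [(tr, te) for tr, te in kf.split(idx, labels)]
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in kf.split(idx)]
    if scheme == "blocked":
        blocks = np.array_split(idx, folds)
        return [
            (np.concatenate([b for j, b in enumerate(blocks) if j != i]), blocks[i])
            for i in range(folds)
        ]
    raise ValueError("scheme must be 'shuffled' or 'blocked'")


def _contiguous_runs(sorted_idx: np.ndarray) -> list[np.ndarray]:
    if len(sorted_idx) == 0:
        return []
    cuts = np.where(np.diff(sorted_idx) > 1)[0] + 1
    return np.split(np.arange(len(sorted_idx)), cuts)


def predict_in_runs(
    model: "stacked_model.StackedFatigueModel", X: np.ndarray, test_idx: np.ndarray
) -> np.ndarray:
    """Final predictions for test rows, smoothing each contiguous run alone.

    Median voting assumes temporal adjacency; a shuffled fold's test set is
    scattered, so the filter is applied separately within each contiguous
    index run rather than across gaps.
    """
    order = np.argsort(test_idx)
    sorted_idx = test_idx[order]
    _, l2 = model.predict_raw(X[sorted_idx])
    final_sorted = np.empty(len(sorted_idx), dtype=int)
    for run in _contiguous_runs(sorted_idx):
        _, final_sorted[run] = model.finalize(l2[run])
    final = np.empty(len(test_idx), dtype=int)
    final[order] = final_sorted
    return final


def cross_validate(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    folds: int = 5,
    scheme: str = "shuffled",
    seed: int = 0,
    vote_scope: str = "session",
    **fit_kwargs,
) -> EvalResult:
    """K-fold cross-validation of the stacked model.

    Each fold fits a fresh model on the training rows and predicts the
    held-out rows. With ``vote_scope="session"`` (default) the out-of-fold
    level-2 predictions of all folds are reassembled into the session's
    temporal order and the median voting runs once over that full series —
    the continuous-monitoring reading, in which every stride's final score
    benefits from its temporal neighbours regardless of fold membership.
    ``vote_scope="fold"`` instead smooths each contiguous index run within a
    fold's own test set (no information crosses fold boundaries at voting
    time). Metrics are computed per fold on the final integer predictions.
    Fold assignment, model fits and therefore metrics are deterministic for
    a fixed seed.
    """
    if vote_scope not in ("session", "fold"):
        raise ValueError("vote_scope must be 'session' or 'fold'")
    X = features.values() if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels disagree in length")
    fold_list = _fold_indices(y, folds, scheme, seed)

    final = np.empty(len(y), dtype=int)
    if vote_scope == "session":
        oof_l2 = np.empty(len(y))
        model = None
        for k, (tr, te) in enumerate(fold_list):
            model = stacked_model.fit(X[tr], y[tr], seed=seed + k, **fit_kwargs)
            _, oof_l2[te] = model.predict_raw(X[te])
        _, final[:] = model.finalize(oof_l2)
    else:
        for k, (tr, te) in enumerate(fold_list):
            model = stacked_model.fit(X[tr], y[tr], seed=seed + k, **fit_kwargs)
            final[te] = predict_in_runs(model, X, te)

    per_r2: list[float] = []
    per_rmse: list[float] = []
    for k, (_, te) in enumerate(fold_list):
        y_te = y[te].astype(float)
        yhat = final[te]
        if np.all(y_te == y_te[0]):
            warnings.warn(
                f"fold {k}: constant test labels, R² undefined (excluded from aggregate)"
            )
            per_r2.append(float("nan"))
        else:
            per_r2.append(r_squared(y_te, yhat))
        per_rmse.append(rmse(y_te, yhat))
    return EvalResult(per_fold_r2=per_r2, per_fold_rmse=per_rmse)


@dataclass
class ImportanceReport:
    """Leave-one-sensor-out importance.

    ``relative_delta_r2[ch]`` is (R²_without_ch − R²_baseline) / R²_baseline;
    greater negative values mean greater importance of the channel.
    """

    baseline_r2: float
    r2_without: dict[str, float]
    relative_delta_r2: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.relative_delta_r2 = {
            ch: (r2 - self.baseline_r2) / self.baseline_r2
            for ch, r2 in self.r2_without.items()
        }

    def most_important(self) -> str:
        """Channel whose removal hurts most (most negative relative change)."""
        return min(self.relative_delta_r2, key=self.relative_delta_r2.get)


def sensor_importance(
    features: FeatureMatrix,
    labels: np.ndarray,
    seed: int = 0,
    folds: int = 5,
    scheme: str = "shuffled",
    **fit_kwargs,
) -> ImportanceReport:
    """Refit with each channel's 46 columns removed; report relative ΔR².

    Uses the same seed for the baseline and every ablated refit so fold
    assignment is paired across comparisons.
    """
    if len(features.channel_ids) < 2:
        raise ValueError("sensor importance needs at least 2 included channels")
    baseline = cross_validate(
        features, labels, folds=folds, scheme=scheme, seed=seed, **fit_kwargs
    )
    r2_without: dict[str, float] = {}
    for ch in features.channel_ids:
        reduced = features.drop_channel(ch)
        res = cross_validate(
            reduced, labels, folds=folds, scheme=scheme, seed=seed, **fit_kwargs
        )
        r2_without[ch] = res.mean_r2
    return ImportanceReport(baseline_r2=baseline.mean_r2, r2_without=r2_without)


def joint_ablation(
    features: FeatureMatrix,
    labels: np.ndarray,
    garment: GarmentConfig,
    joint: str,
    seed: int = 0,
    folds: int = 5,
    scheme: str = "shuffled",
    **fit_kwargs,
) -> EvalResult:
    """Cross-validate using only one joint's channels (+ stride duration)."""
    channels = [
        c.channel_id
        for c in garment.joint_channels(joint)
        if c.channel_id in features.channel_ids
    ]
    if not channels:
        raise ValueError(f"no included channels for joint {joint!r}")
    reduced = features.restrict_to_channels(channels)
    return cross_validate(
        reduced, labels, folds=folds, scheme=scheme, seed=seed, **fit_kwargs
    )
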