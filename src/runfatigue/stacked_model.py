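"""Two-level stacked random-forest RPE regressor with median-vote smoothing.

The estimator mirrors the two-step design used for garment-based exertion
estimation: a first 100-tree random forest maps per-segment features to a
continuous exertion estimate; a second 100-tree forest, trained on the first
model's held-out predictions, snaps that rough estimate onto the discrete
Borg levels the participant actually reported. Because perceived exertion
cannot change between two successive strides, the prediction series is then
smoothed by two passes of a 10-sample running median before rounding to an
integer Borg score in [6, 20].

Stacking needs level-1 predictions that the level-2 forest has not memorised.
Three modes are provided:

* ``"oob"`` (default): level-1 out-of-bag predictions — leakage-controlled
  at no extra cost;
* ``"oof"``: out-of-fold predictions from an internal K-fold split of the
  training rows (K = ``internal_folds``);
* ``"naive"``: in-sample level-1 predictions (reproduces direct stacking).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .features import FeatureMatrix
from .signal_io import RPE_MAX, RPE_MIN

__all__ = [
    "StackedFatigueModel",
    "PredictionTrace",
    "FitError",
    "median_filter",
    "round_half_away",
    "fit",
    "save_model",
    "load_model",
    "N_TREES",
    "VOTE_WINDOW",
]

N_TREES = 100
VOTE_WINDOW = 10
STACKING_MODES = ("oob", "oof", "naive")


class FitError(ValueError):
    """Training data violates the fit contract."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (platform-independent, unlike banker's)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def median_filter(
    series: np.ndarray,
    window: int = VOTE_WINDOW,
    passes: int = 2,
    mode: str = "centered",
) -> np.ndarray:
    """Running-median voting filter.

    ``centered`` places the window (nearly) symmetrically around each
    element — for even lengths one extra sample on the right — and shrinks
    it at the edges. ``trailing`` uses the causal window ending at the
    element (streaming variant). ``window == 1`` is the identity. The filter
    is non-expansive: its output range is contained in the input range.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot median-filter an empty series")
    if window < 1:
        raise ValueError("window must be at least 1")
    if mode not in ("centered", "trailing"):
        raise ValueError("mode must be 'centered' or 'trailing'")
    n = x.size
    for _ in range(passes):
        out = np.empty(n)
        for i in range(n):
            if mode == "centered":
                lo = max(0, i - (window - 1) // 2)
                hi = min(n, i + window // 2 + 1)
            else:
                lo = max(0, i - window + 1)
                hi = i + 1
            out[i] = np.median(x[lo:hi])
        x = out
    return x


@dataclass
class PredictionTrace:
    """All stages of a prediction: raw level-1/2, smoothed, final integer."""

    level1_raw: np.ndarray
    level2_raw: np.ndarray
    smoothed: np.ndarray
    final: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.level1_raw)
        if not (len(self.level2_raw) == len(self.smoothed) == len(self.final) == n):
            raise ValueError("all prediction series must have equal length")


@dataclass
class StackedFatigueModel:
    """Fitted two-level forest plus its smoothing/rounding parameters."""

    level1: RandomForestRegressor
    level2: RandomForestRegressor
    feature_names: list[str]
    seed: int
    stacking: str = "oob"
    internal_folds: int = 5
    vote_window: int = VOTE_WINDOW
    vote_passes: int = 2
    vote_mode: str = "centered"
    rpe_bounds: tuple[int, int] = (RPE_MIN, RPE_MAX)

    def _matrix(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        if isinstance(features, FeatureMatrix):
            if features.columns != self.feature_names:
                raise FitError(
                    "feature columns do not match the columns used in training"
                )
            return features.values()
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise FitError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape[1]}"
            )
        return X

    def predict_raw(
        self, features: FeatureMatrix | np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Continuous level-1 and level-2 predictions, no smoothing."""
        X = self._matrix(features)
        l1 = self.level1.predict(X)
        l2 = self.level2.predict(l1.reshape(-1, 1))
        return l1, l2

    def finalize(self, level2_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Median voting + rounding + clamping of a contiguous series."""
        smoothed = median_filter(
            level2_raw, self.vote_window, self.vote_passes, self.vote_mode
        )
        final = np.clip(round_half_away(smoothed), *self.rpe_bounds).astype(int)
        return smoothed, final

    def predict(self, features: FeatureMatrix | np.ndarray) -> PredictionTrace:
        """Full prediction of one temporally contiguous segment series."""
        l1, l2 = self.predict_raw(features)
        smoothed, final = self.finalize(l2)
        return PredictionTrace(l1, l2, smoothed, final)


def _oob_metric_stub(y_true, y_pred) -> float:
    """Stand-in OOB metric: only oob_prediction_ is wanted, not a score."""
    return 0.0


def _new_forest(seed: int) -> RandomForestRegressor:
    # randomized-subspace forest; the full-feature variant is ~8x slower at
    # these matrix widths with no accuracy gain on this task
    return RandomForestRegressor(
        n_estimators=N_TREES,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
        bootstrap=True,
    )


def fit(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    stacking: str = "oob",
    internal_folds: int = 5,
    vote_window: int = VOTE_WINDOW,
    vote_passes: int = 2,
    vote_mode: str = "centered",
) -> StackedFatigueModel:
    """Fit the two-level forest.

    The level-1 forest is fit on the full training rows. Its held-out
    predictions (per the stacking mode) become the single input column of
    the level-2 forest, fit against the same labels. Deterministic for a
    fixed seed.
    """
    if stacking not in STACKING_MODES:
        raise ValueError(f"stacking must be one of {STACKING_MODES}")
    if isinstance(features, FeatureMatrix):
        X = features.values()
        names = features.columns
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, dtype=float)
    if len(y) != len(X):
        raise FitError("features and labels disagree in length")
    if len(y) < 2 * internal_folds:
        raise FitError(
            f"need at least {2 * internal_folds} rows to fit, got {len(y)}"
        )
    if np.any((y < RPE_MIN) | (y > RPE_MAX)):
        raise FitError(f"labels must lie within [{RPE_MIN}, {RPE_MAX}]")

    rng = np.random.default_rng(seed)
    s1, s2, s_fold = (int(v) for v in rng.integers(2**31, size=3))

    if stacking == "oob":
        level1 = _new_forest(s1)
        level1.set_params(oob_score=_oob_metric_stub)
        level1.fit(X, y)
        held_out = np.asarray(level1.oob_prediction_, dtype=float)
        bad = ~np.isfinite(held_out)
        if bad.any():  # samples in every bootstrap draw (vanishingly rare)
            held_out[bad] = level1.predict(X[bad])
    elif stacking == "oof":
        held_out = np.empty(len(y))
        kf = KFold(n_splits=internal_folds, shuffle=True, random_state=s_fold)
        proto = _new_forest(s1)
        for tr, te in kf.split(X):
            m = clone(proto)
            m.fit(X[tr], y[tr])
            held_out[te] = m.predict(X[te])
        level1 = _new_forest(s1)
        level1.fit(X, y)
    else:  # naive
        level1 = _new_forest(s1)
        level1.fit(X, y)
        held_out = level1.predict(X)

    level2 = _new_forest(s2)
    level2.fit(held_out.reshape(-1, 1), y)

    return StackedFatigueModel(
        level1=level1,
        level2=level2,
        feature_names=list(names),
        seed=seed,
        stacking=stacking,
        internal_folds=internal_folds,
        vote_window=vote_window,
        vote_passes=vote_passes,
        vote_mode=vote_mode,
    )


def save_model(path: str | Path, model: StackedFatigueModel) -> None:
    """Serialize model + manifest (seed, columns, parameters) to one archive."""
    payload = {
        "manifest": {
            "seed": model.seed,
            "stacking": model.stacking,
            "internal_folds": model.internal_folds,
            "vote_window": model.vote_window,
            "vote_passes": model.vote_passes,
            "vote_mode": model.vote_mode,
            "rpe_bounds": list(model.rpe_bounds),
            "feature_names": model.feature_names,
            "n_trees": N_TREES,
        },
        "level1": model.level1,
        "level2": model.level2,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> StackedFatigueModel:
    payload = joblib.load(path)
    m = payload["manifest"]
    return StackedFatigueModel(
        level1=payload["level1"],
        level2=payload["level2"],
        feature_names=list(m["feature_names"]),
        seed=int(m["seed"]),
        stacking=m["stacking"],
        internal_folds=int(m["internal_folds"]),
        vote_window=int(m["vote_window"]),
        vote_passes=int(m["vote_passes"]),
        vote_mode=m["vote_mode"],
        rpe_bounds=tuple(m["rpe_bounds"]),
    )
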