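"""Soft-margin kernel classification of encoded sequences.

A Gaussian radial-basis-function SVM (C = 32, gamma = 2^-7 = 0.0078125 by
default) separates binding from non-binding feature vectors. Features are
linearly rescaled to [-1, 1] using per-feature extrema learned from the
training data only — standard practice for RBF kernels, and switchable off
for sensitivity checks. A linear-kernel variant is reachable through the
config but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureVector, LayoutError

DEFAULT_C = 32.0
DEFAULT_GAMMA = 0.0078125  # 2**-7

#: LIBSVM-style coarse grid: powers of two, exponent step 2.
DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SvmConfig:
    """Kernel parameters: soft-margin cost C and RBF width gamma."""

    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    kernel: str = "rbf"
    scale: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return X
    rows = [fv.values if isinstance(fv, FeatureVector) else np.asarray(fv) for fv in X]
    return np.vstack(rows)


@dataclass
class TrainedModel:
    """A fitted classifier plus the feature-scaling state and layout it was
    trained with; prediction rejects vectors of a different layout."""

    svc: SVC
    config: SvmConfig
    n_features: int
    layout: Optional[tuple[tuple[str, int], ...]] = None
    feat_min: Optional[np.ndarray] = None
    feat_max: Optional[np.ndarray] = None

    def _check_layout(self, X: np.ndarray, layout=None) -> None:
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise LayoutError(
                f"input has {X.shape[1] if X.ndim == 2 else '?'} features, "
                f"model was trained on {self.n_features}"
            )
        if layout is not None and self.layout is not None and tuple(layout) != self.layout:
            raise LayoutError(
                f"block layout {tuple(layout)} differs from training layout "
                f"{self.layout}"
            )

    def _scale(self, X: np.ndarray) -> np.ndarray:
        if self.feat_min is None:
            return X
        span = self.feat_max - self.feat_min
        span = np.where(span == 0, 1.0, span)
        return 2.0 * (X - self.feat_min) / span - 1.0

    def decision_function(self, X, layout=None) -> np.ndarray:
        X = _as_matrix(X)
        self._check_layout(X, layout)
        return self.svc.decision_function(self._scale(X))

    def predict(self, X, layout=None) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels (+1/-1, the sign of the decision value) and the
        decision values themselves (for ROC construction)."""
        scores = self.decision_function(X, layout)
        labels = np.where(scores >= 0, 1, -1)
        return labels, scores

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def train(
    X,
    y,
    config: SvmConfig = SvmConfig(),
    layout: Optional[Sequence[tuple[str, int]]] = None,
) -> TrainedModel:
    """Fit the kernel classifier on encoded vectors with labels in {+1, -1}.

    Deterministic given identical inputs and config; the learned per-feature
    min/max scaling state is stored with the model.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} rows but {len(y)} labels")
    if len(X) < 2 or len(np.unique(y)) < 2:
        raise ValueError("training requires both classes to be present")

    feat_min = feat_max = None
    Xs = X
    if config.scale:
        feat_min = X.min(axis=0)
        feat_max = X.max(axis=0)
        span = np.where(feat_max - feat_min == 0, 1.0, feat_max - feat_min)
        Xs = 2.0 * (X - feat_min) / span - 1.0

    svc = SVC(C=config.C, gamma=config.gamma, kernel=config.kernel)
    svc.fit(Xs, y)
    return TrainedModel(
        svc=svc,
        config=config,
        n_features=X.shape[1],
        layout=tuple(layout) if layout is not None else None,
        feat_min=feat_min,
        feat_max=feat_max,
    )


def grid_search(
    X,
    y,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
    scale: bool = True,
) -> SvmConfig:
    """Exhaustive cross-validated search over a (C, gamma) grid.

    Returns the pair with the highest mean CV accuracy on stratified folds;
    ties break toward smaller C, then smaller gamma.
    """
    if not C_grid or not gamma_grid:
        raise ValueError("parameter grids must be non-empty")
    X = _as_matrix(X)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    best: Optional[tuple[float, float, float]] = None  # (acc, C, gamma)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            config = SvmConfig(C=C, gamma=gamma, kernel=kernel, scale=scale)
            correct = total = 0
            for train_idx, test_idx in splits:
                model = train(X[train_idx], y[train_idx], config)
                labels, _ = model.predict(X[test_idx])
                correct += int((labels == y[test_idx]).sum())
                total += len(test_idx)
            acc = correct / total
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    assert best is not None
    return SvmConfig(C=best[1], gamma=best[2], kernel=kernel, scale=scale)
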