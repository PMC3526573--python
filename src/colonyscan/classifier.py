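"""Random-forest pixel classification of BIF-histogram features.

A forest of 20 trees with 5 candidate variables per split maps each pixel's
28-element texture descriptor to a binary label: 1 for colony (hESC), 0 for
background (including feeder fibroblasts).  The fitted model carries a
fingerprint of the feature configuration (scales, epsilon, window) and
refuses to predict on features computed under a different configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .bif import DEFAULT_EPSILON, DEFAULT_SCALES, DEFAULT_WINDOW, FeatureStack

__all__ = [
    "FeatureConfig",
    "TrainingSet",
    "ColonyClassifier",
    "train",
    "predict_mask",
]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class FeatureConfig:
    """Texture-feature configuration shared by training and prediction."""

    scales: tuple[float, ...] = DEFAULT_SCALES
    epsilon: float = DEFAULT_EPSILON
    window: int = DEFAULT_WINDOW

    @property
    def n_features(self) -> int:
        return 7 * len(self.scales)

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "scales": [float(s) for s in self.scales],
                "epsilon": float(self.epsilon),
                "window": int(self.window),
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    @classmethod
    def of(cls, fs: FeatureStack) -> "FeatureConfig":
        return cls(scales=tuple(fs.scales), epsilon=fs.epsilon, window=fs.window)


@dataclass
class TrainingSet:
    """Labelled pixel features for classifier training.

    ``features`` is N x n_features (counts), ``labels`` is N binary
    (1 = colony, 0 = background).  ``provenance`` optionally records, per
    pixel, the source image id and row/column.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels).astype(np.int8)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (N x F) array")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels lengths differ")
        if len(self.features) < 1:
            raise ValueError("training set is empty")
        if self.features.shape[1] != self.feature_config.n_features:
            raise ValueError(
                f"feature width {self.features.shape[1]} does not match "
                f"configuration ({self.feature_config.n_features})"
            )
        if not np.all(np.isfinite(self.features.astype(np.float64))):
            raise ValueError("features must be finite")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, found {sorted(bad)}")


class ColonyClassifier:
    """Fitted random-forest pixel classifier (sklearn-style fit state).

    Use :func:`train` or :meth:`fit` to build one; :meth:`predict_mask`
    turns a feature stack into a raw binary colony map by majority vote
    over the trees (probability threshold 0.5).
    """

    def __init__(
        self,
        n_trees: int = 20,
        mtry: int = 5,
        seed: int | None = 0,
        feature_config: FeatureConfig | None = None,
    ) -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = int(n_trees)
        self.mtry = int(mtry)
        self.seed = seed
        self.feature_config = feature_config or FeatureConfig()
        if not 1 <= self.mtry <= self.feature_config.n_features:
            raise ValueError(
                f"mtry must be in [1, {self.feature_config.n_features}], got {mtry}"
            )
        self._forest: RandomForestClassifier | None = None

    # -- fitting -----------------------------------------------------------
    def fit(self, data: TrainingSet) -> "ColonyClassifier":
        classes = np.unique(data.labels)
        if len(classes) < 2:
            raise ValueError(
                "training set must contain both colony and background pixels"
            )
        if data.feature_config != self.feature_config:
            raise ValueError("training-set feature configuration mismatch")
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            random_state=self.seed,
            n_jobs=1,
        )
        forest.fit(data.features.astype(np.float32), data.labels)
        self._forest = forest
        return self

    @property
    def is_fitted(self) -> bool:
        return self._forest is not None

    def _require_fitted(self) -> RandomForestClassifier:
        if self._forest is None:
            raise RuntimeError("classifier is not fitted")
        return self._forest

    # -- prediction --------------------------------------------------------
    def _check_features(self, fs: FeatureStack) -> None:
        if FeatureConfig.of(fs).fingerprint() != self.feature_config.fingerprint():
            raise ValueError(
                "feature configuration mismatch: model was trained with "
                f"{self.feature_config}, input stack has {FeatureConfig.of(fs)}"
            )

    def predict_mask(self, features: FeatureStack) -> np.ndarray:
        """Binary H x W colony map (uint8, 1 = colony)."""
        self._check_features(features)
        forest = self._require_fitted()
        h, w, _ = features.features.shape
        pred = forest.predict(features.as_table().astype(np.float32))
        return pred.reshape(h, w).astype(np.uint8)

    def predict_proba_map(self, features: FeatureStack) -> np.ndarray:
        """Per-pixel colony probability (fraction of trees voting colony)."""
        self._check_features(features)
        forest = self._require_fitted()
        h, w, _ = features.features.shape
        idx = list(forest.classes_).index(1)
        proba = forest.predict_proba(features.as_table().astype(np.float32))[:, idx]
        return proba.reshape(h, w)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "seed": self.seed,
            "feature_config": {
                "scales": list(self.feature_config.scales),
                "epsilon": self.feature_config.epsilon,
                "window": self.feature_config.window,
            },
            "fingerprint": self.feature_config.fingerprint(),
            "forest": self._require_fitted(),
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "ColonyClassifier":
        payload = joblib.load(path)
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        fc = payload["feature_config"]
        config = FeatureConfig(
            scales=tuple(fc["scales"]), epsilon=fc["epsilon"], window=fc["window"]
        )
        if config.fingerprint() != payload["fingerprint"]:
            raise ValueError("model archive fingerprint mismatch")
        model = cls(
            n_trees=payload["n_trees"],
            mtry=payload["mtry"],
            seed=payload["seed"],
            feature_config=config,
        )
        model._forest = payload["forest"]
        return model


def train(
    data: TrainingSet,
    n_trees: int = 20,
    mtry: int = 5,
    seed: int | None = 0,
) -> ColonyClassifier:
    """Fit a random forest on labelled pixel features (module-level helper)."""
    return ColonyClassifier(
        n_trees=n_trees, mtry=mtry, seed=seed, feature_config=data.feature_config
    ).fit(data)


def predict_mask(model: ColonyClassifier, features: FeatureStack) -> np.ndarray:
    """Functional alias for :meth:`ColonyClassifier.predict_mask`."""
    return model.predict_mask(features)
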