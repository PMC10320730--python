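"""Gradient-boosted-tree classification of encoded pair features.

The split-gain machinery of gradient boosting is standard, so the model is
LightGBM behind a thin, deterministic configuration surface.  Scores are
association probabilities in [0, 1]; a pair is called positive when its score
strictly exceeds the decision threshold (0.5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier

__all__ = ["ClassifierConfig", "ScoredPairs", "train_classifier", "score_pairs"]


@dataclass(frozen=True)
class ClassifierConfig:
    num_leaves: int = 31
    learning_rate: float = 0.1
    max_depth: int = -1
    feature_fraction: float = 0.9
    bagging_fraction: float = 0.9
    min_data_in_leaf: int = 20
    n_estimators: int = 100
    seed: int = 0
    decision_threshold: float = 0.5
    scale_pos_weight: float | None = None
    # passed verbatim to the underlying booster (expert escape hatch)
    extra_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.num_leaves < 2:
            raise ValueError("num_leaves must be >= 2")
        for name in ("feature_fraction", "bagging_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 < self.decision_threshold < 1):
            raise ValueError("decision_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class ScoredPairs:
    """Pair coordinates with association scores and thresholded calls."""

    pairs: np.ndarray          # (n, 2) of (microbe_index, disease_index)
    scores: np.ndarray         # association probability in [0, 1]
    predicted_labels: np.ndarray
    threshold: float


def train_classifier(
    encoded: np.ndarray, labels: np.ndarray, cfg: ClassifierConfig = ClassifierConfig()
) -> LGBMClassifier:
    """Fit a LightGBM binary classifier on encoded features.

    Requires both classes present.  Runs single-threaded and deterministic so
    repeated fits with the same seed agree.
    """
    encoded = np.asarray(encoded, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("degenerate training set: only one class present")
    params = dict(
        num_leaves=cfg.num_leaves,
        learning_rate=cfg.learning_rate,
        max_depth=cfg.max_depth,
        feature_fraction=cfg.feature_fraction,
        bagging_fraction=cfg.bagging_fraction,
        bagging_freq=1,
        min_data_in_leaf=cfg.min_data_in_leaf,
        n_estimators=cfg.n_estimators,
        random_state=cfg.seed,
        n_jobs=1,
        deterministic=True,
        force_row_wise=True,
        verbosity=-1,
    )
    if cfg.scale_pos_weight is not None:
        params["scale_pos_weight"] = cfg.scale_pos_weight
    params.update(cfg.extra_params)
    model = LGBMClassifier(**params)
    model.fit(encoded, labels)
    return model


def score_pairs(
    model: LGBMClassifier,
    encoded: np.ndarray,
    pairs: np.ndarray | None = None,
    threshold: float = 0.5,
) -> ScoredPairs:
    """Score pairs and call positives with a strict ``score > threshold``."""
    encoded = np.asarray(encoded, dtype=float)
    if encoded.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature width {encoded.shape[1]} does not match model "
            f"({model.n_features_in_})"
        )
    scores = model.predict_proba(encoded)[:, 1]
    predicted = (scores > threshold).astype(np.int8)
    if pairs is None:
        pairs = np.full((len(scores), 2), -1, dtype=int)
    return ScoredPairs(np.asarray(pairs), scores, predicted, threshold)
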