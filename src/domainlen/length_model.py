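"""Random-forest regression of domain length on overlap features.

The ensemble is 100 trees by default, each grown on a bootstrap sample with
floor(sqrt(m)) candidate features per split (m = number of features) and
variance-reduction (squared error) as the split criterion. Evaluation is
based on out-of-bag (OOB) predictions: each domain is predicted only by
trees whose bootstrap sample excluded it, giving an internal held-out
estimate of the observed-vs-predicted correlation without a separate test
split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap

from .features import FeatureMatrix

__all__ = [
    "ModelConfig",
    "FittedLengthModel",
    "fit_length_model",
    "predict",
    "observed_predicted_correlation",
]


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyperparameters; defaults match the reference configuration."""

    n_trees: int = 100
    max_features_rule: str = "sqrt"
    split_criterion: str = "squared_error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features_rule != "sqrt":
            raise ValueError("only the sqrt(m) candidate-feature rule is supported")


@dataclass
class FittedLengthModel:
    """A trained forest plus its OOB predictions on the training domains.

    ``oob_prediction`` is NaN for any domain that landed in every tree's
    bootstrap sample (possible for tiny ensembles); ``oob_defined`` flags
    the rest.
    """

    forest: RandomForestRegressor
    feature_labels: list[str]
    observed: np.ndarray
    oob_prediction: np.ndarray
    config: ModelConfig
    resub_prediction: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def oob_defined(self) -> np.ndarray:
        return ~np.isnan(self.oob_prediction)


def _max_features(m: int) -> int:
    return max(1, math.floor(math.sqrt(m)))


def _oob_predictions(forest: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    """Per-sample mean prediction over trees whose bootstrap excluded it."""
    n = X.shape[0]
    totals = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    try:
        n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    except TypeError:  # older sklearn without the sample_weight argument
        n_boot = _get_n_samples_bootstrap(n, forest.max_samples)
    for tree in forest.estimators_:
        try:
            unsampled = _generate_unsampled_indices(tree.random_state, n, n_boot, None)
        except TypeError:
            unsampled = _generate_unsampled_indices(tree.random_state, n, n_boot)
        if unsampled.size == 0:
            continue
        totals[unsampled] += tree.predict(X[unsampled])
        counts[unsampled] += 1
    with np.errstate(invalid="ignore"):
        out = totals / counts
    out[counts == 0] = np.nan
    return out


def fit_length_model(matrix: FeatureMatrix, cfg: ModelConfig | None = None) -> FittedLengthModel:
    """Fit the bootstrap forest and populate OOB predictions.

    Deterministic given ``cfg.seed``. Requires at least 2 domains and 1
    feature.
    """
    cfg = cfg or ModelConfig()
    if matrix.n_domains < 2:
        raise ValueError("need at least 2 domains to fit")
    if matrix.n_features < 1:
        raise ValueError("need at least 1 feature to fit")
    forest = RandomForestRegressor(
        n_estimators=cfg.n_trees,
        criterion=cfg.split_criterion,
        max_features=_max_features(matrix.n_features),
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(matrix.values, matrix.target)
    oob = _oob_predictions(forest, matrix.values)
    resub = forest.predict(matrix.values)
    return FittedLengthModel(
        forest=forest,
        feature_labels=list(matrix.feature_labels),
        observed=matrix.target.copy(),
        oob_prediction=oob,
        config=cfg,
        resub_prediction=resub,
    )


def predict(model: FittedLengthModel, matrix: FeatureMatrix) -> np.ndarray:
    """Ensemble-mean length predictions for new domains.

    Feature labels must match the training labels as a set; columns are
    reordered internally.
    """
    train, new = set(model.feature_labels), set(matrix.feature_labels)
    if train != new:
        missing = sorted(train - new)
        extra = sorted(new - train)
        raise ValueError(f"feature label mismatch: missing={missing}, extra={extra}")
    order = [matrix.feature_labels.index(l) for l in model.feature_labels]
    return model.forest.predict(matrix.values[:, order])


def observed_predicted_correlation(model: FittedLengthModel, basis: str = "oob") -> float:
    """Pearson correlation between observed lengths and predictions.

    ``basis`` is ``"oob"`` (default, honest internal estimate) or
    ``"resubstitution"`` (predictions on the training data itself, which
    overstates accuracy). Raises if fewer than 3 domains have defined
    predictions or either vector has zero variance.
    """
    if basis == "oob":
        mask = model.oob_defined
        pred = model.oob_prediction[mask]
        obs = model.observed[mask]
    elif basis == "resubstitution":
        pred = model.resub_prediction
        obs = model.observed
    else:
        raise ValueError(f"unknown basis {basis!r}")
    if len(obs) < 3:
        raise ValueError("need >= 3 domains with defined predictions")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("correlation undefined: zero-variance vector")
    r, _ = stats.pearsonr(obs, pred)
    return float(r)
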