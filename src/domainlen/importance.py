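"""Feature ranking by mean decrease of impurity, with contrast-attribute
significance calling.

Importance alone ranks features but says nothing about significance. The
Monte-Carlo procedure here estimates the noise floor with *contrast
attributes* — for each original feature, a random row-permutation of it is
appended to the dataset, destroying any relation to the target while
preserving the marginal distribution. The forest is refit on the augmented
matrix, the standard deviation of the contrast attributes' importance
scores sets a cutoff of 2 x SD on differences between consecutive sorted
scores, and the threshold is the larger score of the last consecutive pair
whose difference exceeds the cutoff; features scoring at or above the
threshold are called significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .length_model import FittedLengthModel, ModelConfig, fit_length_model

__all__ = [
    "ImportanceReport",
    "raw_importances",
    "add_contrast_attributes",
    "significance_threshold",
    "significant_features",
]

CONTRAST_SUFFIX = "__contrast"

#: Sentinel threshold meaning "no feature significant".
NO_THRESHOLD = math.inf


@dataclass
class ImportanceReport:
    """Per-feature importance scores and the significance call.

    ``scores`` covers the original features only (contrast columns are used
    solely for the SD); scores are normalized to sum to 1 over all original
    + contrast columns unless ``normalized`` is False.
    """

    labels: list[str]
    scores: dict[str, float]
    significant: dict[str, bool]
    contrast_sd: float
    cutoff: float
    threshold: float
    normalized: bool
    seed: int
    repeats: int = 1
    contrast_scores: dict[str, float] = field(default_factory=dict)

    @property
    def significant_labels(self) -> list[str]:
        return [l for l in self.ranked_labels() if self.significant[l]]

    def ranked_labels(self) -> list[str]:
        return sorted(self.labels, key=lambda l: -self.scores[l])

    def to_dict(self) -> dict:
        return {
            "scores": self.scores,
            "significant": self.significant,
            "significant_labels": self.significant_labels,
            "contrast_sd": self.contrast_sd,
            "cutoff": self.cutoff,
            "threshold": None if math.isinf(self.threshold) else self.threshold,
            "normalized": self.normalized,
            "seed": self.seed,
            "repeats": self.repeats,
        }


def raw_importances(model: FittedLengthModel, normalize: bool = True) -> dict[str, float]:
    """Mean decrease of impurity per feature, averaged over the ensemble.

    With ``normalize=True`` (default) each tree's impurity decreases are
    normalized to sum to 1 before averaging, so the ensemble scores sum to 1
    and features never chosen for a split score exactly 0.
    """
    if normalize:
        scores = model.forest.feature_importances_
    else:
        per_tree = [
            t.tree_.compute_feature_importances(normalize=False)
            for t in model.forest.estimators_
        ]
        scores = np.mean(per_tree, axis=0)
    return dict(zip(model.feature_labels, (float(s) for s in scores)))


def add_contrast_attributes(matrix: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Append one row-permuted copy of every feature column.

    The contrast column for feature ``x`` is labeled ``x__contrast``; the
    augmented matrix has 2m columns. Reproducible given ``seed``.
    """
    if matrix.n_features < 1:
        raise ValueError("need at least 1 feature")
    clashes = [l for l in matrix.feature_labels if l.endswith(CONTRAST_SUFFIX)]
    if clashes:
        raise ValueError(f"feature labels collide with the contrast suffix: {clashes}")
    rng = np.random.default_rng(seed)
    contrast = np.column_stack(
        [rng.permutation(matrix.values[:, j]) for j in range(matrix.n_features)]
    )
    return FeatureMatrix(
        list(matrix.domain_ids),
        list(matrix.feature_labels) + [l + CONTRAST_SUFFIX for l in matrix.feature_labels],
        np.hstack([matrix.values, contrast]),
        matrix.target.copy(),
    )


def significance_threshold(sorted_scores: np.ndarray | list[float], contrast_sd: float) -> float:
    """Threshold from the last consecutive-score gap exceeding 2 x SD.

    ``sorted_scores`` must be in descending order. Scanning consecutive
    differences, the threshold is the larger score of the LAST pair whose
    difference exceeds ``2 * contrast_sd``; when no pair qualifies the
    sentinel +inf is returned, meaning no feature is significant.
    """
    scores = np.asarray(sorted_scores, dtype=float)
    if np.any(np.diff(scores) > 0):
        raise ValueError("scores must be sorted in descending order")
    if contrast_sd < 0:
        raise ValueError("contrast_sd must be >= 0")
    cutoff = 2.0 * contrast_sd
    threshold = NO_THRESHOLD
    for i in range(len(scores) - 1):
        if scores[i] - scores[i + 1] > cutoff:
            threshold = float(scores[i])
    return threshold


def significant_features(
    matrix: FeatureMatrix,
    cfg: ModelConfig | None = None,
    seed: int = 0,
    repeats: int = 1,
    normalize: bool = True,
) -> ImportanceReport:
    """Full contrast-attribute significance pipeline.

    Augment with contrast columns, refit the forest, average importance
    scores over ``repeats`` independent permutations (1 = the literal
    single-shot procedure), take the SD over contrast scores only, and apply
    the threshold rule to the original features' sorted scores. Contrast
    columns never appear in the significant set.
    """
    cfg = cfg or ModelConfig()
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)

    orig = matrix.feature_labels
    acc = {l: 0.0 for l in orig}
    acc_contrast = {l + CONTRAST_SUFFIX: 0.0 for l in orig}
    for rep_seed in seeds:
        augmented = add_contrast_attributes(matrix, int(rep_seed))
        model = fit_length_model(
            augmented, ModelConfig(cfg.n_trees, cfg.max_features_rule,
                                   cfg.split_criterion, int(rep_seed)),
        )
        scores = raw_importances(model, normalize=normalize)
        for l in acc:
            acc[l] += scores[l]
        for l in acc_contrast:
            acc_contrast[l] += scores[l]
    scores = {l: v / repeats for l, v in acc.items()}
    contrast_scores = {l: v / repeats for l, v in acc_contrast.items()}

    contrast_sd = float(np.std(list(contrast_scores.values())))
    # The threshold scan runs over ALL columns of the augmented fit
    # (original + contrast) sorted together, as in the literal 4-step
    # procedure; only original features are ever flagged significant.
    # Scanning originals alone could not call the m=1 case (no pairs).
    all_scores = sorted(
        list(scores.values()) + list(contrast_scores.values()), reverse=True
    )
    threshold = significance_threshold(all_scores, contrast_sd)
    significant = {l: scores[l] >= threshold for l in orig}
    return ImportanceReport(
        labels=list(orig),
        scores=scores,
        significant=significant,
        contrast_sd=contrast_sd,
        cutoff=2.0 * contrast_sd,
        threshold=threshold,
        normalized=normalize,
        seed=seed,
        repeats=repeats,
        contrast_scores=contrast_scores,
    )
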