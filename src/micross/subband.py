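"""Fisher-score subband ranking and weighted optimal-band selection.

Each subband's discriminability is summarized by the Fisher score

    f_s = Tr(S_B) / Tr(S_W)

with the between-class scatter ``S_B = Σ_i n_i (m_i - m)(m_i - m)ᵀ`` and
within-class scatter ``S_W = Σ_i Σ_j (x_ij - m_i)(x_ij - m_i)ᵀ`` of that
band's feature vectors.  Because EEG band power falls with frequency, the
raw score is reweighted before the argmax:

    ξ_n = w(n) · (f_sⁿ)²,   w(n) = n^(-a) + b

so small (a, b) grids trade off a frequency-decreasing prior against a flat
one.  The grid over (a, b) is judged by inner cross-validated classification
accuracy on the candidate bands' features — the score ξ itself ranks bands
within one (a, b) but is not comparable across weightings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = [
    "SubbandScores",
    "fisher_score",
    "subband_weight",
    "weighted_scores",
    "select_optimal_band",
]

FISHER_EPS = 1e-12  # guards the within-class scatter denominator

DEFAULT_A_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)
DEFAULT_B_GRID = (0.0, 0.5, 1.0)


@dataclass
class SubbandScores:
    """Per-band Fisher scores, weights, ξ criteria and the selected bands.

    ``selected`` holds 1-based band indices, best first.
    """

    fs_scores: np.ndarray
    weights: np.ndarray
    xi: np.ndarray
    a: float
    b: float
    selected: list[int] = field(default_factory=list)
    cv_accuracy: float | None = None


def fisher_score(features: np.ndarray, labels: np.ndarray) -> float:
    """Trace ratio of between- to within-class scatter of the feature vectors."""
    X = np.atleast_2d(np.asarray(features, float))
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    m = X.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for k in classes:
        Xk = X[y == k]
        mk = Xk.mean(axis=0)
        tr_b += Xk.shape[0] * float(np.sum((mk - m) ** 2))
        tr_w += float(np.sum((Xk - mk) ** 2))
    return tr_b / (tr_w + FISHER_EPS)


def subband_weight(n: int, a: float, b: float) -> float:
    """Weight ``w(n) = n^(-a) + b`` for 1-based band index ``n``."""
    if n < 1:
        raise ValueError("band index n is 1-based")
    return float(n) ** (-a) + b


def weighted_scores(
    fs_scores: Sequence[float], a: float, b: float, k_bands: int = 1
) -> SubbandScores:
    """ξ_n = w(n) · f_sⁿ² per band; select the top ``k_bands`` (ties → lowest index)."""
    fs = np.asarray(fs_scores, float)
    n_idx = np.arange(1, fs.size + 1)
    weights = n_idx.astype(float) ** (-a) + b
    xi = weights * fs ** 2
    if np.all(fs == 0):
        warnings.warn("all Fisher scores are zero; selecting lowest band index",
                      RuntimeWarning, stacklevel=2)
    # stable sort on (-xi, index): ties resolve to the lowest band index
    order = sorted(range(fs.size), key=lambda i: (-xi[i], i))
    selected = [i + 1 for i in order[: max(1, k_bands)]]
    return SubbandScores(fs_scores=fs, weights=weights, xi=xi, a=a, b=b,
                         selected=selected)


def _inner_cv_accuracy(
    features: np.ndarray, labels: np.ndarray, seed: int, n_splits: int = 5
) -> float:
    """Stratified k-fold accuracy of a ridge classifier (the single-task
    specialization of the pipeline's multi-task linear classifier)."""
    n_min = int(min(np.sum(labels == +1), np.sum(labels == -1)))
    n_splits = max(2, min(n_splits, n_min))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = cross_val_score(RidgeClassifier(alpha=1.0), features, labels, cv=cv)
    return float(scores.mean())


def select_optimal_band(
    band_features: Sequence[np.ndarray],
    labels: np.ndarray,
    grid_a: Sequence[float] = DEFAULT_A_GRID,
    grid_b: Sequence[float] = DEFAULT_B_GRID,
    k_bands: int = 1,
    seed: int = 0,
) -> SubbandScores:
    """Grid search over (a, b): pick the weighting whose top-``k_bands`` ξ
    selection classifies best under inner cross-validation.

    ``band_features`` is one trial-by-feature matrix per subband, all over
    the same trials.  Ties in CV accuracy resolve to the lexicographically
    smallest (a, b).  The returned :class:`SubbandScores` carries the winning
    weighting, its selection and its CV accuracy.
    """
    if len(grid_a) == 0 or len(grid_b) == 0:
        raise ValueError("grids must be nonempty")
    if k_bands < 1:
        raise ValueError("k_bands must be >= 1")
    labels = np.asarray(labels)
    fs = np.array([fisher_score(F, labels) for F in band_features])

    cache: dict[tuple[int, ...], float] = {}
    best: SubbandScores | None = None
    for a, b in product(sorted(grid_a), sorted(grid_b)):
        scores = weighted_scores(fs, a, b, k_bands=k_bands)
        key = tuple(sorted(scores.selected))
        if key not in cache:
            F_sel = np.concatenate([band_features[i - 1] for i in key], axis=1)
            cache[key] = _inner_cv_accuracy(F_sel, labels, seed=seed)
        scores.cv_accuracy = cache[key]
        if best is None or scores.cv_accuracy > best.cv_accuracy:
            best = scores
    assert best is not None
    return best
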