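"""Euclidean alignment of epoched EEG.

Whitens each subject's trials by the inverse symmetric square root of the
subject's mean trial covariance, so every subject's aligned trials share the
identity as reference covariance.  This shrinks the between-subject
distribution shift that plagues cross-subject decoding, and it is label-free:
all trials (both classes, and unlabeled ones) enter the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet

__all__ = ["AlignmentResult", "mean_trial_covariance", "euclidean_align"]

#: Relative eigenvalue floor applied when inverting the reference covariance.
EIG_FLOOR = 1e-10
#: Ridge factor applied when the reference is rank-deficient.
RIDGE_EPS = 1e-8


@dataclass
class AlignmentResult:
    """Aligned trials plus the reference covariance and its inverse square root."""

    aligned: EpochSet
    reference: np.ndarray  # mean trial covariance, (c, c) SPD
    whitener: np.ndarray   # reference^(-1/2), (c, c)


def mean_trial_covariance(epochs: EpochSet) -> np.ndarray:
    """Mean over trials of the per-trial channel covariance ``X Xᵀ / n_samples``.

    Normalizing each term by the sample count makes the scale variance-like
    and independent of epoch length.  A rank-deficient mean is ridge-conditioned
    (``RIDGE_EPS * trace/c`` added to the diagonal) with a warning.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    if epochs.n_channels < 2:
        raise ValueError("need at least two channels")
    X = epochs.data
    cov = np.einsum("tcs,tds->cd", X, X) / (epochs.n_trials * epochs.n_samples)
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= EIG_FLOOR * max(eigvals[-1], 0.0):
        warnings.warn(
            "mean trial covariance is rank-deficient; applying ridge conditioning",
            RuntimeWarning,
            stacklevel=2,
        )
        cov = cov + RIDGE_EPS * (np.trace(cov) / epochs.n_channels) * np.eye(epochs.n_channels)
    return cov


def _inv_sqrt_spd(mat: np.ndarray) -> np.ndarray:
    """Principal inverse square root via symmetric eigendecomposition."""
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    if vals[-1] <= 0:
        raise np.linalg.LinAlgError("reference covariance is not positive definite")
    vals = np.maximum(vals, EIG_FLOOR * vals[-1])
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def euclidean_align(epochs: EpochSet) -> AlignmentResult:
    """Align trials so the mean trial covariance becomes the identity.

    Every trial is replaced by ``R̄^(-1/2) X_i`` where ``R̄`` is the mean
    trial covariance of the input.  Applying the operation to already-aligned
    data is a no-op (the whitener is the identity).
    """
    reference = mean_trial_covariance(epochs)
    whitener = _inv_sqrt_spd(reference)
    aligned_data = np.einsum("cd,tds->tcs", whitener, epochs.data)
    aligned = epochs.evolve(
        data=aligned_data,
        record={"op": "euclidean_align"},
    )
    return AlignmentResult(aligned=aligned, reference=reference, whitener=whitener)
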