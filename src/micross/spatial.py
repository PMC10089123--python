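"""CSP and regularized CSP spatial filtering, and per-band features.

Common Spatial Patterns (CSP) finds channel-weight vectors ``w`` extremizing
the between-class variance ratio ``wᵀC₁w / wᵀ(C₁+C₂)w`` via the generalized
eigenproblem ``C₁ w = λ (C₁+C₂) w``; eigenvalues lie in (0, 1) and the
filters with the largest and smallest λ are the most discriminative.

Regularized CSP (RCSP) replaces each class covariance with a two-parameter
regularized estimate: β mixes the (scarce) target-subject covariance with
the pooled source-subject covariance, and γ shrinks the mixture toward a
scaled identity — the classic remedy for small-sample covariance estimation:

    Ĉᵏ(β)   = [β·N_l·C̄_tᵏ + (1-β)·N_s·C̄_sᵏ] / [β·N_l + (1-β)·N_s]
    Ĉᵏ(β,γ) = (1-γ)·Ĉᵏ(β) + γ·(trace(Ĉᵏ(β))/c)·I

Per-trial covariances are trace-normalized before averaging, so trials are
commensurate across slow amplitude drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .epochs import EpochSet
from .filterbank import BandSpec, decompose

__all__ = [
    "ClassCovariances",
    "SpatialFilterModel",
    "trial_covariances",
    "class_mean_covariance",
    "csp_fit",
    "rcsp_covariance",
    "rcsp_fit",
    "logvar_features",
    "logvar_from_covariances",
    "bandpower_features",
]

#: How γ-shrinkage scales the identity: toward the average eigenvalue
#: (trace/c) of the β-mixture.  Eq-level notation for this target varies
#: across the RCSP literature; this package fixes it here, once.
SHRINKAGE_TARGET = "average-eigenvalue identity: gamma * (trace(C)/c) * I"

_VAR_FLOOR = 1e-12


@dataclass
class ClassCovariances:
    """Target- and source-domain mean covariance of one class, with trial counts."""

    C_target: np.ndarray | None
    C_source: np.ndarray | None
    n_target: int
    n_source: int
    klass: int = +1

    def __post_init__(self) -> None:
        if self.n_target < 0 or self.n_source < 0 or self.n_target + self.n_source == 0:
            raise ValueError("need a nonnegative, nonzero total trial count")


@dataclass
class SpatialFilterModel:
    """Spatial filters for one subband.

    ``W`` has ``2 * n_pairs`` columns: the ``n_pairs`` filters with the
    largest generalized eigenvalues followed by the ``n_pairs`` with the
    smallest.  Columns are scaled so ``Wᵀ(C₁+C₂)W = I`` on the kept
    subspace, and signed so each filter's largest-magnitude entry is
    positive (determinism across eigensolvers).
    """

    W: np.ndarray
    eigenvalues: np.ndarray  # full spectrum, sorted descending, in (0, 1)
    n_pairs: int
    beta: float = 1.0
    gamma: float = 0.0

    @property
    def n_filters(self) -> int:
        return self.W.shape[1]


# ---------------------------------------------------------------------------
# covariance estimation
# ---------------------------------------------------------------------------

def trial_covariances(epochs: EpochSet, normalize: bool = True) -> np.ndarray:
    """Per-trial channel covariance stack ``(n_trials, c, c)``.

    With ``normalize=True`` each trial's covariance is divided by its trace
    (classic CSP practice); otherwise it is ``X Xᵀ / n_samples``.
    """
    X = epochs.data
    covs = np.einsum("tcs,tds->tcd", X, X)
    if normalize:
        traces = np.trace(covs, axis1=1, axis2=2)
        covs = covs / np.maximum(traces, _VAR_FLOOR)[:, None, None]
    else:
        covs = covs / epochs.n_samples
    return covs


def class_mean_covariance(epochs: EpochSet, k: int) -> np.ndarray:
    """Mean trace-normalized trial covariance of class ``k`` (trace exactly 1)."""
    if epochs.labels is None:
        raise ValueError("epochs are unlabeled")
    mask = epochs.labels == k
    if not mask.any():
        raise ValueError(f"no trials of class {k}")
    covs = trial_covariances(epochs, normalize=True)[mask]
    mean = covs.mean(axis=0)
    return 0.5 * (mean + mean.T)


# ---------------------------------------------------------------------------
# CSP / RCSP fitting
# ---------------------------------------------------------------------------

def _fix_signs(W: np.ndarray) -> np.ndarray:
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def csp_fit(C1: np.ndarray, C2: np.ndarray, n_pairs: int = 2) -> SpatialFilterModel:
    """Solve ``C₁ w = λ (C₁+C₂) w`` and keep the extreme-λ filter pairs."""
    C1 = 0.5 * (np.asarray(C1, float) + np.asarray(C1, float).T)
    C2 = 0.5 * (np.asarray(C2, float) + np.asarray(C2, float).T)
    c = C1.shape[0]
    if 2 * n_pairs > c:
        raise ValueError(f"2 * n_pairs = {2 * n_pairs} exceeds channel count {c}")
    composite = C1 + C2
    try:
        vals, vecs = linalg.eigh(C1, composite)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"composite covariance not SPD: {err}") from err
    order = np.argsort(vals)[::-1]  # descending
    vals, vecs = vals[order], vecs[:, order]
    keep = np.concatenate([np.arange(n_pairs), np.arange(c - n_pairs, c)])
    W = _fix_signs(vecs[:, keep])
    return SpatialFilterModel(W=W, eigenvalues=vals, n_pairs=n_pairs)


def rcsp_covariance(cc: ClassCovariances, beta: float, gamma: float) -> np.ndarray:
    """Regularized class covariance ``Ĉᵏ(β,γ)`` for one class."""
    if not (0 <= beta <= 1 and 0 <= gamma <= 1):
        raise ValueError("beta and gamma must lie in [0, 1]")
    denom = beta * cc.n_target + (1 - beta) * cc.n_source
    if denom == 0:
        raise ValueError(
            f"degenerate mixture: beta={beta} with N_l={cc.n_target}, N_s={cc.n_source}"
        )
    num = np.zeros_like(cc.C_target if cc.C_target is not None else cc.C_source)
    if beta * cc.n_target > 0:
        if cc.C_target is None:
            raise ValueError("beta > 0 with target trials but no target covariance")
        num = num + beta * cc.n_target * cc.C_target
    if (1 - beta) * cc.n_source > 0:
        if cc.C_source is None:
            raise ValueError("beta < 1 with source trials but no source covariance")
        num = num + (1 - beta) * cc.n_source * cc.C_source
    C_beta = num / denom
    c = C_beta.shape[0]
    shrunk = (1 - gamma) * C_beta + gamma * (np.trace(C_beta) / c) * np.eye(c)
    return 0.5 * (shrunk + shrunk.T)


def rcsp_fit(
    target: EpochSet | None,
    source: EpochSet,
    beta: float = 0.0,
    gamma: float = 0.0,
    n_pairs: int = 2,
) -> SpatialFilterModel:
    """RCSP: regularize each class covariance, then run CSP on the pair.

    With ``beta=0`` the target epochs are never touched (strict
    leave-one-subject-out hygiene); with ``beta=1, gamma=0`` the result is
    identical to plain CSP on the target alone.
    """
    covs = {}
    for k in (+1, -1):
        C_t = None
        n_t = 0
        if target is not None and beta > 0:
            C_t = class_mean_covariance(target, k)
            n_t = int(np.sum(target.labels == k))
        elif target is not None and target.labels is not None:
            n_t = int(np.sum(target.labels == k))
        C_s = class_mean_covariance(source, k)
        n_s = int(np.sum(source.labels == k))
        cc = ClassCovariances(
            C_target=C_t, C_source=C_s,
            n_target=n_t if C_t is not None else 0,
            n_source=n_s, klass=k,
        )
        covs[k] = rcsp_covariance(cc, beta, gamma)
    model = csp_fit(covs[+1], covs[-1], n_pairs=n_pairs)
    model.beta, model.gamma = beta, gamma
    return model


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def logvar_from_covariances(covs: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Normalized log-variance features from per-trial covariances.

    For filter ``w`` the projected-signal power is ``wᵀ C w``; features are
    ``log(v_j / Σ_j v_j)``.  Exactly equals :func:`logvar_features` on the
    signals the covariances came from.
    """
    v = np.einsum("cf,tcd,df->tf", W, covs, W)
    v = np.maximum(v, _VAR_FLOOR)
    total = v.sum(axis=1, keepdims=True)
    if np.any(total <= _VAR_FLOOR * v.shape[1] * 1.001):
        warnings.warn("near-zero total projected variance; features floored",
                      RuntimeWarning, stacklevel=2)
    return np.log(v / total)


def logvar_features(epochs: EpochSet, model: SpatialFilterModel) -> np.ndarray:
    """Per-trial normalized log-variance of the spatially filtered signals.

    Variance is the mean square of the projected (zero-phase band-passed,
    hence zero-mean) signal.  The per-trial normalization by total variance
    makes features invariant to trial amplitude scaling.
    """
    covs = trial_covariances(epochs, normalize=False)
    return logvar_from_covariances(covs, model.W)


def bandpower_features(epochs: EpochSet, spec: BandSpec) -> np.ndarray:
    """Log band power per (band, channel): ``n_trials x (n_bands * c)``.

    Power is the mean squared amplitude of the band-filtered signal,
    floored at 1e-12 before the log.
    """
    blocks = []
    for band_epochs in decompose(epochs, spec):
        power = np.mean(band_epochs.data ** 2, axis=-1)  # (n_trials, c)
        blocks.append(np.log(np.maximum(power, _VAR_FLOOR)))
    return np.concatenate(blocks, axis=1)
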