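"""Synthetic multi-subject motor-imagery-like EEG cohorts with known truth.

Each subject's trials are generated as latent sources mixed to the sensors:

* one *discriminative* source, band-limited Gaussian noise confined to
  ``planted_band``, whose variance is multiplied by ``effect_size`` for
  class +1 only — an event-related (de)synchronization analogue, since the
  class difference is purely a band-power change;
* ``n_channels - 1`` broadband background sources of unit power;
* sensor mixing ``A_subject = A₀ (I + subject_shift · P_subject)`` with a
  shared, well-conditioned base matrix ``A₀`` and a per-subject random
  perturbation ``P_subject`` of unit spectral norm — so ``subject_shift``
  directly controls the inter-subject covariance shift that Euclidean
  alignment is meant to remove;
* additive white sensor noise.

Everything is a deterministic function of ``(seed, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet, MONTAGE_8

__all__ = ["SyntheticConfig", "generate_subject", "generate_cohort"]

SENSOR_NOISE_STD = 0.1  # ~ -20 dB relative to unit-power sources


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level ground-truth parameters."""

    n_subjects: int = 9
    trials_per_class: int = 72
    n_channels: int = 8
    fs: float = 250.0
    duration: float = 3.0
    planted_band: tuple[float, float] = (18.0, 26.0)
    effect_size: float = 3.0      # class +1 variance ratio on the planted source
    subject_shift: float = 0.3    # spectral-norm magnitude of mixing perturbation
    noise_floor: float = 1.0      # background source power
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.planted_band
        if not (0 < low < high < self.fs / 2):
            raise ValueError(f"planted_band {self.planted_band} invalid at fs={self.fs}")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if not 0 <= self.subject_shift <= 1:
            raise ValueError("subject_shift must lie in [0, 1]")


def _base_mixing(config: SyntheticConfig) -> np.ndarray:
    """Shared mixing matrix A₀ with singular values clipped into [0.7, 1.5]
    (condition number < 10, keeps CSP numerically stable)."""
    rng = np.random.default_rng([config.seed, 2**16])
    c = config.n_channels
    M = rng.standard_normal((c, c))
    U, s, Vt = np.linalg.svd(M)
    s_clipped = 0.7 + 0.8 * (s - s.min()) / max(s.max() - s.min(), 1e-12)
    return U @ np.diag(s_clipped) @ Vt


def _subject_mixing(config: SyntheticConfig, subject_index: int) -> np.ndarray:
    A0 = _base_mixing(config)
    if config.subject_shift == 0:
        return A0
    rng = np.random.default_rng([config.seed, 2**17, subject_index])
    c = config.n_channels
    P = rng.standard_normal((c, c))
    P /= np.linalg.norm(P, ord=2)  # unit spectral norm
    return A0 @ (np.eye(c) + config.subject_shift * P)


def _bandlimited_noise(
    rng: np.random.Generator, band: tuple[float, float], fs: float,
    shape: tuple[int, ...],
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited with the pipeline's own
    zero-phase Butterworth machinery (self-consistency with the decoder)."""
    raw = rng.standard_normal(shape)
    sos = signal.butter(4, list(band), btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, raw, axis=-1)
    std = filtered.std(axis=-1, keepdims=True)
    return filtered / np.maximum(std, 1e-12)


def generate_subject(config: SyntheticConfig, subject_index: int) -> EpochSet:
    """One subject's balanced two-class trial set, ``(2*trials_per_class, c, T)``.

    Trial order interleaves the classes (+1, -1, +1, ...) so any contiguous
    calibration split stays balanced.
    """
    rng = np.random.default_rng([config.seed, subject_index])
    c = config.n_channels
    T = int(round(config.duration * config.fs))
    n_trials = 2 * config.trials_per_class
    labels = np.where(np.arange(n_trials) % 2 == 0, 1, -1)

    # discriminative source: band-limited, class +1 gets variance * effect_size
    disc = _bandlimited_noise(rng, config.planted_band, config.fs, (n_trials, T))
    amp = np.where(labels == 1, np.sqrt(config.effect_size), 1.0)
    disc = disc * amp[:, None]

    # background sources: broadband white noise at the configured power
    bg = rng.standard_normal((n_trials, c - 1, T)) * np.sqrt(config.noise_floor)
    sources = np.concatenate([disc[:, None, :], bg], axis=1)

    A = _subject_mixing(config, subject_index)
    data = np.einsum("cd,tds->tcs", A, sources)
    data += SENSOR_NOISE_STD * rng.standard_normal(data.shape)

    channels = MONTAGE_8 if c == 8 else tuple(f"CH{i + 1}" for i in range(c))
    return EpochSet(
        data=data,
        fs=config.fs,
        channels=channels,
        labels=labels,
        subject_id=f"sim{subject_index:02d}",
        meta=(
            {
                "op": "simulate",
                "seed": config.seed,
                "subject_index": subject_index,
                "planted_band": list(config.planted_band),
                "effect_size": config.effect_size,
                "subject_shift": config.subject_shift,
            },
        ),
    )


def generate_cohort(config: SyntheticConfig) -> list[EpochSet]:
    """All subjects, sharing one base mixing matrix and one planted effect."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]
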