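"""Epoched EEG container and basic preprocessing.

The :class:`EpochSet` is the currency every pipeline stage consumes and
returns: a ``(n_trials, n_channels, n_samples)`` tensor of epoched EEG (in
microvolts by convention; never enforced numerically), binary class labels,
sampling rate, an ordered channel list, and a provenance trail recording
every transformation applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "MONTAGE_8",
    "bandpass_filter",
    "crop_epochs",
    "select_channels",
]

#: The 8-channel sensorimotor montage used throughout: frontocentral,
#: central and centroparietal electrodes over the hand motor areas.
MONTAGE_8 = ("FC3", "FCz", "FC4", "C3", "Cz", "C4", "CP3", "CP4")


@dataclass
class EpochSet:
    """Labeled multichannel trial tensor.

    Parameters
    ----------
    data
        Real array of shape ``(n_trials, n_channels, n_samples)``.
    fs
        Sampling rate in Hz, > 0.
    channels
        Ordered channel names, one per channel axis entry.
    labels
        Optional integer vector in ``{+1, -1}`` of length ``n_trials``;
        ``None`` for unlabeled data.
    subject_id
        Opaque subject identifier.
    meta
        Ordered provenance records, one dict per transformation applied.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    labels: np.ndarray | None = None
    subject_id: str = ""
    meta: tuple[dict[str, Any], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_trials, n_channels, n_samples); got shape {self.data.shape}"
            )
        if self.data.shape[1] == 0 or self.data.shape[2] == 0:
            raise ValueError("n_channels and n_samples must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0; got {self.fs}")
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[1]} channels"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.data.shape[0],):
                raise ValueError("labels length must equal n_trials")
            bad = set(np.unique(self.labels)) - {-1, 1}
            if bad:
                raise ValueError(f"labels must be in {{+1, -1}}; found {sorted(bad)}")
        self.meta = tuple(self.meta)

    # -- shape accessors ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        """Epoch length in seconds."""
        return self.n_samples / self.fs

    def evolve(self, *, record: dict[str, Any] | None = None, **changes: Any) -> "EpochSet":
        """Return a copy with ``changes`` applied and ``record`` appended to meta."""
        new = replace(self, **changes)
        if record is not None:
            new.meta = self.meta + (dict(record),)
        return new


def _design_bandpass(low: float, high: float, fs: float, order: int) -> np.ndarray:
    if not (0 < low < high):
        raise ValueError(f"invalid band ({low}, {high}): need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(
            f"invalid band ({low}, {high}): high edge must be below Nyquist {fs / 2} Hz"
        )
    if order < 1:
        raise ValueError(f"order must be >= 1; got {order}")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(epochs: EpochSet, low: float, high: float, order: int = 6) -> EpochSet:
    """Zero-phase Butterworth band-pass of every channel of every trial.

    The filter is the stated design order applied forward and backward
    (``sosfiltfilt``), so the effective magnitude response is the squared
    Butterworth response and the phase is zero.  Edge transients are
    suppressed by odd-reflection padding of up to one second (never less
    than 3x the design order, never more than ``n_samples - 1``).
    """
    sos = _design_bandpass(low, high, epochs.fs, order)
    padlen = int(min(epochs.n_samples - 1, max(3 * order, round(epochs.fs))))
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1, padlen=padlen)
    return epochs.evolve(
        data=filtered,
        record={"op": "bandpass", "low": low, "high": high, "order": order,
                "zero_phase": True},
    )


def crop_epochs(epochs: EpochSet, t_start: float, t_end: float) -> EpochSet:
    """Keep samples in the half-open window ``[t_start, t_end)`` seconds.

    ``t = 0`` is trial onset (the cue).  The output has
    ``round((t_end - t_start) * fs)`` samples per trial.
    """
    if not (0 <= t_start < t_end):
        raise ValueError(f"invalid crop window [{t_start}, {t_end})")
    if t_end > epochs.duration + 1e-9:
        raise ValueError(
            f"crop window [{t_start}, {t_end}) s exceeds epoch duration {epochs.duration} s"
        )
    i0 = int(round(t_start * epochs.fs))
    n = int(round((t_end - t_start) * epochs.fs))
    if i0 + n > epochs.n_samples:
        n = epochs.n_samples - i0
    return epochs.evolve(
        data=epochs.data[:, :, i0 : i0 + n],
        record={"op": "crop", "t_start": t_start, "t_end": t_end},
    )


def select_channels(epochs: EpochSet, names: Sequence[str] = MONTAGE_8) -> EpochSet:
    """Return the named channels, in the requested order.

    The default profile is the 8-channel sensorimotor montage
    (FC3, FCz, FC4, C3, Cz, C4, CP3, CP4).
    """
    index = {name: i for i, name in enumerate(epochs.channels)}
    missing = [n for n in names if n not in index]
    if missing:
        raise KeyError(
            f"unknown channel name(s) {missing}; available: {list(epochs.channels)}"
        )
    idx = [index[n] for n in names]
    return epochs.evolve(
        data=epochs.data[:, idx, :],
        channels=tuple(names),
        record={"op": "select_channels", "names": list(names)},
    )
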