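"""Optional adapter for BCI Competition IV-2a GDF recordings.

External data path only: requires `mne` and files the user downloads.  Event
codes 769/770 (cue left / cue right hand) become labels +1 / -1; epochs are
cue-locked.  Not exercised by the test suite.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .epochs import EpochSet

#: 2a annotation codes for the two-class problem.
EVENT_LABELS = {"769": +1, "770": -1}


def read_gdf_epochs(path: str | Path, tmin: float = 0.0, tmax: float = 4.0) -> EpochSet:
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "GDF import needs the optional dependency mne (pip install micross[gdf])"
        ) from err

    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    raw.pick("eeg")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    wanted = {code: lab for code, lab in EVENT_LABELS.items() if code in event_id}
    if not wanted:
        raise ValueError(f"{path}: no left/right-hand cue events found")
    picks = {code: event_id[code] for code in wanted}
    epochs = mne.Epochs(
        raw, events, event_id=picks, tmin=tmin, tmax=tmax,
        baseline=None, preload=True, verbose="error",
    )
    inv = {v: EVENT_LABELS[k] for k, v in picks.items()}
    labels = np.array([inv[e] for e in epochs.events[:, 2]])
    return EpochSet(
        data=epochs.get_data() * 1e6,  # volts -> microvolts
        fs=float(epochs.info["sfreq"]),
        channels=tuple(epochs.ch_names),
        labels=labels,
        subject_id=Path(path).stem,
        meta=({"op": "import_gdf", "file": str(path), "tmin": tmin, "tmax": tmax},),
    )
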