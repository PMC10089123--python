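"""Fixture I/O: one array file per subject plus a JSON metadata sidecar.

The native format is deliberately minimal: ``<prefix>.npy`` holds the trial
tensor, ``<prefix>.json`` holds sampling rate, channels, labels, subject id
and the provenance trail.  Round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .epochs import EpochSet

__all__ = ["save_epochs", "load_epochs", "save_cohort", "load_cohort"]


def save_epochs(epochs: EpochSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.npy`` + ``<prefix>.json``; returns both paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npy = prefix.with_suffix(".npy")
    meta = prefix.with_suffix(".json")
    np.save(npy, epochs.data)
    sidecar = {
        "fs": epochs.fs,
        "channels": list(epochs.channels),
        "labels": None if epochs.labels is None else epochs.labels.tolist(),
        "subject_id": epochs.subject_id,
        "meta": list(epochs.meta),
    }
    meta.write_text(json.dumps(sidecar, indent=1, default=str))
    return npy, meta


def load_epochs(prefix: str | Path) -> EpochSet:
    """Read a subject fixture written by :func:`save_epochs`."""
    prefix = Path(prefix)
    npy = prefix.with_suffix(".npy")
    meta = prefix.with_suffix(".json")
    if not npy.exists() or not meta.exists():
        raise FileNotFoundError(f"fixture {prefix} incomplete: need {npy.name} and {meta.name}")
    try:
        sidecar = json.loads(meta.read_text())
        data = np.load(npy)
        return EpochSet(
            data=data,
            fs=sidecar["fs"],
            channels=tuple(sidecar["channels"]),
            labels=None if sidecar["labels"] is None else np.asarray(sidecar["labels"]),
            subject_id=sidecar.get("subject_id", ""),
            meta=tuple(sidecar.get("meta", [])),
        )
    except (KeyError, ValueError, json.JSONDecodeError) as err:
        raise ValueError(f"malformed fixture {prefix}: {err}") from err


def save_cohort(cohort: list[EpochSet], out_dir: str | Path) -> Path:
    """Write per-subject fixtures plus ``manifest.json``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[str] = []
    for i, epochs in enumerate(cohort):
        stem = epochs.subject_id or f"subject{i:02d}"
        if stem in entries:  # duplicate ids must not overwrite each other
            stem = f"{stem}_{i:02d}"
        save_epochs(epochs, out_dir / stem)
        entries.append(stem)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"subjects": entries}, indent=1))
    return manifest


def load_cohort(in_dir: str | Path) -> list[EpochSet]:
    """Read every subject listed in ``manifest.json``."""
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.json in {in_dir}")
    entries = json.loads(manifest.read_text())["subjects"]
    return [load_epochs(in_dir / stem) for stem in entries]
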