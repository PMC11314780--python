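"""Plain-text interchange format for recordings, matrices and tables.

One recording = a CSV matrix (samples x channels, channel labels as header)
plus a JSON sidecar ``<stem>.json`` holding {fs, channel_labels, montage_id,
subject_id, timepoint}. Connectivity matrices use the same convention with a
{metric, band, epoch_index, n_segments} sidecar. Cohort metadata is a CSV
with empty cells for missing outcome scores. EDF ingestion is available when
``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .recording import MultichannelRecording
from .spectral import ConnectivityMatrix

__all__ = [
    "write_recording",
    "read_recording",
    "write_matrix",
    "read_edf",
    "write_metadata",
    "read_metadata",
]


def write_recording(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write ``<path>.csv`` + ``<path>.json``; returns the CSV path."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    pd.DataFrame(rec.data, columns=rec.channel_labels).to_csv(csv_path, index=False)
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "montage_id": rec.montage_id,
        "subject_id": rec.subject_id,
        "timepoint": rec.timepoint,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(path: str | Path) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    try:
        sidecar = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt sidecar JSON: {json_path}") from exc
    frame = pd.read_csv(csv_path)
    return MultichannelRecording(
        data=frame.to_numpy(dtype=float),
        fs=float(sidecar["fs"]),
        channel_labels=[str(c) for c in sidecar["channel_labels"]],
        montage_id=sidecar.get("montage_id", "SYNTH"),
        subject_id=sidecar.get("subject_id"),
        timepoint=sidecar.get("timepoint"),
    )


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Write one connectivity matrix (CSV + sidecar)."""
    path = Path(path)
    labels = matrix.channel_labels or [str(i) for i in range(matrix.n_channels)]
    pd.DataFrame(matrix.values, columns=labels, index=labels).to_csv(
        path.with_suffix(".csv")
    )
    sidecar = {
        "metric": matrix.metric,
        "band": matrix.band.name if matrix.band else None,
        "epoch_index": matrix.epoch_index,
        "n_segments": matrix.n_segments,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".csv")


def read_edf(path: str | Path, montage_id: str = "CAP60") -> MultichannelRecording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF ingestion requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return MultichannelRecording(
        data=raw.get_data().T,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        montage_id=montage_id,
    )


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    """Metadata CSV: subject_id, timepoint, sex, RC, RLC (empty = missing)."""
    path = Path(path)
    metadata.to_csv(path, index=False)
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"subject_id", "timepoint", "sex"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return frame
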