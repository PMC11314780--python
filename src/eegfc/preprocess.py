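"""Preprocessing: decimation, montage restriction, filtering, re-referencing, epoching.

Reduces a raw multichannel recording to the analysis representation used for
connectivity estimation: 250 Hz, the canonical 52-channel set (for cap data),
1-47 Hz band-limited, average-referenced, cut into fifteen 2-s epochs.

Artifact handling (bad-channel detection, ICA component rejection,
interpolation) is deliberately not implemented; epoch selection accepts an
external boolean mask so that cleaned data from other tools can be slotted in.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import EpochSet, FrequencyBand, MultichannelRecording

__all__ = [
    "ANALYSIS52_LABELS",
    "decimate_to_target",
    "restrict_montage",
    "bandpass_filter",
    "broadband_filter",
    "average_rereference",
    "segment_epochs",
]

# Channel bookkeeping follows the 60-channel cap numbering. Channels 61-64 of
# the 64-cap are ocular; eight outermost channels of the 60-cap are excluded
# as artifact-prone. What remains is the canonical 52-channel analysis set,
# ordered by cap number.
OCULAR_CHANNELS = frozenset(str(i) for i in range(61, 65))
OUTERMOST_CHANNELS = frozenset(["1", "17", "23", "29", "32", "43", "47", "55"])

ANALYSIS52_LABELS: tuple[str, ...] = tuple(
    str(i) for i in range(1, 61) if str(i) not in OUTERMOST_CHANNELS
)
assert len(ANALYSIS52_LABELS) == 52


def decimate_to_target(
    rec: MultichannelRecording, target_fs: float = 250.0
) -> MultichannelRecording:
    """Downsample to ``target_fs`` with FIR anti-alias filtering.

    A recording already at the target rate is returned unchanged (same
    object); the acquisition rate must be an integer multiple of the target.
    """
    if rec.fs == target_fs:
        return rec
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"sample rate {rec.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    data = signal.decimate(rec.data, q, axis=0, ftype="fir", zero_phase=True)
    return rec.copy_with(data=data, fs=target_fs)


def restrict_montage(rec: MultichannelRecording) -> MultichannelRecording:
    """Reduce a cap recording to the canonical 52-channel analysis set.

    CAP64 drops the four ocular channels, CAP128 the channels beyond the
    60-cap reference set; all caps then drop the eight outermost channels.
    Channels are returned in canonical (cap-number) order regardless of input
    order. Calling this on an already-restricted recording is an error: it
    signals a mis-wired pipeline, not a harmless no-op.
    """
    if rec.montage_id == "ANALYSIS52":
        raise ValueError("recording is already restricted to the analysis montage")
    if rec.montage_id not in ("CAP60", "CAP64", "CAP128"):
        raise ValueError(f"unknown montage {rec.montage_id!r}")
    index = {label: i for i, label in enumerate(rec.channel_labels)}
    missing = [c for c in ANALYSIS52_LABELS if c not in index]
    if missing:
        raise ValueError(
            f"montage mismatch: channels {missing} absent from {rec.montage_id} input"
        )
    cols = [index[c] for c in ANALYSIS52_LABELS]
    return rec.copy_with(
        data=rec.data[:, cols],
        channel_labels=list(ANALYSIS52_LABELS),
        montage_id="ANALYSIS52",
    )


def _sos_bandpass(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    rec: MultichannelRecording, band: FrequencyBand, order: int = 4
) -> MultichannelRecording:
    """Zero-phase band-pass: order-``order`` Butterworth applied forward-backward.

    Forward-backward application squares the magnitude response and cancels
    group delay, so band-limited content keeps its phase — a requirement for
    phase-based connectivity downstream.
    """
    band.validate_for_fs(rec.fs)
    sos = _sos_bandpass(band.low, band.high, rec.fs, order=order)
    data = signal.sosfiltfilt(sos, rec.data, axis=0)
    return rec.copy_with(data=data)


def broadband_filter(
    rec: MultichannelRecording, low: float = 1.0, high: float = 47.0
) -> MultichannelRecording:
    """The 1-47 Hz broadband pass applied to the continuous recording."""
    return bandpass_filter(rec, FrequencyBand("broadband", low, high))


def average_rereference(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract the instantaneous across-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return rec.copy_with(data=data)


def segment_epochs(
    rec: MultichannelRecording,
    epoch_length: float = 2.0,
    n_select: int = 15,
    good_mask: np.ndarray | None = None,
) -> EpochSet:
    """Cut consecutive non-overlapping epochs and keep the first ``n_select``.

    Epoch k covers samples [k*L, (k+1)*L) with L = epoch_length*fs. When a
    boolean ``good_mask`` over candidate epochs is given (e.g. from an
    external artifact detector), the first ``n_select`` epochs flagged good
    are kept instead of the first ``n_select`` overall.
    """
    n_per = int(round(epoch_length * rec.fs))
    if n_per < 1:
        raise ValueError("epoch_length too short for the sample rate")
    n_avail = rec.n_samples // n_per
    starts = np.arange(n_avail) * n_per
    if good_mask is not None:
        good_mask = np.asarray(good_mask, dtype=bool)
        if good_mask.shape != (n_avail,):
            raise ValueError(
                f"good_mask must have one entry per candidate epoch ({n_avail})"
            )
        starts = starts[good_mask]
    if len(starts) < n_select:
        raise ValueError(
            f"insufficient clean signal: {len(starts)} usable epochs, need {n_select}"
        )
    starts = starts[:n_select]
    epochs = np.stack([rec.data[s : s + n_per] for s in starts])
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        epoch_length=epoch_length,
        channel_labels=list(rec.channel_labels),
    )
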