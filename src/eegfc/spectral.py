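"""Magnitude-squared coherence per channel pair via Welch cross-spectra.

For channels x, y with segment-averaged auto-spectra Sxx, Syy and
cross-spectrum Sxy,

    MSC(f) = |<Sxy(f)>|^2 / (|<Sxx(f)>| |<Syy(f)>|),

a [0, 1] measure of linear coupling at frequency f: 0 means no linear
interdependence, 1 maximum interdependence. Band values are the mean of
MSC(f) over the frequency bins falling in the half-open band interval.

Note the estimator's small-sample bias: with K averaged segments the expected
MSC of two independent signals is approximately 1/K, not 0; with a single
segment MSC is identically 1 and therefore refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import FrequencyBand

__all__ = [
    "WelchConfig",
    "CrossSpectrum",
    "ConnectivityMatrix",
    "welch_cross_spectra",
    "msc_matrix",
    "mean_offdiag",
]


@dataclass(frozen=True)
class WelchConfig:
    """Welch averaged-periodogram settings.

    Defaults (1-s Hann segments, 50% overlap) give three segments and a 1 Hz
    frequency grid on a 2-s epoch: the finest grid that still averages at
    least three periodograms.
    """

    segment_length: float = 1.0
    overlap_fraction: float = 0.5
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")

    def nperseg(self, fs: float) -> int:
        return int(round(self.segment_length * fs))

    def noverlap(self, fs: float) -> int:
        return int(round(self.nperseg(fs) * self.overlap_fraction))

    def n_segments(self, n_samples: int, fs: float) -> int:
        nper, nov = self.nperseg(fs), self.noverlap(fs)
        if n_samples < nper:
            return 0
        return (n_samples - nper) // (nper - nov) + 1


@dataclass
class CrossSpectrum:
    """Segment-averaged spectra for all channel pairs of one epoch.

    ``Sxx`` is (channels, freqs) real, ``Sxy`` (channels, channels, freqs)
    complex with ``Sxy[i, i] == Sxx[i]``.
    """

    frequencies: np.ndarray
    Sxx: np.ndarray
    Sxy: np.ndarray
    n_segments: int


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel connectivity in one band for one epoch."""

    values: np.ndarray
    metric: str  # "MSC" or "PLI"
    band: FrequencyBand | None = None
    epoch_index: int | None = None
    channel_labels: list[str] | None = None
    n_segments: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def welch_cross_spectra(
    epoch: np.ndarray, fs: float, cfg: WelchConfig | None = None
) -> CrossSpectrum:
    """Welch auto- and cross-spectral densities for one epoch (samples x channels).

    Tapered periodograms of overlapping segments are averaged; the segment
    count is recorded so downstream consumers can reason about estimator
    bias. At least two segments are required.
    """
    cfg = cfg or WelchConfig()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be samples x channels")
    n_samples = epoch.shape[0]
    k = cfg.n_segments(n_samples, fs)
    if k < 2:
        raise ValueError(
            f"epoch yields {k} Welch segment(s); need >= 2 for a meaningful spectrum"
        )
    x = epoch.T  # channels x samples
    freqs, sxy = signal.csd(
        x[:, np.newaxis, :],
        x[np.newaxis, :, :],
        fs=fs,
        window=cfg.window,
        nperseg=cfg.nperseg(fs),
        noverlap=cfg.noverlap(fs),
        detrend="constant",
        axis=-1,
    )
    sxx = np.real(np.einsum("iif->if", sxy)).copy()
    return CrossSpectrum(frequencies=freqs, Sxx=sxx, Sxy=sxy, n_segments=k)


def msc_matrix(
    epoch: np.ndarray,
    fs: float,
    band: FrequencyBand,
    cfg: WelchConfig | None = None,
    epoch_index: int | None = None,
    channel_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Band-averaged magnitude-squared coherence matrix for one epoch.

    The diagonal is stored as 1 (a channel is perfectly coherent with
    itself) and excluded from all whole-brain means.
    """
    cs = welch_cross_spectra(epoch, fs, cfg)
    band.validate_for_fs(fs)
    mask = band.contains(cs.frequencies)
    if not mask.any():
        raise ValueError(
            f"band {band.name} contains no frequency bins on the Welch grid"
        )
    denom = cs.Sxx[:, np.newaxis, :] * cs.Sxx[np.newaxis, :, :]
    num = np.abs(cs.Sxy) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    band_vals = msc[:, :, mask].mean(axis=-1)
    band_vals = np.clip(band_vals, 0.0, 1.0)
    band_vals = 0.5 * (band_vals + band_vals.T)  # kill asymmetric float dust
    np.fill_diagonal(band_vals, 1.0)
    return ConnectivityMatrix(
        values=band_vals,
        metric="MSC",
        band=band,
        epoch_index=epoch_index,
        channel_labels=channel_labels,
        n_segments=cs.n_segments,
    )


def mean_offdiag(matrix: ConnectivityMatrix | np.ndarray) -> float:
    """Whole-brain index: mean of the strict upper triangle of a symmetric matrix."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels for an off-diagonal mean")
    iu = np.triu_indices(n, k=1)
    return float(values[iu].mean())
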