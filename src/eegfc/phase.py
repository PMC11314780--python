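"""Phase lag index from instantaneous Hilbert phases.

For a channel pair with instantaneous phase difference series dphi(t_k),

    PLI = | < sign(dphi(t_k)) > |,

the absolute time-average of the sign of the phase difference. It measures
the asymmetry of the phase-difference distribution: 0 for a symmetric
distribution (no coupling, or coupling at 0 mod pi — the zero-lag couplings
that volume conduction produces), 1 for perfect locking at a consistent
nonzero lag. sign(0) contributes 0, so identical channels give exactly 0.

Signals must be band-limited before phase extraction; the analytic-signal
phase is only meaningful for narrowband input.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

from .recording import FrequencyBand
from .spectral import ConnectivityMatrix

__all__ = ["instantaneous_phase", "pli_matrix", "wrap_phase"]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    out = np.mod(phi + np.pi, 2.0 * np.pi) - np.pi
    # np.mod maps the upper edge to -pi; move it to +pi for (-pi, pi]
    if np.isscalar(out):
        return np.pi if out == -np.pi else out
    out[out == -np.pi] = np.pi
    return out


def instantaneous_phase(data: np.ndarray) -> np.ndarray:
    """Per-sample phase of the analytic signal, wrapped to (-pi, pi].

    ``data`` is samples (1-D) or samples x channels. A constant channel has
    no defined phase and is rejected.
    """
    data = np.asarray(data, dtype=float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, np.newaxis]
    if data.ndim != 2:
        raise ValueError("data must be 1-D or samples x channels")
    if np.any(np.ptp(data, axis=0) == 0):
        raise ValueError("constant (zero-variance) channel: phase undefined")
    phases = np.angle(hilbert(data, axis=0))
    phases = wrap_phase(phases)
    return phases[:, 0] if squeeze else phases


def pli_matrix(
    epoch: np.ndarray,
    band: FrequencyBand | None = None,
    epoch_index: int | None = None,
    channel_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Phase lag index matrix for one band-filtered epoch (samples x channels).

    Phase differences are wrapped differences of wrapped phases, re-wrapped
    to (-pi, pi]. The diagonal is 0 by the sign(0) = 0 convention.
    """
    phases = instantaneous_phase(epoch)
    dphi = phases[:, :, np.newaxis] - phases[:, np.newaxis, :]
    dphi = wrap_phase(dphi)
    pli = np.abs(np.sign(dphi).mean(axis=0))
    pli = 0.5 * (pli + pli.T)
    np.fill_diagonal(pli, 0.0)
    return ConnectivityMatrix(
        values=pli,
        metric="PLI",
        band=band,
        epoch_index=epoch_index,
        channel_labels=channel_labels,
    )
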