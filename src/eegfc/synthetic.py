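"""Surrogate EEG and cohort generation with known ground truth.

Signal model per channel c:

    x_c(t) = coupling_strength * cos(2 pi f t + phi0 - lag_c) + noise_sd * eps_c(t)

with eps_c white Gaussian, independent across channels. Under this model the
phase-based and spectral couplings have analytic limits: at zero noise and a
nonzero constant lag the PLI of a pair is 1, at zero lag it is 0, and both
PLI and MSC rise monotonically with the coupling-to-noise ratio.

Cohorts emulate a two-timepoint infant study: every subject carries a latent
coupling trait; the group mean coupling increases from the first to the
second timepoint; one channel acts as a low-noise "hub" driver so that at
high coupling the strongest pairwise couplings concentrate on hub edges and
the minimum spanning tree crystallises star-ward, while at low coupling
estimation noise dominates and the tree stays closer to a random (more
line-like) shape. Outcome scores are linear in the subject's true coupling
plus Gaussian noise, with follow-up missing completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import MultichannelRecording

__all__ = ["CouplingSpec", "CohortSpec", "Cohort", "generate_coupled_pair", "generate_cohort"]


@dataclass(frozen=True)
class CouplingSpec:
    """Pairwise coupling parameters for a two-channel surrogate."""

    carrier_freq: float = 10.0
    phase_lag: float = np.pi / 4
    coupling_strength: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.carrier_freq <= 0:
            raise ValueError("carrier_freq must be positive")
        # wrap the lag to (-pi, pi]
        lag = np.mod(self.phase_lag + np.pi, 2 * np.pi) - np.pi
        if lag == -np.pi:
            lag = np.pi
        object.__setattr__(self, "phase_lag", float(lag))


def generate_coupled_pair(
    fs: float, duration: float, spec: CouplingSpec, seed: int
) -> MultichannelRecording:
    """Two-channel surrogate where channel 2 lags channel 1 by ``spec.phase_lag``."""
    if spec.carrier_freq >= fs / 2:
        raise ValueError(
            f"carrier {spec.carrier_freq} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration*fs must give at least 2 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    carrier = 2 * np.pi * spec.carrier_freq * t
    ch1 = spec.coupling_strength * np.cos(carrier)
    ch2 = spec.coupling_strength * np.cos(carrier - spec.phase_lag)
    data = np.column_stack([ch1, ch2])
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    return MultichannelRecording(
        data=data, fs=fs, channel_labels=["1", "2"], montage_id="SYNTH"
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-timepoint cohort.

    Default sample sizes mirror a longitudinal infant design: 132 subjects at
    the first timepoint (T6), 61 at the second (T12), 47 seen at both.
    Coupling means, the sex offset, outcome slope/noise and the missing rate
    are free parameters of the generator, not estimates of any real study.
    """

    n_subjects_t6: int = 132
    n_subjects_t12: int = 61
    n_overlap: int = 47
    coupling_mean_t6: float = 0.35
    coupling_mean_t12: float = 0.55
    coupling_sd: float = 0.10
    sex_effect: float = 0.0
    outcome_slope: float = 40.0
    outcome_intercept: float = 75.0
    outcome_noise_sd: float = 6.0
    missing_rate: float = 0.48
    carrier_freq: float = 10.0
    noise_sd: float = 0.7
    hub_noise_sd: float = 0.1
    n_channels: int = 16
    fs: float = 250.0
    duration: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_subjects_t6, self.n_subjects_t12):
            raise ValueError("n_overlap exceeds a timepoint's subject count")
        if min(self.n_subjects_t6, self.n_subjects_t12, self.n_overlap) < 0:
            raise ValueError("subject counts must be non-negative")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        for name in ("coupling_mean_t6", "coupling_mean_t12"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.carrier_freq >= self.fs / 2:
            raise ValueError("carrier frequency above Nyquist")


@dataclass
class Cohort:
    """Bundle of per-subject recordings, metadata and generator ground truth.

    ``metadata`` has one row per subject x available timepoint
    (subject_id, timepoint, sex, RC, RLC; outcome cells NaN when missing);
    ``truth`` records the true coupling per recording.
    """

    spec: CohortSpec
    recordings: dict[tuple[str, str], MultichannelRecording]
    metadata: pd.DataFrame
    truth: pd.DataFrame


def _channel_lags(n_channels: int) -> np.ndarray:
    """Distinct per-channel lags; hub (channel 0) at 0, the rest spread in (0, pi)."""
    lags = np.zeros(n_channels)
    if n_channels > 1:
        lags[1:] = np.linspace(0.35, 2.55, n_channels - 1)
    return lags


def _subject_recording(
    spec: CohortSpec, coupling: float, subj_index: int, tp_code: int
) -> MultichannelRecording:
    """One multichannel recording; substream derived from (seed, subject, timepoint)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed % (2**31), subj_index, tp_code])
    )
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    phi0 = rng.uniform(0, 2 * np.pi)
    carrier = 2 * np.pi * spec.carrier_freq * t + phi0
    lags = _channel_lags(spec.n_channels)
    data = np.empty((n, spec.n_channels))
    # hub: full-amplitude driver with low sensor noise
    data[:, 0] = np.cos(carrier) + spec.hub_noise_sd * rng.standard_normal(n)
    for c in range(1, spec.n_channels):
        data[:, c] = coupling * np.cos(carrier - lags[c]) + spec.noise_sd * (
            rng.standard_normal(n)
        )
    return MultichannelRecording(
        data=data,
        fs=spec.fs,
        channel_labels=[f"ch{c:02d}" for c in range(spec.n_channels)],
        montage_id="SYNTH",
        subject_id=f"S{subj_index:03d}",
        timepoint="T6" if tp_code == 0 else "T12",
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort bundle; identical output for identical spec."""
    master = np.random.default_rng(
        np.random.SeedSequence([spec.seed % (2**31), 10_000])
    )
    n_total = spec.n_subjects_t6 + spec.n_subjects_t12 - spec.n_overlap
    subject_ids = [f"S{i:03d}" for i in range(n_total)]
    # first n_overlap subjects seen at both timepoints, then T6-only, then T12-only
    timepoints_of = {}
    for i in range(n_total):
        if i < spec.n_overlap:
            timepoints_of[i] = ("T6", "T12")
        elif i < spec.n_subjects_t6:
            timepoints_of[i] = ("T6",)
        else:
            timepoints_of[i] = ("T12",)

    sexes = master.choice(["M", "F"], size=n_total)
    traits = master.normal(0.0, spec.coupling_sd, size=n_total)

    recordings: dict[tuple[str, str], MultichannelRecording] = {}
    truth_rows, meta_rows = [], []
    for i, sid in enumerate(subject_ids):
        sex_off = spec.sex_effect if sexes[i] == "F" else 0.0
        couplings = []
        for tp in timepoints_of[i]:
            mean = spec.coupling_mean_t6 if tp == "T6" else spec.coupling_mean_t12
            coupling = float(np.clip(mean + sex_off + traits[i], 0.0, 1.0))
            couplings.append(coupling)
            tp_code = 0 if tp == "T6" else 1
            recordings[(sid, tp)] = _subject_recording(spec, coupling, i, tp_code)
            truth_rows.append(
                {"subject_id": sid, "timepoint": tp, "coupling": coupling}
            )
        # outcome tied linearly to the subject's true mean coupling (MCAR follow-up)
        cbar = float(np.mean(couplings))
        rc = spec.outcome_intercept + spec.outcome_slope * cbar + master.normal(
            0, spec.outcome_noise_sd
        )
        rlc = (
            spec.outcome_intercept - 30.0
            + spec.outcome_slope * cbar
            + master.normal(0, spec.outcome_noise_sd)
        )
        rc_present = master.uniform() >= spec.missing_rate
        rlc_present = master.uniform() >= spec.missing_rate
        for tp in timepoints_of[i]:
            meta_rows.append(
                {
                    "subject_id": sid,
                    "timepoint": tp,
                    "sex": sexes[i],
                    "RC": rc if rc_present else np.nan,
                    "RLC": rlc if rlc_present else np.nan,
                }
            )
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    return Cohort(spec=spec, recordings=recordings, metadata=metadata, truth=truth)
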