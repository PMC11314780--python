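"""End-to-end orchestration: recordings -> features -> statistics -> tables.

Stages: (synthetic or on-disk) recordings -> broadband filter + average
re-reference -> per-band connectivity (MSC from broadband Welch spectra,
PLI from band-filtered epochs) -> MST features per epoch -> subject-level
aggregation -> mixed-model contrasts with BH-FDR -> bootstrap Spearman
outcome correlations. Every run writes a manifest (config echo, seed,
package version) next to its outputs, and identical config + seed gives
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import (
    average_rereference,
    bandpass_filter,
    broadband_filter,
    decimate_to_target,
    restrict_montage,
    segment_epochs,
)
from .mst import build_mst, mst_features
from .phase import pli_matrix
from .recording import DEFAULT_BANDS, FrequencyBand, MultichannelRecording
from .spectral import WelchConfig, mean_offdiag, msc_matrix
from .stats import (
    aggregate_epoch_features,
    bootstrap_spearman,
    fdr_adjust_table,
    fit_group_model,
)
from .synthetic import CohortSpec, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "extract_features"]

logger = logging.getLogger("eegfc")

MST_FEATURES = (
    "LeafFraction",
    "Diameter",
    "Eccentricity",
    "BetweennessCentrality",
    "TreeHierarchy",
    "DegreeCorrelation",
    "Kappa",
)
ALL_FEATURES = ("MeanMSC", "MeanPLI") + MST_FEATURES


class PipelineError(RuntimeError):
    """Stage failure, annotated with the stage and subject involved."""


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the standard analysis settings."""

    bands: tuple[FrequencyBand, ...] = DEFAULT_BANDS
    epoch_length: float = 2.0
    n_epochs: int = 15
    welch: WelchConfig = field(default_factory=WelchConfig)
    n_boot: int = 1000
    seed: int = 0
    broadband: tuple[float, float] = (1.0, 47.0)
    correlation_band: str | None = "gamma"  # band whose features meet the outcomes
    cohort: CohortSpec | None = None  # set -> simulate; else read input_dir
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_epochs < 1 or self.n_boot < 1:
            raise ValueError("counts must be positive")
        edges = sorted((b.low, b.high) for b in self.bands)
        for (l1, h1), (l2, h2) in zip(edges, edges[1:]):
            if l2 < h1:
                raise ValueError("bands overlap under the half-open convention")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        return d


def _preprocess(rec: MultichannelRecording, config: PipelineConfig) -> MultichannelRecording:
    rec = decimate_to_target(rec, 250.0) if rec.fs != 250.0 else rec
    if rec.montage_id in ("CAP60", "CAP64", "CAP128"):
        rec = restrict_montage(rec)
    rec = broadband_filter(rec, *config.broadband)
    rec = average_rereference(rec)
    return rec


def _recording_features(
    rec: MultichannelRecording, config: PipelineConfig
) -> list[dict]:
    """Per-epoch feature rows (MeanMSC, MeanPLI, MST metrics) for one recording."""
    clean = _preprocess(rec, config)
    rows: list[dict] = []
    broadband_epochs = segment_epochs(clean, config.epoch_length, config.n_epochs)
    for band in config.bands:
        band_rec = bandpass_filter(clean, band)
        band_epochs = segment_epochs(band_rec, config.epoch_length, config.n_epochs)
        for e in range(config.n_epochs):
            msc = msc_matrix(
                broadband_epochs.epochs[e], clean.fs, band, config.welch, epoch_index=e
            )
            pli = pli_matrix(band_epochs.epochs[e], band, epoch_index=e)
            tree = build_mst(pli)
            feats = {"MeanMSC": mean_offdiag(msc), "MeanPLI": mean_offdiag(pli)}
            feats.update(mst_features(tree).as_dict())
            for name, value in feats.items():
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "timepoint": rec.timepoint,
                        "band": band.name,
                        "feature": name,
                        "epoch_index": e,
                        "value": value,
                    }
                )
    return rows


def extract_features(
    recordings: dict[tuple[str, str], MultichannelRecording], config: PipelineConfig
) -> pd.DataFrame:
    """Per-epoch feature table for a set of recordings keyed (subject, timepoint)."""
    rows: list[dict] = []
    for (sid, tp), rec in recordings.items():
        logger.info("features: subject %s %s", sid, tp)
        try:
            rows.extend(_recording_features(rec, config))
        except Exception as exc:
            raise PipelineError(f"feature stage failed for subject {sid} {tp}: {exc}") from exc
    return pd.DataFrame(rows)


def _group_stats(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    results = []
    for feature in ALL_FEATURES:
        for band in config.bands:
            sub = records[(records["feature"] == feature) & (records["band"] == band.name)]
            if sub["value"].isna().any():  # e.g. undefined degree correlation
                continue
            if sub["value"].std(ddof=0) == 0:  # constant feature, nothing to test
                logger.warning("skipping constant feature %s/%s", feature, band.name)
                continue
            try:
                results.extend(fit_group_model(records, feature, band.name))
            except Exception as exc:
                raise PipelineError(
                    f"stats stage failed for {feature}/{band.name}: {exc}"
                ) from exc
    fdr_adjust_table(results)
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "band": r.band,
                "effect": r.effect,
                "F": r.f_stat,
                "p": r.p_raw,
                "p_adj": r.p_adjusted,
            }
            for r in results
        ]
    )


def _correlations(
    records: pd.DataFrame, metadata: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Bootstrap Spearman of second-timepoint features against outcome scores."""
    band = config.correlation_band
    if band is None:
        return pd.DataFrame()
    meta_t12 = metadata[metadata["timepoint"] == "T12"][
        ["subject_id", "RC", "RLC"]
    ].drop_duplicates("subject_id")
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), 77]))
    for feature in ALL_FEATURES:
        sub = records[
            (records["feature"] == feature)
            & (records["band"] == band)
            & (records["timepoint"] == "T12")
        ][["subject_id", "value"]]
        merged = sub.merge(meta_t12, on="subject_id", how="inner")
        for outcome in ("RC", "RLC"):
            if outcome not in merged.columns:
                continue
            try:
                res = bootstrap_spearman(
                    merged["value"],
                    merged[outcome],
                    n_boot=config.n_boot,
                    seed=int(rng.integers(2**31)),
                    feature=feature,
                    band=band,
                    outcome=outcome,
                )
            except ValueError:
                continue  # too few complete pairs or degenerate ranks
            rows.append(
                {
                    "feature": res.feature,
                    "band": res.band,
                    "outcome": res.outcome,
                    "r": res.r,
                    "p": res.p_raw,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "n": res.n,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns tables and writes them when output_dir set.

    Returns a dict with keys ``features`` (subject-level), ``per_epoch``,
    ``stats``, ``correlations``, ``manifest``.
    """
    if config.cohort is not None:
        cohort = generate_cohort(config.cohort)
        recordings, metadata = cohort.recordings, cohort.metadata
    elif config.input_dir is not None:
        from .io import read_metadata, read_recording

        input_dir = Path(config.input_dir)
        metadata = read_metadata(input_dir / "metadata.csv")
        recordings = {}
        for csv_path in sorted(input_dir.glob("rec_*.csv")):
            rec = read_recording(csv_path)
            recordings[(rec.subject_id, rec.timepoint)] = rec
        if not recordings:
            raise PipelineError(f"no recordings found in {input_dir}")
    else:
        raise PipelineError("config must set either cohort (simulate) or input_dir")

    per_epoch = extract_features(recordings, config)
    features = aggregate_epoch_features(per_epoch, n_epochs=config.n_epochs)
    records = features.merge(
        metadata[["subject_id", "timepoint", "sex"]].drop_duplicates(),
        on=["subject_id", "timepoint"],
    )
    stats_table = _group_stats(records, config)
    corr_table = _correlations(records, metadata, config)

    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "package": "eegfc",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_recordings": len(recordings),
        "warnings": [
            f"MSC estimator bias ~1/{WelchConfig().n_segments(int(config.epoch_length * 250), 250.0)} "
            "under independence (Welch segment count)"
        ],
    }
    out = {
        "features": records,
        "per_epoch": per_epoch,
        "stats": stats_table,
        "correlations": corr_table,
        "manifest": manifest,
    }
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "features.csv", index=False)
        stats_table.to_csv(outdir / "stats.csv", index=False)
        corr_table.to_csv(outdir / "correlations.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
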