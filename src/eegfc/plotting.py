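"""Basic figures: feature boxplots by timepoint and outcome scatter plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_feature_boxplots", "plot_outcome_scatter"]


def plot_feature_boxplots(features: pd.DataFrame, feature: str, band: str, ax=None):
    """Boxplot of subject-level values by timepoint for one feature x band."""
    sub = features[(features["feature"] == feature) & (features["band"] == band)]
    if sub.empty:
        raise ValueError(f"no data for {feature}/{band}")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    groups = [g["value"].to_numpy() for _, g in sub.groupby("timepoint", sort=True)]
    labels = sorted(sub["timepoint"].unique())
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel(feature)
    ax.set_title(f"{feature} — {band}")
    return ax


def plot_outcome_scatter(features: pd.DataFrame, metadata: pd.DataFrame,
                         feature: str, band: str, outcome: str = "RC", ax=None):
    """Scatter of second-timepoint feature values against an outcome score."""
    sub = features[
        (features["feature"] == feature)
        & (features["band"] == band)
        & (features["timepoint"] == "T12")
    ][["subject_id", "value"]]
    meta = metadata[metadata["timepoint"] == "T12"][
        ["subject_id", outcome]
    ].drop_duplicates("subject_id")
    merged = sub.merge(meta, on="subject_id").dropna()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(merged["value"], merged[outcome], s=18, alpha=0.7)
    ax.set_xlabel(f"{feature} ({band})")
    ax.set_ylabel(outcome)
    return ax
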