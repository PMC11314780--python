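"""Subject-level aggregation, mixed-model group contrasts, FDR, bootstrap Spearman.

Connectivity features are computed per epoch and averaged within subject;
subject-level values enter a linear mixed model with a random intercept per
subject (repeated measures across timepoints) and fixed effects for
timepoint, sex and their interaction, using sum-to-zero factor coding so the
main effects are averaged over the other factor. Raw p-values are adjusted
with the Benjamini-Hochberg step-up procedure within each feature x effect
family across the frequency bands. Outcome associations use Spearman's rho
with a percentile bootstrap over subjects; a correlation is flagged
significant when the confidence interval excludes zero (no multiplicity
adjustment, by design — these analyses are exploratory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import mixedlm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "CorrelationResult",
    "aggregate_epoch_features",
    "fit_group_model",
    "fdr_adjust",
    "fdr_adjust_table",
    "bootstrap_spearman",
]

EFFECTS = ("timepoint", "sex", "interaction")


@dataclass
class StatResult:
    """One effect test for one feature in one band."""

    feature: str
    band: str
    effect: str  # timepoint | sex | interaction
    f_stat: float
    p_raw: float
    p_adjusted: float | None = None


@dataclass
class CorrelationResult:
    """Bootstrap Spearman correlation of one feature against one outcome."""

    feature: str
    band: str
    outcome: str
    r: float
    p_raw: float
    ci_low: float
    ci_high: float
    n: int
    significant: bool


def aggregate_epoch_features(
    per_epoch: pd.DataFrame, n_epochs: int = 15
) -> pd.DataFrame:
    """Average per-epoch feature values within subject x timepoint x band x feature.

    ``per_epoch`` needs columns subject_id, timepoint, band, feature,
    epoch_index, value. Every group must contain exactly ``n_epochs`` epochs;
    a short group indicates lost epochs upstream and is an error.
    """
    required = {"subject_id", "timepoint", "band", "feature", "epoch_index", "value"}
    missing = required - set(per_epoch.columns)
    if missing:
        raise ValueError(f"per-epoch table missing columns: {sorted(missing)}")
    keys = ["subject_id", "timepoint", "band", "feature"]
    counts = per_epoch.groupby(keys, sort=False)["value"].count()
    bad = counts[counts != n_epochs]
    if len(bad):
        first = bad.index[0]
        raise ValueError(
            f"expected {n_epochs} epoch values per group, found {bad.iloc[0]} "
            f"for {dict(zip(keys, first))}"
        )
    out = per_epoch.groupby(keys, sort=False, as_index=False)["value"].mean()
    return out


def fit_group_model(
    records: pd.DataFrame, feature: str, band: str
) -> list[StatResult]:
    """Mixed-model contrasts for one feature x band: timepoint, sex, interaction.

    ``records`` needs columns subject_id, timepoint, sex, band, feature,
    value (one row per subject x timepoint). Fits
    value ~ C(timepoint, Sum) + C(sex, Sum) + interaction with a subject
    random intercept; each single-df effect is reported as the squared Wald
    z statistic (an F statistic on 1 numerator df) with its normal-theory
    p-value. Subjects observed at only one timepoint are handled naturally
    by the likelihood.
    """
    df = records[(records["feature"] == feature) & (records["band"] == band)].copy()
    if df.empty:
        raise ValueError(f"no records for feature={feature!r} band={band!r}")
    for col in ("timepoint", "sex"):
        levels = df[col].nunique()
        if levels < 2:
            raise ValueError(f"factor {col!r} has a single level; design is singular")
    if df["value"].std(ddof=0) == 0:
        raise ValueError("response has zero variance; model is degenerate")
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=["T6", "T12"])
    df["sex"] = pd.Categorical(df["sex"], categories=["M", "F"])
    formula = "value ~ C(timepoint, Sum) + C(sex, Sum) + C(timepoint, Sum):C(sex, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mixedlm(formula, df, groups=df["subject_id"])
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception:
            fit = model.fit(reml=True, method="powell")
    patterns = {
        "timepoint": "C(timepoint, Sum)[S.T6]",
        "sex": "C(sex, Sum)[S.M]",
        "interaction": "C(timepoint, Sum)[S.T6]:C(sex, Sum)[S.M]",
    }
    results = []
    for effect, name in patterns.items():
        if name not in fit.params.index:
            raise RuntimeError(f"term {name!r} not found in fitted model")
        z = fit.params[name] / fit.bse[name]
        f_stat = float(z**2)
        p = float(2 * sps.norm.sf(abs(z)))
        results.append(
            StatResult(feature=feature, band=band, effect=effect, f_stat=f_stat, p_raw=p)
        )
    return results


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_adjust_table(results: list[StatResult]) -> list[StatResult]:
    """Adjust p-values within each feature x effect family across bands (in place)."""
    groups: dict[tuple[str, str], list[StatResult]] = {}
    for r in results:
        groups.setdefault((r.feature, r.effect), []).append(r)
    for members in groups.values():
        adjusted = fdr_adjust([m.p_raw for m in members])
        for m, padj in zip(members, adjusted):
            m.p_adjusted = float(padj)
    return results


def bootstrap_spearman(
    x,
    y,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 95.0,
    feature: str = "",
    band: str = "",
    outcome: str = "",
) -> CorrelationResult:
    """Spearman's rho with a percentile bootstrap CI over paired observations.

    Pairs with a missing member are dropped listwise. The point estimate is
    the full-sample rho; the CI comes from ``n_boot`` resamples of subjects
    (x, y kept together). Significance = the CI excludes zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 complete pairs, have {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance in x or y")
    r, p = sps.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        xb, yb = x[idx[b]], y[idx[b]]
        if np.unique(xb).size < 2 or np.unique(yb).size < 2:
            boot[b] = np.nan
        else:
            boot[b] = sps.spearmanr(xb, yb).statistic
    alpha = (100.0 - ci_level) / 2.0
    lo, hi = np.nanpercentile(boot, [alpha, 100.0 - alpha])
    return CorrelationResult(
        feature=feature,
        band=band,
        outcome=outcome,
        r=float(r),
        p_raw=float(p),
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        significant=not (lo <= 0.0 <= hi),
    )
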