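"""Uptime-normalized root-growth-dynamics statistics.

Daily detection counts are only comparable across devices and days after
normalizing by how much usable data each device produced.  With ``nt``
the number of roots detected on day ``t`` and ``Ut`` the device's daily
fractional uptime, the daily detection rate is

    rt = nt / Ut          (days with Ut <= 0.04 are treated as Ut = 0
                           and ignored: too little data for a stable rate)

and per electrode depth ``d``, aggregating over all paddles,

    rtd = ntd / Utd.

Cumulative detections integrate the rate over non-missing days,
``ct = sum_{i<=t} ri``; time-averaged rates over a day window ``[a, b]``
are means of ``rt`` (or ``rtd``) over the window's non-missing days.
Devices with minimal data in the window (more than half its days with no
data at all, or a data span shorter than 80% of the window) are excluded
from group distributions.

Group contrasts use the one-sided Welch two-sample t test (no equal
variance assumption) with Cohen's d computed on the average variance of
the two groups; genotype-by-treatment interactions use a two-way
fixed-effects ANOVA, Rate = Treatment + Genotype + Treatment:Genotype.

Display series are smoothed with a zero-phase low-pass Butterworth filter
(normalized cutoff 0.4); depth-time matrices are filtered first along
depth, then along time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .device import DeviceGeometry

__all__ = [
    "UPTIME_CUTOFF",
    "RateTable",
    "GroupComparison",
    "daily_rates",
    "cumulative_detections",
    "time_averaged_rate",
    "exclude_sparse",
    "smooth",
    "compare_groups",
    "interaction_anova",
    "irrigation_hours",
    "deeper_half_indices",
]

#: Days with fractional uptime at or below this are ignored when forming
#: rates (treated as no-data days).
UPTIME_CUTOFF = 0.04


@dataclass
class RateTable:
    """Daily rates per device, aggregate and by electrode depth.

    ``rates`` columns: device_id, day, date, nt, Ut, rt (rt is NaN on
    ignored days).  ``depth_rates`` columns: device_id, day, depth_index,
    ntd, Utd, rtd.
    """

    rates: pd.DataFrame
    depth_rates: pd.DataFrame


def daily_rates(
    detections: pd.DataFrame,
    uptime: pd.DataFrame,
    geometry: DeviceGeometry = DeviceGeometry(),
) -> RateTable:
    """Uptime-normalized daily detection rates, aggregate and per depth.

    ``detections`` needs columns ``device_id, day, depth_index``;
    ``uptime`` needs ``device_id, day, Ut`` and the per-depth ``Utd_<k>``
    columns produced by :func:`rhizosense.detect.daily_uptime`.  Days with
    ``Ut <= 0.04`` (or ``Utd <= 0.04`` for the depth table) get a missing
    rate.
    """
    counts = (
        detections.groupby(["device_id", "day"]).size().rename("nt")
        if len(detections)
        else pd.Series(dtype=int, name="nt")
    )
    rates = uptime[[c for c in ("device_id", "day", "date") if c in uptime.columns]]
    rates = rates.merge(
        counts.reset_index(), on=["device_id", "day"], how="left"
    ) if len(detections) else rates.assign(nt=0)
    rates["nt"] = rates.get("nt", 0)
    rates["nt"] = rates["nt"].fillna(0).astype(int)
    rates["Ut"] = uptime["Ut"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rates["rt"] = np.where(
            rates["Ut"] > UPTIME_CUTOFF, rates["nt"] / rates["Ut"], np.nan
        )

    utd_cols = [c for c in uptime.columns if c.startswith("Utd_")]
    depth_long = uptime.melt(
        id_vars=["device_id", "day"],
        value_vars=utd_cols,
        var_name="depth_index",
        value_name="Utd",
    )
    depth_long["depth_index"] = (
        depth_long["depth_index"].str.removeprefix("Utd_").astype(int)
    )
    if len(detections):
        dcounts = (
            detections.groupby(["device_id", "day", "depth_index"])
            .size()
            .rename("ntd")
            .reset_index()
        )
        depth_long = depth_long.merge(
            dcounts, on=["device_id", "day", "depth_index"], how="left"
        )
    else:
        depth_long["ntd"] = 0
    depth_long["ntd"] = depth_long["ntd"].fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        depth_long["rtd"] = np.where(
            depth_long["Utd"] > UPTIME_CUTOFF,
            depth_long["ntd"] / depth_long["Utd"],
            np.nan,
        )
    return RateTable(rates=rates, depth_rates=depth_long)


def cumulative_detections(rates: RateTable | pd.DataFrame) -> pd.DataFrame:
    """Cumulative detections ``ct``: running sum of ``rt`` over non-missing days.

    Missing (ignored) days contribute nothing; the final ``ct`` of each
    device equals the sum of its non-missing daily rates exactly.
    """
    df = rates.rates if isinstance(rates, RateTable) else rates
    out = df[["device_id", "day"]].copy()
    out["ct"] = (
        df["rt"].fillna(0.0).groupby(df["device_id"], sort=False).cumsum()
    )
    return out


def time_averaged_rate(
    rates: RateTable | pd.DataFrame,
    a: int,
    b: int,
    depth_index: int | list[int] | None = None,
) -> pd.DataFrame:
    """Time-averaged rate ``R`` per device over day window ``[a, b]`` inclusive.

    The average is the mean of ``rt`` over the window's non-missing days
    (days ignored by the uptime cutoff carry no weight).  With
    ``depth_index`` set, averages ``rtd`` restricted to those depths
    instead (column ``Rd``).  Devices whose window has no usable day get
    a missing result.
    """
    if a > b:
        raise ValueError(f"window start {a} exceeds end {b}")
    if depth_index is None:
        df = rates.rates if isinstance(rates, RateTable) else rates
        win = df[(df["day"] >= a) & (df["day"] <= b)]
        out = win.groupby("device_id")["rt"].mean().rename("R").reset_index()
    else:
        df = rates.depth_rates if isinstance(rates, RateTable) else rates
        sel = (
            [depth_index] if np.isscalar(depth_index) else list(depth_index)
        )
        win = df[
            (df["day"] >= a)
            & (df["day"] <= b)
            & (df["depth_index"].isin(sel))
        ]
        out = win.groupby("device_id")["rtd"].mean().rename("Rd").reset_index()
    out["a"] = a
    out["b"] = b
    return out


def exclude_sparse(
    averaged: pd.DataFrame,
    rates: RateTable | pd.DataFrame,
    a: int,
    b: int,
    max_missing_fraction: float = 0.5,
    min_span_fraction: float = 0.8,
) -> pd.DataFrame:
    """Drop devices with minimal data in the averaging window.

    A device is excluded when more than ``max_missing_fraction`` of the
    window's days had no data available at all (``Ut = 0``), or when the
    span from its first to last day with data covers less than
    ``min_span_fraction`` of the window's date range.  Note the no-data
    criterion is true zero uptime — a full-day outage — not the 0.04
    low-data cutoff used when forming rates; both thresholds exist
    side by side.
    """
    df = rates.rates if isinstance(rates, RateTable) else rates
    win = df[(df["day"] >= a) & (df["day"] <= b)]
    n_days = b - a + 1
    keep = []
    for dev, grp in win.groupby("device_id"):
        # days absent from the table entirely also count as no-data days
        zero_days = n_days - len(grp) + int((grp["Ut"] == 0).sum())
        if zero_days / n_days > max_missing_fraction:
            continue
        data_days = grp.loc[grp["Ut"] > 0, "day"]
        if len(data_days) == 0:
            continue
        span = (data_days.max() - data_days.min() + 1) / n_days
        if span < min_span_fraction:
            continue
        keep.append(dev)
    return averaged[averaged["device_id"].isin(keep)].reset_index(drop=True)


def smooth(
    x: np.ndarray | pd.Series,
    cutoff: float = 0.4,
    order: int = 1,
    axes: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth smoothing for display series.

    ``cutoff`` is the normalized cutoff frequency as a fraction of the
    Nyquist frequency (0.4 for daily-sampled series here).  The filter is
    first order applied forward and backward (``filtfilt``), so constants
    pass unchanged and event timing is preserved.  Missing values are
    linearly interpolated before filtering (display only — averages never
    use interpolated days).  2-D depth-time matrices are filtered first
    along depth (axis 0), then along time (axis 1).  Series shorter than
    the filter warm-up are returned unfiltered with a warning.
    """
    arr = np.asarray(x, dtype=float)
    b, a = scipy.signal.butter(order, cutoff)
    padlen = 3 * max(len(a), len(b))
    if arr.ndim == 1:
        axes_ = (0,) if axes is None else axes
    elif arr.ndim == 2:
        axes_ = (0, 1) if axes is None else axes
    else:
        raise ValueError("smooth expects a 1-D series or 2-D depth-time matrix")
    out = arr.copy()
    for ax in axes_:
        if out.shape[ax] <= padlen:
            warnings.warn(
                f"series of length {out.shape[ax]} too short to filter; "
                "returned unfiltered",
                stacklevel=2,
            )
            continue
        out = np.apply_along_axis(_interp_nan, ax, out)
        out = scipy.signal.filtfilt(b, a, out, axis=ax)
    return out


def _interp_nan(v: np.ndarray) -> np.ndarray:
    bad = ~np.isfinite(v)
    if bad.any() and (~bad).sum() >= 2:
        idx = np.arange(v.size)
        v = v.copy()
        v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    return v


@dataclass(frozen=True)
class GroupComparison:
    """Welch t contrast between two device groups with effect size."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    d: float  # Cohen's d on the average variance of the two groups
    d_lower_95: float  # one-sided 95% lower confidence bound of d
    direction: str
    valid: bool = True
    reason: str = ""


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    direction: str = "greater",
) -> GroupComparison:
    """Welch two-sample t test (one-sided by default) with Cohen's d.

    ``direction='greater'`` tests mean(A) > mean(B); ``'less'`` the
    reverse; ``'two-sided'`` is available for completeness.  Cohen's d
    uses the average variance of the two groups,
    ``d = (mean_a - mean_b) / sqrt((s2_a + s2_b) / 2)``, with a one-sided
    95% lower confidence bound from its asymptotic standard error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    if va == 0 and vb == 0:
        return GroupComparison(
            len(a), len(b), ma, mb, np.nan, np.nan, np.nan, np.nan, np.nan,
            direction, valid=False, reason="zero variance in both groups",
        )
    res = scipy.stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    d = (ma - mb) / math.sqrt((va + vb) / 2.0)
    n = len(a) + len(b)
    se_d = math.sqrt(n / (len(a) * len(b)) + d * d / (2.0 * n))
    d_lower = d - scipy.stats.norm.ppf(0.95) * se_d
    return GroupComparison(
        n_a=len(a),
        n_b=len(b),
        mean_a=ma,
        mean_b=mb,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        d=d,
        d_lower_95=d_lower,
        direction=direction,
    )


def interaction_anova(
    table: pd.DataFrame,
    value: str = "R",
    treatment: str = "treatment",
    genotype: str = "genotype",
) -> dict[str, float]:
    """Two-way fixed-effects ANOVA, Rate = Treatment + Genotype + interaction.

    Returns the interaction term's F statistic and p-value.  Requires at
    least two levels of each factor and at least two replicates in every
    treatment-genotype cell; an empty cell raises an error naming it.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[value, treatment, genotype]].dropna().copy()
    df.columns = ["y", "trt", "gen"]
    if df["trt"].nunique() < 2 or df["gen"].nunique() < 2:
        raise ValueError("need at least two treatments and two genotypes")
    counts = df.groupby(["trt", "gen"]).size()
    for t_lv in df["trt"].unique():
        for g_lv in df["gen"].unique():
            n_cell = counts.get((t_lv, g_lv), 0)
            if n_cell == 0:
                raise ValueError(f"empty cell: treatment={t_lv!r}, genotype={g_lv!r}")
            if n_cell < 2:
                raise ValueError(
                    f"cell treatment={t_lv!r}, genotype={g_lv!r} has fewer "
                    "than two replicates"
                )
    model = smf.ols("y ~ C(trt) * C(gen)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    row = aov.loc["C(trt):C(gen)"]
    return {"F": float(row["F"]), "p": float(row["PR(>F)"])}


def irrigation_hours(etc_weekly_inches: float, application_rate_in_per_hr: float) -> float:
    """Weekly irrigation time from crop evapotranspiration demand.

    Divides the week's estimated crop water demand (ETc, inches) by the
    system's measured application rate (inches/hour) and rounds to the
    nearest half hour — e.g. 1.99 in at 0.19 in/h gives 10.5 h.
    """
    if application_rate_in_per_hr <= 0:
        raise ValueError("application rate must be positive")
    if etc_weekly_inches < 0:
        raise ValueError("ETc cannot be negative")
    hours = etc_weekly_inches / application_rate_in_per_hr
    return math.floor(hours * 2.0 + 0.5) / 2.0


def deeper_half_indices(geometry: DeviceGeometry = DeviceGeometry()) -> list[int]:
    """Depth indices of the deeper half of electrodes (11-21 of 22)."""
    epp = geometry.electrodes_per_paddle
    return list(range(epp // 2, epp))
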