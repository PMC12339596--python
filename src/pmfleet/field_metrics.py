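"""Field data-quality and exposure summary metrics.

Once a fleet is deployed, four questions dominate data quality review: how
much of the expected record stream was actually captured (per retrieval
path — cloud transmission vs the on-board card — and for their union); how
well a monitor's two optical channels agree (channel imprecision); how
indoor concentrations relate to concurrent outdoor ones (I/O ratios); and
whether applying co-location factors materially shifted the concentration
distributions (two-sample KS test and Cohen's d).  A relative-humidity
screen reports how much of the data lies below the level where optical
monitors start to over-read hygroscopic particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DeploymentMeta, chan

__all__ = [
    "CaptureReport",
    "DistributionComparison",
    "ImprecisionSummary",
    "IORatioResult",
    "capture_rate",
    "imprecision",
    "imprecision_summary",
    "io_ratio",
    "paired_io_ratios",
    "distribution_compare",
    "rh_screen",
]

_WINDOW_S = 600

#: Above this sample size the Shapiro–Wilk p-value is unreliable; the test
#: is skipped with a note (scipy warns beyond N=5000).
SHAPIRO_MAX_N = 5000


@dataclass(frozen=True)
class CaptureReport:
    """Data capture accounting for one monitor's deployment window.

    ``n_expected`` is the number of 10-min boundaries in [deploy_start,
    deploy_end); counts are restricted to that window, and ``n_total`` is
    the size of the union of cloud and SD stamp sets (a stamp recovered
    from both sources counts once).
    """

    monitor_id: str
    n_expected: int
    n_wifi: int
    n_sd: int
    n_total: int
    rate_wifi: float
    rate_sd: float
    rate_total: float


def _window_boundaries(start: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
    first = start.ceil(f"{_WINDOW_S}s")
    return pd.date_range(first, end, freq=f"{_WINDOW_S}s", inclusive="left")


def capture_rate(
    meta: DeploymentMeta,
    wifi_stamps,
    sd_stamps=None,
) -> CaptureReport:
    """Capture rates by source and for the union, over the deployment window."""
    expected = _window_boundaries(meta.deploy_start, meta.deploy_end)
    n_expected = len(expected)
    if n_expected == 0:
        raise ValueError("deployment window contains no 10-min boundaries")
    window = set(expected)

    def clip(stamps) -> set:
        if stamps is None:
            return set()
        return set(pd.DatetimeIndex(stamps)) & window

    wifi = clip(wifi_stamps)
    sd = clip(sd_stamps)
    total = wifi | sd
    return CaptureReport(
        monitor_id=meta.monitor_id,
        n_expected=n_expected,
        n_wifi=len(wifi),
        n_sd=len(sd),
        n_total=len(total),
        rate_wifi=len(wifi) / n_expected,
        rate_sd=len(sd) / n_expected,
        rate_total=len(total) / n_expected,
    )


def imprecision(a, b):
    """Between-channel imprecision |a-b| / (a+b), elementwise.

    A unitless within-monitor consistency measure in [0, 1]; undefined
    (NaN) where both channels read zero — 0/0 carries no precision
    information.  Negative concentrations are a domain error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a[np.isfinite(a)] < 0) or np.any(b[np.isfinite(b)] < 0):
        raise ValueError("imprecision requires nonnegative concentrations")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, np.abs(a - b) / total, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class ImprecisionSummary:
    """Per-monitor and fleet-level channel-imprecision summary.

    ``per_monitor`` has columns median, exceed_share (fraction of stamps
    above the precision limit) and n; ``fleet_median`` is the median of the
    per-monitor medians.
    """

    per_monitor: pd.DataFrame
    fleet_median: float
    limit: float


def imprecision_summary(
    fleet: dict[str, pd.DataFrame],
    parameter: str = "pm2.5_alt",
    *,
    limit: float = 0.20,
) -> ImprecisionSummary:
    """Summarize channel imprecision across a fleet on one parameter."""
    rows = {}
    for mid, frame in fleet.items():
        a_col, b_col = chan(parameter, "a"), chan(parameter, "b")
        if a_col not in frame.columns or b_col not in frame.columns:
            continue
        imp = pd.Series(imprecision(frame[a_col], frame[b_col]), index=frame.index).dropna()
        if imp.empty:
            continue
        rows[mid] = {
            "median": float(imp.median()),
            "exceed_share": float((imp > limit).mean()),
            "n": int(len(imp)),
        }
    per_monitor = pd.DataFrame.from_dict(rows, orient="index")
    fleet_median = float(per_monitor["median"].median()) if len(per_monitor) else math.nan
    return ImprecisionSummary(per_monitor=per_monitor, fleet_median=fleet_median, limit=limit)


@dataclass
class IORatioResult:
    """Concurrent indoor/outdoor concentration ratios for one pairing."""

    ratios: pd.Series
    n_zero_outdoor: int
    median: float
    mean: float
    sd: float


def io_ratio(indoor: pd.Series, outdoor: pd.Series) -> IORatioResult:
    """Per-stamp indoor/outdoor ratio over the concurrent stamps.

    Stamps where the outdoor concentration is zero are omitted (the ratio
    is unbounded) and counted; no cap is applied to large ratios — strong
    indoor sources legitimately push I/O far above 1.
    """
    pair = pd.concat([indoor, outdoor], axis=1, join="inner").dropna()
    if pair.empty:
        return IORatioResult(pd.Series(dtype=float), 0, math.nan, math.nan, math.nan)
    ind, out = pair.iloc[:, 0], pair.iloc[:, 1]
    zero = out == 0
    ratios = (ind[~zero] / out[~zero]).rename("io_ratio")
    return IORatioResult(
        ratios=ratios,
        n_zero_outdoor=int(zero.sum()),
        median=float(ratios.median()) if len(ratios) else math.nan,
        mean=float(ratios.mean()) if len(ratios) else math.nan,
        sd=float(ratios.std()) if len(ratios) > 1 else math.nan,
    )


def paired_io_ratios(
    fleet: dict[str, pd.DataFrame],
    metas: dict[str, DeploymentMeta],
    parameter: str = "pm2.5_alt",
) -> dict[str, IORatioResult]:
    """I/O ratios for every indoor monitor with a declared outdoor pairing."""
    out: dict[str, IORatioResult] = {}
    for mid, meta in metas.items():
        if meta.role != "INDOOR":
            continue
        if meta.paired_outdoor_id is None:
            raise ValueError(f"indoor monitor {mid!r} has no outdoor pairing")
        if mid not in fleet or meta.paired_outdoor_id not in fleet:
            continue
        out[mid] = io_ratio(
            fleet[mid][parameter], fleet[meta.paired_outdoor_id][parameter]
        )
    return out


@dataclass(frozen=True)
class DistributionComparison:
    """Two-sample distribution comparison (KS, Cohen's d, normality, summaries)."""

    ks_statistic: float
    ks_p: float
    cohens_d: float
    shapiro_1: tuple[float, float] | None
    shapiro_2: tuple[float, float] | None
    shapiro_note: str
    summary_1: dict[str, float]
    summary_2: dict[str, float]


def _cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD Cohen's d, (n-1)-weighted pooled variance, order x - y."""
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return math.nan
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    pooled = math.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    if pooled == 0:
        return 0.0 if x.mean() == y.mean() else math.inf
    return float((x.mean() - y.mean()) / pooled)


def _summary(x: np.ndarray) -> dict[str, float]:
    return {
        "n": int(len(x)),
        "median": float(np.median(x)),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if len(x) > 1 else math.nan,
    }


def distribution_compare(sample_1, sample_2) -> DistributionComparison:
    """Compare two samples: two-sample KS test, Cohen's d (sample_1 - sample_2
    order), and per-sample Shapiro–Wilk normality where sample size allows."""
    x = np.asarray(pd.Series(sample_1).dropna(), dtype=float)
    y = np.asarray(pd.Series(sample_2).dropna(), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    ks = stats.ks_2samp(x, y)
    note = ""

    def shapiro(s: np.ndarray) -> tuple[float, float] | None:
        nonlocal note
        if len(s) < 3:
            note = "Shapiro-Wilk skipped: n < 3"
            return None
        if len(s) > SHAPIRO_MAX_N:
            note = f"Shapiro-Wilk skipped: n > {SHAPIRO_MAX_N}"
            return None
        w = stats.shapiro(s)
        return (float(w.statistic), float(w.pvalue))

    return DistributionComparison(
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        cohens_d=_cohens_d(x, y),
        shapiro_1=shapiro(x),
        shapiro_2=shapiro(y),
        shapiro_note=note,
        summary_1=_summary(x),
        summary_2=_summary(y),
    )


def rh_screen(humidity, threshold: float = 60.0) -> float:
    """Fraction of stamps with relative humidity below ``threshold`` %RH.

    Above ~60 %RH optical particle monitors over-read hygroscopically grown
    particles; when nearly all data lie below the threshold no RH correction
    is needed.
    """
    h = pd.Series(np.asarray(humidity, dtype=float)).dropna()
    if h.empty:
        raise ValueError("no humidity data")
    return float((h < threshold).mean())
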