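"""Co-location QA/QC: inclusion criteria, reference regressions, monitor
classification, sentinel transfer, and co-location factors.

Monitors are operated side by side sampling the same air, and each monitor's
readings are regressed against a reference for each of the 16 reported
parameters.  The reference is either a single arbitrary monitor (the one
that recorded the most co-location data) or the per-stamp mean of all
accepted monitors, which concentrates the slope distribution around 1.
Regressions are fitted through the origin for all parameters except
temperature, humidity and pressure, whose sensors show additive offsets.

Monitors whose fit quality (r² >= 0.8 on every parameter) holds are
ACCEPTED; otherwise each optical channel is refitted separately (one failed
channel is a recoverable fault), then failing parameters are refitted with a
free intercept (a pure offset is correctable in post-processing); monitors
failing all three routes are EXCLUDED.  The fitted slopes (and intercepts
where fitted) become per-monitor, per-parameter co-location factors that map
field data onto the fleet-reference scale.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import INTERCEPT_FIT_PARAMETERS, PARAMETERS, chan

__all__ = [
    "MIN_CONCURRENT_POINTS",
    "R2_ACCEPT",
    "RegressionResult",
    "InclusionResult",
    "Status",
    "MonitorStatus",
    "FleetQAResult",
    "fit_monitor",
    "check_inclusion",
    "pick_arbitrary_reference",
    "mean_reference",
    "classify_monitor",
    "fleet_qa",
    "sentinel_reference",
    "apply_factors",
    "effective_frame",
    "retention_rate",
]

#: Minimum concurrent 10-min points for a monitor to enter the analysis
#: (48 h of 10-min data, not necessarily consecutive).
MIN_CONCURRENT_POINTS = 288

#: Minimum acceptable coefficient of determination per parameter.
R2_ACCEPT = 0.8


@dataclass(frozen=True)
class RegressionResult:
    """One monitor-vs-reference least-squares comparison.

    ``slope`` is dimensionless (same parameter on both axes); ``intercept``
    is 0 for through-origin fits.  ``r_squared`` is the coefficient of
    determination about the mean, 1 - SS_res/SS_tot clipped to [0, 1]: for
    intercept fits this equals the squared Pearson correlation, while for
    through-origin fits it correctly degrades when the data carry an
    additive offset the model cannot absorb.  ``ok`` is False when the fit
    is undefined (fewer than 2 concurrent points, or zero variance in the
    monitor values — the signature of a dead sensor).
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    ok: bool = True
    message: str = ""

    @property
    def is_acceptable(self) -> bool:
        return self.ok and self.r_squared >= R2_ACCEPT


def _error_result(n: int, message: str) -> RegressionResult:
    return RegressionResult(math.nan, math.nan, math.nan, n, ok=False, message=message)


def fit_monitor(x, y, intercept_fit: bool = False) -> RegressionResult:
    """Regress reference values ``y`` on monitor values ``x``.

    The reference is the dependent variable, so the fitted slope is the
    factor that maps the monitor onto the reference scale.  Through-origin
    fits (the default) solve min ||y - b x||; intercept fits use ordinary
    least squares.  NaN pairs are dropped; zero variance in ``x`` yields an
    error result rather than an exception — an incalculable slope is how
    dead sensors announce themselves.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    keep = x.notna() & y.notna()
    xv, yv = x[keep].to_numpy(), y[keep].to_numpy()
    n = len(xv)
    if n < 2:
        return _error_result(n, "fewer than 2 concurrent points")
    if np.ptp(xv) == 0:
        return _error_result(n, "zero variance in monitor values (dead sensor?)")
    if intercept_fit:
        fit = stats.linregress(xv, yv)
        slope, intercept = float(fit.slope), float(fit.intercept)
        resid = yv - (slope * xv + intercept)
    else:
        slope = float(np.linalg.lstsq(xv[:, None], yv[:, None], rcond=None)[0][0, 0])
        intercept = 0.0
        resid = yv - slope * xv
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if np.allclose(resid, 0) else 0.0
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    r2 = min(1.0, max(0.0, r2))
    return RegressionResult(slope, intercept, r2, n)


@dataclass(frozen=True)
class InclusionResult:
    """Outcome of the data inclusion criteria for one monitor."""

    passed: bool
    n_concurrent: int
    criteria: dict[str, bool]
    ref_min: float
    ref_max: float


def check_inclusion(
    monitor_values,
    reference_values,
    *,
    min_points: int = MIN_CONCURRENT_POINTS,
) -> InclusionResult:
    """Evaluate the co-location data inclusion criteria for one monitor.

    All four must hold: (1) at least ``min_points`` concurrent 10-min
    points; (2) reference maximum above 1 µg/m³ (functional range of the
    sensor); (3) reference maximum more than twice its minimum; and
    (4) reference range (max - min) more than twice the minimum — (3) and
    (4) both ensure enough spread for a meaningful regression.
    """
    x = pd.Series(np.asarray(monitor_values, dtype=float))
    y = pd.Series(np.asarray(reference_values, dtype=float))
    if len(x) != len(y):
        raise ValueError("monitor and reference values must be paired")
    keep = x.notna() & y.notna()
    yv = y[keep].to_numpy()
    n = len(yv)
    if n == 0:
        criteria = {"min_points": False, "max_gt_1": False, "max_gt_2min": False, "range_gt_2min": False}
        return InclusionResult(False, 0, criteria, math.nan, math.nan)
    ref_min, ref_max = float(yv.min()), float(yv.max())
    criteria = {
        "min_points": n >= min_points,
        "max_gt_1": ref_max > 1.0,
        "max_gt_2min": ref_max > 2.0 * ref_min,
        "range_gt_2min": (ref_max - ref_min) > 2.0 * ref_min,
    }
    return InclusionResult(all(criteria.values()), n, criteria, ref_min, ref_max)


def pick_arbitrary_reference(fleet: dict[str, pd.DataFrame]) -> str:
    """The monitor with the most co-location records (ties: lexicographic id).

    Records are counted on non-missing ``pm2.5_alt`` values (falling back to
    row count when the column is absent).
    """
    if not fleet:
        raise ValueError("empty fleet")

    def n_records(frame: pd.DataFrame) -> int:
        if "pm2.5_alt" in frame.columns:
            return int(frame["pm2.5_alt"].notna().sum())
        return len(frame)

    return min(fleet, key=lambda mid: (-n_records(fleet[mid]), mid))


def mean_reference(
    fleet: dict[str, pd.DataFrame],
    parameters: tuple[str, ...] = PARAMETERS,
) -> pd.DataFrame:
    """Per-stamp mean across monitors, at strictly concurrent stamps only.

    For each parameter, a stamp enters the reference only when *every*
    monitor in ``fleet`` reports a value there; the reference value is the
    arithmetic mean across monitors.  With a single monitor the reference
    is that monitor.
    """
    if not fleet:
        raise ValueError("empty fleet")
    cols = {}
    for p in parameters:
        per_monitor = [f[p] for f in fleet.values() if p in f.columns]
        if len(per_monitor) != len(fleet):
            continue
        stacked = pd.concat(per_monitor, axis=1)
        cols[p] = stacked.dropna(how="any").mean(axis=1)
    return pd.DataFrame(cols)


class Status(enum.Enum):
    ACCEPTED = "ACCEPTED"
    FLAGGED_SINGLE_CHANNEL = "FLAGGED_SINGLE_CHANNEL"
    FLAGGED_OFFSET = "FLAGGED_OFFSET"
    EXCLUDED = "EXCLUDED"


@dataclass
class MonitorStatus:
    """QA classification of one monitor with its failing parameters."""

    status: Status
    channel: str | None = None  # surviving channel for FLAGGED_SINGLE_CHANNEL
    failing: list[str] = field(default_factory=list)
    notes: str = ""


def _fit_params(
    monitor: pd.DataFrame,
    reference: pd.DataFrame,
    parameters,
    *,
    channel: str | None = None,
    force_intercept: bool = False,
) -> dict[str, RegressionResult]:
    out = {}
    for p in parameters:
        col = chan(p, channel) if channel else p
        if col not in monitor.columns or p not in reference.columns:
            out[p] = _error_result(0, f"missing column {col!r}")
            continue
        pair = pd.concat([monitor[col], reference[p]], axis=1, join="inner")
        out[p] = fit_monitor(
            pair.iloc[:, 0],
            pair.iloc[:, 1],
            intercept_fit=force_intercept or p in INTERCEPT_FIT_PARAMETERS,
        )
    return out


def classify_monitor(
    monitor: pd.DataFrame,
    reference: pd.DataFrame,
    parameters: tuple[str, ...] = PARAMETERS,
    *,
    r2_min: float = R2_ACCEPT,
) -> tuple[MonitorStatus, dict[str, RegressionResult]]:
    """Classify one monitor from its per-parameter regressions vs a reference.

    ACCEPTED when every parameter reaches r² >= ``r2_min`` on the combined
    (channel-mean) values.  Otherwise each channel is refitted separately:
    if exactly one channel passes everything the monitor is usable on that
    channel alone (FLAGGED_SINGLE_CHANNEL).  Failing that, the failing
    parameters are refitted with a free intercept: if they then pass, the
    fault is a correctable additive offset (FLAGGED_OFFSET).  Anything else
    is EXCLUDED.
    """
    combined = _fit_params(monitor, reference, parameters)

    def passes(results: dict[str, RegressionResult]) -> bool:
        return all(r.ok and r.r_squared >= r2_min for r in results.values())

    failing = [p for p, r in combined.items() if not (r.ok and r.r_squared >= r2_min)]
    if not failing:
        return MonitorStatus(Status.ACCEPTED), combined

    channel_pass = {}
    for ch in ("a", "b"):
        channel_pass[ch] = passes(_fit_params(monitor, reference, parameters, channel=ch))
    if sum(channel_pass.values()) == 1:
        ch = "a" if channel_pass["a"] else "b"
        return (
            MonitorStatus(
                Status.FLAGGED_SINGLE_CHANNEL,
                channel=ch,
                failing=failing,
                notes=f"channel {ch} passes all parameters; other channel faulty",
            ),
            combined,
        )

    with_intercept = _fit_params(monitor, reference, failing, force_intercept=True)
    if passes(with_intercept):
        return (
            MonitorStatus(
                Status.FLAGGED_OFFSET,
                failing=failing,
                notes="failing parameters recover with a free intercept",
            ),
            combined,
        )
    return (
        MonitorStatus(Status.EXCLUDED, failing=failing, notes="fails all recovery routes"),
        combined,
    )


@dataclass
class FleetQAResult:
    """Everything the co-location pipeline produces for one fleet.

    ``factors`` is a tidy table (monitor_id, parameter, slope, intercept,
    r_squared, n, status, channel); ``summary`` carries per-parameter
    mean/min/max of slope and r² across non-excluded monitors, the fleet
    analogue of the published co-location summary tables.
    """

    mode: str
    reference_id: str
    statuses: dict[str, MonitorStatus]
    regressions: dict[str, dict[str, RegressionResult]]
    factors: pd.DataFrame
    summary: pd.DataFrame
    reference: pd.DataFrame
    inclusion: dict[str, InclusionResult]

    @property
    def n_excluded(self) -> int:
        return sum(1 for s in self.statuses.values() if s.status is Status.EXCLUDED)

    @property
    def retained_fraction(self) -> float:
        return retention_rate(self.n_excluded, len(self.statuses))

    def factors_for(self, monitor_id: str) -> pd.DataFrame:
        return self.factors[self.factors["monitor_id"] == monitor_id]


def retention_rate(n_excluded: int, n_total: int) -> float:
    """Fleet acceptability: fraction of monitors retained, in percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * (n_total - n_excluded) / n_total


def _inclusion_alt(frame: pd.DataFrame) -> pd.Series:
    """The monitor's PM2.5 series used for concurrency counting.

    Normally the combined (channel-mean) values; a monitor with one dead
    channel still records concurrent data on the surviving channel, so fall
    back to the across-channel mean ignoring the missing one.
    """
    alt = frame["pm2.5_alt"]
    if alt.notna().any():
        return alt
    cols = [c for c in (chan("pm2.5_alt", "a"), chan("pm2.5_alt", "b")) if c in frame.columns]
    if cols:
        return frame[cols].mean(axis=1)
    return alt


def effective_frame(frame: pd.DataFrame, status: MonitorStatus) -> pd.DataFrame:
    """The data a non-excluded monitor contributes to the mean reference.

    Flagged single-channel monitors contribute their surviving channel in
    place of the (undefined or contaminated) channel mean.
    """
    if status.status is not Status.FLAGGED_SINGLE_CHANNEL:
        return frame
    out = frame.copy()
    for p in PARAMETERS:
        col = chan(p, status.channel)
        if col in frame.columns:
            out[p] = frame[col]
    return out


def _factor_rows(
    mid: str,
    status: MonitorStatus,
    monitor: pd.DataFrame,
    reference: pd.DataFrame,
    parameters,
    r2_min: float,
) -> tuple[list[dict], dict[str, RegressionResult]]:
    """Final-reference regressions for one non-excluded monitor.

    Flagged-single-channel monitors are fitted on the surviving channel;
    offset-flagged monitors get a free intercept on every parameter so the
    offset is absorbed into the factor.
    """
    channel = status.channel if status.status is Status.FLAGGED_SINGLE_CHANNEL else None
    force_intercept = status.status is Status.FLAGGED_OFFSET
    fits = _fit_params(
        monitor, reference, parameters, channel=channel, force_intercept=force_intercept
    )
    rows = [
        {
            "monitor_id": mid,
            "parameter": p,
            "slope": r.slope,
            "intercept": r.intercept,
            "r_squared": r.r_squared,
            "n": r.n,
            "status": status.status.value,
            "channel": channel or "mean",
        }
        for p, r in fits.items()
        if r.ok
    ]
    return rows, fits


def fleet_qa(
    fleet: dict[str, pd.DataFrame],
    mode: str = "mean",
    *,
    parameters: tuple[str, ...] = PARAMETERS,
    r2_min: float = R2_ACCEPT,
    min_points: int = MIN_CONCURRENT_POINTS,
    check_inclusion_criteria: bool = True,
) -> FleetQAResult:
    """Run the full co-location QA pipeline over a harmonized fleet.

    Pipeline: pick the arbitrary reference (most-recording monitor) ->
    inclusion criteria -> per-parameter regressions vs the arbitrary
    reference -> classify every monitor -> drop EXCLUDED -> build the
    mean-of-monitors reference from the remainder (``mode="mean"``) ->
    regress every non-excluded monitor against the final reference ->
    emit the co-location factor table and per-parameter summary statistics.

    ``fleet`` maps monitor_id to a canonical wide 10-min frame (as produced
    by the harmonize module).
    """
    if mode not in ("mean", "arbitrary"):
        raise ValueError(f"mode must be 'mean' or 'arbitrary', got {mode!r}")
    if not fleet:
        raise ValueError("empty fleet")

    ref_id = pick_arbitrary_reference(fleet)
    arb_ref = fleet[ref_id][[p for p in parameters if p in fleet[ref_id].columns]]

    inclusion: dict[str, InclusionResult] = {}
    statuses: dict[str, MonitorStatus] = {}
    regressions: dict[str, dict[str, RegressionResult]] = {}

    for mid, frame in fleet.items():
        if check_inclusion_criteria and "pm2.5_alt" in frame.columns and "pm2.5_alt" in arb_ref.columns:
            pair = pd.concat(
                [_inclusion_alt(frame), arb_ref["pm2.5_alt"]], axis=1, join="inner"
            )
            inc = check_inclusion(pair.iloc[:, 0], pair.iloc[:, 1], min_points=min_points)
            inclusion[mid] = inc
            if not inc.passed:
                statuses[mid] = MonitorStatus(
                    Status.EXCLUDED,
                    failing=[k for k, v in inc.criteria.items() if not v],
                    notes="failed data inclusion criteria",
                )
                regressions[mid] = {}
                continue
        status, fits = classify_monitor(frame, arb_ref, parameters, r2_min=r2_min)
        statuses[mid] = status
        regressions[mid] = fits

    non_excluded = {
        mid: fleet[mid] for mid, s in statuses.items() if s.status is not Status.EXCLUDED
    }
    if not non_excluded:
        raise ValueError("all monitors excluded; no reference can be formed")

    if mode == "mean":
        effective = {
            mid: effective_frame(f, statuses[mid]) for mid, f in non_excluded.items()
        }
        final_ref = mean_reference(effective, parameters)
    else:
        final_ref = arb_ref

    rows: list[dict] = []
    for mid, frame in non_excluded.items():
        monitor_rows, _ = _factor_rows(
            mid, statuses[mid], frame, final_ref, parameters, r2_min
        )
        rows.extend(monitor_rows)
    factors = pd.DataFrame(
        rows,
        columns=["monitor_id", "parameter", "slope", "intercept", "r_squared", "n", "status", "channel"],
    )

    summary = (
        factors.groupby("parameter")
        .agg(
            slope_mean=("slope", "mean"),
            slope_min=("slope", "min"),
            slope_max=("slope", "max"),
            r2_mean=("r_squared", "mean"),
            r2_min=("r_squared", "min"),
            r2_max=("r_squared", "max"),
            n_monitors=("slope", "size"),
        )
        .reindex([p for p in parameters if p in factors["parameter"].values])
    )

    return FleetQAResult(
        mode=mode,
        reference_id=ref_id,
        statuses=statuses,
        regressions=regressions,
        factors=factors,
        summary=summary,
        reference=final_ref,
        inclusion=inclusion,
    )


def sentinel_reference(result: FleetQAResult, k: int = 5) -> list[str]:
    """Pick the k best-performing monitors to stand in for the fleet reference.

    Late-returning monitors cannot be co-located with the whole fleet; a
    small set of sentinels whose mean approximates the full-fleet mean is
    used instead.  Monitors are scored on the ``pm2.5_alt`` factor-table
    regression by |slope - 1| + (1 - r²), smaller is better; only ACCEPTED
    monitors are eligible.  Ties break lexicographically by id.
    """
    if k < 1:
        raise ValueError("k must be positive")
    alt = result.factors[result.factors["parameter"] == "pm2.5_alt"]
    scores = {}
    for _, row in alt.iterrows():
        mid = row["monitor_id"]
        if result.statuses[mid].status is not Status.ACCEPTED:
            continue
        scores[mid] = abs(row["slope"] - 1.0) + (1.0 - row["r_squared"])
    ranked = sorted(scores, key=lambda mid: (scores[mid], mid))
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} accepted monitors available for {k} sentinels",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]


def apply_factors(
    frame: pd.DataFrame,
    factors: pd.DataFrame,
    monitor_id: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Map a monitor's raw field series onto the reference scale.

    Each parameter with a factor becomes slope*raw (+ intercept where one was
    fitted), applied to the mean column and both channel columns.  Parameters
    without a factor pass through unchanged and are returned in the flag
    list rather than silently adjusted.
    """
    table = factors[factors["monitor_id"] == monitor_id]
    if table.empty:
        raise KeyError(f"no co-location factors for monitor {monitor_id!r}")
    out = frame.copy()
    by_param = table.set_index("parameter")
    missing: list[str] = []
    for p in PARAMETERS:
        cols = [c for c in (p, chan(p, "a"), chan(p, "b")) if c in frame.columns]
        if not cols:
            continue
        if p not in by_param.index:
            missing.append(p)
            continue
        slope = float(by_param.loc[p, "slope"])
        intercept = float(by_param.loc[p, "intercept"])
        for c in cols:
            out[c] = slope * frame[c] + intercept
    return out, missing
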