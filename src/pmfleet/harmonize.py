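"""Resampling, source merging and fleet alignment on a 10-min time base.

Records written to a monitor's SD card arrive at ~2-min spacing whose clock
drifts by seconds per cycle, so raw streams from different monitors are never
synchronized.  Cloud records are natively synchronized at 10-min boundaries.
Harmonization maps every stream onto the common 10-min grid by averaging all
records falling in each window [hh:m0:00, hh:m9:59], merges SD and cloud
streams per monitor (preferring cloud where both report, since its stamps
are natively synchronized), and aligns a fleet of series on a shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import PARAMETERS, Source, chan
from .size_mass import DEFAULT_COEFFICIENTS, AltCoefficients, alt_mass_from_counts

__all__ = [
    "HarmonizedSeries",
    "resample_10min",
    "merge_sources",
    "compute_derived_alt",
    "align_fleet",
    "to_long",
]

_WINDOW = "10min"


@dataclass
class HarmonizedSeries:
    """One monitor's data on the synchronized 10-min grid.

    ``data`` is a canonical wide DataFrame (columns ``p_a``/``p_b``/``p``)
    indexed by exact 10-min boundary stamps; ``provenance`` records per stamp
    whether the value came from the cloud stream, the SD card, or both, and
    ``n_source_records`` how many source records the window averaged.  Where
    both sources report, the SD window means are retained in ``sd_shadow``
    for disagreement diagnostics.
    """

    monitor_id: str
    data: pd.DataFrame
    provenance: pd.Series
    n_source_records: pd.Series
    sd_shadow: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        if len(idx):
            if idx.has_duplicates:
                raise ValueError("duplicate 10-min stamps")
            if not ((idx.second == 0).all() and (idx.minute % 10 == 0).all()):
                raise ValueError("stamps must lie on exact 10-min boundaries")

    def __len__(self) -> int:
        return len(self.data)


def resample_10min(
    records: pd.DataFrame,
    monitor_id: str,
    source: Source = Source.SD,
) -> HarmonizedSeries:
    """Average 2-min records into synchronized 10-min windows.

    Every record with timestamp in [hh:m0:00, hh:m9:59] contributes to the
    window labeled hh:m0:00; the window value is the plain arithmetic mean,
    per parameter per channel, of whatever records fell inside (clock drift
    makes 4–6 typical).  Windows with no records are absent, not NaN rows.
    A single record suffices to emit a window.
    """
    if records.empty:
        empty = pd.DataFrame(index=pd.DatetimeIndex([], tz="UTC", name="timestamp"))
        return HarmonizedSeries(
            monitor_id,
            empty,
            pd.Series(dtype=object),
            pd.Series(dtype=int),
        )
    floored = records.index.floor(_WINDOW)
    grouped = records.groupby(floored)
    data = grouped.mean()
    data.index.name = "timestamp"
    n = grouped.size()
    prov = pd.Series(source.value, index=data.index)
    return HarmonizedSeries(monitor_id, data, prov, n)


def merge_sources(wifi: HarmonizedSeries, sd: HarmonizedSeries) -> HarmonizedSeries:
    """Union the cloud and SD 10-min series of one monitor.

    At stamps where both sources report, the cloud value is used (its stamps
    are natively synchronized) and provenance is ``BOTH``; the SD window
    means at those stamps are kept in ``sd_shadow`` so material disagreement
    can be inspected rather than silently discarded.
    """
    if wifi.monitor_id != sd.monitor_id:
        raise ValueError(
            f"cannot merge different monitors: {wifi.monitor_id!r} vs {sd.monitor_id!r}"
        )
    both = wifi.data.index.intersection(sd.data.index)
    sd_only = sd.data.index.difference(wifi.data.index)
    data_parts = [df for df in (wifi.data, sd.data.loc[sd_only]) if not df.empty]
    prov_parts = [s for s in (wifi.provenance, sd.provenance.loc[sd_only]) if not s.empty]
    data = pd.concat(data_parts).sort_index() if data_parts else wifi.data
    prov = pd.concat(prov_parts).sort_index() if prov_parts else wifi.provenance
    prov.loc[both] = "BOTH"
    n = (
        wifi.n_source_records.reindex(data.index, fill_value=0)
        + sd.n_source_records.reindex(data.index, fill_value=0)
    ).astype(int)
    shadow = sd.data.loc[both] if len(both) else None
    return HarmonizedSeries(wifi.monitor_id, data, prov, n, sd_shadow=shadow)


def compute_derived_alt(
    series: HarmonizedSeries,
    coeffs: AltCoefficients = DEFAULT_COEFFICIENTS,
    *,
    force: bool = False,
) -> HarmonizedSeries:
    """Fill in per-channel ALT mass from the 10-min-averaged size-bin counts.

    ``pm2.5_alt_a`` / ``_b`` are computed from each channel's averaged
    cumulative counts (ALT is linear, so averaging counts then converting
    equals converting then averaging); ``pm2.5_alt`` is the mean of the two
    channels, missing when either channel is.  Cloud-provided ALT values are
    left untouched unless ``force`` recomputes everything.
    """
    data = series.data.copy()
    need = ["0.3_um_count", "0.5_um_count", "1.0_um_count", "2.5_um_count"]
    for ch in ("a", "b"):
        cols = [chan(p, ch) for p in need]
        target = chan("pm2.5_alt", ch)
        if not all(c in data.columns for c in cols):
            continue  # counts missing for this channel -> its alt stays missing
        alt = alt_mass_from_counts(*(data[c] for c in cols), coeffs, clamp_negative=True)
        alt = pd.Series(alt, index=data.index)
        if target in data.columns and not force:
            data[target] = data[target].where(data[target].notna(), alt)
        else:
            data[target] = alt
    a, b = chan("pm2.5_alt", "a"), chan("pm2.5_alt", "b")
    if a in data.columns and b in data.columns:
        mean = (data[a] + data[b]) / 2.0
        if "pm2.5_alt" in data.columns and not force:
            data["pm2.5_alt"] = data["pm2.5_alt"].where(data["pm2.5_alt"].notna(), mean)
        else:
            data["pm2.5_alt"] = mean
    return HarmonizedSeries(
        series.monitor_id, data, series.provenance.copy(),
        series.n_source_records.copy(), series.sd_shadow,
    )


def align_fleet(
    fleet: dict[str, HarmonizedSeries] | dict[str, pd.DataFrame],
    *,
    how: str = "union",
) -> tuple[pd.DatetimeIndex, dict[str, pd.DataFrame]]:
    """Place all monitors of a fleet on one common 10-min grid.

    Returns the grid (union or intersection of the per-monitor stamps) and
    each monitor's frame reindexed onto it, with missing cells explicit NaN.
    """
    if not fleet:
        raise ValueError("align_fleet needs at least one series")
    if how not in ("union", "intersection"):
        raise ValueError(f"how must be 'union' or 'intersection', got {how!r}")
    frames = {
        mid: (s.data if isinstance(s, HarmonizedSeries) else s) for mid, s in fleet.items()
    }
    grid: pd.DatetimeIndex | None = None
    for f in frames.values():
        grid = f.index if grid is None else (
            grid.union(f.index) if how == "union" else grid.intersection(f.index)
        )
    assert grid is not None
    grid = grid.sort_values()
    return grid, {mid: f.reindex(grid) for mid, f in frames.items()}


def to_long(series: HarmonizedSeries) -> pd.DataFrame:
    """Tidy long-format view (monitor_id, timestamp, parameter, channel, value,
    provenance) for report/CSV output."""
    rows = []
    for p in PARAMETERS:
        for ch_label, col in (("a", chan(p, "a")), ("b", chan(p, "b")), ("mean", p)):
            if col not in series.data.columns:
                continue
            vals = series.data[col]
            rows.append(
                pd.DataFrame(
                    {
                        "monitor_id": series.monitor_id,
                        "timestamp": vals.index,
                        "parameter": p,
                        "channel": ch_label,
                        "value": vals.values,
                        "provenance": series.provenance.reindex(vals.index).values,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            columns=["monitor_id", "timestamp", "parameter", "channel", "value", "provenance"]
        )
    return pd.concat(rows, ignore_index=True)
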