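"""Reading and writing the two monitor data dialects.

Dual-channel particle monitors deliver data two ways, with different
structure and *different channel semantics*:

* **SD dialect** — one CSV per UTC day written to the on-board card, one row
  per ~2-min record.  For each reported field the unsuffixed column carries
  channel A and the ``_b`` column channel B — the unsuffixed column is *not*
  the channel average, so the relabeling in :func:`relabel_sd_channels` is
  required before SD data can be compared with cloud data.  The SD dialect
  carries no ALT mass field; it must be computed downstream.

* **Cloud (Wi-Fi) dialect** — rows synchronized to 10-min boundaries
  (hh:m0:00), where each field appears as ``<p>_a``, ``<p>_b`` and ``<p>``,
  the last being the mean of the two channels.

Internally both dialects land in one "canonical wide" representation: a
pandas DataFrame indexed by tz-aware UTC timestamps with, per parameter
``p``, columns ``p_a``, ``p_b`` and ``p`` (channel mean).  Missing values
are NaN, never zero — zero is a legal concentration.
"""

from __future__ import annotations

import enum
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETERS",
    "COUNT_PARAMETERS",
    "INTERCEPT_FIT_PARAMETERS",
    "SD_PARAMETERS",
    "Source",
    "DialectError",
    "DeploymentMeta",
    "chan",
    "parse_sd_file",
    "relabel_sd_channels",
    "parse_wifi_records",
    "write_sd_file",
    "write_wifi_records",
    "sd_filename",
    "read_meta",
    "write_meta",
]

#: The 16 regression parameters of the co-location procedure.
PARAMETERS: tuple[str, ...] = (
    "0.3_um_count",
    "0.5_um_count",
    "1.0_um_count",
    "2.5_um_count",
    "5.0_um_count",
    "10.0_um_count",
    "pm2.5_alt",
    "pm1.0_cf_1",
    "pm2.5_cf_1",
    "pm10.0_cf_1",
    "pm1.0_atm",
    "pm2.5_atm",
    "pm10.0_atm",
    "temperature",
    "humidity",
    "pressure",
)

#: Cumulative number-concentration parameters (particles/dL), by threshold µm.
COUNT_PARAMETERS: tuple[str, ...] = PARAMETERS[:6]

#: Parameters whose monitor-vs-reference regression is fitted with a free
#: intercept (environmental sensors show additive offsets); all others are
#: fitted through the origin.
INTERCEPT_FIT_PARAMETERS: frozenset[str] = frozenset(
    {"temperature", "humidity", "pressure"}
)

#: Parameters present in the SD dialect (no ALT mass on the card).
SD_PARAMETERS: tuple[str, ...] = tuple(p for p in PARAMETERS if p != "pm2.5_alt")

assert len(PARAMETERS) == 16 and len(INTERCEPT_FIT_PARAMETERS) == 3


class Source(enum.Enum):
    """Provenance of a record stream."""

    SD = "SD"
    WIFI = "WIFI"


class DialectError(ValueError):
    """Raised when an input file does not match the expected dialect."""


def chan(parameter: str, channel: str | None = None) -> str:
    """Canonical column name for a parameter/channel.

    ``channel`` is ``"a"``, ``"b"`` or None for the two-channel mean.
    """
    if channel is None:
        return parameter
    if channel not in ("a", "b"):
        raise ValueError(f"channel must be 'a' or 'b', got {channel!r}")
    return f"{parameter}_{channel}"


# ---------------------------------------------------------------------------
# deployment metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeploymentMeta:
    """Where and how one monitor was deployed.

    ``monitor_type`` distinguishes Wi-Fi-only units from units that also log
    to an on-board SD card; indoor monitors may name the outdoor monitor they
    are paired with for indoor/outdoor ratio analysis.
    """

    monitor_id: str
    monitor_type: str  # "WIFI_ONLY" | "WIFI_SD"
    role: str  # "INDOOR" | "OUTDOOR"
    deploy_start: pd.Timestamp
    deploy_end: pd.Timestamp
    paired_outdoor_id: str | None = None

    def __post_init__(self) -> None:
        if self.monitor_type not in ("WIFI_ONLY", "WIFI_SD"):
            raise ValueError(f"unknown monitor_type {self.monitor_type!r}")
        if self.role not in ("INDOOR", "OUTDOOR"):
            raise ValueError(f"unknown role {self.role!r}")
        start = pd.Timestamp(self.deploy_start)
        end = pd.Timestamp(self.deploy_end)
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
        if end.tzinfo is None:
            end = end.tz_localize("UTC")
        object.__setattr__(self, "deploy_start", start)
        object.__setattr__(self, "deploy_end", end)
        if not start < end:
            raise ValueError("deploy_start must precede deploy_end")
        if self.role == "OUTDOOR" and self.paired_outdoor_id is not None:
            raise ValueError("outdoor monitors never name a paired outdoor monitor")


def write_meta(metas: Iterable[DeploymentMeta]) -> str:
    """Serialize deployment metadata to CSV text."""
    rows = [
        {
            "monitor_id": m.monitor_id,
            "monitor_type": m.monitor_type,
            "role": m.role,
            "deploy_start": m.deploy_start.isoformat(),
            "deploy_end": m.deploy_end.isoformat(),
            "paired_outdoor_id": m.paired_outdoor_id or "",
        }
        for m in metas
    ]
    return pd.DataFrame(rows).to_csv(index=False)


def read_meta(source: str | Path) -> list[DeploymentMeta]:
    """Parse deployment metadata from CSV text or a file path."""
    df = pd.read_csv(_as_buffer(source), dtype=str).fillna("")
    return [
        DeploymentMeta(
            monitor_id=row["monitor_id"],
            monitor_type=row["monitor_type"],
            role=row["role"],
            deploy_start=pd.Timestamp(row["deploy_start"]),
            deploy_end=pd.Timestamp(row["deploy_end"]),
            paired_outdoor_id=row["paired_outdoor_id"] or None,
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

#: Default name of the timestamp column in each dialect.  Firmware variants
#: rename columns; pass a ``column_map`` of {file column -> canonical name}
#: to adapt (the timestamp column maps to "timestamp").
SD_TIMESTAMP_COLUMN = "UTCDateTime"
WIFI_TIMESTAMP_COLUMN = "time_stamp"


def _as_buffer(source: str | Path) -> io.StringIO:
    """Accept raw text, a path, or a path-like string transparently."""
    if isinstance(source, Path):
        return io.StringIO(source.read_text())
    s = str(source)
    if s and "\n" not in s:
        p = Path(s)
        if p.is_file():
            return io.StringIO(p.read_text())
    return io.StringIO(s)


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    df = df.rename(columns=lambda c: str(c).strip())
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """Parse epoch-seconds or ISO-8601 stamps to tz-aware UTC; NaT on failure."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if len(raw) and numeric.notna().sum() >= max(1, len(raw) // 2):
        return pd.to_datetime(numeric, unit="s", utc=True)
    return pd.to_datetime(raw, utc=True, errors="coerce", format="ISO8601")


@dataclass
class SDParseResult:
    """Raw-semantics SD records plus the count of rows that could not be read."""

    frame: pd.DataFrame
    n_skipped: int


def parse_sd_file(
    source: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
) -> SDParseResult:
    """Parse one SD-dialect daily CSV into raw-semantics records.

    Channel semantics are preserved exactly as on the card (the unsuffixed
    column is one channel, ``_b`` the other); use
    :func:`relabel_sd_channels` to obtain canonical a/b/mean columns.
    Malformed rows (wrong field count, unparseable timestamp) are skipped and
    counted, not fatal; a missing header is a dialect error.
    """
    bad_rows: list[list[str]] = []
    try:
        df = pd.read_csv(
            _as_buffer(source),
            engine="python",
            on_bad_lines=lambda row: bad_rows.append(row),  # type: ignore[arg-type]
        )
    except pd.errors.EmptyDataError as exc:
        raise DialectError("empty SD file (no header row)") from exc
    df = _apply_column_map(df, column_map)
    ts_col = "timestamp" if "timestamp" in df.columns else SD_TIMESTAMP_COLUMN
    if ts_col not in df.columns:
        raise DialectError(
            f"SD dialect requires a {SD_TIMESTAMP_COLUMN!r} (or mapped 'timestamp') column"
        )
    stamps = _parse_timestamps(df[ts_col])
    n_skipped = len(bad_rows) + int(stamps.isna().sum())
    df = df.loc[stamps.notna()].copy()
    df.index = pd.DatetimeIndex(stamps.dropna(), name="timestamp")
    df = df.drop(columns=[ts_col]).apply(pd.to_numeric, errors="coerce")
    df = df.sort_index()
    return SDParseResult(frame=df, n_skipped=n_skipped)


def relabel_sd_channels(frame: pd.DataFrame) -> pd.DataFrame:
    """Relabel raw SD semantics into canonical a/b/mean columns.

    On the SD card the unsuffixed field holds channel A (not the channel
    average as in the cloud dialect).  For every parameter the unsuffixed
    value becomes ``<p>_a``, the ``_b`` value stays ``<p>_b``, and ``<p>``
    is recomputed as the mean of the two channels — undefined (NaN) when
    either channel is missing.
    """
    out = pd.DataFrame(index=frame.index.copy())
    params = [p for p in SD_PARAMETERS if p in frame.columns or f"{p}_b" in frame.columns]
    for p in params:
        a = frame[p] if p in frame.columns else pd.Series(np.nan, index=frame.index)
        b = frame[f"{p}_b"] if f"{p}_b" in frame.columns else pd.Series(np.nan, index=frame.index)
        out[chan(p, "a")] = a
        out[chan(p, "b")] = b
        out[p] = (a + b) / 2.0
    return out


@dataclass
class WifiParseResult:
    """Canonical cloud records plus consistency diagnostics.

    ``mean_violations`` lists (timestamp, parameter) pairs where the reported
    mean differed from (a+b)/2 beyond tolerance (rows are retained);
    ``highres`` holds rows whose stamps were not on 10-min boundaries — the
    high-resolution (2-min) cloud dialect, to be routed like SD data.
    """

    frame: pd.DataFrame
    mean_violations: list[tuple[pd.Timestamp, str]] = field(default_factory=list)
    highres: pd.DataFrame | None = None


def parse_wifi_records(
    source: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    mean_tol: float = 1e-6,
) -> WifiParseResult:
    """Parse cloud-dialect records (CSV or JSON-lines) into canonical form.

    Rows are expected on exact 10-min boundaries (hh:m0:00); off-boundary
    rows are split out as the 2-min high-resolution dialect.  The dialect's
    mean-consistency invariant (``p`` = mean of ``p_a`` and ``p_b``) is
    checked and violations flagged but retained.
    """
    text = _as_buffer(source).getvalue()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        df = pd.read_json(io.StringIO(text), lines=True, convert_dates=False)
    else:
        try:
            df = pd.read_csv(io.StringIO(text))
        except pd.errors.EmptyDataError as exc:
            raise DialectError("empty cloud payload") from exc
    df = _apply_column_map(df, column_map)
    ts_col = "timestamp" if "timestamp" in df.columns else WIFI_TIMESTAMP_COLUMN
    if ts_col not in df.columns:
        raise DialectError(
            f"cloud dialect requires a {WIFI_TIMESTAMP_COLUMN!r} (or mapped 'timestamp') column"
        )
    stamps = _parse_timestamps(df[ts_col])
    df = df.loc[stamps.notna()].copy()
    df.index = pd.DatetimeIndex(stamps.dropna(), name="timestamp")
    df = df.drop(columns=[ts_col]).apply(pd.to_numeric, errors="coerce").sort_index()

    on_boundary = (df.index.second == 0) & (df.index.minute % 10 == 0)
    highres = df.loc[~on_boundary] if (~on_boundary).any() else None
    df = df.loc[on_boundary]

    violations: list[tuple[pd.Timestamp, str]] = []
    for p in PARAMETERS:
        a, b = chan(p, "a"), chan(p, "b")
        if p in df.columns and a in df.columns and b in df.columns:
            expected = (df[a] + df[b]) / 2.0
            bad = (df[p] - expected).abs() > mean_tol * np.maximum(1.0, expected.abs())
            bad &= expected.notna() & df[p].notna()
            violations.extend((ts, p) for ts in df.index[bad])
    return WifiParseResult(frame=df, mean_violations=violations, highres=highres)


# ---------------------------------------------------------------------------
# writers (bit-faithful for the simulator; parse∘write is the identity)
# ---------------------------------------------------------------------------


def sd_filename(monitor_id: str, day: pd.Timestamp) -> str:
    """Daily SD file name, ``<monitor_id>_<YYYYMMDD>.csv``."""
    return f"{monitor_id}_{pd.Timestamp(day).strftime('%Y%m%d')}.csv"


def write_sd_file(frame: pd.DataFrame) -> str:
    """Serialize raw-semantics SD records (as from :func:`parse_sd_file`) to CSV.

    Float formatting uses Python repr, so a write→parse roundtrip reproduces
    values exactly.
    """
    out = frame.copy()
    out.insert(0, SD_TIMESTAMP_COLUMN, out.index.strftime("%Y-%m-%dT%H:%M:%SZ"))
    return out.to_csv(index=False)


def write_wifi_records(frame: pd.DataFrame, *, jsonl: bool = False) -> str:
    """Serialize canonical cloud records to CSV (or JSON-lines) text."""
    out = frame.copy()
    if jsonl:
        out.insert(0, WIFI_TIMESTAMP_COLUMN, (out.index.view("int64") // 10**9))
        return out.to_json(orient="records", lines=True)
    out.insert(0, WIFI_TIMESTAMP_COLUMN, out.index.strftime("%Y-%m-%dT%H:%M:%S+00:00"))
    return out.to_csv(index=False)


_SD_PAT = re.compile(r"^(?P<mid>.+)_(?P<day>\d{8})\.csv$")


def parse_sd_filename(name: str) -> tuple[str, pd.Timestamp]:
    """Split ``<monitor_id>_<YYYYMMDD>.csv`` into (monitor_id, day)."""
    m = _SD_PAT.match(Path(name).name)
    if not m:
        raise DialectError(f"not an SD daily file name: {name!r}")
    return m.group("mid"), pd.Timestamp(m.group("day"), tz="UTC")
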