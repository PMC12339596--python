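"""Synthetic fleets of dual-channel particle monitors with ground truth.

The simulator emulates the conditions a residential field study actually
produces, so every pipeline stage is testable without any real deployment
data: a shared latent PM2.5 process (ambient infiltration as a lognormal
AR(1) plus intermittent indoor-source spikes with exponential decay),
per-monitor multiplicative gains and fault injections (low-gain units,
additive offsets, dead channels, dead temperature sensors), the three
observed clock-drift regimes of 2-min SD logging, and the two observed
data-loss modes (cloud transmission outages; SD streams that stop
permanently or gap intermittently).

Generated size-bin counts are apportioned from a lognormal number
distribution and scaled so the ALT mass of the bins equals the latent
target exactly; the 10-min cloud payload is computed by the same in-window
averaging the pipeline uses, so the internal-consistency invariants of the
real data hold by construction.  Seeded runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import harmonize
from .io_formats import (
    PARAMETERS,
    SD_PARAMETERS,
    DeploymentMeta,
    Source,
    chan,
    sd_filename,
    write_meta,
    write_sd_file,
    write_wifi_records,
)
from .size_mass import DEFAULT_COEFFICIENTS, AltCoefficients

__all__ = [
    "DriftRegime",
    "FaultSpec",
    "WifiLoss",
    "SdLoss",
    "FleetSimConfig",
    "SimulatedMonitor",
    "SimulatedFleet",
    "drift_clock",
    "unit_bin_profile",
    "generate_bins",
    "simulate_fleet",
    "harmonized_fleet",
    "write_fleet",
]

_THRESHOLDS = (0.3, 0.5, 1.0, 2.5, 5.0, 10.0)
_NOMINAL_S = 120
_DAY_S = 86400


# ---------------------------------------------------------------------------
# clock drift
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftRegime:
    """How a monitor's 2-min logging clock misbehaves over a day.

    ``fixed_loss`` shortens every ``period_s/nominal_s``-th interval by
    ``loss_s`` seconds (the repeatable every-20-min pattern);
    ``variable_loss`` draws the shortfall uniformly from ``loss_range``
    each cycle; ``jitter`` loses ~1 s at random intervals and occasionally
    catches back up, so daily counts stay near nominal.
    """

    kind: str = "none"  # none | fixed_loss | variable_loss | jitter
    loss_s: float = 10.0
    period_s: int = 1200
    loss_range: tuple[float, float] = (5.0, 7.0)
    nominal_s: int = _NOMINAL_S

    def __post_init__(self) -> None:
        if self.kind not in ("none", "fixed_loss", "variable_loss", "jitter"):
            raise ValueError(f"unknown drift regime {self.kind!r}")
        if self.kind == "fixed_loss" and self.loss_s >= self.nominal_s:
            raise ValueError("per-cycle loss must be smaller than the nominal interval")
        if self.kind == "variable_loss" and max(self.loss_range) >= self.nominal_s:
            raise ValueError("per-cycle loss must be smaller than the nominal interval")
        if self.period_s % self.nominal_s:
            raise ValueError("period must be a whole number of nominal intervals")


def drift_clock(
    regime: DriftRegime,
    day_start: pd.Timestamp,
    rng: np.random.Generator | None = None,
) -> pd.DatetimeIndex:
    """Record timestamps for one 24-h logging day under a drift regime.

    The first record falls exactly at ``day_start``; timestamps are strictly
    increasing and only stamps earlier than ``day_start`` + 24 h are
    returned (the logger rolls to a new daily file at midnight UTC).
    """
    day_start = pd.Timestamp(day_start)
    if day_start.tzinfo is None:
        day_start = day_start.tz_localize("UTC")
    per_cycle = regime.period_s // regime.nominal_s
    # upper bound on records even at maximal shortening
    n_max = int(_DAY_S / (regime.nominal_s - (regime.nominal_s - 1) / per_cycle)) + 8

    if regime.kind == "none":
        intervals = np.full(n_max, float(regime.nominal_s))
    elif regime.kind == "fixed_loss":
        intervals = np.full(n_max, float(regime.nominal_s))
        intervals[per_cycle - 1 :: per_cycle] -= regime.loss_s
    elif regime.kind == "variable_loss":
        if rng is None:
            raise ValueError("variable_loss regime needs an rng")
        intervals = np.full(n_max, float(regime.nominal_s))
        n_cycles = len(intervals[per_cycle - 1 :: per_cycle])
        lo, hi = regime.loss_range
        # loggers stamp whole seconds; losses are integer-valued
        intervals[per_cycle - 1 :: per_cycle] -= rng.integers(int(lo), int(hi) + 1, size=n_cycles)
    else:  # jitter: random 1-s losses with occasional catch-up to ~zero drift
        if rng is None:
            raise ValueError("jitter regime needs an rng")
        intervals = np.full(n_max, float(regime.nominal_s))
        losses = rng.random(n_max) < 0.2
        intervals[losses] += 1.0
        behind = np.cumsum(np.where(losses, 1.0, 0.0))
        catchups = np.flatnonzero(rng.random(n_max) < 1 / 200)
        recovered = 0.0
        for i in catchups:
            owed = max(0.0, behind[i] - recovered)
            give_back = min(owed, regime.nominal_s - 1.0)
            intervals[i] -= give_back
            recovered += give_back

    offsets = np.concatenate([[0.0], np.cumsum(intervals)])
    offsets = offsets[offsets < _DAY_S]
    return day_start + pd.to_timedelta(offsets, unit="s")


# ---------------------------------------------------------------------------
# size-bin generation
# ---------------------------------------------------------------------------


def unit_bin_profile(
    gmd: float = 0.25,
    gsd: float = 2.0,
    coeffs: AltCoefficients = DEFAULT_COEFFICIENTS,
) -> np.ndarray:
    """Cumulative counts at the six thresholds for an ALT mass of exactly 1 µg/m³.

    The number size distribution is lognormal with geometric mean diameter
    ``gmd`` (µm) and geometric standard deviation ``gsd``; cumulative counts
    at each optical threshold follow its survival function, scaled so the
    ALT mass of the resulting bins is 1.  Counts for any target mass are
    then ``target * profile`` (ALT is linear and homogeneous).
    """
    if gmd <= 0:
        raise ValueError("geometric mean diameter must be positive")
    if gsd <= 1:
        raise ValueError("geometric standard deviation must exceed 1")
    dist = sps.lognorm(s=np.log(gsd), scale=gmd)
    sf = dist.sf(np.array(_THRESHOLDS))
    n1, n2, n3 = sf[0] - sf[1], sf[1] - sf[2], sf[2] - sf[3]
    mass = coeffs.cf * (coeffs.k1 * n1 + coeffs.k2 * n2 + coeffs.k3 * n3)
    if mass <= 0 or not np.isfinite(mass):
        raise ValueError("degenerate size distribution: no mass in the PM2.5 categories")
    return sf / mass


def generate_bins(
    target_alt: float,
    gmd: float = 0.25,
    gsd: float = 2.0,
    coeffs: AltCoefficients = DEFAULT_COEFFICIENTS,
) -> np.ndarray:
    """Cumulative counts at the six thresholds whose ALT mass equals ``target_alt``."""
    if target_alt < 0:
        raise ValueError("target mass must be nonnegative")
    return target_alt * unit_bin_profile(gmd, gsd, coeffs)


# ---------------------------------------------------------------------------
# fleet configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FaultSpec:
    """Fault injection for one monitor (defaults: a healthy unit).

    ``noise_cv`` overrides the fleet-wide per-channel noise, and
    ``response_power`` bends the concentration response (reading ∝
    latent**power): degraded optics show depressed gain, elevated noise and
    a saturating (sublinear) response, all three of which the QA regression
    sees — a pure deterministic rescaling would still correlate perfectly
    and is not a faulty monitor.
    """

    gain: float = 1.0
    offset: float = 0.0  # additive µg/m³ on both channels' PM readings
    dead_channel: str | None = None  # None | "a" | "b"
    dead_temperature: bool = False
    noise_cv: float | None = None
    response_power: float = 1.0

    @classmethod
    def degraded(cls, gain: float = 0.3, noise_cv: float = 0.5,
                 response_power: float = 0.5) -> "FaultSpec":
        """A failing optical sensor: low gain, heavy noise, saturating response."""
        return cls(gain=gain, noise_cv=noise_cv, response_power=response_power)


@dataclass(frozen=True)
class WifiLoss:
    """Cloud-transmission outages: Poisson block onsets, exponential durations."""

    outages_per_day: float = 0.0
    mean_outage_h: float = 6.0
    never_connected: bool = False


@dataclass(frozen=True)
class SdLoss:
    """SD-card loss: a permanent stop and/or intermittent gaps."""

    p_permanent_stop: float = 0.0
    gaps_per_day: float = 0.0
    mean_gap_h: float = 2.0


@dataclass
class FleetSimConfig:
    """Study conditions for one simulated fleet.

    Defaults mirror the co-location environment the pipeline is built for:
    ambient-infiltrated PM averaging ~4 µg/m³ spanning roughly 0–30 µg/m³,
    intermittent indoor-source spikes, per-monitor gains spread over
    0.85–1.15, and 2 % per-channel multiplicative noise.
    """

    n_monitors: int = 20
    start: str | pd.Timestamp = "2023-11-13"
    n_days: int = 14
    # ambient latent process (lognormal AR(1) on 2-min steps)
    ambient_mean: float = 4.0  # µg/m³
    ambient_log_sd: float = 0.6
    ambient_persistence: float = 0.95
    # indoor-source spikes
    events_per_day: float = 2.0
    event_peak_mean: float = 15.0  # µg/m³
    event_decay_min: float = 30.0
    # number size distribution used to apportion counts
    gmd: float = 0.25  # µm
    gsd: float = 2.0
    # observation model
    noise_cv: float = 0.02
    gain_range: tuple[float, float] = (0.85, 1.15)
    cf1_ratios: tuple[float, float, float] = (0.62, 0.92, 1.00)  # pm1.0/pm2.5/pm10 vs ALT
    atm_ratios: tuple[float, float, float] = (0.60, 0.88, 0.95)
    # faults / drift / loss, keyed by monitor index
    faults: dict[int, FaultSpec] = field(default_factory=dict)
    drift: DriftRegime = field(default_factory=DriftRegime)
    drift_overrides: dict[int, DriftRegime] = field(default_factory=dict)
    wifi_loss: WifiLoss = field(default_factory=WifiLoss)
    sd_loss: SdLoss = field(default_factory=SdLoss)
    monitor_types: dict[int, str] = field(default_factory=dict)  # default WIFI_SD
    # scenario: "colocation" (all share one latent) or "field" (homes with
    # paired outdoor sites and per-home infiltration)
    scenario: str = "colocation"
    n_outdoor_sites: int = 0  # field scenario; 0 -> one site per 8 homes
    infiltration_range: tuple[float, float] = (0.4, 0.8)
    coefficients: AltCoefficients = DEFAULT_COEFFICIENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monitors < 1:
            raise ValueError("need at least one monitor")
        if self.n_days < 1:
            raise ValueError("need at least one day")
        if not (0 <= self.ambient_persistence < 1):
            raise ValueError("persistence must lie in [0, 1)")
        if self.scenario not in ("colocation", "field"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for spec in self.faults.values():
            if spec.dead_channel not in (None, "a", "b"):
                raise ValueError(f"dead_channel must be None/'a'/'b', got {spec.dead_channel!r}")

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = pd.Timestamp(self.start)
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
        return start, start + pd.Timedelta(days=self.n_days)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedMonitor:
    """One simulated monitor: metadata, injected faults, and its data streams.

    ``records`` is the lossless canonical 2-min stream (channel columns);
    ``sd_days`` are raw-dialect daily frames after SD loss (None for
    Wi-Fi-only units); ``cloud`` is the canonical 10-min cloud payload after
    transmission outages; ``truth`` the latent PM2.5 at the record stamps.
    """

    meta: DeploymentMeta
    fault: FaultSpec
    drift: DriftRegime
    records: pd.DataFrame
    sd_days: dict[pd.Timestamp, pd.DataFrame] | None
    cloud: pd.DataFrame
    truth: pd.Series


@dataclass
class SimulatedFleet:
    config: FleetSimConfig
    monitors: dict[str, SimulatedMonitor]
    truth: dict[str, pd.Series]  # latent series per site
    ledger: dict[str, dict]

    def metas(self) -> dict[str, DeploymentMeta]:
        return {mid: m.meta for mid, m in self.monitors.items()}


def _latent_series(times_s: np.ndarray, cfg: FleetSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Lognormal AR(1) ambient plus Poisson indoor spikes, on a seconds grid."""
    n = len(times_s)
    mu = np.log(cfg.ambient_mean) - cfg.ambient_log_sd**2 / 2
    rho, sd = cfg.ambient_persistence, cfg.ambient_log_sd
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = mu + sd * eps[0]
    innov = sd * np.sqrt(1 - rho**2)
    for i in range(1, n):
        x[i] = mu + rho * (x[i - 1] - mu) + innov * eps[i]
    ambient = np.exp(x)

    total_days = (times_s[-1] - times_s[0]) / _DAY_S if n > 1 else 0
    n_events = rng.poisson(cfg.events_per_day * total_days)
    spikes = np.zeros(n)
    tau = cfg.event_decay_min * 60.0
    for _ in range(n_events):
        t0 = rng.uniform(times_s[0], times_s[-1])
        peak = rng.exponential(cfg.event_peak_mean)
        dt = times_s - t0
        mask = dt >= 0
        spikes[mask] += peak * np.exp(-dt[mask] / tau)
    return ambient + spikes


def _env_signals(times_s: np.ndarray, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Diurnal temperature (°F), humidity (%RH) and pressure (mbar) truths."""
    phase = 2 * np.pi * (times_s % _DAY_S) / _DAY_S
    return {
        "temperature": 75.0 + 8.0 * np.sin(phase - np.pi / 2),
        "humidity": 40.0 + 8.0 * np.sin(phase + np.pi / 2),
        "pressure": 1010.0 + 2.0 * np.sin(phase / 2),
    }


def _drop_blocks(
    index: pd.DatetimeIndex,
    starts_s: np.ndarray,
    durations_s: np.ndarray,
    origin: pd.Timestamp,
) -> pd.DatetimeIndex:
    keep = np.ones(len(index), dtype=bool)
    rel = (index - origin).total_seconds().to_numpy()
    for t0, d in zip(starts_s, durations_s):
        keep &= ~((rel >= t0) & (rel < t0 + d))
    return index[keep]


def simulate_fleet(config: FleetSimConfig) -> SimulatedFleet:
    """Generate a full fleet: truth, per-monitor streams, and a fault ledger."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    start, end = cfg.window
    coeffs = cfg.coefficients
    profile = unit_bin_profile(cfg.gmd, cfg.gsd, coeffs)

    ids = [f"PA{i:02d}" for i in range(cfg.n_monitors)]

    # --- site assignment and latent processes --------------------------------
    if cfg.scenario == "colocation":
        site_of = {mid: "site0" for mid in ids}
        roles = {mid: ("INDOOR", None) for mid in ids}
        sites = ["site0"]
    else:
        n_sites = cfg.n_outdoor_sites or max(1, cfg.n_monitors // 8)
        n_sites = min(n_sites, cfg.n_monitors)
        sites = [f"site{j}" for j in range(n_sites)]
        site_of, roles = {}, {}
        for i, mid in enumerate(ids):
            j = i % n_sites
            site_of[mid] = sites[j]
            if i < n_sites:  # the first monitor at each site is the outdoor unit
                roles[mid] = ("OUTDOOR", None)
            else:
                roles[mid] = ("INDOOR", ids[j])

    # lossless nominal 2-min grid shared by truth processes
    grid_s = np.arange(0, cfg.n_days * _DAY_S, _NOMINAL_S, dtype=float)
    site_latent = {s: _latent_series(grid_s, cfg, rng) for s in sites}
    env = _env_signals(grid_s, rng)

    truth_series = {
        s: pd.Series(v, index=start + pd.to_timedelta(grid_s, unit="s"), name="pm2.5_alt")
        for s, v in site_latent.items()
    }

    monitors: dict[str, SimulatedMonitor] = {}
    ledger: dict[str, dict] = {}

    for i, mid in enumerate(ids):
        fault = cfg.faults.get(i, FaultSpec())
        drift = cfg.drift_overrides.get(i, cfg.drift)
        mtype = cfg.monitor_types.get(i, "WIFI_SD")
        role, paired = roles[mid]

        gain = fault.gain if i in cfg.faults else rng.uniform(*cfg.gain_range)

        # record stamps: per-day drifting clocks for the SD logger
        stamps = []
        for d in range(cfg.n_days):
            stamps.append(drift_clock(drift, start + pd.Timedelta(days=d), rng))
        times = stamps[0].append(stamps[1:]) if len(stamps) > 1 else stamps[0]
        rel_s = (times - start).total_seconds().to_numpy()

        # latent and environmental truths sampled at the (drifted) stamps
        base = site_of[mid]
        latent = np.interp(rel_s, grid_s, site_latent[base])
        if cfg.scenario == "field" and role == "INDOOR":
            f_inf = rng.uniform(*cfg.infiltration_range)
            indoor_spikes = _latent_series(rel_s, cfg, rng) - np.interp(
                rel_s, grid_s, site_latent[base]
            )  # reuse process machinery for an independent spike train
            latent = f_inf * latent + np.clip(indoor_spikes, 0, None) * 0.5
        env_at = {k: np.interp(rel_s, grid_s, v) for k, v in env.items()}

        data: dict[str, np.ndarray] = {}
        for ch in ("a", "b"):
            if fault.dead_channel == ch:
                alt_obs = np.full(len(times), np.nan)
            else:
                cv = cfg.noise_cv if fault.noise_cv is None else fault.noise_cv
                noise = 1.0 + cv * rng.standard_normal(len(times))
                response = latent**fault.response_power
                alt_obs = np.clip(gain * response * noise + fault.offset, 0.0, None)
            counts = np.outer(alt_obs, profile)
            for t_idx, p in enumerate(
                ("0.3_um_count", "0.5_um_count", "1.0_um_count",
                 "2.5_um_count", "5.0_um_count", "10.0_um_count")
            ):
                data[chan(p, ch)] = counts[:, t_idx]
            data[chan("pm2.5_alt", ch)] = alt_obs
            for ratios, names in (
                (cfg.cf1_ratios, ("pm1.0_cf_1", "pm2.5_cf_1", "pm10.0_cf_1")),
                (cfg.atm_ratios, ("pm1.0_atm", "pm2.5_atm", "pm10.0_atm")),
            ):
                for r, p in zip(ratios, names):
                    data[chan(p, ch)] = r * alt_obs
            for p in ("temperature", "humidity", "pressure"):
                if p == "temperature" and fault.dead_temperature:
                    data[chan(p, ch)] = np.full(len(times), np.nan)
                else:
                    sensor_offset = rng.normal(0, 0.3)
                    data[chan(p, ch)] = env_at[p] + sensor_offset + rng.normal(
                        0, 0.05, size=len(times)
                    )
        records = pd.DataFrame(data, index=pd.DatetimeIndex(times, name="timestamp"))

        # --- cloud payload: in-window averaging of the lossless stream -------
        floored = records.index.floor("10min")
        cloud = records.groupby(floored).mean()
        cloud.index.name = "timestamp"
        for p in PARAMETERS:
            cloud[p] = (cloud[chan(p, "a")] + cloud[chan(p, "b")]) / 2.0
        cloud = cloud[[c for p in PARAMETERS for c in (chan(p, "a"), chan(p, "b"), p)]]

        wifi_dropped = 0
        if cfg.wifi_loss.never_connected:
            cloud = cloud.iloc[0:0]
        elif cfg.wifi_loss.outages_per_day > 0:
            n_out = rng.poisson(cfg.wifi_loss.outages_per_day * cfg.n_days)
            starts = rng.uniform(0, cfg.n_days * _DAY_S, size=n_out)
            durs = rng.exponential(cfg.wifi_loss.mean_outage_h * 3600, size=n_out)
            kept = _drop_blocks(cloud.index, starts, durs, start)
            wifi_dropped = len(cloud) - len(kept)
            cloud = cloud.loc[kept]

        # --- SD daily files (raw dialect) after SD loss ----------------------
        sd_days = None
        sd_stopped_at = None
        if mtype == "WIFI_SD":
            sd_index = records.index
            if cfg.sd_loss.p_permanent_stop > 0 and rng.random() < cfg.sd_loss.p_permanent_stop:
                stop_s = rng.uniform(0, cfg.n_days * _DAY_S)
                sd_stopped_at = (start + pd.Timedelta(seconds=stop_s)).isoformat()
                sd_index = sd_index[(sd_index - start).total_seconds() < stop_s]
            if cfg.sd_loss.gaps_per_day > 0:
                n_gaps = rng.poisson(cfg.sd_loss.gaps_per_day * cfg.n_days)
                gstarts = rng.uniform(0, cfg.n_days * _DAY_S, size=n_gaps)
                gdurs = rng.exponential(cfg.sd_loss.mean_gap_h * 3600, size=n_gaps)
                sd_index = _drop_blocks(sd_index, gstarts, gdurs, start)
            sd_records = records.loc[sd_index]
            sd_days = {}
            for day, day_frame in sd_records.groupby(sd_records.index.floor("1D")):
                raw = pd.DataFrame(index=day_frame.index)
                for p in SD_PARAMETERS:
                    raw[p] = day_frame[chan(p, "a")]
                    raw[f"{p}_b"] = day_frame[chan(p, "b")]
                sd_days[day] = raw

        meta = DeploymentMeta(
            monitor_id=mid,
            monitor_type=mtype,
            role=role,
            deploy_start=start,
            deploy_end=end,
            paired_outdoor_id=paired,
        )
        monitors[mid] = SimulatedMonitor(
            meta=meta,
            fault=fault,
            drift=drift,
            records=records,
            sd_days=sd_days,
            cloud=cloud,
            truth=pd.Series(latent, index=records.index, name="pm2.5_alt"),
        )
        ledger[mid] = {
            "gain": gain,
            "offset": fault.offset,
            "dead_channel": fault.dead_channel,
            "dead_temperature": fault.dead_temperature,
            "drift": drift.kind,
            "monitor_type": mtype,
            "role": role,
            "site": site_of[mid],
            "wifi_records_dropped": wifi_dropped,
            "sd_stopped_at": sd_stopped_at,
        }

    return SimulatedFleet(config=cfg, monitors=monitors, truth=truth_series, ledger=ledger)


# ---------------------------------------------------------------------------
# convenience: run the real pipeline over a simulated fleet
# ---------------------------------------------------------------------------


def harmonized_fleet(
    fleet: SimulatedFleet,
    *,
    recompute_alt: bool = False,
) -> dict[str, harmonize.HarmonizedSeries]:
    """Push every simulated monitor through the production harmonization path.

    Cloud records are resampled (identity on 10-min stamps), SD daily files
    are relabeled and resampled, both streams merged, and ALT mass derived
    where missing — exactly what a user does with real downloads.
    """
    from .io_formats import relabel_sd_channels  # local to avoid cycle at import

    out = {}
    for mid, mon in fleet.monitors.items():
        wifi_hs = harmonize.resample_10min(mon.cloud, mid, Source.WIFI)
        if mon.sd_days:
            sd_raw = pd.concat(list(mon.sd_days.values())).sort_index()
            sd_hs = harmonize.resample_10min(relabel_sd_channels(sd_raw), mid, Source.SD)
            merged = harmonize.merge_sources(wifi_hs, sd_hs)
        else:
            merged = wifi_hs
        out[mid] = harmonize.compute_derived_alt(
            merged, fleet.config.coefficients, force=recompute_alt
        )
    return out


def write_fleet(fleet: SimulatedFleet, out_dir: str | Path) -> None:
    """Write a simulated fleet to disk in both dialects plus metadata.

    Layout: ``sd/<monitor>_<YYYYMMDD>.csv`` daily files, ``cloud/<monitor>.csv``
    payloads, ``meta.csv`` and ``truth_ledger.json``.
    """
    out = Path(out_dir)
    (out / "sd").mkdir(parents=True, exist_ok=True)
    (out / "cloud").mkdir(parents=True, exist_ok=True)
    for mid, mon in fleet.monitors.items():
        if mon.sd_days:
            for day, frame in mon.sd_days.items():
                (out / "sd" / sd_filename(mid, day)).write_text(write_sd_file(frame))
        if len(mon.cloud):
            (out / "cloud" / f"{mid}.csv").write_text(write_wifi_records(mon.cloud))
    (out / "meta.csv").write_text(write_meta([m.meta for m in fleet.monitors.values()]))
    (out / "truth_ledger.json").write_text(json.dumps(fleet.ledger, indent=2))
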