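"""Capture rates, channel imprecision, I/O ratios, distribution comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmfleet.field_metrics import (
    capture_rate,
    distribution_compare,
    imprecision,
    imprecision_summary,
    io_ratio,
    paired_io_ratios,
    rh_screen,
)
from pmfleet.io_formats import DeploymentMeta


def _meta(hours=24, mid="m", role="INDOOR", paired=None):
    start = pd.Timestamp("2023-06-01", tz="UTC")
    return DeploymentMeta(mid, "WIFI_SD", role, start, start + pd.Timedelta(hours=hours),
                          paired_outdoor_id=paired)


def _stamps(start_min, n, step=10):
    t0 = pd.Timestamp("2023-06-01", tz="UTC")
    return pd.DatetimeIndex([t0 + pd.Timedelta(minutes=start_min + step * i) for i in range(n)])


# ---------------------------------------------------------------------------
# capture rates
# ---------------------------------------------------------------------------


def test_full_wifi_day():
    rep = capture_rate(_meta(24), _stamps(0, 144))
    assert rep.n_expected == 144 and rep.rate_wifi == 1.0 and rep.rate_total == 1.0
    assert rep.n_sd == 0 and rep.rate_sd == 0.0


def test_union_arithmetic():
    """72 cloud + 100 SD stamps with 60 shared -> 112 total of 144 expected."""
    wifi = _stamps(0, 72)
    sd = _stamps(120, 100)
    assert len(set(wifi) & set(sd)) == 60
    rep = capture_rate(_meta(24), wifi, sd)
    assert (rep.n_wifi, rep.n_sd, rep.n_total) == (72, 100, 112)
    assert rep.rate_total == pytest.approx(112 / 144)


def test_no_data_gives_zero_rates():
    rep = capture_rate(_meta(24), None, None)
    assert rep.rate_wifi == rep.rate_sd == rep.rate_total == 0.0


def test_stamps_outside_window_clipped():
    rep = capture_rate(_meta(1), _stamps(-60, 24))  # half before the window
    assert rep.n_expected == 6
    assert rep.n_wifi == 6 and rep.rate_wifi == 1.0


def test_empty_window_is_error():
    start = pd.Timestamp("2023-06-01 00:01", tz="UTC")
    meta = DeploymentMeta("m", "WIFI_SD", "INDOOR", start, start + pd.Timedelta(minutes=5))
    with pytest.raises(ValueError):
        capture_rate(meta, None)


@given(
    wifi=st.sets(st.integers(0, 143), max_size=120),
    sd=st.sets(st.integers(0, 143), max_size=120),
)
@settings(max_examples=100, derandomize=True)
def test_union_bounds_on_random_stamp_sets(wifi, sd):
    """rate_total lies in [max(rate_wifi, rate_sd), min(1, rate_wifi + rate_sd)]."""
    t0 = pd.Timestamp("2023-06-01", tz="UTC")
    to_stamps = lambda ks: pd.DatetimeIndex([t0 + pd.Timedelta(minutes=10 * k) for k in ks])
    rep = capture_rate(_meta(24), to_stamps(wifi), to_stamps(sd))
    assert rep.n_total >= max(rep.n_wifi, rep.n_sd)
    assert rep.n_total <= rep.n_wifi + rep.n_sd
    assert max(rep.rate_wifi, rep.rate_sd) <= rep.rate_total <= min(1.0, rep.rate_wifi + rep.rate_sd)


# ---------------------------------------------------------------------------
# imprecision
# ---------------------------------------------------------------------------


def test_imprecision_hand_values():
    assert imprecision(5.0, 5.0) == 0.0
    assert imprecision(3.0, 1.0) == 0.5
    assert math.isnan(imprecision(0.0, 0.0))
    with pytest.raises(ValueError):
        imprecision(-1.0, 2.0)


@given(a=st.floats(0, 1e3), b=st.floats(0, 1e3), k=st.floats(0.01, 100))
@settings(max_examples=100, derandomize=True)
def test_imprecision_scale_invariant(a, b, k):
    base = imprecision(a, b)
    scaled = imprecision(k * a, k * b)
    if math.isnan(base):
        assert math.isnan(scaled)
    else:
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert 0.0 <= base <= 1.0


def test_imprecision_summary_hand_quantiles():
    idx = pd.date_range("2023-06-01", periods=4, freq="10min", tz="UTC")
    # half the stamps at imprecision 0.5 (a=3,b=1), half at 0 (a=b)
    frame = pd.DataFrame(
        {"pm2.5_alt_a": [3.0, 3.0, 2.0, 2.0], "pm2.5_alt_b": [1.0, 1.0, 2.0, 2.0]},
        index=idx,
    )
    summary = imprecision_summary({"m": frame}, limit=0.20)
    row = summary.per_monitor.loc["m"]
    assert row["median"] == 0.25
    assert row["exceed_share"] == 0.5
    assert summary.fleet_median == 0.25


def test_fleet_median_of_medians():
    idx = pd.date_range("2023-06-01", periods=2, freq="10min", tz="UTC")

    def frame(imp):
        # constant imprecision imp: a = 1+imp, b = 1-imp (|a-b|/(a+b) = imp)
        return pd.DataFrame(
            {"pm2.5_alt_a": [1 + imp] * 2, "pm2.5_alt_b": [1 - imp] * 2}, index=idx
        )

    summary = imprecision_summary({m: frame(v) for m, v in [("x", 0.02), ("y", 0.04), ("z", 0.06)]})
    assert summary.fleet_median == pytest.approx(0.04)


def test_identical_channels_everywhere(clean_frames):
    frames = {
        m: f.assign(**{"pm2.5_alt_b": f["pm2.5_alt_a"]}) for m, f in clean_frames.items()
    }
    summary = imprecision_summary(frames)
    assert (summary.per_monitor["median"] == 0.0).all()
    assert (summary.per_monitor["exceed_share"] == 0.0).all()


# ---------------------------------------------------------------------------
# I/O ratios
# ---------------------------------------------------------------------------


def test_io_ratio_hand_values():
    idx = pd.date_range("2023-06-01", periods=3, freq="10min", tz="UTC")
    indoor = pd.Series([10.0, 4.0, 3.0], index=idx)
    outdoor = pd.Series([5.0, 4.0, 0.0], index=idx)
    res = io_ratio(indoor, outdoor)
    assert list(res.ratios) == [2.0, 1.0]
    assert res.n_zero_outdoor == 1
    assert res.median == pytest.approx(1.5)


def test_io_ratio_of_series_with_itself_is_one():
    idx = pd.date_range("2023-06-01", periods=50, freq="10min", tz="UTC")
    s = pd.Series(np.random.default_rng(0).lognormal(1, 0.5, 50), index=idx)
    res = io_ratio(s, s)
    assert (res.ratios == 1.0).all()


def test_paired_io_requires_pairing():
    idx = pd.date_range("2023-06-01", periods=3, freq="10min", tz="UTC")
    frames = {"in1": pd.DataFrame({"pm2.5_alt": [1.0] * 3}, index=idx)}
    metas = {"in1": _meta(24, "in1", role="INDOOR", paired=None)}
    with pytest.raises(ValueError):
        paired_io_ratios(frames, metas)


def test_paired_io_on_field_fleet():
    from pmfleet.simulate import FleetSimConfig, harmonized_fleet, simulate_fleet

    fleet = simulate_fleet(FleetSimConfig(n_monitors=6, n_days=2, seed=21, scenario="field"))
    frames = {m: s.data for m, s in harmonized_fleet(fleet).items()}
    results = paired_io_ratios(frames, fleet.metas())
    indoor_ids = [m for m, meta in fleet.metas().items() if meta.role == "INDOOR"]
    assert set(results) == set(indoor_ids)
    for res in results.values():
        assert len(res.ratios) > 0 and res.median > 0


# ---------------------------------------------------------------------------
# distribution comparison and RH screen
# ---------------------------------------------------------------------------


def test_identical_samples_ks_zero_d_zero():
    x = np.random.default_rng(1).lognormal(1, 0.6, 500)
    res = distribution_compare(x, x.copy())
    assert res.ks_statistic == 0.0
    assert res.cohens_d == 0.0


def test_ks_invariant_under_shuffle():
    rng = np.random.default_rng(2)
    x = rng.lognormal(1, 0.6, 800)
    shuffled = rng.permutation(x)
    assert distribution_compare(x, shuffled).ks_statistic == 0.0


def test_cohens_d_closed_form_unit_shift():
    """Equal-n normals with means 0 and 1, sd 1: d -> -1 (order sample1 - sample2)."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 20000)
    b = rng.normal(1, 1, 20000)
    res = distribution_compare(a, b)
    assert res.cohens_d == pytest.approx(-1.0, abs=0.05)
    assert res.shapiro_1 is None  # n above the reliable Shapiro range, noted
    assert "skipped" in res.shapiro_note


def test_shapiro_reported_for_small_samples():
    rng = np.random.default_rng(4)
    res = distribution_compare(rng.normal(0, 1, 100), rng.normal(0, 1, 100))
    assert res.shapiro_1 is not None and 0 <= res.shapiro_1[1] <= 1
    assert res.summary_1["n"] == 100


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        distribution_compare([], [1.0, 2.0])


def test_rh_screen():
    assert rh_screen([40.0] * 10) == 1.0
    assert rh_screen([50.0] * 5 + [70.0] * 5) == 0.5
    with pytest.raises(ValueError):
        rh_screen([])
    with pytest.raises(ValueError):
        rh_screen([np.nan, np.nan])
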