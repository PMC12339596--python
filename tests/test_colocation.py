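"""Co-location QA: fits, inclusion criteria, classification, factors, sentinels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pmfleet import colocation
from pmfleet.colocation import (
    MIN_CONCURRENT_POINTS,
    InclusionResult,
    Status,
    apply_factors,
    check_inclusion,
    classify_monitor,
    effective_frame,
    fit_monitor,
    fleet_qa,
    mean_reference,
    pick_arbitrary_reference,
    retention_rate,
    sentinel_reference,
)
from pmfleet.io_formats import PARAMETERS, chan


# ---------------------------------------------------------------------------
# regression core
# ---------------------------------------------------------------------------


def test_identity_fit():
    x = np.arange(1, 50, dtype=float)
    r = fit_monitor(x, x)
    assert r.slope == pytest.approx(1.0) and r.r_squared == pytest.approx(1.0)
    assert r.intercept == 0.0 and r.n == 49


def test_noiseless_double_fit_through_origin():
    x = np.linspace(0.5, 20, 100)
    r = fit_monitor(x, 2 * x)
    assert r.slope == pytest.approx(2.0, rel=1e-12)
    assert r.r_squared == pytest.approx(1.0)


def test_constant_monitor_is_error_result():
    """Zero variance in the monitor values signals a dead sensor, not a crash."""
    r = fit_monitor(np.full(100, 7.0), np.arange(100, dtype=float))
    assert not r.ok and np.isnan(r.slope)
    ri = fit_monitor(np.full(100, 7.0), np.arange(100, dtype=float), intercept_fit=True)
    assert not ri.ok


def test_too_few_points_is_error_result():
    r = fit_monitor([1.0], [2.0])
    assert not r.ok and r.n == 1


@given(st.lists(st.tuples(st.floats(0.1, 100), st.floats(0.1, 100)), min_size=3, max_size=60))
@settings(max_examples=150, derandomize=True)
def test_through_origin_slope_matches_closed_form(pairs):
    """lstsq through-origin slope equals the closed form Σxy/Σx²."""
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    assume(np.ptp(x) > 0)  # constant monitor values are the dead-sensor error case
    r = fit_monitor(x, y)
    assert r.slope == pytest.approx(float(x @ y / (x @ x)), rel=1e-9)


def test_intercept_fit_recovers_offset():
    rng = np.random.default_rng(2)
    x = rng.uniform(60, 90, 400)
    y = x + 3.5 + rng.normal(0, 0.1, 400)
    r = fit_monitor(x, y, intercept_fit=True)
    assert r.slope == pytest.approx(1.0, abs=0.02)
    assert r.intercept == pytest.approx(3.5, abs=0.5)
    assert r.r_squared > 0.99


def test_offset_degrades_through_origin_fit_but_not_intercept_fit():
    """An additive offset the origin fit cannot absorb lowers its r²."""
    rng = np.random.default_rng(3)
    truth = rng.lognormal(1.2, 0.5, 600)
    x = truth + 6.0
    origin = fit_monitor(x, truth)
    withint = fit_monitor(x, truth, intercept_fit=True)
    assert origin.r_squared < 0.8 < withint.r_squared


# ---------------------------------------------------------------------------
# inclusion criteria
# ---------------------------------------------------------------------------


def test_inclusion_study_reference_range_passes():
    """A 0.8–22.7 µg/m³ reference with 500 concurrent points meets all criteria."""
    rng = np.random.default_rng(0)
    ref = np.concatenate([[0.8, 22.7], rng.uniform(0.8, 22.7, 498)])
    res = check_inclusion(ref.copy(), ref)
    assert res.passed and res.n_concurrent == 500
    assert res.ref_min == pytest.approx(0.8) and res.ref_max == pytest.approx(22.7)


def test_inclusion_point_count_boundary():
    ref = np.linspace(0.5, 20, 287)
    res = check_inclusion(ref.copy(), ref)
    assert not res.passed
    assert not res.criteria["min_points"]
    assert all(res.criteria[k] for k in ("max_gt_1", "max_gt_2min", "range_gt_2min"))
    assert check_inclusion(np.linspace(0.5, 20, 288), np.linspace(0.5, 20, 288)).passed


def test_inclusion_constant_reference_fails_range_criteria():
    ref = np.full(400, 5.0)
    res = check_inclusion(ref.copy(), ref)
    assert not res.passed
    assert not res.criteria["max_gt_2min"] and not res.criteria["range_gt_2min"]
    assert res.criteria["min_points"] and res.criteria["max_gt_1"]


def test_inclusion_empty_overlap():
    res = check_inclusion(np.array([np.nan, 1.0]), np.array([1.0, np.nan]))
    assert not res.passed and res.n_concurrent == 0


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------


def _frame_with_alt(values, start="2023-11-13", step_min=10):
    idx = pd.date_range(start, periods=len(values), freq=f"{step_min}min", tz="UTC")
    return pd.DataFrame({"pm2.5_alt": values}, index=idx)


def test_pick_reference_argmax_and_tiebreak():
    fleet = {"B": _frame_with_alt(np.ones(90)), "A": _frame_with_alt(np.ones(100))}
    assert pick_arbitrary_reference(fleet) == "A"
    tie = {"B": _frame_with_alt(np.ones(100)), "A": _frame_with_alt(np.ones(100))}
    assert pick_arbitrary_reference(tie) == "A"


def test_pick_reference_matches_bruteforce_on_fleet(faulty_frames):
    counts = {m: int(f["pm2.5_alt"].notna().sum()) for m, f in faulty_frames.items()}
    best = sorted(counts, key=lambda m: (-counts[m], m))[0]
    assert pick_arbitrary_reference(faulty_frames) == best


def test_mean_reference_hand_values_and_strictness():
    a = _frame_with_alt([2.0, 2.0, np.nan])
    b = _frame_with_alt([4.0, 4.0, 4.0])
    ref = mean_reference({"a": a, "b": b}, ("pm2.5_alt",))
    assert list(ref["pm2.5_alt"]) == [3.0, 3.0]  # third stamp dropped: not concurrent
    single = mean_reference({"a": a}, ("pm2.5_alt",))
    pd.testing.assert_series_equal(single["pm2.5_alt"], a["pm2.5_alt"].dropna(), check_names=False)


# ---------------------------------------------------------------------------
# classification and the fleet pipeline
# ---------------------------------------------------------------------------


def test_clean_fleet_all_accepted_with_unit_slopes(clean_frames):
    res = fleet_qa(clean_frames, mode="mean")
    assert all(s.status is Status.ACCEPTED for s in res.statuses.values())
    alt = res.factors[res.factors["parameter"] == "pm2.5_alt"]
    # mean-of-monitors reference: slopes average 1 by construction
    assert alt["slope"].mean() == pytest.approx(1.0, abs=0.01)
    assert (alt["r_squared"] >= 0.97).all()


def test_fault_taxonomy_classification(faulty_fleet, faulty_frames):
    res = fleet_qa(faulty_frames, mode="mean")
    assert res.statuses["PA05"].status is Status.EXCLUDED  # degraded low-gain unit
    assert res.statuses["PA06"].status is Status.FLAGGED_SINGLE_CHANNEL
    assert res.statuses["PA06"].channel == "b"  # channel A is the dead one
    assert res.statuses["PA07"].status is Status.FLAGGED_OFFSET
    healthy = [m for m in faulty_frames if m not in ("PA05", "PA06", "PA07")]
    assert all(res.statuses[m].status is Status.ACCEPTED for m in healthy)
    # excluded monitors contribute no factors
    assert "PA05" not in set(res.factors["monitor_id"])


def test_excluded_monitor_absent_from_mean_reference(faulty_fleet, faulty_frames):
    """The final reference is built only from non-excluded monitors."""
    res = fleet_qa(faulty_frames, mode="mean")
    kept = {m: effective_frame(faulty_frames[m], res.statuses[m])
            for m, s in res.statuses.items() if s.status is not Status.EXCLUDED}
    expected = mean_reference(kept, ("pm2.5_alt",))
    pd.testing.assert_series_equal(res.reference["pm2.5_alt"], expected["pm2.5_alt"])


def test_single_channel_factor_uses_surviving_channel(faulty_frames):
    res = fleet_qa(faulty_frames, mode="mean")
    rows = res.factors_for("PA06")
    assert (rows["channel"] == "b").all()
    alt_row = rows[rows["parameter"] == "pm2.5_alt"].iloc[0]
    assert alt_row["r_squared"] >= 0.8


def test_offset_factor_carries_intercept(faulty_frames):
    res = fleet_qa(faulty_frames, mode="mean")
    alt_row = res.factors_for("PA07").set_index("parameter").loc["pm2.5_alt"]
    # recovering the injected +6 µg/m³ offset: intercept strongly negative
    assert alt_row["intercept"] < -3.0


def test_arbitrary_mode_uses_most_recording_monitor(clean_frames):
    res = fleet_qa(clean_frames, mode="arbitrary")
    assert res.reference_id in clean_frames
    ref_rows = res.factors_for(res.reference_id)
    alt = ref_rows[ref_rows["parameter"] == "pm2.5_alt"].iloc[0]
    assert alt["slope"] == pytest.approx(1.0) and alt["r_squared"] == pytest.approx(1.0)


def test_mean_mode_slopes_more_concentrated_than_arbitrary(clean_frames):
    """Mean-of-monitors reference tightens the slope distribution around 1.

    The arbitrary reference's trivial self-comparison (slope exactly 1) is
    left out of both sides so the comparison covers the same monitors.
    """
    arb = fleet_qa(clean_frames, mode="arbitrary")
    mean = fleet_qa(clean_frames, mode="mean")

    def dev(r):
        t = r.factors[r.factors["parameter"] == "pm2.5_alt"]
        t = t[t["monitor_id"] != arb.reference_id]
        return t["slope"].sub(1).abs().mean()

    assert dev(mean) <= dev(arb)


def test_retention_arithmetic():
    assert retention_rate(2, 59) == pytest.approx(96.6, abs=0.05)
    assert round(retention_rate(2, 59)) == 97
    assert retention_rate(5, 59) == pytest.approx(91.5, abs=0.05)
    assert round(retention_rate(5, 59)) == 92
    with pytest.raises(ValueError):
        retention_rate(0, 0)


def test_all_excluded_raises():
    """A co-location with no concentration range fails inclusion for every
    monitor, leaving nothing to build a reference from."""
    frames = {m: _frame_with_alt(np.full(400, 5.0)) for m in ("A", "B")}
    with pytest.raises(ValueError):
        fleet_qa(frames, mode="mean")


# ---------------------------------------------------------------------------
# factors and sentinels
# ---------------------------------------------------------------------------


def test_apply_factors_hand_arithmetic(clean_frames):
    res = fleet_qa(clean_frames, mode="mean")
    mid = next(iter(clean_frames))
    slope = float(
        res.factors_for(mid).set_index("parameter").loc["pm2.5_alt", "slope"]
    )
    adjusted, missing = apply_factors(clean_frames[mid], res.factors, mid)
    raw = clean_frames[mid]["pm2.5_alt"]
    pd.testing.assert_series_equal(adjusted["pm2.5_alt"], slope * raw)
    assert missing == []


def test_apply_factors_slope_one_is_identity():
    frame = _frame_with_alt([1.0, 2.0, 3.0])
    factors = pd.DataFrame(
        [{"monitor_id": "m", "parameter": "pm2.5_alt", "slope": 1.0, "intercept": 0.0,
          "r_squared": 1.0, "n": 3, "status": "ACCEPTED", "channel": "mean"}]
    )
    adjusted, _ = apply_factors(frame, factors, "m")
    pd.testing.assert_frame_equal(adjusted, frame)
    scaled, _ = apply_factors(frame * 0 + 10.0, factors.assign(slope=1.1), "m")
    np.testing.assert_allclose(scaled["pm2.5_alt"], 11.0)


def test_apply_factors_missing_parameter_flagged():
    frame = _frame_with_alt([1.0, 2.0])
    frame["temperature"] = [70.0, 71.0]
    factors = pd.DataFrame(
        [{"monitor_id": "m", "parameter": "pm2.5_alt", "slope": 2.0, "intercept": 0.0,
          "r_squared": 1.0, "n": 2, "status": "ACCEPTED", "channel": "mean"}]
    )
    adjusted, missing = apply_factors(frame, factors, "m")
    assert missing == ["temperature"]
    pd.testing.assert_series_equal(adjusted["temperature"], frame["temperature"])
    with pytest.raises(KeyError):
        apply_factors(frame, factors, "unknown")


def test_adjusting_colocation_data_renormalizes_slopes(clean_frames):
    """Applying the factor table to its own co-location data and re-deriving the
    reference gives re-fitted slopes of 1 within tolerance."""
    res = fleet_qa(clean_frames, mode="mean")
    adjusted = {m: apply_factors(f, res.factors, m)[0] for m, f in clean_frames.items()}
    ref = mean_reference(adjusted, ("pm2.5_alt",))
    for m, f in adjusted.items():
        pair = pd.concat([f["pm2.5_alt"], ref["pm2.5_alt"]], axis=1, join="inner").dropna()
        refit = fit_monitor(pair.iloc[:, 0], pair.iloc[:, 1])
        assert refit.slope == pytest.approx(1.0, abs=0.02)


def test_sentinel_selection_argmin(clean_frames):
    res = fleet_qa(clean_frames, mode="mean")
    sentinels = sentinel_reference(res, k=3)
    assert len(sentinels) == 3
    alt = res.factors[res.factors["parameter"] == "pm2.5_alt"].set_index("monitor_id")
    scores = {
        m: abs(alt.loc[m, "slope"] - 1) + (1 - alt.loc[m, "r_squared"]) for m in alt.index
    }
    brute = sorted(scores, key=lambda m: (scores[m], m))[:3]
    assert sentinels == brute


def test_sentinel_shortfall_warns(faulty_frames):
    res = fleet_qa(faulty_frames, mode="mean")
    n_accepted = sum(1 for s in res.statuses.values() if s.status is Status.ACCEPTED)
    with pytest.warns(UserWarning):
        got = sentinel_reference(res, k=n_accepted + 1)
    assert len(got) == n_accepted


def test_sentinel_mean_approximates_fleet_reference(recovery_frames):
    """The 5-sentinel mean tracks the full-fleet mean reference closely."""
    res = fleet_qa(recovery_frames, mode="mean")
    sentinels = sentinel_reference(res, k=5)
    proxy = mean_reference({m: recovery_frames[m] for m in sentinels}, ("pm2.5_alt",))
    pair = pd.concat([proxy["pm2.5_alt"], res.reference["pm2.5_alt"]], axis=1, join="inner").dropna()
    fit = fit_monitor(pair.iloc[:, 0], pair.iloc[:, 1])
    assert fit.slope == pytest.approx(1.0, abs=0.02)
    assert fit.r_squared > 0.99
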