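# Methods

This note records the models, conventions and numerical choices behind
`pmfleet`, and what the simulator-based validation does and does not show
about real deployments.

## Data model and dialect harmonization

All streams converge on a "canonical wide" frame: a pandas DataFrame
indexed by tz-aware UTC timestamps with, for each of the 16 reported
parameters `p`, columns `p_a`, `p_b` (the two optical channels) and `p`
(their mean).  Missing values are NaN, never zero, because zero is a legal
concentration.

The SD dialect stores the channel-A value under the *unsuffixed* column
name, so `relabel_sd_channels` renames it to `p_a` and recomputes `p` as
the channel mean; the mean is left missing when either channel is missing
rather than silently equal to the surviving channel.  The cloud dialect
already carries `p_a`/`p_b`/`p`; the parser verifies the mean-consistency
invariant and flags (but retains) violating rows, and routes rows whose
stamps are off the 10-min boundaries to the high-resolution (2-min) path.

Resampling maps every record with stamp in [hh:m0:00, hh:m9:59] to the
window labeled hh:m0:00 and averages whatever fell inside; one record is
enough to emit a window, because clock drift makes window populations of
4–6 records routine and discarding sparse windows would silently bias
capture statistics.  Merging prefers the cloud value where both sources
report (cloud stamps are natively synchronized); the SD window means at
shared stamps are kept as a shadow copy so material disagreement remains
inspectable.  The ~1-s stamp offset between the two transports is absorbed
by keying on the containing 10-min window.  Real-time clocks are assumed
accurate across monitors; no cross-monitor clock re-registration is
attempted, and no correction of sub-window drift is made.

## ALT mass estimator

Coefficients are computed at import from the bin edges
(0.3, 0.5, 1.0, 2.5 µm): each size category's particles are treated as
spheres at the geometric-mean diameter of its boundaries with density
1 g/cm³, giving per-particle masses that convert #/dL to µg/m³ after the
10⁴ dL/m³ volume factor.  A regression test pins the derived values to
their published 8-, 7- and 8-decimal forms.  CF defaults to 3 (the value
in use when the estimator was adopted); 3.4 is available via
`AltCoefficients.with_cf`, and the estimator is exactly linear in CF and
homogeneous in the counts.  Monotonicity violations in cumulative counts
raise by default; a clamp-to-zero mode exists for noisy 10-min averages.

## Regression and classification

Fits put the reference on the y-axis, so the slope is directly the factor
that maps a monitor onto the reference scale.  Through-origin fits solve
least squares via `numpy.linalg.lstsq` (the closed form Σxy/Σx² serves as
an independent oracle in the tests); intercept fits use
`scipy.stats.linregress`.

r² is reported as the coefficient of determination about the mean,
1 − SS_res/SS_tot clipped to [0, 1].  For intercept fits this equals the
squared Pearson correlation.  For through-origin fits the two differ, and
the difference is load-bearing: squared Pearson is invariant to additive
offsets, so an offset-faulted monitor would look perfect to it, while the
about-the-mean form correctly degrades when the origin-constrained model
cannot absorb an offset — which is exactly what lets the offset branch of
the classifier fire and route such monitors to an intercept-corrected
factor instead of acceptance-by-blindness.

Zero variance in the monitor values makes the slope undefined; this is
returned as an error result rather than an exception because an
incalculable slope is precisely how dead sensors (e.g. a failed
temperature sensor) announce themselves in a QA sweep.

Classification requires r² ≥ 0.8 on *all* 16 parameters (a conjunction).
The recovery ladder is: per-channel refits (exactly one passing channel ⇒
usable single-channel unit), then free-intercept refits on the failing
parameters (all recovering ⇒ correctable offset), else exclusion.
Inclusion criteria run first on the PM2.5 overlap with the arbitrary
reference: ≥ 288 concurrent 10-min points (48 h of data), reference
maximum > 1 µg/m³, maximum > 2× minimum, and range > 2× minimum.  The last
two are both implemented although the range criterion implies the maximum
one — fidelity to the stated procedure over algebraic simplification.  For
a monitor whose channel mean is undefined (dead channel), concurrency is
counted on the surviving channel, since the monitor did record concurrent
data.

The mean-of-monitors reference averages all non-excluded monitors at
strictly concurrent stamps (every monitor present), including the monitor
under test — with fleets of tens of monitors the self-contribution is a
few percent and avoids n distinct leave-one-out references.  Flagged
single-channel monitors contribute their surviving channel.  Offset-flagged
monitors contribute their raw (offset) values, which biases the reference
by roughly offset/n; this mirrors the stated procedure of averaging all
remaining acceptable monitors, and is a known limitation when offset
monitors are numerous.

Sentinel selection scores accepted monitors by |slope − 1| + (1 − r²) on
PM2.5 and takes the k = 5 best (ties broken by id); their per-stamp mean
stands in for the full-fleet reference when late-returned units are
co-located separately.  Factors for single-channel monitors are derived
from, and should be applied to, the surviving channel.

## Field metrics

Expected stamps are the 10-min boundaries in the half-open deployment
window [start, end); capture counts are clipped to the window and the
total is the union of the per-source stamp sets, so a stamp recovered from
both paths counts once.  Channel imprecision |A−B|/(A+B) is missing (not
zero) at A+B = 0, since 0/0 carries no precision information.  Cohen's d
uses the (n−1)-weighted pooled standard deviation.  I/O ratios omit (and
count) zero-outdoor stamps and apply no cap to large ratios, which occur
legitimately under strong indoor sources.  Shapiro–Wilk normality is
skipped with a note outside 3 ≤ n ≤ 5000, where its p-value is undefined
or unreliable.

## Synthetic fleet generator

The generator emulates the conditions the pipeline is meant to survive;
its defaults are the study conditions of a garage co-location fed by
ambient infiltration:

| parameter | default | rationale |
|---|---|---|
| ambient mean | 4 µg/m³ | co-location-range aerosol (raw data ~0.2–28 µg/m³) |
| log-sd / persistence | 0.6 / 0.95 per 2-min step | slowly varying infiltration baseline |
| indoor events | 2 per day, mean peak 15 µg/m³, 30-min decay | intermittent uncharacterized sources |
| number distribution | lognormal, GMD 0.25 µm, GSD 2.0 | accumulation-mode aerosol within the optical range |
| per-channel noise | 2 % multiplicative | matches observed between-channel imprecision of a few percent |
| gains | uniform 0.85–1.15 | observed slope spread of healthy monitors |

Bin counts are apportioned from the lognormal's survival function at the
six thresholds and scaled so the ALT mass of the generated bins equals the
latent target exactly (the profile is normalized to unit mass, so the
round trip is exact up to floating point, well inside the 1 % contract).
Counts are therefore monotone by construction, and the 10-min cloud
payload is computed by the same in-window averaging the pipeline applies,
so the cross-source consistency invariants of real hardware hold by
construction.  Proprietary mass outputs (cf_1, atm variants) are opaque in
reality and are generated as fixed smooth ratios of the ALT mass.

Clock drift regimes: `none` (720 records/day), `fixed_loss(s, 20 min)`
(every 10th 2-min interval shortened by s seconds — 726 records at s = 10,
725 at s = 7), `variable_loss` (integer losses drawn uniformly from 5–7 s,
giving 723–725 records), and `jitter`, which is under-determined in the
observed behavior ("losing" ~1 s at random and catching up): it is
modeled as Bernoulli 1-s losses (p = 0.2 per interval) with occasional
catch-up events, keeping daily counts at 719–720 — a modeling choice, not
an observed mechanism.  Data loss: cloud transmission fails in Poisson
block outages with exponential durations; SD streams either stop
permanently (Bernoulli, uniform stop time) or gap intermittently, the two
modes observed in the field.

Fault taxonomy: per-monitor gain, additive offset, dead channel, dead
temperature sensor, and a *degraded* unit modeled as low gain (0.3) with
elevated noise (cv 0.5) and a saturating response (reading ∝ latent^0.5).
The latter combination matters: classification is purely r²-driven, and a
pure deterministic rescaling still correlates perfectly — a unit that
deserves exclusion must actually lose correlation, as severely degraded
optics do (depressed slopes *and* depressed R² co-occur in practice).

What passing simulator-based tests does **not** show: real aerosol optics
(scattering response, RH growth), true Plantower algorithm behavior,
cross-monitor RTC drift, or the field's actual capture-rate and
imprecision magnitudes, all of which depend on hardware and deployment
conditions outside the generator.  Field-observed headline numbers are
therefore not reproduction targets; the simulator validates the
*machinery* (recovery of injected structure), not the field outcomes.

## Problem sizes used in validation

Validation fleets are sized to exercise the procedure's constraints while
keeping the suite quick: classification-recovery runs use 8 monitors × 3
days of 10-min data (432 concurrent points, comfortably above the 288
floor) over 20 seeded replicates; parameter-recovery runs use 20 monitors
× 14 days (~2000 points).  Recovery tolerances (slopes within 1 ± 0.02
after factor application at 2 % channel noise) follow from the sampling
error of through-origin slopes at those n.

## Known limitations

- The prefer-cloud merge policy discards SD values at shared stamps except
  as shadow metadata; genuine cloud corruption at a shared stamp would win.
- Offset-flagged monitors pollute the mean reference slightly (see above).
- The factor table stores one slope per parameter; channel-level factors
  exist only for single-channel-flagged monitors.
- The generator's spike process is shared in shape between co-location and
  field scenarios; field indoor spikes are an independent draw of the same
  process, not a source-resolved model.
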