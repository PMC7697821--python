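# Methods

## The optimality-degree model

`optdeg` scores greenhouse microclimate measurements for tomato against
stage- and light-specific optimal ranges.  For each variable
ℳ ∈ {T, RH, VPD} a membership function

    Opt(ℳ)_{GS, light} : ℳ → [0, 1]

maps a raw reading onto an optimality degree: 1 inside the optimal plateau
[G1_min, G1_max], 0 at or beyond the failure borders G0_min / G0_max, and a
monotone transition in between.  Growth stages are GS1 (germination/early
growth), GS2 (vegetative) and GS3_5 (flowering through mature fruiting,
whose temperature anchors equal GS2's); light conditions are sun, cloud
and night (GS1 memberships are light-independent).

Vapor pressure deficit is derived from temperature and relative humidity
with the Magnus-type saturation formula

    VPD(T, RH) = (1 − RH/100) · 0.611 · exp(17.27 T / (T + 237.3))  [kPa],

valid for RH ∈ [0, 100] and T > −237.3 °C.  VPD is computed per reading
*before* scoring; it is never derived from period-mean T and RH.

Temperature and humidity memberships are linear ramps between the anchors;
the GS2 night temperature rise has two segments, 0 → 0.5 on
[G0_min, G0.5] and 0.5 → 1 on [G0.5, G1_min], so the half-anchor at 17 °C
scores exactly 0.5.  The GS1 humidity membership is one-sided: it stays 1
above 75 % and only the lower failure border applies.  VPD memberships use
the published fitted branches — a quadratic rise for GS1 and
two-term exponentials a₁e^{k₁v} + a₂e^{k₂v} elsewhere.

### Corrections to the published tables

The published reference tables contain typographic defects.  The shipped
defaults are the corrected forms; each correction is verifiable with
`audit_membership_table`, which evaluates every VPD branch at its borders
(a rising branch must give ≈0 at G0_min and ≈1 at G1_min, a falling branch
the mirror image):

* Descending linear branches are implemented as
  (G0_max − x)/(G0_max − G1_max) — 1 at G1_max, 0 at G0_max — which is
  what the G0/G1 anchor semantics require (the printed expression
  evaluates to 2 at G1_max).
* The GS2 night rising ramp is printed with the same expression for both
  sub-intervals, leaving a discontinuity at G1_min; the second segment is
  implemented as the 0.5 → 1 interpolation above.
* Two VPD rising branches (GS2 sun; GS3_5 cloud) are printed with signs
  that make them evaluate to ≈ −1 where ≈ +1 is required.  Their signs
  are normalized with magnitudes kept as printed.  The as-published signs
  are retained in `literal_printed_params()`; auditing that table flags
  the defective branches with residuals > 1, while the shipped defaults
  pass everywhere within 0.05 (worst endpoint residual 0.023, on the GS1
  quadratic at its lower border).
* The stage-2 sun VPD column header and the stage-2 cloud temperature
  header are mislabelled in print; the range/anchor columns are trusted.
* The GS1 humidity table prints the 75/99 pair ambiguously; 75 is used as
  the ramp target (G1_min), 99 is stored but unused by the one-sided form.
* GS1 VPD uses the tabulated G1_min = 0.030 kPa (the accompanying text
  mentions 0.29 kPa as a favorable minimum; the table is taken as
  authoritative, and parameters are overridable via YAML if a user
  prefers the narrative value).

Boundary conventions: plateaus are closed intervals, supports are open
(the score is exactly 0 at G0_min and G0_max); at interior joins the
plateau wins ties.  Because the fitted branches over/undershoot their
endpoints by up to ~0.02, all membership outputs are clamped to [0, 1]
after evaluation.

Parameters are data, not code: `MembershipParams` serializes to YAML, so a
corrected or alternative crop table can be swapped in without code
changes (`RunConfig.params_path`).

## Aggregation conventions

* **Light classes** — with a lux reading: night < 10 lux, sun ≥ 10,000 lux
  (a conventional overcast/direct-sun boundary), cloud in between.
  Without one, a configurable clock window (default 06:30–18:30) yields
  sun/night only.  All thresholds live in `LightThresholds`.
* **Day/night periods** follow the light classes (day = sun ∪ cloud), so
  period statistics track actual sun presence; a fixed-hours override is
  available by supplying a clock-window-only classification.
* **Hourly means** use label-exclusive-start windows: the 07:00 mean
  averages samples in (06:00, 07:00].  Empty windows are omitted.
* **Descriptive statistics** report mean, sample SD (ddof = 1), min, max,
  range and n per variable × period × height stratum.  Single-sample
  groups report sd = 0 with n = 1 flagging the degeneracy, keeping the
  tabular output well-formed.  The 24-h column is the mean over all
  samples, not the mean of day/night means.
* **OptDeg period means are means of per-reading scores**, never the score
  of the period-mean input.  The two differ by a Jensen gap whenever the
  input distribution straddles a ramp: e.g. temperatures {10, 38} °C under
  GS2 sun have a mean score < 0.2 but their mean (24 °C) scores 1.0.  The
  per-reading convention is the one that measures how often the crop
  actually experienced optimal conditions.
* **Kernel smoother** — local weighted least squares of polynomial degree
  2 with Gaussian weights exp(−(Δt/bandwidth)²), evaluated at each sample
  point; support truncated at 4 bandwidths for speed.  Default bandwidth
  30 min for minute-cadence series (chosen to suppress sensor noise while
  preserving vent/heater transients of ~1 h scale).  Points with fewer
  than degree + 1 neighbours within one bandwidth are passed through and
  flagged.  The fit reproduces any global quadratic exactly and is
  shift/scale-equivariant in the response.

## Horizontal mapping

Each sensor plane (height stratum) is gridded independently — no vertical
interpolation between planes.  The default interpolant is piecewise-linear
on the Delaunay triangulation of the sensor positions: deterministic,
exact at the sensors, and range-preserving (no overshoot), which matters
for fields bounded in [0, 1].  Inverse-distance weighting (power 2) is an
option; kriging is out of scope.  Cells outside the convex hull are masked
(or nearest-neighbour filled with `extrapolate=True`); fewer than three
non-collinear sensors fall back to nearest-neighbour with a warning.  The
default grid is 1 m over the layout bounding box.  `field_summary` reports
the equal-weighted fraction of unmasked cells below a threshold — the
"X % of the greenhouse below OptDeg 0.5" style statistic; note such area
percentages depend on the gridding method and resolution.  Fields export
to long-format CSV and ESRI ASCII grid (square cells required; mask as the
standard no-data value).

## Synthetic greenhouse

The generator emulates the statistical structure of a 20-node wireless
grid in a large asymmetric three-span greenhouse (two horizontal planes at
1.4/2.2 m, or 0.6/2.2 m for a young crop; minute cadence):

    T(t, x) = base + amplitude · max(0, sin(π(h − sunrise)/(sunset − sunrise)))
              + gradient · (x − x̄) + heater(h) − vent_dip(h) + ε,  ε ~ N(0, σ_T²)

RH follows an anti-correlated rule — interpolation between a night level
and a lower day level along the same daylight factor, plus its own
west→east gradient, clipped to [0, 100] — a statistical emulation, not a
psychrometric simulation; no claim downstream depends on physically
consistent humidity dynamics.  Both gradients are positive (temperature
and humidity rising west → east, as vent-driven advection produces in the
emulated house).  Heater windows may wrap midnight; vent effects are
rectangular dips with a configurable linear ramp (default 10 min).
Dropout is i.i.d. per reading — real LoRa losses are bursty, but no burst
statistics are available to emulate.  A lux channel proportional to the
daylight factor feeds the light classifier.  The noise-free, pre-dropout
ground truth is always returned so every downstream statistic has an
oracle.

Preset levels are the emulated study conditions: winter heated day
(day/night T 21.6/16.1 °C, RH 66.4/74.4 %), a ventilated June day with
night thermal inversion below the 17.0 °C ambient (29.1/14.7 °C,
45.1/90.3 %), and a hot July day at the early growth stage (38.8/24.7 °C,
19.3/37.3 %, sensors at 0.6/2.2 m).  `solve_targets` chooses base and
amplitude against the *actual discrete sample grid* (day/night defined by
the lux threshold), so the ground-truth period means equal the configured
targets by construction rather than asymptotically.  Default noise:
σ_T = 0.3 °C, σ_RH = 1–1.5 % (typical calibrated-probe accuracy), dropout
2 %.

What passing tests on synthetic data do **not** show: performance under
bursty telemetry loss, sensor drift/bias, humidity saturation dynamics,
or airflow-driven spatial structure beyond a linear gradient.  The
generator validates the pipeline's arithmetic and conventions, not the
physics of any particular greenhouse.

## Pipeline and problem sizes

`run()` executes ingest (or simulate) → score → aggregate → map → export
and is deterministic given (config, seed); stage failures abort with a
stage-tagged error and remove partial outputs.  The growth stage is a
run-level constant (one stage per measurement campaign).  Contour grids
are exported for the hours of lowest and highest greenhouse-mean VPD —
the extremes worth mapping — unless explicit hours are configured.

Tests and the acceptance script run desk-scale problems: one simulated
day of 20 sensors at 1-min cadence (28,800 nominal readings) for
pipeline-level checks, 1,000 random points per branch for the
oracle-equivalence suite, and single evaluations for the worked reference
values.  The reference-value checks are exact to the printed precision;
simulation-based recoveries use tolerances derived from the configured
noise (e.g. day/night mean T within 0.1 °C at σ_T = 0.3 °C over ~10⁴
samples).

## Known limitations

* Area-percentage statements from gridded fields are method- and
  resolution-dependent; they are reported but not treated as invariants.
* The clock-fallback light rule cannot produce the cloud class, slightly
  sharpening day/night contrasts for datasets without a light channel.
* The GS1 humidity membership never penalizes very humid air (one-sided
  as published), although condensation risk at RH → 100 % is real; the
  VPD score partially compensates, since VPD → 0 scores 0.
* `.asc` export requires square grid cells; use the CSV export otherwise.
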