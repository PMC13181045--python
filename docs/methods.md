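# Methods

This note documents the models, conventions and numerical choices behind
`divetherm`, and what its tests do and do not establish.

## The decoding model

A tag file is a CSV with three row types. A `FIX` row carries the Argos
position (UTC, lat, lon) and a location-quality class from
{Z, B, A, 0, 1, 2, 3}. `DIVE` rows carry the measurements: up to six
depth–temperature pairs per row (one stored record ≙ 30 min of observations
at 5-min spacing), a near-surface temperature (SST) with its elapsed time
before transmission (SSTtime), and the elapsed minutes between the row's most
recent pair and the transmission (DTtime) as the trailing field. `DIAG` rows
(battery and housekeeping telemetry) are discarded at parse time.

Decoding conventions, where the record format left room:

- **DTtime is per record**: each row's DTtime anchors that row's own most
  recent pair; within a row, pairs are stored chronologically, so pair *k*
  counted backward from the last populated slot was acquired at
  `fix_utc − DTtime − 5·k` minutes. A dive's rows appear in the file most
  recent first (increasing DTtime).
- **Segmentation**: rows under one fix belong to the same dive event while
  their reconstructed time ranges abut on the 5-min lattice (next older row's
  DTtime = current DTtime + 5 × its pair count). A gap beyond one sample
  interval starts a new dive. Overlaps and inversions are *not* split — they
  are left for the truncation rule, since they indicate corrupted DTtime
  rather than two dives.
- **Temporal-coherence truncation**: if the merged sample times are not
  strictly increasing, the decoder keeps the longest strictly increasing
  subsequence anchored at the most recent sample (the one best tied to the
  transmission time), discarding the rest. Duplicate timestamps count as
  incoherent. A prefix-anchored variant is available (`truncate="prefix"`),
  which instead trusts the dive's start.
- **Location quality**: only class 0 fixes are retained by default — its
  ~1,500 m precision matches a ~4-km model grid, and it is by far the most
  common class for surfacing turtles; the set is configurable (`allowed_lq`).
  Fixes missing coordinates, time or LQ are dropped along with their dive
  rows.
- **Surfacing samples**: exactly 0 m depth is treated as surfacing (the
  sensor may read air temperature) and discarded; depths in (0, 0.5] m are
  kept — only the literal 0-m reading is suspect. SST/SSTtime are kept as
  profile metadata, not as profile samples, because the dialect reports no
  depth for them.
- **Rejection accounting**: a dive group that cannot be reconstructed
  (missing DTtime, missing depth or temperature in a populated pair slot,
  or nothing left after filtering) becomes a typed rejection with a reason
  code, and `n_dive_groups = n_profiles + n_rejected` is asserted per file.

## Collocation

Profiles are matched to the *nearest sea cell* of the model grid by
great-circle (haversine) distance, with ties broken toward the lowest
(lat-index, lon-index); cells whose top-level value is not finite are land.
Matches farther than 25 km (configurable) are dropped and logged. The daily
model slice is chosen by calendar-date containment of the mid-dive time; the
format does not define how sub-daily times map onto daily fields, and a
date-containment rule keeps observation and model slice on the same civil
day.

Profiles sharing a (cell, date) are pooled before interpolation: temperatures
at identical depths are averaged, the union of depths forms the merged
profile (the merge rule for differing depth grids is a documented choice —
the alternative, per-profile interpolation then averaging, differs only at
second order). The merged profile is linearly interpolated onto the model's
vertical levels, strictly inside the observed depth span — no extrapolation.
A merged profile that collapses to a single depth contributes only at levels
within ±2.5 m of it (half the nominal 5-m vertical step of the dive
simulator).

Strata attached to each pair: meteorological season (DJF/MAM/JJA/SON),
depth-range bins (0–15], (15–30], (30–50], (50–100] m (levels deeper than
100 m carry no depth-range label and are excluded from depth-stratified
tables), and sub-region by point-in-polygon with priority
WACC > NA > MA > SA, else "other". The shipped polygons are explicit
approximations: the bathymetric northern-Adriatic boundary is replaced by a
fixed-latitude chord at 43.3° N, and the WACC is a 0.3°-buffered polyline
along the Italian coast from the Po Delta to the Strait of Otranto. They live
in `src/divetherm/data/adriatic_regions.geojson` and can be replaced wholesale.

## Validation statistics

BIAS is `mean(model − obs)` — positive when the model product is warmer than
the observations. RMSE is the root mean squared difference, and
uRMSE = √(RMSE² − BIAS²) (clamped at zero against floating-point negatives)
is the centered, bias-free error; uRMSE is invariant under any constant model
offset, and the identity uRMSE² + BIAS² = RMSE² holds to round-off for every
emitted row. Pearson r is computed from the covariance formula with sample
(n−1) normalization (the normalization cancels in the ratio); its two-sided
p-value uses the t transformation t = r√((n−2)/(1−r²)) on n−2 degrees of
freedom — the exact null distribution under bivariate normality, and
numerically identical to the beta-distribution form used by
`scipy.stats.pearsonr`, which serves as an independent cross-check in the
tests. Strata with fewer than 3 pairs report counts with NA metrics (never
silently dropped rows). Statistics are pair-weighted (computed over all
matched pairs in a stratum), not averaged per profile first. The headline
reporting filter keeps strata with r > 0.6 and p < 0.05; the unfiltered table
is always written alongside.

Two observation counters are reported per stratum (`n_pairs`, matched
model-level pairs, and `n_dives`, distinct dive events) because "number of
observations" is ambiguous between the two.

## ARGO consistency check

Turtle samples and float samples pair when they share a 1-m depth bin
((0,1], (1,2], …), are within 10 km (inclusive, great circle) and ±15 days.
Per-bin BIAS is float minus turtle (configurable), reported down to 12 m with
per-bin counts; empty bins appear with N = 0 and NA BIAS. The ±15-day window
admits genuine seasonal change (up to ~1.5 °C at the surface for the default
seasonal amplitude), so individual sparsely populated bins can show biases of
that order even for perfectly calibrated sensors; the check is informative in
the aggregate, not bin by bin at small N.

## The synthetic ocean and its limits

Truth temperature is a logistic thermocline under seasonal forcing:

    T(z, t, φ) = T_deep + (T_surf(t, φ) − T_deep) / (1 + exp((z − MLD(t)) / w))
    T_surf(t, φ) = T_mean + A_surf · cos(2π (doy − peak_doy)/365.25) + γ·(φ − φ₀)
    MLD(t): sinusoidal between MLD_winter and MLD_summer, in antiphase with T_surf

Defaults (chosen once, for a temperate shelf sea): T_deep = 13 °C,
T_mean = 19 °C, A_surf = 6 °C, peak day 225, MLD 70 m (winter) / 15 m
(summer), w = 10 m, γ = −0.1 °C/°lat. The form is smooth, bounded between
T_deep and T_surf, and has closed-form checkpoints (mid-point at z = MLD,
saturation at the surface, T_deep at depth) used as test oracles. Dates are
UTC civil dates; day-of-year is an integer with a 365.25 divisor and no
leap-day handling, so all samples of one calendar day see the same truth —
and the dive simulator schedules every dive within a single day, which keeps
an observation and its daily model slice at the same truth time.

The model product samples truth at cell centers (default 1/24° grid, 33
levels: 2-m spacing to 30 m, 5-m spacing to 120 m) and adds a per-level
systematic bias and i.i.d. Gaussian noise; an optional land mask sets cells
to NaN.

Dives are trapezoidal (descent–bottom–ascent, bottom fraction 0.3) with
maximum depths from an exponential distribution (scale 30 m) right-truncated
at the 175-m hard cap, sampled every 5 min, with a final 0-m surfacing sample
to exercise the decoder's discard rule. The vertical excursion per sample is
bounded (1 m/min descent rate, i.e. ≤5 m per sample): with the thermocline
half-width w = 10 m this keeps the piecewise-linear interpolation error of
the logistic profile below ~0.04 °C (error ≤ h²/8 · max|T″| ≈
h²·0.096·ΔT/(8w²)), which is what makes the end-to-end perfect-model closure
(< 0.05 °C on every pair) achievable. Together with the 240-min duration cap
this bounds feasible dives at ≈115 m — well inside the 175-m cap, which
remains enforced. Real turtles descend up to an order of magnitude faster;
consequently the simulator under-represents the coarse vertical sampling of
real deep dives, and the closure results bound only the pipeline's own error,
not the representativeness error of real telemetry. The simulator likewise
omits Argos message corruption, duty-cycled transmission gaps (a
transmission-success probability is exposed, default 1, with no established
value to pin it to), diel behaviour, and any horizontal structure beyond a
linear latitudinal gradient.

ARGO-style floats are truth + i.i.d. noise (0.05 °C) at 1-m resolution,
default three platforms × 40 casts over a year, matching typical cycling
rates.

## Reproducibility and problem sizes

Every generator draws from a `numpy` Generator seeded from its own `seed`
field; the pipeline derives per-stage seeds from the run seed via
`SeedSequence`, so identical configurations give bit-identical outputs
(asserted in the tests by file comparison). Test and acceptance runs use a
year of daily fields over a 1.5° × 2° box with 2–7 tags and 30–100 dives per
tag (a few hundred to ~2,500 matched pairs), sizes at which every statistical
band checked (BIAS within 3σ/√N, uRMSE within 10%) is comfortably resolved.

## Known limitations

- Sub-region polygons are textual approximations; analyses near their
  boundaries inherit that approximation.
- The daily-slice rule ignores sub-daily ocean variability; with daily
  fields this is irreducible.
- The decoder's truncation rule is a documented interpretation of
  "truncate at the first temporally coherent point"; both anchored variants
  are provided, and genuinely ambiguous corrupted records may differ between
  them.
- Pair-weighted statistics over-weight cells visited repeatedly by the same
  animal; no declustering is applied.
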