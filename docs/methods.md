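# Methods

## Model

A compound ejected from the cyclic mobility device after `n` complete cycles
arrives at

    t_n = t0 + n · tp

with `t0` the zero-pass arrival time (transit through the mobility region
without a full cycle) and `tp` the periodic drift time (one cycle of the
device). `t0` is measured directly at a minimal separation time (default
0.01 ms) where every compound is ejected before completing a cycle; it is
far more stable than `tp` because of the short travel distance, so the
measured value — not the fitted intercept — is the canonical `t0` stored
downstream. The fitted intercept is always reported alongside
(`MobilityFit.t0_fitted`) as a diagnostic.

`tp` is the slope of a least-squares line of arrival time versus pass
number. When a pass is observed at several separation times, the per-pass
mean arrival time enters the fit so every pass carries equal weight. Fits
spanning fewer than 5 distinct passes are flagged `low_pass_count`; fits
with R² < 0.99 or within-pass relative dispersion above 1% are flagged
`poor_fit` — the latter is a deliberately blunt heuristic for bimodal or
asymmetrically broadened arrival distributions (e.g. protomers, polymer
series), which this package does not attempt to deconvolve; such compounds
should be excluded, as their peak-picked arrival times are unreliable.

## Pass assignment

The instrument does not record pass numbers, and wrap-around (fast ions
lapping slow ones) makes them non-obvious at long separation times. The
description of the measurement scheme states the outcome — consecutive
passes captured per compound — not an algorithm, so the assignment here is
one defensible realization:

1. Initialise `tp` from a provided seed, or from the lowest-separation-time
   observation lying more than 0.5 ms above `t0`, assumed to be pass 1. (The
   observation *at* `t0` cannot seed the estimate; the 0.5 ms gap skips
   repeated zero-pass sightings. With a schedule step no larger than ~2 ms
   below 40 ms and single-pass times of 5–30 ms, pass 1 cannot be skipped.)
2. Assign `n = round((t − t0)/tp_est)`, rounding exact halves toward the
   lower pass; refit the line `t = a·n + b` by OLS on current inliers;
   reassign; repeat to a fixed point (max 50 iterations).
3. Observations whose median-centred residual exceeds 3× a robust scale
   (1.4826·MAD, floored at 10⁻⁶·tp) are flagged unassigned rather than
   forced onto the line. Centring on the median keeps a single outlier from
   dragging the OLS intercept far enough to disqualify every observation.
   If the iteration revisits a previous state (the inlier mask can 2-cycle
   on borderline observations while the assignments stay fixed), the
   current state is accepted as converged.

On noiseless simulated series the procedure reproduces ground-truth pass
numbers exactly and the fit recovers (t0, tp) to machine precision; at the
0.1% intraday noise level assignments still match ground truth (tested under
wrap-around with tp 10–14 ms).

## Session correction

Between sessions, instruments and traveling-wave settings, `tp` and `t0`
shift affinely: `reference = slope · measured + intercept`, fitted by
unweighted OLS on calibrant compounds co-measured in both sessions
(calibrant counts are small, 5–6, so weighting has nothing to estimate).
Each quantity (`tp`, `t0`, `tn`) gets its own line; they are never pooled.
The direction convention maps the *new* session onto the *reference*
session, so database annotation is a single forward application of the
line. Relative errors use the reference value as denominator throughout;
the mean relative error (MRE) is `mean(100·|v − r|/r)`.

Lipids and nonlipids follow slightly different lines under the traveling
wave. The API carries class tags and warns — but does not refuse — when
lipid analytes are corrected with exclusively nonlipid calibrants. The same
physics powers residual screening: after correcting with lipid calibrants,
features with residual > 0.7% (strict inequality; the threshold is a config
default, not a constant) are flagged out-of-class, and a self-correction
fitted within the flagged group confirms the split when its MRE beats the
cross-class line's MRE on that group.

## Database and annotation

A database entry stores `t0`, `tp` and reconstructed `t_n` for passes 1..N
(default N = 10), with provenance recording the source session and
correction lineage; the `t_n = t0 + n·tp` invariant is revalidated on load
(tolerance 10⁻⁹ ms). Reconstruction is not interpolation toward unmeasured
passes but noise suppression: the fitted line averages out per-pass
measurement error.

Annotation of a measured feature (m/z, corrected arrival time): entries
within 20 ppm of the m/z are kept; for each, the pass minimising the
absolute arrival-time difference is selected and the candidate scored by
the relative difference in percent (comparisons are reported in percent
throughout, so ranking uses the relative rather than absolute error).
Queries beyond the reconstructed pass range are refused unless explicitly
asked to extrapolate. Pass-number estimation ties (a measurement exactly
midway between passes) break to the lower pass. The single-measurement
workflow first corrects query arrival times with an `tn` line fitted on
co-measured calibrants whose passes are estimated from the database, then
searches.

A three-measurement shortcut (`t0`, `t1`, `tn`) is also provided:
`n = (tn − t0)/(t1 − t0)` rounded to nearest, `tp = (tn − t0)/n`, with
`|n_raw − n|` kept as a consistency diagnostic. On noiseless data it equals
the slope fit exactly.

## Simulator

The simulator is the ground-truth oracle. Per compound and separation time
`T` it emits a peak for every pass with `0 ≤ (t0' + n·tp') − T ≤ window`
(window 26.4 ms, matching the acquisition/ejection time; drift-transformed
primes), which reproduces wrap-around and the sliding pass visibility the
extraction must cope with. The true ejection geometry of the instrument is
more intricate; this window model is a stated simplification.

* **Drift** acts as affine maps on `t0` and `tp` (not on raw `t_n`), because
  each quantity empirically follows its own linear correction line;
  class-specific maps generate two-class screening ground truth.
* **Noise** is multiplicative on arrival times (observed variation is
  CV-like). Defaults mirror the observed operating regime: 0.05% for
  within-week stability, 0.1% for intraday multipass variation.
* **Intensity** decays 0.7× per pass above a detection floor, so weak
  compounds vanish at high passes (the low-signal failure mode).
* **Compound ranges**: tp ∈ [10, 14] ms and t0 ∈ [5, 8] ms, inside the
  plausible 5–30 ms single-pass regime; m/z values are spaced 25 Da apart so
  ppm windows never overlap between simulated compounds.
* **Seeds** are mandatory arguments of every stochastic call; there is no
  hidden global RNG state.

What the simulator does *not* emulate: peak shapes (and hence peak-picking
error structure), bimodal arrival distributions, m/z-dependent sensitivity,
chemical noise and co-eluting backgrounds. Passing tests therefore
demonstrate the correctness of the arithmetic, assignment, correction and
search logic under the stated drift/noise model — not robustness to
ill-behaved peak shapes, which the quality flags only detect.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale problems chosen as the
smallest sizes that exercise every mechanism: 2–20 compounds, the full
48-point separation-time ladder (0.01 ms, then 1–20 by 1, 22–40 by 2,
45–100 by 5, 110–150 by 10 ms), 5 calibrants, 50-entry databases with 100
randomized repeats, and 100–200 Monte-Carlo replicates for fit-bias checks.
The two-session experiment in `scripts/acceptance.py` (20 compounds, drift
slope 0.97 / intercept 0.1 ms, noise CV 0.05%, 5 calibrants, 15 scored
analytes) is evaluated at the value level — drift and noise applied directly
to (t0, tp) — which is the quantity the claim is about; the full
series-level pipeline is exercised end-to-end in the test suite and CLI.

Degenerate inputs are errors, not silent results: fewer than 2 calibrant
pairs, all-equal measured values, empty catalogues, zero parsable peak-list
rows, and series tables with no rows all raise. Absence of an m/z match is a
valid `None`/empty result, not an error. Malformed peak-list rows are
excluded but reported with their positions. CSV round trips use
full-precision float formatting (`float_precision="round_trip"` on read), so
reader/writer round trips are bit-identical and reports are byte-identical
for identical config and seed.

## Known limitations

* Overlapping or non-Gaussian arrival distributions are flagged, never
  resolved.
* Corrections are strictly affine; nonlinear (quadratic, power-law) session
  effects are out of scope, as are CCS calibration and MS/MS scoring.
* The database stores one reference session per entry; provenance records
  lineage but no merge policy is imposed when entries are re-measured.
* The ppm convention uses the theoretical (reference) m/z as denominator;
  at 10–20 ppm tolerances the difference from the observed-m/z convention
  is far below the tolerance granularity.
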