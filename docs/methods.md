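# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not establish.

## Signal model and conditioning chain

Recordings are multi-channel voltage series at 500 Hz (Nyquist 250 Hz) from
four muscles of the lever arm: BBL, TBL, brachioradialis and posterior
deltoid. The conditioning chain is:

1. **Band-pass filtering.** Butterworth IIR, default 20–200 Hz, order 4,
   applied forward–backward (`sosfiltfilt`) for zero net phase delay. The
   source study names a Butterworth band-pass but not its cutoffs or order;
   20–200 Hz at order 4 is standard surface-EMG practice within this
   Nyquist bound, and all three parameters are exposed in `FilterSpec`.
   Zero-phase application squares the magnitude response; burst timing is
   unshifted (verified to ±2 samples on symmetric test bursts).
2. **Envelope.** Full-wave rectification then a centered 50-sample moving
   average. Edges use a truncated (shrinking) window rather than
   zero-padding so the envelope does not dip artificially at recording
   boundaries; output length equals input length and values are
   non-negative by construction.
3. **Activation detection.** The analytic-signal (Hilbert) magnitude of the
   filtered channel is thresholded adaptively. Baseline mean and SD are
   estimated from the quietest contiguous segment — the 10% stretch of the
   recording with the lowest mean magnitude, which is a rest period in any
   recording that is not wall-to-wall activity — and the threshold is
   baseline mean + 3 SD (multiplier exposed). Detection is two-stage:
   candidate regions come from the magnitude smoothed over the 25-sample
   minimum duration (sub-minimum structure is noise by definition, and
   smoothing keeps isolated noise spikes from chaining into events), with
   supra-threshold runs merged across gaps shorter than 25 samples; each
   candidate is then timed on the raw magnitude's sustained (≥3-sample)
   crossings and kept only if its supra-threshold sample count reaches the
   minimum duration. Counting samples rather than measuring extent keeps
   the duration rule monotone: raising the minimum duration can only reduce
   the number of events. On high-SNR synthetic schedules (amplitude ≥10×
   baseline SD, duration ≥2× minimum) this yields recall and precision of
   1.0 with onsets within ±10 samples.
   Whether the original analysis applied the transform to the raw, filtered
   or rectified signal is not recoverable; the default here is the filtered
   signal, with `use_hilbert=False` accepting an already-rectified envelope.
4. **Cycle segmentation.** Pull-phase events (BBL/BRD/PDT) are merged into
   per-cycle pull windows and paired with the following push-phase (TBL)
   window; unpairable windows are flagged, never dropped silently.

Sample indexing is 0-based with half-open `[onset, offset)` intervals.

## The weighted MVC statistic

Per run and muscle, MVC = 0.7·A + 0.3·RMS with A = max − min of the
filtered series and RMS its root mean square. The weighting favours
sensitivity to full recruitment peaks while the RMS term tempers outliers.
Two caveats are deliberate package policy:

* the name "MVC" is retained for continuity with the source tables, but the
  quantity is a per-task statistic in arbitrary units, **not** a normalised
  %MVC — no calibration contractions exist;
* the statistic is computed on the full filtered series by default; the
  `restrict_to_activations` option recomputes it on concatenated detected
  bursts only, as a sensitivity analysis.

Muscle coordination is the Pearson correlation between two muscles' MVC
values across the 9 runs. A constant column has no defined correlation and
is reported as NaN with a warning, never silently zeroed.

## L9 design and effect analysis

Factors and numeric level codings, exactly as used for regression:
torso angle λ ∈ {0, 30, 45}°, lever distance L ∈ {0, 50, 100} mm, lever
orientation ψ ∈ {−30, 0, +30}° (pronation negative). `build_l9` assigns the
standard L9 orthogonal array; every (factor, level) appears in 3 runs and
every ordered level pair of two factors in exactly 1 (tested invariant).

* **Main effects** are level means (3 runs each). The mean of a factor's
  three level means equals the grand mean of all 9 runs to 1e-9 relative —
  a balance identity used as a standing test.
* **Interaction grids** average responses over the cross of two factors'
  levels. In an L9 each cell is a single run and two-factor interactions
  are confounded with the remaining main effect: the grids are descriptive
  displays whose margins reproduce the main effects exactly, not orthogonal
  interaction estimates.
* **Quadratic fits** regress the 9 responses on (1, x, x²) of one factor's
  numeric levels via OLS (statsmodels; an independent normal-equations
  solve serves as the test oracle). With three equally replicated levels
  the parabola interpolates the level means, so the intercept equals the
  level-0 mean whenever 0 is a level — true for all three factors here.
  R² is reported in percent; the residual dispersion is reported both as
  SSE and as the residual standard error √(SSE/6) (6 = 9 − 3 degrees of
  freedom), labelled unambiguously because summary tables in this area
  sometimes print the RSE under a "residual sum of squares" heading.
* **Optima** take, per muscle and factor, the level with the smallest mean
  MVC (minimum effort objective); ties break to the earlier design-order
  level with a warning. The **overall recommendation** is the plain
  arithmetic mean of the four muscles' optimal numeric settings per factor
  — no MVC-weighted averaging, matching the source procedure. On the
  packaged tables this yields λ = 0°, L = 37.5 mm, ψ = +15°.
* **Design-space surfaces** evaluate either a bilinear interpolation of an
  interaction grid or the additive combination q_x(x) + q_y(y) − grand mean
  of two quadratic fits over a rectangular grid. The evaluation axes always
  include the design-level knots so surface values at design points are
  exact regardless of resolution; argmin/argmax cells are reported.

## Anthropometry, reach and turning geometry

All geometry is in mm internally; survey tables in cm are converted on use.
Percentiles are empirical with linear interpolation between closest order
statistics (numpy default), pinned for reproducibility; SD uses the n−1
convention. The packaged survey's printed 5th–95th bounds are treated as
fixture data, not as a validation target, because they are not consistently
the normal-theory values of the printed means/SDs.

The four reach constraints use seat height H1 (default 500 mm), seated
shoulder height E, shoulder-grip length K, torso-coronal angle λ and
torso-sagittal angle τ. τ appears only in the lateral-low constraint and
has no published value; it defaults to 0° (upright), which drops the
shoulder term and makes that constraint maximally conservative.

The 360° turning distance is 2π·(L1 + L2)/2 — the turning radius taken as
the mean of the footprint half-lengths. The alternative diagonal reading
2π·√(L1² + L2²) is implemented for comparison but is inconsistent with the
prototype's stated 4870 mm figure (it gives ≈7060 mm). Clearance checks
compare reach left-hand sides against each standard's lower bound and the
turning distance against the largest allowed envelope; unspecified entries
are skipped, not failed.

## Usability summaries

Task times are summarised as mean, sample SD (n−1) and SE = SD/√n, with
reported values rounded half-up to 1 decimal (matching how such times are
quoted). The Likert vocabulary is the fixed 4-category favourability scale
mapped to 4..1; VAS ratings live on [0, 10]. The packaged task-time table's
row means disagree with some separately quoted per-task prose values (e.g.
the straight-corridor row averages 4.0 s where 4.1 s is quoted); the
package always computes from the table, and only table-consistent quoted
values (ramp 14.8 s, 90° turn 21.6 s) are asserted in tests.

## Synthetic data: what it emulates and what it does not

`generate_recording` synthesises each channel as baseline Gaussian noise
(SD 1 a.u.) plus, inside its phase's windows, band-limited Gaussian noise
(20–200 Hz, the spectral support of surface EMG under this Nyquist) scaled
to the channel amplitude (default 10 a.u.) with a 25 ms linear edge taper
to avoid spectral splatter. The default cadence is 1.0 s pull / 1.0 s push /
0.5 s rest — a desk-scale choice, since no cycle timing is published — and
pull engages BBL/BRD/PDT while push engages TBL. Amplitudes are arbitrary
units throughout; no µV calibration is attempted because the source feature
tables are unitless.

`generate_run_suite` maps factor levels to amplitude multipliers
(multiplicative across factors), giving known monotone effect structure for
parameter-recovery tests: with a 1.5× multiplier injected at one torso
level, the design stage steers every muscle's optimum away from that level
in ≥95% of 20 seeded replicates. Because only one level is boosted, the two
unboosted levels are exchangeable in expectation, so "correct recovery" is
defined as avoiding the boosted level rather than naming a unique winner.

Not modelled: motor-unit action-potential shapes, electrode–skin impedance,
movement artefact, mains hum, fatigue-related spectral drift, or
inter-participant variability. Passing tests therefore demonstrate the
correctness of the processing and analysis chain under the stated
stochastic model, not robustness to every artefact of real acquisitions.

Anthropometric samples draw each feature independently from a normal
truncated at ±4 SD; task-time and VAS generators draw normal values clipped
to physical ranges (≥0.5 s; [0, 10]). Clipping biases recovered means
slightly toward the interior; round-trip tests use tolerances that absorb
this.

## Problem sizes and determinism

Test and pipeline defaults keep simulations desk-scale: 1–3 pull–push
cycles per recording (1250–3750 samples × 4 channels), 9-run suites, and
20-replicate recovery experiments — the full suite runs in seconds. Every
stochastic component is driven by an explicit seed through
`numpy.random.default_rng` / `SeedSequence`, and identical configuration
plus seed reproduces recordings bit for bit and report JSON byte for byte.

## Known limitations

* The L9 cannot separate two-factor interactions from main effects; the
  interaction grids and surfaces are exploratory displays.
* The per-run response table averages participants before analysis;
  participant-level variability is not propagated into the effect
  estimates.
* The reach equations are closed-form expressions for a fixed posture, not
  a kinematic digital-human-model simulation.
* The quadratic response curves interpolate three level means; they are
  descriptions of the design range, not extrapolable dose–response models.
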