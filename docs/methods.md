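# Methods

This note documents the models and estimators the package implements,
the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer from the code.

## AFM force spectroscopy

### Model of a retraction curve

A retraction trace is force (pN) vs. cantilever displacement (nm),
baseline ≈ 0 with adhesion force negative while a bond is loaded.  An
unbinding event is a linear force ramp of slope −*k*<sub>eff</sub>
(pN/nm) that terminates in a sharp upward jump back to baseline; the
jump marks bond rupture.  Protocol constants default to the
experimental values: retraction velocity *v* = 5000 nm/s and cantilever
spring constant *k* ≈ 25 pN/nm.  Only the retraction portion is
analyzed; the approach is not modeled.

### Event detection

The detection algorithm (the original analysis used an unpublished
script, so this design is the package's own) is:

1. Moving-average smoothing, window `w = 5` samples (odd, configurable).
2. Candidate regions where the smoothed trace rises by at least
   θ·min(3, w)/w over a 3-sample span.  The scaling compensates the
   smoothing attenuation of a 1-sample jump, so θ is a threshold on the
   *underlying jump height*: with `w = 5` a jump of height *F*<sub>R</sub>
   appears in the smoothed trace as a rise of 3*F*<sub>R</sub>/5.
3. Within each candidate region, the jump is localized on the **raw**
   trace as the largest rise over a ≤ 3-sample span, and the rupture
   minimum is the raw argmin over the three samples ending at the jump
   start.  This caps the planted-vs-detected index offset at 2 samples
   whenever the jump is localized correctly.
4. A 3-sample refractory gap suppresses duplicate detections.

The automatic threshold is θ = max(20 pN, 4 × robust noise SD), with
the noise SD estimated as 1.4826 × MAD of the final 20 % of the trace
(generators keep that stretch event-free; on real data the median-based
estimate tolerates an occasional event sample).  With 5 pN baseline
noise the smoothed 3-span rise has SD ≈ 2.4 pN, so the scaled threshold
(12 pN) sits at ≈ 5σ and the false-positive rate is ≪ 0.01 events per
curve.  The 20 pN floor means events with *F*<sub>R</sub> ≲ 20 pN are
undetectable by design at the default setting; analyses of noiseless
synthetic data may pass an explicit lower threshold.

### Event quantification

- *F*<sub>R</sub> = mean(force over `m_post = 50` samples after the
  minimum, truncated at the next event or trace end) − force at the
  minimum.  Fewer than 3 post-rupture samples flags the event
  unquantifiable.  Because the minimum is an argmin over 3 noisy
  samples, *F*<sub>R</sub> carries a small positive selection bias
  (≈ +2 pN at 5 pN noise), well inside the propagated per-event
  standard error noise·(1 + 1/√`m_post`).
- *k*<sub>eff</sub> = |least-squares slope of force vs. displacement
  over `m_pre = 30` samples ending at the minimum|, refusing windows
  that overlap a previous event.  *F*′ = *k*<sub>eff</sub>·*v* holds
  exactly for every emitted event.
- The window defaults (30 pre, 50 post samples at 1 nm sampling) trade
  bias against variance at the simulated sampling density; both are
  configurable.

### Specificity gate and binding frequency

Quadrant II of the (*F*<sub>R</sub>, *F*′) plane — strictly
*F*<sub>R</sub> > 50 pN and *F*′ > 2000 pN/s — marks specific events;
the strict inequalities follow the ">" convention of the thresholds'
definition.  Per cell, *f*<sub>b</sub> = n<sub>specific</sub>/n<sub>total</sub>
over detected events (cells with zero events are excluded with a
warning; the quantity is undefined for them), and *f*<sub>b,rel</sub>
divides by the reference-condition mean *f*<sub>b</sub>.  Condition
summaries treat the **cell** as the unit of replication
(mean ± SEM over cells) and additionally report pooled quadrant
occupancy fractions over all events, since either grouping may be
wanted.

## Cell migration

### MSD by non-overlapping intervals

For lag *n*Δ*t* the track is partitioned from frame 0 into consecutive
disjoint segments of *n* frames; ⟨*d*²⟩ is the mean squared
end-to-start displacement over the ⌊(frames−1)/*n*⌋ full segments, and
remainder frames are dropped.  This is the strictest disjoint reading
of the interval method; segments are never reused across lags of the
same *n*.

### PRW model and fit

⟨*d*²(*t*)⟩ = 2*S*²*P*[*t* − *P*(1 − e<sup>−*t*/*P*</sup>)] is evaluated
through `expm1` with a Taylor branch (*S*²*t*²(1 − x/3 + x²/12),
x = *t*/*P*) below x < 10⁻⁴, making both the ballistic (→ *S*²*t*²) and
diffusive (→ 2*S*²*P*t) limits accurate to better than 10⁻⁶ relative.

The fit is bounded nonlinear least squares (S ∈ (0, ∞),
P ∈ (Δ*t*/100, 100·*t*<sub>max</sub>)), initialized at
S₀ = √⟨*d*²(Δ*t*)⟩/Δ*t* and P₀ = median lag.  Only lags with at least 2
disjoint segments and within the first half of usable lags enter the
fit: single-segment MSD estimates are degenerate, and long-lag
estimates of an exhausted track dominate the residual otherwise.  R² is
1 − SS<sub>res</sub>/SS<sub>tot</sub> on the fitted points (unweighted).
Non-convergence returns R² = −∞, which any R² filter rejects.  Cells
with R² < 0.5 (strict) are excluded from condition means; a `low_n`
flag marks conditions with fewer than 40 surviving cells, the study's
design minimum.

On simulated tracks at the study conditions (S = 1 µm/min, P = 20 min,
Δ*t* = 5 min, 96 steps) the fit recovers the median S within 10 % and
median P within 30 %, and ≥ 90 % of cells pass the R² filter; exact
model data is recovered to 10⁻⁶ relative with R² = 1.

## Morphodynamics

- Circularity C = 4π*A*/*P*².  Polygons: shoelace area and edge-sum
  perimeter.  Masks: pixel-count area and a Crofton (4-direction)
  boundary perimeter — pixel-count perimeters overestimate boundary
  length and bias C downward.  C is clipped to ≤ 1 only in the
  reporting property; the raw value is retained.
- Area oscillations: for each media switch, the peak is located on a
  3-point smoothed series within a 60-minute window; time-to-peak is
  flagged undefined when no rise above the pre-switch level exists.
- Kymograph edge extraction: per frame the outermost suprathreshold
  pixel (Otsu threshold unless given), after a 3-pixel spatial boxcar
  that suppresses isolated suprathreshold noise pixels beyond the cell;
  frames with no suprathreshold pixel are interpolated from neighbors
  and flagged.
- Protrusion events: steps are classified rising/plateau/falling on a
  3-point smoothed trace (plateau tolerance 0.5 px/frame), ramp
  boundaries are refined by one step against the raw trace (so
  noiseless ramps are recovered exactly), and the trailing plateau
  accepts steps flat on either the raw or the smoothed trace to bridge
  smoothing blur at the boundary.  Event height is measured start-of-
  ramp to peak on the **raw** trace, matching the manual
  line-drawing procedure it reproduces; events under 4 px are
  discarded.  Velocity = height/ramp duration (reported both as
  px/frame and µm/min); lifetime = (ramp + plateau frames) × frame
  interval, in seconds.  Plateau precedence (plateau onset terminates
  the ramp) and the 0.5 px/frame tolerance are this package's choices;
  both are parameters.

## Trajectory metrics

The headpiece-opening distance is *d* = |COM<sub>A</sub>.y −
COM<sub>B</sub>.y| with mass-weighted centers of mass (an unweighted
mode exists for XYZ inputs without masses), defaulting to the
β-propeller region α250–438 and the hybrid region β55–106 ∪ β356–434.
The magnitude is reported, and the metric is deliberately **not**
rotation-invariant in general: it is invariant under translations and
rotations about y, and a 90° rotation about z swaps in the former Δx —
the y-axis is the axis of the input frames and no reorientation is
attempted.  Residue–ion coordination distances use the full 3D COM–COM
distance.

Replicate histograms bin each replicate on shared edges (snapped to
multiples of the bin width), normalize each replicate to sum 1
independently, and report per-bin mean ± SEM across replicates.  The
default bin width of 0.05 nm resolves opening-distance modes ~0.45 nm
apart; values outside an explicit range extend it with a warning so
normalization stays exact.

## Statistics

Two-condition comparisons use the classical pooled-variance Student
t-test (Welch behind a flag); with zero pooled variance, equal means
give p = 1 and unequal means p = 0.  Multi-condition comparisons use
one-way ANOVA with the Bonferroni post-test of classical biology
statistics packages: pairwise t statistics share the pooled
within-group mean square with N − k degrees of freedom, and adjusted
p = min(1, m·p) over the m pairwise comparisons.  The t-test p agrees
with a 10⁵-permutation reference to within ≈ 0.01 absolute on small
normal samples (the residual gap is the finite-sample difference
between the permutation distribution and the t reference, not
Monte-Carlo noise).  Normalized geometric MFI is mean(test geometric
means)/mean(control geometric means).

## Synthetic-data generators

All generators are pure functions of their config; a master
`SeedSequence` spawns independent substreams per curve/replicate, so
outputs are bit-for-bit reproducible and streams are independent.

- **Curves**: Gaussian baseline noise (default 5 pN) plus planted
  linear ramps ending at exactly −*F*<sub>R</sub> with slope
  −*k*<sub>eff</sub> and an instantaneous return to baseline.  The
  populations default to the gate-study conditions: specific
  *F*<sub>R</sub> ~ N(90, 15) pN with *k*<sub>eff</sub> ~ N(0.8, 0.1)
  pN/nm, nonspecific N(30, 10) pN with N(0.2, 0.05) pN/nm, at
  *v* = 5000 nm/s and 1 nm sampling.  Draws are floored at 5 pN /
  0.05 pN/nm to keep ramps well-formed.  Events sit in the first 75 %
  of the trace (leaving the tail for noise estimation) with successive
  minima separated by at least the next ramp length plus 120 samples,
  which exceeds both 3× the slope-fit window and the post-rupture
  window — ground truth stays unambiguous.  The event-count
  distribution per curve defaults to P(0, 1, 2) = (0.3, 0.5, 0.2); the
  source experiments do not report event shapes or noise levels, so
  these defaults are stated, not fitted.
- **Tracks**: each velocity component is a stationary
  Ornstein–Uhlenbeck process with autocovariance (S²/2)e^(−t/P);
  position increments are drawn **jointly** with the velocity update
  from the exact integrated-OU distribution (conditional mean
  P(1−a)v, a = e^(−Δt/P), with the exact 2×2 conditional covariance),
  not an Euler step.  The ensemble MSD therefore equals the closed form
  at every lag, making parameter-recovery tests unbiased.
- **Shapes**: rectangle, regular n-gon and star polygons with truth
  values from each family's closed form, not from the vertex list.
- **Kymographs**: piecewise-linear edge schedule (ramp, plateau, linear
  retraction to baseline) plus Gaussian pixel noise; overlapping events
  are rejected at config time.
- **Frames**: two rigid pseudo-residue groups (chain A resids 250–438,
  chain B resids 55–106 ∪ 356–434, atoms spread over the full ranges)
  whose mass-weighted COM Δy equals the schedule exactly before
  independent per-group rigid jitter; x/z offsets are arbitrary.
  Measured d then has SD √2·jitter_sd and no bias.

What the generators do **not** emulate: thermal polymer stretching
(WLC/FJC) or cantilever hydrodynamics in curves, cell–cell interactions
or drift in tracks, image formation in kymographs, and actual molecular
dynamics in frames.  Passing tests therefore demonstrate correctness of
the estimators under the stated models, not robustness to every
instrumental artifact of real recordings.

## File formats and pipeline

Units are encoded in column names (`_nm`, `_pN`, `_um`, `_min`) with no
implicit conversions.  Coordinate frames travel as multi-model PDB
(MODEL/ENDMDL, Å on disk, nm in memory) or plain XYZ (nm) with a JSON
sidecar mapping atoms to chain/residue; masses come from standard
atomic masses by element.  Tracks and shapes use an image (y-down)
convention; trajectory frames keep their file's native axes.  The
`run` pipeline executes configured stages under one output directory,
validates the whole config before running anything, and writes a
provenance record (config, SHA-256 config hash, seed, package version,
per-stage status); identical configs reproduce identical data files.

## Known limitations

- The event detector assumes near-instantaneous ruptures; slow
  detachments (multi-sample force recovery) would be localized late and
  their *F*<sub>R</sub> underestimated.
- Sub-threshold events (≲ 20 pN at 5 pN noise) are invisible, so
  *f*<sub>b</sub> is a ratio over *detectable* events; comparisons
  across conditions remain monotone in the planted specific fraction.
- The MSD estimator discards remainder frames, costing some efficiency
  on short tracks relative to overlapping-interval estimators (which
  trade it for correlated samples).
- Protrusion plateau/ramp boundaries blur under smoothing; boundary
  refinement is one raw step, so heavy noise (≫ 0.5 px) degrades
  lifetime estimates before velocity estimates.
- The opening distance is meaningful only in the input frames' axis
  convention; no alignment or reorientation is performed.
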