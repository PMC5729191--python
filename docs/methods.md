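# Methods

This note documents the models and numerical choices behind `tonomap`:
the stimulus design, the synthetic cohort generator, each analysis stage,
and known limitations. Problem sizes given here (mesh dimensions, subject
counts, iteration counts) are the package's own defaults, chosen to keep a
full end-to-end run under a minute on one CPU while leaving every
statistical quantity well estimated.

## Stimulus design

Five frequency bands with centres 300, 566, 1068, 2016 and 3805 Hz span
the scale in roughly equal log steps. Each 12.8 s block contains a 0.8 s
visual prompt, a 0.8 s gap, and fourteen 0.8 s mini-sequence slots
(11.2 s of sound); the behavioural task is 1-back repeat detection, with
1–3 repeats per block (probabilities ¼, ½, ¼) spaced at least three slots
apart. Five blocks form a 64 s cycle; a run is 32 s silence + 8 cycles +
32 s silence = 9.6 min, acquired as 584 volumes at TR 1 s of which the
first 8 are discarded (576 retained: 32 + 512 + 32).

Three conditions share this skeleton:

- `tonotopy`: a single band per block, stepping low→high (`up`) or
  high→low (`down`) through the cycle.
- `attn_stepped`: two simultaneous bands per block — the stepped member
  plus a distractor at least 14 semitones away (semitones =
  12·log2(f2/f1)); the prompt cues attention to the stepped member.
  Exactly six band pairs satisfy the constraint: (0,2), (0,3), (0,4),
  (1,3), (1,4), (2,4).
- `attn_random`: identical acoustics to an `attn_stepped` run built from
  the same seed, but the prompt is swapped on exactly 20 of the 40
  blocks, under two constraints: every band is still attended exactly 8
  times (so each band loses 4 stepped slots and gains 4 distractor
  slots), and no band is attended at the same within-cycle position in
  more than 4 of the 8 cycles (aperiodicity). Feasible swap allocations
  are found exactly as a transportation problem via max-flow, randomised
  over equivalent optima by seeded cycle rotations; distractor pairings
  are resampled until the flow is feasible, identically for both
  attention conditions so the acoustics stay shared.

## Synthetic cohort

Surfaces are regular triangulated flat patches (default 40 × 32 vertices
at 1 mm). A continuous band coordinate u ∈ [0, 5) is planted either as a
single monotone gradient or folded into mirror-reversed "fingers".
Planted coordinates keep a 0.1-band margin from band boundaries — a
vertex exactly on a boundary has a genuinely ambiguous phase — and a
0.3-band margin from the *inner* boundaries of the two outermost bands,
because tuning truncated at the ends of the scale pulls the decoded phase
up to ~0.18 band units toward the interior at the widest tuning (measured
from the noiseless forward model).

Per-vertex tuning is a Gaussian bump over band index centred at u, with a
smooth spatial width field (SD 0.35–0.65 bands). Rows are normalised to a
fixed total drive (sum = 5, i.e. unit mean weight): sharper tuning
concentrates the same total response on fewer blocks, so the amplitude at
the stimulus frequency tracks tuning selectivity (peak-minus-mean weight),
with correlation ≈ 0.97 in noiseless runs. (Peak normalisation, in
contrast, makes amplitude peak at band *boundaries*, where two adjacent
bands — 72° apart in phase — add nearly coherently; that inverts the
amplitude–selectivity relation the R1 analysis relies on.)

The simulator builds per-band boxcars at 0.1 s resolution, convolves them
with a gamma-density HRF (mean lag 6 s, SD 3 s; shape 4, scale 1.5 s —
shared with the analyser's design matrix), samples at the TR, and adds:

- attentional gain on the attended stream: multiplicative (weight ×
  gain, default) or additive (+ (gain − 1) mean weights). The
  unattended (distractor) stream responds at the plain tuning weight.
  The default gain is 4.0 — the attended stream drives four times the
  ignored stream — reflecting strongly attention-dominated responses in
  dense two-stream scenes. This is also what makes the randomised-cue
  control work: the stepped member's acoustic drive is periodic in
  *both* attention conditions, so the randomised condition's group
  amplitude converges to ≈ 1/gain of the stepped condition's (measured
  0.23–0.25 at defaults; a gain near 1 could never push it below 0.3).
- stationary AR(1) noise (marginal SD 1.0, lag-1 coefficient 0.4);
- a per-vertex half-cosine drift (period 1168 s, amplitude SD 0.5),
  removed by the 100 s high-pass at analysis.

R1 (a myelin proxy, s⁻¹) is planted as 0.65 + 0.02·coupling·z(selectivity)
plus smooth noise, clipped to [0.55, 0.75]. Cohorts share a group map;
each subject's map is displaced by a smooth field (SD 0.3 bands by
default) and re-derived, so subjects have idiosyncratic but overlapping
maps. The default run plan is 12 runs per subject: 4 tonotopy, 4 stepped,
4 randomised, balanced over sweep directions.

## Fourier mapping

Analysis crops the silent baselines and uses the 512 s stimulation
window, where the stimulus frequency (1/64 Hz) is exactly DFT bin 8. The
complex signal is scaled so its modulus is the sinusoid amplitude and its
argument is the cycle fraction of the response peak. The F statistic is
the stimulus-bin power over the mean power of the noise bins — all
positive-frequency bins except DC, the three lowest frequencies, the
stimulus bin, its 2nd and 3rd harmonics, and Nyquist — and is exactly
F(2, 2K)-distributed for K noise bins under white Gaussian noise
(measured rejection rate 0.0476 at nominal 0.05, n = 8000).

Downward sweeps are combined by conjugation plus a one-sample rotation,
algebraically identical to analysing the time-reversed series; the
complex mean of up and down runs then cancels the shared hemodynamic
delay. Varying the simulated HRF lag between 4 and 8 s moves the combined
phase by 0.010 rad on average (the vertexwise maximum reaches ~0.022 rad
at a few scale-edge vertices where the cycle ramp-in transient interacts
with truncated tuning). Decoding maps phase fraction f to band
⌊5f⌋; with the planting margins above, noiseless recovery is exactly
100%, degrading monotonically with noise SD.

## GLM mapping

Each run is modelled with five HRF-convolved band boxcars, a cue
regressor and an intercept; attention runs model the ignored bands in a
separate, parallel regression. Data and regressors are high-pass filtered
with an orthonormalised discrete-cosine basis (order ⌊2·T·TR/100 s⌋).
AR(1) prewhitening is vectorised across vertices: the lag-1 coefficient
is estimated from OLS residuals and corrected analytically for projection
bias (OLS residuals under-state serial correlation; the expected raw
ratio is a ratio of trace polynomials in ρ of the residual-maker matrix,
evaluated on a grid and inverted), then whitened normal equations are
solved in batch. The residual degrees of freedom subtract the design and
high-pass dimensions. Under pure AR(1) noise the band-coefficient z
values reject at 0.049–0.051 at a nominal two-sided 0.05 (n = 20 000).
Runs combine by inverse-variance weighting (zero-variance exact fits are
floored to combine with equal weight); winner-/loser-takes-all maps take
the per-vertex argmax/argmin, resolving ties to the lowest index with a
flag.

## Surface statistics

Concordance maps are binary agreement between two best-band maps; the
group test is a one-sample t against the 1/5 chance level. Cluster
correction simulates null maps (white Gaussian fields smoothed by a
nearest-neighbour step count matched to the observed map's neighbour
correlation), thresholds at the vertexwise alpha, and records the maximum
suprathreshold cluster area per iteration. Because vertex areas on a mesh
are discrete, cluster areas are heavily tied; the minimum surviving area
is therefore the smallest observed null area whose empirical exceedance
probability is at or below the corrected alpha, not an interpolated
quantile (which can land on a tied value and let the whole tie mass
through). Measured familywise error at corrected alpha 0.001: 0–2 events
per 1000 replicates.

## ROI quilt

Geodesic disk ROIs (radius 4 mm) are flooded around a near-regular
lattice (spacing 8 mm, inset by the radius; 12 ROIs on the default
patch). Per ROI, subject × band mean coefficients from the attention
conditions are regressed on those from tonotopy with a mixed model
(random subject intercept); z is the probit of the t CDF at n − 2 df,
capped at ±8, with one-sided Bonferroni control across ROIs. A planted
slope of 0.8 at n = 8 subjects is recovered with mean 0.80 and lies
within the 95% CI in ≥ 10/12 ROIs; band-permuted profiles yield 0–1
significant ROIs.

## Myelin searchlight

Within each vertex's 4 mm geodesic disk, the normalized covariance
(Pearson by default; a "global" variant divides by whole-map SDs) between
the R1 map and a response-amplitude map is evaluated, returning exactly
±1 for linear relations and NaN (flagged, never propagated) for
degenerate disks. With R1 coupled to selectivity (coupling 1) the mean
normcov against tonotopy-run Fourier amplitude is ≈ 0.93; with coupling 0
it is 0 within Monte-Carlo error. Surface gradients come from per-triangle
linear interpolants aggregated by area-weighted vector averaging (exact
for linear ramps).

## Pipeline

`run_pipeline` executes synthesize → Fourier → GLM → surface statistics →
ROI quilt → searchlight from one YAML configuration and one master seed,
writing CSV overlays, a JSON manifest with per-file SHA-256 checksums,
and a report that is a pure function of the manifest. Schedules, noise,
subject jitter and null simulations all derive their seeds from the
master seed; results are reproducible bit-for-bit across processes
(the max-flow step uses integer node labels so the returned optimum does
not depend on the interpreter's string hash seed).

## Limitations

- The attended and ignored boxcars of the *same* block coincide exactly,
  and attended/ignored coefficients come from separate regressions, so
  each absorbs part of the partner stream's response. `diff_best`
  (attended − ignored at the best band) stays strongly positive, but
  `diff_worst` can go negative when a vertex's worst band is paired with
  its best band; interpret the attended-vs-ignored contrasts with this
  cross-contamination in mind. A joint 10-regressor fit would remove it
  at the cost of changing the method.
- The delay-cancellation residual is quoted as a vertex mean; a few
  scale-edge vertices show residuals up to ~0.022 rad per 2 s of lag
  change due to ramp-in transients.
- Flat patches only: geodesics are exact on these up to mesh
  discretisation, but no curvature-related effects are modelled.
- The simulator shares its HRF with the analyser by default;
  mis-specification can be introduced explicitly via `hrf_lag_s` /
  `hrf_sd_s` but is not part of the default validation.
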