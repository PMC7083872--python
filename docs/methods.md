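# Methods

## Model

A bound, fluorescently tagged molecule observed by interval imaging
disappears through two competing first-order channels: dissociation at
rate k_off (per second of wall-clock time) and photobleaching at rate k_b
(per second of *illuminated* time). With integration time τ_int per frame
and time-lapse spacing τ_tl, the per-frame bleach survival is
exp(−k_b·τ_int), independent of τ_tl, and the probability that a molecule
from population i is still visible after m frames is

    P(M ≥ m) = exp(−k_eff,i · m · τ_tl),   k_eff,i = k_b·τ_int/τ_tl + k_off,i.

Binding kinetics are a one- or two-population exponential mixture with
amplitudes Aᵢ (Σ Aᵢ = 1). Model order is capped at two: the diagnostic and
the fit both degrade sharply when off rates are closer than ~threefold
(see "Resolution limit"), so a third population is rarely identifiable
from this design. Rates are stored as off rates in s⁻¹; lifetimes
τᵢ = 1/k_off,i are presentation-layer reciprocals.

### Frame discretisation

A molecule is counted in a frame only if it is bound for the frame's full
integration window, and bleaching is evaluated once per illuminated
frame. Under this convention the number of observed frames is exactly
M = min(⌊T_bind/τ_tl⌋, ⌊T_bleach/τ_int⌋, n_sm_frames), and the survival
of M is exactly the mixture the fitter assumes — partial-frame occupancy
is not modelled. Events are right-censored at the single-molecule phase
length (100 frames); because the CRTD is fit on cumulative counts, the
censoring needs no special handling. Start frames within an acquisition
are bookkeeping for wall-clock timestamps (used by time-windowed
analyses); dwell censoring is applied at the full phase length regardless
of start frame, keeping the simulated survival identical to the fitted
model.

### Detected events and normalisation

Real pipelines only record events that persist for at least one full
frame, and published event counts are counts of *detected* events. The
simulator therefore returns exactly `n_events_per_tau` detected events
per τ_tl (rejection sampling), and the fitter compares normalised
cumulative counts c(m)/c(1) against the identically normalised model
S(m)/S(1). This conditioning-consistent normalisation recovers generating
parameters exactly on noise-free fixtures; fitting the unnormalised model
against normalised data would be inconsistent at m = 1.

## Estimation

### Per-τ_tl effective rates

k_eff at one τ_tl is the count-weighted least-squares slope of log counts
against time (weights = counts, the Poisson choice). Cumulative counts
are strongly correlated across m, which makes analytic slope variances
unreliable; standard errors instead come from a 32-replicate parametric
bootstrap that resamples the duration histogram multinomially and refits.
Internal bootstrap seeds are fixed constants, so results are
deterministic functions of the data.

### Model-order diagnostic

For a single population, k_eff·τ_tl is affine in τ_tl (slope k_off,
intercept k_b·τ_int). The diagnostic fits this line by weighted least
squares (weights from the k_eff standard errors) and computes the
weighted residual sum as a lack-of-fit statistic. Exponential-mixture
curvature is S-shaped along the τ_tl axis — a quadratic alternative has
essentially no power against it, and an analytic χ² reference is
anti-conservative because the per-point variances are estimated from
correlated counts. The statistic is therefore calibrated by parametric
bootstrap: 99 single-population CRTD series are simulated from the fitted
line itself at the observed event counts, the statistic is recomputed for
each, and the p-value is the rank of the observed value (α = 0.05).
Measured operating characteristics: 10/10 detections of the reference
two-population mixture at its published event count; 3/100 false alarms
across ten random one-population parameter sets at n = 10⁴ events per
τ_tl; ~0.3 s per diagnosis.

### Global fit

All CRTDs are fit jointly with shared {Aᵢ, k_off,i, k_b}, minimising

    Σ_τ Σ_m w(m) · [c(m) − c(1) · S(m)/S(1)]²,   w(m) = 1/max(c(m), 1)

by bounded nonlinear least squares (`scipy.optimize.least_squares`, TRF)
in log-lifetime / log-k_b space, with amplitude linear in (0.01, 0.99).
Bounds: lifetime ∈ [0.05, 5000] s, k_b ∈ [0.1, 50] s⁻¹ — spanning every
value in the reference panels with margin. Eight multi-starts cover
log-spaced lifetime pairs plus one data-driven start from the k_eff·τ_tl
line (slope → k_off, intercept/τ_int → k_b). After an order-2 fit,
populations are sorted fast-first; fits whose lifetime ratio is below 1.5
— under the method's resolution — are collapsed to order 1 with a
warning.

### Bootstrap uncertainties

Ten subsamples of 80% of the compiled events, drawn without replacement
and stratified by τ_tl so every CRTD stays populated; the SD of each
parameter over the replicate fits is reported. Subsampling at 80% without
replacement understates full-sample scatter by roughly a factor of two;
it is kept because it is the procedure the reference uncertainties were
computed with. Replicate seeds derive from one pipeline seed by fixed
offsets.

### Time windows

`window_partition` splits events into consecutive 25-min (1500 s) windows
of acquisition start time; each window is fit independently. The
simulator schedules acquisitions in rounds cycling through the τ_tl grid,
which is what makes windows meaningful — on the 5-point post-UV grid
{0.1, 0.3, 1, 3, 10} s one full round lasts ≈ 24.4 min, i.e. one window.

## Image analysis

* **Flattening** — per-frame illumination is estimated by a large-kernel
  (50 px) median filter computed on a 4×-downsampled copy and resampled
  back (a pure speed optimisation; the estimator is unchanged), then the
  mean over non-cell pixels (or the frame median when no masks are given)
  is subtracted.
* **Discoidal average filter** — mean over a disc of radius 1 px minus
  mean over the annulus (1, 3] px, implemented as a linear convolution
  with zero-padded boundaries; the test suite pins it to a brute-force
  double-loop implementation at 1e-10.
* **Detection** — pixels above median + T × (1.4826 × MAD) of the
  filtered frame are grouped into 8-connected components, one detection
  per component at its intensity-weighted centroid. The threshold
  multiple T defaults to 8 (configurable 7–8); the robust-SD unit is a
  design choice, as the original "relative intensity threshold" does not
  state its unit.
* **Linking** — greedy nearest-neighbour matching of detections in
  consecutive frames within 3 px (318 nm at 106 nm/px), ties broken
  toward the lower detection index; no gap closing, no global assignment
  (densities in the single-molecule phase are low).
* **Copy number** — integrated background-corrected cell intensity
  divided by the single-molecule intensity, the latter estimated as the
  median integrated focus intensity in the single-molecule phase.
* Cell masks are inputs (synthetic or user-supplied label images); no
  segmentation is performed.

## Synthetic data

`simulate_events` draws population labels ~ Multinomial(A), binding times
~ Exponential(1/k_off,i) and bleach times ~ Exponential(1/k_b), then
applies the frame-discretisation rule above. `simulate_movie` renders a
two-phase stack: a bleach-down phase starting from a 5×-dense emitter
population, then the single-molecule phase with each binding event as a
2-D Gaussian (σ ≥ 0.8 px) of fixed total flux on elliptical cells, with
Poisson shot noise plus Gaussian read noise, digitised by rounding to
uint16. Binding start times are uniform over the phase (the least
informative stationary choice — no arrival process is specified by the
design being emulated); event counts are allocated equally across the
τ_tl grid, since per-τ_tl allocations of the reference datasets are not
published.

What the simulator deliberately omits: diffusing (unbound) molecules,
fluorophore blinking/dark states beyond first-order bleaching, EM-gain
register noise, cell growth, drift. Passing round-trip tests therefore
shows the estimator is correct *for the model the analysis assumes*; on
real movies, blinking, diffusive passages and drift can bias lifetimes in
ways these tests do not probe.

## Numerical choices and degenerate inputs

* Empirical CRTDs with fewer than 1000 events warn (quality bar for a
  stable global fit); zero events is an error.
* Flat (non-decaying) counts return k_eff ≈ 0 with a warning rather than
  an error.
* Bootstrap replicates whose fit fails are dropped with a warning; fewer
  than five survivors is an error.
* A constant-zero stack passes through flattening unchanged with a
  warning.
* Simulation and bootstrap refuse to run without a seed.

## Resolution limit and expected precision

Recovery sweeps at 10⁴ events per τ_tl: order-2 models with lifetimes
≥ 3-fold apart recover with ~8% median error; at 1.5-fold ~13%; at
≤ 1.3-fold the error exceeds 35% — consistent with the method's stated
threefold resolution bound, and the reason order-2 fits below ratio 1.5
are collapsed. Long single lifetimes are the hardest regime: with
k_b·τ_int ≈ 0.5–0.7 per frame, every CRTD carries only ~5–6 informative
frames, so a lifetime of ~100–150 s rides as a small perturbation on the
bleach term and its sampling SD at 10⁴–1.6×10⁴ events is 20–50% with
right skew. The round-trip validations in `scripts/acceptance.py` report
single simulations at the reference event counts, so those two quantities
fluctuate accordingly from seed to seed.

## Problem sizes

The test suite simulates 10³–10⁶ events per check and renders movies up
to 256×256 px × 88 frames; the validation script simulates each reference
panel at its published compiled event count (10⁴–8.8×10⁴ events). These
sizes reproduce the published parameters within their published
uncertainties while keeping a full run in about a minute.
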