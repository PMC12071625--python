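# Methods

This note records the models, estimators and numerical choices behind
each analysis stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying methods
left the choice open.

## Synthetic data

**Membrane movies.** Molecules perform 2D Brownian motion with
per-population diffusion coefficients; a fraction `frac_confined`
starts inside circular domains (one molecule per domain, so domain
occupancies are statistically independent) and is reflected at the
domain edge with probability `trap_strength` per attempted crossing —
an escape leaves the molecule diffusing freely at the confined D until
it happens to re-enter.  Frames are rendered as 2D Gaussian PSFs
(σ default 1.3 px) with Poisson shot noise, Gaussian read noise and a
constant camera offset; photobleaching is exponential and irreversible.
Field boundaries either reflect (default) or wrap (`boundary=
"periodic"`).  The periodic mode exists for Fourier-space diagnostics:
with reflecting boundaries, PSFs clipped at the field edge inject
spurious, slowly decaying high-k correlations, which matters only for
noise-free spectral tests (with realistic shot noise those spatial
frequencies are excluded by the signal-to-noise gate anyway).
`membrane_photons` adds diffuse fluorescence inside a circular cell
(85 % of the field by default) so the detection chain's Otsu cell mask
and membrane-mean reference behave as on real TIRF data.
`min_separation` optionally enforces a minimum initial spacing, used by
tracking fixtures so that recovery measures the tracker rather than the
diffraction-limited resolvability of randomly overlapping spots.

Imaging defaults follow the two acquisition regimes the analyses
target: 33.3 frames/s, 3000 frames for single-molecule diffusion
(kICS); 5 frames/s, 300 frames for assembly tracking.  The pixel size
(0.1 µm) and PSF width are documented assumptions of a 100×/NA 1.46
TIRF system, not measured values.

**Assembly traces.** Molecule counts follow a birth–death process:
Poisson arrivals at `arrival_rate`, independent exponential departures
(departure plus bleach rate per molecule).  Each molecule's intensity
is drawn once from a truncated normal (mean 111, SD 40 counts — the
single-mCherry calibration) and contributes until it leaves, so traces
are staircases plus Gaussian readout noise.  `brightness_mode`
chooses whether the unit varies per molecule (default; heterogeneous
step heights within a trace) or per trace (an equal-step staircase
whose unit varies across traces, matching the equal-step model the
fitter assumes).  Note that under per-molecule heterogeneity an
equal-step fitter *cannot* recover every staircase exactly: a molecule
dimmer than about half the fitted unit is necessarily dropped or
double-counted, which is a property of the equal-step model, not of
this implementation.

**Point patterns.** A Neyman–Scott process per channel: Poisson
cluster centers uniform in the ROI, Poisson-distributed members with
Gaussian spread, uniform background.  Channel B re-uses a configurable
fraction of channel-A centers (colocalization).  Each molecule emits
`1 + Poisson(blink_duplication_rate)` localizations, jittered by the
localization precision (default 25 nm) and spread over frames with
bounded gaps, to exercise the blink-merging rule.

**Paired traces.** A logistic ramp (baseline 5, amplitude 9, rise
4 frames, onset at one third of the trace) and its copy delayed by
`delta_frames`, plus independent Gaussian noise expressed as a fraction
of the amplitude.  The positive baseline mimics the camera/membrane
background of real traces and keeps the first-time-point normalization
well defined: a baseline smaller than the noise SD makes the first
value negative for a substantial fraction of traces, which silently
flips the sign of every correlation computed from them.

**What the generators do not emulate:** vesicle docking, 3D diffusion,
raw SMLM frame stacks (the pipeline consumes localization tables),
sCMOS-style structured noise, drift, and chromatic/registration offsets
between channels.  Passing recovery tests on these simulations
therefore demonstrates correctness of the estimators under their
assumed statistical model, not robustness to every artefact of real
recordings.

## Tracking

Detection follows a two-stage scheme per frame: a cell mask from a
30-px median filter, Otsu threshold and 8-px expansion; then Gaussian
smoothing (σ 2 px), white top-hat speckle enhancement (6-px disc) and
local maxima inside the mask.  A candidate is accepted when its raw
6-px-disc mean is at least `intensity_ratio` (default 2) times the
membrane mean, computed over masked pixels outside all candidate discs.
Positions are refined to the intensity-weighted centroid of the
enhanced image in the disc.  Linking is greedy nearest-neighbour with a
Chebyshev gate of 3 px, no gap closing, ties broken by distance then
trajectory id; trajectories must span ≥ 2 consecutive frames.

Trajectory intensity traces store the 6-px-disc **mean** per frame (not
the disc sum), because the single-fluorophore calibration and the
20-frame back-extension are defined on disc means; mixing the two units
would corrupt step fitting.

The diffusion coefficient is the slope/4 of an unweighted linear fit to
the time-averaged MSD at lags 1–4, clipped at zero; the estimator is
deliberately simple since downstream use is a 0.05 µm²/s immobility
threshold, not precision diffusometry.

## Step fitting

Single fluorophores are identified in frame 0 of a calibration movie by
a 2D Gaussian fit in a 6-px window with amplitude/residual-SD ≥ 6, and
kept only when the fixed-position trace is best described by exactly
one downward changepoint (0/1/2-changepoint fits compared with a
penalty of `4·σ̂²·log n` per changepoint; σ̂ is the robust SD of first
differences).  The factor 4 prices a changepoint above the expected
spurious gain of the best-placed split in pure noise (~2σ̂² log n);
with the classic factor 2 the comparison is a coin flip for early
bleachers.  The calibration is the mean ± SD of before/after-step mean
differences.

Staircase fitting is a two-step estimator:

1. **Segmentation** — optimal partitioning (exact dynamic programming)
   of the trace into piecewise-constant segments with penalty
   `3·σ̂²·log n` per changepoint.
2. **Lattice quantization with per-trace unit search** — candidate step
   sizes span `calib.mean ± 2·calib.sd` (81-point grid); for each, the
   baseline is the lattice multiple nearest the pre-assembly mean
   (back-extended frames anchor the zero level), segment means round to
   integer lattice levels, and the step size is then refined by least
   squares given those integer counts.  The candidate minimizing total
   SSE wins; among candidates within a slack of `2σ̂²` per segment the
   **largest** step size is preferred.  The slack resolves an intrinsic
   degeneracy: any sub-multiple `s/2, s/3, …` of the true unit
   reproduces the same staircase levels (with multiplied counts) at
   essentially the same SSE, and a finer lattice can additionally
   absorb ~σ̂² of noise per segment mean, so raw SSE minimization
   systematically halves the unit and doubles every count.

Jumps of |k| > 1 between frames are reported as single events with
signed multiplicity (missing steps).  No monotonicity constraint is
imposed on growth.

## kICS

The movie's per-frame 2D FFT `F(k, t)` gives the raw correlation
`r(k, τ) = ⟨F(k, t)·F*(k, t+τ)⟩_t`; normalizing by the zero-lag power
cancels the PSF transfer function, and circular averaging into bins
uniform in k² (DC excluded) assumes isotropic diffusion.  Numerical
choices that matter:

* **No per-pixel temporal mean subtraction by default.**  The confined
  population's signal is quasi-static on the movie timescale;
  subtracting the temporal mean removes most of it and destroys
  exactly the observables read from it (the late-lag plateau and the
  amplitude ratio; measured bias on simulations ≈ 9× on the ratio).
  Immunity to uniform backgrounds is already provided by excluding the
  DC bin.
* **White-noise floor correction.**  Shot and read noise contribute a
  k-independent floor to `r(k, 0)` only; it is estimated from the
  high-k tail (top 10 % of k², where the transfer function has
  extinguished all signal) and subtracted before normalizing.  Without
  this the normalization attenuates k-dependently and corrupts every
  decay scale.
* **Fit range.**  Fits use k² up to the point where the zero-lag
  signal power still exceeds the noise floor (SNR ≥ 1); beyond it the
  normalized CF is noise.
* **Per-lag fits.**  `R(k², τ) = a_f·e^(−k²·s_f) + a_c·e^(−k²·s_c)`
  with nonnegativity bounds and amplitudes ≤ 2, initialized from a
  single-exponential fit split ±50 % and refined by continuation from
  late lags (where the components are well separated) backwards,
  keeping the best SSE per lag.  When a single exponential fits within
  2 % of the double fit the split is arbitrary and the lag collapses to
  one component.  Components are labelled macro/micro by decay scale
  per lag.
* **Read-outs.**  `D_free`/`D_confined` are slopes of `s_f`/`s_c`
  versus τ over the first 3 valid lags.  The confinement length is
  `2·√(mean s_c)` over the last 25 % of valid lags, where the confined
  MSD has plateaued; the proportionality constant is a convention
  (comparisons across conditions are unaffected), and for a reflecting
  disc of diameter L the Gaussian-phase approximation gives a plateau
  near L/2.  The amplitude ratio is the median of `a_f/a_c` over the
  **resolved** lag window — lags with `s_f ≥ 5·s_c` (the correlation
  has collapsed into two distinct populations) and `s_f·k²_min ≤ 1`
  (the macro amplitude is still anchored by the lowest-k bins).  At
  later lags the macro amplitude becomes an extrapolation from one or
  two bins and the confined component's non-exponential form factor
  leaks into it; on simulations the per-lag ratio drifts from 0.74 to
  4.1 around a true value of 1.0, while the resolved-window median
  stays within ~20 %.

## Clustering

Blink merging chains localizations to the running precision-weighted
centroid (within 100 nm and a 50-frame gap); chain counts conserve the
input row count.  A spatial hash grid keeps this linear-time.  DBSCAN
counts neighbours excluding the point itself; border points are
assigned to the cluster of their **lowest-index** core neighbour — a
deterministic variant of the standard order-dependent assignment that
makes the implementation exactly comparable to a brute-force oracle.
Clusters below 10 members demote to noise.  Cluster area and perimeter
come from the convex hull (shapely); collinear clusters fall back to a
1-nm-buffered hull and are flagged.  Relative density is cluster
density over overall ROI density; circularity is 4πA/P².

## Degree of colocalization

For each channel-A molecule, both channels' neighbour counts are taken
on a 10–500 nm radius ladder (10 nm steps), converted to densities with
border-corrected circle∩ROI areas (shapely, 64-gon circles; exact for
interior molecules), and the two density gradients are compared by
Spearman rank correlation (configurable to Pearson).  Counts exclude
the query molecule and any zero-distance twin, so identical tables
score exactly 1.  Molecules whose own-channel density at 500 nm falls
below the ROI-average density are excluded as score recipients but
still count as neighbours.  Zero-variance gradients score 0.  Edge
correction applies the same area to both channels; this induces a small
positive rank correlation for border molecules under complete spatial
randomness (the CSR mean stays ≈ 0.05 with < 10 % of molecules above
the 0.4 signalling threshold).

Cluster classification: signalling molecule ⇔ DoC ≥ 0.4 (inclusive),
signalling cluster ⇔ ≥ 10 signalling members (inclusive); both
thresholds configurable.

## Temporal cross-correlation ordering

Traces are normalized to their first time point (cosmetic for a
correlation, see below), and the forward/backward cross-correlations
use **global** normalization: whole-trace means and SDs, lag products
averaged over the overlap window.  Per-lag (overlap-window)
renormalization was rejected after measurement: under noise the forward
and backward windows attenuate differently, producing a systematic
ΔCC bias (~−0.02 per lag) that swamps the ordering signal (~+0.08 per
lag) and even flips its sign.  ΔCC(0) = 0 and exact antisymmetry under
channel swap hold by construction.  `sum ΔCC` accumulates lags
0..49 (10 s at 5 frames/s).

`smooth_frames` optionally applies one common moving average to both
channels before correlating.  A shared linear filter preserves the
lead/lag and every symmetry property while suppressing the noise ×
signal cross terms that dominate the variance of the per-pair ordering
statistic; without it, single-pair sign calls at amplitude/noise = 5
are near chance (~60 %) for step-like traces, with a 15-frame (3 s)
window they exceed 95 %.  Ensemble inference (mean, 95 % CI, one-sample
t-test against zero) does not require smoothing.

## Pipeline

Stages run in dependency order (simulate → track → stepfit | kics |
cluster → doc | tccf); every run directory contains the resolved
configuration, the seed and a JSON summary, and a rerun with the same
configuration is bit-identical.  The two-condition study encodes TCR
activation as generator shifts — more and brighter immobile assemblies,
a higher confined fraction, denser clustering — and reports the
qualitative orderings (trajectory count, free/confined amplitude ratio,
percent of molecules in clusters).  Group comparisons use two-tailed
unpaired t-tests, with the caveat that synthetic replicates stand in
for cells.

## Problem sizes

The validation measurements (shared by the test suite and
`scripts/acceptance.py`) use: 25 immobile assemblies × 300 frames for
tracking recovery; 100 Brownian tracks × 300 frames for the diffusion
estimator; 100 staircase traces (≤ 10 steps, noise SD 20) for step
fitting; 200 molecules × 3000 frames at 33.3 fps per kICS movie (one
recovery movie plus a three-point domain-size sweep); 50 random
fixtures (≤ 2000 points) for the DBSCAN oracle; 5000 molecules per CSR
channel × 10 seeds for DoC; 200 trace pairs for TCCF ordering; and
1500-frame movies for the two-condition study.  These sizes give
sampling errors comfortably below the tolerances they are checked
against while keeping a full run in the minutes range.

## Known limitations

* Spot declumping relies on local-maximum separation in the enhanced
  image; heavily overlapping assemblies (< ~3 px apart) merge.
* The equal-step model undercounts traces with strongly heterogeneous
  per-molecule brightness (see Synthetic data).
* The kICS amplitude ratio is reliable only when the resolved-lag
  window is non-empty; very small fields or very fast diffusion leave
  the macro amplitude unanchored.
* DoC edge correction approximates circles as 64-gons (area error
  < 0.2 %, largely cancelling in the density ratio).
* The TCCF module orders events but deliberately does not estimate
  binding/unbinding dwell times; single-rise traces do not constrain
  them.
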