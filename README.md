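# latkit

Single-molecule imaging analysis of step-wise membrane protein assembly,
built around the question of how signalling adaptors such as LAT (linker
for activation of T cells) nucleate into clusters in the plasma membrane
during the first minutes of T-cell receptor triggering.

The package implements the full analysis chain such a study needs, each
stage testable against synthetic ground truth it generates itself:

* **Tracking** (`latkit.tracking`) — TIRF movie spot detection (cell
  mask → Gaussian smoothing → top-hat enhancement → 2× membrane-mean
  rule) and greedy overlap linking with a 3-pixel gate and no gap
  closing; MSD-based diffusion coefficients and the long-lived /
  immobile / late-start trajectory filter with 20-frame back-extension.
* **Step fitting** (`latkit.stepfit`) — single-fluorophore calibration
  from single-step photobleaching (mCherry: 111 ± 40 camera counts) and
  equal-step staircase decomposition of assembly intensity traces:
  penalized changepoint segmentation quantized onto the lattice
  `baseline + k·s`, with the per-trace step size `s` searched over the
  calibration range.  Multi-molecule jumps ("missing steps") are allowed.
* **kICS** (`latkit.kics`) — k-space image correlation spectroscopy.
  The circularly averaged, zero-lag-normalized correlation
  `R(k², τ)` of a movie is fitted per lag with
  `a_f·exp(−k²·s_f) + a_c·exp(−k²·s_c)`; the early-lag slopes of the
  decay scales give `D_free` and `D_confined` (via `s = D·τ`), the
  late-lag confined plateau gives a confinement length
  `2·√(mean s_c)`, and the amplitude ratio `a_f/a_c` measures the
  free-vs-confined population balance.  The excluded DC bin makes all
  of this immune to spatially uniform fluctuations such as vesicles
  crossing the TIRF field.
* **Clustering** (`latkit.clustering`) — blink merging (localizations
  within 100 nm and 50 frames collapse into one molecule), DBSCAN
  (≥ 3 neighbours in 20 nm, clusters of ≥ 10 molecules) and per-ROI
  cluster statistics (percent in clusters, hull area, density,
  circularity).
* **DoC** (`latkit.doc`) — per-molecule degree of colocalization of two
  SMLM channels: rank correlation of the channels' radial density
  gradients over 10–500 nm, in [−1, 1]; molecules with DoC ≥ 0.4 are
  "signalling", clusters with ≥ 10 such molecules are signalling
  clusters.
* **TCCF** (`latkit.tccf`) — temporal cross-correlation event ordering
  for two-colour cluster traces: ΔCC(τ) = forward − backward
  cross-correlation, whose cumulative sum over the first 50 lags is
  positive when channel 2 is recruited after channel 1.
* **Synthetic data** (`latkit.synthdata`) — ground-truth generators for
  every input: two-population membrane diffusion movies with reflecting
  circular domains, birth–death assembly traces, Neyman–Scott
  two-channel point patterns with blinking, and lagged trace pairs.
* **Pipeline** (`latkit.pipeline`, CLI `latkit`) — YAML-configured
  orchestration of all stages, including a synthetic
  activating-vs-resting two-condition comparison.

## Worked example

Fit a staircase to a simulated assembly trace (molecules arriving at
0.1 /s for 60 s, readout noise SD 20 counts) using the single-mCherry
calibration:

```python
from latkit.synthdata import AssemblyTraceConfig, simulate_assembly_trace
from latkit.stepfit import FluorophoreCalibration, fit_steps

cfg = AssemblyTraceConfig(arrival_rate=0.1, departure_rate=0.0, noise_sd=20.0,
                          n_frames=300, brightness_mode="per_trace", seed=12)
trace, truth = simulate_assembly_trace(cfg)
calib = FluorophoreCalibration(mean_intensity=111.0, sd_intensity=40.0,
                               n_molecules=200)
fit = fit_steps(trace, calib)
print(f"fitted step size : {fit.step_size:.1f} counts")
print(f"join events      : {fit.step_times}")
print(f"molecules joined : {fit.joins}, left: {fit.leaves}")
```

prints

```
fitted step size : 110.8 counts
join events      : [(144, 1), (177, 1), (181, 1), (193, 1), (205, 1), (255, 1), (263, 1), (267, 1)]
molecules joined : 8, left: 0
```

i.e. the trace decomposes into eight single-molecule joining events with
a fitted single-fluorophore intensity of 110.8 counts — here matching
the simulation exactly (true arrivals at frames 144, 177, 181, 193,
205, 255, 263, 267; true unit 110.7 counts).

The full synthetic pipeline runs from the shell:

```
latkit run --out myrun --seed 1       # all stages
latkit kics --out myrun2 --seed 1     # one stage (simulating its inputs)
```

Each run directory is self-describing (`resolved_config.yaml`,
`summary.json`, per-stage outputs).

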