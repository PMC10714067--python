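# sealforage

Fine-scale foraging analysis for head-mounted sonar/motion biologging tags
on diving marine predators, built around the deployment design used for
lactating Weddell seals (*Leptonychotes weddellii*) on the Antarctic fast
ice: a head-mounted micro-sonar (25 Hz pings, 7 m range) recording
alongside triaxial acceleration (200–250 Hz), magnetometry and pressure
(50 Hz) and GPS surface fixes.

The package is a library: you import it, feed it multi-rate tag streams
(or generate fully labelled synthetic ones), and it returns tables. It
implements the complete analysis chain:

- **Prey-capture-attempt (PrCA) detection** — the jerk is
  `j[k] = fs · ‖a[k+1] − a[k]‖₂` (m/s³); a centered sliding RMS of `j` is
  thresholded at 150 m/s³, supra-threshold runs separated by gaps < 5 s
  are merged, merged events shorter than 5 s are dropped, and each event
  is tied to its dive and depth. A survival curve of inter-event gaps
  reports a data-driven merge threshold for inspection.
- **Echogram prey characterization** — echo-to-noise-ratio (ENR) images
  in ±5 s windows around each PrCA: seafloor-ridge detection (benthic
  flag), 8-connected prey-trace extraction with seafloor masking,
  single-vs-school counting, reaction classification (*leaving the
  seafloor*: straight negative-slope departure from the ridge;
  *escaping*: curved range-down-then-up trace clear of the floor),
  reaction onset time/distance, and acoustic size (median per-ping
  supra-threshold pixel extent × bin width).
- **Dive-shape clustering** — profiles normalized in time and z-scored in
  depth, smoothed on a cubic B-spline basis, decomposed by functional PCA;
  the leading scores are clustered with Gaussian mixtures (covariance
  family and K selected by BIC), and dives are assigned only when the
  maximum posterior reaches 80 %.
- **Approach behavior** — tilt-compensated pitch/roll/heading,
  dead-reckoned local tracks, band-passed (0.4–2.5 Hz) flipper-stroke
  detection and ±1 s head-turn classification around prey reactions,
  summarized per reaction type.
- **Synthetic deployments** — a first-class generator
  (`sealforage.simulate`) that emulates all of the above with known
  ground truth: five dive archetypes, bimodal RMS-jerk, parameterized prey
  traces and scripted approach behavior, so every stage is testable
  without field data.

## Worked example

```python
from sealforage import SimulationConfig
from sealforage.pipeline import run_pipeline
from sealforage.simulate import simulate_deployment

cfg = SimulationConfig(seed=1)                 # 3 individuals, 107 dives
bundles, truth = simulate_deployment(cfg)
res = run_pipeline(bundles, truth=truth, config=cfg)
print(res.reports["deployment_summary"])
```

prints (abridged):

```
individual  n_dives  n_prcas  n_dives_with_prcas  pct_dives_with_prcas  prca_depth_mean_m  pct_benthic  pct_prey_traces
      ind1       46       38                   8                 17.39              88.25         97.0             37.0
      ind2       21        1                   1                  4.76             106.23        100.0              0.0
      ind3       40        3                   2                  5.00              94.26        100.0             33.0
     total      107       42                  11                 10.28              89.11         98.0             36.0
```

All 42 injected capture attempts are recovered; their pooled mean depth
(89.1 m) sits on the configured 88 ± 30 m distribution; 98 % of echograms
show the seafloor and 36 % a prey trace, matching the scheduled rates.
Every percentage cell is an exact ratio of the count cells beside it.

The `examples/` directory holds one short script per capability
(simulation, detection, echograms, clustering, approach behavior, full
report). A thin CLI wraps the two end-to-end steps:

```bash
sealforage simulate --seed 1 --out dep/
sealforage run --data dep/ --out results/
```

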