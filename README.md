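# smtrack

Simulation and analysis of live-cell single-molecule tracking, focused on a
bias that affects diffusive-state quantification: **inadvertent trajectory
splitting**. When a mobile, fluorophore-labeled molecule blurs during the
camera exposure, intermittently drops below the detection threshold, or
out-runs the tracker's gate radius, one true molecule path fragments into many
short tracks. Because every track contributes one diffusion-coefficient
measurement to mean-squared-displacement (MSD) analysis, mobile molecules get
overcounted and the immobile (e.g. DNA-bound) state occupancy is
underestimated. The effect is amplified for photostable dyes (JFX650-like),
whose molecules stay visible for thousands of frames, relative to
photoswitching dyes (TMR-like), whose blinking cuts all tracks short
regardless of mobility.

The package provides, as importable library + numbered analysis drivers:

* **`smtrack.simulate`** — molecules diffusing by a K-state Brownian model in
  2D spherocylindrical (E. coli-like) cell footprints, switching states by a
  per-frame Markov chain; three-level photophysics (on / dark / bleached);
  motion-blur centroiding by sub-frame averaging; Gaussian localization error;
  displacement-dependent missed detections
  `p_detect = p0 · exp(−(d/d_c)²)`.
* **`smtrack.linking`** — gated trajectory linking (distance < 8 px, same
  cell, one-frame memory) with optimal per-frame-pair assignment, faithfully
  reproducing the splitting behaviour of real pipelines.
* **`smtrack.msd`** — per-track apparent diffusion coefficients from the first
  4 frame-to-frame steps, `D_app = Σdᵢ² / (4·Σlagᵢ·Δt)`; for Brownian motion
  the n-step estimator follows a Gamma law

  `f(x) = (n/D)ⁿ xⁿ⁻¹ e^(−n·x/D) / Γ(n)`  (shape n, mean D),

  so populations are fitted by maximum-likelihood Gamma mixtures with
  optionally fixed component means; **forced computational partitioning**
  (cutting every track into 5-localization windows) as the bias correction.
* **`smtrack.hmm`** — a displacement hidden Markov model (zero-mean isotropic
  2D Gaussian steps with per-axis variance 2·D·Δt), fitted by Baum–Welch with
  seeded restarts and BIC model selection over K; stationary occupancies from
  the fitted transition matrix; Viterbi state paths.
* **`smtrack.report`** — the four-way estimator comparison
  (naive MSD / partitioned MSD / HMM / partitioned HMM) across independent
  simulated repeats, with trajectory-count-weighted means, SEMs, splitting
  factors, duration-by-mobility statistics and Welch tests.

## Worked example

```python
import smtrack as st

cfg = st.jfx650_like_config(n_cells=30)        # photostable-dye world
report = st.bias_experiment(cfg, n_repeats=6, seed=5)
```

Output of `python analysis/05_bias_experiment.py` (the same computation):

```
ground-truth occupancies (immobile/slow/fast): [0.345 0.145 0.51 ]
msd_naive        [0.175 0.337 0.488] (sem [0.008 0.011 0.018])
msd_partitioned  [0.526 0.262 0.212] (sem [0.021 0.011 0.012])
hmm              [0.8   0.153 0.046] (sem [0.018 0.015 0.004])
hmm_partitioned  [0.851 0.11  0.038] (sem [0.028 0.023 0.005])
splitting factor by true mobility: {'immobile': 2.45, 'mobile': 9.20}
duration by apparent mobility: immobile 38.8 frames, mobile 24.4 frames
ordering check: naive 0.175 < partitioned 0.526; truth 0.345; hmm 0.800
```

Reading this: mobile emitting intervals fragment into ~9 tracks each versus
~2.5 for immobile ones, so naive MSD counting underestimates the immobile
occupancy (0.175 vs the true 0.345). Forced partitioning, which cuts tracks
blindly to mobility, restores the immobile weight (0.526) and moves the MSD
result toward the HMM estimate; the HMM itself barely changes under
partitioning (0.80 vs 0.85, Welch p ≈ 0.17). Under this simulator's strong
motion-blur dropout the HMM overshoots the immobile occupancy, because missed
detections censor mobile displacements — see the methods note.

The analysis drivers run in order:

```
python analysis/01_photophysics.py      # switching vs photostable kinetics
python analysis/02_link_and_split.py    # splitting factors, durations
python analysis/03_msd_mixture.py       # Gamma-mixture fits, naive vs partitioned
python analysis/04_hmm_selection.py     # BIC scan over 2-6 states
python analysis/05_bias_experiment.py   # the four-way comparison
```

each writing tables/JSON under `results/`. A thin CLI wraps the same
functions: `smtrack simulate|link|msd|hmm|bias-experiment --help`.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch — simulates a photostable-dye
experiment (3 repeats), links localizations, runs all four occupancy
estimators, prints the occupancy table and splitting factors, and writes the
JSON result file (with a `*_detail.json` companion holding the complete
report).
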