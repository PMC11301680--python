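# Methods

## The problem being modeled

In live-cell single-molecule tracking, a protein such as a DNA-repair
factor alternates between diffusive states — immobile (bound), slowly
diffusing, and fast-diffusing — and the quantity of biological interest
is the occupancy of each state together with its diffusion coefficient.
Two standard estimators exist: (i) per-track apparent diffusion
coefficients pooled into a histogram and fitted with a mixture, and
(ii) a hidden Markov model (HMM) on frame-to-frame displacements.
The package simulates the full measurement chain so that the systematic
differences between these estimators — in particular the mobile-state
overcounting caused by inadvertent trajectory splitting — can be
demonstrated, measured against ground truth, and corrected.

## Simulation model

**Motion.** Each molecule carries a hidden state from a K-state
per-frame Markov chain (state changes at frame boundaries only; D is
constant within a frame). Within a frame, motion is Brownian: the
30 ms exposure is divided into `n_substeps` (default 10) Gaussian
sub-steps with per-axis s.d. `sqrt(2·D·dt_sub)`, followed by one
sub-step for the 0.475 ms camera dead time (Gaussian increments
compose, so one step is exact up to boundary-reflection resolution).
Positions reflect off the spherocylindrical cell footprint by radial
mirroring about the boundary — the simple scheme that preserves the
uniform equilibrium distribution for small steps. Confinement in a
~1 µm-wide cell makes fast-state motion sub-Brownian, exactly as in
rod-shaped bacteria; axial (z) motion is not modeled because a thin
cell keeps molecules near focus.

**Recorded position.** The motion-blur centroid: the mean of the
within-exposure sub-step positions. With `n_substeps = 1` the recorded
positions are stroboscopic samples and the classical `MSD = 4·D·Δt`
holds exactly (verified against a closed-form linear-combination oracle
in the tests); with full-frame exposure the averaging attenuates the
apparent D by roughly `1 − t_exp/(3Δt) ≈ 0.67` and anti-correlates
consecutive displacements.

**Photophysics.** Three levels: on, dark (reversible), bleached
(absorbing, reachable only from on). The state is recorded then
updated each frame, so a dye bleaching with per-frame probability q
emits for Geometric(q) frames (mean 1/q). Two presets bracket the
regimes of interest:

| preset | p_bleach | p_off | p_on | molecules/cell |
|---|---|---|---|---|
| TMR-like (switching) | 0.01 | 0.05 | 5·10⁻⁴ | 200 |
| JFX650-like (photostable) | 0.01 | 0 | 0 | 5 |

These rates are stand-ins chosen to reproduce the qualitative kinetics
(fast initial decay to a sparse blinking plateau vs stepwise
irreversible loss with no reactivation) — no measured photophysical
constants are represented. The 10-fold-reduced labeling density of the
photostable preset mirrors the experimental need for sparse emitters.

**Detection.** A frame of an emitting molecule yields a localization
with probability `p_detect_base · exp(−(d/d_c)²)`, where d is the net
within-exposure travel; defaults `p_detect_base = 0.995`,
`d_c = 0.4 µm`. The law is an invented parameterization of a real
mechanism (motion blur dims the spot below threshold); only its
monotone-decreasing shape matters for the bias. Reported positions are
the blur centroids plus isotropic Gaussian noise (σ = 0.035 µm per
axis by default, a typical tracking precision; not a measured value).
Camera images are never formed; the localization step is modeled
directly at the coordinate level.

**Ground truth world.** The default three-state model uses
D = (0.04, 0.21, 0.99) µm²/s with occupancies (0.35, 0.15, 0.50) and a
transition matrix `s·I + (1−s)·1πᵀ` whose stationary distribution is
exactly π for any stickiness s. The default s = 0.985 gives dwell times
of order 100 frames (a few seconds), matching the rarity of binding /
unbinding transitions for chromosome-associated proteins; the idealized
HMM-recovery world uses s = 0.9 so that a 25 000-step sample contains
enough transitions to constrain the chain. One root seed is split into
named child streams (cells, photophysics, states, motion, detection),
so every stage is independently reproducible and output tables are
bit-identical across runs.

## Linking

Localizations in the same cell are linked frame-to-frame when their
distance is strictly below `gate = 8 px × 0.1 µm/px`; a one-frame
memory lets a track bridge one missed frame under the same absolute
gate. Within each frame pair, assignment is optimal one-to-one
matching: maximum number of gated links first, minimum total squared
displacement among those (an empty matching trivially minimizes cost,
so maximal cardinality is the only coherent reading). Direct unit-lag
matches are resolved before memory candidates compete. The
implementation (scipy `linear_sum_assignment` with a large-cost
padding) is verified against exhaustive enumeration of all feasible
matchings on small instances. Determinism comes from canonical
processing order (cell, frame, x, y).

## MSD / Gamma-mixture estimator

`D_app = Σdᵢ²/(4·Σlagᵢ·Δt)` over the first 4 observed steps of each
track (5 localizations); a bridged gap contributes its true lag of 2,
keeping the estimator unbiased across gaps. Tracks with fewer than 5
localizations are excluded and counted. For ideal Brownian motion
D_app is Gamma-distributed with shape n = 4 and mean D, so the
population is fitted with a K-component Gamma mixture by EM on the raw
values (maximum likelihood; fitting the histogram would add binning
artifacts — a deliberate departure from fitting binned counts,
statistically equivalent in the large-sample limit). Components may be
declared fixed: they keep their D and update only their weight,
mirroring the practice of pinning the immobile and slow states to
HMM-derived values. Exact zeros are clamped to 10⁻⁶ µm²/s before
likelihood evaluation. Multi-start EM (quantile-based then seeded
random initialization) guards against local optima; the likelihood is
asserted non-decreasing.

D_app is *apparent* throughout: localization noise adds ≈ σ²/Δt
(0.040 µm²/s at defaults — as large as the immobile-state D itself)
and blur attenuates the true-motion part; no correction is applied,
matching common practice.

**Forced computational partitioning** cuts every trajectory into
consecutive non-overlapping 5-localization windows (trailing remainder
discarded), blind to mobility, so fragmentation affects mobile and
immobile molecules equally; each window then contributes one D_app.

**Mobility classification** uses D_app ≤ 0.04 µm²/s ⇒ immobile
(boundary assigned to immobile). A left-aligned rolling-window variant
of the estimator (`rolling_D`) serves to visualize state switches along
individual long tracks.

## Displacement HMM

Emissions are zero-mean isotropic 2D Gaussians with per-axis variance
`2·D_k·Δt` (optionally + 2σ² for localization error; off by default,
as displacement-HMM tools conventionally do). Fitting is
maximum-likelihood Baum–Welch over all gap-free segments jointly —
memory-bridged tracks are split upstream rather than modeling lag-2
emissions. Implementation details: scaled forward–backward with
per-step max-shifted emissions (robust to extreme likelihood ratios);
segments sorted by length so recursions run on contiguous active
slices (cost ∝ total steps); per-iteration assertion of likelihood
monotonicity; D floored at 10⁻⁶ µm²/s; 10 restarts with log-uniform D
in [10⁻³, 10] µm²/s and sticky (0.9-diagonal) transition
initialization, seeds derived from the root seed; states relabeled
ascending by D. Model selection minimizes
`BIC = −2·logL + p·ln(n_steps)`, `p = K + K(K−1) + (K−1)`, ties to the
smaller K. The headline occupancy is the stationary distribution of
the fitted transition matrix (unique left eigenvector at eigenvalue 1;
reducible chains raise an error); posterior step fractions are
reported alongside. An independent implementation (hmmlearn) is used
in the tests to cross-check the likelihood under fixed parameters —
never as the estimator.

This EM + BIC machinery deliberately stands in for variational-Bayes
trackers; equivalence is asserted only at the level of recovered
parameters on synthetic data, which is how it is used here.

## The bias experiment

Per repeat (independent seed = independent imaging session):
simulate → link → four estimators. The Gamma mixtures fix the immobile
and slow component means at the same repeat's HMM estimates — the
HMM's apparent D already contains the noise and blur offsets, so this
reproduces the workflow of using HMM insight to anchor the MSD fit.
Ground truth is the realized fraction of molecule-frames per state.
Summaries are trajectory-count-weighted means across repeats with the
plain SEM; method pairs are compared descriptively with Welch's
two-sample test on the immobile occupancy. The splitting factor counts
distinct track ids per contiguous emitting interval, classified by the
interval's time-averaged true D; intervals with no detections are
dropped (they produce no track).

## What a green test does and does not establish

The generator emulates the statistical structure the estimators
assume — multi-state Brownian confinement, blinking, blur, dropout —
not real microscopy: no camera noise or PSF, no z-dimension, no cell
segmentation errors, no dye photochemistry beyond three levels, and
invented (if plausible) photophysics, noise and dropout constants.
Green tests therefore establish internal statistical correctness of
the estimators and the directionality of the splitting bias; they do
not validate absolute occupancies for any real dye or protein.

## Known limitations

* **Dropout censoring biases the HMM too.** With the default dropout
  law, fast-state frames are detected ~2× less often than immobile
  ones, so the steps the HMM sees over-represent immobile molecules
  and its occupancy overshoots the truth (≈ 0.80 vs 0.345 in the
  worked example). The pipeline's orderings (naive < partitioned,
  partitioned closer to HMM) are unaffected, but "HMM ≈ truth" holds
  only when detection is mobility-independent.
* **The no-splitting ablation does not make all estimators unbiased.**
  With detection perfect, the gate permissive, and bleaching off, the
  splitting mechanism is gone, yet (i) the Gamma(4) mixture still
  misallocates ~0.05 of immobile weight because localization noise
  (σ²/Δt ≈ immobile D) and blur reshape the apparent-D distribution
  away from the Gamma law, and (ii) the stationary distribution of a
  sticky transition matrix estimated from 4-step windows is
  ill-conditioned, leaving the partitioned HMM ~0.04 off with high
  repeat-to-repeat variance. The corresponding acceptance checks
  assert the stricter property and are left failing by design; only
  the intact HMM meets the 0.03 tolerance.
* Model selection on realistic (confined, noisy, censored) movies can
  prefer an extra state that absorbs imaging artifacts; the three-state
  selection result holds on idealized data.
* Runtime-driven scale-downs: bias experiments use 30 cells and 3–6
  repeats; ablation movies are 1500 frames. All sizes are configurable.
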