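"""Ground-truth simulator for live-cell single-molecule tracking movies.

Molecules diffuse by multi-state Brownian motion confined to 2D
spherocylindrical cell footprints, switch diffusive state by a per-frame
Markov chain, emit according to a three-level photophysics scheme
(on / dark / bleached), and are observed through motion-blur centroiding,
Gaussian localization error and displacement-dependent missed detections.

The observation model works at the localization level: camera images are
never rendered.  Each frame of each emitting molecule yields at most one
localization, positioned at the exposure-averaged (motion-blur centroid)
true position plus isotropic Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AcquisitionConfig,
    CellGeometry,
    DetectionModel,
    DiffusionModel,
    PhotophysicsModel,
    SimulationConfig,
    ValidationError,
)

__all__ = [
    "MotionResult",
    "SimulationOutput",
    "simulate_state_path",
    "simulate_state_paths",
    "simulate_motion",
    "apply_photophysics",
    "observe",
    "simulate_cell_population",
    "emitting_fraction_timeseries",
]

LOCALIZATION_COLUMNS = ["frame", "x_um", "y_um", "cell_id", "molecule_id"]
GROUND_TRUTH_COLUMNS = [
    "molecule_id", "frame", "state", "true_x_um", "true_y_um",
    "emitting", "detected", "cell_id",
]
CELL_COLUMNS = ["cell_id", "center_x_um", "center_y_um", "length_um", "diameter_um", "orientation_rad"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# hidden-state process


def simulate_state_paths(
    model: DiffusionModel, n_frames: int, n_molecules: int, rng_seed
) -> np.ndarray:
    """Sample ``n_molecules`` independent Markov state paths, shape (M, T)."""
    rng = _as_rng(rng_seed)
    k = model.n_states
    states = np.empty((n_molecules, n_frames), dtype=np.int64)
    cum_init = np.cumsum(model.initial_occupancy)
    cum_T = np.cumsum(model.transition_matrix, axis=1)
    states[:, 0] = np.searchsorted(cum_init, rng.random(n_molecules), side="right").clip(max=k - 1)
    for t in range(1, n_frames):
        u = rng.random(n_molecules)
        rows = cum_T[states[:, t - 1]]
        states[:, t] = (u[:, None] >= rows).sum(axis=1).clip(max=k - 1)
    return states


def simulate_state_path(model: DiffusionModel, n_frames: int, rng_seed) -> np.ndarray:
    """Single Markov state path of length ``n_frames``."""
    return simulate_state_paths(model, n_frames, 1, rng_seed)[0]


# ---------------------------------------------------------------------------
# Brownian motion with reflecting spherocylinder boundary


@dataclass
class MotionResult:
    """True positions per frame (local or lab frame of the caller).

    ``average_um`` is the motion-blur centroid: the mean of the
    within-exposure sub-step positions.  ``exposure_start_um`` and
    ``exposure_end_um`` delimit the net within-exposure travel used by
    the detection model.
    """

    average_um: np.ndarray        # (..., T, 2)
    exposure_start_um: np.ndarray  # (..., T, 2)
    exposure_end_um: np.ndarray    # (..., T, 2)

    @property
    def within_frame_travel_um(self) -> np.ndarray:
        d = self.exposure_end_um - self.exposure_start_um
        return np.hypot(d[..., 0], d[..., 1])


def _reflect_into(pos: np.ndarray, a: np.ndarray, r: np.ndarray, max_iter: int = 64) -> None:
    """Reflect points into spherocylinders (axis half-length a, radius r),
    in place, local coordinates.  Radial mirroring about the boundary."""
    for _ in range(max_iter):
        cx = np.clip(pos[:, 0], -a, a)
        vx = pos[:, 0] - cx
        vy = pos[:, 1]
        d = np.hypot(vx, vy)
        out = d > r
        if not out.any():
            return
        scale = (2.0 * r[out] - d[out]) / d[out]
        pos[out, 0] = cx[out] + vx[out] * scale
        pos[out, 1] = vy[out] * scale
    # pathological step >> cell size: clamp onto the boundary
    cx = np.clip(pos[:, 0], -a, a)
    vx = pos[:, 0] - cx
    vy = pos[:, 1]
    d = np.hypot(vx, vy)
    out = d > r
    scale = r[out] / d[out]
    pos[out, 0] = cx[out] + vx[out] * scale
    pos[out, 1] = vy[out] * scale


def _sample_uniform_in_cells(a: np.ndarray, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform start points in each molecule's footprint (rejection sampling)."""
    m = a.size
    pos = np.empty((m, 2))
    pending = np.arange(m)
    while pending.size:
        u = rng.uniform(-1.0, 1.0, size=(pending.size, 2))
        cand = np.column_stack([u[:, 0] * (a[pending] + r[pending]), u[:, 1] * r[pending]])
        cx = np.clip(cand[:, 0], -a[pending], a[pending])
        ok = np.hypot(cand[:, 0] - cx, cand[:, 1]) <= r[pending]
        pos[pending[ok]] = cand[ok]
        pending = pending[~ok]
    return pos


def _simulate_motion_batch(
    states: np.ndarray,
    D_um2s: np.ndarray,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
    a: np.ndarray | None,
    r: np.ndarray | None,
    start_um: np.ndarray | None = None,
) -> MotionResult:
    """Batch Brownian bridge over frames for M molecules, local coordinates.

    ``a``/``r`` are per-molecule spherocylinder parameters; ``None`` means
    unconfined motion started at the origin (or ``start_um``).
    """
    m, n_frames = states.shape
    D_um2s = np.asarray(D_um2s, dtype=float)
    confined = a is not None
    if confined:
        a = np.broadcast_to(np.asarray(a, dtype=float), (m,)).copy()
        r = np.broadcast_to(np.asarray(r, dtype=float), (m,)).copy()
        if np.any(r <= 0):
            raise ValidationError("zero-area cell geometry")

    if start_um is not None:
        pos = np.array(start_um, dtype=float).reshape(m, 2).copy()
    elif confined:
        pos = _sample_uniform_in_cells(a, r, rng)
    else:
        pos = np.zeros((m, 2))

    nsub = acq.n_substeps
    dt_sub = acq.exposure_s / nsub
    dt_dead = acq.frame_interval_s - acq.exposure_s

    avg = np.empty((m, n_frames, 2))
    start_e = np.empty((m, n_frames, 2))
    end_e = np.empty((m, n_frames, 2))
    for t in range(n_frames):
        D_t = D_um2s[states[:, t]]
        sd = np.sqrt(2.0 * D_t * dt_sub)[:, None]
        start_e[:, t] = pos
        acc = np.zeros((m, 2))
        for _ in range(nsub):
            pos = pos + rng.standard_normal((m, 2)) * sd
            if confined:
                _reflect_into(pos, a, r)
            acc += pos
        avg[:, t] = acc / nsub
        end_e[:, t] = pos
        if dt_dead > 0:
            sd_dead = np.sqrt(2.0 * D_t * dt_dead)[:, None]
            pos = pos + rng.standard_normal((m, 2)) * sd_dead
            if confined:
                _reflect_into(pos, a, r)
    return MotionResult(avg, start_e, end_e)


def simulate_motion(
    states: np.ndarray,
    geometry: CellGeometry | None,
    D_um2s,
    acq: AcquisitionConfig,
    rng_seed,
    start_um: np.ndarray | None = None,
) -> MotionResult:
    """Simulate one molecule's true path given its per-frame state sequence.

    Returns exposure-averaged (motion-blur centroid) positions and the
    exposure endpoints, in the *local* frame of ``geometry`` (or in an
    unconfined plane when ``geometry is None``).
    """
    states = np.asarray(states, dtype=np.int64)[None, :]
    rng = _as_rng(rng_seed)
    if geometry is None:
        a = r = None
    else:
        a = np.array([geometry.axis_half_length_um])
        r = np.array([geometry.radius_um])
    start = None if start_um is None else np.asarray(start_um, dtype=float)[None, :]
    res = _simulate_motion_batch(states, np.asarray(D_um2s, float), acq, rng, a, r, start)
    return MotionResult(res.average_um[0], res.exposure_start_um[0], res.exposure_end_um[0])


def simulate_displacement_segments(
    model: DiffusionModel,
    n_segments: int,
    n_steps: int,
    frame_interval_s: float = 0.030475,
    rng_seed=0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Unconfined, noise-free frame-to-frame displacement segments.

    Draws one hidden state path per segment (initial state from the
    model's initial occupancy) and emits Gaussian displacements with
    per-axis s.d. sqrt(2 * D(state) * dt).  Returns (segments, states)
    where segments is a list of (n_steps, 2) arrays and states the
    (n_segments, n_steps) hidden path.  This is the idealized world in
    which the apparent-D estimator is exactly Gamma and the HMM emission
    model is exact.
    """
    rng = _as_rng(rng_seed)
    states = simulate_state_paths(model, n_steps, n_segments, rng)
    sd = np.sqrt(2.0 * model.D_um2s[states] * frame_interval_s)
    disp = rng.standard_normal((n_segments, n_steps, 2)) * sd[:, :, None]
    return [disp[i] for i in range(n_segments)], states


# ---------------------------------------------------------------------------
# photophysics

_ON, _DARK, _BLEACHED = 0, 1, 2


def apply_photophysics(
    model: PhotophysicsModel, n_frames: int, rng_seed, n_molecules: int | None = None
) -> np.ndarray:
    """Per-frame emitting flags; shape (T,) or (M, T) for a batch.

    The photophysical state is recorded at the start of each frame and
    then updated, so a molecule that starts on and bleaches with
    per-frame probability q emits for Geometric(q) frames (mean 1/q).
    """
    rng = _as_rng(rng_seed)
    m = 1 if n_molecules is None else n_molecules
    state = np.where(rng.random(m) < model.initial_on_fraction, _ON, _DARK)
    emitting = np.zeros((m, n_frames), dtype=bool)
    p_b, p_off, p_on = model.p_bleach_per_frame, model.p_off_per_frame, model.p_on_per_frame
    for t in range(n_frames):
        on = state == _ON
        emitting[:, t] = on
        u = rng.random(m)
        dark = state == _DARK
        state = state.copy()
        state[on & (u < p_b)] = _BLEACHED
        state[on & (u >= p_b) & (u < p_b + p_off)] = _DARK
        state[dark & (u < p_on)] = _ON
    return emitting[0] if n_molecules is None else emitting


# ---------------------------------------------------------------------------
# observation


def observe(
    average_um: np.ndarray,
    within_frame_travel_um: np.ndarray,
    emitting: np.ndarray,
    det: DetectionModel,
    rng_seed,
):
    """Detection and localization-noise model.

    A frame yields a localization iff the molecule is emitting and a
    Bernoulli draw with ``p = p_detect_base * exp(-(d/blur_scale)**2)``
    succeeds, where d is the net within-exposure travel.  Reported
    positions are the motion-blur centroids plus Gaussian noise.

    Returns ``(detected, reported_um)`` with the same leading shape as the
    inputs; ``reported_um`` is defined (noisy) for every frame, meaningful
    only where ``detected``.
    """
    rng = _as_rng(rng_seed)
    average_um = np.asarray(average_um, dtype=float)
    d = np.asarray(within_frame_travel_um, dtype=float)
    emitting = np.asarray(emitting, dtype=bool)
    with np.errstate(under="ignore"):
        p = det.p_detect_base * np.exp(-np.square(d / det.blur_scale_um))
    detected = emitting & (rng.random(d.shape) < p)
    noise = rng.standard_normal(average_um.shape) * det.localization_sigma_um
    return detected, average_um + noise


# ---------------------------------------------------------------------------
# full population


@dataclass
class SimulationOutput:
    """Observed localizations plus the ground truth that produced them."""

    localizations: pd.DataFrame
    ground_truth: pd.DataFrame
    cells: pd.DataFrame
    config: SimulationConfig
    n_frames_simulated: int

    @property
    def cell_geometries(self) -> list[CellGeometry]:
        return [
            CellGeometry(
                length_um=row.length_um,
                diameter_um=row.diameter_um,
                center=(row.center_x_um, row.center_y_um),
                orientation_rad=row.orientation_rad,
            )
            for row in self.cells.itertuples()
        ]


def _empty_output(config: SimulationConfig, cells: pd.DataFrame) -> SimulationOutput:
    locs = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        LOCALIZATION_COLUMNS, [np.int64, float, float, np.int64, np.int64])})
    gt = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        GROUND_TRUTH_COLUMNS, [np.int64, np.int64, np.int64, float, float, bool, bool, np.int64])})
    return SimulationOutput(locs, gt, cells, config, 0)


def simulate_cell_population(config: SimulationConfig, rng_seed) -> SimulationOutput:
    """Simulate a full movie of many cells, returning localization and
    ground-truth tables.

    Deterministic given the seed: the root seed is split into five named
    child streams (cells, photophysics, states, motion, detection) so each
    stage is independently reproducible.  Motion is only simulated up to
    the last frame in which any molecule still emits; ground-truth rows
    are emitted for exactly those frames (``emitting`` would be False and
    positions unobservable beyond them).
    """
    if isinstance(rng_seed, np.random.SeedSequence):
        ss = rng_seed
    else:
        ss = np.random.SeedSequence(rng_seed)
    rng_cells, rng_photo, rng_states, rng_motion, rng_detect = map(
        np.random.default_rng, ss.spawn(5)
    )

    acq = config.acquisition
    n_cells, mpc = config.n_cells, config.molecules_per_cell
    m_total = n_cells * mpc

    lo, hi = config.cell_length_um_range
    lengths = rng_cells.uniform(lo, hi, size=n_cells)
    orientations = rng_cells.uniform(0.0, np.pi, size=n_cells)
    spacing = hi + 2.0 * config.cell_diameter_um
    centers = np.column_stack([np.arange(n_cells) * spacing, np.zeros(n_cells)])
    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells, dtype=np.int64),
        "center_x_um": centers[:, 0],
        "center_y_um": centers[:, 1],
        "length_um": lengths,
        "diameter_um": np.full(n_cells, config.cell_diameter_um),
        "orientation_rad": orientations,
    })
    if m_total == 0:
        return _empty_output(config, cells)

    emitting = apply_photophysics(config.photophysics, acq.n_frames, rng_photo, n_molecules=m_total)
    any_emitting = emitting.any(axis=0)
    if not any_emitting.any():
        return _empty_output(config, cells)
    t_sim = int(np.nonzero(any_emitting)[0][-1]) + 1
    emitting = emitting[:, :t_sim]

    states = simulate_state_paths(config.diffusion, t_sim, m_total, rng_states)

    cell_of_mol = np.repeat(np.arange(n_cells), mpc)
    a_mol = (lengths[cell_of_mol] - config.cell_diameter_um) / 2.0
    r_mol = np.full(m_total, config.cell_diameter_um / 2.0)
    motion = _simulate_motion_batch(
        states, config.diffusion.D_um2s, acq, rng_motion, a_mol, r_mol
    )

    # local -> lab frame per molecule
    cos_t = np.cos(orientations[cell_of_mol])[:, None]
    sin_t = np.sin(orientations[cell_of_mol])[:, None]
    lx, ly = motion.average_um[..., 0], motion.average_um[..., 1]
    true_x = lx * cos_t - ly * sin_t + centers[cell_of_mol, 0][:, None]
    true_y = lx * sin_t + ly * cos_t + centers[cell_of_mol, 1][:, None]
    true_lab = np.stack([true_x, true_y], axis=-1)

    detected, reported = observe(
        true_lab, motion.within_frame_travel_um, emitting, config.detection, rng_detect
    )

    mol_idx = np.repeat(np.arange(m_total), t_sim)
    frame_idx = np.tile(np.arange(t_sim), m_total)
    ground_truth = pd.DataFrame({
        "molecule_id": mol_idx,
        "frame": frame_idx,
        "state": states.ravel(),
        "true_x_um": true_x.ravel(),
        "true_y_um": true_y.ravel(),
        "emitting": emitting.ravel(),
        "detected": detected.ravel(),
        "cell_id": cell_of_mol[mol_idx],
    })

    det_mask = detected.ravel()
    localizations = pd.DataFrame({
        "frame": frame_idx[det_mask],
        "x_um": reported[..., 0].ravel()[det_mask],
        "y_um": reported[..., 1].ravel()[det_mask],
        "cell_id": cell_of_mol[mol_idx][det_mask],
        "molecule_id": mol_idx[det_mask],
    })
    localizations = localizations.sort_values(["frame", "cell_id", "x_um", "y_um"]).reset_index(drop=True)
    return SimulationOutput(localizations, ground_truth, cells, config, t_sim)


def emitting_fraction_timeseries(
    ground_truth: pd.DataFrame, n_frames: int | None = None
) -> pd.DataFrame:
    """Per-cell, per-frame counts of emitting molecules and detected
    localizations (tidy frame: cell_id, frame, n_emitting, n_detected).

    Frames beyond the simulated range (all molecules bleached) are padded
    with zero counts up to ``n_frames``.
    """
    if ground_truth.empty:
        cells = np.array([], dtype=np.int64)
    else:
        cells = np.sort(ground_truth["cell_id"].unique())
    t_max = int(n_frames) if n_frames is not None else (
        int(ground_truth["frame"].max()) + 1 if not ground_truth.empty else 0
    )
    frames = np.arange(t_max)
    out = []
    for cid in cells:
        sub = ground_truth[ground_truth["cell_id"] == cid]
        n_emit = np.zeros(t_max, dtype=np.int64)
        n_det = np.zeros(t_max, dtype=np.int64)
        e = sub.loc[sub["emitting"], "frame"].value_counts()
        d = sub.loc[sub["detected"], "frame"].value_counts()
        n_emit[e.index.to_numpy()] = e.to_numpy()
        n_det[d.index.to_numpy()] = d.to_numpy()
        out.append(pd.DataFrame({
            "cell_id": cid, "frame": frames, "n_emitting": n_emit, "n_detected": n_det,
        }))
    if not out:
        return pd.DataFrame({
            "cell_id": pd.Series(dtype=np.int64), "frame": pd.Series(dtype=np.int64),
            "n_emitting": pd.Series(dtype=np.int64), "n_detected": pd.Series(dtype=np.int64),
        })
    return pd.concat(out, ignore_index=True)
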