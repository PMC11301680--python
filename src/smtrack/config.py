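"""Configuration dataclasses for simulation and analysis.

All spatial quantities are lab-frame micrometers, all times seconds, and
frames are 0-based.  Every container validates its invariants at
construction so downstream code can assume well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "CellGeometry",
    "DiffusionModel",
    "PhotophysicsModel",
    "DetectionModel",
    "SimulationConfig",
    "three_state_model",
    "tmr_like_photophysics",
    "jfx650_like_photophysics",
    "tmr_like_config",
    "jfx650_like_config",
]


class ValidationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera timing for a tracking movie.

    The exposure occupies the first ``exposure_s`` of each frame interval;
    the remainder (default 0.475 ms) is dead time during which molecules
    keep moving but are not imaged.  ``n_substeps`` sub-frame motion steps
    are simulated within each exposure to produce motion-blur centroids.
    """

    frame_interval_s: float = 0.030475
    exposure_s: float = 0.030
    n_frames: int = 5000
    pixel_size_um: float = 0.1
    n_substeps: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.exposure_s <= self.frame_interval_s):
            raise ValidationError("require 0 < exposure_s <= frame_interval_s")
        if self.n_frames <= 0 or self.n_substeps < 1:
            raise ValidationError("n_frames and n_substeps must be positive")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")


@dataclass(frozen=True)
class CellGeometry:
    """2D spherocylindrical cell footprint (rectangle capped by half-discs).

    ``length_um`` is the end-to-end length including the caps; the
    cylindrical axis half-length is ``(length_um - diameter_um) / 2``.
    """

    length_um: float
    diameter_um: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)
    orientation_rad: float = 0.0

    def __post_init__(self) -> None:
        if not (self.length_um >= self.diameter_um > 0):
            raise ValidationError("require length_um >= diameter_um > 0")

    @property
    def axis_half_length_um(self) -> float:
        return 0.5 * (self.length_um - self.diameter_um)

    @property
    def radius_um(self) -> float:
        return 0.5 * self.diameter_um

    def to_local(self, points_um: np.ndarray) -> np.ndarray:
        """Lab-frame -> cell-local coordinates (long axis along x)."""
        p = np.asarray(points_um, dtype=float) - np.asarray(self.center)
        c, s = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        return p @ np.array([[c, -s], [s, c]])

    def to_lab(self, points_um: np.ndarray) -> np.ndarray:
        p = np.asarray(points_um, dtype=float)
        c, s = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        return p @ np.array([[c, s], [-s, c]]) + np.asarray(self.center)

    def contains(self, points_um: np.ndarray, tol_um: float = 0.0) -> np.ndarray:
        """Point-in-spherocylinder test in the lab frame."""
        local = np.atleast_2d(self.to_local(points_um))
        ax = np.clip(local[:, 0], -self.axis_half_length_um, self.axis_half_length_um)
        d = np.hypot(local[:, 0] - ax, local[:, 1])
        return d <= self.radius_um + tol_um


@dataclass
class DiffusionModel:
    """K-state diffusion model: per-state D plus a per-frame Markov chain."""

    D_um2s: np.ndarray
    transition_matrix: np.ndarray
    initial_occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.D_um2s = np.asarray(self.D_um2s, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.initial_occupancy = np.asarray(self.initial_occupancy, dtype=float)
        k = self.D_um2s.size
        if k < 1 or np.any(self.D_um2s < 0):
            raise ValidationError("need K >= 1 diffusion coefficients, all >= 0")
        if self.transition_matrix.shape != (k, k):
            raise ValidationError("transition matrix must be K x K")
        if np.any(self.transition_matrix < 0) or np.any(
            np.abs(self.transition_matrix.sum(axis=1) - 1.0) > 1e-12
        ):
            raise ValidationError("transition matrix rows must sum to 1")
        if self.initial_occupancy.shape != (k,) or np.any(self.initial_occupancy < 0):
            raise ValidationError("initial occupancy must be a length-K probability vector")
        if abs(self.initial_occupancy.sum() - 1.0) > 1e-12:
            raise ValidationError("initial occupancy must sum to 1")

    @property
    def n_states(self) -> int:
        return int(self.D_um2s.size)


@dataclass(frozen=True)
class PhotophysicsModel:
    """Three-level fluorophore scheme: on / dark (reversible) / bleached.

    Bleaching is irreversible and only reachable from the on state.
    A photostable, non-switching dye has both switching rates zero.
    """

    p_bleach_per_frame: float
    p_off_per_frame: float = 0.0
    p_on_per_frame: float = 0.0
    initial_on_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_bleach_per_frame", "p_off_per_frame", "p_on_per_frame", "initial_on_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.p_bleach_per_frame + self.p_off_per_frame > 1.0:
            raise ValidationError("p_bleach + p_off must not exceed 1")


@dataclass(frozen=True)
class DetectionModel:
    """Localization error and displacement-dependent missed detections.

    Detection probability for a frame with within-exposure travel d is
    ``p_detect_base * exp(-(d / blur_scale_um)**2)``: fast molecules blur
    across more pixels, dip below the detection threshold, and drop out.
    ``blur_scale_um = inf`` disables the dropout mechanism.
    """

    localization_sigma_um: float = 0.035
    p_detect_base: float = 0.995
    blur_scale_um: float = 0.4

    def __post_init__(self) -> None:
        if self.localization_sigma_um < 0:
            raise ValidationError("localization_sigma_um must be >= 0")
        if not (0.0 < self.p_detect_base <= 1.0):
            raise ValidationError("p_detect_base must lie in (0, 1]")
        if not self.blur_scale_um > 0:
            raise ValidationError("blur_scale_um must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full stated world for a multi-cell tracking movie."""

    acquisition: AcquisitionConfig
    diffusion: DiffusionModel
    photophysics: PhotophysicsModel
    detection: DetectionModel
    n_cells: int = 10
    molecules_per_cell: int = 5
    cell_length_um_range: tuple[float, float] = (2.0, 4.0)
    cell_diameter_um: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.cell_length_um_range
        if not (self.cell_diameter_um > 0 and lo >= self.cell_diameter_um and hi >= lo):
            raise ValidationError("cell length range must sit above the diameter")
        if self.n_cells < 0 or self.molecules_per_cell < 0:
            raise ValidationError("cell and molecule counts must be >= 0")


def three_state_model(
    D_um2s: Sequence[float] = (0.04, 0.21, 0.99),
    occupancy: Sequence[float] = (0.35, 0.15, 0.50),
    stickiness: float = 0.985,
) -> DiffusionModel:
    """Immobile / slow / fast three-state model.

    The transition matrix is ``s*I + (1-s)*1*pi^T`` which has stationary
    distribution exactly ``pi`` for any stickiness ``s``.  The default
    stickiness gives mean state dwell times of order 100 frames,
    i.e. rare transitions on the timescale of a fluorophore lifetime
    (DNA-repair proteins bind for many seconds, far longer than the
    ~30 ms frame time).
    """
    pi = np.asarray(occupancy, dtype=float)
    pi = pi / pi.sum()
    k = pi.size
    T = stickiness * np.eye(k) + (1.0 - stickiness) * np.tile(pi, (k, 1))
    T = T / T.sum(axis=1, keepdims=True)
    return DiffusionModel(np.asarray(D_um2s, dtype=float), T, pi)


def tmr_like_photophysics() -> PhotophysicsModel:
    """Reversibly photoswitching dye: rapid initial decay to a sparse,
    blinking steady state sustained by slow dark-state recovery."""
    return PhotophysicsModel(
        p_bleach_per_frame=0.01,
        p_off_per_frame=0.05,
        p_on_per_frame=5e-4,
        initial_on_fraction=1.0,
    )


def jfx650_like_photophysics() -> PhotophysicsModel:
    """Photostable dye: no reversible switching, slow irreversible
    bleaching; each molecule yields a single emitting interval."""
    return PhotophysicsModel(
        p_bleach_per_frame=0.01,
        p_off_per_frame=0.0,
        p_on_per_frame=0.0,
        initial_on_fraction=1.0,
    )


def _base_config(photophysics: PhotophysicsModel, default_mpc: int, **overrides) -> SimulationConfig:
    kwargs = dict(
        acquisition=AcquisitionConfig(),
        diffusion=three_state_model(),
        photophysics=photophysics,
        detection=DetectionModel(),
        n_cells=10,
        molecules_per_cell=default_mpc,
    )
    kwargs.update(overrides)  # overrides win, including molecules_per_cell
    return SimulationConfig(**kwargs)


def tmr_like_config(**overrides) -> SimulationConfig:
    """High labeling density: photoswitching keeps emitters sparse."""
    return _base_config(tmr_like_photophysics(), 200, **overrides)


def jfx650_like_config(**overrides) -> SimulationConfig:
    """10-fold reduced labeling density to keep photostable emitters sparse."""
    return _base_config(jfx650_like_photophysics(), 5, **overrides)


def ablation_config(n_frames: int = 1500, n_cells: int = 30, **overrides) -> SimulationConfig:
    """World with every splitting mechanism removed: perfect detection,
    no motion-blur dropout, no mid-movie bleaching.  Every molecule yields
    exactly one full-length track, so no estimator should show the
    mobile-overcounting bias (localization noise and blur centroiding
    remain active — they affect apparent D, not track counts)."""
    kwargs = dict(
        acquisition=AcquisitionConfig(n_frames=n_frames),
        photophysics=PhotophysicsModel(
            p_bleach_per_frame=0.0, p_off_per_frame=0.0, p_on_per_frame=0.0,
            initial_on_fraction=1.0,
        ),
        detection=DetectionModel(p_detect_base=1.0, blur_scale_um=math.inf),
        n_cells=n_cells,
    )
    kwargs.update(overrides)
    return _base_config(kwargs.pop("photophysics"), 5, **kwargs)
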