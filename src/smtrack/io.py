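"""CSV/JSON/YAML serialization with fixed table schemas."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import (
    AcquisitionConfig,
    DetectionModel,
    DiffusionModel,
    PhotophysicsModel,
    SimulationConfig,
)
from .simulate import SimulationOutput

LOCALIZATION_SCHEMA = ["frame", "x_um", "y_um", "cell_id", "molecule_id"]
GROUND_TRUTH_SCHEMA = [
    "molecule_id", "frame", "state", "true_x_um", "true_y_um", "emitting", "detected", "cell_id",
]
CELL_SCHEMA = ["cell_id", "center_x_um", "center_y_um", "length_um", "diameter_um", "orientation_rad"]
TRAJECTORY_SCHEMA = ["track_id", "frame", "x_um", "y_um", "cell_id"]


def write_simulation(output: SimulationOutput, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    output.localizations.to_csv(out / "localizations.csv", index=False)
    output.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    output.cells.to_csv(out / "cells.csv", index=False)


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOCALIZATION_SCHEMA[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    return df


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_SCHEMA) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    return df


def write_trajectories(trajectories: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trajectories.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_simulation_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a nested YAML mapping with sections
    acquisition / diffusion / photophysics / detection / population."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    acq = AcquisitionConfig(**raw.get("acquisition", {}))
    diff_raw = raw.get("diffusion", {})
    diffusion = DiffusionModel(
        D_um2s=np.asarray(diff_raw["D_um2s"], dtype=float),
        transition_matrix=np.asarray(diff_raw["transition_matrix"], dtype=float),
        initial_occupancy=np.asarray(diff_raw["initial_occupancy"], dtype=float),
    )
    photo = PhotophysicsModel(**raw.get("photophysics", {}))
    det = DetectionModel(**raw.get("detection", {}))
    pop = raw.get("population", {})
    return SimulationConfig(
        acquisition=acq,
        diffusion=diffusion,
        photophysics=photo,
        detection=det,
        n_cells=int(pop.get("n_cells", 10)),
        molecules_per_cell=int(pop.get("molecules_per_cell", 5)),
        cell_length_um_range=tuple(pop.get("cell_length_um_range", (2.0, 4.0))),
        cell_diameter_um=float(pop.get("cell_diameter_um", 1.0)),
    )


def dump_simulation_config(config: SimulationConfig, path) -> None:
    raw = {
        "acquisition": {
            "frame_interval_s": config.acquisition.frame_interval_s,
            "exposure_s": config.acquisition.exposure_s,
            "n_frames": config.acquisition.n_frames,
            "pixel_size_um": config.acquisition.pixel_size_um,
            "n_substeps": config.acquisition.n_substeps,
        },
        "diffusion": {
            "D_um2s": config.diffusion.D_um2s.tolist(),
            "transition_matrix": config.diffusion.transition_matrix.tolist(),
            "initial_occupancy": config.diffusion.initial_occupancy.tolist(),
        },
        "photophysics": {
            "p_bleach_per_frame": config.photophysics.p_bleach_per_frame,
            "p_off_per_frame": config.photophysics.p_off_per_frame,
            "p_on_per_frame": config.photophysics.p_on_per_frame,
            "initial_on_fraction": config.photophysics.initial_on_fraction,
        },
        "detection": {
            "localization_sigma_um": config.detection.localization_sigma_um,
            "p_detect_base": config.detection.p_detect_base,
            "blur_scale_um": config.detection.blur_scale_um,
        },
        "population": {
            "n_cells": config.n_cells,
            "molecules_per_cell": config.molecules_per_cell,
            "cell_length_um_range": list(config.cell_length_um_range),
            "cell_diameter_um": config.cell_diameter_um,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
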