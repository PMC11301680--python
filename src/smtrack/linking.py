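"""Trajectory linking with a gate radius and a short memory.

Localizations in consecutive frames of the same cell are linked when
their distance is strictly below the gate (8 pixels by default); a
memory of one frame lets a track bridge a single missed detection.
Within each frame pair, links are chosen by optimal one-to-one matching:
maximum number of gated links first, minimum total squared displacement
among those.  Direct (unit-lag) matches are resolved before gap
candidates compete for the remaining localizations.

The linker intentionally reproduces the splitting behaviour of real
tracking pipelines: a dropout longer than the memory, or a displacement
beyond the gate, starts a new track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import ValidationError

__all__ = ["LinkerConfig", "link_localizations", "split_at_gaps"]

TRAJECTORY_COLUMNS = ["track_id", "frame", "x_um", "y_um", "cell_id"]


@dataclass(frozen=True)
class LinkerConfig:
    gate_radius_px: float = 8.0
    pixel_size_um: float = 0.1
    memory_frames: int = 1

    def __post_init__(self) -> None:
        if self.gate_radius_px <= 0 or self.pixel_size_um <= 0:
            raise ValidationError("gate radius and pixel size must be positive")
        if self.memory_frames < 0:
            raise ValidationError("memory_frames must be >= 0")

    @property
    def gate_um(self) -> float:
        return self.gate_radius_px * self.pixel_size_um


def _gated_assignment(
    track_xy: np.ndarray, loc_xy: np.ndarray, gate2: float
) -> list[tuple[int, int]]:
    """Maximum-cardinality, minimum-total-squared-displacement matching
    between open tracks and localizations, gated at distance < gate."""
    diff = track_xy[:, None, :] - loc_xy[None, :, :]
    cost = np.einsum("ijk,ijk->ij", diff, diff)
    feasible = cost < gate2
    if not feasible.any():
        return []
    big = gate2 * (min(cost.shape) + 1.0) + 1.0
    cost = np.where(feasible, cost, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]


def link_localizations(localizations: pd.DataFrame, config: LinkerConfig = LinkerConfig()) -> pd.DataFrame:
    """Link a localization table into trajectories.

    Returns a trajectory table (track_id, frame, x_um, y_um, cell_id and,
    when present in the input, molecule_id) in which every input
    localization appears exactly once; unlinkable localizations become
    single-frame tracks.
    """
    if "cell_id" not in localizations.columns:
        raise ValidationError("localizations must carry a cell_id column")
    gate2 = config.gate_um ** 2
    has_mol = "molecule_id" in localizations.columns

    out_track_id = np.empty(len(localizations), dtype=np.int64)
    next_track = 0
    # canonical processing order makes assignment ties deterministic
    order_cols = ["cell_id", "frame", "x_um", "y_um"]
    ordered = localizations.reset_index(drop=True).sort_values(order_cols, kind="mergesort")

    for _, cell_df in ordered.groupby("cell_id", sort=True):
        frames = cell_df["frame"].to_numpy()
        xy = cell_df[["x_um", "y_um"]].to_numpy()
        idx = cell_df.index.to_numpy()  # positions in the original table

        # open tracks: id, last frame, last position
        track_last_xy: list[np.ndarray] = []
        track_ids: list[int] = []
        open_by_last: dict[int, list[int]] = {}

        for f in np.unique(frames):
            in_frame = np.nonzero(frames == f)[0]
            unmatched = list(in_frame)
            extended: list[int] = []
            for gap in range(1, config.memory_frames + 2):
                cand = open_by_last.get(f - gap)
                if not cand or not unmatched:
                    continue
                pairs = _gated_assignment(
                    np.array([track_last_xy[t] for t in cand]),
                    xy[unmatched], gate2,
                )
                taken_tracks, taken_locs = [], []
                for ti, lj in pairs:
                    t = cand[ti]
                    j = unmatched[lj]
                    out_track_id[idx[j]] = track_ids[t]
                    track_last_xy[t] = xy[j]
                    taken_tracks.append(t)
                    taken_locs.append(j)
                    extended.append(t)
                open_by_last[f - gap] = [t for t in cand if t not in taken_tracks]
                unmatched = [j for j in unmatched if j not in taken_locs]
            for j in unmatched:
                t = len(track_ids)
                track_ids.append(next_track)
                track_last_xy.append(xy[j])
                out_track_id[idx[j]] = next_track
                next_track += 1
                extended.append(t)
            open_by_last[f] = extended

    result = localizations.reset_index(drop=True).copy()
    result["track_id"] = out_track_id
    cols = TRAJECTORY_COLUMNS + (["molecule_id"] if has_mol else [])
    return result[cols].sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)


def split_at_gaps(trajectories: pd.DataFrame, drop_singletons: bool = False) -> pd.DataFrame:
    """Cut memory-bridged trajectories into gap-free segments.

    Each output segment has strictly consecutive frames.  A trajectory
    with g bridged gaps yields g + 1 segments; segment ids are fresh and
    the parent track id is retained.  With ``drop_singletons`` segments
    of a single localization are removed (they carry no displacement and
    are useless as HMM input).
    """
    if trajectories.empty:
        out = trajectories.copy()
        out["segment_id"] = pd.Series(dtype=np.int64)
        return out
    df = trajectories.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
    tid = df["track_id"].to_numpy()
    frames = df["frame"].to_numpy()
    new_track = np.empty(len(df), dtype=bool)
    new_track[0] = True
    new_track[1:] = tid[1:] != tid[:-1]
    gap = np.empty(len(df), dtype=bool)
    gap[0] = False
    gap[1:] = (~new_track[1:]) & (frames[1:] != frames[:-1] + 1)
    df["segment_id"] = np.cumsum(new_track | gap) - 1
    if drop_singletons:
        sizes = df.groupby("segment_id")["frame"].transform("size")
        df = df[sizes > 1].reset_index(drop=True)
    return df
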