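import numpy as np
import pandas as pd
import pytest

import smtrack as st


@pytest.fixture(scope="session")
def three_state():
    return st.three_state_model(stickiness=0.9)


@pytest.fixture(scope="session")
def acq():
    return st.AcquisitionConfig()


def make_track(positions, frames=None, track_id=0, cell_id=0):
    """Trajectory DataFrame from an (n, 2) position array."""
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return pd.DataFrame({
        "track_id": track_id,
        "frame": np.asarray(frames),
        "x_um": positions[:, 0],
        "y_um": positions[:, 1],
        "cell_id": cell_id,
    })


def segments_to_trajectories(segments):
    """Positions-from-displacements trajectory table, one track per segment."""
    rows = []
    for i, d in enumerate(segments):
        pos = np.vstack([[0.0, 0.0], np.cumsum(d, axis=0)])
        rows.append(make_track(pos, track_id=i))
    return pd.concat(rows, ignore_index=True)
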