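"""Per-track apparent diffusion coefficients and Gamma-mixture fitting.

Each trajectory yields one apparent diffusion coefficient from the MSD
of its first few frame-to-frame steps:

    D_app = sum(d_i^2) / (4 * sum(lag_i) * dt)

over the first ``n_steps`` observed displacements (lag_i = 1, or 2 across
a memory-bridged gap).  For Brownian motion the n-step estimator is
Gamma-distributed with shape n and mean D, so a population with K
diffusive states is fitted as a K-component mixture of such Gamma
densities by maximum likelihood (EM) on the raw values; components may
have their D fixed (updating only their weight), mirroring the practice
of pinning the immobile and slow states to values known from an HMM fit.

D_app is *apparent*: localization noise adds ~sigma^2/dt and motion blur
subtracts a dynamic-error term; no correction is applied.

Forced computational partitioning cuts every track into consecutive
5-localization windows regardless of mobility, so that track
fragmentation affects mobile and immobile molecules equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .config import ValidationError

__all__ = [
    "DEFAULT_MOBILITY_THRESHOLD",
    "GammaComponent",
    "GammaMixtureFit",
    "estimate_D",
    "estimate_D_table",
    "gamma_pdf",
    "fit_gamma_mixture",
    "partition_trajectories",
    "classify_mobility",
    "rolling_D",
]

DEFAULT_MOBILITY_THRESHOLD = 0.04  # um^2/s
D_FLOOR = 1e-6  # um^2/s; avoids log(0) for exact-zero estimates


def estimate_D(
    trajectory: pd.DataFrame,
    n_steps: int = 4,
    frame_interval_s: float = 0.030475,
) -> float:
    """Apparent D of one trajectory from its first ``n_steps`` displacements.

    Raises ``ValidationError`` if the trajectory is too short; batch code
    should use :func:`estimate_D_table`, which counts rejections instead.
    """
    df = trajectory.sort_values("frame")
    if len(df) < n_steps + 1:
        raise ValidationError(f"trajectory needs >= {n_steps + 1} localizations")
    x = df["x_um"].to_numpy()[: n_steps + 1]
    y = df["y_um"].to_numpy()[: n_steps + 1]
    f = df["frame"].to_numpy()[: n_steps + 1]
    d2 = np.diff(x) ** 2 + np.diff(y) ** 2
    lags = np.diff(f)
    return float(d2.sum() / (4.0 * lags.sum() * frame_interval_s))


def estimate_D_table(
    trajectories: pd.DataFrame,
    n_steps: int = 4,
    frame_interval_s: float = 0.030475,
    track_col: str = "track_id",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorized per-track D estimates.

    Returns ``(estimates, rejections)`` where estimates has columns
    track_id, D_app_um2s, n_steps, duration_frames, n_localizations and
    rejections counts tracks too short for the estimator.
    """
    if trajectories.empty:
        empty = pd.DataFrame({
            "track_id": pd.Series(dtype=np.int64),
            "D_app_um2s": pd.Series(dtype=float),
            "n_steps": pd.Series(dtype=np.int64),
            "duration_frames": pd.Series(dtype=np.int64),
            "n_localizations": pd.Series(dtype=np.int64),
        })
        return empty, {"too_short": 0}

    df = trajectories.sort_values([track_col, "frame"], kind="mergesort")
    tid = df[track_col].to_numpy()
    x = df["x_um"].to_numpy()
    y = df["y_um"].to_numpy()
    f = df["frame"].to_numpy()

    track_ids, starts = np.unique(tid, return_index=True)
    sizes = np.diff(np.append(starts, len(df)))
    first_frame = f[starts]
    last_frame = f[np.append(starts[1:], len(df)) - 1]

    same = np.zeros(len(df), dtype=bool)
    same[1:] = tid[1:] == tid[:-1]
    pos_in_track = np.arange(len(df)) - np.repeat(starts, sizes)
    # step i of a track sits at the row of its second localization
    step_ok = same & (pos_in_track >= 1) & (pos_in_track <= n_steps)
    d2 = np.zeros(len(df))
    lag = np.zeros(len(df))
    d2[1:] = (x[1:] - x[:-1]) ** 2 + (y[1:] - y[:-1]) ** 2
    lag[1:] = f[1:] - f[:-1]
    d2[~step_ok] = 0.0
    lag[~step_ok] = 0.0

    track_index = np.repeat(np.arange(track_ids.size), sizes)
    sum_d2 = np.bincount(track_index, weights=d2, minlength=track_ids.size)
    sum_lag = np.bincount(track_index, weights=lag, minlength=track_ids.size)

    usable = sizes >= n_steps + 1
    rejections = {"too_short": int((~usable).sum())}
    with np.errstate(invalid="ignore", divide="ignore"):
        d_app = sum_d2 / (4.0 * sum_lag * frame_interval_s)
    estimates = pd.DataFrame({
        "track_id": track_ids[usable],
        "D_app_um2s": d_app[usable],
        "n_steps": np.full(int(usable.sum()), n_steps, dtype=np.int64),
        "duration_frames": (last_frame - first_frame + 1)[usable].astype(np.int64),
        "n_localizations": sizes[usable].astype(np.int64),
    }).reset_index(drop=True)
    return estimates, rejections


def gamma_pdf(x, n_steps: int, D: float):
    """Density of the n-step apparent-D estimator for true diffusivity D:
    Gamma with shape n and mean D, f(x) = (n/D)^n x^(n-1) e^(-nx/D) / G(n)."""
    if int(n_steps) != n_steps or n_steps < 1:
        raise ValidationError("n_steps must be a positive integer")
    if D <= 0:
        raise ValidationError("D must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValidationError("x must be >= 0")
    return stats.gamma.pdf(x, a=n_steps, scale=D / n_steps)


@dataclass(frozen=True)
class GammaComponent:
    D: float
    weight: float
    fixed: bool


@dataclass
class GammaMixtureFit:
    components: list[GammaComponent]
    n_steps: int
    log_likelihood: float
    n_observations: int
    converged: bool
    n_iterations: int = 0

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def D_values(self) -> np.ndarray:
        return np.array([c.D for c in self.components])

    def to_dict(self) -> dict:
        return {
            "components": [
                {"D": c.D, "weight": c.weight, "fixed": c.fixed} for c in self.components
            ],
            "n_steps": self.n_steps,
            "log_likelihood": self.log_likelihood,
            "n_observations": self.n_observations,
            "converged": self.converged,
        }


def fit_gamma_mixture(
    d_values,
    n_steps: int,
    n_components: int,
    fixed_D=(),
    n_restarts: int = 5,
    rng_seed: int = 0,
    max_iterations: int = 1000,
    tol: float = 1e-9,
) -> GammaMixtureFit:
    """Maximum-likelihood Gamma-mixture fit of raw apparent-D values via EM.

    ``fixed_D`` components keep their D and update only their weight; the
    remaining components update both.  Multi-start: restart 0 initializes
    the free D values at evenly spaced quantiles of the data, later
    restarts at seeded random quantiles; the best likelihood wins.
    Components are returned sorted by D.
    """
    x = np.asarray(d_values, dtype=float)
    if x.size == 0:
        raise ValidationError("d_values must be non-empty")
    if np.any(x < 0):
        raise ValidationError("d_values must be non-negative")
    fixed_D = np.asarray(list(fixed_D), dtype=float)
    if np.any(fixed_D <= 0):
        raise ValidationError("fixed_D entries must be positive")
    k = int(n_components)
    n_fixed = fixed_D.size
    if k < max(n_fixed, 1):
        raise ValidationError("n_components must cover all fixed components")
    x = np.clip(x, D_FLOOR, None)
    n = int(n_steps)
    n_free = k - n_fixed
    rng = np.random.default_rng(rng_seed)

    def run_em(d_init: np.ndarray):
        D = d_init.copy()
        w = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iterations + 1):
            logp = stats.gamma.logpdf(x[:, None], a=n, scale=D[None, :] / n)
            logp += np.log(np.clip(w, 1e-300, None))[None, :]
            row_ll = logsumexp(logp, axis=1)
            ll = float(row_ll.sum())
            resp = np.exp(logp - row_ll[:, None])
            w = resp.mean(axis=0)
            w = np.clip(w, 1e-12, None)
            w = w / w.sum()
            for j in range(n_fixed, k):
                denom = resp[:, j].sum()
                if denom > 0:
                    D[j] = max(float(resp[:, j] @ x / denom), D_FLOOR)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(1.0, abs(ll)):
                converged = True
                break
            ll_prev = ll
        return ll, D, w, converged, it

    best = None
    for restart in range(max(1, n_restarts)):
        if n_free > 0:
            if restart == 0:
                q = np.linspace(0.15, 0.9, n_free + 2)[1:-1] if n_free > 1 else np.array([0.75])
            else:
                q = rng.uniform(0.05, 0.95, size=n_free)
            free_init = np.maximum(np.quantile(x, q), D_FLOOR)
        else:
            free_init = np.empty(0)
        d_init = np.concatenate([fixed_D, np.sort(free_init)])
        result = run_em(d_init)
        if best is None or result[0] > best[0]:
            best = result
        if n_free == 0:
            break
    ll, D, w, converged, it = best
    fixed_flags = np.array([True] * n_fixed + [False] * n_free)
    order = np.argsort(D, kind="stable")
    components = [
        GammaComponent(D=float(D[j]), weight=float(w[j]), fixed=bool(fixed_flags[j]))
        for j in order
    ]
    return GammaMixtureFit(
        components=components,
        n_steps=n,
        log_likelihood=ll,
        n_observations=int(x.size),
        converged=converged,
        n_iterations=it,
    )


def partition_trajectories(
    trajectories: pd.DataFrame,
    window_frames: int = 5,
    track_col: str = "track_id",
) -> pd.DataFrame:
    """Forced computational partitioning.

    Cuts each trajectory, in time order, into consecutive non-overlapping
    windows of ``window_frames`` localizations; a trailing remainder
    shorter than the window is discarded.  The cut is blind to mobility.
    Output tracks get fresh ids in column ``track_id``; the parent id is
    kept in ``parent_track_id``.
    """
    if window_frames < 2:
        raise ValidationError("window_frames must be >= 2")
    if trajectories.empty:
        out = trajectories.copy().rename(columns={track_col: "parent_track_id"})
        out["track_id"] = pd.Series(dtype=np.int64)
        return out
    df = trajectories.sort_values([track_col, "frame"], kind="mergesort").reset_index(drop=True)
    pos = df.groupby(track_col, sort=False).cumcount().to_numpy()
    sizes = df.groupby(track_col, sort=False)[track_col].transform("size").to_numpy()
    keep = pos < window_frames * (sizes // window_frames)
    df = df[keep].copy()
    sub = pos[keep] // window_frames
    df = df.rename(columns={track_col: "parent_track_id"})
    if len(df) == 0:
        df["track_id"] = np.empty(0, dtype=np.int64)
        return df.reset_index(drop=True)
    parent = df["parent_track_id"].to_numpy()
    key = parent.astype(np.int64) * (int(sub.max()) + 1) + sub
    new_id = np.unique(key, return_inverse=True)[1]
    df["track_id"] = new_id.astype(np.int64)
    return df.reset_index(drop=True)


def classify_mobility(d_app, threshold: float = DEFAULT_MOBILITY_THRESHOLD):
    """Immobile (D_app <= threshold, boundary inclusive) vs mobile."""
    d = np.asarray(d_app, dtype=float)
    labels = np.where(d <= threshold, "immobile", "mobile")
    return labels if d.ndim else labels[()]


def rolling_D(
    trajectory: pd.DataFrame,
    window_frames: int = 5,
    frame_interval_s: float = 0.030475,
) -> np.ndarray:
    """Left-aligned sliding-window apparent D along one trajectory.

    Window i covers localizations i .. i + window - 1 (window - 1 steps);
    the series has length len - window + 1 and is empty for short tracks.
    Used to visualize state switches along individual long-lived tracks.
    """
    if window_frames < 2:
        raise ValidationError("window_frames must be >= 2")
    df = trajectory.sort_values("frame")
    x = df["x_um"].to_numpy()
    y = df["y_um"].to_numpy()
    f = df["frame"].to_numpy()
    n = len(df)
    if n < window_frames:
        return np.empty(0)
    d2 = (x[1:] - x[:-1]) ** 2 + (y[1:] - y[:-1]) ** 2
    lag = (f[1:] - f[:-1]).astype(float)
    c_d2 = np.concatenate([[0.0], np.cumsum(d2)])
    c_lag = np.concatenate([[0.0], np.cumsum(lag)])
    w = window_frames - 1  # steps per window
    num = c_d2[w:] - c_d2[:-w]
    den = c_lag[w:] - c_lag[:-w]
    return num / (4.0 * den * frame_interval_s)
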