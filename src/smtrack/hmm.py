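"""Displacement-based hidden Markov model of diffusive states.

The observable is the frame-to-frame displacement vector of a molecule;
in hidden state k it is an isotropic zero-mean 2D Gaussian with per-axis
variance 2*D_k*dt (optionally inflated by 2*sigma^2 of localization
error).  The hidden state evolves by a per-frame Markov chain.  Fitting
is maximum-likelihood Baum-Welch over all gap-free segments jointly,
with multiple seeded restarts; the number of states is chosen by BIC.
This stands in for variational-Bayes trackers (vbSPT-style tools) at the
level of recovered parameters: state D values, transition probabilities,
and occupancies.  The headline occupancy is the stationary distribution
of the fitted transition matrix; posterior step fractions are reported
alongside.

Segments must have unit frame lags: bridge-gap trajectories are split
upstream (``linking.split_at_gaps``) rather than modeling lag-2 emissions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .config import ValidationError

__all__ = [
    "HMMConfig",
    "HMMFit",
    "displacements_from_trajectories",
    "fit_hmm",
    "select_model",
    "stationary_occupancies",
    "viterbi_states",
]

_D_FLOOR = 1e-6  # um^2/s, avoids zero-variance emissions
_TINY = 1e-300


@dataclass(frozen=True)
class HMMConfig:
    n_states: int | None = None
    k_range: tuple[int, int] = (2, 6)
    max_iterations: int = 300
    convergence_tol: float = 1e-7
    n_restarts: int = 10
    rng_seed: int = 0
    frame_interval_s: float = 0.030475
    include_localization_error: bool = False
    sigma_um: float = 0.0

    def __post_init__(self) -> None:
        if self.n_states is not None and self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence_tol must be positive")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValidationError("invalid k_range")


@dataclass
class HMMFit:
    n_states: int
    D_um2s: np.ndarray
    transition_matrix: np.ndarray
    stationary_occupancy: np.ndarray
    initial_distribution: np.ndarray
    posterior_occupancy: np.ndarray
    log_likelihood: float
    bic: float
    n_steps_used: int
    converged: bool
    frame_interval_s: float = 0.030475
    sigma2_um2: float = 0.0

    def to_dict(self) -> dict:
        return {
            "K": self.n_states,
            "D_um2s": self.D_um2s.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "stationary_occupancy": self.stationary_occupancy.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
            "posterior_occupancy": self.posterior_occupancy.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_steps_used": self.n_steps_used,
            "converged": self.converged,
        }


def displacements_from_trajectories(
    trajectories: pd.DataFrame, track_col: str = "segment_id"
) -> list[np.ndarray]:
    """Frame-to-frame displacement arrays, one (n_i, 2) array per segment.

    Requires consecutive frames within each segment (raises otherwise);
    segments with fewer than 2 localizations are dropped.
    """
    out: list[np.ndarray] = []
    df = trajectories.sort_values([track_col, "frame"], kind="mergesort")
    for _, seg in df.groupby(track_col, sort=True):
        if len(seg) < 2:
            continue
        f = seg["frame"].to_numpy()
        if np.any(np.diff(f) != 1):
            raise ValidationError(
                "segments must be gap-free; run linking.split_at_gaps first"
            )
        xy = seg[["x_um", "y_um"]].to_numpy()
        out.append(np.diff(xy, axis=0))
    return out


def _pack(displacements: list[np.ndarray]):
    """Pad segments into (S, T_max) arrays, sorted by length descending.

    Sorting makes the set of segments still active at time t a contiguous
    leading slice, so the forward/backward recursions can run on slices
    and total work scales with the number of steps, not S * T_max.
    """
    segs = [np.asarray(d, dtype=float) for d in displacements if len(d) >= 1]
    if not segs:
        raise ValidationError("need at least one segment with one displacement")
    segs.sort(key=len, reverse=True)
    lengths = np.array([len(d) for d in segs])
    t_max = int(lengths.max())
    s = len(segs)
    r2 = np.zeros((s, t_max))
    mask = np.zeros((s, t_max), dtype=bool)
    for i, d in enumerate(segs):
        r2[i, : len(d)] = d[:, 0] ** 2 + d[:, 1] ** 2
        mask[i, : len(d)] = True
    # n_active[t] = number of segments with a step at time t
    n_active = np.searchsorted(-lengths, -(np.arange(t_max) + 1), side="right")
    return r2, mask, lengths, n_active


def _n_parameters(k: int) -> int:
    return k + k * (k - 1) + (k - 1)


def _em(r2, mask, n_active, k, variances0, transition0, initial0, max_iterations, tol, var_floor):
    """Baum-Welch on packed squared displacements; per-axis variances.

    Segments are sorted by length descending so the active set at each
    time is the leading slice of size ``n_active[t]``.  Returns
    (loglik, variances, transition, initial, gamma, converged) and
    asserts the EM monotonicity of the log-likelihood every iteration.
    """
    s, t_max = r2.shape
    si, ti = np.nonzero(mask)
    r2_flat = r2[si, ti]
    v = variances0.copy()
    T = transition0.copy()
    pi = initial0.copy()
    ll_prev = -np.inf
    converged = False
    gamma = None
    Bs = np.ones((s, t_max, k))
    alpha = np.zeros((s, t_max, k))
    beta = np.ones((s, t_max, k))
    c = np.ones((s, t_max))
    for _ in range(max_iterations):
        # emission densities on valid steps only, max-shifted per step
        with np.errstate(under="ignore"):
            logB = -np.log(2.0 * np.pi * v)[None, :] - r2_flat[:, None] / (2.0 * v)[None, :]
        shift = logB.max(axis=1)
        Bs[si, ti] = np.exp(logB - shift[:, None])

        a = pi[None, :] * Bs[:, 0, :]
        c0 = np.maximum(a.sum(axis=1), _TINY)
        alpha[:, 0] = a / c0[:, None]
        c[:, 0] = c0
        for t in range(1, t_max):
            na = n_active[t]
            a = (alpha[:na, t - 1] @ T) * Bs[:na, t, :]
            ct = np.maximum(a.sum(axis=1), _TINY)
            alpha[:na, t] = a / ct[:, None]
            c[:na, t] = ct
        ll = float(np.log(c[si, ti]).sum() + shift.sum())
        assert ll >= ll_prev - 1e-6 * max(1.0, abs(ll_prev)), "EM log-likelihood decreased"

        # backward: beta stays 1 at and beyond each segment's last step
        beta[:, t_max - 1] = 1.0
        for t in range(t_max - 2, -1, -1):
            na = n_active[t + 1]
            beta[:na, t] = (Bs[:na, t + 1, :] * beta[:na, t + 1]) @ T.T / c[:na, t + 1, None]
            beta[na : n_active[t], t] = 1.0

        gamma_flat = alpha[si, ti] * beta[si, ti]
        gamma_flat /= np.maximum(gamma_flat.sum(axis=1), _TINY)[:, None]

        counts = np.zeros((k, k))
        for t in range(t_max - 1):
            na = n_active[t + 1]
            if na == 0:
                break
            right = (Bs[:na, t + 1, :] * beta[:na, t + 1]) / c[:na, t + 1, None]
            counts += np.einsum("si,ij,sj->ij", alpha[:na, t], T, right)

        gamma0 = alpha[:, 0] * beta[:, 0]
        gamma0 /= np.maximum(gamma0.sum(axis=1), _TINY)[:, None]
        pi = np.clip(gamma0.mean(axis=0), 0.0, None)
        pi = pi / pi.sum()
        row = counts.sum(axis=1, keepdims=True)
        T = np.where(row > 0, counts / np.maximum(row, _TINY), T)
        T = T / T.sum(axis=1, keepdims=True)
        denom = gamma_flat.sum(axis=0)
        num = gamma_flat.T @ r2_flat
        v_new = np.where(denom > 0, num / np.maximum(2.0 * denom, _TINY), v)
        v = np.maximum(v_new, var_floor)

        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
    gamma = np.zeros((s, t_max, k))
    gamma[si, ti] = gamma_flat
    return ll, v, T, pi, gamma, converged


def fit_hmm(displacements: list[np.ndarray], config: HMMConfig) -> HMMFit:
    """Fit a fixed-size displacement HMM by Baum-Welch with restarts.

    States are relabeled in ascending order of D on output.
    """
    if config.n_states is None:
        raise ValidationError("config.n_states must be set for fit_hmm")
    k = config.n_states
    r2, mask, _, n_active = _pack(displacements)
    n_steps = int(mask.sum())
    if n_steps <= _n_parameters(k):
        raise ValidationError(
            f"{n_steps} steps cannot constrain {_n_parameters(k)} parameters (K={k})"
        )
    dt = config.frame_interval_s
    sigma2 = config.sigma_um ** 2 if config.include_localization_error else 0.0

    ss = np.random.SeedSequence([int(config.rng_seed) % (2**31), k])
    rngs = [np.random.default_rng(child) for child in ss.spawn(max(1, config.n_restarts))]

    best = None
    for rng in rngs:
        if k == 1:
            D0 = np.array([max(float(r2[mask].mean()) / (4.0 * dt), _D_FLOOR)])
        else:
            D0 = np.sort(np.exp(rng.uniform(np.log(1e-3), np.log(10.0), size=k)))
        v0 = 2.0 * D0 * dt + 2.0 * sigma2
        T0 = np.full((k, k), 0.1 / max(k - 1, 1))
        np.fill_diagonal(T0, 0.9 if k > 1 else 1.0)
        T0 = T0 / T0.sum(axis=1, keepdims=True)
        pi0 = np.full(k, 1.0 / k)
        var_floor = 2.0 * _D_FLOOR * dt + 2.0 * sigma2
        result = _em(r2, mask, n_active, k, v0, T0, pi0,
                     config.max_iterations, config.convergence_tol, var_floor)
        if best is None or result[0] > best[0]:
            best = result
    ll, v, T, pi, gamma, converged = best

    D = np.maximum((v - 2.0 * sigma2) / (2.0 * dt), _D_FLOOR)
    order = np.argsort(D, kind="stable")
    D = D[order]
    T = T[np.ix_(order, order)]
    pi = pi[order]
    posterior = gamma.sum(axis=(0, 1))[order]
    posterior = posterior / posterior.sum()
    stationary = stationary_occupancies(T)
    bic = -2.0 * ll + _n_parameters(k) * np.log(n_steps)
    return HMMFit(
        n_states=k,
        D_um2s=D,
        transition_matrix=T,
        stationary_occupancy=stationary,
        initial_distribution=pi,
        posterior_occupancy=posterior,
        log_likelihood=ll,
        bic=bic,
        n_steps_used=n_steps,
        converged=converged,
        frame_interval_s=dt,
        sigma2_um2=sigma2,
    )


def select_model(displacements: list[np.ndarray], config: HMMConfig) -> HMMFit:
    """Fit each K in ``config.k_range`` and return the BIC-minimizing fit
    (ties favour the smaller model)."""
    k_min, k_max = config.k_range
    best: HMMFit | None = None
    for k in range(k_min, k_max + 1):
        fit = fit_hmm(displacements, replace(config, n_states=k))
        if best is None or fit.bic < best.bic:
            best = fit
    return best


def stationary_occupancies(transition_matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Unique stationary distribution pi with pi @ T = pi.

    Solved as the left eigenvector at eigenvalue 1; a reducible chain
    (eigenvalue 1 with multiplicity > 1) raises ``ValidationError``.
    """
    T = np.asarray(transition_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValidationError("transition matrix must be square")
    if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("transition matrix must be row-stochastic")
    if T.shape[0] == 1:
        return np.array([1.0])
    w, vl = scipy.linalg.eig(T, left=True, right=False)
    at_one = np.abs(w - 1.0) < tol
    if at_one.sum() != 1:
        raise ValidationError("no unique stationary distribution (chain is reducible)")
    pi = np.real(vl[:, at_one].ravel())
    pi = pi / pi.sum()
    if np.any(pi < -1e-10):
        raise ValidationError("stationary vector has negative entries")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def viterbi_states(displacements: np.ndarray, fit: HMMFit) -> np.ndarray:
    """Most probable state path for one gap-free segment (MAP by dynamic
    programming); ties resolve toward the lower state index."""
    d = np.asarray(displacements, dtype=float)
    r2 = d[:, 0] ** 2 + d[:, 1] ** 2
    n = r2.size
    k = fit.n_states
    v = 2.0 * fit.D_um2s * fit.frame_interval_s + 2.0 * fit.sigma2_um2
    with np.errstate(under="ignore", divide="ignore"):
        logB = -np.log(2.0 * np.pi * v)[None, :] - r2[:, None] / (2.0 * v)[None, :]
        log_pi = np.log(np.clip(fit.initial_distribution, 0.0, None))
        logT = np.log(np.clip(fit.transition_matrix, 0.0, None))
    delta = log_pi + logB[0]
    psi = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + logT
        psi[t] = np.argmax(cand, axis=0)  # first max -> lowest index on ties
        delta = cand[psi[t], np.arange(k)] + logB[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path
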