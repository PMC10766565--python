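"""Self-consistent non-parametric reweighting of pooled umbrella samples.

Frames from all umbrella windows are pooled and each frame k receives a
weight

    w_k = c / sum_i n_i exp(-(U_i(r_k) - F_i)/RT)

with the per-window perturbed free energies F_i satisfying

    exp(-F_i/RT) = sum_k w_k exp(-U_i(r_k)/RT).

This is the multistate reweighting fixed point (an MBAR-type estimator,
generalized to unequal per-window sample counts n_i; with equal n_i the
equations reduce to the equal-count form).  The weights target the unbiased
ensemble of whatever base Hamiltonian the windows share, so any PMF over any
sufficiently sampled CV can be built from them afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .constants import rt
from .io_cv import CVTrajectory, WindowConfig


class ReweightError(RuntimeError):
    pass


@dataclass
class BiasedSampleSet:
    """Pooled frames from all windows.

    ``cv_values`` is a (frames x CVs) table; ``window_of_origin`` maps each
    frame to the index of the window that generated it (order of
    ``window_ids``).
    """

    cv_values: pd.DataFrame
    window_of_origin: np.ndarray
    window_ids: list[str]
    temperature: float

    def __post_init__(self) -> None:
        self.window_of_origin = np.asarray(self.window_of_origin, dtype=np.intp)
        if len(self.window_of_origin) != len(self.cv_values):
            raise ValueError("window_of_origin length must match frame count")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.cv_values)

    @property
    def n_per_window(self) -> np.ndarray:
        return np.bincount(self.window_of_origin, minlength=len(self.window_ids))

    def cv(self, name: str) -> np.ndarray:
        return self.cv_values[name].to_numpy(dtype=float)


def pool_trajectories(
    trajectories: list[CVTrajectory],
    config: WindowConfig,
    discard_fraction: float = 0.0,
) -> BiasedSampleSet:
    """Pool per-window trajectories into one sample set.

    ``discard_fraction`` drops that leading fraction of each window's frames
    as equilibration before pooling.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    by_id = {t.window_id: t for t in trajectories}
    frames = []
    origin = []
    for i, wid in enumerate(config.window_ids):
        if wid not in by_id:
            raise ValueError(f"no trajectory for window {wid!r}")
        vals = by_id[wid].values
        start = int(discard_fraction * len(vals))
        vals = vals.iloc[start:]
        frames.append(vals)
        origin.append(np.full(len(vals), i, dtype=np.intp))
    return BiasedSampleSet(
        cv_values=pd.concat(frames, ignore_index=True),
        window_of_origin=np.concatenate(origin),
        window_ids=list(config.window_ids),
        temperature=config.temperature,
    )


@dataclass
class ReweightResult:
    """Converged per-frame weights and per-window free energies."""

    weights: np.ndarray
    perturbed_free_energies: np.ndarray  # kcal/mol, anchored F_1 = 0
    n_iterations: int
    converged: bool
    max_residual: float
    log_weights: np.ndarray = field(repr=False, default=None)


def bias_energy_matrix(
    samples: BiasedSampleSet, config: WindowConfig
) -> np.ndarray:
    """(frames x windows) matrix of total bias energies in kcal/mol.

    Entry (k, i) is the sum over window i's biases of 1/2 k (v_k - center)^2.
    """
    n = samples.n_frames
    u = np.zeros((n, config.n_windows))
    for i, (wid, biases) in enumerate(config.windows):
        for b in biases:
            if b.cv not in samples.cv_values.columns:
                raise ReweightError(
                    f"window {wid!r} biases CV {b.cv!r} absent from samples"
                )
            u[:, i] += b.energy(samples.cv(b.cv))
    return u


class _Solver:
    """Matmul-based evaluation of the fixed-point step and of the convex
    objective, sharing one exp(-beta*U) table.

    All exponentials are taken against per-call maximum shifts, so the
    linear-space arithmetic is safe for any finite bias matrix: a column of
    exp(-beta*U) that underflows entirely corresponds to a window whose bias
    is effectively infinite for every sample, which is rejected upstream.
    """

    def __init__(self, u, n_i, beta, scale=None):
        self.beta = beta
        self.n_i = n_i
        self.log_n = np.log(n_i)
        self.scale = scale  # per-frame multiplicities (None = all ones)
        self.boltz = np.exp(-beta * u)  # frames x windows

    def _denominator(self, f):
        a = self.log_n + self.beta * f
        shift = a.max()
        denom = self.boltz @ np.exp(a - shift)
        return denom, shift

    def step(self, f):
        """One fixed-point update; returns (new F anchored at 0, log w)."""
        denom, _ = self._denominator(f)
        log_w = -np.log(denom)
        if self.scale is not None:
            with np.errstate(divide="ignore"):
                log_w = log_w + np.log(self.scale)
        m = log_w.max()
        ew = np.exp(log_w - m)
        total = ew.sum()
        w = ew / total
        log_w = log_w - m - np.log(total)
        t = w @ self.boltz
        with np.errstate(divide="ignore"):
            f_new = -np.log(t) / self.beta
        return f_new - f_new[0], log_w

    def objective(self, bf):
        """Value and gradient (in beta*F) of the convex pooled
        log-likelihood whose stationary point is the fixed point."""
        f = bf / self.beta
        denom, shift = self._denominator(f)
        log_denom = np.log(denom) + shift
        if self.scale is None:
            value = log_denom.sum() - float(self.n_i @ bf)
            q = 1.0 / denom
        else:
            value = float(self.scale @ log_denom) - float(self.n_i @ bf)
            q = self.scale / denom
        a = self.log_n + self.beta * f
        grad = (q @ self.boltz) * np.exp(a - shift) - self.n_i
        return value, grad


def solve_weights(
    samples: BiasedSampleSet,
    config: WindowConfig,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    frame_scales: np.ndarray | None = None,
    f_init: np.ndarray | None = None,
    warm_start: bool = True,
) -> ReweightResult:
    """Solve the reweighting fixed point for pooled biased samples.

    Deterministic given its inputs.  ``frame_scales`` are optional
    nonnegative per-frame multiplicities (used by the Bayesian bootstrap);
    ``f_init`` seeds the iteration, ``warm_start=True`` additionally runs an
    L-BFGS minimization of the equivalent convex objective before polishing
    with the fixed-point iteration (same solution, far fewer iterations).

    Raises
    ------
    ReweightError
        If some window's bias energy is infinite for every frame (that
        window contributes no information and the equations are singular).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    u = bias_energy_matrix(samples, config)
    if not np.all(np.isfinite(u.min(axis=0))):
        bad = [config.window_ids[i] for i in np.where(~np.isfinite(u.min(axis=0)))[0]]
        raise ReweightError(f"bias energy infinite for all samples in window(s) {bad}")
    beta = 1.0 / rt(samples.temperature)
    n_i = samples.n_per_window.astype(float)
    if np.any(n_i == 0):
        empty = [config.window_ids[i] for i in np.where(n_i == 0)[0]]
        raise ReweightError(f"window(s) with zero samples: {empty}")
    log_n = np.log(n_i)

    scale = None
    if frame_scales is not None:
        frame_scales = np.asarray(frame_scales, dtype=float)
        if frame_scales.shape != (samples.n_frames,):
            raise ValueError("frame_scales must have one entry per frame")
        if np.any(frame_scales < 0):
            raise ValueError("frame_scales must be nonnegative")
        scale = frame_scales

    solver = _Solver(u, n_i, beta, scale=scale)
    f = np.zeros(config.n_windows) if f_init is None else np.array(f_init, dtype=float)

    if warm_start and config.n_windows > 1:
        res = minimize(
            solver.objective,
            beta * f,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-9},
        )
        f = res.x / beta
        f = f - f[0]

    converged = False
    residual = np.inf
    log_w = None
    for iteration in range(1, max_iter + 1):
        f_new, log_w = solver.step(f)
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            converged = True
            break
    if log_w is None:  # max_iter == 0 guard
        f, log_w = solver.step(f)
        iteration = 0
    return ReweightResult(
        weights=np.exp(log_w),
        perturbed_free_energies=f,
        n_iterations=iteration,
        converged=converged,
        max_residual=residual,
        log_weights=log_w,
    )
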