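"""Block Bayesian bootstrap over trajectory blocks.

Each window's frames are partitioned into contiguous blocks; per resample,
each window independently draws Dirichlet(1, ..., 1) weights over its blocks
and every frame is scaled by its block's Dirichlet weight times the block
count, renormalized so the window's total multiplicity equals its frame
count.  The estimator (typically the full reweighting + PMF pipeline) is
re-run on each resample; the spread of the resampled estimates is the error
bar.  Contiguous blocks keep autocorrelated frames together, so the error
estimate reflects the trajectory's correlation structure rather than the
(optimistic) i.i.d. assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .reweight import BiasedSampleSet


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapPlan:
    n_resamples: int = 100
    n_blocks: int = 20               # blocks per window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass
class BootstrapResult:
    mean: np.ndarray | float
    sd: np.ndarray | float
    values: np.ndarray               # per-resample estimates
    n_failed: int = 0


def block_ids(n_frames: int, n_blocks: int) -> np.ndarray:
    """Contiguous block label per frame; the last block absorbs remainders."""
    n_blocks = min(n_blocks, n_frames)
    size = n_frames // n_blocks
    ids = np.minimum(np.arange(n_frames) // size, n_blocks - 1)
    return ids


def resample_scales(
    samples: BiasedSampleSet, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """One Bayesian-bootstrap multiplicity per frame (window totals kept)."""
    scales = np.empty(samples.n_frames)
    for w in range(len(samples.window_ids)):
        idx = np.where(samples.window_of_origin == w)[0]
        nb = min(n_blocks, len(idx))
        blocks = block_ids(len(idx), nb)
        g = rng.dirichlet(np.ones(blocks.max() + 1))
        s = g[blocks]
        scales[idx] = s * len(idx) / s.sum()
    return scales


def block_bayesian_bootstrap(
    samples: BiasedSampleSet,
    plan: BootstrapPlan,
    estimator: Callable[[BiasedSampleSet, np.ndarray], float | np.ndarray],
) -> BootstrapResult:
    """Re-run ``estimator(samples, frame_scales)`` over Dirichlet resamples.

    Deterministic given ``plan.seed``.  Estimator failures are recorded and
    excluded (not retried, to keep seed reproducibility); more than 10%
    failures is a hard error.
    """
    rng = np.random.default_rng(plan.seed)
    values = []
    n_failed = 0
    for _ in range(plan.n_resamples):
        scales = resample_scales(samples, plan.n_blocks, rng)
        try:
            values.append(estimator(samples, scales))
        except Exception as exc:  # noqa: BLE001 - estimator is user code
            n_failed += 1
            warnings.warn(f"bootstrap resample failed and was excluded: {exc}")
    if n_failed > 0.1 * plan.n_resamples:
        raise BootstrapError(
            f"{n_failed}/{plan.n_resamples} bootstrap resamples failed"
        )
    arr = np.asarray(values, dtype=float)
    return BootstrapResult(
        mean=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=1),
        values=arr,
        n_failed=n_failed,
    )
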