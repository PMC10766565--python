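"""Assembly of the absolute binding free energy ΔG° and K_d.

The stratification identity assembled here is

    ΔG° = -ΔG(x_B) + Σ ΔU_restraints + ΔG_V

with ΔG(x_B) the grid-PMF difference between the bulk and the pocket
center, ΔU the restraint corrections, and the volume term

    ΔG_V = -RT ln(V_P / V_B),   V_P = ∫_pocket e^{-ΔG(x)/RT} dV,
    V_B = 1 L / N_A ≈ 1661 Å³ (1 M standard state).

The budget stores the grid term in the tabulated (pocket-minus-bulk)
convention, i.e. grid_pmf_difference = -ΔG(x_B) <= 0 for a binder, so that

    ΔG° = grid_pmf_difference + Σ ΔU + ΔG_V.

K_d follows from ΔG° = RT ln(K_d / 1 M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import STANDARD_VOLUME_A3, rt
from .corrections import RestraintCorrection
from .pmf import GridPMF


@dataclass
class PocketVolume:
    """Boltzmann-weighted pocket volume with its convergence series."""

    v_pocket: float                    # Å^3
    dg_sorted: np.ndarray              # voxel ΔG ascending, kcal/mol
    cumulative_volume: np.ndarray      # running V_P over the sorted voxels


@dataclass
class VolumeTerms:
    v_pocket: float
    v_bulk: float
    dg_pocket: float
    dg_bulk: float
    dg_volume: float
    temperature: float


@dataclass
class FreeEnergyBudget:
    grid_pmf_difference: float         # pocket minus bulk (= -ΔG(x_B))
    corrections: list[RestraintCorrection]
    dg_volume: float
    dg_standard: float
    kd: float                          # molar
    temperature: float
    grid_pmf_difference_err: float = 0.0
    dg_volume_err: float = 0.0
    dg_standard_err: float = 0.0
    kd_interval: tuple[float, float] | None = None
    terms: dict = field(default_factory=dict)


def pocket_volume(grid: GridPMF, radius_cutoff: float | None = None) -> PocketVolume:
    """V_P = Σ_occupied voxels e^{-ΔG(x)/RT} · voxel³.

    By default all occupied voxels enter the sum; only those near the pocket
    center contribute appreciably because ΔG rises steeply away from it.
    ``radius_cutoff`` (Å from the pocket center) restricts the sum for
    sensitivity analysis only.  The cumulative series over voxels sorted by
    ascending ΔG makes the convergence of the sum inspectable.
    """
    if grid.n_voxels == 0:
        raise ValueError("empty grid")
    beta = 1.0 / rt(grid.temperature)
    dg = grid.dg
    if radius_cutoff is not None:
        keep = grid.radii() <= radius_cutoff
        if not np.any(keep):
            raise ValueError("radius_cutoff excludes every voxel")
        dg = dg[keep]
    order = np.argsort(dg)
    dg_sorted = dg[order]
    contrib = np.exp(-beta * dg_sorted) * grid.voxel_size**3
    cumulative = np.cumsum(contrib)
    return PocketVolume(
        v_pocket=float(cumulative[-1]),
        dg_sorted=dg_sorted,
        cumulative_volume=cumulative,
    )


def volume_terms(
    v_pocket: float,
    temperature: float,
    v_bulk: float = STANDARD_VOLUME_A3,
) -> VolumeTerms:
    """Standard-state volume contributions (all volumes in Å³)."""
    if v_pocket <= 0 or v_bulk <= 0:
        raise ValueError("volumes must be positive")
    rt_ = rt(temperature)
    dg_bulk = -rt_ * math.log(v_bulk)
    dg_pocket = -rt_ * math.log(v_pocket)
    return VolumeTerms(
        v_pocket=v_pocket,
        v_bulk=v_bulk,
        dg_pocket=dg_pocket,
        dg_bulk=dg_bulk,
        dg_volume=dg_pocket - dg_bulk,
        temperature=temperature,
    )


def dg_from_kd(kd: float, temperature: float) -> float:
    """ΔG° = RT ln(K_d / 1 M); kd in molar."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return rt(temperature) * math.log(kd)


def kd_from_dg(dg_standard: float, temperature: float) -> float:
    """Inverse of :func:`dg_from_kd` (exact round trip)."""
    return math.exp(dg_standard / rt(temperature))


def assemble_dg0(
    grid_pmf_difference: float,
    corrections: list[RestraintCorrection],
    dg_volume: float,
    temperature: float,
    grid_pmf_difference_err: float = 0.0,
    dg_volume_err: float = 0.0,
) -> FreeEnergyBudget:
    """Sum the free-energy budget and convert to K_d.

    ``grid_pmf_difference`` uses the tabulated pocket-minus-bulk convention
    (negative for a binder).  Errors are propagated as the root sum of
    squares of the per-term standard deviations; the K_d interval maps
    ΔG° ± σ through the exponential.
    """
    if dg_volume is None:
        raise ValueError("dg_volume is required (the term is never optional)")
    dg0 = grid_pmf_difference + sum(c.du for c in corrections) + dg_volume
    var = grid_pmf_difference_err**2 + dg_volume_err**2
    var += sum(c.du_err**2 for c in corrections)
    err = math.sqrt(var)
    kd = kd_from_dg(dg0, temperature)
    interval = (
        kd_from_dg(dg0 - err, temperature),
        kd_from_dg(dg0 + err, temperature),
    )
    terms = {"grid_pmf_difference": grid_pmf_difference, "dg_volume": dg_volume}
    for c in corrections:
        terms[f"du_{c.cv}"] = c.du
    return FreeEnergyBudget(
        grid_pmf_difference=grid_pmf_difference,
        corrections=list(corrections),
        dg_volume=dg_volume,
        dg_standard=dg0,
        kd=kd,
        temperature=temperature,
        grid_pmf_difference_err=grid_pmf_difference_err,
        dg_volume_err=dg_volume_err,
        dg_standard_err=err,
        kd_interval=interval,
        terms=terms,
    )
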