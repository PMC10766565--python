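"""Ligand orientation angle Ω: Euler conversion, the analytic bulk
distribution on SO(3), and restraint ensemble averages by quadrature.

Ω is the single rotation angle (in [0, π]) separating the ligand's current
orientation from a reference orientation — the angle of the optimal-
superposition quaternion.  For a freely tumbling ligand in the bulk the
orientation is uniform on SO(3) and Ω has the closed-form density

    p(Ω) = (1 - cos Ω) / π,        0 <= Ω <= π.

The module reproduces this density numerically by accumulating Ω over a
discretized Euler-angle lattice, and computes restrained-ensemble averages
<exp(-k ζ² / 2RT)> from any 1-D PMF by trapezoidal quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import rt
from .pmf import PMFProfile


@dataclass(frozen=True)
class EulerTriple:
    """Euler angles (intrinsic z-y-x); phi, psi in [0, 2π), theta in [0, π]."""

    phi: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        if not (0 <= self.theta <= np.pi):
            raise ValueError(f"theta must be in [0, pi], got {self.theta}")


@dataclass
class OrientationPMF:
    """F(Ω) on a grid in [0, π]; provenance distinguishes the analytic bulk
    reference from a sampled binding-pocket PMF."""

    omega_grid: np.ndarray
    f: np.ndarray
    provenance: str  # "analytic-bulk" | "sampled-pocket"
    density: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega_grid = np.asarray(self.omega_grid, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if np.any(self.omega_grid < 0) or np.any(self.omega_grid > np.pi + 1e-12):
            raise ValueError("omega grid must lie in [0, pi]")
        if not np.all(np.diff(self.omega_grid) > 0):
            raise ValueError("omega grid must be strictly increasing")


def omega_from_euler(e: EulerTriple) -> float:
    """Rotation angle of the orientation described by an Euler triple.

    Uses the half-angle quaternion identity

        cos(Ω/2) = cos(φ/2) cos(θ/2) cos(ψ/2) + sin(φ/2) sin(θ/2) sin(ψ/2)

    which is the scalar quaternion component of the intrinsic z-y-x
    composition Rz(φ) Ry(θ) Rx(ψ).  The absolute value maps the quaternion
    double cover onto Ω in [0, π].
    """
    c = np.cos(e.phi / 2) * np.cos(e.theta / 2) * np.cos(e.psi / 2) + np.sin(
        e.phi / 2
    ) * np.sin(e.theta / 2) * np.sin(e.psi / 2)
    return float(2.0 * np.arccos(np.clip(abs(c), 0.0, 1.0)))


def closed_form_bulk_density(omega: np.ndarray) -> np.ndarray:
    """Density of the rotation angle of a uniformly distributed rotation."""
    return (1.0 - np.cos(omega)) / np.pi


def bulk_orientation_pmf(
    bin_deg: float = 1.0,
    temperature: float = 300.0,
    method: str = "lattice",
) -> OrientationPMF:
    """Unbiased bulk PMF of the orientation angle, F(Ω) = -RT ln p(Ω).

    method="lattice" accumulates p(Ω) over a bin_deg-spaced Euler lattice
    (360/bin_deg × 180/bin_deg × 360/bin_deg cells) with the Haar weight of
    the chart; method="closed-form" evaluates (1 - cos Ω)/π directly on a
    bin_deg-spaced Ω grid (use a fine grid, e.g. 0.01°, when the PMF feeds a
    sharply restrained quadrature).

    The Ω grid is at bin centers, so Ω = 0 (where p = 0, F = +inf) is never
    a grid point.

    Note on the measure: the half-angle identity used for Ω belongs to a
    Tait-Bryan chart whose uniform (Haar) weight is cos(pitch) with pitch in
    [-π/2, π/2].  Substituting θ = pitch + π/2 gives the familiar weight
    sin θ dφ dθ dψ / 8π² with θ in [0, π]; the lattice below integrates in
    the pitch variable, which is the same measure.
    """
    if bin_deg <= 0:
        raise ValueError("bin_deg must be positive")
    n_om = int(round(180.0 / bin_deg))
    if not np.isclose(n_om * bin_deg, 180.0):
        raise ValueError("bin_deg must divide 180")
    h = np.deg2rad(bin_deg)
    centers = (np.arange(n_om) + 0.5) * h

    if method == "closed-form":
        p = closed_form_bulk_density(centers)
    elif method == "lattice":
        p = _lattice_density(bin_deg, n_om, h)
    else:
        raise ValueError(f"unknown method {method!r}")

    with np.errstate(divide="ignore"):
        f = -rt(temperature) * np.log(p)
    f = f - np.min(f[np.isfinite(f)])
    return OrientationPMF(
        omega_grid=centers, f=f, provenance="analytic-bulk", density=p
    )


def _lattice_density(bin_deg: float, n_om: int, h: float) -> np.ndarray:
    """Accumulate the rotation-angle density over the Euler lattice.

    Iterates over the pitch slabs; each lattice cell's Haar weight is shared
    linearly between the two nearest Ω bins (cloud-in-cell), which removes
    the O(h) aliasing of nearest-bin assignment.
    """
    n_phi = int(round(360.0 / bin_deg))
    if not np.isclose(n_phi * bin_deg, 360.0):
        raise ValueError("bin_deg must divide 360")
    phi = (np.arange(n_phi) + 0.5) * h
    pitch = (np.arange(n_om) + 0.5) * h - np.pi / 2
    cp, sp = np.cos(phi / 2), np.sin(phi / 2)
    hist = np.zeros(n_om)
    for t in pitch:
        c = np.outer(cp, cp) * np.cos(t / 2) + np.outer(sp, sp) * np.sin(t / 2)
        om = 2.0 * np.arccos(np.clip(np.abs(c), 0.0, 1.0))
        u = om / h - 0.5
        base = np.floor(u)
        frac = u - base
        i0 = np.clip(base.astype(np.int64), 0, n_om - 1).ravel()
        i1 = np.clip(i0 + 1, 0, n_om - 1)
        w = np.cos(t)  # Haar weight of the pitch slab
        hist += w * np.bincount(i0, weights=(1 - frac).ravel(), minlength=n_om)
        hist += w * np.bincount(i1, weights=frac.ravel(), minlength=n_om)
    return hist / (hist.sum() * h)


def restraint_average_from_pmf(
    pmf: OrientationPMF | PMFProfile,
    k: float,
    temperature: float,
) -> float:
    """Boltzmann average of the restraint factor under a 1-D PMF:

        <exp(-k ζ²/2RT)> = ∫ e^{-(F(ζ) + k ζ²/2)/RT} dζ / ∫ e^{-F(ζ)/RT} dζ

    by trapezoidal quadrature on the PMF's own grid, evaluated in log space.
    k = 0 returns exactly 1.  k is in kcal/mol per (CV unit)².
    """
    if k < 0:
        raise ValueError("force constant must be nonnegative")
    grid, f = _grid_and_f(pmf)
    if len(grid) < 2:
        raise ValueError("PMF grid too small for quadrature")
    if k == 0:
        return 1.0
    rt_ = rt(temperature)
    bias = 0.5 * k * grid**2
    # trapezoid weights on a possibly non-uniform grid
    dw = np.zeros(len(grid))
    dg = np.diff(grid)
    dw[:-1] += 0.5 * dg
    dw[1:] += 0.5 * dg
    log_dw = np.log(dw)
    log_num = logsumexp(log_dw - (f + bias) / rt_)
    log_den = logsumexp(log_dw - f / rt_)
    if not np.isfinite(log_num):
        raise ValueError(
            "restrained average underflows to zero; use a finer PMF grid"
        )
    return float(np.exp(log_num - log_den))


def _grid_and_f(pmf: OrientationPMF | PMFProfile) -> tuple[np.ndarray, np.ndarray]:
    """Extract (grid, finite F) from either PMF type, dropping unoccupied or
    infinite points."""
    if isinstance(pmf, OrientationPMF):
        grid, f = pmf.omega_grid, pmf.f
        mask = np.isfinite(f)
    elif isinstance(pmf, PMFProfile):
        grid, f = pmf.bin_centers, pmf.pmf
        mask = pmf.occupied & np.isfinite(f)
    else:
        raise TypeError(f"unsupported PMF type {type(pmf)!r}")
    if not np.any(mask):
        raise ValueError("PMF has no occupied points")
    return grid[mask], f[mask]
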