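"""Synthetic data: Metropolis samplers on analytic toy potentials under
harmonic biases, plus quadrature oracles for true PMFs, pocket volumes and
binding free energies.

The toy binding system is a Gaussian attractive pocket for a "ligand" point
particle at position x (Å) with an optional internal angle ω in [0, π]
coupled to the pocket:

    U(x, ω) = -ε exp(-|x|²/2σ²) + ½ κ_Ω exp(-|x|²/2σ²) ω²

The angle has a flat base measure on [0, π], so its bulk PMF is exactly
flat and every downstream quantity (grid PMF, pocket volume, restraint
corrections, ΔG°) has a one-dimensional quadrature oracle.  Umbrella windows
bias the pocket distance d = |x| exactly as distance-based umbrella sampling
would; an always-on harmonic restraint on ω emulates the restrained
protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .constants import STANDARD_VOLUME_A3, rt
from .io_cv import BiasSpec, CVTrajectory, WindowConfig
from .pmf import PMFProfile


@dataclass
class ToyPotential:
    """Analytic potential over named coordinates with optional derived CVs.

    ``energy`` maps a coordinate vector (ordered as ``coords``) to kcal/mol.
    ``reflect`` gives reflecting boundaries for bounded coordinates (e.g.
    the angle ω on [0, π]).  ``derived`` adds read-only CVs computed from
    the coordinates (e.g. the pocket distance d).
    """

    name: str
    coords: list[str]
    energy: Callable[[np.ndarray], float]
    derived: dict[str, Callable[[np.ndarray], float]] = field(default_factory=dict)
    reflect: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def cvs(self) -> list[str]:
        return self.coords + list(self.derived)

    def record(self, x: np.ndarray) -> list[float]:
        return list(x) + [f(x) for f in self.derived.values()]


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


def sample_metropolis(
    potential: ToyPotential,
    biases: list[BiasSpec],
    temperature: float,
    n_samples: int,
    step_size: float | dict[str, float] = 0.5,
    seed: int = 0,
    burn_in: int = 300,
    x0: np.ndarray | None = None,
    window_id: str = "w00",
) -> CVTrajectory:
    """Metropolis chain targeting exp(-β (U₀ + Σ biases)).

    Free coordinates are updated jointly with Gaussian proposals; each
    reflected coordinate gets its own single-coordinate move per sweep so a
    stiff restraint on one coordinate cannot freeze the others.  Biases may
    act on coordinates or derived CVs.  A warning is issued when an
    acceptance rate falls outside (0.05, 0.95).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    steps = (
        {c: float(step_size) for c in potential.coords}
        if np.isscalar(step_size)
        else dict(step_size)
    )
    for c in potential.coords:
        if steps.get(c, 0) <= 0:
            raise ValueError(f"step size for coordinate {c!r} must be positive")
    beta = 1.0 / rt(temperature)
    rng = np.random.default_rng(seed)
    cv_names = potential.cvs
    cv_pos = {name: i for i, name in enumerate(cv_names)}
    bias_list = [(cv_pos[b.cv], b) for b in biases]

    free = [i for i, c in enumerate(potential.coords) if c not in potential.reflect]
    bounded = [
        (i, potential.reflect[c]) for i, c in enumerate(potential.coords)
        if c in potential.reflect
    ]
    sigma_free = np.array([steps[potential.coords[i]] for i in free])

    def total_energy(x: np.ndarray) -> float:
        rec = potential.record(x)
        e = potential.energy(x)
        for pos, b in bias_list:
            e += b.energy(rec[pos])
        return e

    x = np.zeros(len(potential.coords)) if x0 is None else np.array(x0, dtype=float)
    for i, (lo, hi) in bounded:
        x[i] = _reflect(x[i], lo, hi)
    e = total_energy(x)
    n_total = burn_in + n_samples
    out = np.empty((n_samples, len(cv_names)))
    acc_free = 0
    acc_bounded = np.zeros(len(bounded), dtype=int)

    prop_free = rng.standard_normal((n_total, len(free))) * sigma_free
    prop_b = rng.standard_normal((n_total, len(bounded)))
    u_free = rng.random(n_total)
    u_b = rng.random((n_total, len(bounded)))

    for t in range(n_total):
        if free:
            xn = x.copy()
            xn[free] += prop_free[t]
            en = total_energy(xn)
            if en - e <= 0 or u_free[t] < np.exp(-beta * (en - e)):
                x, e = xn, en
                acc_free += 1
        for j, (i, (lo, hi)) in enumerate(bounded):
            xn = x.copy()
            xn[i] = _reflect(x[i] + prop_b[t, j] * steps[potential.coords[i]], lo, hi)
            en = total_energy(xn)
            if en - e <= 0 or u_b[t, j] < np.exp(-beta * (en - e)):
                x, e = xn, en
                acc_bounded[j] += 1
        if t >= burn_in:
            out[t - burn_in] = potential.record(x)

    rates = ([acc_free / n_total] if free else []) + list(acc_bounded / n_total)
    for rate in rates:
        if not 0.05 < rate < 0.95:
            warnings.warn(
                f"Metropolis acceptance rate {rate:.3f} outside (0.05, 0.95); "
                "consider retuning step_size"
            )
    return CVTrajectory(
        window_id=window_id,
        steps=np.arange(n_samples, dtype=np.int64),
        values=pd.DataFrame(out, columns=cv_names),
    )


@dataclass
class OracleResult:
    """Quadrature ground truth for a toy binding system."""

    true_pmf_grid: np.ndarray         # |x| grid, Å
    true_pmf: np.ndarray              # ΔG(|x|), kcal/mol
    true_dg_bulk: float               # ΔG(x_B), kcal/mol (positive for binder)
    true_v_pocket: float              # Å^3
    true_dg0: float                   # kcal/mol
    quadrature_resolution: float      # radial grid spacing, Å
    dg0_refinement_change: float      # |Δ dg0| under 2x refinement


@dataclass
class ToyBindingSystem:
    potential: ToyPotential
    oracle: OracleResult
    well_depth: float
    pocket_width: float
    box_side: float
    orientation_coupling: float
    temperature: float
    pocket_radius: float

    def bulk_angle_pmf(self, n: int = 512) -> PMFProfile:
        """Exact (flat) bulk PMF of the toy angle on [0, π]."""
        grid = (np.arange(n) + 0.5) * np.pi / n
        return PMFProfile(
            cv="omega",
            bin_centers=grid,
            pmf=np.zeros(n),
            occupied=np.ones(n, dtype=bool),
            temperature=self.temperature,
        )


def _radial_free_energy(
    r: np.ndarray | float,
    eps: float,
    sigma: float,
    kappa_omega: float,
    temperature: float,
) -> np.ndarray:
    """G(|x|) of the toy system with the angle integrated out."""
    rt_ = rt(temperature)
    g = np.exp(-np.square(r) / (2 * sigma**2))
    if kappa_omega == 0.0:
        return -eps * g
    gs = np.atleast_1d(g)
    z = np.array(
        [
            quad(lambda w, kk=kappa_omega * gi: np.exp(-0.5 * kk * w * w / rt_),
                 0.0, np.pi, epsabs=1e-12, epsrel=1e-12)[0]
            for gi in gs
        ]
    )
    out = -eps * gs - rt_ * np.log(z / np.pi)  # normalized so G -> 0 in bulk
    return out if np.ndim(r) else float(out[0])


def toy_binding_system(
    well_depth: float = 10.0,
    pocket_width: float = 2.0,
    box_side: float = 30.0,
    orientation_coupling: float = 0.0,
    temperature: float = 300.0,
    pocket_radius: float | None = None,
    oracle_resolution: float = 0.01,
) -> ToyBindingSystem:
    """Gaussian-pocket toy binding system with its quadrature oracle.

    The oracle evaluates ΔG(|x|), the Boltzmann pocket volume V_P over
    r <= pocket_radius and the absolute binding free energy

        ΔG° = -ΔG(x_B) - RT ln(V_P / V_B)

    by radial quadrature, and reports how much ΔG° moves under a 2x
    refinement of the radial grid.  With well_depth = 0 the grid PMF is
    identically 0 and ΔG° reduces to the pure volume term for the nominal
    pocket region.
    """
    eps, sigma, L = well_depth, pocket_width, box_side
    if eps < 0 or sigma <= 0:
        raise ValueError("need well_depth >= 0 and pocket_width > 0")
    rt_ = rt(temperature)
    # bulk flatness check at |x| = L/2
    u_edge = abs(
        _radial_free_energy(L / 2, eps, sigma, orientation_coupling, temperature)
    )
    if u_edge > 1e-3 * rt_:
        raise ValueError(
            f"box_side {L} too small: |U| at |x|=L/2 is {u_edge:.2e} kcal/mol "
            f"(> 1e-3 RT); the bulk region is not flat"
        )
    if pocket_radius is None:
        pocket_radius = L / 4

    def dg0_at(h: float) -> tuple[np.ndarray, np.ndarray, float, float, float]:
        r = np.arange(0.0, pocket_radius + h, h)
        dg = _radial_free_energy(r, eps, sigma, orientation_coupling, temperature)
        dg = dg - dg[0]
        dg_bulk = float(
            _radial_free_energy(L / 2, eps, sigma, orientation_coupling, temperature)
            - _radial_free_energy(0.0, eps, sigma, orientation_coupling, temperature)
        )
        integrand = 4 * np.pi * r**2 * np.exp(-dg / rt_)
        v_pocket = float(np.trapezoid(integrand, r))
        dg0 = -dg_bulk - rt_ * np.log(v_pocket / STANDARD_VOLUME_A3)
        return r, dg, dg_bulk, v_pocket, dg0

    h = oracle_resolution
    r, dg, dg_bulk, v_pocket, dg0 = dg0_at(h)
    _, _, _, _, dg0_fine = dg0_at(h / 2)

    oracle = OracleResult(
        true_pmf_grid=r,
        true_pmf=dg,
        true_dg_bulk=dg_bulk,
        true_v_pocket=v_pocket,
        true_dg0=dg0_fine,
        quadrature_resolution=h / 2,
        dg0_refinement_change=abs(dg0_fine - dg0),
    )

    two_sigma_sq = 2 * sigma**2
    kom = orientation_coupling

    if kom > 0.0:
        coords = ["x", "y", "z", "omega"]

        def energy(v: np.ndarray) -> float:
            g = np.exp(-(v[0] ** 2 + v[1] ** 2 + v[2] ** 2) / two_sigma_sq)
            return -eps * g + 0.5 * kom * g * v[3] ** 2

        reflect = {"omega": (0.0, np.pi)}
    else:
        coords = ["x", "y", "z"]

        def energy(v: np.ndarray) -> float:
            return -eps * np.exp(-(v[0] ** 2 + v[1] ** 2 + v[2] ** 2) / two_sigma_sq)

        reflect = {}

    potential = ToyPotential(
        name="gaussian-pocket",
        coords=coords,
        energy=energy,
        derived={"d": lambda v: float(np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2))},
        reflect=reflect,
    )
    return ToyBindingSystem(
        potential=potential,
        oracle=oracle,
        well_depth=eps,
        pocket_width=sigma,
        box_side=L,
        orientation_coupling=kom,
        temperature=temperature,
        pocket_radius=pocket_radius,
    )


def harmonic_potential(kappa: float = 1.0, n_dim: int = 1) -> ToyPotential:
    """Isotropic harmonic well ½ κ |x|² (test workhorse)."""
    coords = ["x", "y", "z"][:n_dim]
    return ToyPotential(
        name="harmonic",
        coords=coords,
        energy=lambda v: 0.5 * kappa * float(np.dot(v, v)),
    )


def distance_window_config(
    n_windows: int = 31,
    d_min: float = 0.0,
    d_max: float = 15.0,
    force_constant: float = 2.0,
    temperature: float = 300.0,
) -> WindowConfig:
    """Umbrella windows with equally spaced harmonic centers on d = |x|."""
    centers = np.linspace(d_min, d_max, n_windows)
    windows = [
        (f"w{i:02d}", [BiasSpec(cv="d", center=float(c), force_constant=force_constant)])
        for i, c in enumerate(centers)
    ]
    return WindowConfig(windows=windows, temperature=temperature, declared_cvs=["d"])
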