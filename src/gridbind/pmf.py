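"""PMF construction from weighted samples by nearest-bin weighted histograms.

G(zeta_i) = -RT ln sum_k w_k [zeta(r_k) nearest to zeta_i]

covering 1-D profiles over a scalar CV, the 3-D grid PMF over ligand
position voxels, and radial shell averages of a grid PMF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import rt


@dataclass
class PMFProfile:
    """1-D PMF over a scalar CV, min-shifted to zero over occupied bins."""

    cv: str
    bin_centers: np.ndarray
    pmf: np.ndarray              # kcal/mol; NaN on unoccupied bins
    occupied: np.ndarray         # bool per bin
    stderr: np.ndarray | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.pmf = np.asarray(self.pmf, dtype=float)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin centers must be strictly increasing")


@dataclass
class GridPMF:
    """3-D binned ligand-position PMF relative to the lowest-PMF voxel.

    ``indices`` are integer voxel offsets from the origin voxel (the voxel
    with the lowest PMF), so ΔG at offset (0,0,0) is exactly 0 and all
    entries are >= 0 at construction time.  ``origin_index`` keeps the
    absolute lattice index of the origin voxel so grids at different voxel
    sizes can be aligned.
    """

    voxel_size: float
    indices: np.ndarray          # (M, 3) int offsets from the origin voxel
    dg: np.ndarray               # (M,) kcal/mol
    temperature: float
    origin_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.dg = np.asarray(self.dg, dtype=float)
        if self.indices.shape != (len(self.dg), 3):
            raise ValueError("indices must be (M, 3) matching dg")

    @property
    def n_voxels(self) -> int:
        return len(self.dg)

    def radii(self) -> np.ndarray:
        """Distance |x| of each voxel center from the origin voxel center."""
        return np.linalg.norm(self.indices * self.voxel_size, axis=1)


@dataclass
class RadialProfile:
    shell_centers: np.ndarray
    mean_pmf: np.ndarray
    sd_pmf: np.ndarray
    n_voxels: np.ndarray


def nearest_bin_indices(values: np.ndarray, bin_centers: np.ndarray) -> np.ndarray:
    """Assign each value to the nearest bin center; exact ties go to the
    lower-index bin."""
    midpoints = 0.5 * (bin_centers[:-1] + bin_centers[1:])
    # side='left': a value exactly on a midpoint sorts before it -> lower bin
    return np.searchsorted(midpoints, values, side="left")


def weighted_pmf(
    weights: np.ndarray,
    cv_values: np.ndarray,
    bins: np.ndarray,
    temperature: float,
    cv: str = "cv",
) -> PMFProfile:
    """Nearest-bin weighted histogram PMF, min-shifted to 0.

    Unoccupied bins (zero accumulated weight) are flagged, with NaN PMF.
    """
    weights = np.asarray(weights, dtype=float)
    cv_values = np.asarray(cv_values, dtype=float)
    bins = np.asarray(bins, dtype=float)
    if weights.shape != cv_values.shape:
        raise ValueError("weights and cv_values must have the same shape")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    idx = nearest_bin_indices(cv_values, bins)
    acc = np.bincount(idx, weights=weights, minlength=len(bins))
    occupied = acc > 0
    pmf = np.full(len(bins), np.nan)
    with np.errstate(divide="ignore"):
        pmf[occupied] = -rt(temperature) * np.log(acc[occupied] / total)
    pmf[occupied] -= pmf[occupied].min()
    return PMFProfile(
        cv=cv, bin_centers=bins, pmf=pmf, occupied=occupied, temperature=temperature
    )


def grid_pmf(
    weights: np.ndarray,
    positions: np.ndarray,
    voxel_size: float,
    temperature: float,
) -> GridPMF:
    """Bin weighted samples on a regular 3-D lattice and return the PMF
    relative to the minimum-PMF voxel.

    Voxel v contains positions with floor(x / voxel_size) == v, so the
    lattice is anchored at the coordinate origin and refinements by integer
    factors nest exactly.
    """
    weights = np.asarray(weights, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be (N, 3)")
    if len(weights) != len(positions):
        raise ValueError("weights and positions must match")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    if weights.sum() <= 0:
        raise ValueError("total weight is zero")
    vidx = np.floor(positions / voxel_size).astype(np.int64)
    # pack the triple into one int64 key: far faster than unique(axis=0)
    lo = vidx.min(axis=0)
    span = vidx.max(axis=0) - lo + 1
    key = ((vidx[:, 0] - lo[0]) * span[1] + (vidx[:, 1] - lo[1])) * span[2] + (
        vidx[:, 2] - lo[2]
    )
    uniq_key, inverse = np.unique(key, return_inverse=True)
    kz = uniq_key % span[2]
    kxy = uniq_key // span[2]
    uniq = np.column_stack((kxy // span[1], kxy % span[1], kz)) + lo
    acc = np.bincount(inverse, weights=weights, minlength=len(uniq))
    keep = acc > 0
    uniq, acc = uniq[keep], acc[keep]
    i0 = int(np.argmax(acc))
    dg = -rt(temperature) * np.log(acc / acc[i0])
    return GridPMF(
        voxel_size=float(voxel_size),
        indices=uniq - uniq[i0],
        dg=dg,
        temperature=temperature,
        origin_index=uniq[i0].copy(),
    )


def coarsen_grid(grid: GridPMF, factor: int = 2) -> GridPMF:
    """Re-bin a grid PMF onto a ``factor``-times coarser lattice by
    Boltzmann-summing voxel probabilities (exact refinement consistency)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    beta = 1.0 / rt(grid.temperature)
    origin = grid.origin_index if grid.origin_index is not None else np.zeros(3, np.int64)
    absolute = grid.indices + origin
    coarse_idx = np.floor_divide(absolute, factor)
    uniq, inverse = np.unique(coarse_idx, axis=0, return_inverse=True)
    prob = np.bincount(inverse, weights=np.exp(-beta * grid.dg), minlength=len(uniq))
    i0 = int(np.argmax(prob))
    dg = -rt(grid.temperature) * np.log(prob / prob[i0])
    return GridPMF(
        voxel_size=grid.voxel_size * factor,
        indices=uniq - uniq[i0],
        dg=dg,
        temperature=grid.temperature,
        origin_index=uniq[i0].copy(),
    )


def radial_profile(grid: GridPMF, shell_width: float = 1.0) -> RadialProfile:
    """Group voxels into spherical shells of |x| and average their PMFs.

    Error bars are the population standard deviation over the voxels in the
    shell (zero for single-voxel shells).
    """
    if shell_width <= 0:
        raise ValueError("shell_width must be positive")
    if grid.n_voxels == 0:
        raise ValueError("empty grid")
    r = grid.radii()
    shell = np.floor(r / shell_width).astype(np.int64)
    order = np.unique(shell)
    centers, means, sds, counts = [], [], [], []
    for s in order:
        vals = grid.dg[shell == s]
        centers.append((s + 0.5) * shell_width)
        means.append(vals.mean())
        sds.append(vals.std())  # population sd
        counts.append(len(vals))
    return RadialProfile(
        shell_centers=np.asarray(centers),
        mean_pmf=np.asarray(means),
        sd_pmf=np.asarray(sds),
        n_voxels=np.asarray(counts),
    )


def bulk_level(grid: GridPMF, r_min: float, r_max: float) -> float:
    """PMF offset of the bulk plateau relative to the origin voxel.

    Computed as -RT ln of the average voxel probability over the spherical
    shell r_min <= |x| < r_max, where the average divides by the *geometric*
    voxel count of the shell (empty voxels count as zero), so sparse
    coverage of the bulk does not bias the estimate upward.
    """
    if not 0 <= r_min < r_max:
        raise ValueError("need 0 <= r_min < r_max")
    beta = 1.0 / rt(grid.temperature)
    r = grid.radii()
    in_shell = (r >= r_min) & (r < r_max)
    if not np.any(in_shell):
        raise ValueError("no occupied voxels in the requested bulk shell")
    shell_weight = np.exp(-beta * grid.dg[in_shell]).sum()
    m = int(np.ceil(r_max / grid.voxel_size)) + 1
    ax = np.arange(-m, m + 1)
    lattice = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
    rg = np.linalg.norm(lattice * grid.voxel_size, axis=1)
    n_geom = int(np.count_nonzero((rg >= r_min) & (rg < r_max)))
    return float(-rt(grid.temperature) * np.log(shell_weight / n_geom))
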