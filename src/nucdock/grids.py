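"""Grid digitization and FFT-based translational search.

Both molecules are digitized onto regular cubic grids.  The receptor grid
carries a negative core penalty inside the molecular core and a soft surface
field (kernel-smoothed, capped at 1) around the surface; the ligand grid is a
binary occupancy mask.  The shape-complementarity score of a translation is
the grid correlation sum(R[g] * L[g - t]), evaluated for all placements of
the ligand box inside the receptor box via zero-padded FFT correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage, signal

from nucdock.config import DockConfig
from nucdock.errors import ContractViolation, GridSizeError
from nucdock.structures import Structure


@dataclass
class GridMap:
    """Regular 3D scalar field over a molecule's padded bounding box."""

    origin: np.ndarray  # (3,) A
    spacing: float
    values: np.ndarray  # (nx, ny, nz)
    role: str  # "receptor" | "ligand"

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def cell_center(self, index: np.ndarray) -> np.ndarray:
        """Cartesian center of integer cell index/indices."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass(frozen=True)
class TranslationHit:
    offset: tuple[int, int, int]  # grid units along (x, y, z)
    shape_score: float


def _occupancy(coords: np.ndarray, origin: np.ndarray, dims: tuple[int, int, int],
               spacing: float, r_occ: float) -> np.ndarray:
    """Boolean grid: cell center within r_occ of any atom center."""
    occ = np.zeros(dims, dtype=bool)
    frac = (coords - origin) / spacing  # fractional cell index per atom
    reach = int(np.ceil(r_occ / spacing)) + 1
    rng = np.arange(-reach, reach + 1)
    di, dj, dk = np.meshgrid(rng, rng, rng, indexing="ij")
    stencil = np.stack([di.ravel(), dj.ravel(), dk.ravel()], axis=1)  # (m, 3)
    r2 = (r_occ / spacing) ** 2
    base = np.round(frac).astype(int)
    cells = base[:, None, :] + stencil[None, :, :]  # (n_atoms, m, 3)
    d2 = ((cells - frac[:, None, :]) ** 2).sum(axis=2)
    hits = cells[d2 <= r2]
    inside = np.all((hits >= 0) & (hits < np.array(dims)), axis=1)
    hits = hits[inside]
    occ[hits[:, 0], hits[:, 1], hits[:, 2]] = True
    return occ


def _kernel_stencil(kernel: str, cutoff_spacings: float) -> np.ndarray:
    """Weight stencil over integer cell offsets within the cutoff."""
    reach = int(np.floor(cutoff_spacings))
    rng = np.arange(-reach, reach + 1)
    di, dj, dk = np.meshgrid(rng, rng, rng, indexing="ij")
    r = np.sqrt(di**2 + dj**2 + dk**2)  # distance in grid spacings
    if kernel == "gaussian":
        w = np.exp(-(r**2))
    elif kernel == "paper_literal":
        # literal printed form e^(-1/r^2); zero at r = 0 by its own limit
        with np.errstate(divide="ignore"):
            w = np.where(r > 0, np.exp(-1.0 / np.where(r > 0, r, 1.0) ** 2), 0.0)
    else:
        raise ContractViolation(f"unknown kernel {kernel!r}")
    w[r > cutoff_spacings] = 0.0
    return w


def digitize(
    s: Structure,
    spacing: float = 1.2,
    padding: float = 0.0,
    role: str = "receptor",
    **kwargs,
) -> GridMap:
    """Digitize a structure onto a regular grid.

    Receptor role: fully buried occupied cells ("core", all 26 neighbors
    occupied) are set to ``core_penalty``; every other cell receives the soft
    surface value ``min(1, sum_c w(d(g, c)))`` over occupied surface cells c
    within the kernel cutoff.  Ligand role: binary occupancy.
    """
    coords = s.coords()
    if len(coords) == 0:
        raise ContractViolation("cannot digitize an empty structure")
    return digitize_coords(coords, spacing=spacing, padding=padding,
                           role=role, **kwargs)


def digitize_coords(
    coords: np.ndarray,
    spacing: float = 1.2,
    padding: float = 0.0,
    role: str = "receptor",
    r_occ: float = 2.6,
    core_penalty: float = -15.0,
    kernel: str = "gaussian",
    kernel_cutoff: float = 2.0,
    max_cells: int = 256**3,
) -> GridMap:
    """Coordinate-array form of :func:`digitize` (hot path of the driver)."""
    if role not in ("receptor", "ligand"):
        raise ContractViolation(f"role must be receptor|ligand, got {role!r}")
    if spacing <= 0:
        raise ContractViolation("spacing must be positive")
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        raise ContractViolation("cannot digitize an empty coordinate set")

    lo = coords.min(axis=0) - padding - r_occ
    hi = coords.max(axis=0) + padding + r_occ
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) + 1 for a in range(3))
    n_cells = int(np.prod(dims))
    if n_cells > max_cells:
        raise GridSizeError(
            f"grid of {dims} = {n_cells} cells exceeds max {max_cells}; "
            f"increase the grid spacing"
        )
    origin = lo

    occ = _occupancy(coords, origin, dims, spacing, r_occ)
    if role == "ligand":
        return GridMap(origin=origin, spacing=spacing,
                       values=occ.astype(float), role=role)

    occ8 = occ.astype(np.uint8)
    core = occ & (
        ndimage.minimum_filter(occ8, size=3, mode="constant", cval=0) == 1
    )
    surface = occ & ~core
    stencil = _kernel_stencil(kernel, kernel_cutoff)
    soft = ndimage.convolve(surface.astype(float), stencil,
                            mode="constant", cval=0.0)
    values = np.minimum(soft, 1.0)
    values[core] = core_penalty
    return GridMap(origin=origin, spacing=spacing, values=values, role=role)


def _check_compatible(receptor_grid: GridMap, ligand_grid: GridMap) -> None:
    if abs(receptor_grid.spacing - ligand_grid.spacing) > 1e-12:
        raise ContractViolation(
            f"grid spacing mismatch: {receptor_grid.spacing} vs "
            f"{ligand_grid.spacing}"
        )
    if any(l > r for l, r in zip(ligand_grid.dims, receptor_grid.dims)):
        raise ContractViolation(
            f"ligand grid {ligand_grid.dims} larger than receptor grid "
            f"{receptor_grid.dims}"
        )


def fft_translation_scan(receptor_grid: GridMap, ligand_grid: GridMap) -> np.ndarray:
    """Correlation score field over all in-box integer translations.

    ``out[t] = sum_g R[g] * L[g - t]`` for offsets ``t`` keeping the ligand
    box inside the receptor box; shape ``Nr - Nl + 1`` per axis.
    """
    _check_compatible(receptor_grid, ligand_grid)
    lig_rev = ligand_grid.values[::-1, ::-1, ::-1]
    return signal.fftconvolve(receptor_grid.values, lig_rev, mode="valid")


class TranslationScanner:
    """FFT scanner with the receptor transform precomputed once.

    Numerically equivalent to :func:`fft_translation_scan`; avoids repeating
    the receptor FFT across the thousands of per-rotation ligand scans.
    ``max_ligand_dim`` bounds the ligand grid size over all rotations.
    """

    def __init__(self, receptor_grid: GridMap, max_ligand_dim: int):
        self.receptor_grid = receptor_grid
        nr = receptor_grid.dims
        self._full = tuple(
            sp_fft.next_fast_len(nr[a] + max_ligand_dim - 1, real=True)
            for a in range(3)
        )
        self._rf = sp_fft.rfftn(receptor_grid.values, s=self._full)

    def scan(self, ligand_grid: GridMap) -> np.ndarray:
        _check_compatible(self.receptor_grid, ligand_grid)
        nl = ligand_grid.dims
        nr = self.receptor_grid.dims
        lf = sp_fft.rfftn(ligand_grid.values[::-1, ::-1, ::-1], s=self._full)
        conv = sp_fft.irfftn(self._rf * lf, s=self._full)
        return conv[
            nl[0] - 1 : nr[0],
            nl[1] - 1 : nr[1],
            nl[2] - 1 : nr[2],
        ].copy()


def direct_translation_scan(receptor_grid: GridMap, ligand_grid: GridMap) -> np.ndarray:
    """Brute-force direct-summation reference for the FFT scan (slow)."""
    _check_compatible(receptor_grid, ligand_grid)
    R = receptor_grid.values
    L = ligand_grid.values
    out_dims = tuple(R.shape[a] - L.shape[a] + 1 for a in range(3))
    out = np.zeros(out_dims)
    for i in range(out_dims[0]):
        for j in range(out_dims[1]):
            for k in range(out_dims[2]):
                block = R[i : i + L.shape[0], j : j + L.shape[1], k : k + L.shape[2]]
                out[i, j, k] = float(np.sum(block * L))
    return out


def top_translations(score_field: np.ndarray, k: int = 10) -> list[TranslationHit]:
    """k best offsets, descending score; ties by lexicographic (z, y, x)."""
    if k < 1:
        raise ContractViolation("k must be >= 1")
    scores = score_field.ravel()
    nx, ny, nz = score_field.shape
    ix, iy, iz = np.unravel_index(np.arange(scores.size), score_field.shape)
    # primary: -score; then z, y, x ascending (last lexsort key is primary)
    order = np.lexsort((ix, iy, iz, -scores))
    top = order[:k]
    return [
        TranslationHit(offset=(int(ix[o]), int(iy[o]), int(iz[o])),
                       shape_score=float(scores[o]))
        for o in top
    ]


def grids_from_config(config: DockConfig):
    """Keyword bundle for :func:`digitize` drawn from a DockConfig."""
    return dict(
        spacing=config.spacing,
        r_occ=config.occupancy_radius,
        core_penalty=config.core_penalty,
        kernel=config.kernel,
        kernel_cutoff=config.kernel_cutoff,
        max_cells=config.max_grid_cells,
    )
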