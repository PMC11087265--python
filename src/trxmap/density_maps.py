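"""Electron-density and difference-density map synthesis and statistics.

Maps are Fourier syntheses ``rho(x) = (1/V) sum_hkl F(hkl) exp(-2 pi i h.x)``
evaluated by FFT on a regular grid over one unit cell.  Difference (DED)
maps use difference amplitudes with ground-state phases and omit the (000)
term, so they average to zero over the cell.  The map sigma used for
contouring is the mean of the per-delay rms values of a DED series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.fft import next_fast_len

from ._cell import cell_volume, orth_matrix
from .reflections import DifferenceSet, ReflectionSet

__all__ = [
    "MapGrid",
    "RegionMask",
    "SigmaStats",
    "synthesize_map",
    "map_to_structure_factors",
    "ded_map",
    "map_sigma",
    "region_mask",
    "write_map",
    "read_map",
]

log = logging.getLogger(__name__)


@dataclass
class MapGrid:
    """Real-space density sampled on a regular grid over one unit cell.

    ``values[i, j, k]`` is the density (e Å^-3) at fractional position
    ``(i/nx, j/ny, k/nz)``.
    """

    cell: tuple[float, float, float, float, float, float]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def volume(self) -> float:
        return cell_volume(self.cell)

    def copy(self) -> "MapGrid":
        return MapGrid(self.cell, self.values.copy())

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.values**2)))

    def value_at_frac(self, frac_xyz) -> float:
        """Density at the voxel nearest a fractional position."""
        idx = tuple(
            int(round(float(x) % 1.0 * n)) % n
            for x, n in zip(frac_xyz, self.shape)
        )
        return float(self.values[idx])

    def frac_of_voxel(self, idx) -> tuple[float, float, float]:
        return tuple(i / n for i, n in zip(idx, self.shape))


@dataclass
class RegionMask:
    """Boolean voxel selection within a radius of one or more centers."""

    centers: tuple[tuple[float, float, float], ...]
    radius: float
    mask: np.ndarray  # boolean, same shape as the parent MapGrid

    def __post_init__(self):
        if not self.mask.any():
            raise ValueError("region mask selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SigmaStats:
    """Per-delay rms of DED values and their mean (the contouring sigma)."""

    per_delay_rms: dict[float, float]
    sigma: float


# ---------------------------------------------------------------------------
# Fourier synthesis


def default_shape(cell, dmin: float, samples_per_dmin: float = 3.0):
    """Grid with spacing <= dmin / samples_per_dmin along each axis."""
    a, b, c = cell[:3]
    return tuple(
        next_fast_len(int(np.ceil(samples_per_dmin * edge / dmin)))
        for edge in (a, b, c)
    )


def _fill_recip_grid(hkl, f_complex, shape):
    """Place F(hkl) on an FFT grid with Hermitian completion."""
    nx, ny, nz = shape
    half = np.array([nx, ny, nz]) // 2
    if np.any(np.abs(hkl).max(axis=0) > half):
        log.warning(
            "map grid %s is below the Nyquist rate for the data; "
            "aliasing may occur", shape,
        )
    grid = np.zeros(shape, complex)
    occupied = np.zeros(shape, bool)
    i1, i2, i3 = (hkl[:, 0] % nx, hkl[:, 1] % ny, hkl[:, 2] % nz)
    grid[i1, i2, i3] = f_complex
    occupied[i1, i2, i3] = True
    j1, j2, j3 = ((-hkl[:, 0]) % nx, (-hkl[:, 1]) % ny, (-hkl[:, 2]) % nz)
    free = ~occupied[j1, j2, j3]
    grid[j1[free], j2[free], j3[free]] = np.conj(f_complex[free])
    return grid


def synthesize_map(
    refl: ReflectionSet, shape: tuple[int, int, int] | None = None
) -> MapGrid:
    """Fourier synthesis of a phased reflection set.

    Missing reflections contribute zero.  The reciprocal grid is completed
    to Hermitian symmetry so the synthesized density is exactly real.
    """
    if not refl.has_phases:
        raise ValueError("synthesize_map requires phases")
    if shape is None:
        s = refl.s_array()
        smax = float(s.max())
        dmin = 1.0 / smax if smax > 0 else max(refl.cell[:3])
        shape = default_shape(refl.cell, dmin)
    grid = _fill_recip_grid(refl.hkl, refl.complex_f(), shape)
    rho = np.fft.fftn(grid).real / cell_volume(refl.cell)
    return MapGrid(refl.cell, rho)


def map_to_structure_factors(mapgrid: MapGrid, hkl: np.ndarray) -> np.ndarray:
    """Inverse operation of :func:`synthesize_map`: complex F at given hkl.

    Exact for densities that are band-limited to the grid (always true for
    maps produced by :func:`synthesize_map` on the same shape).
    """
    ft = np.fft.ifftn(mapgrid.values) * mapgrid.volume
    nx, ny, nz = mapgrid.shape
    return ft[hkl[:, 0] % nx, hkl[:, 1] % ny, hkl[:, 2] % nz]


def ded_map(
    diff: DifferenceSet,
    ground_phases: ReflectionSet,
    shape: tuple[int, int, int] | None = None,
) -> MapGrid:
    """Difference electron-density map from difference amplitudes.

    Coefficients are ``dF(hkl) = d|F|(hkl) exp(i phi_ground(hkl))`` (the
    difference-Fourier approximation); the (000) term is omitted, so the map
    has zero mean.  Raises if any difference reflection lacks a ground phase.
    """
    if not ground_phases.has_phases:
        raise ValueError("ground reflection set carries no phases")
    m = diff.data.merge(
        ground_phases.data[["h", "k", "l", "phase"]], on=["h", "k", "l"],
        how="left",
    )
    if m["phase"].isna().any():
        row = m[m["phase"].isna()].iloc[0]
        raise ValueError(
            f"no ground phase for reflection ({row.h} {row.k} {row.l})"
        )
    not000 = ~((m["h"] == 0) & (m["k"] == 0) & (m["l"] == 0))
    m = m[not000]
    refl = ReflectionSet.from_arrays(
        diff.cell,
        m[["h", "k", "l"]].to_numpy(),
        np.abs(m["dF"].to_numpy()),
        phase=np.where(
            m["dF"].to_numpy() >= 0, m["phase"].to_numpy(),
            m["phase"].to_numpy() + np.pi,
        ),
        label="ded",
    )
    return synthesize_map(refl, shape)


def map_sigma(maps: dict[float, MapGrid]) -> SigmaStats:
    """Per-delay rms of a DED-map series and their mean sigma."""
    if not maps:
        raise ValueError("at least one map is required")
    per = {t: m.rms() for t, m in maps.items()}
    return SigmaStats(per, float(np.mean(list(per.values()))))


def region_mask(mapgrid: MapGrid, centers, radius: float) -> RegionMask:
    """Select voxels within ``radius`` Å of any center (minimum image)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = tuple(tuple(float(x) for x in c) for c in np.atleast_2d(centers))
    nx, ny, nz = mapgrid.shape
    fx = np.arange(nx) / nx
    fy = np.arange(ny) / ny
    fz = np.arange(nz) / nz
    orth = orth_matrix(mapgrid.cell)
    mask = np.zeros(mapgrid.shape, bool)
    for c in centers:
        dx = (fx - c[0] + 0.5) % 1.0 - 0.5
        dy = (fy - c[1] + 0.5) % 1.0 - 0.5
        dz = (fz - c[2] + 0.5) % 1.0 - 0.5
        frac = np.stack(
            np.meshgrid(dx, dy, dz, indexing="ij"), axis=-1
        )  # (nx,ny,nz,3)
        cart = frac @ orth.T
        mask |= (cart**2).sum(axis=-1) <= radius**2
    return RegionMask(centers, radius, mask)


# ---------------------------------------------------------------------------
# CCP4/MRC I/O (mode 2, via gemmi)


def write_map(mapgrid: MapGrid, path) -> None:
    grid = gemmi.FloatGrid(np.ascontiguousarray(mapgrid.values, np.float32))
    grid.unit_cell = gemmi.UnitCell(*mapgrid.cell)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> MapGrid:
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read CCP4/MRC map {path.name}: {exc}") from exc
    cell = ccp4.grid.unit_cell
    values = np.array(ccp4.grid, copy=True).astype(float)
    return MapGrid(
        (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma), values
    )
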