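"""SVD decomposition of masked DED time series.

The masked voxels of each delay's difference map form one column of a
voxels-by-delays matrix A.  Its thin SVD ``A = U S V^T`` separates
time-invariant spatial features (left singular vectors), their weights
(singular values) and their time profiles (right singular vectors).
Signal-bearing components are screened by relative singular value and by
the lag-1 autocorrelation of their time profile: smooth kinetics correlate
from delay to delay, noise does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .density_maps import MapGrid, RegionMask

__all__ = ["SVDResult", "assemble_matrix", "svd", "select_components",
           "lag1_autocorr", "reembed"]

log = logging.getLogger(__name__)


@dataclass
class SVDResult:
    lsv: np.ndarray        # (voxels, r)
    sv: np.ndarray         # (r,) descending
    rsv: np.ndarray        # (delays, r)
    autocorr: np.ndarray   # (r,) lag-1 autocorrelation of each RSV
    delays: tuple[float, ...]
    mask: RegionMask | None = None

    def rsv_trace(self, rank: int) -> tuple[np.ndarray, np.ndarray]:
        """(delays, values) of the rank-th component (1-based)."""
        return np.array(self.delays), self.rsv[:, rank - 1]


def assemble_matrix(
    maps: dict[float, MapGrid], mask: RegionMask
) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Stack masked voxels of each delay into a voxels-by-delays matrix.

    Returns ``(matrix, voxel_index, delays)`` where ``voxel_index`` is the
    (n_voxels, 3) array of grid indices allowing exact re-embedding.
    Delays are processed in ascending order.
    """
    delays = tuple(sorted(maps))
    shapes = {maps[t].shape for t in delays}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched shapes: {sorted(shapes)}")
    if next(iter(shapes)) != mask.mask.shape:
        raise ValueError("mask shape does not match the maps")
    voxel_index = np.argwhere(mask.mask)
    matrix = np.column_stack([maps[t].values[mask.mask] for t in delays])
    return matrix, voxel_index, delays


def reembed(
    column: np.ndarray, voxel_index: np.ndarray, cell, shape
) -> MapGrid:
    """Scatter a masked-voxel vector back into a zero-filled map."""
    values = np.zeros(shape)
    values[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = column
    return MapGrid(cell, values)


def lag1_autocorr(x: np.ndarray) -> float:
    """Lag-1 Pearson autocorrelation of a sequence in delay order."""
    x = np.asarray(x, float)
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def svd(
    matrix: np.ndarray,
    delays: tuple[float, ...] | None = None,
    mask: RegionMask | None = None,
) -> SVDResult:
    """Thin SVD with a deterministic sign convention.

    The element of largest magnitude in each left singular vector is made
    positive (ties broken by the first such element); the corresponding
    right singular vector is flipped to preserve the product.
    """
    matrix = np.asarray(matrix, float)
    if not np.isfinite(matrix).all():
        raise ValueError("matrix contains non-finite entries")
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    v = vt.T
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] *= -1
            v[:, j] *= -1
    if delays is None:
        delays = tuple(range(matrix.shape[1]))
    autocorr = np.array([lag1_autocorr(v[:, j]) for j in range(v.shape[1])])
    return SVDResult(u, s, v, autocorr, tuple(delays), mask)


def select_components(
    res: SVDResult, sv_frac_min: float = 0.05, autocorr_min: float = 0.5
) -> list[int]:
    """Ranks (1-based) passing both singular-value and autocorrelation cuts."""
    if res.sv.size == 0 or res.sv[0] == 0:
        log.warning("all singular values are zero; no components selected")
        return []
    picked = [
        j + 1
        for j in range(len(res.sv))
        if res.sv[j] / res.sv[0] >= sv_frac_min and res.autocorr[j] >= autocorr_min
    ]
    if not picked:
        log.warning("no SVD components pass the selection thresholds")
    return picked
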