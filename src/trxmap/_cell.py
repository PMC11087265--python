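"""Unit-cell metric helpers shared across modules."""

from __future__ import annotations

import math

import numpy as np


def orth_matrix(cell) -> np.ndarray:
    """Orthogonalization matrix (fractional -> Cartesian Å), PDB convention."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    cos_al, cos_be, cos_ga = np.cos([al, be, ga])
    sin_ga = np.sin(ga)
    v = math.sqrt(
        1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
    )
    return np.array(
        [
            [a, b * cos_ga, c * cos_be],
            [0.0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
            [0.0, 0.0, c * v / sin_ga],
        ]
    )


def cell_volume(cell) -> float:
    return float(abs(np.linalg.det(orth_matrix(cell))))


def s_of_hkl(cell, hkl) -> np.ndarray:
    """s = 1/d (Å^-1) for an (n, 3) array of Miller indices."""
    frac_mat = np.linalg.inv(orth_matrix(cell))
    return np.linalg.norm(np.atleast_2d(hkl) @ frac_mat, axis=1)
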