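"""Extrapolated structure factors, photoconversion-yield scan, geometry.

A species-associated difference map is turned back into signed difference
amplitudes by Fourier transformation and projection onto the ground-state
phases.  Extrapolated amplitudes are then

    |F|_extr(hkl) = |F|_ground(hkl) + (1/p) d|F|_SA(hkl)

where p is the photoconversion yield.  p is found by scanning: too small a
p over-amplifies the difference term and digs spurious negative density
into the extrapolated map at occupied atom sites, so the chosen p is the
smallest one whose minimum density over a set of probe sites stays above
a (negative) threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_maps import MapGrid, map_to_structure_factors, synthesize_map
from .reflections import DifferenceSet, ReflectionSet
from .toy_crystal import CrystalModel

__all__ = [
    "ExtrapolationResult",
    "GeometryReport",
    "saded_to_delta_amplitudes",
    "extrapolate",
    "scan_p",
    "fe_doming",
    "zr_zr_distance",
    "geometry_report",
]

log = logging.getLogger(__name__)


@dataclass
class ExtrapolationResult:
    """Chosen yield, extrapolated amplitudes, and the p-scan trace."""

    p: float
    extr_amplitudes: ReflectionSet
    criterion_trace: pd.DataFrame  # columns p, min_density
    satisfied: bool
    n_clamped: int


@dataclass
class GeometryReport:
    """Fe doming and Zr-Zr distance of a model, with deltas vs ground."""

    label: str
    fe_doming: float
    zr_zr: float
    delta_doming: float | None = None
    delta_zr_zr: float | None = None


def saded_to_delta_amplitudes(
    saded: MapGrid, ground: ReflectionSet
) -> DifferenceSet:
    """Signed species-associated difference amplitudes from a SADED map.

    The map is Fourier-transformed at the ground set's indices and the
    complex coefficient projected onto the ground-phase direction, giving a
    signed scalar per reflection.  The (000) term (absent from DED maps) is
    reported as zero.
    """
    if not ground.has_phases:
        raise ValueError("ground reflection set must carry phases")
    if tuple(saded.cell) != tuple(ground.cell):
        raise ValueError("SADED map and ground set have different cells")
    hkl = ground.hkl
    f_map = map_to_structure_factors(saded, hkl)
    signed = (f_map * np.exp(-1j * ground.phase)).real
    df = pd.DataFrame(
        {"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "dF": signed}
    )
    return DifferenceSet(ground.cell, df, reference_label="saded")


def extrapolate(
    ground: ReflectionSet, delta_sa: DifferenceSet, p: float
) -> tuple[ReflectionSet, int]:
    """|F|_extr = |F|_ground + (1/p) d|F|_SA; negatives clamped to zero.

    Returns the extrapolated set and the number of clamped reflections.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"photoconversion yield p must be in (0, 1], got {p}")
    m = ground.data.merge(delta_sa.data, on=["h", "k", "l"])
    if m.empty:
        raise ValueError("ground set and difference set share no reflections")
    extr = m["F"].to_numpy() + m["dF"].to_numpy() / p
    n_clamped = int((extr < 0).sum())
    if n_clamped:
        log.info("clamped %d negative extrapolated amplitudes at p=%.3g",
                 n_clamped, p)
    extr = np.clip(extr, 0.0, None)
    phase = m["phase"].to_numpy() if "phase" in m else None
    out = ReflectionSet.from_arrays(
        ground.cell, m[["h", "k", "l"]].to_numpy(), extr, phase=phase,
        label=f"extrapolated(p={p:g})",
    )
    return out, n_clamped


def scan_p(
    ground: ReflectionSet,
    delta_sa: DifferenceSet,
    probe_sites,
    p_grid=None,
    threshold: float | None = None,
    shape=None,
) -> ExtrapolationResult:
    """Scan photoconversion yields; pick the smallest acceptable one.

    For each p (ascending) the extrapolated map is synthesized with ground
    phases and the minimum density over the probe sites recorded.  The
    chosen p is the smallest whose minimum is >= -threshold.  ``threshold``
    defaults to the rms (1 sigma) of each candidate extrapolated map.  If no
    p qualifies, p = 1 is returned with ``satisfied=False``.
    """
    if p_grid is None:
        p_grid = np.round(np.arange(0.05, 1.0001, 0.05), 10)
    p_grid = np.asarray(sorted(p_grid), float)
    if p_grid[0] <= 0 or p_grid[-1] > 1:
        raise ValueError("p_grid values must lie in (0, 1]")
    probe_sites = np.atleast_2d(probe_sites)

    rows = []
    best_p, best_extr, best_clamp = None, None, 0
    for p in p_grid:
        extr, n_clamped = extrapolate(ground, delta_sa, float(p))
        emap = synthesize_map(extr, shape)
        vals = [emap.value_at_frac(site) for site in probe_sites]
        min_density = float(min(vals))
        thr = emap.rms() if threshold is None else float(threshold)
        ok = min_density >= -thr
        rows.append((float(p), min_density, thr, ok))
        if ok and best_p is None:
            best_p, best_extr, best_clamp = float(p), extr, n_clamped
    trace = pd.DataFrame(rows, columns=["p", "min_density", "threshold", "ok"])
    if best_p is None:
        extr, best_clamp = extrapolate(ground, delta_sa, 1.0)
        return ExtrapolationResult(1.0, extr, trace, False, best_clamp)
    return ExtrapolationResult(best_p, best_extr, trace, True, best_clamp)


# ---------------------------------------------------------------------------
# Geometry metrics


def fe_doming(
    model: CrystalModel,
    fe_label: str = "FE",
    plane_labels: tuple[str, str, str, str] = ("N1", "N2", "N3", "N4"),
) -> float:
    """Distance (Å) of the Fe atom from the least-squares plane of 4 sites."""
    orth = model.orth_matrix()
    pts = np.array(
        [orth @ np.array(model.site(lbl).frac_xyz) for lbl in plane_labels]
    )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # plane normal = smallest principal axis of the point cloud
    _, sing, vt = np.linalg.svd(centered)
    if sing[1] < 1e-8 * max(sing[0], 1e-300):
        raise ValueError("plane sites are collinear; no unique plane")
    normal = vt[2]
    fe = orth @ np.array(model.site(fe_label).frac_xyz)
    return float(abs(np.dot(fe - centroid, normal)))


def zr_zr_distance(
    model: CrystalModel, zr_labels: tuple[str, str] = ("ZR1", "ZR2")
) -> float:
    """Minimum-image Cartesian distance between the two Zr disorder sites."""
    a, b = (model.site(lbl) for lbl in zr_labels)
    return model.min_image_distance(a.frac_xyz, b.frac_xyz)


def geometry_report(
    model: CrystalModel, ground: CrystalModel | None = None, **labels
) -> GeometryReport:
    """Fe doming and Zr-Zr metrics for a model, optionally vs a ground state."""
    d = fe_doming(model, **{k: v for k, v in labels.items()
                            if k in ("fe_label", "plane_labels")})
    z = zr_zr_distance(model, **{k: v for k, v in labels.items()
                                 if k in ("zr_labels",)})
    dd = dz = None
    if ground is not None:
        dd = d - fe_doming(ground)
        dz = z - zr_zr_distance(ground)
    return GeometryReport(model.label, d, z, dd, dz)
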