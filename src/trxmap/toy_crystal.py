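"""Synthetic toy crystal: a minimal MOF-like model and its forward simulation.

The package's analysis chain (difference maps, SVD kinetics, global fitting,
species decomposition, extrapolation) is exercised on a small synthetic
crystal that emulates the photophysics of an iron-porphyrin / hexazirconium
MOF after CO photodissociation: an oscillatory species (Fe doming /
Zr-disorder oscillation), a transient CO-dissociated species, and a
vibrationally hot species with inflated displacement parameters.

Everything lives in a primitive orthogonal P1 cell; structure factors are
computed by direct summation with (by default) constant atomic form factors
``f = Z`` so that analytic identities (Friedel symmetry, F(000) electron
count, the phase-shift theorem) hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._cell import orth_matrix, s_of_hkl
from .kinetic_fit import KineticParams
from .reflections import ReflectionSet

__all__ = [
    "AtomSite",
    "CrystalModel",
    "SpeciesSet",
    "DelayGrid",
    "ELEMENT_Z",
    "DEFAULT_DELAYS_PS",
    "NEGATIVE_REFERENCE_PS",
    "default_delay_grid",
    "build_toy_mof",
    "structure_factors",
    "simulate_timeseries",
    "thermal_ded_reference",
]

# Electron counts for the handful of elements the toy model uses.
ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "FE": 26, "ZR": 40}

#: Pump-probe delay grid (ps). 32 delays were enumerated for the published
#: experiment; a 0 ps dataset exists in the deposition list, giving 33 points
#: total. The packaged default includes the 0 ps point.
DEFAULT_DELAYS_PS: tuple[float, ...] = (
    -3.9, -2.4, -0.6, -0.2, 0.0, 0.1, 0.4, 0.6, 0.85, 1.1, 1.35, 1.6, 1.85,
    2.1, 2.35, 2.6, 2.85, 3.1, 3.35, 3.6, 4.1, 5.1, 7.1, 10.1, 17.9, 31.7,
    56.3, 100.0, 178.0, 316.0, 562.0, 1000.0, 3000.0,
)

#: Negative delays averaged into the pre-excitation reference.
NEGATIVE_REFERENCE_PS: tuple[float, ...] = (-3.9, -2.4, -0.6, -0.2)


@dataclass(frozen=True)
class AtomSite:
    """One scatterer: element, fractional position, occupancy, isotropic B.

    ``b_iso`` is the isotropic atomic displacement parameter in Å²; it enters
    the structure factor as ``exp(-B s^2 / 4)`` with ``s = 1/d``.
    """

    label: str
    element: str
    frac_xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 3.0

    def __post_init__(self):
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if self.b_iso < 0:
            raise ValueError(f"b_iso must be >= 0, got {self.b_iso}")
        if self.z_electrons <= 0:
            raise ValueError(f"unknown element {self.element!r}")
        object.__setattr__(
            self, "frac_xyz", tuple(float(x) % 1.0 for x in self.frac_xyz)
        )

    @property
    def z_electrons(self) -> int:
        return ELEMENT_Z.get(self.element.upper(), 0)


@dataclass(frozen=True)
class CrystalModel:
    """A P1 crystal: unit cell (lengths Å, angles deg) plus ordered sites."""

    cell: tuple[float, float, float, float, float, float]
    sites: tuple[AtomSite, ...]
    label: str = ""

    def __post_init__(self):
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0 < ang < 180 for ang in (al, be, ga)):
            raise ValueError("cell angles must lie in (0, 180) degrees")
        object.__setattr__(self, "sites", tuple(self.sites))

    # -- geometry helpers -------------------------------------------------

    def orth_matrix(self) -> np.ndarray:
        """3x3 orthogonalization matrix (fractional -> Cartesian Å)."""
        return orth_matrix(self.cell)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orth_matrix())))

    def site(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(f"no site labelled {label!r} in model {self.label!r}")

    def frac_array(self) -> np.ndarray:
        return np.array([s.frac_xyz for s in self.sites])

    def min_image_distance(self, xyz1, xyz2) -> float:
        """Cartesian distance under the minimum-image convention."""
        d = np.asarray(xyz1, float) - np.asarray(xyz2, float)
        d -= np.round(d)
        return float(np.linalg.norm(self.orth_matrix() @ d))

    def with_sites(self, sites, label=None) -> "CrystalModel":
        return CrystalModel(self.cell, tuple(sites), label or self.label)


@dataclass(frozen=True)
class SpeciesSet:
    """Ground state plus the three photoproduct structures.

    ``i_osc_plus`` / ``i_osc_minus`` are the two turning points of the
    oscillatory species; they differ from ground only by Fe/Zr displacements
    of opposite sign along the doming / d axis.
    """

    ground: CrystalModel
    i_tr: CrystalModel
    i_hot: CrystalModel
    i_osc_plus: CrystalModel
    i_osc_minus: CrystalModel

    def __post_init__(self):
        cells = {m.cell for m in self.members.values()}
        if len(cells) != 1:
            raise ValueError("all species must share the same unit cell")

    @property
    def members(self) -> dict[str, CrystalModel]:
        return {
            "ground": self.ground,
            "i_tr": self.i_tr,
            "i_hot": self.i_hot,
            "i_osc_plus": self.i_osc_plus,
            "i_osc_minus": self.i_osc_minus,
        }


@dataclass(frozen=True)
class DelayGrid:
    """Ordered pump-probe delays (ps) and the negative-delay reference subset."""

    delays: tuple[float, ...]
    negative_reference: tuple[float, ...]

    def __post_init__(self):
        d = tuple(float(x) for x in self.delays)
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("delays must be strictly increasing")
        ref = tuple(float(x) for x in self.negative_reference)
        if not set(ref) <= set(d):
            raise ValueError("negative_reference must be a subset of delays")
        if any(t >= 0 for t in ref):
            raise ValueError("negative_reference delays must all be < 0")
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "negative_reference", ref)


def default_delay_grid() -> DelayGrid:
    return DelayGrid(DEFAULT_DELAYS_PS, NEGATIVE_REFERENCE_PS)


# ---------------------------------------------------------------------------
# Toy model construction


def build_toy_mof(
    cell_edge: float = 20.0,
    doming_ground: float = 0.597,
    doming_tr: float = 0.716,
    doming_hot: float | None = None,
    osc_shift_plus: float = 0.443,
    osc_shift_minus: float = 0.312,
    zrzr_ground: float = 0.841,
    zrzr_tr: float = 0.907,
    zrzr_hot: float = 0.891,
    zrzr_osc_plus: float = 1.057,
    delta_b_hot: float = 5.0,
    clash_min: float = 0.5,
) -> SpeciesSet:
    """Build the toy MOF species set.

    The ground state holds an Fe atom domed below a square of four nitrogens
    (pyrrole-plane proxy), an axial C-O ligand above the plane, and a
    half-occupied Zr disorder pair along the x ("d") axis.  Doming is the
    distance of Fe from the N4 plane; the oscillatory turning points shift Fe
    by ``+osc_shift_plus`` (more domed) and ``-osc_shift_minus`` (less domed)
    from the ground position.  ``i_hot`` carries every B inflated by
    ``delta_b_hot``.  Defaults are the geometry of the published ground /
    photoproduct structures.

    Every site is paired with an inversion-related copy (label suffix
    ``_B``), making the arrangement centrosymmetric: all structure factors
    are real, phases are 0 or pi, and the difference-Fourier approximation
    recovers difference density at full weight — as it does for the real
    (centrosymmetric) crystal.  The code still treats the cell as plain P1.

    Raises ``ValueError`` if a geometry override brings two sites (other than
    the intentional Zr disorder pair) closer than ``clash_min`` Å.
    """
    a = cell_edge
    cell = (a, a, a, 90.0, 90.0, 90.0)

    def frac(x, y, z):
        return (x / a, y / a, z / a)

    # porphyrin assembly centred at 0.3a, Zr pair at (0.75, 0.25, 0.25);
    # their inversion images land far away at 0.7a and (0.25, 0.75, 0.75)
    cx = cy = plane_z = a * 0.3
    ring_r = 2.0  # N-square half-diagonal, Å
    zr_center = np.array([a * 0.75, a * 0.25, a * 0.25])

    def build(name, doming, zr_sep, co_occ=1.0, fe_b=2.0, lig_b=3.0, zr_b=2.0):
        fe_z = plane_z - doming
        c_z = fe_z + 1.85  # Fe-C bond
        o_z = c_z + 1.13  # C-O bond
        half = zr_sep / 2.0
        sites = [
            AtomSite("FE", "Fe", frac(cx, cy, fe_z), 1.0, fe_b),
            AtomSite("N1", "N", frac(cx + ring_r, cy, plane_z), 1.0, lig_b),
            AtomSite("N2", "N", frac(cx - ring_r, cy, plane_z), 1.0, lig_b),
            AtomSite("N3", "N", frac(cx, cy + ring_r, plane_z), 1.0, lig_b),
            AtomSite("N4", "N", frac(cx, cy - ring_r, plane_z), 1.0, lig_b),
            AtomSite("C_CO", "C", frac(cx, cy, c_z), co_occ, lig_b),
            AtomSite("O_CO", "O", frac(cx, cy, o_z), co_occ, lig_b),
            AtomSite(
                "ZR1", "Zr",
                frac(zr_center[0] - half, zr_center[1], zr_center[2]), 0.5, zr_b,
            ),
            AtomSite(
                "ZR2", "Zr",
                frac(zr_center[0] + half, zr_center[1], zr_center[2]), 0.5, zr_b,
            ),
        ]
        sites += [
            replace(
                s,
                label=s.label + "_B",
                frac_xyz=tuple((-x) % 1.0 for x in s.frac_xyz),
            )
            for s in sites
        ]
        return CrystalModel(cell, tuple(sites), label=name)

    ground = build("ground", doming_ground, zrzr_ground)
    i_tr = build("i_tr", doming_tr, zrzr_tr, co_occ=0.0)
    # hot structure: ground-like geometry (doming unchanged by default),
    # slightly widened Zr disorder, all displacement parameters inflated
    if doming_hot is None:
        doming_hot = doming_ground
    i_hot = build("i_hot", doming_hot, zrzr_hot)
    i_hot = i_hot.with_sites(
        [replace(s, b_iso=s.b_iso + delta_b_hot) for s in i_hot.sites], "i_hot"
    )
    # opposite-sign Zr displacement for the two oscillation turning points
    zrzr_osc_minus = max(2 * zrzr_ground - zrzr_osc_plus, 0.05)
    i_osc_plus = build("i_osc_plus", doming_ground + osc_shift_plus, zrzr_osc_plus)
    i_osc_minus = build("i_osc_minus", doming_ground - osc_shift_minus, zrzr_osc_minus)

    species = SpeciesSet(ground, i_tr, i_hot, i_osc_plus, i_osc_minus)
    for model in species.members.values():
        _check_clashes(model, clash_min)
    return species


def _check_clashes(model: CrystalModel, clash_min: float) -> None:
    sites = model.sites
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            # half-occupied same-element pairs are intentional disorder
            if (
                sites[i].element == sites[j].element
                and sites[i].occupancy < 1.0
                and sites[j].occupancy < 1.0
            ):
                continue
            d = model.min_image_distance(sites[i].frac_xyz, sites[j].frac_xyz)
            if d < clash_min:
                raise ValueError(
                    f"sites {sites[i].label} and {sites[j].label} in model "
                    f"{model.label!r} clash: {d:.3f} Å < {clash_min} Å"
                )


# ---------------------------------------------------------------------------
# Structure factors by direct summation


def _hkl_grid(cell, hmax: int, dmin: float) -> tuple[np.ndarray, np.ndarray]:
    """All (h,k,l) with |index| <= hmax and d >= dmin, plus their s = 1/d."""
    rng = np.arange(-hmax, hmax + 1)
    h, k, l = np.meshgrid(rng, rng, rng, indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    s = s_of_hkl(cell, hkl)  # 1/d, with s=0 at the origin
    keep = (s <= 1.0 / dmin) | (s == 0.0)
    return hkl[keep], s[keep]


def structure_factors(
    model: CrystalModel,
    hmax: int = 12,
    dmin: float = 1.6,
    form_factor: str = "constant",
) -> ReflectionSet:
    """Direct-summation structure factors on a full Friedel-complete index box.

    F(hkl) = sum_j o_j f_j(s) exp(-B_j s^2/4) exp(2 pi i (h,k,l).x_j) with
    s = 1/d.  ``form_factor='constant'`` uses f = Z (exact analytic checks);
    ``'gaussian'`` applies a single-Gaussian falloff f = Z exp(-b_el s^2/4)
    with a crude element-width proxy.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    if not model.sites:
        raise ValueError("model has no atom sites")
    hkl, s = _hkl_grid(model.cell, hmax, dmin)
    if len(hkl) <= 1:  # only the (000) term left
        raise ValueError(f"no reflections survive the dmin={dmin} Å cutoff")

    frac = model.frac_array()  # (n_at, 3)
    occ = np.array([site.occupancy for site in model.sites])
    b = np.array([site.b_iso for site in model.sites])
    z = np.array([float(site.z_electrons) for site in model.sites])

    s2 = s**2
    if form_factor == "constant":
        f = z[None, :] * np.ones((len(hkl), 1))
    elif form_factor == "gaussian":
        # single-Gaussian proxy: heavier atoms are more compact
        b_el = 20.0 / np.sqrt(z)
        f = z[None, :] * np.exp(-b_el[None, :] * s2[:, None] / 4.0)
    else:
        raise ValueError(f"unknown form_factor {form_factor!r}")

    debye = np.exp(-b[None, :] * s2[:, None] / 4.0)
    phase = np.exp(2j * np.pi * (hkl @ frac.T))
    fcalc = ((occ[None, :] * f * debye) * phase).sum(axis=1)

    return ReflectionSet.from_arrays(
        cell=model.cell,
        hkl=hkl,
        amplitude=np.abs(fcalc),
        phase=np.angle(fcalc),
        label=model.label or "calc",
    )


# ---------------------------------------------------------------------------
# Time-series simulation


def simulate_timeseries(
    species: SpeciesSet,
    kin: KineticParams,
    grid: DelayGrid,
    excited_fraction: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    peaks: tuple[float, float, float] = (0.25 / 1.45, 0.20 / 1.45, 1.00 / 1.45),
    hmax: int = 12,
    dmin: float = 1.6,
) -> dict[float, ReflectionSet]:
    """Simulate amplitude time series from the three-species kinetic model.

    Per delay t the unit-cell structure factor is the coherent mixture

        F(t) = (1 - e(t)) F_ground + c_tr(t) F_tr + c_hot(t) F_hot
               + c_osc(t) (F_osc_plus - F_osc_minus) / 2

    with e(t) = c_tr(t) + c_hot(t).  The oscillatory species enters as a
    signed population on the half-difference of the two turning-point
    structures (linear response: the lattice swings between the plus and
    minus structures with the damped-cosine profile), so its contribution
    is population-neutral and carries no (000) term.  Peak populations are
    ``excited_fraction * peaks`` for (osc, tr, hot); the default peaks are
    the study's per-species photoconversion yields (0.25, 0.20, 1.00)
    normalized to unit sum so the mixture stays physical.  Amplitudes are
    emitted with multiplicative Gaussian noise of relative standard
    deviation ``noise_sd``, reproducible from ``seed``.
    """
    from .species_maps import species_profiles

    if not 0.0 <= excited_fraction <= 1.0:
        raise ValueError("excited_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    p_osc, p_tr, p_hot = (excited_fraction * p for p in peaks)
    if p_osc + p_tr + p_hot > 1.0 + 1e-12:
        raise ValueError(
            f"sum of peak populations {p_osc + p_tr + p_hot:.3f} exceeds 1 "
            "(over-excitation)"
        )

    fs = {
        name: structure_factors(m, hmax=hmax, dmin=dmin).complex_f()
        for name, m in species.members.items()
    }
    template = structure_factors(species.ground, hmax=hmax, dmin=dmin)

    profiles = species_profiles(kin, grid.delays)
    rng = np.random.default_rng(seed)

    f_osc_diff = 0.5 * (fs["i_osc_plus"] - fs["i_osc_minus"])
    out: dict[float, ReflectionSet] = {}
    for i, t in enumerate(grid.delays):
        c_osc = p_osc * profiles.c_osc[i]
        c_tr = p_tr * profiles.c_tr[i]
        c_hot = p_hot * profiles.c_hot[i]
        e = c_tr + c_hot
        f_mix = (
            (1.0 - e) * fs["ground"]
            + c_tr * fs["i_tr"]
            + c_hot * fs["i_hot"]
            + c_osc * f_osc_diff
        )
        amp = np.abs(f_mix)
        if noise_sd > 0:
            amp = amp * (1.0 + noise_sd * rng.standard_normal(amp.shape))
            amp = np.clip(amp, 0.0, None)
        out[t] = template.with_amplitudes(amp, phase=None, label=f"t={t}ps")
    return out


def write_model_cif(model: CrystalModel, path) -> None:
    """Write a minimal CIF-style description: cell plus an atom-site loop."""
    a, b, c, al, be, ga = model.cell
    lines = [
        f"data_{model.label or 'model'}",
        f"_cell_length_a {a:.4f}",
        f"_cell_length_b {b:.4f}",
        f"_cell_length_c {c:.4f}",
        f"_cell_angle_alpha {al:.3f}",
        f"_cell_angle_beta {be:.3f}",
        f"_cell_angle_gamma {ga:.3f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_B_iso_or_equiv",
    ]
    for s in model.sites:
        x, y, z = s.frac_xyz
        lines.append(
            f"{s.label} {s.element} {x:.6f} {y:.6f} {z:.6f} "
            f"{s.occupancy:.4f} {s.b_iso:.4f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def thermal_ded_reference(
    model: CrystalModel,
    delta_b: float = 5.0,
    gridshape: tuple[int, int, int] | None = None,
    hmax: int = 12,
    dmin: float = 1.6,
):
    """Simulated thermal difference map: ED(B + dB) - ED(B).

    Inflating every isotropic displacement parameter broadens each atomic
    peak while conserving its electron count, so the difference map is
    negative at atom centres and positive in an isotropic shell around them —
    the signature of a vibrationally hot structure.
    """
    from .density_maps import synthesize_map

    if delta_b <= 0:
        raise ValueError("delta_b must be positive")
    hot = model.with_sites(
        [replace(s, b_iso=s.b_iso + delta_b) for s in model.sites], "thermal"
    )
    f_cold = structure_factors(model, hmax=hmax, dmin=dmin)
    f_hot = structure_factors(hot, hmax=hmax, dmin=dmin)
    m_cold = synthesize_map(f_cold, gridshape)
    m_hot = synthesize_map(f_hot, gridshape)
    out = m_hot.copy()
    out.values = m_hot.values - m_cold.values
    return out
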