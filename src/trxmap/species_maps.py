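"""Species time profiles, linear map decomposition, heat-free maps.

The three-species kinetic model assigns each photoproduct a fixed spatial
difference signature (its species-associated difference map, SADED) and a
known time profile: a damped cosine for the oscillatory species, an
instantaneously formed exponential decay for the transient species, and a
biexponential rise to a plateau for the vibrationally hot species — all
convolved with the Gaussian IRF.  Given those profiles, the per-voxel time
series of the DED maps is decomposed by linear least squares into the three
SADED maps; removing the hot contribution yields heat-free maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density_maps import MapGrid
from .kinetic_fit import (
    KineticParams,
    conv_biexp_rise,
    conv_damped_cos,
    conv_exp,
)

__all__ = ["SpeciesProfiles", "SpeciesDecomposition", "species_profiles",
           "decompose", "heat_free"]

SPECIES = ("osc", "tr", "hot")


@dataclass
class SpeciesProfiles:
    """Dimensionless time profiles of the three species on a delay grid.

    ``c_osc`` is signed (oscillation about zero) with unit peak magnitude;
    ``c_tr`` has unit peak; ``c_hot`` rises to a unit plateau.
    """

    delays: tuple[float, ...]
    c_osc: np.ndarray
    c_tr: np.ndarray
    c_hot: np.ndarray

    def matrix(self, species=SPECIES) -> np.ndarray:
        """(delays, n_species) design matrix in the given species order."""
        cols = {"osc": self.c_osc, "tr": self.c_tr, "hot": self.c_hot}
        return np.column_stack([cols[s] for s in species])


@dataclass
class SpeciesDecomposition:
    """SADED maps, their profiles, and fitted per-delay amplitudes."""

    saded: dict[str, MapGrid]
    profiles: SpeciesProfiles
    species: tuple[str, ...]
    amplitudes: dict[str, np.ndarray]  # species -> per-delay fitted amplitude
    residual_maps: dict[float, MapGrid]


def _peak_normalized(fn, delays, tmax: float):
    """Evaluate a profile at the delays, normalized to its dense-grid peak."""
    dense = np.linspace(-1.0, tmax, 20001)
    peak = float(np.max(np.abs(fn(dense))))
    return np.asarray(fn(np.asarray(delays, float))) / peak


def species_profiles(kin: KineticParams, delays) -> SpeciesProfiles:
    """IRF-convolved species profiles evaluated on a delay grid.

    c_tr: exp decay (tau_decay), unit peak.  c_osc: damped cosine (period,
    tau_damp, phase), unit peak magnitude.  c_hot: biexponential rise
    (tau_rise1/2, rise_weight), unit plateau by construction.
    """
    delays = tuple(float(t) for t in delays)
    t = np.asarray(delays, float)
    s = kin.sigma
    c_tr = _peak_normalized(
        lambda x: conv_exp(x, kin.t0, kin.tau_decay, s), delays, 5 * kin.sigma + 2.0
    )
    c_osc = _peak_normalized(
        lambda x: conv_damped_cos(x, kin.t0, kin.period, kin.tau_damp, kin.phase, s),
        delays,
        kin.t0 + 2 * kin.period,
    )
    c_hot = conv_biexp_rise(t, kin.t0, kin.tau_rise1, kin.tau_rise2,
                            kin.rise_weight, s)
    return SpeciesProfiles(delays, c_osc, c_tr, c_hot)


def decompose(
    maps: dict[float, MapGrid],
    profiles: SpeciesProfiles,
    species: tuple[str, ...] = SPECIES,
) -> SpeciesDecomposition:
    """Voxel-wise linear least squares DED(v, t) = sum_k SADED_k(v) c_k(t).

    Uses whole-cell maps.  Also returns, per species, the per-delay amplitude
    obtained by projecting each delay's map onto the recovered SADED maps
    (the time-course surface used to validate the kinetic model).
    """
    delays = tuple(sorted(maps))
    if list(delays) != list(profiles.delays):
        raise ValueError("map delays do not match the profile delay grid")
    if len(delays) < len(species):
        raise ValueError("need at least as many delays as species")
    c = profiles.matrix(species)  # (n_t, n_s)
    # reject collinear profile pairs before attempting the solve
    norms = np.linalg.norm(c, axis=0)
    if np.any(norms == 0):
        dead = species[int(np.argmin(norms))]
        raise ValueError(f"profile for species {dead!r} is identically zero")
    gram = (c / norms).T @ (c / norms)
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            if abs(gram[i, j]) > 1.0 - 1e-10:
                raise ValueError(
                    f"profiles for {species[i]!r} and {species[j]!r} are "
                    "collinear; the decomposition is rank-deficient"
                )

    cell = maps[delays[0]].cell
    shape = maps[delays[0]].shape
    data = np.stack([maps[t].values.ravel() for t in delays])  # (n_t, n_vox)
    coef, *_ = np.linalg.lstsq(c, data, rcond=None)  # (n_s, n_vox)
    fitted = c @ coef
    resid = data - fitted

    saded = {
        s: MapGrid(cell, coef[i].reshape(shape)) for i, s in enumerate(species)
    }
    # per-delay amplitude of each SADED in the data (least-squares projection
    # of each delay's map onto the SADED basis)
    basis = coef.T  # (n_vox, n_s)
    amps, *_ = np.linalg.lstsq(basis, data.T, rcond=None)  # (n_s, n_t)
    amplitudes = {s: amps[i] for i, s in enumerate(species)}
    residual_maps = {
        t: MapGrid(cell, resid[i].reshape(shape)) for i, t in enumerate(delays)
    }
    return SpeciesDecomposition(saded, profiles, tuple(species), amplitudes,
                                residual_maps)


def heat_free(
    maps: dict[float, MapGrid], decomp: SpeciesDecomposition
) -> dict[float, MapGrid]:
    """Remove the hot-species contribution from each delay's DED map."""
    if "hot" not in decomp.saded:
        raise ValueError("decomposition does not include a hot species")
    hot = decomp.saded["hot"].values
    out = {}
    for i, t in enumerate(decomp.profiles.delays):
        m = maps[t]
        out[t] = MapGrid(m.cell, m.values - decomp.profiles.c_hot[i] * hot)
    return out
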