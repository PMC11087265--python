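"""Toy crystal construction, direct-summation structure factors, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trxmap import (
    AtomSite,
    CrystalModel,
    KineticParams,
    build_toy_mof,
    default_delay_grid,
    simulate_timeseries,
    structure_factors,
    thermal_ded_reference,
)
from trxmap.extrapolation import fe_doming, zr_zr_distance
from trxmap.toy_crystal import (
    NEGATIVE_REFERENCE_PS,
    DEFAULT_DELAYS_PS,
    DelayGrid,
    write_model_cif,
)

CELL = (20.0, 20.0, 20.0, 90.0, 90.0, 90.0)


class TestTypes:
    def test_atom_site_validation(self):
        with pytest.raises(ValueError):
            AtomSite("X", "Fe", (0, 0, 0), occupancy=1.5)
        with pytest.raises(ValueError):
            AtomSite("X", "Fe", (0, 0, 0), b_iso=-1.0)
        with pytest.raises(ValueError):
            AtomSite("X", "Xx", (0, 0, 0))

    def test_fractional_coordinates_wrap(self):
        s = AtomSite("X", "C", (1.25, -0.25, 0.5))
        assert s.frac_xyz == (0.25, 0.75, 0.5)

    def test_cell_validation(self):
        with pytest.raises(ValueError):
            CrystalModel((0, 1, 1, 90, 90, 90), ())
        with pytest.raises(ValueError):
            CrystalModel((1, 1, 1, 190, 90, 90), ())

    def test_delay_grid_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            DelayGrid((0.0, 0.0, 1.0), ())
        with pytest.raises(ValueError, match="subset"):
            DelayGrid((0.0, 1.0), (-1.0,))
        with pytest.raises(ValueError, match="< 0"):
            DelayGrid((0.0, 1.0), (0.0,))

    def test_default_grid_matches_published_protocol(self):
        g = default_delay_grid()
        assert len(g.delays) == 33
        assert g.negative_reference == (-3.9, -2.4, -0.6, -0.2)
        assert 0.0 in g.delays


class TestBuildToyMof:
    def test_default_geometry(self, species):
        assert fe_doming(species.ground) == pytest.approx(0.597, abs=1e-9)
        assert fe_doming(species.i_tr) == pytest.approx(0.716, abs=1e-9)
        assert zr_zr_distance(species.ground) == pytest.approx(0.841, abs=1e-9)
        assert zr_zr_distance(species.i_tr) == pytest.approx(0.907, abs=1e-9)
        assert zr_zr_distance(species.i_hot) == pytest.approx(0.891, abs=1e-9)

    def test_transient_state_loses_co_only(self, species):
        for a, b in zip(species.ground.sites, species.i_tr.sites):
            if a.label.startswith(("C_CO", "O_CO")):
                assert b.occupancy == 0.0
            else:
                assert b.occupancy == a.occupancy

    def test_hot_state_b_inflated(self, species):
        for a, b in zip(species.ground.sites, species.i_hot.sites):
            assert b.b_iso == pytest.approx(a.b_iso + 5.0)

    def test_oscillation_turning_points(self, species):
        assert fe_doming(species.i_osc_plus) == pytest.approx(
            0.597 + 0.443, abs=1e-9
        )
        assert fe_doming(species.i_osc_minus) == pytest.approx(
            0.597 - 0.312, abs=1e-9
        )

    def test_zero_displacement_override(self):
        sp = build_toy_mof(doming_tr=0.597)
        fe_g = sp.ground.site("FE").frac_xyz
        fe_t = sp.i_tr.site("FE").frac_xyz
        assert fe_g == fe_t

    def test_centrosymmetric_arrangement(self, species):
        for s in species.ground.sites:
            if s.label.endswith("_B"):
                continue
            mate = species.ground.site(s.label + "_B")
            for x, y in zip(s.frac_xyz, mate.frac_xyz):
                assert ((-x) % 1.0) == pytest.approx(y, abs=1e-12)

    def test_clash_rejected(self):
        # the Fe-C bond (1.85 A) violates a 2 A clash threshold
        with pytest.raises(ValueError, match="clash"):
            build_toy_mof(clash_min=2.0)

    def test_write_model_cif(self, species, tmp_path):
        path = tmp_path / "ground.cif"
        write_model_cif(species.ground, path)
        text = path.read_text()
        assert "_cell_length_a 20.0000" in text
        assert "_atom_site_fract_x" in text
        assert text.count("\nFE ") == 1


class TestStructureFactors:
    def test_point_scatterer_constant_amplitude(self):
        model = CrystalModel(
            CELL, (AtomSite("C1", "C", (0.1, 0.2, 0.3), 1.0, 0.0),)
        )
        f = structure_factors(model, hmax=4, dmin=4.0)
        assert np.allclose(f.amplitude, 6.0, atol=1e-10)

    def test_friedel_symmetry(self, f_ground):
        lookup = {
            (h, k, l): amp
            for (h, k, l), amp in zip(map(tuple, f_ground.hkl),
                                      f_ground.amplitude)
        }
        for (h, k, l), amp in lookup.items():
            assert amp == pytest.approx(lookup[(-h, -k, -l)], abs=1e-9)

    def test_f000_counts_electrons(self, species, f_ground):
        row = f_ground.data.query("h == 0 and k == 0 and l == 0")
        total = sum(s.occupancy * s.z_electrons for s in species.ground.sites)
        assert row["F"].iloc[0] == pytest.approx(total, abs=1e-9)

    def test_shift_theorem(self):
        base = CrystalModel(CELL, (AtomSite("C1", "C", (0.1, 0.2, 0.3)),))
        shifted = CrystalModel(CELL, (AtomSite("C1", "C", (0.6, 0.2, 0.3)),))
        f0 = structure_factors(base, hmax=2, dmin=5.0)
        f1 = structure_factors(shifted, hmax=2, dmin=5.0)
        p0 = f0.data.query("h == 1 and k == 0 and l == 0")["phase"].iloc[0]
        p1 = f1.data.query("h == 1 and k == 0 and l == 0")["phase"].iloc[0]
        delta = (p1 - p0) % (2 * np.pi)
        assert delta == pytest.approx(np.pi, abs=1e-9)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="no atom sites"):
            structure_factors(CrystalModel(CELL, ()), hmax=2, dmin=5.0)

    def test_too_loose_dmin_names_cutoff(self):
        model = CrystalModel(CELL, (AtomSite("C1", "C", (0, 0, 0)),))
        with pytest.raises(ValueError, match="dmin"):
            structure_factors(model, hmax=1, dmin=30.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 0.999), st.floats(0, 0.999), st.floats(0, 0.999)
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_friedel_holds_for_random_models(self, coords):
        sites = tuple(
            AtomSite(f"C{i}", "C", xyz, 1.0, 2.0)
            for i, xyz in enumerate(coords)
        )
        f = structure_factors(CrystalModel(CELL, sites), hmax=3, dmin=5.0)
        lookup = {
            (h, k, l): amp
            for (h, k, l), amp in zip(map(tuple, f.hkl), f.amplitude)
        }
        for (h, k, l), amp in lookup.items():
            assert amp == pytest.approx(lookup[(-h, -k, -l)], abs=1e-9)


class TestSimulateTimeseries:
    def test_no_photolysis_returns_ground(self, species, kin, grid, f_ground):
        out = simulate_timeseries(species, kin, grid, excited_fraction=0.0,
                                  noise_sd=0.0, seed=1, hmax=6, dmin=2.5)
        fg = structure_factors(species.ground, hmax=6, dmin=2.5)
        for t in grid.delays:
            assert np.allclose(out[t].amplitude, fg.amplitude, atol=1e-10)

    def test_negative_delay_equals_ground(self, series, species):
        fg = structure_factors(species.ground, hmax=12, dmin=1.6)
        assert np.allclose(series[-3.9].amplitude, fg.amplitude, atol=1e-9)

    def test_same_seed_bit_identical(self, species, kin, grid):
        a = simulate_timeseries(species, kin, grid, 0.5, 0.02, 123,
                                hmax=6, dmin=2.5)
        b = simulate_timeseries(species, kin, grid, 0.5, 0.02, 123,
                                hmax=6, dmin=2.5)
        for t in grid.delays:
            assert np.array_equal(a[t].amplitude, b[t].amplitude)

    def test_over_excitation_rejected(self, species, kin, grid):
        with pytest.raises(ValueError, match="over-excitation"):
            simulate_timeseries(species, kin, grid, 1.0, 0.0, 0,
                                peaks=(0.5, 0.5, 0.5), hmax=4, dmin=4.0)

    def test_small_signal_linearity(self, species, kin, grid):
        """|dF| scales linearly with excited fraction below 5% excitation."""
        out = {}
        fg = structure_factors(species.ground, hmax=8, dmin=2.0)
        for ef in (0.025, 0.05):
            ser = simulate_timeseries(species, kin, grid, ef, 0.0, 0,
                                      hmax=8, dmin=2.0)
            out[ef] = ser[3000.0].amplitude - fg.amplitude
        ratio = np.linalg.norm(out[0.05]) / np.linalg.norm(out[0.025])
        assert ratio == pytest.approx(2.0, rel=0.01)


class TestThermalDedReference:
    def test_negative_at_centers_positive_shell(self, species):
        ded = thermal_ded_reference(species.ground, delta_b=5.0,
                                    hmax=12, dmin=1.6)
        for lbl in ("FE", "ZR1", "FE_B"):
            site = species.ground.site(lbl)
            assert ded.value_at_frac(site.frac_xyz) < 0

    def test_single_atom_shell_average_positive(self):
        model = CrystalModel(
            CELL, (AtomSite("C1", "C", (0.5, 0.5, 0.5), 1.0, 3.0),)
        )
        ded = thermal_ded_reference(model, delta_b=5.0, hmax=10, dmin=2.0)
        assert ded.value_at_frac((0.5, 0.5, 0.5)) < 0
        # spherical shell at ~1.3 A radius
        shell = []
        for theta in np.linspace(0, np.pi, 8):
            for phi in np.linspace(0, 2 * np.pi, 12):
                offset = 1.3 * np.array(
                    [
                        np.sin(theta) * np.cos(phi),
                        np.sin(theta) * np.sin(phi),
                        np.cos(theta),
                    ]
                )
                shell.append(ded.value_at_frac(0.5 + offset / 20.0))
        assert np.mean(shell) > 0

    def test_map_integral_is_zero(self, species):
        ded = thermal_ded_reference(species.ground, delta_b=5.0,
                                    hmax=8, dmin=2.0)
        assert abs(ded.values.mean()) < 1e-12

    def test_continuity_small_delta_b(self, species):
        small = thermal_ded_reference(species.ground, delta_b=1e-4,
                                      hmax=8, dmin=2.0)
        assert np.max(np.abs(small.values)) < 1e-2

    def test_rejects_nonpositive_delta_b(self, species):
        with pytest.raises(ValueError):
            thermal_ded_reference(species.ground, delta_b=0.0)


def test_hot_only_series_matches_thermal_reference_at_late_delay(
    species, kin, grid, f_ground
):
    """A purely thermal simulation reproduces the B-inflation difference map."""
    from trxmap.density_maps import ded_map
    from trxmap.reflections import difference_amplitudes, reference_amplitudes
    from conftest import cosine_similarity

    ser = simulate_timeseries(species, kin, grid, 1.0, 0.0, 0,
                              peaks=(0.0, 0.0, 1.0), hmax=12, dmin=1.6)
    ref = reference_amplitudes(ser, grid)
    late = ded_map(difference_amplitudes(ser[3000.0], ref), f_ground)
    thermal = thermal_ded_reference(species.ground, delta_b=5.0,
                                    hmax=12, dmin=1.6)
    assert cosine_similarity(late.values, thermal.values) > 0.99
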