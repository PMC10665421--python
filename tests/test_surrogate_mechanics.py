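"""Surrogate gap mechanics: sections, springs, kinematics, strain fields."""

import numpy as np
import pytest

from fractrial import Materials, SurrogateGeometry, density_to_modulus
from fractrial.strain_invariants import hydrostatic_strain
from fractrial.surrogate_mechanics import (
    GapMotion,
    build_mesh,
    cell_strain_field,
    gap_kinematics,
    section_properties,
    strain_tensors,
)


@pytest.fixture
def geom():
    return SurrogateGeometry()


@pytest.fixture
def mat():
    return Materials()


class TestDensityToModulus:
    def test_unit_density_gives_power_law_coefficient(self):
        assert density_to_modulus(1.0) == pytest.approx(6570.0, rel=1e-12)

    def test_zero_density_gives_zero(self):
        assert density_to_modulus(0.0) == 0.0

    def test_power_law_at_high_density(self):
        # independent evaluation 6570 * exp(1.37 * ln 1.8)
        expected = 6570.0 * np.exp(1.37 * np.log(1.8))
        assert density_to_modulus(1.8) == pytest.approx(expected, abs=1.0)
        assert expected == pytest.approx(14700, abs=60)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            density_to_modulus(-0.1)


class TestSectionProperties:
    def test_nail_circle_area_and_moment(self, geom, mat):
        stiff = section_properties(geom, mat)
        assert stiff.nail_area == pytest.approx(np.pi * 5.5**2, rel=1e-12)
        assert stiff.nail_area == pytest.approx(95.03, abs=0.01)
        assert stiff.nail_I == pytest.approx(np.pi * 5.5**4 / 4.0, rel=1e-12)
        assert stiff.nail_I == pytest.approx(718.7, abs=0.1)
        assert stiff.nail_J == pytest.approx(2 * stiff.nail_I, rel=1e-12)

    def test_doubling_all_moduli_doubles_every_stiffness(self, geom, mat):
        s1 = section_properties(geom, mat)
        mat2 = mat.model_copy(update={"nail_E": 2 * mat.nail_E, "tissue_E": 2 * mat.tissue_E})
        s2 = section_properties(geom, mat2)
        for name in ("k_axial", "k_bend_x", "k_bend_y", "k_shear", "k_torsion"):
            assert getattr(s2, name) == pytest.approx(2 * getattr(s1, name), rel=1e-12)

    def test_elastic_fragments_soften_the_construct(self, geom, mat):
        rigid = section_properties(geom, mat)
        elastic = section_properties(geom, mat.model_copy(update={"fragment_density": 1.5}))
        assert elastic.k_axial < rigid.k_axial
        assert elastic.k_bend_x < rigid.k_bend_x

    def test_geometry_invariants(self, geom):
        assert geom.nail_radius < geom.inner_cortical_radius < geom.outer_radius
        assert geom.outer_radius < geom.callus_outer_radius
        with pytest.raises(ValueError, match="nail"):
            SurrogateGeometry(tibia_length=200.0)  # canal too narrow for the nail


class TestGapKinematics:
    def test_axial_single_spring_closed_form(self, geom):
        # tissue made mechanically negligible: nail spring dominates
        mat = Materials(tissue_E=1e-9)
        stiff = section_properties(geom, mat)
        motion = gap_kinematics([0.0, 0.0, -1000.0], [0.0, 0.0, 0.0], stiff)
        expected = -1000.0 * 3.0 / (110_000.0 * np.pi * 5.5**2)
        assert motion.dz == pytest.approx(expected, rel=1e-6)
        assert motion.dz == pytest.approx(-2.87e-4, abs=0.005e-4)

    def test_zero_load_zero_motion(self, geom, mat):
        stiff = section_properties(geom, mat)
        motion = gap_kinematics([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], stiff)
        assert np.all(motion.as_array() == 0.0)

    def test_motion_linear_in_load(self, geom, mat, rng):
        stiff = section_properties(geom, mat)
        force = rng.normal(0, 500, 3)
        moment = rng.normal(0, 5, 3)
        m1 = gap_kinematics(force, moment, stiff).as_array()
        m3 = gap_kinematics(3.0 * force, 3.0 * moment, stiff).as_array()
        np.testing.assert_allclose(m3, 3.0 * m1, rtol=1e-12)


class TestMesh:
    def test_cell_areas_sum_to_annulus_areas(self, geom):
        mesh = build_mesh(geom)
        gap_area = np.pi * (geom.outer_radius**2 - geom.nail_radius**2)
        callus_area = np.pi * (geom.callus_outer_radius**2 - geom.outer_radius**2)
        assert mesh.area[mesh.region == "gap"].sum() == pytest.approx(gap_area, rel=0.01)
        assert mesh.area[mesh.region == "callus"].sum() == pytest.approx(callus_area, rel=0.01)

    def test_cell_counts_match_resolution(self, geom):
        mesh = build_mesh(geom)
        assert (mesh.region == "gap").sum() == geom.n_r_gap * geom.n_theta_gap
        assert (mesh.region == "callus").sum() == geom.n_r_callus * geom.n_theta_callus


class TestCellStrainField:
    def test_pure_axial_motion_gives_uniform_field(self, geom, mat):
        motion = GapMotion(0.0, 0.0, -3e-4, 0.0, 0.0, 0.0)
        field = cell_strain_field(motion, geom, mat)
        np.testing.assert_allclose(field["ezz"], -1e-4, rtol=1e-12)
        np.testing.assert_allclose(field["exz"], 0.0, atol=1e-18)
        np.testing.assert_allclose(field["eyz"], 0.0, atol=1e-18)
        np.testing.assert_allclose(field["exx"], mat.tissue_nu * 1e-4, rtol=1e-12)

    def test_pure_bending_is_antisymmetric_about_neutral_axis(self, geom, mat):
        motion = GapMotion(0.0, 0.0, 0.0, 1e-4, 0.0, 0.0)
        field = cell_strain_field(motion, geom, mat)
        y, ezz, area = field["y_mm"], field["ezz"], field["area_mm2"]
        assert (ezz[y > 1e-9] > 0).all()  # +y side in tension
        assert (ezz[y < -1e-9] < 0).all()
        # area-weighted mean vanishes over the centered annulus
        scale = np.abs(ezz).max()
        assert abs(np.average(ezz, weights=area)) < 1e-10 * scale

    def test_pure_torsion_shear_grows_with_radius(self, geom, mat):
        motion = GapMotion(0.0, 0.0, 0.0, 0.0, 0.0, 2e-4)
        field = cell_strain_field(motion, geom, mat)
        r = np.hypot(field["x_mm"], field["y_mm"])
        gamma = 2.0 * np.hypot(field["exz"], field["eyz"])
        np.testing.assert_allclose(gamma, motion.theta_z * r / geom.gap_height, rtol=1e-12)

    def test_field_linear_in_motion_scale(self, geom, mat, rng):
        m = rng.normal(0, 1e-4, 6)
        f1 = cell_strain_field(GapMotion(*m), geom, mat)
        f2 = cell_strain_field(GapMotion(*(2.5 * m)), geom, mat)
        cols = ["exx", "eyy", "ezz", "exy", "exz", "eyz"]
        np.testing.assert_allclose(f2[cols], 2.5 * f1[cols], rtol=1e-12)

    def test_compression_gives_negative_mean_hydrostatic(self, geom, mat):
        stiff = section_properties(geom, mat)
        motion = gap_kinematics([50.0, 30.0, -1800.0], [5.0, 7.0, 2.0], stiff)
        field = cell_strain_field(motion, geom, mat)
        hydro = hydrostatic_strain(strain_tensors(field))
        assert np.average(hydro, weights=field["area_mm2"]) < 0

    def test_mesh_refinement_converges(self, geom, mat):
        stiff = section_properties(geom, mat)
        motion = gap_kinematics([60.0, 40.0, -2000.0], [6.0, 8.0, 2.5], stiff)
        fine_geom = geom.model_copy(
            update={
                "n_r_gap": 2 * geom.n_r_gap,
                "n_theta_gap": 2 * geom.n_theta_gap,
                "n_r_callus": 2 * geom.n_r_callus,
                "n_theta_callus": 2 * geom.n_theta_callus,
            }
        )
        for g in ("gap", "callus"):
            medians = []
            for gg in (geom, fine_geom):
                field = cell_strain_field(motion, gg, mat)
                mask = field["region"] == g
                from fractrial.strain_invariants import octahedral_shear

                medians.append(np.median(octahedral_shear(strain_tensors(field[mask]))))
            assert medians[1] == pytest.approx(medians[0], rel=0.01)
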