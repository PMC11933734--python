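"""Geometry primitives: torsion sign convention, superposition RMSD, circular
statistics, descriptor evaluation — each cross-checked against an independent
construction where the value is not obvious."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from esiptkit.errors import DegenerateGeometryError, SelectionError, ValidationError
from esiptkit.geometry import (
    DescriptorSpec,
    circular_mean,
    distance,
    evaluate_descriptors,
    kabsch_rmsd,
    torsion,
    wrap_degrees,
)
from esiptkit.synthetic import build_ensemble, default_template

finite_coord = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite_coord, finite_coord, finite_coord).map(np.array)


def _quadruple_with_known_torsion(angle_deg):
    """Independent rotation-matrix construction of four points whose dihedral
    is ``angle_deg`` by design: start planar-cis and rotate p4 about the
    p2→p3 axis."""
    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([1.0, 0.0, 0.0])
    p3 = np.array([1.0, 1.5, 0.0])
    p4_cis = p3 + np.array([-1.2, 0.0, 0.0])  # cis to p1: torsion 0
    rot = Rotation.from_rotvec(np.radians(angle_deg) * np.array([0.0, 1.0, 0.0]))
    return p1, p2, p3, p3 + rot.apply(p4_cis - p3)


class TestTorsion:
    def test_planar_syn_is_zero(self):
        assert torsion((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)) == pytest.approx(0.0)

    def test_planar_anti_is_180(self):
        assert torsion((0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 1, 0)) == pytest.approx(180.0)

    def test_right_handed_quarter_turn_is_plus_90(self):
        assert torsion((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)) == pytest.approx(90.0)

    @pytest.mark.parametrize("angle", [-179.0, -90.0, -30.5, 0.0, 12.25, 90.0, 179.5, 180.0])
    def test_matches_rotation_matrix_construction(self, angle):
        p1, p2, p3, p4 = _quadruple_with_known_torsion(angle)
        assert torsion(p1, p2, p3, p4) == pytest.approx(wrap_degrees(angle), abs=1e-9)

    @given(st.floats(-179.0, 179.0))
    def test_invariant_under_atom_order_reversal(self, angle):
        # reversing the quadruple negates all three bond vectors pairwise,
        # leaving both atan2 arguments unchanged: same signed angle
        p1, p2, p3, p4 = _quadruple_with_known_torsion(angle)
        assert torsion(p4, p3, p2, p1) == pytest.approx(torsion(p1, p2, p3, p4), abs=1e-9)

    @given(st.floats(-179.0, 179.0))
    def test_sign_flips_under_mirror_reflection(self, angle):
        p1, p2, p3, p4 = _quadruple_with_known_torsion(angle)
        mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in (p1, p2, p3, p4)]
        assert torsion(*mirrored) == pytest.approx(-torsion(p1, p2, p3, p4), abs=1e-9)

    @given(st.floats(-170, 170), point, st.floats(-np.pi, np.pi), st.floats(0.1, 2 * np.pi))
    def test_invariant_under_rigid_motion(self, angle, shift, rotangle, axis_angle):
        pts = _quadruple_with_known_torsion(angle)
        axis = np.array([np.cos(axis_angle), np.sin(axis_angle), 0.3])
        rot = Rotation.from_rotvec(rotangle * axis / np.linalg.norm(axis))
        moved = [rot.apply(p) + shift for p in pts]
        assert torsion(*moved) == pytest.approx(torsion(*pts), abs=1e-7)

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            torsion((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestDistance:
    def test_axis_aligned(self):
        assert distance((0, 0, 0), (0, 0, 3)) == pytest.approx(3.0)

    def test_zero_for_identical_points(self):
        assert distance((1.5, -2, 7), (1.5, -2, 7)) == 0.0

    def test_pythagorean_triple(self):
        assert distance((1, 2, 2), (0, 0, 0)) == pytest.approx(3.0)


class TestKabschRmsd:
    def test_identical_sets_give_zero(self, rng):
        pts = rng.normal(size=(6, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-7)

    def test_rigid_motion_gives_zero(self, rng):
        pts = rng.normal(size=(5, 3))
        rot = Rotation.from_euler("z", 37, degrees=True)
        moved = rot.apply(pts) + np.array([1.0, 2.0, 3.0])
        assert kabsch_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-8)

    def test_never_exceeds_unsuperposed_rmsd(self, rng):
        for _ in range(10):
            a = rng.normal(size=(7, 3))
            b = a + rng.normal(scale=0.4, size=(7, 3))
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert kabsch_rmsd(a, b) <= raw + 1e-12

    def test_matches_rotation_grid_oracle(self, rng):
        """Brute-force oracle: coarse rotation grid plus local refinement."""
        from scipy.optimize import minimize

        ref = np.array([[0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0.3, 1.0, 1.2]], dtype=float)
        mobile = ref + rng.normal(scale=0.3, size=ref.shape)
        ref_c = ref - ref.mean(axis=0)
        mob_c = mobile - mobile.mean(axis=0)

        def rmsd_for(euler):
            rot = Rotation.from_euler("zyz", euler, degrees=True)
            return np.sqrt(np.mean(np.sum((ref_c - rot.apply(mob_c)) ** 2, axis=1)))

        grid = [
            (a, b, c)
            for a in range(0, 360, 10)
            for b in range(0, 181, 10)
            for c in range(0, 360, 10)
        ]
        best = min(grid, key=rmsd_for)
        refined = minimize(rmsd_for, best, method="Nelder-Mead", options={"xatol": 1e-6})
        assert kabsch_rmsd(ref, mobile) == pytest.approx(refined.fun, abs=1e-3)

    def test_selection_subsets_atoms(self, rng):
        pts = rng.normal(size=(8, 3))
        moved = pts.copy()
        moved[5:] += 10.0  # perturb atoms outside the selection
        assert kabsch_rmsd(pts, moved, selection=[0, 1, 2, 3, 4]) == pytest.approx(0.0, abs=1e-7)

    def test_fewer_than_three_atoms_raises(self):
        with pytest.raises(ValidationError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCircularMean:
    def test_symmetric_cluster(self):
        assert circular_mean([10, 20, 30]) == pytest.approx(20.0)

    def test_wraparound_case_arithmetic_mean_gets_wrong(self):
        assert circular_mean([170, -170]) == pytest.approx(180.0)

    def test_quarter(self):
        assert circular_mean([0, 90]) == pytest.approx(45.0)

    @given(st.lists(st.floats(-180, 180), min_size=1, max_size=10), st.integers(-3, 3))
    def test_invariant_under_adding_full_turns(self, angles, turns):
        try:
            base = circular_mean(angles)
        except DegenerateGeometryError:
            return
        shifted = [angles[0] + 360 * turns] + angles[1:]
        assert circular_mean(shifted) == pytest.approx(base, abs=1e-8)

    def test_vanishing_resultant_raises(self):
        with pytest.raises(DegenerateGeometryError):
            circular_mean([0.0, 180.0])


class TestEvaluateDescriptors:
    def test_recovers_generator_torsions(self, template, rng):
        torsions = np.column_stack(
            [rng.uniform(-179, 179, size=20), rng.uniform(-179, 179, size=20)]
        )
        ens = build_ensemble(torsions, template)
        matrix = evaluate_descriptors(ens, template.descriptor_specs()[:2])
        np.testing.assert_allclose(matrix.values, torsions, atol=1e-6)

    def test_constant_torsion_column(self, template):
        ens = build_ensemble(np.tile([60.0, 0.0], (5, 1)), template)
        matrix = evaluate_descriptors(ens, template.descriptor_specs())
        np.testing.assert_allclose(matrix.column("dihedral_1"), 60.0, atol=1e-6)

    def test_empty_spec_list_gives_zero_columns(self, template):
        ens = build_ensemble(np.zeros((3, 2)), template)
        matrix = evaluate_descriptors(ens, [])
        assert matrix.values.shape == (3, 0)

    def test_shape_matches_specs(self, template, rng):
        ens = build_ensemble(rng.uniform(-170, 170, size=(10, 2)), template)
        matrix = evaluate_descriptors(ens, template.descriptor_specs())
        assert matrix.values.shape == (10, 3)
        assert matrix.descriptor_names == ["dihedral_1", "dihedral_2", "d_N_HO"]

    def test_unresolvable_selector_names_spec(self, template):
        ens = build_ensemble(np.zeros((2, 2)), template)
        bad = DescriptorSpec("broken", "distance", ((1, "N3"), (1, "ZZ9")))
        with pytest.raises(SelectionError, match="broken"):
            evaluate_descriptors(ens, [bad])

    def test_csv_round_trip(self, template, rng, tmp_path):
        ens = build_ensemble(rng.uniform(-170, 170, size=(6, 2)), template)
        matrix = evaluate_descriptors(ens, template.descriptor_specs())
        path = tmp_path / "m.csv"
        matrix.to_csv(path)
        from esiptkit.geometry import DescriptorMatrix

        back = DescriptorMatrix.from_csv(path)
        assert back.descriptor_names == matrix.descriptor_names
        assert back.kinds == matrix.kinds
        np.testing.assert_allclose(back.values, matrix.values, atol=1e-9)
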