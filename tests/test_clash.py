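"""Clash detection, axis rotation, and minimal relief rotation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrxgeom.clash import (
    AtomSet,
    ClashParams,
    atom_set,
    detect_clashes,
    min_relief_rotation,
    rotate_about_axis,
)
from nrxgeom.errors import DegenerateInputError, MissingRadiusError, NrxGeomError
from nrxgeom.model import Atom, Residue, StructureModel
from nrxgeom.simulate import make_clash_scene

from conftest import single_atom_model


def two_carbon_sets(distance):
    a = atom_set(single_atom_model(chain="A", number=1))
    b = atom_set(single_atom_model(coord=(distance, 0.0, 0.0), chain="B", number=900))
    return a, b


class TestDetectClashes:
    def test_contact_above_threshold_is_clean(self):
        a, b = two_carbon_sets(3.5)
        assert detect_clashes(a, b, ClashParams(overlap_tolerance=0.4)) == []

    def test_overlap_depth_is_analytic(self):
        a, b = two_carbon_sets(2.9)
        clashes = detect_clashes(a, b, ClashParams(overlap_tolerance=0.4))
        assert len(clashes) == 1
        assert clashes[0].overlap == pytest.approx(0.1, abs=1e-9)  # (1.7+1.7-0.4) - 2.9

    def test_chain_neighbours_ignored(self):
        # residues 5 and 6 on the same chain, atoms overlapping
        r5 = Residue(5, "GLY", [Atom("CA", "C", [0.0, 0.0, 0.0])])
        r6 = Residue(6, "GLY", [Atom("CA", "C", [1.0, 0.0, 0.0])])
        m = StructureModel(id="adj", chains={"A": [r5, r6]})
        s5 = atom_set(m, residue_range=(5, 5))
        s6 = atom_set(m, residue_range=(6, 6))
        assert detect_clashes(s5, s6, ClashParams(neighbor_exclusion=2)) == []
        assert len(detect_clashes(s5, s6, ClashParams(neighbor_exclusion=0))) == 1

    def test_missing_radius_raises(self):
        with pytest.raises(MissingRadiusError):
            atom_set(single_atom_model(element="ZZ"))

    def test_grid_result_identical_to_all_pairs(self):
        """KD-tree pruned search returns exactly the brute-force pair set."""
        rng = np.random.default_rng(21)
        pa = rng.uniform(-10, 10, (150, 3))
        pb = rng.uniform(-10, 10, (150, 3))
        a = AtomSet(pa, np.full(150, 1.7), [("A", i * 10, "CA") for i in range(150)])
        b = AtomSet(pb, np.full(150, 1.7), [("B", i * 10, "CA") for i in range(150)])
        params = ClashParams(overlap_tolerance=0.4, neighbor_exclusion=0)
        got = {(c.atom_a, c.atom_b) for c in detect_clashes(a, b, params)}
        cutoff = 1.7 + 1.7 - 0.4
        expected = {
            (a.labels[i], b.labels[j])
            for i in range(150)
            for j in range(150)
            if np.linalg.norm(pa[i] - pb[j]) < cutoff
        }
        assert got == expected


class TestRotateAboutAxis:
    def test_full_turn_is_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(40, 3))
        out = rotate_about_axis(pts, [1.0, 2.0, 3.0], [0.0, 0.0, 1.0], 360.0)
        assert np.abs(out - pts).max() < 1e-9

    def test_point_on_axis_is_fixed(self):
        pivot = np.array([5.0, 5.0, 5.0])
        on_axis = pivot + 3.0 * np.array([0.0, 0.0, 1.0])
        out = rotate_about_axis(on_axis[None, :], pivot, [0.0, 0.0, 1.0], 77.0)
        assert np.abs(out[0] - on_axis).max() < 1e-9

    def test_quarter_turn_about_z(self):
        out = rotate_about_axis(np.array([[1.0, 0.0, 0.0]]), np.zeros(3), [0, 0, 1], 90.0)
        assert np.allclose(out[0], [0.0, 1.0, 0.0], atol=1e-12)

    def test_zero_axis_rejected(self):
        with pytest.raises(DegenerateInputError):
            rotate_about_axis(np.zeros((1, 3)), np.zeros(3), [0.0, 0.0, 0.0], 10.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-180, 180, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_rigidity_preserves_pairwise_distances(self, angle, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(scale=5.0, size=(12, 3))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        out = rotate_about_axis(pts, rng.normal(size=3), axis, angle)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d1 = np.linalg.norm(out[:, None] - out[None, :], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9


class TestMinRelief:
    def test_clash_free_input_reports_zero(self):
        a, b = two_carbon_sets(10.0)
        res = min_relief_rotation(a, b, np.zeros(3))
        assert res.min_relief_angle == 0.0
        assert res.initial_clashes == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_single_atom_closed_form_within_one_grid_step(self, seed):
        """The scanned angle matches the analytic law-of-cosines solution
        to within the 1-degree grid resolution across 20 geometries."""
        rng = np.random.default_rng(seed)
        arm = rng.uniform(5.0, 15.0)
        gap = -rng.uniform(0.1, 1.5)
        scene = make_clash_scene(seed, kind="single_atom", arm_length=arm, gap=gap)
        mobile = atom_set(scene["mobile"])
        static = atom_set(scene["static"])
        res = min_relief_rotation(mobile, static, scene["pivot"], scene["params"])
        assert res.found
        assert res.min_relief_angle >= scene["analytic_angle"] - 1e-9
        assert res.min_relief_angle - scene["analytic_angle"] <= 1.0 + 1e-9

    def test_multi_atom_matches_independent_oracle(self):
        scene = make_clash_scene(33, kind="multi", gap=-0.8)
        mobile = atom_set(scene["mobile"])
        static = atom_set(scene["static"])
        res = min_relief_rotation(mobile, static, scene["pivot"], scene["params"])
        assert res.min_relief_angle == pytest.approx(scene["oracle_angle"], abs=1e-9)

    def test_monotone_in_overlap_tolerance(self):
        scene = make_clash_scene(3, kind="single_atom", arm_length=8.0, gap=-1.0)
        mobile = atom_set(scene["mobile"])
        static = atom_set(scene["static"])
        angles = []
        for tol in (0.0, 0.4, 0.8):
            res = min_relief_rotation(
                mobile, static, scene["pivot"], ClashParams(overlap_tolerance=tol)
            )
            angles.append(res.min_relief_angle if res.found else math.inf)
        assert angles[0] >= angles[1] >= angles[2]

    def test_unrelievable_scene_reports_residual(self):
        # static atom sitting exactly on the pivot cannot be escaped by rotation
        mobile = atom_set(single_atom_model(coord=(1.0, 0.0, 0.0), chain="M", number=1))
        static = atom_set(single_atom_model(coord=(0.0, 0.0, 0.0), chain="S", number=900))
        res = min_relief_rotation(mobile, static, np.zeros(3), angle_max=30.0)
        assert not res.found
        assert res.residual_clashes >= 1
        assert res.min_relief_angle is None

    def test_result_independent_of_atom_order(self):
        scene = make_clash_scene(9, kind="multi", gap=-0.6)
        mobile = atom_set(scene["mobile"])
        static = atom_set(scene["static"])
        res1 = min_relief_rotation(mobile, static, scene["pivot"], scene["params"])
        perm = np.random.default_rng(0).permutation(len(mobile))
        shuffled = AtomSet(
            mobile.coords[perm], mobile.radii[perm], [mobile.labels[i] for i in perm]
        )
        res2 = min_relief_rotation(shuffled, static, scene["pivot"], scene["params"])
        assert res1.min_relief_angle == res2.min_relief_angle
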