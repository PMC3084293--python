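"""Kabsch superposition, correspondences and iterative alignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nrxgeom.errors import DegenerateInputError, NrxGeomError
from nrxgeom.model import Atom, Residue, StructureModel
from nrxgeom.superpose import (
    RigidTransform,
    kabsch,
    pair_by_numbering,
    relative_transform,
    structure_align,
)
from nrxgeom.simulate import _helix_residues


def random_cloud(rng, n=30):
    return rng.normal(scale=5.0, size=(n, 3))


def helix_model(n=30, start=1, chain="A"):
    return StructureModel(
        id="helix",
        chains={chain: _helix_residues(start, n, np.zeros(3), np.array([1.0, 0.0, 0.0]))},
    )


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        x = random_cloud(rng)
        T, rmsd = kabsch(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert T.rotation_angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        x = random_cloud(rng)
        R = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
        y = x @ R.T + np.array([3.0, -2.0, 7.0])
        T, rmsd = kabsch(y, x)
        assert T.rotation_angle_deg == pytest.approx(37.0, abs=1e-9)
        assert rmsd < 1e-8

    def test_mirror_image_never_reflected(self):
        rng = np.random.default_rng(2)
        x = random_cloud(rng)
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        T, rmsd = kabsch(x, mirrored)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1  # no proper rotation can undo a reflection of a chiral cloud

    def test_rmsd_symmetric_and_motion_invariant(self):
        rng = np.random.default_rng(3)
        a, b = random_cloud(rng), random_cloud(rng)
        _, r_ab = kabsch(a, b)
        _, r_ba = kabsch(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        Q = Rotation.random(random_state=4).as_matrix()
        t = np.array([10.0, -5.0, 2.0])
        _, r_moved = kabsch(a @ Q.T + t, b @ Q.T + t)
        assert r_moved == pytest.approx(r_ab, abs=1e-9)

    @pytest.mark.parametrize("bad", ["two_points", "collinear"])
    def test_degenerate_inputs_rejected(self, bad):
        if bad == "two_points":
            pts = np.array([[0.0, 0, 0], [1, 0, 0]])
        else:
            pts = np.outer(np.arange(10.0), [1.0, 0, 0])
        with pytest.raises(DegenerateInputError):
            kabsch(pts, pts)


class TestRigidTransform:
    def test_reflection_rejected_at_construction(self):
        with pytest.raises(NrxGeomError):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))

    def test_relative_transform_of_identical_is_identity(self):
        T = RigidTransform(Rotation.from_euler("x", 20, degrees=True).as_matrix(), np.ones(3))
        rel = relative_transform(T, T)
        assert rel.rotation_angle_deg == pytest.approx(0.0, abs=1e-9)
        assert rel.translation_magnitude == pytest.approx(0.0, abs=1e-9)

    def test_relative_transform_same_axis_angles_subtract(self):
        ax = np.array([0.0, 0.0, 1.0])
        Ta = RigidTransform(Rotation.from_rotvec(np.radians(10) * ax).as_matrix(), np.zeros(3))
        Tb = RigidTransform(Rotation.from_rotvec(np.radians(25) * ax).as_matrix(), np.zeros(3))
        assert relative_transform(Ta, Tb).rotation_angle_deg == pytest.approx(15.0, abs=1e-9)

    def test_compose_with_inverse_is_identity(self):
        rng = np.random.default_rng(5)
        T = RigidTransform(Rotation.random(random_state=6).as_matrix(), rng.normal(size=3))
        I = T.compose(T.inverse())
        assert I.rotation_angle_deg == pytest.approx(0.0, abs=1e-6)
        assert I.translation_magnitude == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_align_vectors(self):
        """Independent cross-check of the rotation against scipy's solver."""
        rng = np.random.default_rng(7)
        x = random_cloud(rng, 25)
        y = random_cloud(rng, 25)
        T, _ = kabsch(x, y)
        R_scipy, _ = Rotation.align_vectors(x - x.mean(0), y - y.mean(0))
        assert np.allclose(T.rotation, R_scipy.as_matrix(), atol=1e-8)


class TestPairByNumbering:
    def test_identity_pairs_every_residue(self):
        m = helix_model(25)
        corr = pair_by_numbering(m, m)
        assert corr.n_matched == 25

    def test_offset_mapping(self):
        a = helix_model(25, start=1086)
        b = helix_model(25, start=84)
        corr = pair_by_numbering(a, b, offset=-1002)
        assert corr.n_matched == 25

    def test_disjoint_numbering_errors(self):
        a = helix_model(10, start=1)
        b = helix_model(10, start=500)
        with pytest.raises(NrxGeomError):
            pair_by_numbering(a, b)


class TestStructureAlign:
    def test_exact_copy_matches_everything(self):
        m = helix_model(40)
        res = structure_align(m, m, seed="numbering")
        assert res.correspondence.n_matched == 40
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed_method", ["numbering", "sequence"])
    def test_displaced_residues_pruned(self, seed_method):
        """20% of residues pushed 10 Å off: they are dropped and the
        remaining pairs superpose essentially exactly."""
        m = helix_model(40)
        moved = helix_model(40)
        displaced = {5, 6, 13, 21, 29, 30, 37, 38}
        for r in moved.chains["A"]:
            if r.auth_number in displaced:
                r.atoms[0].coord = r.atoms[0].coord + np.array([0.0, 10.0, 0.0])
        res = structure_align(m, moved, seed=seed_method, prune_cutoff=4.5)
        matched_numbers = {p[0].auth_number for p in res.correspondence.pairs}
        assert matched_numbers.isdisjoint(displaced)
        assert res.correspondence.n_matched == 40 - len(displaced)
        assert res.rmsd < 1e-6

    def test_rmsd_history_non_increasing_under_pruning(self):
        m = helix_model(40)
        moved = helix_model(40)
        for r in moved.chains["A"]:
            if r.auth_number % 5 == 0:
                r.atoms[0].coord = r.atoms[0].coord + np.array([0.0, 10.0, 0.0])
        res = structure_align(m, moved, seed="numbering")
        hist = res.rmsd_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))

    def test_too_few_residues_rejected(self):
        m = helix_model(10)
        with pytest.raises(DegenerateInputError):
            structure_align(m, m)


class TestRecoveryProperty:
    def test_100_random_transforms_recovered(self):
        """Angle to 1e-6 deg and RMSD to 1e-8 Å across 100 seeded draws;
        det(R) always +1 even for reflected inputs."""
        worst_angle, worst_rmsd = 0.0, 0.0
        for seed in range(100):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.normal(scale=8.0, size=(20, 3))
            angle = rng.uniform(0.0, 180.0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
            y = x @ R.T + rng.normal(scale=20.0, size=3)
            T, rmsd = kabsch(y, x)
            worst_angle = max(worst_angle, abs(T.rotation_angle_deg - angle))
            worst_rmsd = max(worst_rmsd, rmsd)
            Tm, _ = kabsch(x, x * np.array([-1.0, 1.0, 1.0]))
            assert np.linalg.det(Tm.rotation) == pytest.approx(1.0, abs=1e-9)
        assert worst_angle < 1e-6
        assert worst_rmsd < 1e-8
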