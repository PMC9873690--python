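"""Superposition, screw decomposition and rigid-domain partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tmelevate.errors import ContractError, DegenerateGeometryError
from tmelevate.rigid_body import (Transform, decompose_domains, domain_motion_report,
                                  per_helix_transforms, rotation_angle, screw_decompose,
                                  superpose)
from tmelevate.synthetic_data import BundleSpec, block_rotation_spec, build_bundle

from conftest import random_rotation


def rotation_about(axis, angle_deg, point=(0.0, 0.0, 0.0)) -> Transform:
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis, float)
                               / np.linalg.norm(axis)).as_matrix()
    point = np.asarray(point, float)
    return Transform(rot, point - rot @ point)


def brute_force_rmsd(mobile, reference, grid_deg=5.0):
    """Oracle: minimum RMSD over a dense Euler-angle rotation grid."""
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)
    grid = np.deg2rad(np.arange(0.0, 360.0, grid_deg))
    half = np.deg2rad(np.arange(0.0, 180.0 + grid_deg, grid_deg))
    angles = np.stack(np.meshgrid(grid, half, grid, indexing="ij"), axis=-1).reshape(-1, 3)
    mats = Rotation.from_euler("zyz", angles).as_matrix()
    rotated = np.einsum("rij,nj->rni", mats, mobile)
    rmsds = np.sqrt(((rotated - reference) ** 2).sum(axis=2).mean(axis=1))
    return float(rmsds.min())


class TestSuperpose:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(scale=5.0, size=(12, 3))
        planted = rotation_about([0, 0, 1], 30.0)
        moved = planted.apply(pts) + np.array([1.0, 2.0, 3.0])
        t, rmsd = superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert rotation_angle(t) == pytest.approx(30.0, abs=1e-9)

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(2)
        a = rng.normal(scale=4.0, size=(15, 3))
        b = a + rng.normal(scale=0.5, size=(15, 3))
        assert superpose(a, b)[1] == pytest.approx(superpose(b, a)[1], abs=1e-9)

    @pytest.mark.parametrize("n_points", [4, 5, 6])
    def test_matches_brute_force_grid_oracle(self, n_points):
        rng = np.random.default_rng(n_points)
        a = rng.normal(scale=3.0, size=(n_points, 3))
        b = rng.normal(scale=3.0, size=(n_points, 3))
        _, kabsch = superpose(a, b)
        grid = brute_force_rmsd(a, b, grid_deg=5.0)
        assert kabsch <= grid + 1e-9
        # a 5-degree grid cannot miss the optimum by more than the worst
        # extra displacement of a point under a half-grid-step rotation
        bound = 2.0 * np.sin(np.deg2rad(5.0)) * np.abs(a).max() * np.sqrt(3)
        assert grid - kabsch <= bound

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_input_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)


class TestRotationAngle:
    def test_identity_and_halfturn(self):
        assert rotation_angle(Transform.identity()) == pytest.approx(0.0)
        assert rotation_angle(rotation_about([1, 1, 0], 180.0)) == pytest.approx(180.0)

    def test_composition_with_inverse_is_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t = Transform(random_rotation(rng), rng.normal(size=3))
            assert rotation_angle(t.compose(t.inverse())) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_change_of_basis(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            r = random_rotation(rng)
            q = random_rotation(rng)
            t = Transform(r, np.zeros(3))
            conjugated = Transform(q @ r @ q.T, np.zeros(3))
            assert rotation_angle(conjugated) == pytest.approx(rotation_angle(t), abs=1e-9)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(5)
        t = Transform(random_rotation(rng), rng.normal(size=3))
        back = Transform.from_row(t.as_row())
        assert np.allclose(back.rotation, t.rotation)
        assert np.allclose(back.translation, t.translation)


class TestScrewDecompose:
    def test_pure_rotation_through_origin(self):
        screw = screw_decompose(rotation_about([0, 0, 1], 90.0))
        assert abs(screw.direction @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert screw.angle == pytest.approx(90.0, abs=1e-9)
        assert screw.pitch == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(screw.point_on_axis[:2], 0.0, atol=1e-9)

    def test_offset_axis_located(self):
        screw = screw_decompose(rotation_about([0, 0, 1], 90.0, point=(5.0, 0.0, 0.0)))
        assert screw.point_on_axis[0] == pytest.approx(5.0, abs=1e-6)
        assert screw.point_on_axis[1] == pytest.approx(0.0, abs=1e-6)

    def test_axis_point_moves_only_along_axis(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            t = Transform(random_rotation(rng), rng.normal(scale=5.0, size=3))
            if rotation_angle(t) < 0.5:
                continue
            screw = screw_decompose(t)
            displaced = t.apply(screw.point_on_axis[None, :])[0] - screw.point_on_axis
            perp = displaced - (displaced @ screw.direction) * screw.direction
            assert np.linalg.norm(perp) < 1e-6

    def test_near_identity_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            screw_decompose(rotation_about([0, 0, 1], 0.01))


unit_quaternions = st.tuples(
    *([st.floats(-1.0, 1.0)] * 4)
).filter(lambda q: np.linalg.norm(q) > 1e-3).map(
    lambda q: np.asarray(q) / np.linalg.norm(q))


class TestTransformProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(q=unit_quaternions,
           shift=st.tuples(*([st.floats(-20.0, 20.0)] * 3)))
    def test_angle_in_range_and_inverse_symmetric(self, q, shift):
        rot = Rotation.from_quat(q).as_matrix()
        t = Transform(rot, np.asarray(shift))
        angle = rotation_angle(t)
        assert 0.0 <= angle <= 180.0
        assert rotation_angle(t.inverse()) == pytest.approx(angle, abs=1e-8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(q=unit_quaternions, seed=st.integers(0, 2**16))
    def test_superpose_recovers_exact_rigid_motion(self, q, seed):
        rot = Rotation.from_quat(q).as_matrix()
        pts = np.random.default_rng(seed).normal(scale=4.0, size=(8, 3))
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        t, rmsd = superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(t.rotation, rot, atol=1e-8)


class TestDomainDecomposition:
    def test_planted_block_rotation_recovered(self):
        spec = block_rotation_spec(9.0, noise_sigma=0.2, seed=42)
        a, b, truth = build_bundle(spec)
        part = decompose_domains(a, b, truth.topology, anchor_helix="h1")
        assert part.assignment == truth.partition.assignment
        report = domain_motion_report(a, b, truth.topology, part)
        assert report.interdomain_rotation == pytest.approx(9.0, abs=0.5)

    def test_identical_models_flag_single_domain(self):
        a, _, truth = build_bundle(BundleSpec(seed=9))
        part = decompose_domains(a, a, truth.topology, anchor_helix="h1")
        assert part.single_domain

    def test_self_report_is_null_motion(self):
        spec = block_rotation_spec(9.0, noise_sigma=0.0, seed=0)
        a, _, truth = build_bundle(spec)
        report = domain_motion_report(a, a, truth.topology, truth.partition)
        assert report.overall_rmsd == pytest.approx(0.0, abs=1e-9)
        assert report.interdomain_rotation == pytest.approx(0.0, abs=1e-6)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in report.domain_rmsd.values())

    def test_hinge_reported_near_planted_axis(self):
        # noiseless: hinge passes through the extracellular face (z = top)
        spec = block_rotation_spec(12.0, noise_sigma=0.0, seed=0)
        a, b, truth = build_bundle(spec)
        report = domain_motion_report(a, b, truth.topology, truth.partition)
        helix, residue = report.hinge_helix_end
        seg = truth.topology[helix]
        ec_res = seg.end if seg.extracellular_end == "end" else seg.start
        assert residue == ec_res

    def test_sparse_helix_skipped_with_warning(self, study):
        truncated = study.apo.subset(
            [r for r in study.apo.residue_numbers()
             if not (study.topology["a8"].start + 2 <= r <= study.topology["a8"].end)])
        with pytest.warns(UserWarning, match="a8"):
            transforms = per_helix_transforms(study.holo, truncated, study.topology)
        assert "a8" not in transforms

    def test_standin_partition_and_angle(self, study):
        part = decompose_domains(study.holo, study.apo, study.topology)
        assert part.domain("I") == ["a1", "a4", "a5", "a6"]
        assert part.domain("II") == ["a2", "a3", "a7", "a8"]
        report = domain_motion_report(study.holo, study.apo, study.topology, part)
        assert report.interdomain_rotation == pytest.approx(study.hinge_angle, abs=0.5)
        # hinge planted at the extracellular end of a6
        assert report.hinge_helix_end == ("a6", study.topology["a6"].start)
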