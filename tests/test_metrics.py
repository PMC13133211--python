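import numpy as np
import pytest
from scipy import stats

from x2br.geometry import TriMesh
from x2br.metrics import (
    MetricsConfig,
    MetricsReport,
    axis_errors,
    chamfer_l1,
    evaluate_pair,
    fscore,
    iou_voxelized,
    normal_consistency,
    sample_surface,
)


from conftest import box_mesh


def _unit_cube(offset=(0, 0, 0)):
    return box_mesh((1, 1, 1), center=np.asarray(offset) + 0.5)


def _brute_chamfer(P, G):
    d = np.abs(P[:, None, :] - G[None, :, :]).sum(axis=2)  # L1
    return d.min(axis=1).mean() + d.min(axis=0).mean()


def _brute_fscore(P, G, t):
    d = np.linalg.norm(P[:, None, :] - G[None, :, :], axis=2)
    precision = (d.min(axis=1) < t).mean()
    recall = (d.min(axis=0) < t).mean()
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


class TestIoU:
    def test_identity(self, capsule_mesh):
        assert iou_voxelized(capsule_mesh, capsule_mesh, pitch=1 / 32) == 1.0

    def test_disjoint(self):
        a = _unit_cube((0, 0, 0))
        b = _unit_cube((3, 0, 0))
        assert iou_voxelized(a, b, pitch=0.25) == 0.0

    def test_half_offset_cubes(self):
        a = _unit_cube((0, 0, 0))
        b = _unit_cube((0.5, 0, 0))
        # exact overlap ratio 0.5 / 1.5 = 1/3
        assert iou_voxelized(a, b, pitch=1 / 64) == pytest.approx(1 / 3, rel=0.05)


class TestSampleSurface:
    def test_count_and_on_surface(self, sphere_mesh):
        pts, normals = sample_surface(sphere_mesh, 5_000, seed=1)
        assert len(pts) == 5_000
        assert np.allclose(np.linalg.norm(normals, axis=1), 1.0)
        # icosphere r=0.4: all samples lie on a face plane within its radius band
        r = np.linalg.norm(pts, axis=1)
        assert r.max() <= 0.4 + 1e-9 and r.min() >= 0.39

    def test_area_weighting(self):
        # two triangles with areas 1 and 4 -> counts ~ 1:4
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [10, 0, 0], [14, 0, 0], [10, 2, 0],
                      [0, 0, 1]])
        m = TriMesh(v, [[0, 1, 2], [3, 4, 5], [0, 2, 6]])
        pts, _ = sample_surface(m, 100_000, seed=0)
        counts = np.array([
            np.count_nonzero(pts[:, 0] < 5),
            np.count_nonzero(pts[:, 0] >= 5),
        ])
        areas = np.array([1 + 1, 4.0])  # two small faces vs one large
        expected = areas / areas.sum() * 100_000
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=1)

    def test_deterministic(self, sphere_mesh):
        a, _ = sample_surface(sphere_mesh, 100, seed=5)
        b, _ = sample_surface(sphere_mesh, 100, seed=5)
        assert np.array_equal(a, b)


class TestChamfer:
    def test_zero_on_identical(self, rng):
        P = rng.normal(size=(50, 3))
        assert chamfer_l1(P, P) == 0.0

    def test_single_point_closed_form(self):
        assert chamfer_l1(np.zeros((1, 3)), np.array([[1.0, 0, 0]])) == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        P = rng.normal(size=(100, 3))
        G = rng.normal(size=(100, 3))
        assert chamfer_l1(P, G) == pytest.approx(_brute_chamfer(P, G), abs=1e-12)

    def test_halved_convention(self, rng):
        P, G = rng.normal(size=(30, 3)), rng.normal(size=(40, 3))
        assert chamfer_l1(P, G, halved=True) == pytest.approx(chamfer_l1(P, G) / 2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            chamfer_l1(np.zeros((0, 3)), np.zeros((5, 3)))


class TestFscore:
    def test_identical(self, rng):
        P = rng.normal(size=(50, 3))
        assert fscore(P, P, t=0.02) == 1.0

    def test_all_far(self):
        assert fscore(np.zeros((5, 3)), np.ones((5, 3)) * 10, t=0.02) == 0.0

    def test_half_overlap_two_thirds(self):
        G = np.array([[0, 0, 0], [5, 0, 0]], dtype=float)
        P = np.array([[0, 0, 0]], dtype=float)
        # precision 1, recall 0.5 -> F = 2/3
        assert fscore(P, G, t=0.1) == pytest.approx(2 / 3)

    def test_matches_brute_force(self, rng):
        P = rng.normal(scale=0.1, size=(100, 3))
        G = rng.normal(scale=0.1, size=(100, 3))
        t = 0.05
        assert fscore(P, G, t) == pytest.approx(_brute_fscore(P, G, t), abs=1e-12)

    def test_monotone_in_threshold(self, rng):
        P = rng.normal(scale=0.1, size=(200, 3))
        G = rng.normal(scale=0.1, size=(200, 3))
        values = [fscore(P, G, t) for t in (0.01, 0.02, 0.05, 0.1, 0.5)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestNormalConsistency:
    def test_identical(self, sphere_mesh):
        pts, normals = sample_surface(sphere_mesh, 1000, seed=0)
        assert normal_consistency(pts, normals, pts, normals) == pytest.approx(1.0)

    def test_orthogonal(self):
        pts = np.random.default_rng(1).normal(size=(100, 3))
        nx = np.tile([1.0, 0, 0], (100, 1))
        ny = np.tile([0, 1.0, 0], (100, 1))
        assert normal_consistency(pts, nx, pts, ny) == pytest.approx(0.0)

    def test_random_orientations_half(self, rng):
        n = 10_000
        pts_a = rng.normal(size=(n, 3))
        pts_b = rng.normal(size=(n, 3))
        na = rng.normal(size=(n, 3))
        nb = rng.normal(size=(n, 3))
        na /= np.linalg.norm(na, axis=1, keepdims=True)
        nb /= np.linalg.norm(nb, axis=1, keepdims=True)
        # E|cos(theta)| = 0.5 for independent uniform orientations
        assert normal_consistency(pts_a, na, pts_b, nb) == pytest.approx(0.5, abs=0.02)

    def test_zero_normal_rejected(self):
        pts = np.zeros((2, 3))
        bad = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValueError):
            normal_consistency(pts, bad, pts, bad)


class TestAxisErrors:
    def test_identity(self, capsule_mesh):
        maxe, maye, maze = axis_errors(capsule_mesh, capsule_mesh)
        assert max(maxe, maye, maze) < 1e-12

    def test_rigid_transform_cancelled_by_icp(self, capsule_mesh):
        ang = np.deg2rad(8)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        moved = capsule_mesh.transformed(rotation=rot, translation=[0.05, -0.02, 0.01])
        maxe, maye, maze = axis_errors(moved, capsule_mesh)
        assert max(maxe, maye, maze) < 1e-6

    def test_translation_without_icp(self, capsule_mesh):
        # delta below half the minimal vertex spacing so nearest-neighbor
        # correspondences stay exact
        delta = 0.01
        moved = capsule_mesh.translated([0, 0, delta])
        maxe, maye, maze = axis_errors(moved, capsule_mesh, icp_align=False)
        assert maze == pytest.approx(delta, abs=1e-9)
        assert maxe == pytest.approx(0.0, abs=1e-9)
        assert maye == pytest.approx(0.0, abs=1e-9)


class TestEvaluatePair:
    def test_identity_bundle(self, capsule_mesh):
        cfg = MetricsConfig(n_samples=2000, pitch=1 / 32)
        report = evaluate_pair(capsule_mesh, capsule_mesh, cfg)
        assert report.iou == 1.0
        assert report.fscore == 1.0
        assert report.chamfer_l1 == 0.0  # shared sample seed -> identical sets
        assert report.normal_consistency == pytest.approx(1.0)
        assert max(report.maxe, report.maye, report.maze) < 1e-12

    def test_report_roundtrip(self, capsule_mesh):
        cfg = MetricsConfig(n_samples=500, pitch=1 / 16)
        report = evaluate_pair(capsule_mesh, capsule_mesh, cfg)
        assert MetricsReport.from_json(report.to_json()) == report

    def test_sampling_stability(self, sphere_mesh, capsule_mesh):
        values = []
        for seed in (0, 1):
            cfg = MetricsConfig(n_samples=50_000, pitch=1 / 16, seed=seed)
            pts_p, _ = sample_surface(sphere_mesh, cfg.n_samples, seed=cfg.seed)
            pts_g, _ = sample_surface(capsule_mesh, cfg.n_samples, seed=cfg.seed + 1)
            values.append(chamfer_l1(pts_p, pts_g))
        assert abs(values[0] - values[1]) / values[0] < 0.01

    def test_common_rigid_transform_invariance(self, capsule_mesh, sphere_mesh):
        cfg = MetricsConfig(n_samples=5000, pitch=1 / 32)
        base = evaluate_pair(sphere_mesh, capsule_mesh, cfg)
        ang = np.deg2rad(15)
        rot = np.array([[1, 0, 0], [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        a = sphere_mesh.transformed(rotation=rot, translation=[0.1, 0.2, 0.3])
        b = capsule_mesh.transformed(rotation=rot, translation=[0.1, 0.2, 0.3])
        moved = evaluate_pair(a, b, cfg)
        assert moved.chamfer_l1 == pytest.approx(base.chamfer_l1, rel=0.02)
        assert moved.fscore == pytest.approx(base.fscore, abs=0.02)
        assert moved.iou == pytest.approx(base.iou, abs=0.05)
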