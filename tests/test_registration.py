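import numpy as np
import pytest

from x2br.geometry import MeshError, PartLabeledMesh, TriMesh
from x2br.phantoms import deform_known, make_toy_thorax
from x2br.registration import (
    CpdParams,
    RigidTransform,
    assemble_template,
    build_kernel,
    cpd_nonrigid,
    gbcpd_nonrigid,
    geodesic_distances,
    icp_rigid,
)


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))


class TestIcp:
    def test_identity(self, rng):
        pts = rng.normal(size=(100, 3))
        tf = icp_rigid(pts, pts)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0, atol=1e-9)

    def test_rotation_recovery(self, rng):
        src = rng.normal(size=(200, 3))
        R = _rot_z(10.0)
        tf = icp_rigid(src, src @ R.T)
        angle = np.rad2deg(np.arccos(np.clip((np.trace(tf.rotation @ R.T) - 1) / 2, -1, 1)))
        assert angle < 0.1

    def test_translation_recovery(self, rng):
        src = rng.normal(size=(150, 3))
        tf = icp_rigid(src, src + [0.1, 0, 0])
        assert np.allclose(tf.translation, [0.1, 0, 0], atol=1e-6)

    def test_degenerate_rejected(self):
        line = np.linspace(0, 1, 10)[:, None] * np.array([1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear|3 points"):
            icp_rigid(line, line)


class TestGeodesicDistances:
    def test_adjacent_vertices_edge_length(self, capsule_mesh):
        e = capsule_mesh.edges_unique()[0]
        d = geodesic_distances(capsule_mesh, [e[0]])
        expected = np.linalg.norm(
            capsule_mesh.vertices[e[0]] - capsule_mesh.vertices[e[1]]
        )
        assert d[0, e[1]] == pytest.approx(expected)

    def test_straight_strip_equals_euclidean(self):
        # planar triangulated strip: shortest path along collinear vertices
        n = 6
        v = np.array(
            [[i, 0.0, 0.0] for i in range(n)] + [[i + 0.5, 1.0, 0.0] for i in range(n - 1)]
        )
        faces = []
        for i in range(n - 1):
            faces.append([i, i + 1, n + i])
        mesh = TriMesh(v, np.asarray(faces))
        d = geodesic_distances(mesh, [0])
        assert d[0, n - 1] == pytest.approx(n - 1.0)

    def test_antipodal_close_to_great_circle(self):
        from x2br.phantoms import icosphere

        for sub in (1, 2, 3):
            sph = icosphere(sub)
            # vertex 0 of the icosahedron has an exact antipode in the mesh
            target = np.argmin(np.linalg.norm(sph.vertices + sph.vertices[0], axis=1))
            d = geodesic_distances(sph, [0])[0, target]
            # graph paths upper-bound the true geodesic pi*r; on a
            # triangulated sphere the lattice dilation stays below 2/sqrt(3)
            assert 1.0 - 1e-9 <= d / np.pi <= 2.0 / np.sqrt(3.0)

    def test_disconnected_parts_infinite(self, small_thorax):
        d = geodesic_distances(small_thorax.mesh, [0])
        assert np.isinf(d).any()

    def test_empty_subset_rejected(self, capsule_mesh):
        with pytest.raises(ValueError):
            geodesic_distances(capsule_mesh, [])


class TestBuildKernel:
    def test_zero_distance_diagonal(self, rng):
        pts = rng.normal(size=(40, 3))
        from scipy.spatial.distance import cdist

        G = build_kernel(cdist(pts, pts), beta=0.5).matrix()
        assert np.allclose(np.diag(G), 1.0)

    def test_beta_limit_all_ones(self, rng):
        from scipy.spatial.distance import cdist

        pts = rng.normal(size=(20, 3))
        G = build_kernel(cdist(pts, pts), beta=1e6).matrix()
        assert np.allclose(G, 1.0, atol=1e-9)

    def test_low_rank_error_bound(self, rng):
        from scipy.spatial.distance import cdist

        pts = rng.normal(size=(200, 3))
        d = cdist(pts, pts)
        full = build_kernel(d, beta=0.8)
        G = full.matrix()
        eigvals = np.sort(np.linalg.eigvalsh(G))[::-1]
        k = 20
        approx = build_kernel(d, beta=0.8, k=k).matrix()
        # spectral bound: rank-k truncation error <= (k+1)-th eigenvalue * n
        assert np.abs(G - approx).max() <= eigvals[k] * len(pts) + 1e-9

    def test_infinite_distances_zero_coupling(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        G = build_kernel(d, beta=1.0).matrix()
        assert G[0, 1] == 0.0 and G[1, 0] == 0.0

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            build_kernel(np.zeros((2, 2)), beta=0.0)


class TestCpdNonrigid:
    def test_identity_target(self, capsule_mesh):
        params = CpdParams(beta=32.0, max_iter=50, tol=1e-8)
        field, deformed = cpd_nonrigid(capsule_mesh, capsule_mesh.vertices, params)
        diag = capsule_mesh.bbox_diagonal()
        assert np.linalg.norm(field.displacements, axis=1).mean() <= 1e-3 * diag
        assert np.array_equal(deformed.faces, capsule_mesh.faces)

    def test_objective_monotone(self, capsule_mesh):
        deformed_gt, _ = deform_known(capsule_mesh, "bend", 0.03, seed=1)
        field, _ = cpd_nonrigid(capsule_mesh, deformed_gt.vertices,
                                CpdParams(max_iter=40))
        trace = np.asarray(field.objective_trace)
        increases = np.diff(trace)
        assert increases.max() <= 1e-8 * np.maximum(np.abs(trace[:-1]), 1.0).max()

    def test_bend_recovery(self, capsule_mesh):
        deformed_gt, _ = deform_known(capsule_mesh, "bend", 0.05, seed=3)
        params = CpdParams(beta=32.0, lam=2.0, max_iter=150, tol=1e-8)
        _, registered = cpd_nonrigid(capsule_mesh, deformed_gt.vertices, params)
        err = np.linalg.norm(registered.vertices - deformed_gt.vertices, axis=1).mean()
        assert err <= 0.1 * 0.05

    def test_outlier_robustness(self, capsule_mesh, rng):
        deformed_gt, _ = deform_known(capsule_mesh, "bend", 0.03, seed=2)
        params = CpdParams(beta=32.0, max_iter=150, tol=1e-8, outlier_weight=0.1,
                           anneal=0.95)  # annealed to escape the diffuse optimum
        _, clean = cpd_nonrigid(capsule_mesh, deformed_gt.vertices, params)
        n_out = len(deformed_gt.vertices) // 5
        outliers = rng.uniform(-0.5, 0.5, size=(n_out, 3))
        noisy_target = np.vstack([deformed_gt.vertices, outliers])
        _, noisy = cpd_nonrigid(capsule_mesh, noisy_target, params)
        err_clean = np.linalg.norm(clean.vertices - deformed_gt.vertices, axis=1).mean()
        err_noisy = np.linalg.norm(noisy.vertices - deformed_gt.vertices, axis=1).mean()
        assert err_noisy <= max(2.0 * err_clean, 0.005)

    def test_empty_rejected(self, capsule_mesh):
        with pytest.raises(ValueError):
            cpd_nonrigid(capsule_mesh, np.zeros((0, 3)))


class TestGbcpd:
    @pytest.fixture(scope="class")
    def articulated(self):
        thorax = make_toy_thorax(4, 3, jitter=0.0, seed=11, resolution=1)
        with pytest.warns(RuntimeWarning):
            deformed, disp = deform_known(thorax, "part_articulation", 0.05, seed=4)
        return thorax, deformed, disp

    def test_zero_deformation(self, small_thorax):
        params = CpdParams(beta=30.0, lam=200.0, max_iter=50, tol=1e-8)
        field, out = gbcpd_nonrigid(small_thorax, small_thorax.mesh.vertices, params)
        diag = small_thorax.mesh.bbox_diagonal()
        # decoupled closed components may slide marginally along symmetric
        # directions; displacements stay within 0.2% of the diagonal
        assert np.linalg.norm(field.displacements, axis=1).mean() <= 2e-3 * diag
        assert field.kernel_type == "geodesic"

    def test_topology_preserved(self, small_thorax):
        _, out = gbcpd_nonrigid(small_thorax, small_thorax.mesh.vertices,
                                CpdParams(max_iter=10))
        assert out.n_vertices == small_thorax.mesh.n_vertices
        assert np.array_equal(out.faces, small_thorax.mesh.faces)

    def test_geodesic_beats_euclidean_on_articulation(self, articulated):
        thorax, deformed, disp = articulated
        moved = np.linalg.norm(disp, axis=1) > 0
        # coherence width ~ bounding-box scale and a stiff regularizer: the
        # euclidean kernel then couples adjacent parts while the geodesic
        # kernel lets the articulated pair move freely
        beta = 0.87 / thorax.mesh.mean_edge_length()
        params = CpdParams(beta=beta, lam=200.0, max_iter=50, tol=1e-6)
        _, geo = gbcpd_nonrigid(thorax, deformed.mesh.vertices, params)
        _, euc = cpd_nonrigid(thorax.mesh, deformed.mesh.vertices,
                              CpdParams(**{**params.__dict__, "kernel_type": "euclidean"}))
        err_geo = np.linalg.norm(geo.vertices - deformed.mesh.vertices, axis=1)
        err_euc = np.linalg.norm(euc.vertices - deformed.mesh.vertices, axis=1)
        assert err_geo[moved].mean() < err_euc[moved].mean()
        assert err_geo.mean() < err_euc.mean()

    def test_low_rank_matches_full_rank(self, small_thorax):
        deformed, _ = deform_known(small_thorax.mesh, "bend", 0.02, seed=6)
        beta = 0.87 / small_thorax.mesh.mean_edge_length()
        full_params = CpdParams(beta=beta, lam=2.0, max_iter=25, tol=1e-7)
        lr_params = CpdParams(beta=beta, lam=2.0, max_iter=25, tol=1e-7, low_rank=200)
        _, full = gbcpd_nonrigid(small_thorax, deformed.vertices, full_params)
        _, low = gbcpd_nonrigid(small_thorax, deformed.vertices, lr_params)
        diff = np.linalg.norm(full.vertices - low.vertices, axis=1).mean()
        assert diff < 0.01 * small_thorax.mesh.bbox_diagonal()


class TestAssembleTemplate:
    def test_all_parts(self, small_thorax):
        out = assemble_template(small_thorax, small_thorax.part_names)
        assert out.mesh.n_faces == small_thorax.mesh.n_faces

    def test_subset(self, small_thorax):
        out = assemble_template(small_thorax, ["spine", "rib_pair_01"])
        assert set(out.part_names) == {"spine", "rib_pair_01"}

    def test_accepts_box_objects(self, small_thorax):
        from x2br.projection import project_part_bboxes

        boxes = project_part_bboxes(small_thorax, angle=0.0)
        out = assemble_template(small_thorax, boxes)
        assert set(out.part_names) == set(small_thorax.part_names)

    def test_empty_detection_rejected(self, small_thorax):
        with pytest.raises(MeshError):
            assemble_template(small_thorax, [])

    def test_unknown_part_rejected(self, small_thorax):
        with pytest.raises(MeshError, match="unknown"):
            assemble_template(small_thorax, ["scapula"])
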