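"""Alignment, depth projection and landmark correspondence."""

import numpy as np
import pytest
import trimesh

from ocuprost import geometry, rings, synth
from ocuprost.errors import AlignmentDegenerateError, GeometryError


def _canonical_markers(r=6.0):
    return dict(p_N=np.array([r, 0.0, 0.0]), p_S=np.array([0.0, r, 0.0]),
                p_T=np.array([-r, 0.0, 0.0]), p_I=np.array([0.0, -r, 0.0]))


def _scan_from(mesh, markers, side="right"):
    return geometry.MarkedScan(vertices=mesh.vertices, faces=mesh.faces,
                               eye_side=side, **markers)


class TestAlignShape:
    def test_canonical_markers_are_fixed_point(self):
        mesh = trimesh.creation.icosphere(2, radius=6.0)
        scan = _scan_from(mesh, _canonical_markers())
        out = geometry.align_shape(scan)
        assert np.allclose(out.vertices, mesh.vertices, atol=1e-9)

    def test_recovers_random_rigid_transform(self):
        rng = np.random.default_rng(0)
        mesh = trimesh.creation.icosphere(2, radius=6.0)
        markers = _canonical_markers()
        Q, t = synth._random_rigid(rng, 15.0)
        moved = {k: v @ Q.T + t for k, v in markers.items()}
        scan = geometry.MarkedScan(vertices=mesh.vertices @ Q.T + t,
                                   faces=mesh.faces, eye_side="right", **moved)
        out = geometry.align_shape(scan)
        assert np.linalg.norm(out.vertices - mesh.vertices, axis=1).max() < 1e-9
        # aligned markers land on the axes
        m = out.markers  # rows S, N, I, T
        assert abs(m[1][1]) < 1e-9 and m[1][0] > 0      # N on +x
        assert abs(m[0][0]) < 1e-9 and m[0][1] > 0      # S on +y

    def test_left_eye_mirrored_with_flipped_faces(self):
        mesh = trimesh.creation.icosphere(2, radius=6.0)
        scan = _scan_from(mesh, _canonical_markers(), side="left")
        out = geometry.align_shape(scan)
        assert np.allclose(out.vertices[:, 0], -mesh.vertices[:, 0])
        assert np.allclose(out.vertices[:, 1:], mesh.vertices[:, 1:])
        m_out = trimesh.Trimesh(out.vertices, out.faces, process=False)
        assert m_out.volume > 0  # winding still outward after the mirror

    def test_idempotent_on_aligned_markers(self):
        rng = np.random.default_rng(4)
        mesh = trimesh.creation.icosphere(2, radius=6.0)
        markers = _canonical_markers()
        Q, t = synth._random_rigid(rng, 5.0)
        moved = {k: v @ Q.T + t for k, v in markers.items()}
        once = geometry.align_shape(geometry.MarkedScan(
            vertices=mesh.vertices @ Q.T + t, faces=mesh.faces, **moved))
        m = once.markers
        twice = geometry.align_shape(geometry.MarkedScan(
            vertices=once.vertices, faces=once.faces,
            p_S=m[0], p_N=m[1], p_I=m[2], p_T=m[3]))
        assert np.linalg.norm(twice.vertices - once.vertices, axis=1).max() < 1e-9

    def test_collinear_markers_raise(self):
        mesh = trimesh.creation.icosphere(1)
        bad = dict(p_N=np.array([1.0, 0, 0]), p_S=np.array([2.0, 0, 0]),
                   p_I=np.array([3.0, 0, 0]), p_T=np.array([4.0, 0, 0]))
        with pytest.raises(AlignmentDegenerateError):
            geometry.align_shape(_scan_from(mesh, bad))


class TestDepthProject:
    def test_hemisphere_apex_depth(self):
        sphere = trimesh.creation.icosphere(4, radius=1.0)
        img = geometry.depth_project(sphere.vertices, sphere.faces, "front",
                                     resolution=256, extent=4.0)
        c = img.xy_to_pixel(np.array([[0.0, 0.0]]))[0]
        centre = img.values[int(round(c[1])), int(round(c[0]))]
        assert abs(centre - 1.0) <= img.pixel_pitch

    def test_front_depth_not_less_than_back(self):
        mesh = synth._shell_mesh(10, 11, 3, 9, 0.8, 3)
        f = geometry.depth_project(mesh.vertices, mesh.faces, "front")
        b = geometry.depth_project(mesh.vertices, mesh.faces, "back")
        both = f.valid_mask & b.valid_mask
        assert np.all(f.values[both] >= b.values[both] - 1e-9)

    def test_projected_sphere_area_matches_circle(self):
        sphere = trimesh.creation.icosphere(4, radius=5.0)
        img = geometry.depth_project(sphere.vertices, sphere.faces, "front",
                                     resolution=256, extent=16.0)
        area = img.valid_mask.sum() * img.pixel_pitch ** 2
        assert abs(area - np.pi * 25.0) / (np.pi * 25.0) < 0.02

    def test_empty_mesh_raises(self):
        with pytest.raises(GeometryError):
            geometry.depth_project(np.zeros((0, 3)), np.zeros((0, 3), int), "front")


class TestCorrespondence:
    def test_point_and_face_counts(self, canonical_landmarks):
        lm = canonical_landmarks
        assert lm.points.shape == (838, 3)
        assert lm.front_count == 189 and lm.back_count == 649
        assert lm.faces.shape == (1672, 3)

    def test_closed_genus_zero_surface(self, canonical_landmarks):
        F = canonical_landmarks.faces
        edges = {tuple(sorted(e)) for f in F for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0]))}
        assert len(edges) == 2508
        assert 838 - len(edges) + len(F) == 2
        m = trimesh.Trimesh(canonical_landmarks.points, F, process=False)
        assert m.is_watertight and m.is_winding_consistent

    def test_axisymmetric_shape_gives_constant_ring_depth(self):
        # true surface of revolution (bicone, finite silhouette slope):
        # every correspondence ring shares a single z up to sampling error
        n_seg, R, cf, cb = 192, 10.0, 3.0, 8.0
        ang = np.arange(n_seg) * 2 * np.pi / n_seg
        equator = np.stack([R * np.cos(ang), R * np.sin(ang), np.zeros(n_seg)], axis=1)
        V = np.vstack([[[0, 0, cf]], equator, [[0, 0, -cb]]])
        F = []
        for j in range(n_seg):
            a, b = 1 + j, 1 + (j + 1) % n_seg
            F.append((0, a, b))
            F.append((n_seg + 1, b, a))
        lm = geometry.generate_correspondence(
            geometry.AlignedShape(vertices=V, faces=np.asarray(F)))
        for ring in range(1, len(rings.FRONT_RING_COUNTS) + 1):
            z = lm.points[rings.front_ring_slice(ring), 2]
            assert z.max() - z.min() < 0.03  # bilinear + edge-march tolerance

    def test_commutes_with_90_degree_rotation(self, canonical_scan):
        aligned = geometry.align_shape(canonical_scan)
        lm = geometry.generate_correspondence(aligned)
        c, s = 0.0, 1.0
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        rot = geometry.AlignedShape(vertices=aligned.vertices @ R.T,
                                    faces=aligned.faces)
        lm_rot = geometry.generate_correspondence(rot)
        # rotating the ring point sets back must reproduce the originals
        for ring_slice in [rings.front_ring_slice(r) for r in range(1, 7)]:
            p0 = lm.points[ring_slice] @ R.T
            p1 = lm_rot.points[ring_slice]
            n = len(p0)
            shift = n // 4  # 90 degrees worth of ring positions
            assert np.allclose(np.roll(p0, shift, axis=0), p1, atol=0.05)

    def test_convex_shape_mesh_has_no_self_intersections(self):
        sphere = trimesh.creation.icosphere(3)
        v = sphere.vertices * [9.0, 10.0, 7.0]
        lm = geometry.generate_correspondence(
            geometry.AlignedShape(vertices=v, faces=sphere.faces))
        m = trimesh.Trimesh(lm.points, lm.faces, process=False)
        assert m.is_watertight and m.is_volume


class TestSampleDepth:
    def test_bilinear_matches_plane(self):
        # depths linear in x: bilinear sampling must be exact
        n = 32
        vals = np.tile(np.arange(n, dtype=float), (n, 1))
        img = geometry.DepthImage(values=vals, valid_mask=np.ones((n, n), bool),
                                  pixel_pitch=1.0, origin=(0.0, 0.0))
        out = geometry.sample_depth(img, np.array([[3.25, 5.5], [10.75, 2.0]]))
        assert np.allclose(out, [3.25, 10.75])

    def test_gap_beyond_two_pixels_raises(self):
        n = 16
        mask = np.zeros((n, n), bool)
        mask[:4] = True
        img = geometry.DepthImage(values=np.zeros((n, n)), valid_mask=mask,
                                  pixel_pitch=1.0, origin=(0.0, 0.0))
        with pytest.raises(geometry.CorrespondenceError):
            geometry.sample_depth(img, np.array([[8.0, 12.0]]))
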