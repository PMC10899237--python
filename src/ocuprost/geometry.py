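"""Canonical alignment, depth projection and landmark correspondence.

The canonical (iris-plane) frame used throughout the pipeline: the iris lies
in the x-y plane with the limbus centre at the origin, +x points nasal, +y
superior and +z toward the cornea dome.  Left-eye geometry is mirrored
across the y-z plane so every shape fits a right socket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import rings
from .errors import AlignmentDegenerateError, CorrespondenceError, GeometryError

Side = Literal["left", "right"]

#: resolution / extent of the depth projections used for correspondence
CORRESPONDENCE_RESOLUTION = 512
CORRESPONDENCE_EXTENT_MM = 32.0


@dataclass
class MarkedScan:
    """A scanned prosthesis mesh with the four limbus/crosshair marker points.

    Marker points are the intersections of the limbus ring marking with the
    crosshair: superior, nasal, inferior and temporal, in mm, in the scanner
    frame.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray     # (m, 3) int
    p_S: np.ndarray
    p_N: np.ndarray
    p_I: np.ndarray
    p_T: np.ndarray
    eye_side: Side = "right"

    def markers(self) -> np.ndarray:
        return np.stack([self.p_S, self.p_N, self.p_I, self.p_T])


@dataclass
class AlignedShape:
    """A prosthesis mesh expressed in the canonical iris-plane frame."""

    vertices: np.ndarray
    faces: np.ndarray
    markers: np.ndarray | None = None  # aligned (S, N, I, T) rows, for diagnostics


@dataclass
class DepthImage:
    """Orthographic z-depth map of a surface over a square x-y window."""

    values: np.ndarray      # (H, W) depth along z in mm
    valid_mask: np.ndarray  # (H, W) bool
    pixel_pitch: float      # mm / px
    origin: tuple[float, float]  # (x, y) of pixel (0, 0) centre, mm

    def xy_to_pixel(self, xy: np.ndarray) -> np.ndarray:
        """Continuous (col, row) pixel coordinates of points (x, y) in mm."""
        xy = np.atleast_2d(xy)
        col = (xy[:, 0] - self.origin[0]) / self.pixel_pitch
        row = (xy[:, 1] - self.origin[1]) / self.pixel_pitch
        return np.stack([col, row], axis=1)


@dataclass
class LandmarkMesh:
    """The 838-vertex correspondence representation of a prosthesis shape.

    All instances share the fixed face list (1672 triangles) so a shape is
    fully described by its ordered point cloud.
    """

    points: np.ndarray  # (838, 3) mm
    faces: np.ndarray = field(default_factory=lambda: rings.FACES)
    front_count: int = rings.FRONT_COUNT
    back_count: int = rings.BACK_COUNT

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (rings.TOTAL_POINTS, 3):
            raise ValueError(f"expected ({rings.TOTAL_POINTS}, 3) points, got {self.points.shape}")

    @property
    def front_points(self) -> np.ndarray:
        return self.points[: self.front_count]

    @property
    def back_points(self) -> np.ndarray:
        return self.points[self.front_count:]

    def limbus_ring(self) -> np.ndarray:
        """Coordinates of the limbus landmarks (front ring 3)."""
        return self.points[rings.limbus_indices()]

    def limbus_diameter(self) -> float:
        ring = self.limbus_ring()
        return float(2.0 * np.mean(np.hypot(ring[:, 0], ring[:, 1])))

    def flatten(self) -> np.ndarray:
        return self.points.reshape(-1)

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "LandmarkMesh":
        return cls(points=np.asarray(flat, dtype=float).reshape(rings.TOTAL_POINTS, 3))


# canonical marker targets: N -> +x, S -> +y, I -> -y, T -> -x
_MARKER_TARGETS = {
    "N": np.array([1.0, 0.0, 0.0]),
    "S": np.array([0.0, 1.0, 0.0]),
    "I": np.array([0.0, -1.0, 0.0]),
    "T": np.array([-1.0, 0.0, 0.0]),
}


def align_shape(scan: MarkedScan) -> AlignedShape:
    """Rigidly align a marked scan into the canonical iris-plane frame.

    The mesh is translated so the marker centroid sits at the origin and
    rotated by the least-squares solution mapping the centred markers onto
    the axis directions (nasal +x, superior +y).  The least-squares matrix is
    projected to the nearest proper rotation (SVD orthogonalization) so the
    transform stays rigid.  Left-eye scans are mirrored across the y-z plane
    afterwards, with triangle winding flipped.
    """
    P_rows = np.stack([scan.p_N, scan.p_S, scan.p_I, scan.p_T]).astype(float)
    centroid = P_rows.mean(axis=0)
    P = P_rows - centroid
    # degenerate if the markers do not span a plane
    sv = np.linalg.svd(P, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300) or sv[0] == 0.0:
        raise AlignmentDegenerateError("marker points are collinear or coincident")
    T = np.stack([_MARKER_TARGETS[k] for k in ("N", "S", "I", "T")])
    R_ls, *_ = np.linalg.lstsq(P, T, rcond=None)
    U, _, Vt = np.linalg.svd(R_ls)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ D @ Vt

    vertices = (scan.vertices - centroid) @ R
    markers = (np.stack([scan.p_S, scan.p_N, scan.p_I, scan.p_T]) - centroid) @ R
    faces = np.asarray(scan.faces).copy()
    if scan.eye_side == "left":
        vertices = vertices * np.array([-1.0, 1.0, 1.0])
        markers = markers * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]
    return AlignedShape(vertices=vertices, faces=faces, markers=markers)


def depth_project(
    vertices: np.ndarray,
    faces: np.ndarray,
    side: Literal["front", "back"],
    resolution: int = CORRESPONDENCE_RESOLUTION,
    extent: float = CORRESPONDENCE_EXTENT_MM,
) -> DepthImage:
    """Orthographic z-projection of a mesh onto a square pixel grid.

    ``front`` keeps the surface point nearest the viewer at +z (the maximum
    z per pixel), ``back`` the farthest (minimum z).  Pixels whose centre is
    not covered by any triangle are invalid.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        raise GeometryError("cannot project an empty mesh")
    pitch = extent / resolution
    origin = (-extent / 2 + pitch / 2, -extent / 2 + pitch / 2)
    buf = np.full((resolution, resolution), -np.inf if side == "front" else np.inf)

    tri = vertices[faces]  # (m, 3, 3)
    for p0, p1, p2 in tri:
        xs = np.array([p0[0], p1[0], p2[0]])
        ys = np.array([p0[1], p1[1], p2[1]])
        j0 = max(int(np.floor((xs.min() - origin[0]) / pitch)), 0)
        j1 = min(int(np.ceil((xs.max() - origin[0]) / pitch)), resolution - 1)
        i0 = max(int(np.floor((ys.min() - origin[1]) / pitch)), 0)
        i1 = min(int(np.ceil((ys.max() - origin[1]) / pitch)), resolution - 1)
        if j1 < j0 or i1 < i0:
            continue
        d = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
        if abs(d) < 1e-14:
            continue  # silhouette-degenerate in projection
        px = origin[0] + np.arange(j0, j1 + 1) * pitch
        py = origin[1] + np.arange(i0, i1 + 1) * pitch
        gx, gy = np.meshgrid(px, py)
        w0 = ((p1[0] - gx) * (p2[1] - gy) - (p2[0] - gx) * (p1[1] - gy)) / d
        w1 = ((p2[0] - gx) * (p0[1] - gy) - (p0[0] - gx) * (p2[1] - gy)) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-12) & (w1 >= -1e-12) & (w2 >= -1e-12)
        if not inside.any():
            continue
        z = w0 * p0[2] + w1 * p1[2] + w2 * p2[2]
        sub = buf[i0:i1 + 1, j0:j1 + 1]
        if side == "front":
            np.copyto(sub, np.maximum(sub, np.where(inside, z, -np.inf)))
        else:
            np.copyto(sub, np.minimum(sub, np.where(inside, z, np.inf)))
    valid = np.isfinite(buf)
    values = np.where(valid, buf, 0.0)
    return DepthImage(values=values, valid_mask=valid, pixel_pitch=pitch, origin=origin)


def sample_depth(img: DepthImage, xy: np.ndarray, max_gap_px: float = 2.0) -> np.ndarray:
    """Bilinear depth at (x, y) mm positions, nearest-valid fallback at edges.

    Raises :class:`CorrespondenceError` when no valid pixel lies within
    ``max_gap_px`` of a requested sample (a hole in the projection).
    """
    pix = img.xy_to_pixel(np.atleast_2d(xy))
    H, W = img.values.shape
    out = np.empty(len(pix))
    for n, (c, r) in enumerate(pix):
        c0, r0 = int(np.floor(c)), int(np.floor(r))
        fc, fr = c - c0, r - r0
        ok = True
        acc = 0.0
        for (ri, ci, w) in (
            (r0, c0, (1 - fr) * (1 - fc)),
            (r0, c0 + 1, (1 - fr) * fc),
            (r0 + 1, c0, fr * (1 - fc)),
            (r0 + 1, c0 + 1, fr * fc),
        ):
            if 0 <= ri < H and 0 <= ci < W and img.valid_mask[ri, ci]:
                acc += w * img.values[ri, ci]
            elif w > 1e-12:
                ok = False
                break
        if ok:
            out[n] = acc
            continue
        # nearest valid pixel within the allowed gap
        ri0 = max(int(np.floor(r - max_gap_px)), 0)
        ri1 = min(int(np.ceil(r + max_gap_px)), H - 1)
        ci0 = max(int(np.floor(c - max_gap_px)), 0)
        ci1 = min(int(np.ceil(c + max_gap_px)), W - 1)
        patch = img.valid_mask[ri0:ri1 + 1, ci0:ci1 + 1]
        if not patch.any():
            raise CorrespondenceError(
                f"projection hole at ({xy[n] if np.ndim(xy) > 1 else xy}): "
                f"no valid pixel within {max_gap_px} px"
            )
        rr, cc = np.nonzero(patch)
        d2 = (rr + ri0 - r) ** 2 + (cc + ci0 - c) ** 2
        k = int(np.argmin(d2))
        if d2[k] > max_gap_px ** 2:
            raise CorrespondenceError("projection hole exceeds the allowed gap")
        out[n] = img.values[rr[k] + ri0, cc[k] + ci0]
    return out


def _edge_radii(mask: np.ndarray, pitch: float, origin: tuple[float, float],
                extent: float) -> np.ndarray:
    """Radial distance from the origin to the projection silhouette, per direction."""
    H, W = mask.shape
    step = pitch / 2.0
    n_steps = int(extent / step)
    radii = np.empty(rings.N_DIRECTIONS)
    angles = np.arange(rings.N_DIRECTIONS) * 2 * np.pi / rings.N_DIRECTIONS
    for k, a in enumerate(angles):
        dx, dy = np.cos(a), np.sin(a)
        r_last = 0.0
        for s in range(1, n_steps):
            x, y = dx * s * step, dy * s * step
            ci = int(round((x - origin[0]) / pitch))
            ri = int(round((y - origin[1]) / pitch))
            if not (0 <= ri < H and 0 <= ci < W) or not mask[ri, ci]:
                break
            r_last = s * step
        if r_last <= 0:
            raise CorrespondenceError(f"projection does not cover the origin (direction {k})")
        radii[k] = r_last
    return radii


def generate_correspondence(shape: AlignedShape) -> LandmarkMesh:
    """Place the 838 corresponding landmarks on an aligned prosthesis shape.

    Front and back depth projections are traced radially from the origin for
    48 directions at 7.5 degree steps; points are placed at the fixed ring
    fractions of :mod:`ocuprost.rings` and their depths sampled bilinearly.
    """
    front = depth_project(shape.vertices, shape.faces, "front")
    back = depth_project(shape.vertices, shape.faces, "back")
    H, W = front.valid_mask.shape
    c0 = front.xy_to_pixel(np.array([[0.0, 0.0]]))[0]
    if not front.valid_mask[int(round(c0[1])), int(round(c0[0]))]:
        raise CorrespondenceError("front projection does not cover the origin")

    radii = _edge_radii(front.valid_mask, front.pixel_pitch, front.origin,
                        CORRESPONDENCE_EXTENT_MM)

    pts = np.zeros((rings.TOTAL_POINTS, 3))
    # centres
    pts[0, 2] = sample_depth(front, np.array([[0.0, 0.0]]))[0]
    pts[rings.FRONT_COUNT, 2] = sample_depth(back, np.array([[0.0, 0.0]]))[0]

    for which, img, counts, fracs, ring_slice in (
        ("front", front, rings.FRONT_RING_COUNTS, rings.FRONT_RING_FRACTIONS,
         rings.front_ring_slice),
        ("back", back, rings.BACK_RING_COUNTS, rings.BACK_RING_FRACTIONS,
         rings.back_ring_slice),
    ):
        for r, (count, frac) in enumerate(zip(counts, fracs), start=1):
            dirs = rings.ring_direction_indices(count)
            ang = dirs * 2 * np.pi / rings.N_DIRECTIONS
            rr = frac * radii[dirs]
            xy = np.stack([rr * np.cos(ang), rr * np.sin(ang)], axis=1)
            z = sample_depth(img, xy)
            sl = ring_slice(r)
            pts[sl, 0] = xy[:, 0]
            pts[sl, 1] = xy[:, 1]
            pts[sl, 2] = z
    return LandmarkMesh(points=pts)
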