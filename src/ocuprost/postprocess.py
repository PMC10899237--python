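"""Anterior rework, oversizing, clear coat, smoothing and the safety gate.

Predicted shapes get a renormalised cornea (mean-shape cornea scaled so the
apex sits 2.5 mm above the iris plane and the limbus matches the iris
diameter), a locally varying 5% enlargement that spares the cornea, a
spatially varying clear-coat displacement, and two rounds of a
volume-increasing Loop-style subdivision.  Reconstructed shapes (directly
from a scanned prosthesis) skip the enlargement and carry a uniform 0.2 mm
coat.  Shapes exceeding a 30 x 29 x 20 mm bounding box are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import trimesh

from . import rings
from .errors import GeometryError
from .geometry import AlignedShape, LandmarkMesh, MarkedScan, align_shape, generate_correspondence

CORNEA_APEX_Z = 2.5          # mm above the iris plane after renormalisation
OVERSIZE_FACTOR = 1.05
OVERSIZE_BLEND_MM = 2.0      # cosine blend width outside the limbus
COAT_MIN = 0.1               # mm
COAT_MAX = 0.5
COAT_UNIFORM = 0.2           # reconstructed-mode coat
SAFETY_BBOX = (30.0, 29.0, 20.0)  # width, height, depth in mm

#: vertex indices of the cornea region (front centre through the limbus ring)
CORNEA_INDICES = np.arange(rings.front_ring_slice(rings.LIMBUS_RING).stop)


@dataclass
class ProcessedShape:
    vertices: np.ndarray
    faces: np.ndarray
    clearcoat: np.ndarray     # per-vertex coat thickness, mm
    provenance: Literal["predicted", "reconstructed"]
    bbox: tuple[float, float, float]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def _bbox(vertices: np.ndarray) -> tuple[float, float, float]:
    ext = vertices.max(axis=0) - vertices.min(axis=0)
    return (float(ext[0]), float(ext[1]), float(ext[2]))


def renormalize_cornea(shape: LandmarkMesh, iris_diameter: float,
                       mean_shape: LandmarkMesh) -> LandmarkMesh:
    """Replace the cornea with the mean-shape cornea scaled to the iris.

    The mean cornea is scaled in x-y so its limbus diameter equals the iris
    diameter and affinely in z so the limbus lands on the iris plane and the
    apex at 2.5 mm.  Rings 4 and 5 blend toward the displaced limbus so the
    transition stays smooth; everything else, in particular the whole
    posterior surface, is untouched.
    """
    if not 8.0 < iris_diameter < 14.0:
        raise ValueError(f"iris diameter {iris_diameter} mm outside (8, 14)")
    pts = shape.points.copy()
    mean = mean_shape.points

    limbus_idx = rings.limbus_indices()
    r_target = iris_diameter / 2.0
    m_limbus = mean[limbus_idx]
    r_mean = np.mean(np.hypot(m_limbus[:, 0], m_limbus[:, 1]))
    z_limbus_mean = m_limbus[:, 2].mean()
    z_apex_mean = mean[0, 2]
    if abs(z_apex_mean - z_limbus_mean) < 1e-9:
        raise GeometryError("degenerate mean cornea (flat)")

    old_limbus = pts[limbus_idx].copy()
    cornea = mean[CORNEA_INDICES].copy()
    cornea[:, :2] *= r_target / r_mean
    cornea[:, 2] = (cornea[:, 2] - z_limbus_mean) * (CORNEA_APEX_Z / (z_apex_mean - z_limbus_mean))
    pts[CORNEA_INDICES] = cornea

    # smooth transition: rings 4 and 5 follow a fraction of the limbus shift
    disp24 = pts[limbus_idx] - old_limbus
    # limbus ring samples every 2nd direction; interpolate to all 48
    disp48 = np.empty((48, 3))
    disp48[::2] = disp24
    disp48[1::2] = 0.5 * (disp24 + np.roll(disp24, -1, axis=0))
    for ring, weight in ((4, 0.5), (5, 0.15)):
        sl = rings.front_ring_slice(ring)
        pts[sl] += weight * disp48
    return LandmarkMesh(points=pts)


def _smoothstep(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    u = np.clip((t - lo) / (hi - lo), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def oversize_and_coat(shape: LandmarkMesh,
                      mode: Literal["predicted", "reconstructed"]) -> ProcessedShape:
    """Locally varying 5% enlargement (sparing the cornea) and clear coat.

    Predicted mode scales vertices radially about the origin with a cosine
    blend from 1.0 inside the limbus to 1.05 two millimetres outside it, and
    assigns a coat thickening toward the lid regions (large |y|) and the
    equatorial edge.  Reconstructed mode keeps the geometry and uses a
    uniform 0.2 mm coat.
    """
    pts = shape.points.copy()
    n = len(pts)
    if mode == "reconstructed":
        coat = np.full(n, COAT_UNIFORM)
        return ProcessedShape(vertices=pts, faces=shape.faces, clearcoat=coat,
                              provenance="reconstructed", bbox=_bbox(pts))

    ring3 = shape.limbus_ring()
    r_limbus = float(np.hypot(ring3[:, 0], ring3[:, 1]).max())  # spare ALL of the cornea
    rho = np.hypot(pts[:, 0], pts[:, 1])
    is_front = np.arange(n) < shape.front_count
    t = np.clip((rho - r_limbus) / OVERSIZE_BLEND_MM, 0.0, 1.0)
    blend = 0.5 * (1.0 - np.cos(np.pi * t))
    scale = np.where(is_front, 1.0 + (OVERSIZE_FACTOR - 1.0) * blend, OVERSIZE_FACTOR)
    pts = pts * scale[:, None]

    b_half = np.abs(pts[:, 1]).max()
    rho_max = np.hypot(pts[:, 0], pts[:, 1]).max()
    lid = _smoothstep(np.abs(pts[:, 1]) / max(b_half, 1e-9), 0.45, 0.9)
    edge = _smoothstep(np.hypot(pts[:, 0], pts[:, 1]) / max(rho_max, 1e-9), 0.75, 1.0)
    coat = COAT_MIN + (COAT_MAX - COAT_MIN) * np.maximum(lid, edge)
    return ProcessedShape(vertices=pts, faces=shape.faces, clearcoat=coat,
                          provenance="predicted", bbox=_bbox(pts))


def _loop_once(V: np.ndarray, F: np.ndarray,
               attrs: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """One round of Loop subdivision with outward (volume-increasing) placement."""
    mesh = trimesh.Trimesh(V, F, process=False)
    if not mesh.is_watertight:
        raise GeometryError("subdivision smoothing requires a closed manifold mesh")
    normals = np.asarray(mesh.vertex_normals)

    e_all = np.sort(F[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    edges, inv = np.unique(e_all, axis=0, return_inverse=True)
    n_v, n_e = len(V), len(edges)

    # opposite vertices of each edge (two per interior edge on a closed mesh)
    opp_sum = np.zeros((n_e, 3))
    opp_cnt = np.zeros(n_e)
    thirds = F[:, [2, 0, 1]].reshape(-1)  # vertex opposite each face edge
    np.add.at(opp_sum, inv, V[thirds])
    np.add.at(opp_cnt, inv, 1.0)
    if np.any(opp_cnt != 2):
        raise GeometryError("subdivision smoothing requires a closed manifold mesh")

    mid = 0.5 * (V[edges[:, 0]] + V[edges[:, 1]])
    odd_loop = 0.375 * (V[edges[:, 0]] + V[edges[:, 1]]) + 0.125 * opp_sum
    odd_norm = normals[edges[:, 0]] + normals[edges[:, 1]]
    odd_norm /= np.maximum(np.linalg.norm(odd_norm, axis=1, keepdims=True), 1e-12)
    # reflect across the tangent plane through the linear midpoint
    d = np.einsum("ij,ij->i", mid - odd_loop, odd_norm)
    odd = odd_loop + 2.0 * np.clip(d, 0.0, None)[:, None] * odd_norm

    # even vertices: Loop stencil, then the same outward reflection
    deg = np.zeros(n_v)
    nb_sum = np.zeros((n_v, 3))
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)
    np.add.at(nb_sum, edges[:, 0], V[edges[:, 1]])
    np.add.at(nb_sum, edges[:, 1], V[edges[:, 0]])
    beta = (0.625 - (0.375 + 0.25 * np.cos(2 * np.pi / deg)) ** 2) / deg
    even_loop = (1.0 - deg * beta)[:, None] * V + beta[:, None] * nb_sum
    d_even = np.einsum("ij,ij->i", V - even_loop, normals)
    even = even_loop + 2.0 * np.clip(d_even, 0.0, None)[:, None] * normals

    V_new = np.vstack([even, odd])
    eid = inv.reshape(-1, 3) + n_v  # midpoint ids per face edge (01, 12, 20)
    a, b, c = F[:, 0], F[:, 1], F[:, 2]
    mab, mbc, mca = eid[:, 0], eid[:, 1], eid[:, 2]
    F_new = np.concatenate([
        np.stack([a, mab, mca], axis=1),
        np.stack([b, mbc, mab], axis=1),
        np.stack([c, mca, mbc], axis=1),
        np.stack([mab, mbc, mca], axis=1),
    ])
    attrs_new = None
    if attrs is not None:
        attrs_new = np.concatenate([attrs, 0.5 * (attrs[edges[:, 0]] + attrs[edges[:, 1]])])
    return V_new, F_new, attrs_new


def subdivide_smooth(vertices: np.ndarray, faces: np.ndarray, iterations: int = 2,
                     attrs: np.ndarray | None = None):
    """Volume-increasing Loop-style subdivision smoothing.

    Odd and even vertices use the standard Loop stencils, then each vertex
    that the stencil pulled inward (along its interpolated outward normal) is
    reflected to the outside, so the enclosed volume grows instead of
    shrinking.  Face count quadruples per round.  Per-vertex attributes, if
    given, are carried along by edge averaging.
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=np.int64)
    for _ in range(iterations):
        V, F, attrs = _loop_once(V, F, attrs)
    return (V, F, attrs) if attrs is not None else (V, F)


def safety_gate(shape: ProcessedShape | np.ndarray,
                limits: tuple[float, float, float] = SAFETY_BBOX) -> bool:
    """True (accept) unless the bounding box is strictly larger than the limit."""
    bbox = shape.bbox if isinstance(shape, ProcessedShape) else _bbox(np.asarray(shape))
    return all(b <= lim for b, lim in zip(bbox, limits))


def finish_shape(shape: LandmarkMesh, mean_shape: LandmarkMesh, iris_diameter: float,
                 mode: Literal["predicted", "reconstructed"],
                 subdivision_iterations: int = 2) -> ProcessedShape:
    """Cornea renormalisation, oversize/coat and smoothing for either path."""
    renorm = renormalize_cornea(shape, iris_diameter, mean_shape)
    proc = oversize_and_coat(renorm, mode)
    V, F, coat = subdivide_smooth(proc.vertices, proc.faces,
                                  iterations=subdivision_iterations,
                                  attrs=proc.clearcoat)
    return ProcessedShape(vertices=V, faces=F, clearcoat=coat,
                          provenance=proc.provenance, bbox=_bbox(V))


def reconstruct_shape(scan: MarkedScan, mean_shape: LandmarkMesh | None = None,
                      iris_diameter: float | None = None,
                      subdivision_iterations: int = 2) -> ProcessedShape:
    """Replicate an existing prosthesis from a marked scan.

    The aligned correspondence landmarks are used directly (never projected
    through the SSM, which could not represent out-of-span shapes), then
    post-processed in reconstructed mode: no 5% enlargement and a uniform
    0.2 mm clear coat.
    """
    aligned = align_shape(scan)
    lm = generate_correspondence(aligned)
    if iris_diameter is None:
        iris_diameter = float(np.clip(lm.limbus_diameter(), 8.5, 13.5))
    return finish_shape(lm, mean_shape if mean_shape is not None else lm,
                        iris_diameter, "reconstructed",
                        subdivision_iterations=subdivision_iterations)
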