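"""Versioned ring scheme of the landmark correspondence representation.

The prosthesis surface is sampled on radial lines from the origin of the
front and back depth projections: 48 directions at 7.5 degree increments,
with points placed at fixed fractional distances along each line.  Points at
the same fraction form a ring; sparse rings skip directions uniformly so the
point density stays roughly homogeneous near the poles.  The scheme below is
version 1 and is frozen: it yields exactly 189 front + 649 back = 838
landmarks, the limbus is marked by the third front ring, and the shared
triangulation closes the surface with 1672 faces (E = 2508, V - E + F = 2).
"""

from __future__ import annotations

import numpy as np

RING_SCHEME_VERSION = 1

N_DIRECTIONS = 48
ANGLE_STEP_DEG = 7.5

#: points per front ring, centre vertex excluded; ring 3 (count 24) is the limbus
FRONT_RING_COUNTS = (8, 12, 24, 48, 48, 48)
#: fractional distance of each front ring along the radial line (1.0 = silhouette)
FRONT_RING_FRACTIONS = (0.12, 0.26, 0.42, 0.65, 0.85, 1.0)
#: index of the limbus ring on the front, 1-based as rings are counted
LIMBUS_RING = 3

BACK_RING_COUNTS = (8, 16) + (48,) * 13
BACK_RING_FRACTIONS = (
    0.06, 0.14, 0.24, 0.33, 0.41, 0.49, 0.57, 0.64,
    0.71, 0.78, 0.84, 0.90, 0.95, 0.98, 1.0,
)

FRONT_COUNT = 1 + sum(FRONT_RING_COUNTS)   # 189
BACK_COUNT = 1 + sum(BACK_RING_COUNTS)     # 649
TOTAL_POINTS = FRONT_COUNT + BACK_COUNT    # 838
TOTAL_FACES = 1672


def ring_direction_indices(count: int) -> np.ndarray:
    """Direction indices sampled by a ring of ``count`` points (uniform skip)."""
    if N_DIRECTIONS % count:
        raise ValueError(f"ring count {count} must divide {N_DIRECTIONS}")
    return np.arange(count) * (N_DIRECTIONS // count)


def ring_angles(count: int) -> np.ndarray:
    """Angles (radians) of a ring's points, counter-clockwise from +x."""
    return ring_direction_indices(count) * (2.0 * np.pi / N_DIRECTIONS)


def front_ring_slice(ring: int) -> slice:
    """Vertex-index slice of 1-based front ring ``ring`` (0 = centre vertex)."""
    if ring == 0:
        return slice(0, 1)
    start = 1 + sum(FRONT_RING_COUNTS[: ring - 1])
    return slice(start, start + FRONT_RING_COUNTS[ring - 1])


def back_ring_slice(ring: int) -> slice:
    """Vertex-index slice of 1-based back ring ``ring`` (0 = back centre)."""
    if ring == 0:
        return slice(FRONT_COUNT, FRONT_COUNT + 1)
    start = FRONT_COUNT + 1 + sum(BACK_RING_COUNTS[: ring - 1])
    return slice(start, start + BACK_RING_COUNTS[ring - 1])


def limbus_indices() -> np.ndarray:
    """Vertex indices of the limbus ring (front ring 3)."""
    s = front_ring_slice(LIMBUS_RING)
    return np.arange(s.start, s.stop)


def _stitch(inner: np.ndarray, outer: np.ndarray, flip: bool) -> list[tuple[int, int, int]]:
    """Triangulate the band between two concentric rings.

    ``inner``/``outer`` are vertex indices ordered counter-clockwise starting
    at angle 0; each ring samples a uniform subset of the 48 directions.  A
    merge walk over the two angle sequences yields len(inner) + len(outer)
    triangles.  ``flip`` reverses the winding (used for the back surface).
    """
    na, nb = len(inner), len(outer)
    ang_a = ring_angles(na)
    ang_b = ring_angles(nb)
    tris: list[tuple[int, int, int]] = []
    ia = ib = 0
    while ia < na or ib < nb:
        a_next = ang_a[ia + 1] if ia + 1 < na else (2 * np.pi if ia < na else np.inf)
        b_next = ang_b[ib + 1] if ib + 1 < nb else (2 * np.pi if ib < nb else np.inf)
        if b_next <= a_next:  # advance outer ring
            t = (inner[ia % na], outer[ib % nb], outer[(ib + 1) % nb])
            ib += 1
        else:  # advance inner ring
            t = (inner[ia % na], outer[ib % nb], inner[(ia + 1) % na])
            ia += 1
        tris.append((t[0], t[2], t[1]) if flip else t)
    return tris


def _fan(centre: int, ring: np.ndarray, flip: bool) -> list[tuple[int, int, int]]:
    n = len(ring)
    tris = [(centre, ring[j], ring[(j + 1) % n]) for j in range(n)]
    return [(a, c, b) for a, b, c in tris] if flip else tris


def build_face_table() -> np.ndarray:
    """Construct the shared closed triangulation over the 838 landmarks.

    Winding convention: outward-facing normals (+z on the front cap, -z on
    the back cap, radial on the silhouette band).
    """
    faces: list[tuple[int, int, int]] = []
    # front: cap + ring bands, CCW seen from +z
    r1 = np.arange(front_ring_slice(1).start, front_ring_slice(1).stop)
    faces += _fan(0, r1, flip=False)
    for r in range(1, len(FRONT_RING_COUNTS)):
        sa, sb = front_ring_slice(r), front_ring_slice(r + 1)
        faces += _stitch(np.arange(sa.start, sa.stop), np.arange(sb.start, sb.stop), flip=False)
    # back: mirrored winding
    b1 = np.arange(back_ring_slice(1).start, back_ring_slice(1).stop)
    faces += _fan(FRONT_COUNT, b1, flip=True)
    for r in range(1, len(BACK_RING_COUNTS)):
        sa, sb = back_ring_slice(r), back_ring_slice(r + 1)
        faces += _stitch(np.arange(sa.start, sa.stop), np.arange(sb.start, sb.stop), flip=True)
    # silhouette band between the two outline rings (both full 48-point rings)
    sf = front_ring_slice(len(FRONT_RING_COUNTS))
    sb = back_ring_slice(len(BACK_RING_COUNTS))
    f = np.arange(sf.start, sf.stop)
    b = np.arange(sb.start, sb.stop)
    for j in range(N_DIRECTIONS):
        jn = (j + 1) % N_DIRECTIONS
        faces.append((f[j], b[j], b[jn]))
        faces.append((f[j], b[jn], f[jn]))
    out = np.asarray(faces, dtype=np.int64)
    assert out.shape == (TOTAL_FACES, 3)
    return out


#: the fixed shared face list of every landmark mesh
FACES: np.ndarray = build_face_table()
FACES.setflags(write=False)
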