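"""Iris/pupil segmentation, texture unwrapping and iris geometry.

Boundary detection runs a multi-scale Daugman integro-differential search
(image pyramid, four scales) on the enhancement image I_enh = C* - L*
computed in CIELCh, which is large inside the (chromatic, mid-lightness)
iris and strongly negative on the bright achromatic sclera.  The limbus is
then refined to an ellipse of constant area over a grid of axis ratios and
orientations.  The iris annulus is unwrapped to a 4096 x 1024 angle-radius
texture (pupil at the bottom) whose lightness contrast is stretched to
counter light transport in the printing materials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import trimesh
from skimage import color as skcolor
from skimage.transform import rescale

from .errors import DetectionFailureError, GeometryError

TEXTURE_WIDTH = 4096
TEXTURE_HEIGHT = 1024
PUPIL_BLACK_ROWS = 16
CONTRAST_FACTOR = 1.5
DAUGMAN_SCALES = (8, 4, 2, 1)
ELLIPSE_RATIOS = np.round(np.arange(1.0, 0.85 - 1e-9, -0.01), 4)
ELLIPSE_ANGLES_DEG = np.arange(0, 180, 5)


@dataclass
class IrisSegmentation:
    iris_centre: tuple[float, float]   # (x, y) px
    iris_radius: float
    ellipse_axes: tuple[float, float]  # semi-axes (a, b), a along ellipse_angle
    ellipse_angle: float               # radians
    pupil_centre: tuple[float, float]
    pupil_radius: float

    def iris_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the iris/pupil region (inside the limbus ellipse)."""
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        dx = xx - self.iris_centre[0]
        dy = yy - self.iris_centre[1]
        ca, sa = np.cos(self.ellipse_angle), np.sin(self.ellipse_angle)
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        a, b = self.ellipse_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def enhancement_image(lab: np.ndarray) -> np.ndarray:
    """I_enh: chroma minus lightness in CIELCh."""
    lch = skcolor.lab2lch(lab)
    return lch[..., 1] - lch[..., 0]


def _circle_response(img: np.ndarray, cx: float, cy: float,
                     radii: np.ndarray, n_angles: int = 96) -> np.ndarray:
    """Gaussian-smoothed radial derivative of the circular line integral."""
    ang = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    cosa, sina = np.cos(ang), np.sin(ang)
    xs = cx + radii[:, None] * cosa
    ys = cy + radii[:, None] * sina
    vals = ndi.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1,
                               mode="nearest").reshape(len(radii), n_angles)
    integral = vals.mean(axis=1)
    deriv = np.gradient(integral, radii)
    return ndi.gaussian_filter1d(deriv, sigma=1.0)


def _daugman_search(img: np.ndarray, centres: np.ndarray, radii: np.ndarray,
                    sign: float) -> tuple[float, float, float, float]:
    """Best (cx, cy, r, response) maximizing sign * smoothed radial derivative."""
    best = (-np.inf, 0.0, 0.0, 0.0)
    for cx, cy in centres:
        resp = sign * _circle_response(img, cx, cy, radii)
        i = int(np.argmax(resp))
        if resp[i] > best[0]:
            best = (resp[i], cx, cy, radii[i])
    return best[1], best[2], best[3], best[0]


def _multiscale_daugman(img: np.ndarray, r_range: tuple[float, float], sign: float,
                        centre_hint: tuple[float, float] | None = None,
                        hint_radius: float | None = None) -> tuple[float, float, float]:
    H, W = img.shape
    cx = cy = r = None
    for scale in DAUGMAN_SCALES:
        f = 1.0 / scale
        im = rescale(img, f, anti_aliasing=scale > 1, order=1) if scale > 1 else img
        h, w = im.shape
        lo = max(r_range[0] * f, 2.0)
        hi = max(r_range[1] * f, lo + 2.0)
        radii = np.arange(lo, hi + 1.0)
        if cx is None:
            if centre_hint is not None:
                gx, gy = centre_hint[0] * f, centre_hint[1] * f
                span = (hint_radius or 8.0) * f
                xs = np.arange(max(gx - span, 1), min(gx + span, w - 2), 1.0)
                ys = np.arange(max(gy - span, 1), min(gy + span, h - 2), 1.0)
            else:
                xs = np.arange(w * 0.25, w * 0.75, 1.0)
                ys = np.arange(h * 0.25, h * 0.75, 1.0)
            centres = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        else:
            gx, gy = cx * 2, cy * 2  # previous scale is exactly 2x coarser
            xs = np.arange(gx - 4, gx + 4.5)
            ys = np.arange(gy - 4, gy + 4.5)
            if centre_hint is not None:
                # stay inside the hinted centre box at every scale
                span = (hint_radius or 8.0) * f
                xs = xs[np.abs(xs - centre_hint[0] * f) <= span]
                ys = ys[np.abs(ys - centre_hint[1] * f) <= span]
                if len(xs) == 0:
                    xs = np.array([centre_hint[0] * f])
                if len(ys) == 0:
                    ys = np.array([centre_hint[1] * f])
            centres = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
            radii = np.arange(max(r * 2 - 4, lo, 2.0), min(r * 2 + 4.5, hi + 1.0))
            if len(radii) == 0:
                radii = np.array([np.clip(r * 2, lo, hi)])
        bx, by, br, resp = _daugman_search(im, centres, radii, sign)
        if not np.isfinite(resp) or resp <= 0:
            raise DetectionFailureError("no boundary response above the floor")
        cx, cy, r = bx, by, br
    return float(cx), float(cy), float(r)


def _ellipse_objective(img: np.ndarray, cx: float, cy: float, a: float, b: float,
                       angle: float, n_angles: int = 180) -> float:
    """Inside-minus-outside intensity contrast across the ellipse boundary."""
    t = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    ca, sa = np.cos(angle), np.sin(angle)
    ex = a * np.cos(t)
    ey = b * np.sin(t)
    px = cx + ca * ex - sa * ey
    py = cy + sa * ex + ca * ey
    vals = []
    for s in (0.96, 1.04):
        sx = cx + s * (px - cx)
        sy = cy + s * (py - cy)
        vals.append(ndi.map_coordinates(img, [sy, sx], order=1, mode="nearest").sum())
    return vals[0] - vals[1]  # inside - outside


def detect_iris(I_clean: np.ndarray) -> IrisSegmentation:
    """Locate limbus and pupil boundaries in a characterized (CIELAB) image.

    Multi-scale Daugman search for the limbus (negative radial derivative of
    I_enh) and, inside it, the pupil (positive derivative); then an
    elliptical refinement of the limbus at constant area over a grid of axis
    ratios (1.0 to 0.85) and orientations.
    """
    enh = enhancement_image(I_clean)
    H, W = enh.shape
    r_max = 0.45 * min(H, W)
    cx, cy, r = _multiscale_daugman(enh, (0.08 * min(H, W), r_max), sign=-1.0)

    # on I_enh the (dark, achromatic) pupil is the global maximum; its
    # plateau centroid is a centre anchor robust to limbus ellipticity
    yy, xx = np.mgrid[0:H, 0:W]
    window = (np.hypot(xx - cx, yy - cy) < 0.7 * r)
    plateau = window & (enh >= enh[window].max() - 3.0)
    anchor = (float(xx[plateau].mean()), float(yy[plateau].mean()))

    # both boundaries are crossed with a negative radial derivative of I_enh
    px, py, pr = _multiscale_daugman(
        enh, (max(0.15 * r, 3.0), 0.6 * r), sign=-1.0,
        centre_hint=anchor, hint_radius=3.0)

    # an elliptical limbus smears the circular response and can pull its
    # centre sideways; re-fit the limbus circle constrained to the anchor
    cx, cy, r = _multiscale_daugman(
        enh, (0.75 * r, 1.3 * r), sign=-1.0,
        centre_hint=anchor, hint_radius=1.5)

    best = (-np.inf, r, r, 0.0)
    for ratio in ELLIPSE_RATIOS:
        a = r / np.sqrt(ratio)
        b = r * np.sqrt(ratio)
        for ang in ELLIPSE_ANGLES_DEG:
            angle = np.deg2rad(float(ang))
            score = _ellipse_objective(enh, cx, cy, a, b, angle)
            if score > best[0] + 1e-12:
                best = (score, a, b, angle)
            if ratio == 1.0:
                break  # a circle is rotation invariant
    _, a, b, angle = best
    return IrisSegmentation(iris_centre=(cx, cy), iris_radius=r,
                            ellipse_axes=(a, b), ellipse_angle=angle,
                            pupil_centre=(px, py), pupil_radius=pr)


def _limbus_radius_at(seg: IrisSegmentation, phi: np.ndarray) -> np.ndarray:
    a, b = seg.ellipse_axes
    psi = phi - seg.ellipse_angle
    return a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)


def unwrap_iris(I_clean: np.ndarray, seg: IrisSegmentation,
                width: int = TEXTURE_WIDTH, height: int = TEXTURE_HEIGHT,
                occlusion_mask: np.ndarray | None = None) -> np.ndarray:
    """Unwrap the iris annulus to an angle x radius texture (pupil at bottom).

    Column j covers angle 2 pi j / width; row 0 samples the limbus boundary
    and the bottom row the pupil boundary, with bilinear interpolation in the
    source image.  Pixels under an optional occlusion mask are filled from
    the nearest unoccluded column of the same row.
    """
    phi = np.arange(width) * 2 * np.pi / width
    r_l = _limbus_radius_at(seg, phi)
    frac = 1.0 - np.arange(height) / (height - 1.0)
    rho = seg.pupil_radius + frac[:, None] * (r_l[None, :] - seg.pupil_radius)
    xs = seg.iris_centre[0] + rho * np.cos(phi)[None, :]
    ys = seg.iris_centre[1] + rho * np.sin(phi)[None, :]
    tex = np.stack([
        ndi.map_coordinates(I_clean[..., c], [ys, xs], order=1, mode="nearest")
        for c in range(I_clean.shape[-1])
    ], axis=-1)
    if occlusion_mask is not None:
        occ = ndi.map_coordinates(occlusion_mask.astype(float), [ys, xs],
                                  order=0, mode="nearest") > 0.5
        for row in range(height):
            bad = occ[row]
            if bad.any() and not bad.all():
                cols = np.arange(width)
                good = cols[~bad]
                for col in cols[bad]:
                    j = good[np.argmin(np.minimum(np.abs(good - col),
                                                  width - np.abs(good - col)))]
                    tex[row, col] = tex[row, j]
    return tex


def enhance_contrast(texture: np.ndarray, factor: float = CONTRAST_FACTOR,
                     pupil_rows: int = PUPIL_BLACK_ROWS) -> np.ndarray:
    """Row-wise lightness stretch preserving the global mean; pupil blacked.

    L*_{r,c} <- factor (L*_{r,c} - rowmean_r) + rowmean_r, then the global
    mean is restored by an offset, and finally the bottom rows (the pupil)
    are set to pure black.
    """
    out = texture.astype(float).copy()
    L = out[..., 0]
    L0 = L.mean()
    row_mean = L.mean(axis=1, keepdims=True)
    L = factor * (L - row_mean) + row_mean
    L = L + (L0 - L.mean())
    out[..., 0] = L
    if pupil_rows > 0:
        out[-pupil_rows:, :, 0] = 0.0
        out[-pupil_rows:, :, 1:] = 0.0
    return out


# ---------------------------------------------------------------------------
# iris geometry


@dataclass
class IrisGeometry:
    disc: trimesh.Trimesh
    uv: np.ndarray             # per-vertex (u, v) = (angle/2pi, fractional radius)
    pupil_radius: float        # mm
    limbus_radius: float
    cylinder: trimesh.Trimesh  # black pupil backing


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    edges = mesh.edges_sorted
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    loops = []
    seen: set[int] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxts = [v for v in adj[cur] if v != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        loops.append(np.asarray(loop))
    return loops


def build_iris_geometry(iris_mesh: trimesh.Trimesh,
                        cylinder_height: float = 1.5) -> IrisGeometry:
    """Prepare the OCT iris surface mesh for texturing and assembly.

    The pupil boundary is circularized to its average radius and closed with
    a fan cap; UVs follow the angle/fractional-radius convention of the iris
    texture; a black cylinder of the pupil radius is placed behind the pupil
    to darken it against light transport in the print.
    """
    loops = _boundary_loops(iris_mesh)
    if len(loops) != 2:
        raise GeometryError(f"iris mesh must be an annular disc, found {len(loops)} boundary loops")
    V = iris_mesh.vertices.copy()
    radii = [np.mean(np.hypot(V[lp, 0], V[lp, 1])) for lp in loops]
    inner = loops[int(np.argmin(radii))]
    outer = loops[int(np.argmax(radii))]
    r_pupil = float(min(radii))
    r_limbus = float(max(radii))

    # normalize the pupil boundary to a smooth circle of the average radius
    ang = np.arctan2(V[inner, 1], V[inner, 0])
    z_mean = V[inner, 2].mean()
    V[inner, 0] = r_pupil * np.cos(ang)
    V[inner, 1] = r_pupil * np.sin(ang)
    V[inner, 2] = z_mean

    # close the pupil with a centre vertex and fan
    centre_idx = len(V)
    V = np.vstack([V, [[0.0, 0.0, z_mean]]])
    order = inner[np.argsort(np.arctan2(V[inner, 1], V[inner, 0]))]
    F = iris_mesh.faces
    # match cap winding to the existing surface orientation (+z facing)
    up = trimesh.Trimesh(iris_mesh.vertices, F, process=False).face_normals[:, 2].mean() >= 0
    cap = []
    for i in range(len(order)):
        a, b = int(order[i]), int(order[(i + 1) % len(order)])
        cap.append((centre_idx, a, b) if up else (centre_idx, b, a))
    F = np.vstack([F, np.asarray(cap)])
    disc = trimesh.Trimesh(V, F, process=False)

    rho = np.hypot(V[:, 0], V[:, 1])
    phi = np.mod(np.arctan2(V[:, 1], V[:, 0]), 2 * np.pi)
    uv = np.stack([phi / (2 * np.pi), np.clip(rho / r_limbus, 0.0, 1.0)], axis=1)

    cyl = trimesh.creation.cylinder(radius=r_pupil, height=cylinder_height, sections=48)
    cyl.apply_translation([0.0, 0.0, z_mean - cylinder_height / 2 - 0.05])
    return IrisGeometry(disc=disc, uv=uv, pupil_radius=r_pupil,
                        limbus_radius=r_limbus, cylinder=cyl)
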