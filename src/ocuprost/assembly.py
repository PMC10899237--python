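"""Model assembly and textured OBJ export.

The final prosthesis model combines the processed body shape (sclera UVs by
spherical mapping about the origin), the iris disc fused at the limbus
plane, and the black pupil cylinder.  CIELAB textures are converted to sRGB
(Bradford D50 -> D65 adaptation) at write time since OBJ/MTL carries device
RGB; geometry goes out as a multi-group OBJ with an MTL referencing the
texture PNGs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import color as skcolor

from .iris import IrisGeometry
from .postprocess import ProcessedShape
from . import rings

# Bradford chromatic adaptation, D50 -> D65
_BRADFORD_D50_D65 = np.array([
    [0.9555766, -0.0230393, 0.0631636],
    [-0.0282895, 1.0099416, 0.0210077],
    [0.0122982, -0.0204830, 1.3299098],
])


def lab_to_srgb(lab: np.ndarray) -> np.ndarray:
    """CIELAB (D50/2) -> sRGB with Bradford adaptation, clipped to [0, 1]."""
    xyz = skcolor.lab2xyz(lab, illuminant="D50", observer="2")
    xyz_d65 = xyz @ _BRADFORD_D50_D65.T
    return np.clip(skcolor.xyz2rgb(xyz_d65), 0.0, 1.0)


def _write_png16(path: str | Path, arr: np.ndarray) -> None:
    """Write a uint16 greyscale or RGB PNG (no installed codec emits 16-bit RGB)."""
    import struct
    import zlib

    arr = np.ascontiguousarray(arr, dtype=">u2")
    if arr.ndim == 2:
        colour_type = 0
        h, w = arr.shape
    elif arr.ndim == 3 and arr.shape[2] == 3:
        colour_type = 2
        h, w = arr.shape[:2]
    else:
        raise ValueError("expected (H, W) or (H, W, 3) uint16 data")

    def chunk(tag: bytes, data: bytes) -> bytes:
        return (struct.pack(">I", len(data)) + tag + data
                + struct.pack(">I", zlib.crc32(tag + data) & 0xFFFFFFFF))

    ihdr = struct.pack(">IIBBBBB", w, h, 16, colour_type, 0, 0, 0)
    raw = b"".join(b"\x00" + arr[i].tobytes() for i in range(h))
    with open(path, "wb") as fh:
        fh.write(b"\x89PNG\r\n\x1a\n")
        fh.write(chunk(b"IHDR", ihdr))
        fh.write(chunk(b"IDAT", zlib.compress(raw, 6)))
        fh.write(chunk(b"IEND", b""))


def write_texture_png(path: str | Path, lab: np.ndarray) -> None:
    """16-bit sRGB PNG from a CIELAB texture."""
    rgb = lab_to_srgb(lab)
    _write_png16(Path(path), (rgb * 65535.0 + 0.5).astype(np.uint16))


def write_displacement_png(path: str | Path, disp: np.ndarray,
                           max_mm: float = 1.0) -> None:
    """16-bit greyscale PNG encoding displacement in mm (0 .. max_mm)."""
    scaled = np.clip(disp / max_mm, 0.0, 1.0)
    _write_png16(Path(path), (scaled * 65535.0 + 0.5).astype(np.uint16))


def spherical_uv(vertices: np.ndarray) -> np.ndarray:
    """Sclera UVs: azimuth about +z and polar angle from the limbus plane.

    u wraps the azimuth, v runs from 0 at the limbus (iris plane) to 1 at
    the posterior pole; the anterior (cornea) clamps to v = 0.
    """
    x, y, z = vertices[:, 0], vertices[:, 1], vertices[:, 2]
    rho = np.maximum(np.sqrt(x * x + y * y + z * z), 1e-12)
    theta = np.arccos(np.clip(z / rho, -1.0, 1.0))  # 0 at +z pole
    u = np.mod(np.arctan2(y, x), 2 * np.pi) / (2 * np.pi)
    v = np.clip((theta - np.pi / 2) / (np.pi / 2), 0.0, 1.0)
    return np.stack([u, v], axis=1)


def rasterize_vertex_map(uv: np.ndarray, values: np.ndarray,
                         width: int = 1024, height: int = 512) -> np.ndarray:
    """Scatter per-vertex scalars into a UV-space map, nearest-filled."""
    import scipy.ndimage as ndi
    img = np.zeros((height, width))
    cnt = np.zeros((height, width))
    jj = np.clip((uv[:, 0] * (width - 1)).astype(int), 0, width - 1)
    ii = np.clip((uv[:, 1] * (height - 1)).astype(int), 0, height - 1)
    np.add.at(img, (ii, jj), values)
    np.add.at(cnt, (ii, jj), 1.0)
    filled = cnt > 0
    img[filled] /= cnt[filled]
    if not filled.all() and filled.any():
        ind = ndi.distance_transform_edt(~filled, return_distances=False,
                                         return_indices=True)
        img = img[tuple(ind)]
    return ndi.median_filter(img, size=3)


@dataclass
class ProsthesisModel:
    body_vertices: np.ndarray
    body_faces: np.ndarray
    body_uv: np.ndarray
    iris_geometry: IrisGeometry
    sclera_texture_lab: np.ndarray   # (2048, 4096, 3)
    iris_texture_lab: np.ndarray     # (1024, 4096, 3)
    clearcoat: np.ndarray            # per-body-vertex mm
    metadata: dict = field(default_factory=dict)

    def limbus_seam_gap(self) -> float:
        """Largest distance from the iris-disc rim to the body limbus ring.

        Measured against the closed ring polyline (not just its vertices) so
        angular sampling differences do not register as gaps.
        """
        rim = self.iris_geometry.disc.vertices[
            _outer_loop(self.iris_geometry.disc)]
        ring = self.body_vertices[rings.limbus_indices()]
        a = ring
        b = np.roll(ring, -1, axis=0)
        ab = b - a                                   # (m, 3) ring segments
        denom = np.einsum("ij,ij->i", ab, ab)
        ap = rim[:, None, :] - a[None, :, :]         # (n, m, 3)
        t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / np.maximum(denom, 1e-12), 0, 1)
        closest = a[None] + t[..., None] * ab[None]
        d = np.linalg.norm(rim[:, None, :] - closest, axis=2)
        return float(d.min(axis=1).max())


def _ring_at_angles(ring: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radius and z of the closed ring polyline where the ray at angle phi
    crosses it (chord interpolation, so points land exactly on the polyline)."""
    ring_phi = np.arctan2(ring[:, 1], ring[:, 0])
    order = np.argsort(ring_phi)
    ring = ring[order]
    ring_phi = ring_phi[order]
    m = len(ring)
    seg = np.searchsorted(ring_phi, phi, side="right") - 1  # -1 wraps to last
    a = ring[seg % m]
    b = ring[(seg + 1) % m]
    d = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    cross_a = a[:, 0] * d[:, 1] - a[:, 1] * d[:, 0]
    ab = b[:, :2] - a[:, :2]
    cross_ab = ab[:, 0] * d[:, 1] - ab[:, 1] * d[:, 0]
    t = np.clip(-cross_a / np.where(np.abs(cross_ab) < 1e-12, 1e-12, cross_ab), 0.0, 1.0)
    p = a[:, :2] + t[:, None] * ab
    r = np.hypot(p[:, 0], p[:, 1])
    z = a[:, 2] + t * (b[:, 2] - a[:, 2])
    return r, z


def _outer_loop(disc) -> np.ndarray:
    from .iris import _boundary_loops
    loops = _boundary_loops(disc)
    radii = [np.mean(np.hypot(disc.vertices[lp, 0], disc.vertices[lp, 1]))
             for lp in loops]
    return loops[int(np.argmax(radii))]


def assemble_model(processed: ProcessedShape, iris_geo: IrisGeometry,
                   sclera_texture_lab: np.ndarray, iris_texture_lab: np.ndarray,
                   metadata: dict | None = None) -> ProsthesisModel:
    """Fuse body, iris disc and pupil cylinder into the print-ready model.

    The iris disc is scaled in x-y so its rim meets the body's limbus ring
    and shifted so it sits on the limbus plane; the black pupil cylinder
    follows the same transform.
    """
    body_v = processed.vertices
    ring = body_v[rings.limbus_indices()]
    r_body = float(np.mean(np.hypot(ring[:, 0], ring[:, 1])))
    z_body = float(np.mean(ring[:, 2]))

    geo = iris_geo
    # conform the disc to the body's actual limbus ring: per-angle radial
    # scale and z offset, fading from the rim toward the (circular) pupil
    disc = geo.disc.copy()
    dv = disc.vertices.copy()
    phi_v = np.arctan2(dv[:, 1], dv[:, 0])
    rho_v = np.hypot(dv[:, 0], dv[:, 1])
    r_at, z_at = _ring_at_angles(ring, phi_v)
    frac = np.clip((rho_v - geo.pupil_radius)
                   / max(geo.limbus_radius - geo.pupil_radius, 1e-9), 0.0, 1.0)
    s_mean = r_body / geo.limbus_radius
    s_v = (1.0 - frac) * s_mean + frac * (r_at / geo.limbus_radius)
    rim_z = float(np.mean(dv[_outer_loop(disc), 2]))
    dv[:, 0] *= s_v
    dv[:, 1] *= s_v
    dv[:, 2] += (z_body - rim_z) + frac * (z_at - z_body)
    disc.vertices = dv
    cyl = geo.cylinder.copy()
    cyl.vertices = cyl.vertices * [s_mean, s_mean, 1.0] + [0.0, 0.0, z_body - rim_z]
    fused = IrisGeometry(disc=disc, uv=geo.uv, pupil_radius=geo.pupil_radius * s_mean,
                         limbus_radius=r_body, cylinder=cyl)

    uv = spherical_uv(body_v)
    meta = dict(metadata or {})
    meta.setdefault("provenance", processed.provenance)
    meta.setdefault("ring_scheme_version", rings.RING_SCHEME_VERSION)
    return ProsthesisModel(body_vertices=body_v, body_faces=processed.faces,
                           body_uv=uv, iris_geometry=fused,
                           sclera_texture_lab=sclera_texture_lab,
                           iris_texture_lab=iris_texture_lab,
                           clearcoat=processed.clearcoat, metadata=meta)


def _write_group(fh, name: str, material: str, V: np.ndarray, F: np.ndarray,
                 UV: np.ndarray | None, v_off: int, vt_off: int) -> tuple[int, int]:
    fh.write(f"g {name}\nusemtl {material}\n")
    for v in V:
        fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
    if UV is not None:
        for t in UV:
            fh.write(f"vt {t[0]:.6f} {t[1]:.6f}\n")
        for f in F:
            idx = " ".join(f"{v_off + i + 1}/{vt_off + i + 1}" for i in f)
            fh.write(f"f {idx}\n")
        return v_off + len(V), vt_off + len(V)
    for f in F:
        fh.write("f " + " ".join(str(v_off + i + 1) for i in f) + "\n")
    return v_off + len(V), vt_off


def write_model(model: ProsthesisModel, out_dir: str | Path, stem: str = "prosthesis") -> Path:
    """Write OBJ + MTL + texture/displacement PNGs + metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_texture_png(out / f"{stem}_sclera.png", model.sclera_texture_lab)
    write_texture_png(out / f"{stem}_iris.png", model.iris_texture_lab)
    coat_map = rasterize_vertex_map(model.body_uv, model.clearcoat)
    write_displacement_png(out / f"{stem}_clearcoat.png", coat_map)

    mtl = out / f"{stem}.mtl"
    with open(mtl, "w") as fh:
        fh.write(f"newmtl sclera\nKd 1 1 1\nmap_Kd {stem}_sclera.png\n\n")
        fh.write(f"newmtl iris\nKd 1 1 1\nmap_Kd {stem}_iris.png\n\n")
        fh.write("newmtl pupil_black\nKd 0 0 0\n")

    obj = out / f"{stem}.obj"
    geo = model.iris_geometry
    with open(obj, "w") as fh:
        fh.write(f"mtllib {stem}.mtl\n")
        v_off = vt_off = 0
        v_off, vt_off = _write_group(fh, "body", "sclera", model.body_vertices,
                                     model.body_faces, model.body_uv, v_off, vt_off)
        v_off, vt_off = _write_group(fh, "iris", "iris", geo.disc.vertices,
                                     geo.disc.faces, _disc_uv(geo), v_off, vt_off)
        v_off, vt_off = _write_group(fh, "pupil_cylinder", "pupil_black",
                                     geo.cylinder.vertices, geo.cylinder.faces,
                                     None, v_off, vt_off)
    with open(out / f"{stem}_meta.json", "w") as fh:
        json.dump(model.metadata, fh, indent=2)
    return obj


def _disc_uv(geo: IrisGeometry) -> np.ndarray:
    uv = geo.uv
    if len(uv) == len(geo.disc.vertices):
        return uv
    # the closing fan added a centre vertex after UV assignment
    extra = np.tile([[0.0, 0.0]], (len(geo.disc.vertices) - len(uv), 1))
    return np.vstack([uv, extra])


def read_metadata(out_dir: str | Path, stem: str = "prosthesis") -> dict:
    with open(Path(out_dir) / f"{stem}_meta.json") as fh:
        return json.load(fh)
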