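"""Synthetic test-data generators.

Every generator is a pure function of (parameters, seed).  The prosthesis
family emulates the shell-like geometry of hand-made ocular prostheses: a
shallow anterior dome with a cornea, a deep posterior surface, and a
low-dimensional size/shape variation matching the bounding-box envelope of
real stock prostheses (18.5 x 15.9 x 9.7 mm to 28.6 x 32.3 x 22.2 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import MarkedScan, Side


@dataclass
class ProsthesisFamilyConfig:
    """Parameter ranges of the synthetic prosthesis shape family.

    Semi-axes are half-widths in mm; the family is five-dimensional
    (half-width a, half-height b, front depth c_f, back depth c_b, back bump
    amplitude) which keeps the population close to a low-rank linear model.
    """

    a_range: tuple[float, float] = (9.25, 14.3)
    b_range: tuple[float, float] = (7.95, 16.15)
    cf_range: tuple[float, float] = (2.0, 4.5)
    cb_min: float = 7.0
    depth_range: tuple[float, float] = (9.7, 22.2)
    bump_range: tuple[float, float] = (0.0, 1.5)
    subdivisions: int = 4
    rigid_rotation: bool = True
    translation_scale: float = 20.0


def _shell_mesh(a: float, b: float, cf: float, cb: float, bump: float,
                subdivisions: int = 4) -> trimesh.Trimesh:
    """Prosthesis-like closed shell in the canonical frame (right eye)."""
    base = trimesh.creation.icosphere(subdivisions=subdivisions)
    u = base.vertices
    v = np.empty_like(u)
    v[:, 0] = u[:, 0] * a
    v[:, 1] = u[:, 1] * b
    zscale = np.where(u[:, 2] >= 0, cf, cb)
    v[:, 2] = u[:, 2] * zscale
    # posterior bump, vanishing toward the equator so markers stay analytic
    w = np.exp(-(((u[:, 0] - 0.25) ** 2 + (u[:, 1] + 0.1) ** 2) / 0.18)) * np.clip(-u[:, 2], 0, 1)
    v[:, 2] -= bump * w
    return trimesh.Trimesh(vertices=v, faces=base.faces, process=False)


def _random_rigid(rng: np.random.Generator, translation_scale: float) -> tuple[np.ndarray, np.ndarray]:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-translation_scale, translation_scale, size=3)
    return Q, t


def gen_prosthesis(params: np.ndarray, rng: np.random.Generator,
                   config: ProsthesisFamilyConfig, eye_side: Side = "right") -> MarkedScan:
    """One marked scan from family parameters (a, b, cf, cb, bump)."""
    a, b, cf, cb, bump = params
    mesh = _shell_mesh(a, b, cf, cb, bump, config.subdivisions)
    # canonical markers on the equatorial (limbus) ring
    p_N = np.array([a, 0.0, 0.0])
    p_S = np.array([0.0, b, 0.0])
    p_T = np.array([-a, 0.0, 0.0])
    p_I = np.array([0.0, -b, 0.0])
    verts = mesh.vertices
    faces = mesh.faces.copy()
    if eye_side == "left":
        verts = verts * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]
        p_N, p_T = p_N * [-1, 1, 1], p_T * [-1, 1, 1]
    if config.rigid_rotation:
        Q, t = _random_rigid(rng, config.translation_scale)
    else:
        Q, t = np.eye(3), np.zeros(3)
    tf = lambda p: p @ Q.T + t
    return MarkedScan(vertices=tf(verts), faces=faces, p_S=tf(p_S), p_N=tf(p_N),
                      p_I=tf(p_I), p_T=tf(p_T), eye_side=eye_side)


def sample_family_params(n: int, rng: np.random.Generator,
                         config: ProsthesisFamilyConfig | None = None) -> np.ndarray:
    config = config or ProsthesisFamilyConfig()
    a = rng.uniform(*config.a_range, size=n)
    b = rng.uniform(*config.b_range, size=n)
    cf = rng.uniform(*config.cf_range, size=n)
    bump = rng.uniform(*config.bump_range, size=n)
    cb_lo = np.maximum(config.cb_min, config.depth_range[0] - cf)
    cb_hi = config.depth_range[1] - cf - bump
    cb = rng.uniform(cb_lo, cb_hi)
    return np.stack([a, b, cf, cb, bump], axis=1)


def gen_prosthesis_set(n: int, seed: int = 0,
                       config: ProsthesisFamilyConfig | None = None) -> list[MarkedScan]:
    """Generate ``n`` marked prosthesis scans in random scanner poses."""
    config = config or ProsthesisFamilyConfig()
    rng = np.random.default_rng(seed)
    params = sample_family_params(n, rng, config)
    return [gen_prosthesis(p, rng, config) for p in params]


# ---------------------------------------------------------------------------
# OCT socket volume


@dataclass
class OCTNoiseConfig:
    """Speckle model for synthetic OCT: multiplicative gamma noise on tissue
    plus sparse bright salt dots.  Defaults are noise-free; tests enable what
    they need."""

    speckle_shape: float = 0.0   # gamma shape parameter; 0 disables speckle
    salt_density: float = 0.0    # fraction of voxels hit by bright dots
    salt_value: int = 160


def gen_oct_volume(
    truth_fn,
    conformer,
    n_y: int = 256,
    slice_shape: tuple[int, int] = (2145, 1877),
    zA_centre: float = 3.0,
    tilt: tuple[float, float] = (0.0, 0.0),
    noise: OCTNoiseConfig | None = None,
    seed: int = 0,
    gaze_deg: float = 6.0,
):
    """Render a synthetic AS-OCT raster volume of a socket behind a conformer.

    ``truth_fn(x, y)`` returns the socket surface z (mm, canonical frame,
    negative into the socket) or NaN outside the surface.  The renderer
    emulates the acquisition physics that the extraction pipeline corrects:
    the gaze axis is rotated ``gaze_deg`` about y relative to the canonical
    frame, surfaces seen through the window appear shallower by 0.35 x
    thickness, the beam is displaced laterally by refraction through the
    tilted window, and the window itself is drawn at ``zA_centre`` depth with
    the given plane slopes (dz/dx, dz/dy).

    Returns ``(OCTVolume, truth)`` where truth carries the per-column ground
    truth surface in the canonical frame.
    """
    from .socket_extraction import EMPIRIC_DEPTH_FACTOR, EXTENT_X_MM, EXTENT_Y_MM, EXTENT_Z_MM
    from .socket_extraction import OCTVolume

    noise = noise or OCTNoiseConfig()
    rng = np.random.default_rng(seed)
    n_x, n_z = slice_shape
    px = EXTENT_X_MM / n_x
    py = EXTENT_Y_MM / n_y
    pz = EXTENT_Z_MM / n_z
    x_mm = (np.arange(n_x) + 0.5) * px - EXTENT_X_MM / 2
    z_mm = (np.arange(n_z) + 0.5) * pz
    r_w = conformer.window_diameter / 2.0
    d = conformer.window_thickness
    off = conformer.window_offset

    # beam displacement by refraction through the tilted window
    sx, sy = tilt
    n_vec = np.array([-sx, -sy, 1.0])
    n_vec = n_vec / np.linalg.norm(n_vec)
    theta_i = np.arccos(n_vec[2])
    shift = np.zeros(2)
    if theta_i > 1e-12:
        theta_t = np.arcsin(np.sin(theta_i) / conformer.refractive_index)
        mag = d * np.sin(theta_i - theta_t) / np.cos(theta_t)
        shift = mag * n_vec[:2] / np.linalg.norm(n_vec[:2])

    th = np.deg2rad(gaze_deg)
    c, s = np.cos(th), np.sin(th)

    line_len_mm = 0.35
    ramp_mm = 0.3
    slices = np.zeros((n_y, n_x, n_z), dtype=np.uint8)
    for iy in range(n_y):
        y = EXTENT_Y_MM / 2 - (iy + 0.5) * py
        img = np.zeros((n_x, n_z), dtype=np.float32)
        rho = np.hypot(x_mm, y)
        in_win = rho <= r_w
        tA = zA_centre + sx * x_mm + sy * y
        # one-sided interface reflections: signal starts at the interface
        for t0 in (tA, tA + d):
            band = (z_mm[None, :] >= t0[:, None]) & (z_mm[None, :] < (t0 + line_len_mm)[:, None])
            img[in_win] = np.maximum(img[in_win], np.where(band[in_win], 130.0, 0.0))
        # tissue: invert the correction chain to find the rendered depth
        x_p = x_mm + shift[0]
        y_p = y + shift[1]
        z_a = truth_fn(x_p, np.full_like(x_p, y_p))
        for _ in range(3):  # gaze-rotation fixed point
            x_rot = c * x_p + s * z_a
            z_t = truth_fn(x_rot, np.full_like(x_rot, y_p))
            z_a = np.where(np.isfinite(z_t), (z_t + s * x_p) / c, np.nan)
        zA0 = zA_centre  # anterior plane at the window centre
        z_surf = zA0 - (z_a + off + EMPIRIC_DEPTH_FACTOR * d)
        has = in_win & np.isfinite(z_surf) & (z_surf > tA + d + 0.8) & (z_surf < EXTENT_Z_MM - 0.2)
        rise = np.clip((z_mm[None, :] - z_surf[:, None]) / ramp_mm, 0.0, 1.0)
        decay = np.exp(-np.clip(z_mm[None, :] - z_surf[:, None], 0.0, None) / 6.0)
        tissue = 190.0 * rise * decay
        if noise.speckle_shape > 0:
            k = noise.speckle_shape
            tissue = tissue * rng.gamma(k, 1.0 / k, size=tissue.shape)
        img[has] = np.maximum(img[has], tissue[has])
        if noise.salt_density > 0:
            dots = rng.random(img.shape) < noise.salt_density
            img = np.maximum(img, np.where(dots, float(noise.salt_value), 0.0))
        slices[iy] = np.clip(img, 0, 255).astype(np.uint8)

    truth = {
        "surface": truth_fn,
        "zA_centre": zA_centre,
        "tilt": tilt,
        "gaze_deg": gaze_deg,
    }
    return OCTVolume(slices=slices, conformer_id=conformer.id), truth


def hemispherical_socket(radius: float = 11.0, depth_offset: float = 0.0):
    """Analytic hemispherical socket surface in the canonical frame."""

    def fn(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r2 = x ** 2 + y ** 2
        z = np.full_like(x, np.nan)
        ok = r2 < radius ** 2 * 0.96
        z[ok] = -np.sqrt(radius ** 2 - r2[ok]) + radius - 12.0 - depth_offset
        return z

    return fn


# ---------------------------------------------------------------------------
# eye photograph


@dataclass
class EyePhotoConfig:
    """Scene parameters of the synthetic fellow-eye photograph.

    The scene is composed in CIELAB and pushed through a known camera mixing
    matrix, so segmentation, palette and characterization ground truths are
    all analytic.
    """

    size: tuple[int, int] = (512, 512)
    iris_radius: float = 120.0      # px
    pupil_radius: float = 42.0
    centre: tuple[float, float] | None = None   # defaults to image centre
    iris_lab: tuple[float, float, float] = (42.0, 8.0, 24.0)   # hazel
    pupil_lab: tuple[float, float, float] = (4.0, 0.0, 0.0)
    sclera_lab: tuple[float, float, float] = (78.0, 2.0, 6.0)
    stain_labs: tuple = ((71.0, 4.0, 12.0), (66.0, 8.0, 16.0))
    skin_lab: tuple[float, float, float] = (55.0, 16.0, 18.0)
    vein_lab: tuple[float, float, float] = (62.0, 38.0, 22.0)
    streak_amplitudes: tuple[float, float] = (5.0, 3.0)
    radial_amplitude: float = 4.0
    n_veins: int = 25
    n_highlights: int = 0
    highlight_delta_l: float = 40.0
    aperture: tuple[float, float] = (0.44, 0.34)  # opening semi-axes, image fractions
    psf_sigma: float = 2.0   # optical blur of the capture, px


def gen_eye_photo(config: EyePhotoConfig | None = None, seed: int = 0) -> dict:
    """Synthetic eye photo with full ground truth.

    Returns a dict with the CIELAB scene (``lab``), the camera image
    (``camera_rgb``) obtained through a known XYZ-to-camera mixing matrix
    (``camera_from_xyz``), a label map (1 pupil, 2 iris, 3 sclera, 4 skin),
    iris/pupil centre and radii, the injected stain palette, and the vein and
    highlight masks.
    """
    from .colour import lab_to_xyz

    config = config or EyePhotoConfig()
    rng = np.random.default_rng(seed)
    H, W = config.size
    cy, cx = (H / 2.0, W / 2.0) if config.centre is None else config.centre[::-1]
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    r = np.hypot(xx - cx, yy - cy)
    phi = np.arctan2(yy - cy, xx - cx)

    lab = np.empty((H, W, 3))
    lab[:] = config.sclera_lab

    # sclera staining blobs (smooth blotches of the two injected colours)
    for i, colour in enumerate(config.stain_labs):
        blob = np.zeros((H, W))
        for _ in range(6):
            bx, by = rng.uniform(0.1, 0.9) * W, rng.uniform(0.1, 0.9) * H
            s = rng.uniform(18, 45)
            blob += np.exp(-((xx - bx) ** 2 + (yy - by) ** 2) / (2 * s * s))
        m = blob > np.quantile(blob, 0.92)
        lab[m] = colour

    # veins: short red random walks on the sclera
    vein_mask = np.zeros((H, W), dtype=bool)
    for _ in range(config.n_veins):
        x = rng.uniform(0, W)
        y = rng.uniform(0, H)
        d = rng.uniform(0, 2 * np.pi)
        for _ in range(rng.integers(30, 90)):
            d += rng.normal(0, 0.3)
            x = (x + 2.0 * np.cos(d)) % W
            y = np.clip(y + 2.0 * np.sin(d), 0, H - 1)
            vein_mask[int(y), int(x)] = True
    vein_mask &= r > config.iris_radius * 1.05
    import scipy.ndimage as ndi
    vein_mask = ndi.binary_dilation(vein_mask)
    lab[vein_mask] = config.vein_lab

    # iris with radial streaks, then pupil
    iris = r <= config.iris_radius
    s1, s2 = config.streak_amplitudes
    streak = s1 * np.sin(24 * phi) + s2 * np.sin(7 * phi + 1.3)
    radial = config.radial_amplitude * np.cos(np.pi * r / max(config.iris_radius, 1))
    lab[iris] = np.asarray(config.iris_lab)
    lab[..., 0][iris] += (streak + radial)[iris]
    pupil = r <= config.pupil_radius
    lab[pupil] = config.pupil_lab

    # skin outside the aperture ellipse
    ax, by_ = config.aperture[0] * W, config.aperture[1] * H
    skin = ((xx - W / 2) / ax) ** 2 + ((yy - H / 2) / by_) ** 2 > 1.0
    lab[skin] = config.skin_lab

    labels = np.full((H, W), 3, dtype=np.int32)
    labels[iris] = 2
    labels[pupil] = 1
    labels[skin] = 4

    highlight_mask = np.zeros((H, W), dtype=bool)
    for _ in range(config.n_highlights):
        hx = cx + rng.uniform(-0.5, 0.5) * config.iris_radius
        hy = cy + rng.uniform(-0.5, 0.5) * config.iris_radius
        dot = np.hypot(xx - hx, yy - hy) <= 2.5
        highlight_mask |= dot
        lab[..., 0][dot] = np.minimum(lab[..., 0][dot] + config.highlight_delta_l, 99.0)

    # optical point-spread blur: real captures have no hard edges, which
    # matters for the median-based highlight rule downstream
    if config.psf_sigma > 0:
        for c in range(3):
            lab[..., c] = ndi.gaussian_filter(lab[..., c], config.psf_sigma)

    # camera: known mixing of XYZ (a perturbed inverse-sRGB-like matrix)
    M_cam = np.array([
        [2.9, -1.4, -0.45],
        [-0.95, 1.85, 0.05],
        [0.06, -0.22, 1.45],
    ])
    xyz = lab_to_xyz(lab)
    camera_rgb = np.clip(xyz @ M_cam.T, 0.0, 1.0)

    return {
        "lab": lab,
        "camera_rgb": camera_rgb,
        "camera_from_xyz": M_cam,
        "labels": labels,
        "iris_centre": (cx, cy),
        "iris_radius": config.iris_radius,
        "pupil_radius": config.pupil_radius,
        "palette": np.asarray(config.stain_labs + (config.sclera_lab,)),
        "vein_mask": vein_mask,
        "highlight_mask": highlight_mask,
    }


def gen_iris_disc(r_pupil: float = 1.8, r_limbus: float = 6.0,
                  boundary_sigma: float = 0.0, n_ring: int = 48,
                  n_radial: int = 8, dome: float = 0.4, seed: int = 0) -> "trimesh.Trimesh":
    """Annular iris surface mesh like the one exported by the OCT software.

    ``boundary_sigma`` adds radial raggedness to the pupil boundary (mm).
    """
    rng = np.random.default_rng(seed)
    ang = np.arange(n_ring) * 2 * np.pi / n_ring
    radii = np.linspace(r_pupil, r_limbus, n_radial)
    verts = []
    for i, rr in enumerate(radii):
        rads = np.full(n_ring, rr)
        if i == 0 and boundary_sigma > 0:
            rads = rads + rng.normal(0, boundary_sigma, n_ring)
        z = dome * (1.0 - (rr / r_limbus) ** 2)
        verts.append(np.stack([rads * np.cos(ang), rads * np.sin(ang),
                               np.full(n_ring, z)], axis=1))
    V = np.concatenate(verts)
    F = []
    for i in range(n_radial - 1):
        for j in range(n_ring):
            a = i * n_ring + j
            b = i * n_ring + (j + 1) % n_ring
            c = (i + 1) * n_ring + j
            d = (i + 1) * n_ring + (j + 1) % n_ring
            F.append((a, d, b))
            F.append((a, c, d))
    return trimesh.Trimesh(V, np.asarray(F), process=False)
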