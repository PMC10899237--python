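"""Socket surface extraction from AS-OCT raster volumes.

The raster scan is 256 greyscale slices of 2145 x 1877 px, each covering
16 mm (lateral x) by 14 mm (depth z), with the 256 slices spanning 16 mm in
y.  Slices are thresholded, median-filtered and pooled down to 536 x 469,
stacked into volume tensors, and the conformer window surfaces and socket
surface are found by per-column tracing along depth.  Three corrections
(refraction through the tilted window, an empiric depth bias, frame
alignment plus 6 degree gaze) produce the socket depth map D_S on a
256 x 256 grid in the canonical iris-plane frame (socket surface at
negative z, deeper = more negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .conformers import ConformerSpec
from .errors import NoWindowFoundError, SocketAreaError

# canonical acquisition geometry
SLICE_WIDTH = 2145      # px, lateral x
SLICE_DEPTH = 1877      # px, depth z
N_SLICES = 256          # y
EXTENT_X_MM = 16.0
EXTENT_Z_MM = 14.0
EXTENT_Y_MM = 16.0
VOLUME_WIDTH = 536
VOLUME_DEPTH = 469
THRESHOLD = 25
EDGE_THRESHOLD = -0.05
GRID_SIZE = 256         # D_S resolution
GRID_EXTENT_MM = 16.0
MIN_AREA_MM2 = 32.0
GAZE_ANGLE_DEG = 6.0
EMPIRIC_DEPTH_FACTOR = 0.35
SOCKET_TRACE_OFFSET = 10  # voxels below the posterior window where tracing starts


@dataclass
class OCTVolume:
    """Raster scan volume: ``slices[y]`` is one slice image with axes (x, z)."""

    slices: np.ndarray  # (n_y, n_x, n_z) uint8
    conformer_id: str = ""
    extent_x: float = EXTENT_X_MM
    extent_y: float = EXTENT_Y_MM
    extent_z: float = EXTENT_Z_MM

    @property
    def is_canonical(self) -> bool:
        return self.slices.shape == (N_SLICES, SLICE_WIDTH, SLICE_DEPTH)


@dataclass
class FilteredVolumes:
    V_Median: np.ndarray  # (w, n_y, d) float in [0, 1]
    V_Edge: np.ndarray    # same shape, bool
    pitch: tuple[float, float, float]  # mm per voxel along (x, y, z)


@dataclass
class WindowSurfaces:
    D_A: np.ndarray  # (w, n_y) anterior first-hit depth, voxels
    M_A: np.ndarray
    P_A: np.ndarray  # plane coefficients (a, b, c): z = a x + b y + c, voxel units
    D_B: np.ndarray
    M_B: np.ndarray
    P_B: np.ndarray
    tau: float       # conformer window thickness in voxels


@dataclass
class SocketDepthMap:
    values: np.ndarray      # (256, 256) aligned-frame z in mm (negative into socket)
    mask: np.ndarray        # (256, 256) bool
    pixel_pitch: float
    origin: tuple[float, float]
    area_mm2: float
    points: np.ndarray | None = None  # corrected point cloud P_S, (n, 3) mm


def threshold_slice(B: np.ndarray, b_th: int = THRESHOLD) -> np.ndarray:
    """Clip-and-rescale an 8-bit slice to [0, 1]: (max(B, b_th) - b_th)/(255 - b_th)."""
    B = np.asarray(B, dtype=np.float32)
    return (np.maximum(B, b_th) - b_th) / (255.0 - b_th)


def _median_pool2(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    img = img[: 2 * (h // 2), : 2 * (w // 2)]
    blocks = img.reshape(h // 2, 2, w // 2, 2).transpose(0, 2, 1, 3).reshape(h // 2, w // 2, 4)
    s = np.sort(blocks, axis=-1)
    return 0.5 * (s[..., 1] + s[..., 2])


def _max_pool4(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    img = img[: 4 * (h // 4), : 4 * (w // 4)]
    return img.reshape(h // 4, 4, w // 4, 4).max(axis=(1, 3))


def downsample_slice(Bp: np.ndarray, strict: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Median cascade and max pooling: full-res slice -> (B_Median, B_Max).

    The denoising cascade is median(k=5) -> 2x2 median pool -> median(k=3)
    -> 2x2 median pool; trailing odd rows/columns are dropped at each pool so
    a 2145 x 1877 slice maps to exactly 536 x 469.  B_Max is plain 4x4 max
    pooling of the same input.
    """
    if strict and Bp.shape != (SLICE_WIDTH, SLICE_DEPTH):
        raise ValueError(f"expected ({SLICE_WIDTH}, {SLICE_DEPTH}) slice, got {Bp.shape}")
    m = ndi.median_filter(Bp, size=5, mode="nearest")
    m = _median_pool2(m)
    m = ndi.median_filter(m, size=3, mode="nearest")
    B_Median = _median_pool2(m)
    B_Max = _max_pool4(Bp)
    return B_Median, B_Max


# separable size-5 Sobel second-derivative kernels (derivative along z)
_SOBEL_D2 = np.array([1.0, 0.0, -2.0, 0.0, 1.0])
_SOBEL_SMOOTH = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def edge_map(B_Median: np.ndarray, B_Max: np.ndarray,
             threshold: float = EDGE_THRESHOLD) -> np.ndarray:
    """Boolean edge image: strong negative 2nd depth-derivative of masked B_Max.

    B_Max is masked to pixels where B_Median is non-zero, the second
    derivative along the depth axis is taken with a separable size-5 Sobel
    kernel (smoothing normalised to unit gain), and pixels below the
    threshold are marked.
    """
    if B_Median.shape != B_Max.shape:
        raise ValueError("B_Median and B_Max must have equal shapes")
    masked = np.where(B_Median > 0, B_Max, 0.0)
    g = ndi.convolve1d(masked, _SOBEL_D2, axis=1, mode="nearest")
    g = ndi.convolve1d(g, _SOBEL_SMOOTH, axis=0, mode="nearest")
    return g < threshold


def build_filtered_volumes(volume: OCTVolume) -> FilteredVolumes:
    """Threshold, downsample and edge-filter all slices into volume tensors."""
    n_y = volume.slices.shape[0]
    strict = volume.is_canonical
    med_slices = []
    edge_slices = []
    for iy in range(n_y):
        Bp = threshold_slice(volume.slices[iy])
        B_Median, B_Max = downsample_slice(Bp, strict=strict)
        med_slices.append(B_Median)
        edge_slices.append(edge_map(B_Median, B_Max))
    V_Median = np.stack(med_slices, axis=1)  # (w, n_y, d)
    V_Edge = np.stack(edge_slices, axis=1)
    w, _, d = V_Median.shape
    pitch = (volume.extent_x / w, volume.extent_y / n_y, volume.extent_z / d)
    return FilteredVolumes(V_Median=V_Median, V_Edge=V_Edge, pitch=pitch)


def _first_hit(V: np.ndarray, start: np.ndarray | int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-column index of the first True at depth >= start; valid flag."""
    n_z = V.shape[2]
    zidx = np.arange(n_z)
    if np.isscalar(start):
        gate = V & (zidx >= start)
    else:
        gate = V & (zidx[None, None, :] >= np.asarray(start)[..., None])
    hit = gate.any(axis=2)
    first = gate.argmax(axis=2)
    return first.astype(float), hit


def _fit_plane(D: np.ndarray, M: np.ndarray) -> np.ndarray:
    xs, ys = np.nonzero(M)
    A = np.stack([xs, ys, np.ones_like(xs)], axis=1).astype(float)
    coef, *_ = np.linalg.lstsq(A, D[M], rcond=None)
    return coef


def _eval_plane(coef: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    xs = np.arange(shape[0])[:, None]
    ys = np.arange(shape[1])[None, :]
    return coef[0] * xs + coef[1] * ys + coef[2]


def trace_window(fv: FilteredVolumes, conformer: ConformerSpec,
                 min_columns: int = 500) -> WindowSurfaces:
    """Trace the anterior/posterior conformer window surfaces in V_Edge.

    Anterior: first edge hit per column, mask-initialised below
    median + 0.75 tau, then 8 rounds of plane-fit refinement keeping columns
    within 0.5 tau of the plane.  Posterior: first edge hit at or below
    D_A + 0.5 tau with 4 refinement rounds, then median filtering and
    morphological opening to clean the mask.
    """
    V_E = fv.V_Edge
    tau = conformer.window_thickness / fv.pitch[2]
    D_A, has_A = _first_hit(V_E, 0)
    if has_A.sum() < min_columns:
        raise NoWindowFoundError(
            f"only {int(has_A.sum())} columns with edge hits (< {min_columns})")
    M_A = has_A & (D_A < (np.median(D_A[has_A]) + 0.75 * tau))
    P_A = _fit_plane(D_A, M_A)
    for _ in range(8):
        P_A = _fit_plane(D_A, M_A)
        M_A = has_A & (np.abs(D_A - _eval_plane(P_A, D_A.shape)) < 0.5 * tau)

    start = np.where(has_A, D_A + 0.5 * tau, 0.0)
    D_B, has_B = _first_hit(V_E, start)
    M_B = M_A & has_B
    P_B = _fit_plane(D_B, M_B)
    for _ in range(4):
        P_B = _fit_plane(D_B, M_B)
        M_B = has_B & (np.abs(D_B - _eval_plane(P_B, D_B.shape)) < 0.5 * tau)
    M_B = ndi.median_filter(M_B, size=3)
    M_B = ndi.binary_opening(M_B)
    return WindowSurfaces(D_A=D_A, M_A=M_A, P_A=P_A, D_B=D_B, M_B=M_B, P_B=P_B, tau=tau)


def trace_socket(fv: FilteredVolumes, windows: WindowSurfaces,
                 start_offset: int = SOCKET_TRACE_OFFSET,
                 outlier_mm: float = 0.5,
                 min_area_mm2: float = MIN_AREA_MM2,
                 chunk: int = 16384) -> tuple[np.ndarray, np.ndarray]:
    """Trace the socket surface per column in V_Median below the window.

    Starting at z0 = D_B + offset, z1 is the brightest voxel below z0, z2 the
    voxel with the steepest intensity rise relative to z0, and the surface z3
    is the last zero-intensity voxel before z2.  A 5x5 median comparison
    drops outlier columns; the result aborts when the masked area falls below
    the minimum.
    """
    V_M = fv.V_Median
    w, n_y, n_z = V_M.shape
    cols = np.nonzero(windows.M_B)
    z0_all = np.clip(windows.D_B[cols] + start_offset, 0, n_z - 2).astype(int)
    D = np.full((w, n_y), np.nan)
    valid = np.zeros((w, n_y), dtype=bool)
    zidx = np.arange(n_z)
    for lo in range(0, len(cols[0]), chunk):
        sl = slice(lo, lo + chunk)
        cx, cy = cols[0][sl], cols[1][sl]
        z0 = z0_all[sl]
        prof = V_M[cx, cy, :]  # (m, n_z)
        v0 = prof[np.arange(len(z0)), z0]
        after = zidx[None, :] > z0[:, None]
        z1 = np.where(after, prof, -np.inf).argmax(axis=1)
        dz = zidx[None, :] - z0[:, None]
        upto = after & (zidx[None, :] <= z1[:, None])
        slopes = np.where(upto, (prof - v0[:, None]) / np.maximum(dz, 1), -np.inf)
        z2 = slopes.argmax(axis=1)
        zeros = (prof == 0) & (zidx[None, :] < z2[:, None])
        # a column needs actual signal below z0 and a zero gap before it
        ok = zeros.any(axis=1) & (np.where(after, prof, 0.0).max(axis=1) > 0)
        z3 = n_z - 1 - zeros[:, ::-1].argmax(axis=1)
        D[cx[ok], cy[ok]] = z3[ok]
        valid[cx[ok], cy[ok]] = True

    # outlier rejection against a 5x5 median of the (gap-filled) depth map
    if valid.any():
        filled = D.copy()
        if (~valid).any():
            ind = ndi.distance_transform_edt(~valid, return_distances=False, return_indices=True)
            filled = D[tuple(ind)]
        med = ndi.median_filter(filled, size=5)
        thr = outlier_mm / fv.pitch[2]
        valid &= np.abs(D - med) <= thr

    area = valid.sum() * fv.pitch[0] * fv.pitch[1]
    if area < min_area_mm2:
        raise SocketAreaError(
            f"extracted mask covers {area:.1f} mm^2 (< {min_area_mm2} mm^2); aborting")
    return D, valid


def correct_and_grid(D_raw: np.ndarray, M_raw: np.ndarray,
                     windows: WindowSurfaces, conformer: ConformerSpec,
                     fv: FilteredVolumes,
                     gaze_deg: float = GAZE_ANGLE_DEG,
                     grid_size: int = GRID_SIZE,
                     grid_extent: float = GRID_EXTENT_MM) -> SocketDepthMap:
    """Apply the three depth corrections and resample onto the D_S grid.

    1. Refraction through the tilted window (Snell, n = 1.5; thin-window
       model correcting the in-plane beam displacement) plus the empiric
       depth correction of -0.35 d for effective window thickness d.
    2. Axial shift so the anterior window plane passes through z = -offset
       (the window sits ``window_offset`` below the iris plane, which maps to
       z = 0 of the canonical frame).
    3. 6 degree gaze rotation about the y-axis.
    """
    px, py, pz = fv.pitch
    w, n_y = D_raw.shape
    xs, ys = np.nonzero(M_raw)
    if len(xs) == 0:
        raise SocketAreaError("empty socket mask")
    x_mm = (xs + 0.5) * px - fv.V_Median.shape[0] * px / 2.0
    y_mm = fv.V_Median.shape[1] * py / 2.0 - (ys + 0.5) * py
    # the surface sits at the leading boundary of the first signal voxel (z3 + 1)
    z_vol = (D_raw[xs, ys] + 1.0) * pz

    # window plane normal in mm units
    a, b, _ = windows.P_A
    dzdx = a * pz / px
    dzdy = b * pz / py
    n_vec = np.array([-dzdx, -dzdy, 1.0])
    norm = np.linalg.norm(n_vec)
    if not np.isfinite(norm) or norm < 1e-12:
        raise ValueError("degenerate window plane normal")
    n_vec /= norm
    theta_i = np.arccos(np.clip(n_vec[2], -1.0, 1.0))
    d_eff = conformer.window_thickness
    if theta_i > 1e-9:
        theta_t = np.arcsin(np.sin(theta_i) / conformer.refractive_index)
        shift = d_eff * np.sin(theta_i - theta_t) / np.cos(theta_t)
        horiz = n_vec[:2] / np.linalg.norm(n_vec[:2])
        x_mm = x_mm + shift * horiz[0]
        y_mm = y_mm + shift * horiz[1]

    # axial alignment: anterior plane (at the M_A centroid) -> z = -offset
    ax, ay = np.nonzero(windows.M_A)
    cx, cy = ax.mean(), ay.mean()
    zA0 = (windows.P_A[0] * cx + windows.P_A[1] * cy + windows.P_A[2] + 0.5) * pz
    z_aligned = -(z_vol - zA0) - conformer.window_offset - EMPIRIC_DEPTH_FACTOR * d_eff

    # gaze correction: rotate about y toward nasal
    th = np.deg2rad(gaze_deg)
    c, s = np.cos(th), np.sin(th)
    x_rot = c * x_mm + s * z_aligned
    z_rot = -s * x_mm + c * z_aligned
    pts = np.stack([x_rot, y_mm, z_rot], axis=1)

    pitch = grid_extent / grid_size
    origin = (-grid_extent / 2 + pitch / 2, -grid_extent / 2 + pitch / 2)
    jj = np.round((pts[:, 0] - origin[0]) / pitch).astype(int)
    ii = np.round((pts[:, 1] - origin[1]) / pitch).astype(int)
    keep = (ii >= 0) & (ii < grid_size) & (jj >= 0) & (jj < grid_size)
    acc = np.zeros((grid_size, grid_size))
    cnt = np.zeros((grid_size, grid_size))
    np.add.at(acc, (ii[keep], jj[keep]), pts[keep, 2])
    np.add.at(cnt, (ii[keep], jj[keep]), 1.0)
    mask = cnt > 0
    values = np.where(mask, acc / np.maximum(cnt, 1), 0.0)
    area = float(mask.sum() * pitch * pitch)
    return SocketDepthMap(values=values, mask=mask, pixel_pitch=pitch,
                          origin=origin, area_mm2=area, points=pts)


def extract_socket(volume: OCTVolume, conformer: ConformerSpec,
                   min_columns: int = 500,
                   grid_size: int = GRID_SIZE) -> SocketDepthMap:
    """Full extraction chain: filter volume, trace window and socket, correct.

    ``grid_size`` defaults to the canonical 256; reduced-resolution volumes
    should use a proportionally coarser grid so D_S stays dense.
    """
    fv = build_filtered_volumes(volume)
    windows = trace_window(fv, conformer, min_columns=min_columns)
    D_raw, M_raw = trace_socket(fv, windows)
    return correct_and_grid(D_raw, M_raw, windows, conformer, fv,
                            grid_size=grid_size)
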