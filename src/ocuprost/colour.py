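"""Camera colour characterization and eye-photo processing.

Camera RGB is mapped to CIELAB (D50 illuminant, 2 degree observer) in two
stages: a linear 3x3 matrix A into CIEXYZ followed by the XYZ -> Lab
transform, then a root-polynomial correction with a 3x7 matrix B on the
features (L*, a*, b*, sqrt(L*a*), sqrt(L*b*), sqrt(a*b*), 1).  Because a*
and b* are signed, the roots use the signed convention sign(x) sqrt(|x|).
Both matrices are least-squares fits to measured colour patches (the
reference set is 24 colour-checker + 24 iris + 15 sclera patches).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import color as skcolor
from skimage.restoration import denoise_nl_means

from .errors import InsufficientDataError

WHITE_POINT = "D50"
OBSERVER = "2"
#: the reference patch-set composition: colour checker + iris + sclera
REFERENCE_PATCH_COUNTS = (24, 24, 15)
HIGHLIGHT_DELTA_L = 10.0
HIGHLIGHT_MEDIAN_SIZE = 15
HIGHLIGHT_DILATE_ITER = 2


def xyz_to_lab(xyz: np.ndarray) -> np.ndarray:
    """Gamma: CIEXYZ -> CIELAB under D50/2."""
    return skcolor.xyz2lab(xyz, illuminant=WHITE_POINT, observer=OBSERVER)

def lab_to_xyz(lab: np.ndarray) -> np.ndarray:
    return skcolor.lab2xyz(lab, illuminant=WHITE_POINT, observer=OBSERVER)


def signed_root(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.sqrt(np.abs(x))


def root_polynomial_features(lab: np.ndarray) -> np.ndarray:
    """(L*, a*, b*, sqrt(L*a*), sqrt(L*b*), sqrt(a*b*), 1), signed roots."""
    lab = np.asarray(lab, dtype=float)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    return np.stack([
        L, a, b,
        signed_root(L * a), signed_root(L * b), signed_root(a * b),
        np.ones_like(L),
    ], axis=-1)


@dataclass
class ColourCharacterization:
    A: np.ndarray               # 3x3 camera RGB -> XYZ
    B: np.ndarray               # 3x7 Lab feature correction
    residual_mean: float        # CIEDE2000 on the training patches
    residual_max: float
    white_point: str = WHITE_POINT
    observer: str = OBSERVER

    def apply(self, rgb: np.ndarray) -> np.ndarray:
        """Characterize camera RGB (any leading shape, last axis 3) to CIELAB."""
        rgb = np.asarray(rgb, dtype=float)
        xyz = rgb @ self.A.T
        lab = xyz_to_lab(np.clip(xyz, 0.0, None))
        return root_polynomial_features(lab) @ self.B.T

    def to_json(self) -> str:
        return json.dumps({
            "A": self.A.tolist(), "B": self.B.tolist(),
            "residual_mean": self.residual_mean, "residual_max": self.residual_max,
            "white_point": self.white_point, "observer": self.observer,
        })

    @classmethod
    def from_json(cls, text: str) -> "ColourCharacterization":
        d = json.loads(text)
        return cls(A=np.asarray(d["A"]), B=np.asarray(d["B"]),
                   residual_mean=d["residual_mean"], residual_max=d["residual_max"],
                   white_point=d["white_point"], observer=d["observer"])


def fit_characterization(rgb: np.ndarray, lab: np.ndarray) -> ColourCharacterization:
    """Fit the two-stage characterization to RGB/CIELAB patch pairs."""
    rgb = np.asarray(rgb, dtype=float)
    lab = np.asarray(lab, dtype=float)
    if len(rgb) < 10:
        raise InsufficientDataError(f"need >= 10 patch pairs, got {len(rgb)}")
    if np.linalg.matrix_rank(rgb) < 3:
        raise InsufficientDataError("patch set is rank deficient in RGB")
    xyz_target = lab_to_xyz(lab)
    A, *_ = np.linalg.lstsq(rgb, xyz_target, rcond=None)
    A = A.T
    lab0 = xyz_to_lab(np.clip(rgb @ A.T, 0.0, None))
    feats = root_polynomial_features(lab0)
    B, *_ = np.linalg.lstsq(feats, lab, rcond=None)
    B = B.T
    corrected = feats @ B.T
    dE = skcolor.deltaE_ciede2000(lab, corrected)
    return ColourCharacterization(A=A, B=B, residual_mean=float(np.mean(dE)),
                                  residual_max=float(np.max(dE)))


# ---------------------------------------------------------------------------
# raw image chain


@dataclass
class CameraCalibration:
    dark_mean: float            # mean pixel value of the dark frame
    flat: np.ndarray            # dark-corrected white-patch image W
    flat_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.flat_mean == 0.0:
            self.flat_mean = float(np.mean(self.flat))


@dataclass
class EyeImage:
    """Named processing stages of one eye photograph (immutable once set)."""

    stages: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.stages[key]


def demosaic_bilinear(raw: np.ndarray, pattern: str = "GRBG") -> np.ndarray:
    """Bilinear demosaic of a single-plane Bayer image (GR row order)."""
    if pattern != "GRBG":
        raise ValueError("only the camera's GR Bayer pattern is supported")
    H, W = raw.shape
    out = np.zeros((H, W, 3), dtype=float)
    masks = np.zeros((3, H, W), dtype=bool)
    masks[1, 0::2, 0::2] = True   # G on even rows/cols
    masks[0, 0::2, 1::2] = True   # R
    masks[2, 1::2, 0::2] = True   # B
    masks[1, 1::2, 1::2] = True   # G
    k_g = np.array([[0, 1, 0], [1, 4, 1], [0, 1, 0]], dtype=float) / 4.0
    k_rb = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float) / 4.0
    for ch, k in ((0, k_rb), (1, k_g), (2, k_rb)):
        plane = np.where(masks[ch], raw, 0.0)
        out[..., ch] = ndi.convolve(plane, k, mode="mirror")
    return out


def process_raw(image: np.ndarray, calib: CameraCalibration,
                characterization: ColourCharacterization,
                strong_h: float = 15.0 / 255.0, light_h: float = 1.5) -> EyeImage:
    """Raw-to-CIELAB chain: demosaic, strong denoise, dark/flat correction,
    characterization, light denoise.

    2-D input is treated as a GR-pattern Bayer plane and demosaiced; 3-D
    input is taken as camera RGB and the demosaic stage is skipped.  All
    intermediate stages are kept for inspection: ``raw``, ``I`` (demosaiced),
    ``I_denoised``, ``I_prime`` (dark-corrected), ``I_flat`` (flat-fielded),
    ``I_col`` (CIELAB).
    """
    if calib is None:
        raise ValueError("camera calibration is required")
    stages: dict[str, np.ndarray] = {"raw": np.asarray(image, dtype=float)}
    I = stages["raw"]
    if I.ndim == 2:
        I = demosaic_bilinear(I)
    stages["I"] = I
    I_dn = denoise_nl_means(I, h=strong_h, patch_size=5, patch_distance=6,
                            channel_axis=-1, fast_mode=True)
    stages["I_denoised"] = I_dn
    I_p = I_dn - calib.dark_mean
    stages["I_prime"] = I_p
    flat = calib.flat if calib.flat.ndim == I_p.ndim else calib.flat[..., None]
    I_pp = calib.flat_mean * (I_p / np.maximum(flat, 1e-9))
    stages["I_flat"] = I_pp
    lab = characterization.apply(np.clip(I_pp, 0.0, None))
    lab = denoise_nl_means(lab, h=light_h, patch_size=5, patch_distance=6,
                           channel_axis=-1, fast_mode=True)
    stages["I_col"] = lab
    return EyeImage(stages=stages)


def diffusion_inpaint(image: np.ndarray, mask: np.ndarray, iterations: int = 300) -> np.ndarray:
    """Jacobi diffusion fill of masked pixels from their neighbourhood."""
    out = image.astype(float).copy()
    if not mask.any():
        return out
    # seed masked pixels with the nearest unmasked value for fast convergence
    ind = ndi.distance_transform_edt(mask, return_distances=False, return_indices=True)
    out[mask] = out[tuple(ind)][mask]
    k = np.array([[0.0, 0.25, 0.0], [0.25, 0.0, 0.25], [0.0, 0.25, 0.0]])
    for _ in range(iterations):
        sm = ndi.convolve(out, k, mode="nearest")
        out[mask] = sm[mask]
    return out


def remove_highlights(I_col: np.ndarray, I_raw: np.ndarray,
                      saturation_level: float = 1.0 - 1e-6,
                      delta_L: float = HIGHLIGHT_DELTA_L) -> tuple[np.ndarray, np.ndarray]:
    """Mask and inpaint specular highlights in the characterized image.

    A pixel is flagged when the raw capture is oversaturated or its lightness
    deviates more than ``delta_L`` from the 15x15 median of L*; the mask is
    dilated twice (3x3) and each Lab channel diffusion-inpainted over it.
    """
    L = I_col[..., 0]
    med = ndi.median_filter(L, size=HIGHLIGHT_MEDIAN_SIZE)
    mask = np.abs(L - med) > delta_L
    raw = np.asarray(I_raw, dtype=float)
    over = raw >= saturation_level
    if over.ndim == 3:
        over = over.any(axis=-1)
    mask |= over
    mask = ndi.binary_dilation(mask, structure=np.ones((3, 3), bool),
                               iterations=HIGHLIGHT_DILATE_ITER)
    if mask.mean() > 0.30:
        warnings.warn(f"highlight mask covers {100 * mask.mean():.0f}% of the image")
    clean = np.stack([diffusion_inpaint(I_col[..., c], mask) for c in range(3)], axis=-1)
    return clean, mask
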