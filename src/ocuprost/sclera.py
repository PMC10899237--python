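"""Sclera appearance: segmentation, palette, staining and vein synthesis.

The sclera region of the characterized eye photo is segmented with a seeded
watershed, reduced to a 9-colour CIELAB palette by k-means, and reproduced
procedurally: Perlin-noise stain maps over a lightness-weighted base colour,
plus a three-layer procedural vein network rendered with per-vein colour
profiles.  Two scalar parameters th (thickness) and br (branching ratio)
scale the vein recipes; both default to 1.0, inside the 0.9-1.5 span used
clinically.

The vein recipe table, the 10 seed positions and the 15 colour profiles
stand in for hand-tuned supplementary data of the original workflow; they
are versioned constants chosen to give a plausibly layered network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import color as skcolor
from skimage.segmentation import watershed
from sklearn.cluster import KMeans

from .errors import DetectionFailureError, InsufficientDataError
from .noise import PerlinNoise3D

TEXTURE_WIDTH = 4096
TEXTURE_HEIGHT = 2048
STAIN_COVERAGE = 0.90
N_PALETTE = 9
LABEL_PUPIL, LABEL_IRIS, LABEL_SCLERA, LABEL_SKIN = 1, 2, 3, 4
#: domain-unit y of the limbus boundary in the 2:1 vein domain (x in [0,2))
VEIN_LIMBUS_Y = 0.06
VEIN_TABLE_VERSION = 1


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class ScleraSegmentation:
    labels: np.ndarray       # M_E: watershed label image
    sclera_mask: np.ndarray  # M_W: refined sclera mask
    sclera_pixels: np.ndarray  # I_S: (n, 3) CIELAB pixels inside M_W
    median_image: np.ndarray   # I_median


def _median_cascade(lab: np.ndarray, iterations: int = 20) -> np.ndarray:
    out = lab.astype(float).copy()
    for i in range(iterations):
        size = 5 if i % 2 == 0 else 3
        for c in range(out.shape[-1]):
            out[..., c] = ndi.median_filter(out[..., c], size=size)
    return out


def segment_sclera(I_col: np.ndarray, iris_mask: np.ndarray,
                   min_contrast: float = 5.0) -> ScleraSegmentation:
    """Watershed segmentation into pupil, iris, sclera and aperture/skin.

    Seeds come from the central horizontal cross-section of the median-
    blurred image: the darkest pixel marks the pupil, the brightest pixels
    left and right of it the sclera, and the lightness-derivative extrema in
    between the limbus/pupil boundaries enclosing the iris seeds.  The
    refined mask M_W drops dark pixels (L* < 50), a dilated iris mask, and
    reddish vein pixels (C* > 8, hue in [345, 60] degrees).
    """
    I_median = _median_cascade(I_col)
    L = I_median[..., 0]
    H, W = L.shape
    row = H // 2
    profile = L[row]
    x_lo, x_hi = int(0.1 * W), int(0.9 * W)
    x_pupil = x_lo + int(np.argmin(profile[x_lo:x_hi]))
    if profile.max() - profile[x_pupil] < min_contrast:
        raise DetectionFailureError("no dark pupil minimum on the central cross-section")
    x_scl_l = x_lo + int(np.argmax(profile[x_lo:x_pupil])) if x_pupil > x_lo else x_lo
    x_scl_r = x_pupil + int(np.argmax(profile[x_pupil:x_hi]))
    deriv = np.gradient(profile)
    seeds_iris = []
    for lo, hi in ((x_scl_l, x_pupil), (x_pupil, x_scl_r)):
        if hi - lo < 4:
            continue
        d = deriv[lo:hi]
        limbus = lo + int(np.argmax(np.abs(d)))
        seeds_iris.append((limbus + x_pupil) // 2)

    markers = np.zeros((H, W), dtype=np.int32)
    markers[row, x_pupil] = LABEL_PUPIL
    for x in seeds_iris:
        markers[row, x] = LABEL_IRIS
    markers[row, x_scl_l] = LABEL_SCLERA
    markers[row, x_scl_r] = LABEL_SCLERA
    for r, c in ((2, 2), (2, W - 3), (H - 3, 2), (H - 3, W - 3)):
        markers[r, c] = LABEL_SKIN
    grad = ndi.gaussian_gradient_magnitude(L, sigma=2.0)
    labels = watershed(grad, markers)

    lch = skcolor.lab2lch(I_col)
    Lc, C, hdeg = lch[..., 0], lch[..., 1], np.rad2deg(lch[..., 2]) % 360.0
    veiny = (C > 8.0) & ((hdeg >= 345.0) | (hdeg <= 60.0))
    iris_dil = ndi.binary_dilation(iris_mask, iterations=5)
    M_W = (labels == LABEL_SCLERA) & (Lc >= 50.0) & ~iris_dil & ~veiny
    return ScleraSegmentation(labels=labels, sclera_mask=M_W,
                              sclera_pixels=I_col[M_W], median_image=I_median)


# ---------------------------------------------------------------------------
# palette


@dataclass
class ScleraPalette:
    colours: np.ndarray      # (n, 3) CIELAB cluster centres g_i
    weights: np.ndarray      # lightness weights w_i
    base_colour: np.ndarray  # g_B

    @property
    def n(self) -> int:
        return len(self.colours)


def palette_base_colour(colours: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lightness-weighted base colour: w_i = (L_i - Lmin)/(Lmax - Lmin),
    g_B = sum(w_i g_i)/sum(w_i); uniform weights in the equal-lightness limit."""
    L = colours[:, 0]
    L_min, L_max = L.min(), L.max()
    if L_max - L_min < 1e-12:
        w = np.ones(len(colours))
    else:
        w = (L - L_min) / (L_max - L_min)
    base = (w[:, None] * colours).sum(axis=0) / w.sum()
    return base, w


def extract_palette(sclera_pixels: np.ndarray, n_colours: int = N_PALETTE,
                    seed: int = 0, min_pixels: int = 1000) -> ScleraPalette:
    """k-means (k-means++ init) palette of the masked sclera pixels."""
    pix = np.asarray(sclera_pixels, dtype=float)
    if len(pix) < min_pixels:
        raise InsufficientDataError(f"only {len(pix)} sclera pixels (< {min_pixels})")
    km = KMeans(n_clusters=n_colours, init="k-means++", n_init=3,
                random_state=seed).fit(pix)
    colours = km.cluster_centers_
    order = np.argsort(-colours[:, 0])  # deterministic: brightest first
    colours = colours[order]
    base, w = palette_base_colour(colours)
    return ScleraPalette(colours=colours, weights=w, base_colour=base)


# ---------------------------------------------------------------------------
# staining texture


@dataclass
class ScleraTexture:
    lab: np.ndarray                 # (H, W, 3) CIELAB
    stain_fraction: float
    colour_index: np.ndarray        # per-pixel palette index, -1 = base
    vein_depth: np.ndarray | None = None  # per-pixel depth of the topmost vein


def render_staining(palette: ScleraPalette, seed: int = 0,
                    width: int = TEXTURE_WIDTH, height: int = TEXTURE_HEIGHT,
                    coverage: float = STAIN_COVERAGE, freq: float = 6.0) -> ScleraTexture:
    """Perlin-stain texture over the base colour, seamless across u.

    Each palette colour gets a 3D-noise weight map sampled on a cylinder
    (matching seams at the vertical borders); the per-pixel argmax colour is
    painted wherever the maximum weight exceeds its (1 - coverage) histogram
    quantile, so the stained fraction is the requested coverage and the
    colours occupy roughly equal areas.
    """
    noise = PerlinNoise3D(seed)
    u = 2.0 * (np.arange(width, dtype=np.float32) + 0.5) / width
    v = (np.arange(height, dtype=np.float32) + 0.5) / height
    # phase/origin offsets keep the u seam away from the noise-lattice planes
    theta = np.pi * u + 0.37
    cx = np.cos(theta) * (freq / np.pi) + 13.1
    cy = np.sin(theta) * (freq / np.pi) + 7.7
    gx = np.broadcast_to(cx[None, :], (height, width))
    gy = np.broadcast_to(cy[None, :], (height, width))
    # stains are slightly elongated along u (circumferential), like real
    # conjunctival staining bands
    gz = np.broadcast_to((v * freq * 2.0)[:, None], (height, width))
    fields = np.stack([noise.fbm(gx, gy, gz + 37.0 * (i + 1), octaves=2)
                       for i in range(palette.n)])
    scale = float(np.std(fields))
    # histogram equalisation of the per-colour areas: bias each weight map
    # until the argmax partition splits the stained area evenly
    bias = np.zeros(palette.n, dtype=np.float32)
    target = coverage / palette.n
    for _ in range(25):
        biased = fields + bias[:, None, None]
        best = biased.max(axis=0)
        idx = biased.argmax(axis=0).astype(np.int8)
        thr = np.quantile(best, 1.0 - coverage)
        stained = best > thr
        areas = np.array([(stained & (idx == i)).mean() for i in range(palette.n)])
        err = areas / target - 1.0
        if np.abs(err).max() < 0.03:
            break
        bias -= (0.35 * scale * err).astype(np.float32)
    tex = np.empty((height, width, 3))
    tex[:] = palette.base_colour
    tex[stained] = palette.colours[idx[stained]]
    colour_index = np.where(stained, idx, -1).astype(np.int8)
    return ScleraTexture(lab=tex, stain_fraction=float(stained.mean()),
                         colour_index=colour_index)


# ---------------------------------------------------------------------------
# vein network


@dataclass(frozen=True)
class VeinRecipe:
    layer: int
    thickness: float      # initial half-width, domain units
    decay: float          # mean per-step relative thinning
    depth: float          # 0 (shallow) .. 1 (deep)
    step: float           # node spacing, domain units
    max_steps: int
    turn_sigma: float     # radians, per-step heading noise
    bias: float           # pull of the heading toward the limbus (0..1)
    branch_rate: float    # branching events per node at br = 1
    min_thickness: float  # growth stops below this fraction of `thickness`


def _make_recipes() -> tuple[VeinRecipe, ...]:
    specs = []
    # layer 1: long, deep, straight trunks from the fornix
    for i, (t, st, mx) in enumerate([(0.012, 0.030, 70), (0.010, 0.026, 80),
                                     (0.014, 0.034, 60), (0.011, 0.028, 75),
                                     (0.013, 0.032, 65)]):
        specs.append(VeinRecipe(1, t, 0.004 + 0.001 * i, 0.85 - 0.03 * i, st, mx,
                                0.12 + 0.02 * i, 0.55, 0.06, 0.25))
    # layer 2: medium branches
    for i, (t, st, mx) in enumerate([(0.006, 0.022, 45), (0.005, 0.020, 50),
                                     (0.007, 0.024, 40), (0.0055, 0.021, 48),
                                     (0.0065, 0.023, 42)]):
        specs.append(VeinRecipe(2, t, 0.008 + 0.002 * i, 0.5 - 0.04 * i, st, mx,
                                0.30 + 0.03 * i, 0.35, 0.05, 0.2))
    # layer 3: fine, shallow, wiggly capillaries (terminal)
    for i, (t, st, mx) in enumerate([(0.003, 0.015, 30), (0.0025, 0.014, 32),
                                     (0.0035, 0.016, 28), (0.0028, 0.015, 30),
                                     (0.0032, 0.015, 26)]):
        specs.append(VeinRecipe(3, t, 0.015 + 0.003 * i, 0.2 - 0.03 * i, st, mx,
                                0.50 + 0.04 * i, 0.25, 0.0, 0.2))
    return tuple(specs)


RECIPES: tuple[VeinRecipe, ...] = _make_recipes()

#: 10 first-layer seed positions in the 2:1 domain, along the fornix border,
#: denser toward the caruncle side (u near 0)
SEED_POSITIONS = np.array([
    [0.08, 0.95], [0.28, 0.98], [0.52, 0.94], [0.75, 0.97], [0.98, 0.95],
    [1.18, 0.98], [1.42, 0.94], [1.62, 0.97], [1.82, 0.95], [1.95, 0.92],
])


@dataclass
class Vein:
    nodes: np.ndarray       # (n, 2) positions, x in [0, 2) wrapped, y in [limbus, 1]
    thickness: np.ndarray   # (n,) half-widths (already scaled by th)
    depth: float
    layer: int
    recipe_id: int


@dataclass
class VeinNetwork:
    veins: list[Vein]
    th: float
    br: float
    seed: int


def _grow_single(recipe: VeinRecipe, start: np.ndarray, direction: np.ndarray,
                 t0: float, depth: float, rng: np.random.Generator,
                 limbus_y: float = VEIN_LIMBUS_Y) -> tuple[np.ndarray, np.ndarray]:
    """Grow one vein; thickness returned unscaled (relative units)."""
    pos = start.astype(float).copy()
    d = direction / np.linalg.norm(direction)
    nodes = [pos.copy()]
    thick = [t0]
    t = t0
    for _ in range(recipe.max_steps):
        a = rng.normal(0.0, recipe.turn_sigma)
        c, s = np.cos(a), np.sin(a)
        d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
        target = np.array([0.0, -1.0])  # toward the limbus
        d = (1.0 - recipe.bias * 0.15) * d + recipe.bias * 0.15 * target
        d /= np.linalg.norm(d)
        pos = pos + recipe.step * d
        pos[0] = pos[0] % 2.0
        t = t * (1.0 - abs(rng.normal(recipe.decay, recipe.decay * 0.5)))
        if pos[1] <= limbus_y or pos[1] >= 1.0:
            break  # reached the limbus (or left the domain at the fornix)
        if t < recipe.min_thickness * recipe.thickness:
            break  # too thin
        nodes.append(pos.copy())
        thick.append(t)
    return np.asarray(nodes), np.asarray(thick)


def grow_veins(th: float = 1.0, br: float = 1.0, seed: int = 0) -> VeinNetwork:
    """Grow the three-layer vein network in the 2:1 dimensionless domain.

    Layer-1 veins start at the 10 fornix seed positions; grown veins branch
    into next-layer veins at randomly selected nodes (reduced thickness, same
    depth, a randomly selected recipe of the next layer).  ``th`` scales all
    thicknesses, ``br`` all branching rates; neither alters the random
    stream, so runs with the same seed differ only in the scaled values.
    """
    if not (0.0 < th <= 3.0) or not (0.0 <= br <= 3.0):
        raise ValueError("th must be in (0, 3], br in [0, 3]")
    rng = np.random.default_rng(seed)
    veins: list[Vein] = []
    layer_recipes = {L: [i for i, r in enumerate(RECIPES) if r.layer == L] for L in (1, 2, 3)}
    queue: list[tuple[int, np.ndarray, np.ndarray, float, float]] = []
    for sp in SEED_POSITIONS:
        rid = int(rng.choice(layer_recipes[1]))
        direction = np.array([rng.normal(0.0, 0.3), -1.0])
        queue.append((rid, sp.copy(), direction, RECIPES[rid].thickness, RECIPES[rid].depth))
    while queue:
        rid, start, direction, t0, depth = queue.pop(0)
        recipe = RECIPES[rid]
        nodes, thick = _grow_single(recipe, start, direction, t0, depth, rng)
        veins.append(Vein(nodes=nodes, thickness=thick * th, depth=depth,
                          layer=recipe.layer, recipe_id=rid))
        if recipe.layer < 3 and len(nodes) > 2:
            n_branch = int(rng.poisson(br * recipe.branch_rate * len(nodes)))
            for _ in range(n_branch):
                j = int(rng.integers(1, len(nodes)))
                nrid = int(rng.choice(layer_recipes[recipe.layer + 1]))
                a = rng.uniform(0.0, 2 * np.pi)
                queue.append((nrid, nodes[j].copy(),
                              np.array([np.cos(a), np.sin(a)]),
                              0.7 * thick[j], depth))
    return VeinNetwork(veins=veins, th=th, br=br, seed=seed)


# ---------------------------------------------------------------------------
# vein profiles and rendering

PROFILE_SAMPLES = 21


def _make_profiles() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """15 synthetic cross-sections: (colours, alphas, widths, depths).

    Each profile is 21 CIELAB+alpha samples across the vein: a reddish core
    fading to transparent flanks.  Width/depth labels span the recipe ranges.
    These are synthetic stand-ins for profiles sampled from photographs.
    """
    widths = np.linspace(0.002, 0.016, 15)
    depths = np.tile(np.array([0.85, 0.65, 0.45, 0.25, 0.1]), 3)[:15]
    x = np.linspace(-1.0, 1.0, PROFILE_SAMPLES)
    colours = np.zeros((15, PROFILE_SAMPLES, 3))
    alphas = np.zeros((15, PROFILE_SAMPLES))
    for i in range(15):
        core = np.exp(-(x / 0.45) ** 2)
        alphas[i] = core * (0.95 - 0.03 * (i % 5))
        L = 45.0 - 8.0 * core + i % 5
        a = 20.0 + 18.0 * core
        b = 8.0 + 10.0 * core
        colours[i] = np.stack([L, a, b], axis=1)
    return colours, alphas, widths, depths


PROFILE_COLOURS, PROFILE_ALPHAS, PROFILE_WIDTHS, PROFILE_DEPTHS = _make_profiles()
THICKNESS_WEIGHT = 5.0


def select_profile(thickness: float, depth: float) -> int:
    """Profile with minimal weighted squared distance; thickness weighted 5x."""
    cost = THICKNESS_WEIGHT * (PROFILE_WIDTHS - thickness) ** 2 + (PROFILE_DEPTHS - depth) ** 2
    return int(np.argmin(cost))


def _quadratic_bspline(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                       t: np.ndarray) -> np.ndarray:
    """Uniform quadratic B-spline segment over a 3-node window."""
    w0 = 0.5 * (1.0 - t) ** 2
    w1 = -t * t + t + 0.5
    w2 = 0.5 * t * t
    return w0[:, None] * p0 + w1[:, None] * p1 + w2[:, None] * p2


def render_veins(network: VeinNetwork, staining: ScleraTexture,
                 jitter_amplitude: float = 0.35, jitter_frequency: float = 9.0,
                 min_halfwidth_px: float = 1.0) -> ScleraTexture:
    """Rasterize the vein network over the staining texture.

    Vein chains are sampled along sliding-window quadratic B-splines, the
    centreline displaced by a sinusoidal perpendicular offset, and each
    sample stamps its selected 21-value colour/alpha profile by distance to
    the curve.  Veins are composited deep-to-shallow so shallower veins win
    at crossings; a depth map records the topmost vein depth per pixel.
    """
    H, W = staining.lab.shape[:2]
    sx = W / 2.0   # domain x in [0, 2)
    sy = H / 1.0
    out = staining.lab.copy()
    depth_map = np.full((H, W), np.inf)

    for vein in sorted(network.veins, key=lambda v: -v.depth):
        nodes = vein.nodes
        if len(nodes) < 2:
            continue
        pid = select_profile(float(vein.thickness[0]), vein.depth)
        prof_col = PROFILE_COLOURS[pid]
        prof_alpha = PROFILE_ALPHAS[pid]
        # pad the chain so the spline interpolates the end nodes
        padded = np.vstack([nodes[0], nodes, nodes[-1]])
        thick_pad = np.concatenate([[vein.thickness[0]], vein.thickness,
                                    [vein.thickness[-1]]])
        arclen = 0.0
        for i in range(len(padded) - 2):
            p0, p1, p2 = padded[i], padded[i + 1], padded[i + 2]
            seg_px = max(np.linalg.norm((p2 - p0) / 2) * sx, 1.0)
            t = np.linspace(0.0, 1.0, max(int(seg_px * 1.5), 3), endpoint=False)
            pts = _quadratic_bspline(p0, p1, p2, t)
            tk = (1 - t) * thick_pad[i + 1] + t * thick_pad[i + 2]
            tang = np.gradient(pts, axis=0)
            nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
            nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-12)
            s_local = arclen + np.cumsum(np.linalg.norm(tang, axis=1))
            arclen = s_local[-1] if len(s_local) else arclen
            if jitter_amplitude > 0:
                offs = jitter_amplitude * tk * np.sin(2 * np.pi * jitter_frequency * s_local / 0.1)
                pts = pts + offs[:, None] * nrm
            for p, tki in zip(pts, tk):
                cxp = p[0] * sx
                cyp = p[1] * sy
                hw = max(tki * sx, min_halfwidth_px)
                r = int(np.ceil(hw)) + 1
                iy0 = int(np.floor(cyp)) - r
                iy1 = int(np.floor(cyp)) + r + 1
                ys = np.clip(np.arange(iy0, iy1), 0, H - 1)
                xs = (np.arange(int(np.floor(cxp)) - r, int(np.floor(cxp)) + r + 1)) % W
                gy, gx = np.meshgrid(ys, xs, indexing="ij")
                dxp = (gx - cxp + W / 2.0) % W - W / 2.0
                dist = np.hypot(dxp, gy - cyp)
                inside = dist <= hw
                if not inside.any():
                    continue
                pi = np.clip(np.round(10.0 + 10.0 * dist / hw), 0, PROFILE_SAMPLES - 1
                             ).astype(int)
                alpha = np.where(inside, prof_alpha[pi], 0.0)
                col = prof_col[pi]
                sel = alpha > 0
                yy, xx = gy[sel], gx[sel]
                a = alpha[sel][:, None]
                out[yy, xx] = (1 - a) * out[yy, xx] + a * col[sel]
                deeper = alpha > 0.3
                dm = depth_map[gy[deeper], gx[deeper]]
                depth_map[gy[deeper], gx[deeper]] = np.minimum(dm, vein.depth)
    return ScleraTexture(lab=out, stain_fraction=staining.stain_fraction,
                         colour_index=staining.colour_index,
                         vein_depth=depth_map)
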