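"""Shape prediction: fit the SSM to a socket depth map.

The fit minimises E(x) = E_dist(x) + E_ref(x): a masked mean-squared
difference between the orthographic z-projection of the back of S(x) and the
socket depth map D_S, plus a weighted pull toward a target shape x_t.  The
target interpolates between the mean shape and the conformer's base shape,
x_t = alpha * x_c.  Optimisation is bounded L-BFGS-B inside the +/-3
standard-deviation hypercube with modes enabled three at a time
(coarse-to-fine); if the solution saturates the hypercube an extended fit
adds a z-translation and a rotation about y, penalised quadratically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.optimize import minimize
from scipy.spatial import Delaunay

from .conformers import ConformerSpec
from .geometry import LandmarkMesh
from .socket_extraction import SocketDepthMap
from .ssm import ShapeModel, synthesize

DEFAULT_W_REF = (2048.0, 1024.0, 512.0, 256.0, 128.0, 64.0, 32.0, 16.0, 16.0, 16.0)


@dataclass
class FitConfig:
    w_dist: float = 10000.0
    w_ref_head: tuple[float, ...] = DEFAULT_W_REF
    w_ref_tail: float = 16.0     # weight for modes beyond the printed vector
    w_ext: float = 10000.0
    box: float = 3.0             # hypercube half-width, standard deviations
    theta_limit_deg: float = 30.0
    z_limit_mm: float = 2.5
    alphas: tuple[float, ...] = (0.0, 0.5, 0.9)
    mode_step: int = 3
    edge_tol: float = 1e-6       # saturation tolerance triggering the fallback
    fd_step: float = 1e-3        # forward finite-difference step per mode
    maxiter: int = 200

    def w_ref(self, k: int) -> np.ndarray:
        head = np.asarray(self.w_ref_head, dtype=float)
        if k <= len(head):
            return head[:k]
        return np.concatenate([head, np.full(k - len(head), self.w_ref_tail)])


@dataclass
class FitResult:
    x_f: np.ndarray
    theta: float            # radians
    z: float                # mm
    energy: float
    energy_trace: list[float]
    fallback_used: bool
    alpha: float


def back_depth_map(shape: LandmarkMesh, depth: SocketDepthMap,
                   theta: float = 0.0, z: float = 0.0) -> np.ndarray:
    """Z_z: orthographic z-depth of the (rigidly perturbed) back surface.

    The back surface is a height field over its x-y projection; its depth at
    the D_S pixel centres is obtained by piecewise-linear interpolation of
    the 649 back landmarks.  Pixels outside the silhouette are NaN.
    """
    pts = shape.back_points
    if theta != 0.0 or z != 0.0:
        c, s = np.cos(theta), np.sin(theta)
        x = c * pts[:, 0] + s * pts[:, 2]
        zz = -s * pts[:, 0] + c * pts[:, 2] + z
        pts = np.stack([x, pts[:, 1], zz], axis=1)
    n = depth.values.shape[0]
    ax = depth.origin[0] + np.arange(n) * depth.pixel_pitch
    gx, gy = np.meshgrid(ax, depth.origin[1] + np.arange(n) * depth.pixel_pitch)
    interp = LinearNDInterpolator(pts[:, :2], pts[:, 2])
    return interp(np.stack([gx.ravel(), gy.ravel()], axis=1)).reshape(n, n)


def energy_dist(x: np.ndarray, depth: SocketDepthMap, model: ShapeModel,
                config: FitConfig | None = None,
                theta: float = 0.0, z: float = 0.0) -> float:
    """Masked mean-squared back-surface-to-socket distance, weighted w_dist."""
    config = config or FitConfig()
    if not depth.mask.any():
        raise ValueError("empty socket mask")
    shape = synthesize(model, np.asarray(x, dtype=float))
    Z = back_depth_map(shape, depth, theta=theta, z=z)
    diff = Z - depth.values
    sel = depth.mask & np.isfinite(Z)
    n_mask = depth.mask.sum()
    # pixels of M_S the projection misses contribute the worst in-mask residual,
    # keeping the energy finite while penalising shapes that undershoot the mask
    if sel.any():
        worst = np.max(diff[sel] ** 2, initial=0.0)
        total = np.sum(diff[sel] ** 2) + worst * (n_mask - sel.sum())
    else:
        total = 1e6 * n_mask
    return float(config.w_dist / n_mask * total)


def energy_ref(x: np.ndarray, x_t: np.ndarray, config: FitConfig | None = None) -> float:
    """L2 norm of the element-wise weighted difference to the target shape."""
    config = config or FitConfig()
    x = np.asarray(x, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if x.shape != x_t.shape:
        raise ValueError("x and x_t must have equal length")
    w = config.w_ref(len(x))
    return float(np.linalg.norm(w * (x - x_t)))


def make_target(x_c: np.ndarray, alpha: float) -> np.ndarray:
    """Target shape x_t = (1 - alpha) x_m + alpha x_c = alpha x_c."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * np.asarray(x_c, dtype=float)


def total_energy(x: np.ndarray, x_t: np.ndarray, depth: SocketDepthMap,
                 model: ShapeModel, config: FitConfig,
                 theta: float = 0.0, z: float = 0.0,
                 extended: bool = False) -> float:
    e = energy_dist(x, depth, model, config, theta=theta, z=z) + energy_ref(x, x_t, config)
    if extended:
        e += config.w_ext * (theta ** 2 + z ** 2)
    return e


def _fit_stage(x0: np.ndarray, active: np.ndarray, x_t: np.ndarray,
               depth: SocketDepthMap, model: ShapeModel, config: FitConfig,
               trace: list[float]) -> np.ndarray:
    """L-BFGS-B over the active coordinates, inactive ones pinned at x0."""
    x_full = x0.copy()
    idx = np.nonzero(active)[0]

    def f(xa: np.ndarray) -> float:
        x_full[idx] = xa
        e = total_energy(x_full, x_t, depth, model, config)
        trace.append(e)
        return e

    res = minimize(f, x_full[idx], method="L-BFGS-B",
                   bounds=[(-config.box, config.box)] * len(idx),
                   options={"maxiter": config.maxiter, "eps": config.fd_step})
    if not res.success and "MAXLS" not in str(res.message):
        warnings.warn(f"shape fit stage did not fully converge: {res.message}")
    x_full[idx] = res.x
    return x_full


def _fit_extended(x0: np.ndarray, x_t: np.ndarray, depth: SocketDepthMap,
                  model: ShapeModel, config: FitConfig,
                  trace: list[float]) -> tuple[np.ndarray, float, float]:
    th_lim = np.deg2rad(config.theta_limit_deg)
    k = len(x0)

    def f(v: np.ndarray) -> float:
        e = total_energy(v[:k], x_t, depth, model, config,
                         theta=v[k], z=v[k + 1], extended=True)
        trace.append(e)
        return e

    bounds = [(-config.box, config.box)] * k + [(-th_lim, th_lim),
                                                (-config.z_limit_mm, config.z_limit_mm)]
    res = minimize(f, np.concatenate([x0, [0.0, 0.0]]), method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": config.maxiter, "eps": config.fd_step})
    return res.x[:k], float(res.x[k]), float(res.x[k + 1])


def fit_shape(depth: SocketDepthMap, model: ShapeModel, conformer: ConformerSpec,
              config: FitConfig | None = None,
              alphas: tuple[float, ...] | None = None) -> list[FitResult]:
    """Fit the shape model to a socket depth map, one result per alpha."""
    config = config or FitConfig()
    alphas = alphas if alphas is not None else config.alphas
    k = model.k
    results = []
    for alpha in alphas:
        x_c = np.zeros(k)
        x_c[: min(k, len(conformer.x_c))] = conformer.x_c[:k]
        x_t = make_target(x_c, alpha)
        trace: list[float] = []
        x = np.clip(x_t.copy(), -config.box, config.box)
        # coarse-to-fine: enable modes in steps of mode_step, earlier modes stay free
        for m in range(config.mode_step, k + config.mode_step, config.mode_step):
            active = np.zeros(k, dtype=bool)
            active[: min(m, k)] = True
            x = _fit_stage(x, active, x_t, depth, model, config, trace)
        theta = z = 0.0
        fallback = bool(np.any(np.abs(x) >= config.box - config.edge_tol))
        if fallback:
            x, theta, z = _fit_extended(x, x_t, depth, model, config, trace)
        e = total_energy(x, x_t, depth, model, config, theta=theta, z=z,
                         extended=fallback)
        results.append(FitResult(x_f=x, theta=theta, z=z, energy=e,
                                 energy_trace=trace, fallback_used=fallback,
                                 alpha=alpha))
    return results


def back_surface_error(shape: LandmarkMesh, depth: SocketDepthMap) -> float:
    """Masked mean |Z_z(shape) - D_S| in mm (reported fit diagnostic)."""
    Z = back_depth_map(shape, depth)
    sel = depth.mask & np.isfinite(Z)
    return float(np.mean(np.abs(Z[sel] - depth.values[sel])))
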