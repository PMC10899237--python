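"""PCA statistical shape model over landmark meshes.

The model is a linear map from shape space to mesh space,

    S(x) = S_m + sum_i x_i * sigma_i * C_i,

with mean shape ``S_m``, unit principal directions ``C_i`` and per-mode
standard deviations ``sigma_i``, so shape coordinates are expressed in
standard deviations per mode.  No Procrustes size normalisation is applied:
prosthesis size correlates with shape and the rotation is already fixed by
the marker alignment, so size variation is deliberately kept in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import rings
from .errors import InsufficientDataError
from .geometry import LandmarkMesh

MODEL_FORMAT_VERSION = 1


@dataclass
class ShapeModel:
    mean_shape: LandmarkMesh
    modes: np.ndarray        # (k, 838, 3), unit norm as flattened vectors
    sigmas: np.ndarray       # (k,), non-increasing, mm
    explained_variance: np.ndarray  # fractions over all computed modes
    n_samples: int
    zero_variance: bool = False

    @property
    def k(self) -> int:
        return len(self.sigmas)

    def save(self, path: str) -> None:
        meta = json.dumps({
            "format_version": MODEL_FORMAT_VERSION,
            "ring_scheme_version": rings.RING_SCHEME_VERSION,
            "n_samples": self.n_samples,
            "k": self.k,
            "zero_variance": self.zero_variance,
        })
        np.savez_compressed(
            path, mean=self.mean_shape.points, modes=self.modes,
            sigmas=self.sigmas, explained_variance=self.explained_variance,
            meta=np.array(meta),
        )

    @classmethod
    def load(cls, path: str) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                mean_shape=LandmarkMesh(points=z["mean"]),
                modes=z["modes"], sigmas=z["sigmas"],
                explained_variance=z["explained_variance"],
                n_samples=meta["n_samples"],
                zero_variance=meta.get("zero_variance", False),
            )


def _data_matrix(shapes: list[LandmarkMesh]) -> np.ndarray:
    return np.stack([s.flatten() for s in shapes])


def build_model(shapes: list[LandmarkMesh], variance_target: float = 0.98) -> ShapeModel:
    """Fit the PCA shape model by SVD of the centred flattened-vertex matrix.

    ``k`` is the smallest mode count whose cumulative explained variance
    reaches ``variance_target`` (applied to variance, not std).  The sample
    covariance uses the n-1 divisor; each mode's sign is fixed by making its
    largest-magnitude component positive.
    """
    if len(shapes) < 3:
        raise InsufficientDataError(f"need >= 3 training shapes, got {len(shapes)}")
    X = _data_matrix(shapes)
    n = len(shapes)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2 / (n - 1)
    total = var.sum()
    if total <= 1e-24:
        # all training shapes identical: one zero-variance mode
        mode = np.zeros((1, rings.TOTAL_POINTS, 3))
        mode[0, 0, 0] = 1.0
        return ShapeModel(
            mean_shape=LandmarkMesh.from_flat(mean), modes=mode,
            sigmas=np.zeros(1), explained_variance=np.array([1.0]),
            n_samples=n, zero_variance=True,
        )
    frac = var / total
    k = int(np.searchsorted(np.cumsum(frac), variance_target - 1e-12) + 1)
    k = min(k, len(s))
    modes = Vt[:k]
    # deterministic sign: largest-magnitude component positive
    for i in range(k):
        j = np.argmax(np.abs(modes[i]))
        if modes[i, j] < 0:
            modes[i] = -modes[i]
    sigmas = np.sqrt(var[:k])
    return ShapeModel(
        mean_shape=LandmarkMesh.from_flat(mean),
        modes=modes.reshape(k, rings.TOTAL_POINTS, 3),
        sigmas=sigmas, explained_variance=frac, n_samples=n,
    )


def synthesize(model: ShapeModel, x: np.ndarray) -> LandmarkMesh:
    """Mesh-space shape S(x) for shape-space coordinates x (length k)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.k,):
        raise ValueError(f"expected shape vector of length {model.k}, got {x.shape}")
    if model.zero_variance and np.any((model.sigmas == 0) & (x != 0)):
        raise ValueError("nonzero coordinate requested on a zero-variance mode")
    flat = model.mean_shape.flatten() + np.tensordot(
        x * model.sigmas, model.modes.reshape(model.k, -1), axes=1)
    return LandmarkMesh.from_flat(flat)


def project(model: ShapeModel, shape: LandmarkMesh) -> np.ndarray:
    """Least-squares shape-space coordinates S^{-1}(shape).

    Because the modes are orthonormal this is the inner product with each
    mode divided by its sigma; the orthogonal-complement residual is dropped,
    so S(S^{-1}(shape)) generally differs from the input.
    """
    d = shape.flatten() - model.mean_shape.flatten()
    coeff = model.modes.reshape(model.k, -1) @ d
    if np.any(model.sigmas == 0):
        raise ValueError("cannot project onto a zero-variance mode")
    return coeff / model.sigmas


def _mean_vertex_distance(a: LandmarkMesh, b: LandmarkMesh) -> float:
    return float(np.mean(np.linalg.norm(a.points - b.points, axis=1)))


def evaluate_model(shapes: list[LandmarkMesh], variance_target: float = 0.98,
                   n_specificity_samples: int = 10000, seed: int = 0) -> dict:
    """Replication, leave-one-out generalization and specificity of the SSM.

    All three are mean (+/- sd) Euclidean per-vertex distances in mm:
    replication projects each training shape through the full model;
    generalization retrains with the shape held out; specificity samples
    standard-normal shape vectors and measures the distance to the nearest
    training shape.
    """
    if len(shapes) < 4:
        raise InsufficientDataError("need >= 4 shapes to evaluate")
    model = build_model(shapes, variance_target)

    rep = [_mean_vertex_distance(s, synthesize(model, project(model, s))) for s in shapes]

    gen = []
    for i in range(len(shapes)):
        rest = shapes[:i] + shapes[i + 1:]
        m = build_model(rest, variance_target)
        gen.append(_mean_vertex_distance(shapes[i], synthesize(m, project(m, shapes[i]))))

    rng = np.random.default_rng(seed)
    train = np.stack([s.points for s in shapes])  # (n, 838, 3)
    spec = []
    for _ in range(n_specificity_samples):
        x = rng.standard_normal(model.k)
        pts = synthesize(model, x).points
        d = np.linalg.norm(train - pts[None], axis=2).mean(axis=1)
        spec.append(d.min())
    spec = np.asarray(spec)

    return {
        "replication": (float(np.mean(rep)), float(np.std(rep))),
        "generalization": (float(np.mean(gen)), float(np.std(gen))),
        "specificity": (float(spec.mean()), float(spec.std())),
        "k": model.k,
    }
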