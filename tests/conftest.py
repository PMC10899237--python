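"""Shared synthetic fixtures; everything is generated at run time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ocuprost import geometry, ssm, synth

warnings.filterwarnings("ignore", message="shape fit stage")


@pytest.fixture(scope="session")
def family_landmarks() -> list[geometry.LandmarkMesh]:
    """Aligned correspondence landmarks of 20 synthetic prostheses."""
    fam = synth.ProsthesisFamilyConfig(subdivisions=3)
    scans = synth.gen_prosthesis_set(20, seed=3, config=fam)
    return [geometry.generate_correspondence(geometry.align_shape(s)) for s in scans]


@pytest.fixture(scope="session")
def family_model(family_landmarks) -> ssm.ShapeModel:
    return ssm.build_model(family_landmarks)


@pytest.fixture(scope="session")
def tight_landmarks() -> list[geometry.LandmarkMesh]:
    """A tightly clustered training set (small per-mode variance)."""
    fam = synth.ProsthesisFamilyConfig(
        subdivisions=3, a_range=(11.5, 12.1), b_range=(11.5, 12.1),
        cf_range=(3.0, 3.3), cb_min=11.0, depth_range=(14.2, 15.2),
        bump_range=(0.0, 0.25))
    scans = synth.gen_prosthesis_set(16, seed=3, config=fam)
    return [geometry.generate_correspondence(geometry.align_shape(s)) for s in scans]


@pytest.fixture(scope="session")
def tight_model(tight_landmarks) -> ssm.ShapeModel:
    return ssm.build_model(tight_landmarks)


@pytest.fixture(scope="session")
def linear5_shapes() -> tuple[list[geometry.LandmarkMesh], np.ndarray]:
    """Training shapes drawn from an exactly linear 5-mode generator.

    Returns (shapes, modes) where modes are the orthonormal generator
    directions in flattened-vertex space.
    """
    rng = np.random.default_rng(11)
    base = np.zeros((838, 3))
    # a smooth, non-degenerate base configuration
    t = np.linspace(0, 2 * np.pi, 838, endpoint=False)
    base[:, 0] = 10 * np.cos(t)
    base[:, 1] = 10 * np.sin(t)
    base[:, 2] = np.linspace(-8, 3, 838)
    modes = np.linalg.qr(rng.normal(size=(838 * 3, 5)))[0].T  # (5, 2514)
    sig = np.array([5.0, 4.0, 3.0, 2.0, 1.5])
    shapes = []
    for _ in range(40):
        x = rng.standard_normal(5)
        flat = base.reshape(-1) + (x * sig) @ modes
        flat = flat + rng.normal(0, 1e-4, flat.shape)  # tiny noise
        shapes.append(geometry.LandmarkMesh.from_flat(flat))
    return shapes, modes


@pytest.fixture(scope="session")
def eye_photo() -> dict:
    return synth.gen_eye_photo(seed=2)


@pytest.fixture(scope="session")
def canonical_scan() -> synth.MarkedScan:
    """One synthetic scan in the canonical pose (no rigid transform)."""
    fam = synth.ProsthesisFamilyConfig(subdivisions=3, rigid_rotation=False,
                                       translation_scale=0.0)
    return synth.gen_prosthesis_set(1, seed=5, config=fam)[0]


@pytest.fixture(scope="session")
def canonical_landmarks(canonical_scan) -> geometry.LandmarkMesh:
    return geometry.generate_correspondence(geometry.align_shape(canonical_scan))


@pytest.fixture(scope="session")
def pipeline_artifacts():
    """One full synthetic end-to-end run shared across test modules."""
    from ocuprost.pipeline import run_pipeline
    return run_pipeline(seed=1)


def depth_map_from_shape(shape, n=128, extent=16.0):
    """Socket depth map synthesized from a landmark mesh's back surface."""
    from ocuprost import fitting
    from ocuprost.socket_extraction import SocketDepthMap
    pitch = extent / n
    dm = SocketDepthMap(values=np.zeros((n, n)), mask=np.zeros((n, n), bool),
                        pixel_pitch=pitch, origin=(-extent / 2 + pitch / 2,) * 2,
                        area_mm2=0.0)
    Z = fitting.back_depth_map(shape, dm)
    dm.mask = np.isfinite(Z)
    dm.values = np.where(dm.mask, Z, 0.0)
    dm.area_mm2 = float(dm.mask.sum() * pitch * pitch)
    return dm
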