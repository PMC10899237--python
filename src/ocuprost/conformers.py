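"""Conformer library: window-cut base shapes and per-conformer metadata.

A conformer is a transparent shape worn in the socket during OCT capture.
Its geometry is an SSM base shape whose anterior is cut by a plane parallel
to the iris plane, offset 1.8 mm below it, with a conical frustum recess
forming a flat circular window (diameter about 15 mm, thickness 1.5 mm).
The flat window is the depth reference of the raster scan; the shape vector
and window geometry are stored in a registry keyed by conformer id and
retrieved at extraction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import GeometryError
from .geometry import LandmarkMesh, Side
from .ssm import ShapeModel, project

#: default frustum wall slope measured from the window plane normal
DEFAULT_WALL_SLOPE_DEG = 30.0


@dataclass
class ConformerSpec:
    id: str
    x_c: np.ndarray            # base-shape coordinates S^{-1}(shape)
    window_offset: float = 1.8   # mm below the iris plane
    window_thickness: float = 1.5  # mm
    window_diameter: float = 15.0  # mm
    refractive_index: float = 1.5
    side: Side = "right"

    def __post_init__(self) -> None:
        self.x_c = np.asarray(self.x_c, dtype=float)
        if not (10.0 < self.window_diameter < 16.0):
            raise ValueError(f"window diameter {self.window_diameter} outside (10, 16) mm")
        if self.window_thickness <= 0:
            raise ValueError("window thickness must be positive")
        if not np.all(np.isfinite(self.x_c)):
            raise ValueError("x_c must be finite")

    def window_area(self) -> float:
        """Maximum socket area visible through the window, mm^2."""
        return float(np.pi * (self.window_diameter / 2.0) ** 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["x_c"] = self.x_c.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConformerSpec":
        return cls(**{**d, "x_c": np.asarray(d["x_c"], dtype=float)})


def make_conformer(model: ShapeModel, base: LandmarkMesh, conformer_id: str,
                   window_offset: float = 1.8, window_thickness: float = 1.5,
                   window_diameter: float = 15.0, side: Side = "right",
                   wall_slope_deg: float = DEFAULT_WALL_SLOPE_DEG,
                   ) -> tuple[ConformerSpec, LandmarkMesh]:
    """Derive a conformer from a base shape: registry entry plus geometry.

    The anterior is flattened onto the window plane (z = -offset) inside the
    window radius; outside it the cut follows a conical frustum of the given
    wall slope.  The frustum is geometry-only: extraction uses only the
    stored thickness, offset and refractive index.  Left-side conformers are
    mirrored across the y-z plane.
    """
    x_c = project(model, base)
    z_w = -window_offset
    r_w = window_diameter / 2.0
    pts = base.points.copy()
    apex_z = pts[:, 2].max()
    if apex_z <= z_w:
        raise GeometryError(
            f"base shape too shallow to cut: apex z {apex_z:.2f} <= window plane {z_w:.2f}")
    rho = np.hypot(pts[:, 0], pts[:, 1])
    slope = np.tan(np.deg2rad(wall_slope_deg))
    # admissible z: flat inside the window, conical frustum wall outside
    z_cap = np.where(rho <= r_w, z_w, z_w + (rho - r_w) / max(slope, 1e-9))
    pts[:, 2] = np.minimum(pts[:, 2], z_cap)
    if side == "left":
        pts = pts * np.array([-1.0, 1.0, 1.0])
    spec = ConformerSpec(id=conformer_id, x_c=x_c, window_offset=window_offset,
                         window_thickness=window_thickness,
                         window_diameter=window_diameter, side=side)
    return spec, LandmarkMesh(points=pts)


class ConformerRegistry:
    """JSON-backed table of conformer specs keyed by id."""

    def __init__(self, specs: dict[str, ConformerSpec] | None = None) -> None:
        self._specs: dict[str, ConformerSpec] = dict(specs or {})

    def add(self, spec: ConformerSpec) -> None:
        self._specs[spec.id] = spec

    def get(self, conformer_id: str) -> ConformerSpec:
        return self._specs[conformer_id]

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, conformer_id: str) -> bool:
        return conformer_id in self._specs

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: v.to_dict() for k, v in self._specs.items()}, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "ConformerRegistry":
        with open(path) as fh:
            raw = json.load(fh)
        return cls({k: ConformerSpec.from_dict(v) for k, v in raw.items()})
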