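"""File formats: marked scans, OCT slice directories, depth maps, patches."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import trimesh

from .geometry import MarkedScan
from .socket_extraction import OCTVolume, SocketDepthMap

_MARKER_KEYS = ("S", "N", "I", "T")


def write_marked_scan(scan: MarkedScan, mesh_path: str | Path) -> None:
    """STL/OBJ mesh plus a plain-text sidecar with the four marker points."""
    mesh_path = Path(mesh_path)
    trimesh.Trimesh(scan.vertices, scan.faces, process=False).export(mesh_path)
    with open(mesh_path.with_suffix(".markers.txt"), "w") as fh:
        fh.write(f"# marker points (mm), eye_side={scan.eye_side}\n")
        for key in _MARKER_KEYS:
            p = getattr(scan, f"p_{key}")
            fh.write(f"{key} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def read_marked_scan(mesh_path: str | Path) -> MarkedScan:
    mesh_path = Path(mesh_path)
    mesh = trimesh.load_mesh(mesh_path)
    markers: dict[str, np.ndarray] = {}
    eye_side = "right"
    with open(mesh_path.with_suffix(".markers.txt")) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "eye_side=" in line:
                    eye_side = line.split("eye_side=")[1].strip()
                continue
            if not line:
                continue
            key, *coords = line.split()
            markers[key] = np.asarray([float(c) for c in coords])
    missing = [k for k in _MARKER_KEYS if k not in markers]
    if missing:
        raise ValueError(f"marker sidecar is missing points: {missing}")
    return MarkedScan(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces),
                      p_S=markers["S"], p_N=markers["N"], p_I=markers["I"],
                      p_T=markers["T"], eye_side=eye_side)


def write_oct_volume(volume: OCTVolume, out_dir: str | Path) -> None:
    """Slice PNGs (slice_000.png ...) plus a manifest with the conformer id."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, sl in enumerate(volume.slices):
        iio.imwrite(out / f"slice_{i:03d}.png", sl)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"conformer_id": volume.conformer_id,
                   "n_slices": len(volume.slices),
                   "extent_mm": [volume.extent_x, volume.extent_y, volume.extent_z]},
                  fh, indent=2)


def read_oct_volume(in_dir: str | Path) -> OCTVolume:
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    files = sorted(in_dir.glob("slice_*.png")) or sorted(in_dir.glob("slice_*.bmp"))
    slices = np.stack([iio.imread(f) for f in files])
    ex, ey, ez = manifest.get("extent_mm", [16.0, 16.0, 14.0])
    return OCTVolume(slices=slices, conformer_id=manifest.get("conformer_id", ""),
                     extent_x=ex, extent_y=ey, extent_z=ez)


def write_depth_map(depth: SocketDepthMap, prefix: str | Path) -> None:
    """32-bit float TIFF + mask PNG + JSON (area, grid geometry)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(prefix) + "_depth.tiff", depth.values.astype(np.float32))
    iio.imwrite(str(prefix) + "_mask.png", (depth.mask * 255).astype(np.uint8))
    with open(str(prefix) + "_depth.json", "w") as fh:
        json.dump({"area_mm2": depth.area_mm2, "pixel_pitch": depth.pixel_pitch,
                   "origin": list(depth.origin)}, fh, indent=2)


def read_depth_map(prefix: str | Path) -> SocketDepthMap:
    prefix = str(prefix)
    values = tifffile.imread(prefix + "_depth.tiff").astype(float)
    mask = iio.imread(prefix + "_mask.png") > 127
    with open(prefix + "_depth.json") as fh:
        meta = json.load(fh)
    return SocketDepthMap(values=values, mask=mask, pixel_pitch=meta["pixel_pitch"],
                          origin=tuple(meta["origin"]), area_mm2=meta["area_mm2"])


def read_patches_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Colour patches as CSV rows R,G,B,L,a,b (header optional)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line[0].isalpha() or line.startswith("#"):
                continue
            rows.append([float(v) for v in line.split(",")])
    arr = np.asarray(rows)
    return arr[:, :3], arr[:, 3:6]


def write_patches_csv(path: str | Path, rgb: np.ndarray, lab: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("R,G,B,L,a,b\n")
        for c, l in zip(rgb, lab):
            fh.write(",".join(f"{v:.6f}" for v in (*c, *l)) + "\n")
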