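"""End-to-end orchestration on synthetic inputs.

Chains every stage of the design pipeline — training-set generation,
statistical shape model, conformer, synthetic OCT capture, socket
extraction, shape fitting, post-processing, appearance synthesis and model
assembly — on fully synthetic data with known ground truth.  Problem sizes
default to a desk-scale configuration (documented in the methods note);
the canonical full-resolution acquisition geometry remains available
through the individual modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assembly, colour, conformers, fitting, geometry, iris, postprocess
from . import sclera as sclera_mod
from . import socket_extraction as sockx
from . import ssm, synth


@dataclass
class PipelineConfig:
    n_train: int = 20
    mesh_subdivisions: int = 3
    oct_n_y: int = 48
    oct_slice_shape: tuple[int, int] = (400, 360)
    photo_size: tuple[int, int] = (384, 384)
    texture_size: tuple[int, int] = (512, 1024)     # (height, width) sclera
    iris_texture_size: tuple[int, int] = (256, 1024)
    alphas: tuple[float, ...] = (0.0, 0.5, 0.9)
    th: float = 1.0
    br: float = 1.2
    iris_diameter: float = 11.8


def build_training_model(seed: int, config: PipelineConfig) -> tuple[ssm.ShapeModel, list]:
    """Synthetic training set -> aligned landmark meshes -> SSM."""
    fam = synth.ProsthesisFamilyConfig(subdivisions=config.mesh_subdivisions)
    scans = synth.gen_prosthesis_set(config.n_train, seed=seed, config=fam)
    landmarks = [geometry.generate_correspondence(geometry.align_shape(s)) for s in scans]
    model = ssm.build_model(landmarks)
    return model, landmarks


def run_pipeline(seed: int = 0, out_dir: str | Path | None = None,
                 config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic design pipeline; returns all stage artifacts."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)

    # shape model and conformer
    model, landmarks = build_training_model(seed, config)
    conf_spec, _ = conformers.make_conformer(model, landmarks[0], "A05")
    registry = conformers.ConformerRegistry()
    registry.add(conf_spec)

    # target socket: a shape synthesized from known coordinates
    x_true = np.clip(rng.standard_normal(model.k), -1.8, 1.8)
    target = ssm.synthesize(model, x_true)
    interp = _back_interp(target)
    volume, truth = synth.gen_oct_volume(
        interp, conf_spec, n_y=config.oct_n_y,
        slice_shape=config.oct_slice_shape, seed=seed)
    depth = sockx.extract_socket(volume, conf_spec)

    # fit and post-process per alpha, keeping shapes passing the safety gate
    fits = fitting.fit_shape(depth, model, conf_spec,
                             alphas=config.alphas)
    processed = {}
    for res in fits:
        shape = ssm.synthesize(model, res.x_f)
        proc = postprocess.finish_shape(shape, model.mean_shape,
                                        config.iris_diameter, "predicted")
        if postprocess.safety_gate(proc):
            processed[res.alpha] = (res, proc)

    # appearance from the synthetic fellow-eye photo
    photo = synth.gen_eye_photo(synth.EyePhotoConfig(size=config.photo_size), seed=seed)
    lab = photo["lab"]
    seg = iris.detect_iris(lab)
    iris_tex = iris.unwrap_iris(lab, seg, width=config.iris_texture_size[1],
                                height=config.iris_texture_size[0])
    iris_tex = iris.enhance_contrast(iris_tex)
    sseg = sclera_mod.segment_sclera(lab, seg.iris_mask(lab.shape[:2]))
    palette = sclera_mod.extract_palette(sseg.sclera_pixels, seed=seed)
    stain = sclera_mod.render_staining(palette, seed=seed,
                                       height=config.texture_size[0],
                                       width=config.texture_size[1])
    network = sclera_mod.grow_veins(th=config.th, br=config.br, seed=seed)
    sclera_tex = sclera_mod.render_veins(network, stain)

    # geometry of the iris disc (stands in for the OCT software export)
    disc = synth.gen_iris_disc(r_pupil=0.55 * config.iris_diameter / 2 * 0.5,
                               r_limbus=config.iris_diameter / 2, seed=seed)
    iris_geo = iris.build_iris_geometry(disc)

    models = {}
    for alpha, (res, proc) in processed.items():
        pm = assembly.assemble_model(
            proc, iris_geo, sclera_tex.lab, iris_tex,
            metadata={"conformer_id": conf_spec.id, "alpha": alpha,
                      "th": config.th, "br": config.br, "seed": seed})
        models[alpha] = pm
        if out_dir is not None:
            assembly.write_model(pm, out_dir, stem=f"prosthesis_a{alpha:g}".replace(".", "_"))

    return {
        "model": model, "landmarks": landmarks, "conformer": conf_spec,
        "registry": registry, "x_true": x_true, "target": target,
        "volume": volume, "truth": truth, "depth": depth, "fits": fits,
        "processed": processed, "photo": photo, "segmentation": seg,
        "iris_texture": iris_tex, "palette": palette, "sclera_texture": sclera_tex,
        "network": network, "iris_geometry": iris_geo, "models": models,
    }


def _back_interp(lm: geometry.LandmarkMesh):
    """Back-surface height field of a landmark mesh as an (x, y) -> z callable."""
    from scipy.interpolate import LinearNDInterpolator
    pts = lm.back_points
    f = LinearNDInterpolator(pts[:, :2], pts[:, 2])

    def fn(x, y):
        return f(np.stack([np.asarray(x, dtype=float),
                           np.asarray(y, dtype=float)], axis=-1))

    return fn
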