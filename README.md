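# ocuprost

Automated, data-driven design of custom ocular prostheses.

After the loss of an eye, a prosthetic eye must match both the geometry of
the individual anophthalmic socket and the appearance of the fellow eye.
`ocuprost` implements the computational core of a digital end-to-end
workflow for this task, aimed at researchers in medical image analysis and
computational fabrication:

- **Shape.** Scanned prostheses with four limbus/crosshair marker points are
  rigidly aligned into a canonical iris-plane frame and reduced to a fixed
  correspondence representation: 838 landmarks (189 anterior, 649 posterior)
  on radial rays at 7.5° steps, sharing a closed 1672-triangle face list.
  A PCA statistical shape model (SSM) over these landmarks,

      S(x) = S_m + Σᵢ xᵢ σᵢ Cᵢ ,

  with mean shape `S_m`, unit modes `Cᵢ` and per-mode standard deviations
  `σᵢ`, maps shape vectors `x` (in standard deviations per mode) to meshes.
- **Socket capture.** An anterior-segment OCT raster scan taken through a
  transparent conformer (flat reference window, offset 1.8 mm below the iris
  plane) is filtered, traced column-by-column for the window and socket
  surfaces, corrected for refraction (n = 1.5), an empiric depth bias
  (−0.35·thickness) and a 6° gaze angle, and gridded into a 256×256 socket
  depth map `D_S` with validity mask `M_S`.
- **Prediction.** The prosthesis shape is found by bounded L-BFGS-B
  minimisation of

      E(x) = w_dist/|M_S| · Σ_M_S (Z_z(S(x)) − D_S)² + ‖w_ref (x − x_t)‖₂ ,

  where `Z_z` projects the back of `S(x)` orthographically onto the grid and
  `x_t = α·x_c` biases the fit toward the conformer's base shape
  (α ∈ {0, 0.5, 0.9}).  Modes are enabled three at a time inside a ±3σ box;
  box-edge saturation triggers an extended fit with a penalised z-shift and
  y-rotation.  Post-processing renormalises the cornea (apex at 2.5 mm,
  limbus = iris diameter), enlarges the body by 5% sparing the cornea, adds
  a clear-coat displacement, smooths with a volume-increasing Loop-style
  subdivision, and rejects shapes larger than 30 × 29 × 20 mm.
- **Appearance.** Camera RGB is characterised to CIELAB (D50/2°) by a linear
  3×3 matrix into XYZ plus a 3×7 root-polynomial correction fitted on colour
  patches.  The iris is segmented with a multi-scale Daugman search plus a
  constant-area elliptical refinement and unwrapped to a 4096×1024 texture;
  the sclera is segmented by seeded watershed, reduced to a 9-colour k-means
  palette, and reproduced as a seamless Perlin staining texture plus a
  three-layer procedural vein network rendered with colour/alpha profiles.
- **Assembly.** Body, iris disc and black pupil cylinder are fused at the
  limbus plane and exported as textured OBJ/MTL with 16-bit PNG textures.

No clinical data ships with the package; the `synth` module generates all
inputs (marked prosthesis scans, OCT socket volumes with analytic ground
truth, characterised eye photographs) for tests and demonstrations.

## Worked example

```
$ ocuprost pipeline --seed 1 --out out/
socket area: 13.0 mm^2
alpha=0: model written
alpha=0.5: model written
alpha=0.9: model written
outputs in out/
```

This generates a 20-prosthesis synthetic training set, trains the SSM,
derives a conformer, renders a reduced-resolution OCT capture of a socket
synthesized from known shape coordinates, extracts `D_S` (the printed area
counts valid depth-map pixels; at this reduced scan resolution the map is
sparsely populated), fits the model at each α, post-processes the shapes,
synthesizes iris/sclera textures from a synthetic eye photo, and writes one
textured OBJ (plus MTL, texture PNGs and metadata JSON) per α that passes
the size gate.

Library use mirrors the CLI; for example:

```python
from ocuprost import geometry, ssm, synth

scans = synth.gen_prosthesis_set(20, seed=1)
landmarks = [geometry.generate_correspondence(geometry.align_shape(s))
             for s in scans]
model = ssm.build_model(landmarks)          # 98% variance target
print(model.k, model.sigmas[:3])
```

Individual stages are exposed as `ocuprost synth | build-ssm |
make-conformers | extract-socket | fit-shape | evaluate | pipeline`.

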