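# gastro3d

Whole-stomach 3D reconstruction from monocular gastroendoscopy video.

Screening endoscopy images of the gastric mucosa are nearly texture-less, so
feature-based structure-from-motion (SfM) cannot hold the camera track and the
organ shape together. Spraying indigo-carmine (IC) dye fixes that — the dye
pools in the mucosal grooves and paints a dense high-contrast pattern — but it
costs procedure time. This package implements the alternative: learn an
*unpaired* image-to-image translation from no-dye frames to virtual
dye-sprayed (VIC) frames, run incremental SfM on the translated single-channel
images, mesh and texture the organ with the original no-dye colors, and refine
any region of interest with local multi-view stereo and photometric mesh
refinement. A synthetic endoscopy simulator with exact ground truth drives all
quantitative evaluation.

## The model in brief

**Translation.** Two generators G_A (no-dye → dye) and G_B (dye → no-dye) and
two discriminators D_A, D_B are trained on unpaired sets with the
cycle-consistent least-squares adversarial objective

    L = L_GAN(G_A, D_B) + L_GAN(G_B, D_A) + λ_cyc·L_cyc + λ_idt·L_idt

with `L_GAN = E[(D(b) − 1)²] + E[D(G(a))²]`, L1 cycle and identity terms, and
defaults λ_cyc = 10, λ_idt = 5. Three channel pairings are supported —
`rgb2rgb`, `r2r`, and `g2r` (no-dye **g**reen → dye **r**ed, the default,
pairing the most-textured channel of each domain). Because the endoscope
captures R, G, B sequentially, the color planes of one frame are mutually
misaligned; single-channel processing sidesteps the artifact, and the
simulator reproduces it as a per-channel pixel shift.

**Reconstruction.** SIFT keypoints on the VIC red planes, exhaustive pairwise
matching with ratio test and essential-matrix RANSAC verification, incremental
SfM (two-view initialization, PnP registration with a temporal smoothness
prior, sparse bundle adjustment with an analytic Jacobian), iterated
plane-RANSAC outlier removal, implicit-surface meshing (signed-distance field
+ marching cubes) and per-face best-view texturing from the no-dye RGB frames.

**Localization and refinement.** A selected frame is localized by retrieving
its estimated pose and projecting its image onto the faces it sees. The N
frames sharing the most tracks with it (default N = 22) feed a plane-sweep
multi-view stereo, and the resulting local mesh is polished by a photometric
consistency + displacement-smoothness objective.

## Worked example

```python
from gastro3d.cli_io import PipelineConfig, run_pipeline

cfg = PipelineConfig.from_dict({"seed": 0, "output_dir": "run0"})
result = run_pipeline(cfg)
print(result["stats"])
```

prints (exact numbers are deterministic for a given seed):

```
{'n_input_frames': 20, 'n_registered': 20, 'pct_registered': 100.0,
 'avg_observation': 6.59, 'mean_reprojection_px': 0.118, 'n_points': 690,
 'n_outliers_removed': 0, 'mesh_vertices': 14436, 'mesh_faces': 28312,
 'untextured_face_fraction': 0.006}
```

meaning: all 20 simulated frames were registered, each retained 3D point is
observed in 6.6 frames on average with a mean reprojection error of 0.12 px,
no spurious planar structure was found, and 99.4% of the final mesh faces
received a texture from some no-dye frame. The run directory contains
the rendered frames, ground truth (mesh, camera file, depth maps), the
`cameras/images/points3D` text triple, the cleaned cloud and the textured OBJ.

The same pipeline is scriptable from the shell:

```
gastro3d simulate -o frames --seed 0          # synthetic sequence + ground truth
gastro3d run -c config.yaml                    # full reconstruction
gastro3d localize --run-dir run0 --frame 9 --refine
```

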