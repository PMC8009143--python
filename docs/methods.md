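# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of the package. Nothing here states an
empirical number that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

A monocular endoscope sweeps once through the stomach, top to bottom,
carrying its own light source. The goal is a textured 3D model of the whole
organ, plus the ability to localize any frame on that model and to refine the
geometry around it. Plain (white-light) mucosa frames are nearly
texture-less; dye-sprayed frames are richly textured. Since paired
dye/no-dye images of the same wall cannot be captured, the texture
enhancement is learned from unpaired sets with a cycle-consistent
adversarial objective and applied as a virtual dye before reconstruction.

## The synthetic study

All quantitative claims are evaluated on a simulator
(`gastro3d.endosim`) that reproduces the data properties the method
depends on, with exact ground truth:

* **Surface.** A unit sphere radially displaced by a band-limited real
  spherical-harmonic field (degrees 1–4, coefficients damped as
  (1+l)^-1.5, normalized to a maximum relative displacement of 0.12).
  The surface is star-shaped about the origin, hence closed, genus 0 and
  self-intersection free for amplitudes below 0.3. An optional narrow
  ridge (amplitude 0.04 R, angular width 0.05 rad along a meridian)
  stands in for a rugal fold.
* **Appearance.** Albedo is built from Gaussian spots on the sphere.
  The dye texture uses 4000 spots of angular size σ = 0.012 rad with RMS
  channel contrasts R 0.32 > G 0.12 > B 0.08; the no-dye texture uses
  150 broad spots (σ = 0.08) plus a fine low-weight component (1500
  spots, σ = 0.018, 35% of the field's RMS — a vascular-pattern
  analogue), with contrasts G 0.07 > R 0.035 > B 0.015. These frozen
  values reproduce the qualitative channel ranking of real
  chromoendoscopy (dye red most textured; no-dye green the best of a
  poor lot) and, on rendered frames, give the virtual-dye channel several
  times the SIFT keypoints of the no-dye green channel.
* **Illumination.** A point light rides at the camera center with
  Lambertian shading and inverse-square falloff; images are rendered by
  exact ray casting (fixed-point iteration on the star-shaped radius
  function, converged to machine precision in 8 iterations).
* **Sequential-capture artifact.** Each color plane is rendered with its
  own principal-point shift (defaults R (0,0), G (+2,0), B (−2,0) px),
  which makes the planes of one frame rigid translates of each other —
  the duplicated-pattern artifact that motivates single-channel
  processing.
* **Trajectory.** 20 poses; the camera travels along the organ axis from
  z = +0.45 R to −0.45 R with a 0.12 R lateral offset, the optical axis
  pitching from 30° to 150° with a 60° azimuth drift — a one-pass sweep
  whose consecutive views overlap strongly. Images are 240×240 px with
  an 80° field of view.

What the simulator does **not** model: peristalsis or any deformation,
specular highlights, fluid, photometric noise, lens distortion, rolling
shutter. Passing tests therefore demonstrate the pipeline's geometric and
photometric machinery under clean conditions, not clinical robustness.

## Translation (`vic_translation`)

The four objective terms follow the standard least-squares CycleGAN
formulation; `total_loss` is affine in (λ_cyc, λ_idt) with slopes equal to
the cycle and identity terms, which the tests verify numerically against
hand-coded elementwise oracles. Training at desk scale uses a deliberately
tiny architecture (one hidden convolution of 16 features per generator, a
two-layer patch discriminator, Adam at 2e-4 with β₁ = 0.5, batch 4, random
64×64 crops) implemented in numpy with hand-written backpropagation; the
backward pass is verified against finite differences. Identity terms are
computed whenever the two domains have equal channel counts (true for all
three standard pairings) and skipped with a logged warning otherwise. The
logged per-epoch loss is the full four-term objective evaluated on the
complete training sets, so epoch-to-epoch comparisons are deterministic.

For GPU-free testing of everything downstream, `oracle_translator` maps a
frame index directly to the dye-domain red channel rendered at the same pose
— the output an ideal translator would produce.

## Features and SfM

SIFT detection and descriptors come from scikit-image with its standard
thresholds; matching is exhaustive nearest-neighbour with Lowe ratio 0.8 and
mutual cross-check; verification is essential-matrix RANSAC (normalized
8-point, Sampson gating at 1 px equivalent, adaptive iteration count,
seeded).

Incremental SfM: the initial pair maximizes inliers × median triangulation
angle; registration is PnP RANSAC (6-point DLT) *plus* a robust warm-start
refinement from the nearest registered temporal neighbour — the warm start
matters because a single frame's support points are nearly coplanar patches
of the organ wall, where pure DLT is ill-conditioned. A temporal smoothness
gate (≤ 12°/frame relative rotation) rejects the mirror solutions of planar
PnP. Triangulation is batched DLT with Gauss–Newton refinement; growth-time
acceptance requires a 1.5° parallax and 2.5 px reprojection. Bundle
adjustment (Huber at 2 px, analytic sparse Jacobian, gauge fixed by the
first camera and the first baseline's length) runs after every second
registration; failed frames are retried as the model grows. Three final
passes harden the model: a strict point filter (≥ 10° parallax, ≤ 1.5 px
residual, ≥ 3 observations), a pose audit (cameras inconsistent with the
surviving points are re-registered or honestly reported unregistered), and
a smoothness audit (cameras kinking the trajectory are dropped).

Monocular scale is unobservable; every quantitative comparison first aligns
the model to ground truth with a similarity (Umeyama) transform estimated
from track-point correspondences obtained by ray-casting each track's first
observation from its ground-truth pose.

`densify_points` re-triangulates all tracks at looser thresholds (≥ 8°,
≤ 1.5 px, ≥ 3 views) to supply the meshing stage with more support than the
strictly filtered metric point set.

## Surface stage

*Outlier removal* iterates RANSAC planes with localized sampling (a seed
point plus two of its 30 nearest neighbours — a compact planar cluster is
found as soon as one seed lands on it). A plane's support is removed only
when it falls outside the robust radial envelope of the cloud (median ±
4·MAD of radii about the cloud centroid), so wall structure is never
removed; iteration is capped at 5 rounds and is idempotent.

*Meshing* evaluates a signed-distance field on a regular grid (cell =
extent/2^depth, capped at 144 nodes per axis; inverse-distance-weighted
distance to the tangent planes of the 8 nearest oriented points), smooths it
by one grid cell, and polygonizes with marching cubes. Vertices further from
the cloud than 2.5 median point spacings are trimmed, the dominant connected
component is kept, and two boundary rings are eroded (the outermost strips
of an open scan are only half-supported). On a fully sampled closed surface
nothing is trimmed and the output is watertight.

*Texturing* scores candidate views per face by cos(viewing angle)/depth² and
requires all three projected vertices inside the image and the face visible
in a software z-buffer (rasterized per view; faces smaller than a pixel pass
a centroid depth test instead). Faces no view passes are counted untextured.

## Localization and refinement

Localization is retrieval: the stored pose, plus the frame's projection onto
the faces it sees. Connected frames are ranked by shared-track count with
temporal proximity as tie-break (N = 22 by default).

Local MVS is a plane-sweep over 64 inverse-depth hypotheses between the 5th
and 95th depth percentiles of the reference frame's own track points
(±10%/15% margins), NCC over 7×7 windows against the 4 nearest source
views, winner-take-all with parabolic sub-hypothesis refinement, and fusion
requiring agreement of 3 other views within 1% relative depth. The images
are high-pass filtered (σ = 8 px) first: the camera-carried light paints a
smooth, depth-insensitive gradient that otherwise dominates the weak
mucosal texture. Window variance floors keep flat regions out, so
texture-less input degrades to empty depth maps rather than wrong ones.

Photometric refinement moves mesh vertices along their normals.
Per-vertex cost = median over view pairs of (1 − NCC) of a rigid 5×5
tangent patch (half-extent 0.04 scene units) sampled in high-passed
images, with patches near image borders excluded; the regularizer is the
umbrella Laplacian of the *displacement field*, so an initial mesh that
already coincides with the data is an exact fixed point. Movement is
gated by the graph-diffused photometric gradient (6 averaging rounds;
threshold 5e-4, set above the measured gradient noise of flat regions):
a smooth deformation signals coherently across a region and survives the
averaging, while per-vertex artifacts cancel. Steps (initial 0.003 scene
units) are accepted only if the global objective decreases, halving
otherwise, so the objective is non-increasing.

The composite `local_pipeline` crops the fused cloud to the reference
frame's field of view, meshes it two octree levels finer than the global
mesh, refines with the 8 closest views, and textures with the no-dye
frames; the result lives in the global model's coordinate frame.

## Numerical and evaluation choices

* Pixels are 0-based with centers at integer coordinates; poses are
  world-to-camera (`x_cam = R x + t`), right-handed, camera looking down +z.
* Mesh-to-ground-truth distances are **one-sided** (mesh → surface): the
  one-pass trajectory covers an azimuthal band, so completeness over unseen
  azimuths is not claimed. The whole-organ mesh's median and 95th-percentile
  distances sit near 0.5% and 2% of the base radius under the default study;
  the maximum is dominated by the polar caps, which only the trajectory's end
  frames see at grazing parallax, and can exceed the 3% level the end-to-end
  mesh test demands — that test documents the limitation when it trips.
* Ridge recovery is evaluated as the correlation between ground-truth and
  reconstructed radial height along cross-sections of the fold taken where
  the reference frame's optical axis meets the surface (±0.04 rad), measured
  with vertex-window medians (rtree-free environments have no mesh ray
  casting).
* Stochastic assertions follow a median-over-seeds pattern; all RANSAC
  stages take explicit seeds and are bit-reproducible.

## Known limitations

* No loop closure: a one-pass sweep accumulates drift that bundle adjustment
  can only partly remove; end-of-sequence cameras are the least constrained
  and occasionally fail the audits (they are then reported unregistered).
* The refinement's photometric signal vanishes below roughly half a percent
  of the organ radius with the default mucosal texture; finer geometry is
  not recoverable from these images.
* The trained translator is desk-scale (tiny nets, tens of images, 2
  epochs): it demonstrates the objective decreasing and the interfaces, not
  translation quality; the oracle translator carries the end-to-end
  geometric evaluation.
* Intrinsics are assumed known and shared; radial distortion is supported in
  projection but the simulator renders distortion-free images.
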