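# Methods

## Model

voxray renders 3-D scalar fields with the emission–absorption optical
model: every sample along a per-pixel viewing ray emits light in
proportion to its transfer-function color and opacity and is
attenuated by the accumulated opacity in front of it. Integration is
a fixed-step front-to-back march; compositing uses the *under*
operator on a premultiplied RGBA accumulator,

    A ← A + (1 − A)·α_s,    C ← C + (1 − A)·α_s·c_s,

which is associative and keeps pixel alpha non-decreasing. The final
ray color is over-blended onto a configurable background.

All sampling happens in normalized volume coordinates: the shared
bounding box maps to the unit cube, grid node *i* of an axis with *n*
nodes sits at *i/(n−1)*, and scalar values are globally min–max
normalized by the volume's `scalar_range` before transfer-function
lookup (no window/level stage). Positions outside the unit cube
sample as 0; inside, interpolation is trilinear with clamp-to-edge
addressing. Transfer functions are piecewise-linear in color and
opacity independently, clamped outside their first/last control
points.

### Programmable stages

The integration loop exposes three caller-pluggable stages with an
enforced mutation contract (violations raise an error naming the
stage):

| stage | runs | may mutate |
|---|---|---|
| Init | once per render | ray endpoints/direction, starting distance, initial pixel, user state |
| Volume | per volume per step | the step's `sampleRGBA`, user state |
| StopCondition | per step | nothing (returns a per-ray boolean) |

Volume stages chain in scene order and each sees the sample
accumulated by its predecessors at the same position, which is what
makes two-volume effects (decluttering, flow modulation) one-line
shaders. The loop condition is
`currentDistance < |rayEnd − rayStart|`, so an Init stage that pushes
`currentDistance` forward (carving) simply skips samples. `user_state`
is an open per-ray key→array store so presets can keep working
variables (the peeling layer counter and accumulator) without
engine-side schema.

The engine marches all live rays in lockstep with numpy; stages
receive arrays over the currently live rays and the same preset code
drives one ray or a full image. A deliberately naive per-pixel,
per-sample scalar-loop renderer (`voxray.reference`) re-derives
default-mode rendering from first principles — its own pinhole
construction, slab intersection, trilinear interpolation, transfer
function lookup and compositing — and serves as an independent oracle;
the two agree to ~4e-16 per channel on the test scenes.

### Ray setup

Rays are generated analytically: a pinhole camera (vertical field of
view, square pixels, pixel centers at half-integer coordinates, row 0
at the top) and a slab-method ray/box intersection give each pixel's
entry/exit points, clipped against the near/far planes so a camera
inside the volume still yields well-formed rays. Grazing or
degenerate intersections count as misses; missed rays take the
background color. An optional per-pixel depth image (camera-space
distance along the ray, 0 = no geometry) further clips integration so
no sample lands beyond externally rendered opaque geometry.

### Gradients and lighting

`compute_gradient` returns the *un-divided* central difference
`g_i = S(p − h·e_i) − S(p + h·e_i)` (no division by 2h): edge
enhancement's thresholds (step interval (0.02, 0.06)) are calibrated
against raw intensity differences, and the Blinn-Phong normal only
needs the direction. The sign makes the direction point out of bright
structures so lighting reads correctly for bright-on-dark anatomy;
edge enhancement uses only |ĝ·r̂| and is sign-invariant. Gradients
with magnitude below 1e-12 collapse to a zero direction, and the
Blinn-Phong preset then degrades to its ambient term. The light
defaults to a headlight (co-located with the camera); a fixed
direction is configurable.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `step` | 1/(2·max grid dim) | normalized length | two samples per voxel of the finest axis |
| `ert_threshold` | disabled | alpha | 0.99 bounds truncation error by 0.01 per premultiplied channel |
| `opacity_reference_step` | disabled | normalized length | see numerical choices |
| carving `sphere_radius` | 0.15 | normalized length | a few voxel diameters at typical grids |
| peeling `t_high`, `t_low` | 0.9, 0.05 | alpha | a layer ends only after becoming nearly opaque and hitting a near-transparent sample |
| edge `sample_threshold`, `grad_step`, `(step_min, step_max)` | 0.1, 0.0005, (0.02, 0.06) | alpha, length, intensity diff | stock silhouette calibration for raw-difference gradients |
| flow `spatial_frequency`, `temporal_frequency`, baseline, amplitude | 1000, 5, 0.75, 0.25 | rad per unit sample, rad/s | modulation stays in [0.5, 1.0]; frame period 2π/5 s |

## Numerical choices

* **Opacity correction is opt-in.** By default a Volume stage's alpha
  is composited exactly once per step, whatever the step size — the
  verbatim per-sample semantics under which a homogeneous medium
  accumulates exactly 1 − (1 − α)ⁿ over n steps. Under these
  semantics the rendered image is *not* step-size invariant (optically
  thin pixels scale with sample count), so for step-refinement studies
  `opacity_reference_step` rescales each alpha to
  1 − (1 − α)^(step/reference); the image then converges first-order
  in the step, and halving the step twice contracts the maximum pixel
  change by ~0.3× per halving on the smooth test phantom.
* Samples emitted outside [0, 1] are clamped before compositing, with
  a once-per-render warning.
* Ties and grazing ray/box contacts are treated as misses;
  entry/exit points are clamped into the unit cube against rounding.
* The final image is premultiplied RGBA; PNG output un-premultiplies
  and quantizes to 8 bits rounding half up.

## Phantoms

The generator emulates the data classes the effects were designed
around, on the unit cube with values in [0, 1] (so raw and normalized
intensities coincide) and bit-exact reproducibility from a JSON
serializable spec and seed:

* **sphere** — solid ball with an optional linear transition band
  (carving and smooth-gradient tests);
* **shells** — concentric spheres of distinct values; the default
  (core 0.9, gap 0.0, shell 0.5) pairs with a transfer function whose
  opacity lives in two disjoint bands, making opacity peeling's layer
  boundaries exact;
* **tube_tree** — a tube around a polyline plus a companion volume
  holding within-tube arclength, pre-scaled (default 5·2π/1000) so
  the flow shader's 1000 rad spatial frequency lays five visible
  wavelengths along the vessel;
* **ramp** — clamp(p·d, 0, 1), whose interior un-divided gradient is
  exactly −2h·d, the analytic fixture for edge enhancement;
* optional additive Gaussian noise, clamped to the scalar range,
  deterministic per seed.

What phantoms do *not* model: scanner physics (partial volume,
bias fields, Rician noise), anatomical vasculature, or real
hemodynamics — the flow volume is a geometric arclength, not a
simulation. Tests passing on phantoms validate the renderer's
mathematics, not clinical image quality.

Default problem sizes in the test suite and acceptance script — 48³
to 64³ grids, 64×64 images, 10⁴ random rays per geometric oracle —
are chosen so the full verification cycle completes in seconds while
every property under test (interpolation error, compositing closed
forms, oracle equivalences) is already at its asymptotic behavior at
these sizes.

## Design choices on open points

* The per-step scratch accumulator goes by `sampleRGBA` throughout
  (the same quantity is sometimes called a "full sample" in
  multi-volume contexts).
* Multi-volume scenes must share one bounding box; grids may differ
  in resolution since sampling is in normalized coordinates.
* The finished ray is over-blended onto the background rather than
  returned raw; with a transparent background the premultiplied
  accumulator passes through unchanged.
* Opacity peeling's discarded pre-peel samples do not feed early ray
  termination: the stop condition only sees `pixelRGBA`, which
  pre-peel samples never touch.
* The pseudo-chroma-depth preset maps near → red, far → blue;
  aerial perspective fades white → background color with distance.
  Both are just depth transfer functions over the same shader and can
  be overridden.
* Effect presets are referenced by registry name in configuration
  files; arbitrary code is never executed from configuration — custom
  stages are a library-level API only.

## Limitations

* Single-pass ray casting: no access to neighboring rays, hence no
  shadows, ambient occlusion or halos.
* No multi-dimensional transfer functions and no pre-integrated
  lookup tables.
* Nearest-neighbor header support only for NRRD (attached raw/ASCII
  data, diagonal space directions); NIfTI affines are reduced to
  their diagonal spacing + translation.
* CPU throughput is adequate for the tested scene sizes (tens of
  milliseconds to seconds), not for interactive clinical use.
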