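"""Rendering-effect presets built on the shader-stage contract.

Each factory returns an :class:`~voxray.shading.Effect` whose stages are
vectorized over rays (arrays with a leading ray axis), so the same
preset drives a single ray or a full image.  The registry maps the
names accepted in render configurations:

``default``
    Plain emission-absorption compositing of the transfer-function
    sample.
``carving``
    Init stage that pushes each ray's start past a sphere centered on
    the interaction point, cutting an interactively movable cavity out
    of the volume.
``opacity_peeling``
    Discards the first ``wanted_layer`` opacity layers along each ray:
    opacity accumulates in a working variable until it exceeds
    ``t_high``; when the next sample's alpha then drops below ``t_low``
    a layer boundary is declared and the count advances.  Samples
    contribute only after the requested number of layers has passed.
``declutter``
    For a companion mask volume: multiplies the accumulated per-step
    sample of the preceding volumes by the mask's color-mapped sample
    (color-mapped, not raw, so the mask's transfer function steers the
    amount of decluttering interactively).
``chroma_depth`` / ``pseudo_chroma_depth`` / ``aerial_perspective``
    Color encodes camera distance (normalized by the camera-to-volume
    distance range) while alpha still comes from the volume's intensity.
    The three variants differ only in the depth color map.
``edge_enhance``
    Keeps only samples whose intensity gradient is strong and roughly
    perpendicular to the ray (silhouettes):
    ``alpha = smoothstep(step_min, step_max, |g| * (1 - |g_hat . r|))``.
``blinn_phong``
    Gradient-lit compositing; the base shader under edge enhancement,
    decluttering and blood flow.
``blood_flow``
    For a companion within-vessel arclength volume: modulates the
    already-accumulated color by a traveling sine of the raw distance
    sample, animating flow as ``time`` advances.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .shading import Effect, ShaderContext, blinn_phong, smoothstep
from .volume import TransferFunction, sample_tf

__all__ = [
    "default_shader",
    "carving",
    "opacity_peeling",
    "declutter",
    "chroma_depth",
    "pseudo_chroma_depth",
    "aerial_perspective",
    "edge_enhance",
    "blinn_phong_shader",
    "blood_flow",
    "REGISTRY",
    "make_effect",
    "effect_names",
]


def default_shader() -> Effect:
    """Transfer-function compositing, the default Volume stage."""

    def volume(ctx: ShaderContext) -> None:
        acc = ctx.volumes[ctx.volumeIndex]
        ctx.state.sampleRGBA += acc.sample_with_tf(ctx.state.pos)

    return Effect(volume=volume, name="default")


def carving(sphere_radius: float = 0.15) -> Effect:
    """Init stage that skips the ray segment inside a carving sphere.

    The sphere is centered at the interaction point.  For each ray the
    closest-approach distance ``d`` to the center is found by projecting
    the center onto the ray; when ``d < r`` and the far intersection
    ``t_proj + sqrt(r^2 - d^2)`` lies ahead of the ray origin,
    ``currentDistance`` jumps to that far intersection so integration
    resumes behind the sphere.
    """
    if not sphere_radius > 0:
        raise ValueError(f"sphere_radius must be positive, got {sphere_radius}")

    def init(ctx: ShaderContext) -> None:
        start, d = ctx.ray.start, ctx.ray.dir
        center = ctx.interactionPoint1
        center_dir = center - start
        t_proj = np.sum(center_dir * d, axis=-1)
        closest = start + t_proj[..., None] * d
        miss_dist = np.linalg.norm(closest - center, axis=-1)
        hits = miss_dist < sphere_radius
        half_chord = np.sqrt(np.maximum(sphere_radius**2 - miss_dist**2, 0.0))
        t_exit = t_proj + half_chord
        apply = hits & (t_exit > 0.0)
        cd = ctx.state.currentDistance
        cd[...] = np.where(apply, t_exit, cd)

    return Effect(init=init, name="carving")


def opacity_peeling(wanted_layer: int = 1, t_high: float = 0.9,
                    t_low: float = 0.05) -> Effect:
    """Peel away the first ``wanted_layer`` opacity layers of each ray."""
    if wanted_layer < 0:
        raise ValueError(f"wanted_layer must be >= 0, got {wanted_layer}")
    if not 0.0 <= t_low < t_high:
        raise ValueError(
            f"need 0 <= t_low < t_high, got t_low={t_low}, t_high={t_high}"
        )

    def init(ctx: ShaderContext) -> None:
        n = ctx.n_rays
        ctx.state.user_state["currentLayer"] = np.zeros(n, dtype=np.int64)
        ctx.state.user_state["layerAlpha"] = np.zeros(n)

    def volume(ctx: ShaderContext) -> None:
        acc = ctx.volumes[ctx.volumeIndex]
        s = acc.sample_with_tf(ctx.state.pos)
        layer = ctx.state.user_state["currentLayer"]
        layer_alpha = ctx.state.user_state["layerAlpha"]
        peeling = layer < wanted_layer
        a = s[..., 3]
        grown = layer_alpha + (1.0 - layer_alpha) * a
        layer_alpha[peeling] = grown[peeling]
        peel = peeling & (layer_alpha > t_high) & (a < t_low)
        layer[peel] += 1
        layer_alpha[peel] = 0.0
        done = ~peeling
        ctx.state.sampleRGBA[done] += s[done]

    return Effect(init=init, volume=volume, name="opacity_peeling")


def declutter() -> Effect:
    """Mask-volume Volume stage: gate the chain's accumulated sample.

    Must run after a base shader in the volume chain; multiplies the
    accumulated ``sampleRGBA`` componentwise by this volume's
    color-mapped sample.
    """

    def volume(ctx: ShaderContext) -> None:
        acc = ctx.volumes[ctx.volumeIndex]
        ctx.state.sampleRGBA *= acc.sample_with_tf(ctx.state.pos)

    return Effect(volume=volume, name="declutter")


def chroma_depth(depth_tf: TransferFunction | None = None) -> Effect:
    """Depth-cue shading: hue from camera distance, alpha from intensity.

    The sample's color is the transfer function evaluated at the
    camera distance normalized by the camera-to-volume (min, max)
    distance range; its alpha is the ordinary intensity-driven opacity,
    so intensity-transparent regions stay invisible whatever their
    depth.  ``depth_tf`` overrides the color source (the volume's own
    transfer function by default); swapping the color map alone turns
    the same stage into pseudo chroma-depth or aerial perspective.
    """

    def volume(ctx: ShaderContext) -> None:
        acc = ctx.volumes[ctx.volumeIndex]
        alpha_sample = acc.sample_with_tf(ctx.state.pos)
        dist = np.linalg.norm(ctx.state.pos - ctx.cameraPosition, axis=-1)
        dmin, dmax = ctx.volumeDistanceRange
        ndist = (dist - dmin) / (dmax - dmin)
        tf = depth_tf if depth_tf is not None else acc.tf
        s = sample_tf(tf, ndist)
        s[..., 3] = alpha_sample[..., 3]
        ctx.state.sampleRGBA += s

    return Effect(volume=volume, name="chroma_depth")


def pseudo_chroma_depth() -> Effect:
    """Two-color chroma-depth: red for near, blue for far structures."""
    tf = TransferFunction([[0.0, 1, 0, 0], [1.0, 0, 0, 1]], [[0.0, 1.0]])
    eff = chroma_depth(depth_tf=tf)
    eff.name = "pseudo_chroma_depth"
    return eff


def aerial_perspective(background: Sequence[float] = (0.0, 0.0, 0.0)) -> Effect:
    """Aerial perspective: distant content fades toward the background."""
    r, g, b = background
    tf = TransferFunction([[0.0, 1, 1, 1], [1.0, r, g, b]], [[0.0, 1.0]])
    eff = chroma_depth(depth_tf=tf)
    eff.name = "aerial_perspective"
    return eff


def edge_enhance(sample_threshold: float = 0.1, grad_step: float = 0.0005,
                 step_min: float = 0.02, step_max: float = 0.06,
                 edge_color: Sequence[float] = (1.0, 0.0, 0.0)) -> Effect:
    """Silhouette rendering from the view-perpendicular gradient.

    A sample contributes only when its transfer-function alpha exceeds
    ``sample_threshold`` and its (un-divided central difference)
    gradient is non-zero; the emitted alpha is
    ``smoothstep(step_min, step_max, |g| * (1 - |g_hat . rayDir|))``
    with the constant ``edge_color``.  Because only ``|g_hat . r|``
    enters, the result is invariant to flipping the gradient sign.
    """
    if not step_min < step_max:
        raise ValueError(f"need step_min < step_max, got ({step_min}, {step_max})")
    edge_color = np.clip(np.asarray(edge_color, dtype=np.float64), 0, 1)

    def volume(ctx: ShaderContext) -> None:
        acc = ctx.volumes[ctx.volumeIndex]
        s = acc.sample_with_tf(ctx.state.pos)
        g = acc.gradient(ctx.state.pos, grad_step)
        keep = (s[..., 3] > sample_threshold) & (g.magnitude > 0.0)
        if not np.any(keep):
            return
        factor = g.magnitude * (
            1.0 - np.abs(np.sum(ctx.ray.dir * g.direction, axis=-1))
        )
        alpha = smoothstep(step_min, step_max, factor)
        out = np.zeros(s.shape)
        out[..., :3] = edge_color
        out[..., 3] = alpha
        ctx.state.sampleRGBA[keep] += out[keep]

    return Effect(volume=volume, name="edge_enhance")


def blinn_phong_shader(light_dir: Sequence[float] | None = None,
                       k_ambient: float = 0.3, k_diffuse: float = 0.7,
                       k_specular: float = 0.2, shininess: float = 32.0,
                       grad_step: float = 0.0005) -> Effect:
    """Gradient-lit transfer-function compositing.

    The surface normal is the normalized finite-difference gradient
    (pointing out of bright structures).  ``light_dir`` is a fixed
    direction *toward* the light in normalized volume space; when
    omitted, the light rides with the camera (headlight).  Zero-gradient
    regions fall back to the ambient-weighted sample.
    """

    def volume(ctx: ShaderContext) -> None:
        acc = ctx.volumes[ctx.volumeIndex]
        s = acc.sample_with_tf(ctx.state.pos)
        g = acc.gradient(ctx.state.pos, grad_step)
        view = ctx.cameraPosition - ctx.state.pos
        view = view / np.maximum(np.linalg.norm(view, axis=-1, keepdims=True),
                                 1e-300)
        l = view if light_dir is None else np.asarray(light_dir, dtype=np.float64)
        shaded = blinn_phong(g.direction, l, view, s, k_ambient=k_ambient,
                             k_diffuse=k_diffuse, k_specular=k_specular,
                             shininess=shininess)
        ctx.state.sampleRGBA += shaded

    return Effect(volume=volume, name="blinn_phong")


def blood_flow(spatial_frequency: float = 1000.0, temporal_frequency: float = 5.0,
               baseline: float = 0.75, amplitude: float = 0.25) -> Effect:
    """Traveling-wave color modulation for a flow-distance volume.

    Must run after a base shader.  The *raw* sample of this volume (the
    within-vessel arclength) phases a sine,
    ``baseline + amplitude * sin(spatial_frequency * s + temporal_frequency * t)``,
    which multiplies the accumulated RGB (alpha untouched).  With the
    defaults the factor stays in ``[0.5, 1.0]`` and a frame period of
    ``2 pi / temporal_frequency`` seconds.
    """
    if not (spatial_frequency > 0 and temporal_frequency > 0):
        raise ValueError("frequencies must be positive")

    def volume(ctx: ShaderContext) -> None:
        acc = ctx.volumes[ctx.volumeIndex]
        raw = acc.sample(ctx.state.pos)
        sine = baseline + amplitude * np.sin(
            spatial_frequency * raw + ctx.time * temporal_frequency
        )
        ctx.state.sampleRGBA[..., :3] *= sine[..., None]

    return Effect(volume=volume, name="blood_flow")


REGISTRY: dict[str, Callable[..., Effect]] = {
    "default": default_shader,
    "carving": carving,
    "opacity_peeling": opacity_peeling,
    "declutter": declutter,
    "chroma_depth": chroma_depth,
    "pseudo_chroma_depth": pseudo_chroma_depth,
    "aerial_perspective": aerial_perspective,
    "edge_enhance": edge_enhance,
    "blinn_phong": blinn_phong_shader,
    "blood_flow": blood_flow,
}


def effect_names() -> list[str]:
    return sorted(REGISTRY)


def make_effect(name: str, params: dict | None = None) -> Effect:
    """Instantiate a registered effect by name with keyword ``params``."""
    try:
        factory = REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown effect '{name}'; available: {', '.join(effect_names())}"
        ) from None
    try:
        return factory(**(params or {}))
    except TypeError as e:
        raise ValueError(f"bad parameters for effect '{name}': {e}") from e
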