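"""Shader-stage contract and the math built-ins shared by effect presets.

Ray integration exposes three pluggable stages:

* **Init** — runs once per render before the loop.  May mutate the ray
  endpoints/direction, the initial ``currentDistance``, ``pixelRGBA``
  and the open ``user_state`` store.
* **Volume** — runs once per volume per integration step.  May mutate
  only the per-step ``sampleRGBA`` accumulator and ``user_state``;
  shaders for later volumes in the chain observe the ``sampleRGBA``
  written by earlier ones.
* **StopCondition** — runs once per step, mutates nothing, and returns
  a boolean (per-ray) that terminates integration early.

Stages receive a :class:`ShaderContext`.  The engine is vectorized: all
array fields carry a leading ray axis, so a stage written with numpy
broadcasting serves one ray or a whole image identically.  Fields a
stage is not contracted to mutate are handed over as read-only arrays;
writing to them raises, and the engine re-raises a
:class:`ShaderStageError` naming the offending stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .volume import (
    GradientSample,
    ScalarVolume,
    TransferFunction,
    compute_gradient,
    sample_tf,
    sample_volume,
    sample_volume_with_tf,
)

__all__ = [
    "ShaderContext",
    "ShaderStageError",
    "VolumeAccessor",
    "RayView",
    "IntegrationState",
    "smoothstep",
    "blinn_phong",
]


class ShaderStageError(RuntimeError):
    """A shader stage raised or violated its mutation contract."""


class VolumeAccessor:
    """Per-volume sampling facade handed to shaders via ``ctx.volumes``."""

    def __init__(self, volume: ScalarVolume, tf: TransferFunction):
        self.volume = volume
        self.tf = tf

    def sample(self, pos: np.ndarray) -> np.ndarray:
        """Raw (range-normalized) intensity at ``pos``."""
        return sample_volume(self.volume, pos)

    def sample_tf(self, s: np.ndarray) -> np.ndarray:
        """Transfer function lookup at normalized scalar ``s``."""
        return sample_tf(self.tf, s)

    def sample_with_tf(self, pos: np.ndarray) -> np.ndarray:
        """Color-mapped sample: ``sample_tf(sample(pos))``."""
        return sample_volume_with_tf(self.volume, self.tf, pos)

    def gradient(self, pos: np.ndarray, grad_step: float) -> GradientSample:
        return compute_gradient(self.volume, pos, grad_step)


@dataclass
class RayView:
    """Ray fields exposed to a shader stage (arrays over rays)."""

    start: np.ndarray  # (n, 3) normalized entry points
    end: np.ndarray    # (n, 3) normalized exit points
    dir: np.ndarray    # (n, 3) unit directions in normalized space


@dataclass
class IntegrationState:
    """Mutable per-ray integration state visible to shader stages."""

    pos: np.ndarray              # (n, 3) current sample positions
    currentDistance: np.ndarray  # (n,) arclength from rayStart
    pixelRGBA: np.ndarray        # (n, 4) premultiplied accumulator
    sampleRGBA: np.ndarray       # (n, 4) per-step scratch (non-premultiplied)
    user_state: dict = field(default_factory=dict)


@dataclass
class ShaderContext:
    """Everything a shader stage can see.

    ``cameraPosition``, ``interactionPoint1`` and the ray fields are in
    normalized volume coordinates; ``volumeDistanceRange`` is the
    (min, max) camera-to-volume distance in the same units; ``time`` is
    the animation clock in seconds.  ``volumeIndex`` identifies which
    volume's Volume stage is currently running.
    """

    ray: RayView
    state: IntegrationState
    cameraPosition: np.ndarray
    volumeDistanceRange: tuple[float, float]
    time: float
    interactionPoint1: np.ndarray
    volumes: list[VolumeAccessor]
    volumeIndex: int = 0
    n_rays: int = 0


@dataclass
class Effect:
    """A bundle of optional shader stages forming one rendering effect.

    ``volume`` runs as the Volume stage of the node it is attached to;
    ``init`` and ``stop`` (if present) are hoisted to the render's Init
    and StopCondition slots.
    """

    volume: Callable[[ShaderContext], None] | None = None
    init: Callable[[ShaderContext], None] | None = None
    stop: Callable[[ShaderContext], np.ndarray] | None = None
    name: str = "anonymous"


def smoothstep(e0: float, e1: float, x: np.ndarray) -> np.ndarray:
    """Hermite smoothstep: 0 below ``e0``, 1 above ``e1``, C1 in between.

    Matches the GLSL definition ``t^2 (3 - 2 t)`` with
    ``t = clamp((x - e0) / (e1 - e0), 0, 1)``.
    """
    if not e0 < e1:
        raise ValueError(f"smoothstep needs e0 < e1, got ({e0}, {e1})")
    t = np.clip((np.asarray(x, dtype=np.float64) - e0) / (e1 - e0), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _normalize_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.where(n > 0, v / np.where(n > 0, n, 1.0), 0.0)


def blinn_phong(
    normal: np.ndarray,
    light_dir: np.ndarray,
    view_dir: np.ndarray,
    base: np.ndarray,
    k_ambient: float = 0.3,
    k_diffuse: float = 0.7,
    k_specular: float = 0.2,
    shininess: float = 32.0,
) -> np.ndarray:
    """Blinn-Phong shading of a non-premultiplied RGBA ``base`` sample.

    ``color = base.rgb * (k_a + k_d * max(0, n.l)) + k_s * max(0, n.h)^p``
    with ``h`` the normalized half vector between light and view
    directions.  Alpha passes through untouched.  A zero normal
    (homogeneous region) degrades gracefully to the ambient term.
    """
    normal = np.asarray(normal, dtype=np.float64)
    base = np.asarray(base, dtype=np.float64)
    l = _normalize_rows(np.broadcast_to(np.asarray(light_dir, dtype=np.float64),
                                        normal.shape).copy())
    v = _normalize_rows(np.broadcast_to(np.asarray(view_dir, dtype=np.float64),
                                        normal.shape).copy())
    h = _normalize_rows(l + v)
    nl = np.maximum(0.0, np.sum(normal * l, axis=-1))
    nh = np.maximum(0.0, np.sum(normal * h, axis=-1))
    out = base.copy()
    out[..., :3] = base[..., :3] * (k_ambient + k_diffuse * nl)[..., None]
    out[..., :3] += (k_specular * nh**shininess)[..., None]
    return out
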