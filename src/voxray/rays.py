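"""Camera, ray setup and the programmable ray-integration loop.

Per-pixel rays are produced analytically: a pinhole camera model and a
slab-method ray/box intersection yield, for every pixel, the entry and
exit point of the ray with the shared volume bounding box, clipped to
the camera's near/far planes (so a camera inside the volume still gets
well-formed rays) and optionally to an externally supplied depth image.
Entry/exit points are then converted to normalized volume coordinates
where all sampling happens.

Integration follows the emission-absorption model: starting at the
entry point, the loop repeatedly zeroes a per-step ``sampleRGBA``
scratch, chains the Volume stage of every volume in scene order (later
volumes see the accumulated scratch of earlier ones), clamps and
composites the result into the premultiplied ``pixelRGBA`` accumulator
with the front-to-back *under* operator

    a' = a + (1 - a) * sa
    c' = c + (1 - a) * sa * sc

advances by a fixed arclength ``step``, and evaluates the stop
condition (early ray termination at an alpha threshold, plus any
user-supplied StopCondition stage).  The loop runs while
``currentDistance < |rayEnd - rayStart|``; an Init stage that pushes
``currentDistance`` forward therefore skips samples.  The engine steps
all live rays in lockstep with numpy, which is what makes CPU rendering
tractable; a deliberately naive per-pixel reference lives in
:mod:`voxray.reference`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .shading import (
    Effect,
    IntegrationState,
    RayView,
    ShaderContext,
    ShaderStageError,
    VolumeAccessor,
)
from .volume import ScalarVolume, TransferFunction

log = logging.getLogger(__name__)

__all__ = [
    "Camera",
    "Ray",
    "RayBundle",
    "RenderSettings",
    "VolumeNode",
    "Scene",
    "RenderedImage",
    "intersect_ray_box",
    "generate_rays",
    "adjust_ray_with_depth",
    "composite",
    "volume_distance_range",
    "integrate_ray",
    "render",
]

_EPS = 1e-12


@dataclass
class Camera:
    """Perspective pinhole camera in world coordinates.

    ``vfov`` is the full vertical field of view in degrees; ``width`` /
    ``height`` the image size in pixels; ``near`` / ``far`` the clip
    plane distances along the view axis.
    """

    position: Sequence[float]
    target: Sequence[float]
    up: Sequence[float] = (0.0, 1.0, 0.0)
    vfov: float = 30.0
    width: int = 64
    height: int = 64
    near: float = 0.01
    far: float = 100.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64)
        self.up = np.asarray(self.up, dtype=np.float64)
        fwd = self.target - self.position
        if np.linalg.norm(fwd) < _EPS:
            raise ValueError("camera position and target coincide")
        if np.linalg.norm(np.cross(fwd, self.up)) < _EPS:
            raise ValueError("camera up vector is parallel to the view direction")
        if not 0.0 < self.vfov < 180.0:
            raise ValueError(f"vfov must be in (0, 180) degrees, got {self.vfov}")
        if not 0.0 < self.near < self.far:
            raise ValueError(f"need 0 < near < far, got ({self.near}, {self.far})")
        if self.width < 1 or self.height < 1:
            raise ValueError("image must be at least 1x1 pixels")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Right-handed (forward, right, up) orthonormal view basis."""
        fwd = self.target - self.position
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, self.up)
        right = right / np.linalg.norm(right)
        up = np.cross(right, fwd)
        return fwd, right, up


@dataclass
class Ray:
    """A single ray in normalized volume space."""

    start: np.ndarray
    end: np.ndarray
    dir: np.ndarray
    active: bool = True

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.float64)
        self.end = np.asarray(self.end, dtype=np.float64)
        self.dir = np.asarray(self.dir, dtype=np.float64)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class RayBundle:
    """One ray per pixel, flattened row-major (row 0 = top of image)."""

    start: np.ndarray   # (N, 3)
    end: np.ndarray     # (N, 3)
    dir: np.ndarray     # (N, 3)
    active: np.ndarray  # (N,) bool
    width: int
    height: int

    def pixel_of(self, index: int) -> tuple[int, int]:
        return index // self.width, index % self.width


@dataclass
class RenderSettings:
    """Integration parameters.

    ``step`` is the arclength between samples in normalized units
    (default: half the smallest normalized voxel edge of the scene,
    i.e. ``1 / (2 * max grid dimension)``).  ``ert_threshold`` enables
    early ray termination once the accumulated alpha reaches it
    (``None`` disables).  ``background`` is non-premultiplied RGBA that
    the finished ray color is over-blended onto.  ``time`` drives
    animated shaders; ``interaction_point`` is the user-steered 3-D
    point (normalized coordinates) that effects like carving consume.

    ``opacity_reference_step`` enables opacity correction: each
    composited alpha ``a`` becomes ``1 - (1 - a)^(step / reference)``,
    so the transfer function's opacities are calibrated at the
    reference step and the rendered image converges (first order) as
    ``step`` is refined.  The default ``None`` keeps raw per-sample
    semantics: the shader's alpha is composited exactly once per step,
    whatever the step size.
    """

    step: float | None = None
    ert_threshold: float | None = None
    background: Sequence[float] = (0.0, 0.0, 0.0, 1.0)
    time: float = 0.0
    interaction_point: Sequence[float] = (0.5, 0.5, 0.5)
    opacity_reference_step: float | None = None

    def __post_init__(self) -> None:
        if self.step is not None and not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.opacity_reference_step is not None \
                and not self.opacity_reference_step > 0:
            raise ValueError("opacity_reference_step must be positive or None")
        if self.ert_threshold is not None and not 0.0 < self.ert_threshold <= 1.0:
            raise ValueError(
                f"ert_threshold must be in (0, 1] or None, got {self.ert_threshold}"
            )
        self.background = np.clip(np.asarray(self.background, dtype=np.float64), 0, 1)
        self.interaction_point = np.asarray(self.interaction_point, dtype=np.float64)


@dataclass
class VolumeNode:
    """One volume in a scene: data, transfer function, Volume effect."""

    volume: ScalarVolume
    tf: TransferFunction
    effect: Effect | None = None
    name: str = ""


@dataclass
class Scene:
    """An ordered list of volumes sharing one bounding box, plus the
    scene-level Init and StopCondition effects."""

    nodes: list[VolumeNode]
    init: Effect | None = None
    stop: Effect | None = None

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("scene needs at least one volume")
        b0 = self.nodes[0].volume.bbox
        for i, node in enumerate(self.nodes[1:], start=1):
            b = node.volume.bbox
            if not (np.allclose(b[0], b0[0]) and np.allclose(b[1], b0[1])):
                raise ValueError(
                    f"volume {i} bounding box {b[0]}..{b[1]} differs from "
                    f"volume 0 ({b0[0]}..{b0[1]}); all volumes in a scene "
                    "must share one bounding box"
                )

    @property
    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes[0].volume.bbox

    def default_step(self) -> float:
        return 1.0 / (2.0 * max(max(n.volume.dims) for n in self.nodes))


@dataclass
class RenderedImage:
    """RGBA raster; ``rgba`` is (height, width, 4) float with
    premultiplied alpha."""

    rgba: np.ndarray

    def to_uint8(self) -> np.ndarray:
        """8-bit straight-alpha RGBA, rounding half up."""
        p = self.rgba
        a = p[..., 3:4]
        straight = np.concatenate([np.divide(p[..., :3], a, where=a > _EPS,
                                             out=np.zeros_like(p[..., :3])),
                                   a], axis=-1)
        return np.floor(np.clip(straight, 0, 1) * 255.0 + 0.5).astype(np.uint8)


def intersect_ray_box(
    origin: np.ndarray,
    direction: np.ndarray,
    box_min: Sequence[float] = (0, 0, 0),
    box_max: Sequence[float] = (1, 1, 1),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slab-method ray/AABB intersection.

    Broadcasts over leading axes of ``origin``/``direction`` (unit
    directions assumed).  Returns ``(t_near, t_far, hit)``; ``hit`` is
    False when the box is entirely behind the origin or the parameter
    interval is degenerate (grazing contact counts as a miss).
    """
    origin = np.asarray(origin, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    bmin = np.asarray(box_min, dtype=np.float64)
    bmax = np.asarray(box_max, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (bmin - origin) / direction
        t2 = (bmax - origin) / direction
    # fmin/fmax drop the NaNs produced by 0/0 on exact slab grazes
    tmin = np.fmin(t1, t2)
    tmax = np.fmax(t1, t2)
    t_near = np.max(tmin, axis=-1)
    t_far = np.min(tmax, axis=-1)
    hit = (t_far > np.maximum(t_near, 0.0)) & (t_far - t_near > _EPS)
    hit = hit & np.isfinite(t_far) & np.isfinite(t_near)
    return t_near, t_far, hit


def generate_rays(
    camera: Camera,
    bbox: tuple[np.ndarray, np.ndarray],
    depth_image: np.ndarray | None = None,
) -> RayBundle:
    """Per-pixel rays through the bbox, in normalized volume coordinates.

    Rays pass through pixel centers ``(i + 0.5, j + 0.5)`` with image
    row 0 at the top.  The world-space parameter interval is clipped to
    the near/far planes and, when ``depth_image`` is given (camera-space
    distance per pixel, 0 meaning no geometry), to the depth point, so
    no sample lands beyond opaque external geometry.  Rays that miss the
    box (or are fully clipped) come back inactive.
    """
    fwd, right, up = camera.basis()
    W, H = camera.width, camera.height
    tanv = math.tan(math.radians(camera.vfov) / 2.0)
    aspect = W / H
    px = (2.0 * (np.arange(W) + 0.5) / W - 1.0) * tanv * aspect
    py = (1.0 - 2.0 * (np.arange(H) + 0.5) / H) * tanv
    dirs = (fwd[None, None, :]
            + px[None, :, None] * right[None, None, :]
            + py[:, None, None] * up[None, None, :])
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    dirs = dirs.reshape(-1, 3)
    cos = dirs @ fwd  # > 0 for any valid fov

    t_near, t_far, hit = intersect_ray_box(camera.position, dirs, *bbox)
    t0 = np.maximum.reduce([t_near, camera.near / cos, np.zeros_like(t_near)])
    t1 = np.minimum(t_far, camera.far / cos)
    if depth_image is not None:
        depth = np.asarray(depth_image, dtype=np.float64).reshape(-1)
        if depth.shape[0] != W * H:
            raise ValueError(
                f"depth image has {depth.shape[0]} pixels, camera expects {W * H}"
            )
        has_geom = depth > 0
        t1 = np.where(has_geom, np.minimum(t1, depth), t1)
    active = hit & (t1 > t0 + _EPS)

    bmin, bmax = bbox
    extent = bmax - bmin
    p0 = (camera.position + t0[:, None] * dirs - bmin) / extent
    p1 = (camera.position + t1[:, None] * dirs - bmin) / extent
    np.clip(p0, 0.0, 1.0, out=p0)
    np.clip(p1, 0.0, 1.0, out=p1)
    seg = p1 - p0
    seg_len = np.linalg.norm(seg, axis=-1, keepdims=True)
    ndir = np.where(seg_len > _EPS, seg / np.where(seg_len > _EPS, seg_len, 1.0), 0.0)
    active &= seg_len[:, 0] > _EPS
    return RayBundle(start=p0, end=p1, dir=ndir, active=active, width=W, height=H)


def adjust_ray_with_depth(ray: Ray, depth: float, camera_position: np.ndarray) -> Ray:
    """Clip a ray so no sample lies beyond a depth point.

    ``depth`` is a camera-space distance along the ray (same units as
    the ray's coordinates).  If the depth point precedes ``rayStart``
    the ray is inactivated; if it lies beyond ``rayEnd`` the ray is
    returned unchanged.
    """
    if depth is None or depth <= 0:
        return ray
    camera_position = np.asarray(camera_position, dtype=np.float64)
    t_start = float(np.dot(ray.start - camera_position, ray.dir))
    rel = depth - t_start
    if rel <= 0:
        return Ray(ray.start.copy(), ray.start.copy(), ray.dir.copy(), active=False)
    if rel >= ray.length:
        return ray
    return Ray(ray.start.copy(), ray.start + rel * ray.dir, ray.dir.copy(),
               active=ray.active)


def composite(pixel: np.ndarray, sample: np.ndarray) -> np.ndarray:
    """Front-to-back *under* operator.

    ``pixel`` is premultiplied RGBA, ``sample`` non-premultiplied; the
    result is premultiplied.  Broadcasts over leading axes.
    """
    pixel = np.asarray(pixel, dtype=np.float64)
    sample = np.asarray(sample, dtype=np.float64)
    a = pixel[..., 3]
    w = (1.0 - a) * sample[..., 3]
    out = np.empty(np.broadcast_shapes(pixel.shape, sample.shape))
    out[..., :3] = pixel[..., :3] + w[..., None] * sample[..., :3]
    out[..., 3] = a + w
    return out


def volume_distance_range(
    point: np.ndarray,
    box_min: Sequence[float] = (0, 0, 0),
    box_max: Sequence[float] = (1, 1, 1),
) -> tuple[float, float]:
    """(min, max) distance from ``point`` to an axis-aligned box.

    The minimum is 0 when the point is inside; the maximum is the
    distance to the farthest corner.
    """
    p = np.asarray(point, dtype=np.float64)
    bmin = np.asarray(box_min, dtype=np.float64)
    bmax = np.asarray(box_max, dtype=np.float64)
    nearest = np.clip(p, bmin, bmax)
    dmin = float(np.linalg.norm(nearest - p))
    farthest = np.where(np.abs(p - bmin) > np.abs(p - bmax), bmin, bmax)
    dmax = float(np.linalg.norm(farthest - p))
    return dmin, dmax


# ---------------------------------------------------------------------------
# integration engine


def _read_only(arr: np.ndarray) -> np.ndarray:
    view = arr.view()
    view.flags.writeable = False
    return view


class _Engine:
    """Lockstep integration of a ray bundle over one scene."""

    def __init__(self, bundle: RayBundle, scene: Scene, camera: Camera,
                 settings: RenderSettings):
        self.bundle = bundle
        self.scene = scene
        self.settings = settings
        self.step = settings.step if settings.step is not None else scene.default_step()
        bmin, bmax = scene.bbox
        self.cam_n = _read_only((np.asarray(camera.position) - bmin) / (bmax - bmin))
        self.vdr = volume_distance_range(self.cam_n)
        self.ip = _read_only(settings.interaction_point.copy())
        self.accessors = [VolumeAccessor(n.volume, n.tf) for n in scene.nodes]
        N = bundle.start.shape[0]
        self.N = N
        self.start = bundle.start.copy()
        self.end = bundle.end.copy()
        self.dir = bundle.dir.copy()
        self.active = bundle.active.copy()
        self.curdist = np.zeros(N)
        self.pixel = np.zeros((N, 4))
        self.user_state: dict[str, np.ndarray] = {}
        self._warned_clamp = False

    # -- context assembly ---------------------------------------------------

    def _ctx(self, idx, *, stage: str, sample=None, vol_index=0,
             us: dict | None = None) -> ShaderContext:
        writable_ray = stage == "init"
        pos = self.start[idx] + self.curdist[idx, None] * self.dir[idx]
        ray = RayView(self.start[idx], self.end[idx], self.dir[idx])
        curdist = self.curdist[idx]
        pixel = self.pixel[idx]
        if not writable_ray:
            ray = RayView(_read_only(ray.start), _read_only(ray.end),
                          _read_only(ray.dir))
            curdist = _read_only(curdist)
        if stage != "init":
            pixel = _read_only(pixel)
        pos = _read_only(pos)
        if sample is None:
            sample = np.zeros((len(idx), 4))
            if stage == "stop":
                sample = _read_only(sample)
        if us is None:
            us = {k: v[idx] for k, v in self.user_state.items()}
            if stage == "stop":
                us = {k: _read_only(v) for k, v in us.items()}
        state = IntegrationState(pos=pos, currentDistance=curdist,
                                 pixelRGBA=pixel, sampleRGBA=sample,
                                 user_state=us)
        return ShaderContext(ray=ray, state=state, cameraPosition=self.cam_n,
                             volumeDistanceRange=self.vdr,
                             time=self.settings.time,
                             interactionPoint1=self.ip,
                             volumes=self.accessors, volumeIndex=vol_index,
                             n_rays=len(idx))

    def _call(self, stage: str, name: str, fn, ctx, idx):
        try:
            return fn(ctx)
        except Exception as e:  # noqa: BLE001 - re-raised with context
            row, col = self.bundle.pixel_of(int(idx[0])) if len(idx) else (-1, -1)
            raise ShaderStageError(
                f"{stage} shader '{name}' failed (first affected pixel "
                f"row={row}, col={col}): {e}"
            ) from e

    def _scatter_user_state(self, idx, us: dict) -> None:
        for key, val in us.items():
            val = np.asarray(val)
            if key not in self.user_state:
                full = np.zeros((self.N,) + val.shape[1:], dtype=val.dtype)
                self.user_state[key] = full
            self.user_state[key][idx] = val

    # -- stages -------------------------------------------------------------

    def run_init(self) -> None:
        inits = []
        if self.scene.init is not None and self.scene.init.init is not None:
            inits.append((self.scene.init.name, self.scene.init.init))
        for node in self.scene.nodes:
            if node.effect is not None and node.effect.init is not None:
                inits.append((node.effect.name, node.effect.init))
        if not inits:
            return
        idx = np.flatnonzero(self.active)
        if len(idx) == 0:
            return
        ray = RayView(self.start[idx], self.end[idx], self.dir[idx])
        curdist = self.curdist[idx]
        pixel = self.pixel[idx]
        us = {k: v[idx] for k, v in self.user_state.items()}
        state = IntegrationState(pos=_read_only(ray.start.copy()),
                                 currentDistance=curdist, pixelRGBA=pixel,
                                 sampleRGBA=np.zeros((len(idx), 4)),
                                 user_state=us)
        ctx = ShaderContext(ray=ray, state=state, cameraPosition=self.cam_n,
                            volumeDistanceRange=self.vdr,
                            time=self.settings.time, interactionPoint1=self.ip,
                            volumes=self.accessors, n_rays=len(idx))
        for name, fn in inits:
            self._call("Init", name, fn, ctx, idx)
        self.start[idx] = ray.start
        self.end[idx] = ray.end
        self.dir[idx] = ray.dir
        self.curdist[idx] = state.currentDistance
        self.pixel[idx] = state.pixelRGBA
        self._scatter_user_state(idx, state.user_state)

    def run(self) -> np.ndarray:
        from .effects import default_shader  # local import: effects builds on shading

        self.run_init()
        default = default_shader()
        length = np.linalg.norm(self.end - self.start, axis=-1)
        thr = self.settings.ert_threshold
        stop_fn = None
        stop_name = ""
        if self.scene.stop is not None and self.scene.stop.stop is not None:
            stop_fn = self.scene.stop.stop
            stop_name = self.scene.stop.name
        alive = self.active & (self.curdist < length)
        while alive.any():
            idx = np.flatnonzero(alive)
            m = len(idx)
            sample = np.zeros((m, 4))
            us = {k: v[idx] for k, v in self.user_state.items()}
            for vi, node in enumerate(self.scene.nodes):
                fn = node.effect.volume if (node.effect and node.effect.volume) \
                    else default.volume
                name = node.effect.name if node.effect else default.name
                ctx = self._ctx(idx, stage="volume", sample=sample,
                                vol_index=vi, us=us)
                self._call("Volume", name, fn, ctx, idx)
                sample = ctx.state.sampleRGBA  # in case the shader rebound it
                us = ctx.state.user_state
            self._scatter_user_state(idx, us)
            if not self._warned_clamp and (sample.min() < -1e-9
                                           or sample.max() > 1 + 1e-9):
                log.warning("Volume shader emitted out-of-range components; "
                            "clamping to [0, 1]")
                self._warned_clamp = True
            np.clip(sample, 0.0, 1.0, out=sample)
            ref = self.settings.opacity_reference_step
            if ref is not None:
                sample[:, 3] = 1.0 - (1.0 - sample[:, 3]) ** (self.step / ref)
            a = self.pixel[idx, 3]
            w = (1.0 - a) * sample[:, 3]
            self.pixel[idx, :3] += w[:, None] * sample[:, :3]
            self.pixel[idx, 3] = a + w
            self.curdist[idx] += self.step
            stopped = np.zeros(m, dtype=bool)
            if thr is not None:
                stopped |= self.pixel[idx, 3] >= thr
            if stop_fn is not None:
                ctx = self._ctx(idx, stage="stop")
                res = self._call("StopCondition", stop_name, stop_fn, ctx, idx)
                stopped |= np.asarray(res, dtype=bool)
            if stopped.any():
                self.active[idx[stopped]] = False
            alive = self.active & (self.curdist < length)

        bg = self.settings.background
        out = np.empty((self.N, 4))
        w = (1.0 - self.pixel[:, 3]) * bg[3]
        out[:, :3] = self.pixel[:, :3] + w[:, None] * bg[:3]
        out[:, 3] = self.pixel[:, 3] + w
        return out


def integrate_ray(ray: Ray, scene: Scene, camera: Camera,
                  settings: RenderSettings) -> np.ndarray:
    """Integrate a single ray; returns the premultiplied RGBA pixel
    (already over-blended onto the background)."""
    bundle = RayBundle(start=ray.start[None, :], end=ray.end[None, :],
                       dir=ray.dir[None, :],
                       active=np.array([ray.active]), width=1, height=1)
    engine = _Engine(bundle, scene, camera, settings)
    return engine.run()[0]


def render(scene: Scene, camera: Camera,
           settings: RenderSettings | None = None,
           depth_image: np.ndarray | None = None) -> RenderedImage:
    """Render the scene; deterministic for fixed inputs.

    ``depth_image`` is an optional (height, width) array of camera-space
    distances (0 = no geometry) that clips each ray's integration range.
    """
    if settings is None:
        settings = RenderSettings()
    bundle = generate_rays(camera, scene.bbox, depth_image)
    engine = _Engine(bundle, scene, camera, settings)
    flat = engine.run()
    return RenderedImage(flat.reshape(camera.height, camera.width, 4))
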