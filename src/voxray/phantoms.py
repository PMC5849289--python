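"""Seedable synthetic volumes for exercising every rendering effect.

Four phantom families stand in for the data classes the effects were
designed around: a head-like blob (carving), concentric shells
(opacity-peeling layers), a tubular vessel with a companion
within-tube arclength volume (decluttering and flow animation), and a
linear ramp whose gradient is known analytically (edge enhancement).

All phantoms are generated on the normalized unit cube (grid node
``i`` at coordinate ``i/(n-1)``) with raw values in ``[0, 1]`` and
``scalar_range = (0, 1)``, so raw and normalized intensities coincide.
Everything is bit-reproducible from a :class:`PhantomSpec` and its
seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .volume import ScalarVolume

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_sphere_phantom",
    "make_shell_phantom",
    "make_tube_phantom",
    "make_ramp_phantom",
    "add_noise",
    "grid_coords",
]

KINDS = ("sphere", "shells", "tube_tree", "ramp")


@dataclass
class PhantomSpec:
    """Declarative phantom description; serializes round-trip to JSON."""

    kind: str
    dims: tuple[int, int, int] = (48, 48, 48)
    params: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind '{self.kind}'; one of {KINDS}")
        self.dims = tuple(int(d) for d in self.dims)
        if len(self.dims) != 3 or min(self.dims) < 8:
            raise ValueError(f"dims must be 3 values >= 8, got {self.dims}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        return cls(kind=d["kind"], dims=tuple(d["dims"]),
                   params=d.get("params", {}),
                   noise_sigma=d.get("noise_sigma", 0.0),
                   seed=d.get("seed", 0))


def grid_coords(dims: Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized coordinates of the grid nodes, as an open meshgrid."""
    axes = [np.linspace(0.0, 1.0, n) for n in dims]
    return np.meshgrid(*axes, indexing="ij", sparse=True)  # type: ignore[return-value]


def _finish(values: np.ndarray, spec: PhantomSpec) -> ScalarVolume:
    vol = ScalarVolume(values, scalar_range=(0.0, 1.0))
    if spec.noise_sigma > 0:
        vol = add_noise(vol, spec.noise_sigma, spec.seed)
    return vol


def make_sphere_phantom(spec: PhantomSpec) -> ScalarVolume:
    """A solid ball: ``inside`` value within ``radius`` of ``center``,
    ``outside`` elsewhere, with an optional linear transition band of
    width ``edge_width`` straddling the surface (for smooth gradients).
    """
    p = spec.params
    center = np.asarray(p.get("center", (0.5, 0.5, 0.5)), dtype=np.float64)
    radius = float(p.get("radius", 0.35))
    inside = float(p.get("inside", 1.0))
    outside = float(p.get("outside", 0.0))
    edge = float(p.get("edge_width", 0.0))
    x, y, z = grid_coords(spec.dims)
    r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    if edge > 0:
        t = np.clip((radius + edge / 2 - r) / edge, 0.0, 1.0)
    else:
        t = (r <= radius).astype(np.float64)
    return _finish(outside + (inside - outside) * t, spec)


def make_shell_phantom(spec: PhantomSpec) -> ScalarVolume:
    """Concentric spherical shells of distinct values.

    ``radii`` are strictly increasing; region ``r < radii[0]`` takes
    ``values[0]``, the annulus ``radii[i-1] <= r < radii[i]`` takes
    ``values[i]``, and everything beyond the last radius takes
    ``outside``.  A center ray therefore crosses ``2 * len(radii)``
    material transitions.
    """
    p = spec.params
    radii = [float(r) for r in p.get("radii", (0.15, 0.25, 0.4))]
    values = [float(v) for v in p.get("values", (0.9, 0.0, 0.5))]
    outside = float(p.get("outside", 0.0))
    center = np.asarray(p.get("center", (0.5, 0.5, 0.5)), dtype=np.float64)
    if len(radii) != len(values) or not radii:
        raise ValueError("radii and values must be non-empty and equally long")
    if (np.diff(radii) <= 0).any():
        raise ValueError(f"radii must be strictly increasing, got {radii}")
    x, y, z = grid_coords(spec.dims)
    r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    out = np.full(spec.dims, outside)
    for radius, value in zip(reversed(radii), reversed(values)):
        out[r < radius] = value
    return _finish(out, spec)


def make_tube_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, ScalarVolume]:
    """A tubular vessel along a polyline, plus its arclength companion.

    Returns ``(intensity, distance)``.  The intensity volume holds
    ``inside`` within ``radius`` of the path and ``outside`` elsewhere.
    The distance volume holds, for in-tube voxels, the arclength from
    the path start to the nearest path point, normalized to the total
    path length and scaled by ``distance_scale``; out-of-tube voxels
    are 0.  With the default scale ``n_wavelengths * 2 pi / 1000`` the
    stock flow shader's 1000.0 spatial frequency lays
    ``n_wavelengths`` full waves along the tube.
    """
    p = spec.params
    path = np.asarray(p.get("path", [(0.15, 0.5, 0.5), (0.5, 0.6, 0.5),
                                     (0.85, 0.5, 0.5)]), dtype=np.float64)
    radius = float(p.get("radius", 0.08))
    inside = float(p.get("inside", 1.0))
    outside = float(p.get("outside", 0.0))
    n_wavelengths = float(p.get("n_wavelengths", 5.0))
    distance_scale = float(p.get("distance_scale",
                                 n_wavelengths * 2.0 * np.pi / 1000.0))
    if path.ndim != 2 or path.shape[0] < 2 or path.shape[1] != 3:
        raise ValueError("path must be a polyline of >= 2 points in 3-D")

    x, y, z = grid_coords(spec.dims)
    pts = np.stack(np.broadcast_arrays(x, y, z), axis=-1)  # (nx,ny,nz,3)
    flat = pts.reshape(-1, 3)

    seg_vec = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    best_d2 = np.full(flat.shape[0], np.inf)
    best_arc = np.zeros(flat.shape[0])
    for a, v, ln, arc0 in zip(path[:-1], seg_vec, seg_len, cum[:-1]):
        t = np.clip((flat - a) @ v / (ln * ln), 0.0, 1.0)
        closest = a + t[:, None] * v
        d2 = np.sum((flat - closest) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_arc[better] = arc0 + t[better] * ln

    in_tube = best_d2 <= radius * radius
    intensity = np.where(in_tube, inside, outside).reshape(spec.dims)
    dist = np.where(in_tube, best_arc / total * distance_scale, 0.0)
    dist = dist.reshape(spec.dims)
    vol = _finish(intensity, spec)
    dvol = ScalarVolume(dist, scalar_range=(0.0, 1.0))
    return vol, dvol


def make_ramp_phantom(spec: PhantomSpec) -> ScalarVolume:
    """Linear field ``f(p) = clamp(p . direction, 0, 1)``.

    Its interior un-divided central-difference gradient is exactly
    ``-2 h * direction`` for step ``h``, which makes it the analytic
    fixture for gradient and edge-enhancement checks.
    """
    p = spec.params
    direction = np.asarray(p.get("direction", (1.0, 0.0, 0.0)), dtype=np.float64)
    x, y, z = grid_coords(spec.dims)
    f = x * direction[0] + y * direction[1] + z * direction[2]
    return _finish(np.clip(f, 0.0, 1.0) * np.ones(spec.dims), spec)


def make_phantom(spec: PhantomSpec):
    """Dispatch on ``spec.kind``; tube phantoms return a volume pair."""
    return {
        "sphere": make_sphere_phantom,
        "shells": make_shell_phantom,
        "tube_tree": make_tube_phantom,
        "ramp": make_ramp_phantom,
    }[spec.kind](spec)


def add_noise(volume: ScalarVolume, sigma: float, seed: int) -> ScalarVolume:
    """Additive zero-mean Gaussian noise, clamped to the scalar range.

    Deterministic per seed; ``sigma`` is in raw value units.
    """
    if sigma == 0:
        return volume
    rng = np.random.default_rng(seed)
    lo, hi = volume.scalar_range
    noisy = np.clip(volume.values + rng.normal(0.0, sigma, volume.values.shape),
                    lo, hi)
    return ScalarVolume(noisy, scalar_range=volume.scalar_range, bbox=volume.bbox)
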