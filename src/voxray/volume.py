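"""Scalar volumes, transfer functions, and the sampling built-ins.

A :class:`ScalarVolume` is a rectilinear 3-D scalar grid addressed in
*normalized volume coordinates*: positions live in the unit cube
``[0, 1]^3`` regardless of grid resolution or physical extent, with the
first grid node of each axis at 0 and the last at 1.  Sample values
returned by :func:`sample_volume` are normalized to ``[0, 1]`` using the
volume's ``scalar_range`` (global min-max; no window/level step is
applied).  Colors and opacities come from a piecewise-linear
:class:`TransferFunction` over the normalized scalar.

RGBA values are plain float arrays of shape ``(..., 4)``.  Transfer
function output is *non-premultiplied*; the ray-integration accumulator
is premultiplied (see :mod:`voxray.rays`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ScalarVolume",
    "TransferFunction",
    "GradientSample",
    "sample_volume",
    "sample_tf",
    "sample_volume_with_tf",
    "compute_gradient",
]

_GRAD_EPS = 1e-12


@dataclass
class ScalarVolume:
    """A 3-D scalar field on a rectilinear grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Raw scalar samples; ``values[i, j, k]`` sits at normalized
        coordinate ``(i/(nx-1), j/(ny-1), k/(nz-1))``.
    scalar_range : (float, float)
        Raw value interval mapped to normalized ``[0, 1]`` for transfer
        function lookup.  Defaults to the data min/max.
    bbox : (ndarray, ndarray)
        World-space axis-aligned bounding box ``(min_corner, max_corner)``.
        All volumes rendered together must share one bbox.  Defaults to
        the unit cube.
    """

    values: np.ndarray
    scalar_range: tuple[float, float] | None = None
    bbox: tuple[np.ndarray, np.ndarray] | None = None
    _normalized: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"volume data must be 3-D, got {self.values.ndim} dimensions"
            )
        if min(self.values.shape) < 2:
            raise ValueError(f"each axis needs >= 2 samples, got {self.values.shape}")
        if self.scalar_range is None:
            self.scalar_range = (float(self.values.min()), float(self.values.max()))
        lo, hi = self.scalar_range
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ValueError(f"degenerate scalar range ({lo}, {hi}): need min < max")
        if self.bbox is None:
            self.bbox = (np.zeros(3), np.ones(3))
        bmin = np.asarray(self.bbox[0], dtype=np.float64)
        bmax = np.asarray(self.bbox[1], dtype=np.float64)
        if not (bmax > bmin).all():
            raise ValueError(f"degenerate bounding box {bmin}..{bmax}")
        self.bbox = (bmin, bmax)
        self._normalized = (self.values - lo) / (hi - lo)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


class GradientSample(NamedTuple):
    """Finite-difference gradient: unit ``direction`` and ``magnitude``.

    ``direction`` is the zero vector exactly when ``magnitude`` vanishes.
    The magnitude is the *un-divided* central difference (no division by
    the step), matching the raw-intensity-difference scale on which the
    edge-enhancement thresholds operate.
    """

    direction: np.ndarray  # (..., 3)
    magnitude: np.ndarray  # (...)


@dataclass
class TransferFunction:
    """Piecewise-linear color and opacity over the normalized scalar.

    ``color_points`` is a sorted sequence of ``(s, r, g, b)`` and
    ``opacity_points`` of ``(s, a)``, with every component in ``[0, 1]``.
    The two tracks interpolate independently and clamp outside the first
    and last control point.
    """

    color_points: Sequence[Sequence[float]]
    opacity_points: Sequence[Sequence[float]]

    def __post_init__(self) -> None:
        cp = np.asarray(self.color_points, dtype=np.float64)
        op = np.asarray(self.opacity_points, dtype=np.float64)
        for name, pts, width in (("color", cp, 4), ("opacity", op, 2)):
            if pts.ndim != 2 or pts.shape[1] != width or pts.shape[0] < 1:
                raise ValueError(
                    f"{name} points must be a non-empty list of "
                    f"{width}-tuples, got shape {pts.shape}"
                )
            for i, row in enumerate(pts):
                if ((row < 0) | (row > 1)).any():
                    raise ValueError(
                        f"{name} point {i} has components outside [0, 1]: "
                        f"{row.tolist()}"
                    )
            if (np.diff(pts[:, 0]) < 0).any():
                bad = int(np.argmax(np.diff(pts[:, 0]) < 0)) + 1
                raise ValueError(
                    f"{name} point {bad} breaks scalar ordering: {pts[bad].tolist()}"
                )
        self._cs, self._cr, self._cg, self._cb = cp.T
        self._os, self._oa = op.T

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunction":
        try:
            return cls(d["color"], d["opacity"])
        except KeyError as e:
            raise ValueError(f"transfer function document missing key {e}") from e

    @classmethod
    def from_json_file(cls, path) -> "TransferFunction":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def constant(cls, r: float, g: float, b: float, a: float) -> "TransferFunction":
        return cls([[0.0, r, g, b]], [[0.0, a]])

    @classmethod
    def grayscale_ramp(cls, max_alpha: float = 1.0) -> "TransferFunction":
        return cls([[0, 0, 0, 0], [1, 1, 1, 1]], [[0, 0], [1, max_alpha]])


def sample_volume(volume: ScalarVolume, pos: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated, range-normalized scalar at ``pos``.

    ``pos`` has shape ``(..., 3)`` in normalized volume coordinates.
    Positions outside the unit cube return 0 (transparent under any
    transfer function with ``a(0) = 0``); inside, interpolation clamps
    to the edge voxels, mimicking GPU clamp-to-edge addressing.
    """
    pos = np.asarray(pos, dtype=np.float64)
    scalar_in = pos.ndim == 1
    p = np.atleast_2d(pos)
    inside = ((p >= 0.0) & (p <= 1.0)).all(axis=-1)
    dims = np.asarray(volume.dims, dtype=np.float64)
    coords = (p * (dims - 1.0)).T  # (3, n) in voxel index units
    out = map_coordinates(volume._normalized, coords, order=1, mode="nearest")
    out = np.where(inside, out, 0.0)
    return out[0] if scalar_in else out.reshape(pos.shape[:-1])


def sample_tf(tf: TransferFunction, s: np.ndarray) -> np.ndarray:
    """Evaluate the transfer function; returns non-premultiplied RGBA.

    Color and opacity tracks interpolate independently, clamped at their
    respective end points.
    """
    s = np.asarray(s, dtype=np.float64)
    out = np.empty(s.shape + (4,))
    out[..., 0] = np.interp(s, tf._cs, tf._cr)
    out[..., 1] = np.interp(s, tf._cs, tf._cg)
    out[..., 2] = np.interp(s, tf._cs, tf._cb)
    out[..., 3] = np.interp(s, tf._os, tf._oa)
    return out


def sample_volume_with_tf(
    volume: ScalarVolume, tf: TransferFunction, pos: np.ndarray
) -> np.ndarray:
    """Sample the volume and map the result through its transfer function."""
    return sample_tf(tf, sample_volume(volume, pos))


def compute_gradient(
    volume: ScalarVolume, pos: np.ndarray, grad_step: float
) -> GradientSample:
    """Central-difference intensity gradient at ``pos``.

    Computes the un-divided difference
    ``g_i = S(pos - h e_i) - S(pos + h e_i)`` per axis (``S`` being
    :func:`sample_volume`), so on a bright object the direction points
    outward, from high toward low intensity.  ``magnitude = |g|`` scales
    linearly with ``grad_step`` on a linear field; near-zero gradients
    (``|g| < 1e-12``) collapse to a zero direction.
    """
    if not grad_step > 0:
        raise ValueError(f"grad_step must be positive, got {grad_step}")
    pos = np.asarray(pos, dtype=np.float64)
    g = np.empty(pos.shape)
    for i in range(3):
        e = np.zeros(3)
        e[i] = grad_step
        g[..., i] = sample_volume(volume, pos - e) - sample_volume(volume, pos + e)
    mag = np.linalg.norm(g, axis=-1)
    safe = np.where(mag < _GRAD_EPS, 1.0, mag)
    direction = np.where(mag[..., None] < _GRAD_EPS, 0.0, g / safe[..., None])
    mag = np.where(mag < _GRAD_EPS, 0.0, mag)
    return GradientSample(direction, mag)
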