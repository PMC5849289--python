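"""Deliberately naive per-pixel reference renderer.

This module re-derives default-mode rendering from first principles —
its own pinhole construction, its own slab intersection, scalar-loop
trilinear interpolation and transfer-function lookup, and step-by-step
under-operator compositing — sharing no code with the vectorized
engine in :mod:`voxray.rays`.  It exists purely as a validation
oracle: agreement between the two renderers checks the engine's
geometry, sampling and compositing end to end.  It only implements the
default Volume stage (plain transfer-function compositing over one or
more volumes) plus optional early ray termination, and it is slow —
use tiny scenes.
"""

from __future__ import annotations

import math

import numpy as np

from .rays import Camera, RenderedImage, RenderSettings, Scene

__all__ = ["render_reference"]


def _trilinear(values: np.ndarray, lo: float, hi: float, p) -> float:
    """Scalar-loop trilinear interpolation of the range-normalized grid."""
    for c in p:
        if c < 0.0 or c > 1.0:
            return 0.0
    nx, ny, nz = values.shape
    fx = p[0] * (nx - 1)
    fy = p[1] * (ny - 1)
    fz = p[2] * (nz - 1)
    i0 = min(int(math.floor(fx)), nx - 2)
    j0 = min(int(math.floor(fy)), ny - 2)
    k0 = min(int(math.floor(fz)), nz - 2)
    tx, ty, tz = fx - i0, fy - j0, fz - k0
    acc = 0.0
    for di in (0, 1):
        wx = tx if di else 1.0 - tx
        for dj in (0, 1):
            wy = ty if dj else 1.0 - ty
            for dk in (0, 1):
                wz = tz if dk else 1.0 - tz
                acc += wx * wy * wz * values[i0 + di, j0 + dj, k0 + dk]
    return (acc - lo) / (hi - lo)


def _interp_track(xs, ys, x: float) -> float:
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for i in range(1, len(xs)):
        if x <= xs[i]:
            span = xs[i] - xs[i - 1]
            if span == 0.0:
                return ys[i]
            t = (x - xs[i - 1]) / span
            return ys[i - 1] + t * (ys[i] - ys[i - 1])
    return ys[-1]


def _tf_lookup(tf, s: float) -> tuple[float, float, float, float]:
    r = _interp_track(tf._cs, tf._cr, s)
    g = _interp_track(tf._cs, tf._cg, s)
    b = _interp_track(tf._cs, tf._cb, s)
    a = _interp_track(tf._os, tf._oa, s)
    return r, g, b, a


def render_reference(scene: Scene, camera: Camera,
                     settings: RenderSettings | None = None) -> RenderedImage:
    """Default-mode render, one pixel and one sample at a time."""
    if settings is None:
        settings = RenderSettings()
    step = settings.step if settings.step is not None else scene.default_step()
    thr = settings.ert_threshold
    ref_step = settings.opacity_reference_step
    bg = settings.background
    bmin, bmax = scene.bbox
    extent = bmax - bmin
    nodes = [(n.volume.values, n.volume.scalar_range[0],
              n.volume.scalar_range[1], n.tf) for n in scene.nodes]

    fwd, right, up = camera.basis()
    W, H = camera.width, camera.height
    tanv = math.tan(math.radians(camera.vfov) / 2.0)
    aspect = W / H
    out = np.empty((H, W, 4))

    for row in range(H):
        py = (1.0 - 2.0 * (row + 0.5) / H) * tanv
        for col in range(W):
            px = (2.0 * (col + 0.5) / W - 1.0) * tanv * aspect
            d = fwd + px * right + py * up
            d = d / np.linalg.norm(d)
            cos = float(d @ fwd)

            # slab intersection with the world box
            t_lo, t_hi = -math.inf, math.inf
            ok = True
            for ax in range(3):
                o, dd = camera.position[ax], d[ax]
                if dd == 0.0:
                    if o < bmin[ax] or o > bmax[ax]:
                        ok = False
                        break
                    continue
                ta = (bmin[ax] - o) / dd
                tb = (bmax[ax] - o) / dd
                if ta > tb:
                    ta, tb = tb, ta
                t_lo = max(t_lo, ta)
                t_hi = min(t_hi, tb)
            t0 = max(t_lo, camera.near / cos, 0.0)
            t1 = min(t_hi, camera.far / cos)
            if not ok or t1 <= t0 + 1e-12:
                out[row, col, :3] = np.asarray(bg[:3]) * bg[3]
                out[row, col, 3] = bg[3]
                continue

            p0 = (camera.position + t0 * d - bmin) / extent
            p1 = (camera.position + t1 * d - bmin) / extent
            p0 = np.clip(p0, 0.0, 1.0)
            p1 = np.clip(p1, 0.0, 1.0)
            seg = p1 - p0
            length = float(np.linalg.norm(seg))
            rdir = seg / length

            pr = pg = pb = pa = 0.0
            dist = 0.0
            while dist < length:
                pos = p0 + dist * rdir
                sr = sg = sb = sa = 0.0
                for values, lo, hi, tf in nodes:
                    s = _trilinear(values, lo, hi, pos)
                    r, g, b, a = _tf_lookup(tf, s)
                    sr += r
                    sg += g
                    sb += b
                    sa += a
                sr = min(max(sr, 0.0), 1.0)
                sg = min(max(sg, 0.0), 1.0)
                sb = min(max(sb, 0.0), 1.0)
                sa = min(max(sa, 0.0), 1.0)
                if ref_step is not None:
                    sa = 1.0 - (1.0 - sa) ** (step / ref_step)
                w = (1.0 - pa) * sa
                pr += w * sr
                pg += w * sg
                pb += w * sb
                pa += w
                dist += step
                if thr is not None and pa >= thr:
                    break

            w = (1.0 - pa) * bg[3]
            out[row, col, 0] = pr + w * bg[0]
            out[row, col, 1] = pg + w * bg[1]
            out[row, col, 2] = pb + w * bg[2]
            out[row, col, 3] = pa + w
    return RenderedImage(out)
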