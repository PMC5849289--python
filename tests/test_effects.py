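"""Effect presets against hand traces and analytic oracles."""

import numpy as np
import pytest

import voxray as vx
from voxray.effects import (
    aerial_perspective,
    blinn_phong_shader,
    blood_flow,
    carving,
    chroma_depth,
    declutter,
    default_shader,
    edge_enhance,
    make_effect,
    opacity_peeling,
    pseudo_chroma_depth,
)
from voxray.phantoms import PhantomSpec, make_ramp_phantom, make_sphere_phantom
from voxray.shading import IntegrationState, RayView, ShaderContext, VolumeAccessor
from voxray.rays import volume_distance_range
from voxray.volume import ScalarVolume, TransferFunction


class PrescribedAccessor:
    """Stand-in volume accessor returning prescribed RGBA / raw samples."""

    def __init__(self, rgba=None, raw=None):
        self._rgba = None if rgba is None else np.asarray(rgba, dtype=float)
        self._raw = None if raw is None else np.asarray(raw, dtype=float)

    def sample_with_tf(self, pos):
        return np.broadcast_to(self._rgba, pos.shape[:-1] + (4,)).copy()

    def sample(self, pos):
        return np.broadcast_to(self._raw, pos.shape[:-1]).copy()


def make_ctx(volumes, pos, ray_dir=(0.0, 0.0, -1.0), cam=(0.5, 0.5, 2.0),
             time=0.0, ip=(0.5, 0.5, 0.5), user_state=None, start=None,
             curdist=None):
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    n = pos.shape[0]
    d = np.broadcast_to(np.asarray(ray_dir, dtype=float), (n, 3)).copy()
    start = pos.copy() if start is None else np.atleast_2d(np.asarray(start, float))
    cam = np.asarray(cam, dtype=float)
    state = IntegrationState(
        pos=pos,
        currentDistance=np.zeros(n) if curdist is None else np.asarray(curdist, float),
        pixelRGBA=np.zeros((n, 4)),
        sampleRGBA=np.zeros((n, 4)),
        user_state=user_state if user_state is not None else {},
    )
    return ShaderContext(ray=RayView(start, start + d, d), state=state,
                         cameraPosition=cam,
                         volumeDistanceRange=volume_distance_range(cam),
                         time=time, interactionPoint1=np.asarray(ip, float),
                         volumes=volumes, volumeIndex=0, n_rays=n)


# ---------------------------------------------------------------------------
# volume carving


class TestCarving:
    def test_ray_through_center_advances_past_far_side(self):
        eff = carving(sphere_radius=0.2)
        ctx = make_ctx([], pos=[[0.5, 0.5, 1.0]], ray_dir=(0, 0, -1),
                       ip=(0.5, 0.5, 0.5))
        eff.init(ctx)
        # chord through center: distance to center (0.5) + radius
        assert ctx.state.currentDistance[0] == pytest.approx(0.7, abs=1e-12)

    def test_perpendicular_miss_leaves_distance_unchanged(self):
        eff = carving(sphere_radius=0.2)
        ctx = make_ctx([], pos=[[0.5, 0.9, 1.0]], ray_dir=(0, 0, -1),
                       ip=(0.5, 0.5, 0.5))  # miss distance 0.4 >= 0.2
        eff.init(ctx)
        assert ctx.state.currentDistance[0] == 0.0

    def test_sphere_fully_behind_origin_unchanged(self):
        eff = carving(sphere_radius=0.2)
        ctx = make_ctx([], pos=[[0.5, 0.5, 0.0]], ray_dir=(0, 0, -1),
                       ip=(0.5, 0.5, 0.5), start=[[0.5, 0.5, 0.0]])
        # center is at +z of the start, ray goes to -z: exit distance < 0
        eff.init(ctx)
        assert ctx.state.currentDistance[0] == 0.0

    def test_matches_quadratic_solve_oracle(self, rng):
        n = 10_000
        starts = rng.uniform(-0.5, 1.5, (n, 3))
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        center = np.array([0.45, 0.55, 0.5])
        r = 0.3
        eff = carving(sphere_radius=r)
        ctx = make_ctx([], pos=starts, ip=center)
        ctx.ray.dir[...] = dirs
        eff.init(ctx)
        got = ctx.state.currentDistance
        # oracle: solve |start + t d - c|^2 = r^2 for the larger root
        oc = starts - center
        b = np.sum(oc * dirs, axis=1)
        disc = b * b - (np.sum(oc * oc, axis=1) - r * r)
        t_far = -b + np.sqrt(np.maximum(disc, 0.0))
        want = np.where((disc > 0) & (t_far > 0), t_far, 0.0)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_non_intersecting_pixels_bit_identical(self, sphere_scene,
                                                   head_on_camera):
        ip = (0.35, 0.6, 0.7)
        r = 0.12
        settings = vx.RenderSettings(interaction_point=ip)
        plain = vx.render(sphere_scene, head_on_camera, settings)
        carved_scene = vx.Scene(sphere_scene.nodes, init=carving(r))
        carved = vx.render(carved_scene, head_on_camera, settings)
        bundle = vx.generate_rays(head_on_camera, sphere_scene.bbox)
        oc = bundle.start - np.asarray(ip)
        b = np.sum(oc * bundle.dir, axis=1)
        disc = b * b - (np.sum(oc * oc, axis=1) - r * r)
        untouched = (disc <= 0).reshape(64, 64)
        assert untouched.any() and not untouched.all()
        np.testing.assert_array_equal(plain.rgba[untouched],
                                      carved.rgba[untouched])
        assert (plain.rgba != carved.rgba).any()

    def test_ray_swallowed_by_sphere_returns_background(self, sphere_scene,
                                                        head_on_camera):
        settings = vx.RenderSettings(interaction_point=(0.5, 0.5, 0.5),
                                     background=(0.1, 0.0, 0.3, 1.0))
        scene = vx.Scene(sphere_scene.nodes, init=carving(1.0))
        img = vx.render(scene, head_on_camera, settings)
        assert (img.rgba == np.array([0.1, 0.0, 0.3, 1.0])).all()


# ---------------------------------------------------------------------------
# opacity peeling


class TestOpacityPeeling:
    def test_wanted_layer_zero_is_identity(self, shell_volume, shell_tf,
                                           head_on_camera):
        plain = vx.render(vx.Scene([vx.VolumeNode(shell_volume, shell_tf)]),
                          head_on_camera, vx.RenderSettings())
        peel0 = vx.render(
            vx.Scene([vx.VolumeNode(shell_volume, shell_tf,
                                    effect=opacity_peeling(wanted_layer=0))]),
            head_on_camera, vx.RenderSettings())
        np.testing.assert_array_equal(plain.rgba, peel0.rgba)

    def test_four_sample_hand_trace(self):
        """Alphas (.8, .8, .01, .5): layerAlpha .8 -> .96, peel at the .01
        sample (layerAlpha > .9, alpha < .05), then .5 contributes."""
        eff = opacity_peeling(wanted_layer=1, t_high=0.9, t_low=0.05)
        us = {}
        ctx = make_ctx([PrescribedAccessor(rgba=[0, 0, 0, 0])],
                       pos=[[0.5, 0.5, 0.5]], user_state=us)
        eff.init(ctx)
        contributions = []
        layer_alphas = []
        for a in (0.8, 0.8, 0.01, 0.5):
            ctx.volumes[0] = PrescribedAccessor(rgba=[0.3, 0.2, 0.1, a])
            ctx.state.sampleRGBA[...] = 0.0
            eff.volume(ctx)
            contributions.append(ctx.state.sampleRGBA[0, 3])
            layer_alphas.append(us["layerAlpha"][0])
        assert contributions[:3] == [0.0, 0.0, 0.0]
        assert layer_alphas[0] == pytest.approx(0.8)
        assert layer_alphas[1] == pytest.approx(0.96)
        assert layer_alphas[2] == 0.0  # reset on peel
        assert us["currentLayer"][0] == 1
        assert contributions[3] == pytest.approx(0.5)

    def test_peeling_reveals_inner_shell(self, shell_volume, shell_tf,
                                         head_on_camera):
        """wantedLayer=1 center rays match rendering the core alone."""
        settings = vx.RenderSettings(step=0.008, background=(0, 0, 0, 1))
        peeled = vx.render(
            vx.Scene([vx.VolumeNode(shell_volume, shell_tf,
                                    effect=opacity_peeling(wanted_layer=1))]),
            head_on_camera, settings)
        inner_only = ScalarVolume(
            np.where(shell_volume.values == 0.5, 0.0, shell_volume.values),
            scalar_range=(0.0, 1.0))
        plain = vx.render(vx.Scene([vx.VolumeNode(inner_only, shell_tf)]),
                          head_on_camera, settings)
        bundle = vx.generate_rays(head_on_camera, shell_volume.bbox)
        center = np.array([0.5, 0.5, 0.5])
        oc = bundle.start - center
        b = np.sum(oc * bundle.dir, axis=1)
        miss = np.sqrt(np.sum(oc * oc, axis=1) - b * b)
        central = (miss < 0.075).reshape(64, 64)  # rays well inside the core
        assert central.sum() > 20
        np.testing.assert_allclose(peeled.rgba[central], plain.rgba[central],
                                   atol=1e-6)

    def test_more_layers_never_increase_alpha(self, shell_volume, shell_tf,
                                              head_on_camera):
        settings = vx.RenderSettings(background=(0, 0, 0, 0))
        alphas = []
        for wanted in (0, 1, 2):
            img = vx.render(
                vx.Scene([vx.VolumeNode(shell_volume, shell_tf,
                                        effect=opacity_peeling(wanted))]),
                head_on_camera, settings)
            alphas.append(img.rgba[32, 32, 3])
        assert alphas[0] >= alphas[1] >= alphas[2]


# ---------------------------------------------------------------------------
# decluttering


class TestDeclutter:
    def _two_volume_scene(self, base_vol, base_tf, mask_tf):
        mask = ScalarVolume(np.full(base_vol.dims, 0.5), scalar_range=(0, 1))
        return vx.Scene([
            vx.VolumeNode(base_vol, base_tf),
            vx.VolumeNode(mask, mask_tf, effect=declutter()),
        ])

    def test_identity_mask_is_noop(self, sphere_volume, sphere_tf,
                                   head_on_camera):
        plain = vx.render(vx.Scene([vx.VolumeNode(sphere_volume, sphere_tf)]),
                          head_on_camera, vx.RenderSettings())
        ident = TransferFunction.constant(1, 1, 1, 1)
        masked = vx.render(self._two_volume_scene(sphere_volume, sphere_tf,
                                                  ident),
                           head_on_camera, vx.RenderSettings())
        np.testing.assert_array_equal(plain.rgba, masked.rgba)

    def test_zero_mask_annihilates(self, sphere_volume, sphere_tf,
                                   head_on_camera):
        zero = TransferFunction.constant(0, 0, 0, 0)
        settings = vx.RenderSettings(background=(0.2, 0.3, 0.4, 1.0))
        masked = vx.render(self._two_volume_scene(sphere_volume, sphere_tf,
                                                  zero),
                           head_on_camera, settings)
        assert (masked.rgba == np.array([0.2, 0.3, 0.4, 1.0])).all()

    def test_componentwise_product(self):
        eff = declutter()
        ctx = make_ctx([PrescribedAccessor(rgba=[0.5, 0.5, 0.5, 0.5])],
                       pos=[[0.5, 0.5, 0.5]])
        ctx.state.sampleRGBA[...] = [1.0, 0.2, 0.0, 0.8]
        eff.volume(ctx)
        np.testing.assert_allclose(ctx.state.sampleRGBA[0],
                                   [0.5, 0.1, 0.0, 0.4])


# ---------------------------------------------------------------------------
# chroma-depth family


class TestChromaDepth:
    def _ctx_at(self, pos, tf_alpha=0.7):
        vol = ScalarVolume(np.full((8, 8, 8), 0.5), scalar_range=(0, 1))
        tf = TransferFunction([[0, 1, 0, 0], [1, 0, 0, 1]],
                              [[0, tf_alpha]])
        acc = VolumeAccessor(vol, tf)
        return make_ctx([acc], pos=pos, cam=(0.5, 0.5, 2.0))

    def test_nearest_point_gets_tf_zero_color(self):
        ctx = self._ctx_at([[0.5, 0.5, 1.0]])  # nearest box point to camera
        chroma_depth().volume(ctx)
        np.testing.assert_allclose(ctx.state.sampleRGBA[0, :3], [1, 0, 0],
                                   atol=1e-12)

    def test_farthest_corner_gets_tf_one_color(self):
        ctx = self._ctx_at([[0.0, 0.0, 0.0]])  # farthest corner from camera
        chroma_depth().volume(ctx)
        np.testing.assert_allclose(ctx.state.sampleRGBA[0, :3], [0, 0, 1],
                                   atol=1e-12)

    def test_alpha_comes_from_intensity_not_depth(self):
        ctx = self._ctx_at([[0.5, 0.5, 1.0]], tf_alpha=0.0)
        chroma_depth().volume(ctx)
        assert ctx.state.sampleRGBA[0, 3] == 0.0

    def test_constant_color_tf_equals_default_render(self, head_on_camera):
        vol_spec = PhantomSpec("sphere", dims=(32, 32, 32),
                               params={"radius": 0.3, "edge_width": 0.1})
        vol = make_sphere_phantom(vol_spec)
        tf = TransferFunction([[0, 0.2, 0.5, 0.9], [1, 0.2, 0.5, 0.9]],
                              [[0, 0], [1, 0.5]])
        plain = vx.render(vx.Scene([vx.VolumeNode(vol, tf)]), head_on_camera,
                          vx.RenderSettings())
        depth = vx.render(vx.Scene([vx.VolumeNode(vol, tf,
                                                  effect=chroma_depth())]),
                          head_on_camera, vx.RenderSettings())
        np.testing.assert_allclose(plain.rgba, depth.rgba, atol=1e-12)

    def test_preset_variants_register(self):
        assert pseudo_chroma_depth().name == "pseudo_chroma_depth"
        assert aerial_perspective().name == "aerial_perspective"
        assert make_effect("pseudo_chroma_depth").volume is not None


# ---------------------------------------------------------------------------
# edge enhancement


class TestEdgeEnhance:
    @staticmethod
    def _ramp_accessor(direction=(1.0, 0.0, 0.0)):
        spec = PhantomSpec("ramp", dims=(32, 32, 32),
                           params={"direction": list(direction)})
        vol = make_ramp_phantom(spec)
        tf = TransferFunction.grayscale_ramp()  # alpha = intensity
        return VolumeAccessor(vol, tf)

    def test_gradient_parallel_to_ray_gives_zero(self):
        acc = self._ramp_accessor()
        eff = edge_enhance(grad_step=0.05)
        ctx = make_ctx([acc], pos=[[0.5, 0.5, 0.5]], ray_dir=(1, 0, 0))
        eff.volume(ctx)
        assert ctx.state.sampleRGBA[0, 3] == 0.0

    def test_perpendicular_strong_gradient_saturates_red(self):
        acc = self._ramp_accessor()
        eff = edge_enhance(grad_step=0.04)  # |g| = 0.08 >= step_max
        ctx = make_ctx([acc], pos=[[0.5, 0.5, 0.5]], ray_dir=(0, 0, -1))
        eff.volume(ctx)
        np.testing.assert_allclose(ctx.state.sampleRGBA[0], [1, 0, 0, 1],
                                   atol=1e-12)

    def test_45_degree_ramp_matches_closed_form(self):
        h = 0.05
        acc = self._ramp_accessor()
        eff = edge_enhance(grad_step=h)
        d = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        pts = np.stack([np.linspace(0.25, 0.75, 9)] * 3, axis=1)
        ctx = make_ctx([acc], pos=pts, ray_dir=d)
        eff.volume(ctx)
        g_mag = 2 * h  # un-divided central difference of a unit-slope ramp
        want = vx.smoothstep(0.02, 0.06, g_mag * (1 - np.cos(np.pi / 4)))
        np.testing.assert_allclose(ctx.state.sampleRGBA[:, 3], want, atol=1e-9)

    def test_alpha_invariant_to_gradient_sign_flip(self):
        eff = edge_enhance(grad_step=0.03)
        for direction in ((1, 0, 0), (-1, 0, 0)):
            acc = self._ramp_accessor()
            if direction[0] < 0:
                flipped = ScalarVolume(1.0 - acc.volume.values,
                                       scalar_range=(0, 1))
                acc = VolumeAccessor(flipped, acc.tf)
            ctx = make_ctx([acc], pos=[[0.5, 0.5, 0.5]], ray_dir=(0, 0, -1))
            eff.volume(ctx)
            if direction == (1, 0, 0):
                base = ctx.state.sampleRGBA[0, 3]
            else:
                assert ctx.state.sampleRGBA[0, 3] == pytest.approx(base,
                                                                   abs=1e-12)

    def test_low_alpha_samples_are_skipped(self):
        acc = self._ramp_accessor()
        eff = edge_enhance(sample_threshold=0.95, grad_step=0.04)
        ctx = make_ctx([acc], pos=[[0.5, 0.5, 0.5]], ray_dir=(0, 0, -1))
        eff.volume(ctx)
        assert (ctx.state.sampleRGBA == 0).all()


# ---------------------------------------------------------------------------
# Blinn-Phong volume shader


class TestBlinnPhongShader:
    def test_constant_interior_falls_back_to_ambient(self):
        vol = ScalarVolume(np.full((8, 8, 8), 1.0), scalar_range=(0, 2))
        tf = TransferFunction.constant(0.8, 0.6, 0.4, 0.5)
        acc = VolumeAccessor(vol, tf)
        eff = blinn_phong_shader(k_ambient=0.3)
        ctx = make_ctx([acc], pos=[[0.5, 0.5, 0.5]])
        eff.volume(ctx)
        np.testing.assert_allclose(ctx.state.sampleRGBA[0],
                                   [0.24, 0.18, 0.12, 0.5], atol=1e-12)

    def test_brightest_on_lit_hemisphere(self, sphere_volume, sphere_tf):
        acc = VolumeAccessor(sphere_volume, sphere_tf)
        eff = blinn_phong_shader(light_dir=(0, 0, 1), k_specular=0.0,
                                 grad_step=0.02)
        # surface points on the +z and -z hemisphere
        zs = [0.5 + 0.35, 0.5 - 0.35]
        bright = []
        for z in zs:
            ctx = make_ctx([acc], pos=[[0.5, 0.5, z]], ray_dir=(0, 0, -1))
            eff.volume(ctx)
            bright.append(ctx.state.sampleRGBA[0, :3].sum())
        assert bright[0] > bright[1]

    def test_lit_sample_matches_formula_oracle(self, sphere_volume, sphere_tf):
        acc = VolumeAccessor(sphere_volume, sphere_tf)
        ka, kd, ks, p = 0.25, 0.6, 0.15, 8.0
        h = 0.02
        eff = blinn_phong_shader(light_dir=(0, 0, 1), k_ambient=ka,
                                 k_diffuse=kd, k_specular=ks, shininess=p,
                                 grad_step=h)
        pos = np.array([[0.5, 0.5, 0.85]])
        cam = np.array([0.5, 0.5, 2.0])
        ctx = make_ctx([acc], pos=pos, cam=cam)
        eff.volume(ctx)
        g = vx.compute_gradient(sphere_volume, pos[0], h)
        base = vx.sample_volume_with_tf(sphere_volume, sphere_tf, pos[0])
        view = cam - pos[0]
        view /= np.linalg.norm(view)
        want = vx.blinn_phong(g.direction, (0, 0, 1), view, base, k_ambient=ka,
                              k_diffuse=kd, k_specular=ks, shininess=p)
        np.testing.assert_allclose(ctx.state.sampleRGBA[0], want, atol=1e-12)

    def test_chains_with_edge_enhance(self, sphere_volume, sphere_tf,
                                      head_on_camera):
        scene = vx.Scene([
            vx.VolumeNode(sphere_volume, sphere_tf,
                          effect=blinn_phong_shader(grad_step=0.02)),
            vx.VolumeNode(sphere_volume, sphere_tf,
                          effect=edge_enhance(grad_step=0.02)),
        ])
        img = vx.render(scene, head_on_camera, vx.RenderSettings())
        assert np.isfinite(img.rgba).all()


# ---------------------------------------------------------------------------
# blood flow animation


class TestBloodFlow:
    def test_zero_sample_time_zero_gives_baseline(self):
        eff = blood_flow()
        ctx = make_ctx([PrescribedAccessor(raw=0.0)], pos=[[0.5, 0.5, 0.5]])
        ctx.state.sampleRGBA[...] = [1.0, 1.0, 1.0, 0.6]
        eff.volume(ctx)
        np.testing.assert_allclose(ctx.state.sampleRGBA[0],
                                   [0.75, 0.75, 0.75, 0.6])

    def test_factor_bounded_half_to_one(self, rng):
        eff = blood_flow()
        raws = rng.uniform(0, 1, 200)
        for t in (0.0, 1.3, 7.7):
            ctx = make_ctx([PrescribedAccessor(raw=raws)],
                           pos=np.tile([0.5, 0.5, 0.5], (200, 1)), time=t)
            ctx.state.sampleRGBA[...] = 1.0
            eff.volume(ctx)
            rgb = ctx.state.sampleRGBA[:, :3]
            assert (rgb >= 0.5 - 1e-12).all() and (rgb <= 1.0 + 1e-12).all()

    def test_temporal_period_two_pi_over_five(self):
        from voxray.phantoms import make_tube_phantom
        spec = PhantomSpec("tube_tree", dims=(32, 32, 32))
        tube, dist = make_tube_phantom(spec)
        tf = TransferFunction([[0, 0.9, 0.2, 0.1], [1, 0.9, 0.2, 0.1]],
                              [[0, 0], [1, 0.8]])
        scene = vx.Scene([
            vx.VolumeNode(tube, tf),
            vx.VolumeNode(dist, TransferFunction.grayscale_ramp(),
                          effect=blood_flow()),
        ])
        cam = vx.Camera(position=(0.5, 0.5, 2.2), target=(0.5, 0.5, 0.5),
                        width=32, height=32, vfov=40)
        t0 = 0.4
        a = vx.render(scene, cam, vx.RenderSettings(time=t0))
        b = vx.render(scene, cam, vx.RenderSettings(time=t0 + 2 * np.pi / 5))
        np.testing.assert_allclose(a.rgba, b.rgba, atol=1e-9)
        c = vx.render(scene, cam, vx.RenderSettings(time=t0 + 0.3))
        assert np.abs(a.rgba - c.rgba).max() > 1e-6  # animation is visible
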