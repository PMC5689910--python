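"""Ray-caster: fusion, compositing, surface detection, shading, clipping,
and full-image oracle comparisons."""

import numpy as np
import pytest

from fuse4d.render import (
    Camera,
    ImageLayer,
    Scene,
    SurfaceLayer,
    composite_front_to_back,
    detect_surface_crossing,
    fuse_sample,
    in_roi,
    mask_visibility,
    render,
    shade_blinn_phong,
)
from fuse4d.volume import (
    BinaryVolume,
    Grid3D,
    ScalarVolume,
    TransferFunction,
    WindowLevel,
    tf_from_window,
)

from oracles import dense_integrator, over_back_to_front


def sphere_volume(grid, center, radius):
    idx = np.indices(grid.dims).reshape(3, -1).T.astype(float)
    pts = grid.voxel_to_world(idx)
    m = (np.linalg.norm(pts - np.asarray(center), axis=1) <= radius).reshape(grid.dims)
    return m


class TestFuseSample:
    def test_singleton_identity(self):
        C, a = fuse_sample([[(0.2, 0.4, 0.6)]], [[0.5]], [3.0])
        assert np.allclose(C, [[0.2, 0.4, 0.6]]) and np.allclose(a, 0.5)

    def test_equal_weight_mean(self):
        C, a = fuse_sample(
            np.array([[(1.0, 0, 0)], [(0, 0, 1.0)]]),
            np.array([[0.4], [0.8]]),
            [1.0, 1.0],
        )
        assert np.allclose(C[0], [0.5, 0, 0.5])
        assert np.allclose(a, 0.6)

    def test_weight_normalization(self):
        cols = np.array([[(0.9, 0.1, 0.3)], [(0.2, 0.8, 0.5)]])
        alphas = np.array([[0.3], [0.7]])
        C1, a1 = fuse_sample(cols, alphas, [2.0, 2.0])
        C2, a2 = fuse_sample(cols, alphas, [0.5, 0.5])
        assert np.allclose(C1, C2) and np.allclose(a1, a2)

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError, match="zero"):
            fuse_sample(np.zeros((2, 1, 3)), np.zeros((2, 1)), [0.0, 0.0])


class TestCompositing:
    def test_single_opaque_sample(self):
        C, A = composite_front_to_back([((0.3, 0.6, 0.9), 1.0)])
        assert np.allclose(C, [0.3, 0.6, 0.9]) and A == 1.0

    def test_two_half_transparent(self):
        c1, c2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        C, A = composite_front_to_back([(c1, 0.5), (c2, 0.5)])
        assert A == pytest.approx(0.75)
        assert np.allclose(C, 0.5 * c1 + 0.25 * c2)

    def test_matches_back_to_front_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            samples = [
                (rng.random(3), rng.random()) for _ in range(rng.integers(1, 50))
            ]
            Cf, Af = composite_front_to_back(samples, early_termination=False)
            Cb, Ab = over_back_to_front(samples)
            assert np.max(np.abs(Cf - Cb)) < 1e-9
            assert abs(Af - Ab) < 1e-9

    def test_early_termination_tolerance(self):
        rng = np.random.default_rng(9)
        samples = [(rng.random(3), rng.uniform(0.3, 0.9)) for _ in range(100)]
        C1, A1 = composite_front_to_back(samples, early_termination=True)
        C2, A2 = composite_front_to_back(samples, early_termination=False)
        assert np.max(np.abs(C1 - C2)) < 1e-2


class TestSurfaceCrossing:
    def _binary_layer(self):
        g = Grid3D(np.zeros(3), np.ones(3), (10, 10, 10))
        m = np.zeros((10, 10, 10), np.uint8)
        m[:5] = 1
        return SurfaceLayer(BinaryVolume(g, [m], name="half"))

    def test_midpoint_crossing(self):
        layer = self._binary_layer()
        # indicator goes 1 -> 0 across the x=4..5 face; crossing at x=4.5
        res = detect_surface_crossing(layer, np.array([4.0, 5, 5]), np.array([5.0, 5, 5]))
        assert res is not None
        frac, normal = res
        assert frac == pytest.approx(0.5)
        assert np.allclose(normal, [1.0, 0, 0], atol=1e-6)  # outward from the slab

    def test_both_inside_none(self):
        layer = self._binary_layer()
        assert detect_surface_crossing(
            layer, np.array([1.0, 5, 5]), np.array([2.0, 5, 5])
        ) is None

    def test_dose_inverse_interpolation(self):
        g = Grid3D(np.zeros(3), np.ones(3), (4, 4, 4))
        ramp = np.fromfunction(lambda i, j, k: 10.0 * i, (4, 4, 4))
        from fuse4d.volume import DoseVolume

        layer = SurfaceLayer(DoseVolume(g, ramp), iso=37.5 / 1.5)
        # dose 30 Gy at p0 and 40 Gy (ramp=10*x) — doses 20 and 30 at x=2,3
        res = detect_surface_crossing(
            layer, np.array([2.0, 1, 1]), np.array([3.0, 1, 1])
        )
        assert res is not None
        assert res[0] == pytest.approx(0.5)

    def test_fraction_formula(self):
        # field 30 at p0, 40 at p1, iso 37.5 -> fraction 0.75
        f0, f1, iso = 30.0, 40.0, 37.5
        assert (f0 - iso) / (f0 - f1) == pytest.approx(0.75)
        g = Grid3D(np.zeros(3), np.ones(3), (6, 1, 1))
        from fuse4d.volume import DoseVolume

        vals = np.arange(6, dtype=float).reshape(6, 1, 1) * 10.0
        layer = SurfaceLayer(DoseVolume(g, vals), iso=37.5)
        res = detect_surface_crossing(layer, np.array([3.0, 0, 0]), np.array([4.0, 0, 0]))
        assert res[0] == pytest.approx(0.75)


class TestShading:
    def test_perpendicular_light(self):
        rgb = shade_blinn_phong(
            [0, 0, 1], [1, 0, 0], [0, 0, 1], [0.5, 0.5, 0.5],
            ambient=0.2, diffuse=0.8, specular=0.0,
        )
        assert np.allclose(rgb, 0.2 * np.array([0.5, 0.5, 0.5]))

    def test_full_diffuse(self):
        rgb = shade_blinn_phong(
            [0, 0, 1], [0, 0, 1], [0, 0, 1], [0.9, 0.4, 0.1],
            ambient=0.1, diffuse=0.9, specular=0.0,
        )
        assert np.allclose(rgb, np.minimum(1.0, np.array([0.9, 0.4, 0.1])))

    def test_clamped_on_random_inputs(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            rgb = shade_blinn_phong(
                rng.normal(size=3), rng.normal(size=3) + 1e-3,
                rng.normal(size=3) + 1e-3, rng.random(3),
                ambient=rng.random(), diffuse=rng.random(),
                specular=rng.random(), shininess=rng.uniform(1, 64),
            )
            assert np.all(rgb >= 0) and np.all(rgb <= 1)

    def test_degenerate_normal_returns_base(self):
        base = [0.3, 0.5, 0.7]
        rgb = shade_blinn_phong([0, 0, 0], [0, 0, 1], [0, 0, 1], base)
        assert np.allclose(rgb, base)


class TestClippingAndMasks:
    def _scene(self, roi=((0, 1), (0, 1), (0, 1))):
        g = Grid3D(np.zeros(3), np.ones(3), (10, 10, 10))
        return Scene(reference=g, roi=np.asarray(roi, float))

    def test_full_box_inside(self):
        s = self._scene()
        assert in_roi(s, np.array([4.0, 4.0, 4.0]))

    def test_on_clip_plane_is_inside(self):
        s = self._scene()
        assert in_roi(s, np.array([-0.5, 0.0, 0.0]))  # exactly on the box face

    def test_outside_shrunk_roi(self):
        s = self._scene(roi=((0.4, 0.6), (0, 1), (0, 1)))
        # 0.3 of the x-extent: x = -0.5 + 0.3*10 = 2.5
        assert not in_roi(s, np.array([2.5, 4.0, 4.0]))

    def test_mask_visibility_semantics(self):
        g = Grid3D(np.zeros(3), np.ones(3), (10, 10, 10))
        m1 = np.zeros((10, 10, 10), np.uint8); m1[:3] = 1
        m2 = np.zeros((10, 10, 10), np.uint8); m2[7:] = 1
        masks = {
            "a": BinaryVolume(g, [m1], name="a"),
            "b": BinaryVolume(g, [m2], name="b"),
        }
        vol = ScalarVolume(g, [np.zeros((10, 10, 10))])
        tf = tf_from_window(WindowLevel(0, 1), 1.0, (1, 1, 1))
        unmasked = ImageLayer(vol, tf)
        masked = ImageLayer(vol, tf, masks=["a", "b"])
        p_in_a = np.array([1.0, 5, 5])
        p_in_none = np.array([5.0, 5, 5])
        assert mask_visibility(unmasked, p_in_none, masks)
        assert mask_visibility(masked, p_in_a, masks)
        assert not mask_visibility(masked, p_in_none, masks)
        assert mask_visibility(masked, np.array([8.0, 5, 5]), masks)


def make_sphere_scene(shaded=False, opacity=1.0, **scene_kw):
    g = Grid3D(np.zeros(3), np.ones(3), (40, 40, 40))
    m = sphere_volume(g, (19.5, 19.5, 19.5), 12.0)
    sphere = BinaryVolume(g, [m.astype(np.uint8)], name="sphere")
    layer = SurfaceLayer(sphere, color=(0.2, 0.9, 0.4, opacity), shaded=shaded)
    scene = Scene(reference=g, surface_layers=[layer], **scene_kw)
    cam = Camera(
        eye=np.array([19.5, -150.0, 19.5]),
        look_at=np.array([19.5, 19.5, 19.5]),
        up=np.array([0.0, 0.0, 1.0]),
        fov_deg=25.0,
        width=33,
        height=33,
    )
    return scene, cam


class TestRender:
    def test_empty_scene_is_background(self):
        g = Grid3D(np.zeros(3), np.ones(3), (10, 10, 10))
        scene = Scene(reference=g, background=(0.1, 0.2, 0.3))
        cam = Camera(eye=np.array([5.0, -50, 5]), look_at=np.array([5.0, 5, 5]),
                     width=8, height=8)
        res = render(scene, cam)
        assert np.allclose(res.rgba[..., :3], [0.1, 0.2, 0.3])
        assert np.allclose(res.rgba[..., 3], 0.0)
        assert not np.isfinite(res.depth).any()

    def test_zero_extent_roi_is_background(self):
        scene, cam = make_sphere_scene()
        scene.roi = np.array([[0.0, 1e-9], [0, 1], [0, 1]])
        res = render(scene, cam)
        assert np.allclose(res.rgba[..., 3], 0.0, atol=1e-6)

    def test_center_pixel_front_pole_shading(self):
        """The centre pixel of a head-on view of an opaque shaded sphere
        shows the analytic front-pole normal shaded by the scene lights."""
        scene, cam = make_sphere_scene(shaded=True)
        scene.light_dir = np.array([0.0, -1.0, 0.0])  # toward the camera side
        res = render(scene, cam)
        centre = res.rgba[16, 16, :3]
        normal = np.array([0.0, -1.0, 0.0])  # analytic front-pole normal
        view = np.array([0.0, -1.0, 0.0])
        expected = shade_blinn_phong(
            normal, scene.light_dir, view, np.array([0.2, 0.9, 0.4]),
            scene.ambient, scene.diffuse, scene.specular, scene.shininess,
        )
        assert np.max(np.abs(centre - expected)) < 1e-3

    def test_depth_matches_analytic_sphere(self):
        scene, cam = make_sphere_scene()
        res = render(scene, cam)
        d = res.depth[16, 16]
        # analytic: eye at y=-150, surface at y=7.5 -> distance 157.5 - eps
        assert abs(d - (19.5 - 12.0 + 150.0)) < scene.step_size() + 0.5

    def test_nested_opaque_surfaces_outer_wins(self):
        g = Grid3D(np.zeros(3), np.ones(3), (40, 40, 40))
        outer = sphere_volume(g, (19.5, 19.5, 19.5), 14.0)
        inner = sphere_volume(g, (19.5, 19.5, 19.5), 7.0)
        layers = [
            SurfaceLayer(BinaryVolume(g, [inner.astype(np.uint8)], name="in"),
                         color=(1.0, 0.0, 0.0, 1.0), shaded=False),
            SurfaceLayer(BinaryVolume(g, [outer.astype(np.uint8)], name="out"),
                         color=(0.0, 0.0, 1.0, 1.0), shaded=False),
        ]
        scene = Scene(reference=g, surface_layers=layers)
        cam = Camera(eye=np.array([19.5, -150.0, 19.5]),
                     look_at=np.array([19.5, 19.5, 19.5]), width=17, height=17)
        res = render(scene, cam)
        covered = res.rgba[..., 3] > 0.5
        assert covered.any()
        assert np.allclose(res.rgba[covered][:, :3], [0.0, 0.0, 1.0], atol=1e-6)

    def test_transparent_surface_attenuates_volume(self):
        g = Grid3D(np.zeros(3), np.ones(3), (40, 40, 40))
        m = sphere_volume(g, (19.5, 19.5, 19.5), 10.0)
        vol = ScalarVolume(g, [np.full(g.dims, 100.0)])
        tf = TransferFunction([0.0, 100.0], [[1, 1, 1, 0.0], [1, 1, 1, 0.02]])
        layer = ImageLayer(vol, tf)
        surf = SurfaceLayer(BinaryVolume(g, [m.astype(np.uint8)], name="s"),
                            color=(1.0, 0.0, 0.0, 0.5), shaded=False)
        scene = Scene(reference=g, image_layers=[layer], surface_layers=[surf],
                      early_termination=False)
        cam = Camera(eye=np.array([19.5, -150.0, 19.5]),
                     look_at=np.array([19.5, 19.5, 19.5]), width=9, height=9)
        res = render(scene, cam)
        centre = res.rgba[4, 4]
        edge = res.rgba[0, 0]
        # red surface contributes at the centre but not at the corner
        assert centre[0] > edge[0] + 0.2

    def test_disabling_layer_equals_removing_it(self, small_phantom):
        b = small_phantom
        tf_ct = tf_from_window(WindowLevel(-1000, 200), 0.3, (1, 1, 1))
        tf_pet = tf_from_window(WindowLevel(1.5, 6.0), 0.7, (1, 0.3, 0))
        cam = Camera(eye=np.array([0, -220.0, 0]), look_at=np.zeros(3),
                     width=24, height=24)
        both = Scene(
            reference=b.planning_ct.grid,
            image_layers=[
                ImageLayer(b.planning_ct, tf_ct, name="ct"),
                ImageLayer(b.pet4d, tf_pet, name="pet", enabled=False),
            ],
        )
        only = Scene(
            reference=b.planning_ct.grid,
            image_layers=[ImageLayer(b.planning_ct, tf_ct, name="ct")],
        )
        # identical step sizes so the marching grids agree
        both.step_mm = only.step_mm = 0.5
        r1 = render(both, cam)
        r2 = render(only, cam)
        assert np.array_equal(r1.rgba, r2.rgba)

    def test_empty_mask_equals_disabled(self, small_phantom):
        b = small_phantom
        tf_pet = tf_from_window(WindowLevel(1.5, 6.0), 0.7, (1, 0.3, 0))
        empty = BinaryVolume(
            b.planning_ct.grid, [np.zeros(b.planning_ct.grid.dims, np.uint8)],
            name="empty",
        )
        cam = Camera(eye=np.array([0, -220.0, 0]), look_at=np.zeros(3),
                     width=24, height=24)
        masked = Scene(
            reference=b.planning_ct.grid,
            image_layers=[ImageLayer(b.pet4d, tf_pet, name="pet", masks=["empty"])],
            masks={"empty": empty},
            step_mm=1.0,
        )
        disabled = Scene(
            reference=b.planning_ct.grid,
            image_layers=[ImageLayer(b.pet4d, tf_pet, name="pet", enabled=False)],
            step_mm=1.0,
        )
        assert np.array_equal(render(masked, cam).rgba, render(disabled, cam).rgba)

    def test_time_bin_changes_only_4d_covered_pixels(self, small_phantom):
        b = small_phantom
        tf_ct = tf_from_window(WindowLevel(-1000, 200), 0.3, (1, 1, 1))
        tf_pet = tf_from_window(WindowLevel(1.5, 6.0), 0.7, (1, 0.3, 0))
        cam = Camera(eye=np.array([0, -220.0, 0]), look_at=np.zeros(3),
                     width=32, height=32)
        layers = [
            ImageLayer(b.planning_ct, tf_ct, name="ct"),
            ImageLayer(b.pet4d, tf_pet, name="pet"),
        ]

        def render_at(t):
            s = Scene(reference=b.planning_ct.grid, image_layers=layers,
                      time_bin=t, step_mm=1.0, early_termination=False)
            return render(s, cam)

        r0, r1 = render_at(0), render_at(1)
        changed = np.any(r0.rgba != r1.rgba, axis=-1)
        assert changed.any()  # the breathing PET blob moved
        # pixels whose rays never cross the PET grid are bit-identical
        o, d = cam.rays()
        lo = b.pet4d.grid.origin - b.pet4d.grid.spacing / 2
        hi = (
            b.pet4d.grid.origin
            + (np.array(b.pet4d.grid.dims) - 1) * b.pet4d.grid.spacing
            + b.pet4d.grid.spacing / 2
        )
        from oracles import ray_box_intersect

        misses = np.array(
            [ray_box_intersect(o[i], d[i], lo, hi)[0]
             > ray_box_intersect(o[i], d[i], lo, hi)[1] for i in range(len(o))]
        ).reshape(32, 32)
        assert not changed[misses].any()

    def test_unknown_mask_errors(self, small_phantom):
        b = small_phantom
        tf = tf_from_window(WindowLevel(-1000, 200), 0.3, (1, 1, 1))
        with pytest.raises(KeyError, match="ghost"):
            Scene(
                reference=b.planning_ct.grid,
                image_layers=[ImageLayer(b.planning_ct, tf, masks=["ghost"])],
            )


class TestRenderOracle:
    @pytest.mark.parametrize("kind", ["sphere", "ramp"])
    def test_single_layer_matches_dense_integrator(self, kind):
        g = Grid3D(np.zeros(3), np.array([2.0, 2.0, 2.0]), (20, 20, 20))
        if kind == "sphere":
            data = sphere_volume(g, (19.0, 19.0, 19.0), 14.0).astype(float) * 80.0
        else:
            data = np.fromfunction(lambda i, j, k: 4.0 * i + 2.0 * k, g.dims)
        vol = ScalarVolume(g, [data])
        tf = tf_from_window(WindowLevel(10.0, 70.0), 0.7, (0.9, 0.5, 0.2))
        scene = Scene(
            reference=g,
            image_layers=[ImageLayer(vol, tf)],
            background=(0.05, 0.05, 0.1),
            early_termination=False,
            step_mm=1.0,
        )
        cam = Camera(eye=np.array([19.0, -120.0, 25.0]),
                     look_at=np.array([19.0, 19.0, 19.0]), fov_deg=30.0,
                     width=16, height=16)
        res = render(scene, cam)
        oracle = dense_integrator(
            data, g, tf.values, tf.colors, cam, 1.0, background=(0.05, 0.05, 0.1)
        )
        assert np.max(np.abs(res.rgba - oracle)) < 1e-3


class TestMixedResolution:
    def test_coarse_native_equals_preupsampled(self):
        """Rendering a 4-mm volume in its own grid equals rendering a 1-mm
        trilinear upsample of it when the ray samples coincide with the fine
        voxel centres — resampling-free fusion, verified behaviorally."""
        rng = np.random.default_rng(12)
        coarse_g = Grid3D(np.array([5.0, -3.0, 2.0]), np.full(3, 4.0), (8, 8, 8))
        coarse = rng.uniform(0, 100, (8, 8, 8))
        fine_g = Grid3D(coarse_g.origin - 1.5, np.ones(3), (32, 32, 32))
        idx = np.indices((32, 32, 32)).reshape(3, -1).T.astype(float)
        cvol = ScalarVolume(coarse_g, [coarse])
        fine_vals, _ = cvol.sample(fine_g.voxel_to_world(idx))
        fine = fine_vals.reshape(32, 32, 32)
        fvol = ScalarVolume(fine_g, [fine])

        tf = tf_from_window(WindowLevel(20.0, 80.0), 0.7, (1.0, 0.4, 0.1))
        centre = coarse_g.origin + np.array([14.0, 14.0, 0.0])
        cam = Camera(
            eye=np.array([centre[0], centre[1], coarse_g.origin[2] - 100.0]),
            look_at=np.array([centre[0], centre[1], coarse_g.origin[2]]),
            up=np.array([0.0, 1.0, 0.0]),
            width=32, height=32,
            orthographic=True, ortho_height=32.0,
        )

        def render_layer(vol):
            scene = Scene(reference=fine_g, image_layers=[ImageLayer(vol, tf)],
                          step_mm=1.0, early_termination=False)
            return render(scene, cam).rgba

        img_coarse = render_layer(cvol)
        img_fine = render_layer(fvol)
        assert np.max(np.abs(img_coarse - img_fine)) < 1e-3
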