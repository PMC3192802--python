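"""Scene construction, membership queries and geometric invariants."""

import json
import math

import numpy as np
import pytest

from dendrocrowd.brownian import Scene, SpineGeometry, build_scene, make_calibrated_scene
from dendrocrowd.reduced import calibrate_geometry


class TestSceneValidation:
    def test_bare_cylinder_membership(self):
        scene = Scene(cylinder_radius=0.5, cylinder_length=10.0)
        pts = np.array(
            [
                [5.0, 0.0, 0.0],
                [5.0, 0.3, 0.39],
                [5.0, 0.4, 0.4],   # r > 0.5 → outside
                [-0.1, 0.0, 0.0],
                [10.1, 0.0, 0.0],
            ]
        )
        np.testing.assert_array_equal(
            scene.contains(pts), [True, True, False, False, False]
        )

    def test_barriers_must_be_inside_and_sorted(self):
        with pytest.raises(ValueError, match="inside"):
            Scene(0.5, 10.0, barrier_positions=(0.0,), hole_radius=(0.1,))
        with pytest.raises(ValueError, match="increasing"):
            Scene(0.5, 10.0, barrier_positions=(3.0, 2.0), hole_radius=(0.1, 0.1))
        with pytest.raises(ValueError, match="one hole radius"):
            Scene(0.5, 10.0, barrier_positions=(3.0,), hole_radius=())

    def test_hole_must_fit_inside_cross_section(self):
        with pytest.raises(ValueError):
            Scene(0.5, 10.0, barrier_positions=(5.0,), hole_radius=(0.6,))
        with pytest.raises(ValueError, match="fully inside"):
            Scene(
                0.5, 10.0,
                barrier_positions=(5.0,),
                hole_radius=(0.2,),
                hole_centers=((0.4, 0.0),),
            )

    def test_window_end_requires_radius(self):
        with pytest.raises(ValueError, match="window"):
            Scene(0.5, 10.0, end_conditions=("window", "reflecting"))

    def test_spine_membership_covers_neck_and_head(self):
        spine = SpineGeometry(attach_position=5.0, neck_radius=0.3,
                              neck_length=0.2, head_radius=0.4)
        scene = Scene(0.5, 10.0, spine=spine)
        z_base = math.sqrt(0.5**2 - 0.3**2)
        inside_neck = [5.0, 0.0, z_base + 0.1]
        inside_head = [5.0, 0.0, z_base + 0.2 + math.sqrt(0.4**2 - 0.3**2)]
        outside = [5.0, 0.0, z_base + 0.2 + 2 * 0.4 + 0.3]
        beside_neck = [5.0, 0.35, z_base + 0.1]
        assert scene.contains(np.array(inside_neck))
        assert scene.contains(np.array(inside_head))
        assert not scene.contains(np.array(outside))
        assert not scene.contains(np.array(beside_neck))

    def test_json_listing_is_parseable(self):
        scene = Scene(0.5, 10.0, barrier_positions=(5.0,), hole_radius=(0.1,))
        listing = json.loads(scene.to_json())
        assert listing["cylinder_radius_um"] == 0.5
        assert len(listing["barriers"]) == 1


class TestBuildScene:
    def test_from_config_mapping(self):
        scene = build_scene(
            {
                "cylinder_radius": 0.5,
                "cylinder_length": 10.0,
                "barrier_positions": [2.0, 4.0],
                "hole_radius": [0.05, 0.05],
                "end_conditions": ["absorbing", "reflecting"],
            }
        )
        assert scene.barriers.size == 2
        assert scene.end_conditions == ("absorbing", "reflecting")

    def test_calibrated_scene_has_expected_barrier_count(self):
        spec = calibrate_geometry(0.05, 0.5)
        total = 20.0
        scene = make_calibrated_scene(spec, total)
        assert len(scene.barrier_positions) == int(total // spec.L) - 1
        np.testing.assert_allclose(np.diff(scene.barriers), spec.L, rtol=1e-9)
        np.testing.assert_allclose(scene.hole_radii, spec.eps)

    def test_randomized_hole_centers_stay_inside(self):
        spec = calibrate_geometry(0.05, 0.5)
        scene = make_calibrated_scene(
            spec, 20.0, hole_center_policy="random",
            rng=np.random.default_rng(3),
        )
        rim = np.hypot(*scene.hole_yz.T) + scene.hole_radii
        assert np.all(rim <= spec.a + 1e-12)

    def test_jittered_scene_preserves_order(self):
        spec = calibrate_geometry(0.05, 0.5)
        scene = make_calibrated_scene(
            spec, 20.0, jitter_sigma=0.2 * spec.L,
            rng=np.random.default_rng(1),
        )
        assert np.all(np.diff(scene.barriers) > 0)
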