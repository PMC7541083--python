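"""Backbone construction, Voronoi segmentation and the dF/F pipeline."""

import numpy as np
import pandas as pd
import pytest

from aplocal import (
    Backbone,
    StandardBackbone,
    align_recordings,
    assign_voxels,
    build_backbone,
    compute_dff,
    exclude_noisy_nodes,
    make_synthetic_movie,
    normalized_inhibitory_effect,
    place_nodes,
    smooth_and_interpolate,
    standardize_backbones,
)


def straight_y_backbone(cal=160.0, vert=100.0, horiz=90.0):
    return build_backbone(
        {
            "peduncle_calyx": [[0, 0, 0], [0, cal, 0]],
            "vertical": [[0, 0, 0], [0, 0, vert]],
            "horizontal": [[0, 0, 0], [horiz, 0, 0]],
        }
    )


# ----------------------------------------------------------- backbone
class TestBackbone:
    def test_straight_y_lengths(self):
        bb = straight_y_backbone(100.0, 120.0, 160.0)
        assert bb.branch_lengths == pytest.approx(
            {"peduncle_calyx": 100.0, "vertical": 120.0, "horizontal": 160.0}
        )

    def test_collinear_polyline_length(self):
        pts = [[0, 0, 0], [0, 1, 0], [0, 2.5, 0], [0, 4, 0], [0, 7, 0]]
        bb = build_backbone(
            {"peduncle_calyx": pts, "vertical": [[0, 0, 0], [0, 0, 1]],
             "horizontal": [[0, 0, 0], [1, 0, 0]]}
        )
        assert bb.branch_lengths["peduncle_calyx"] == pytest.approx(7.0)

    def test_jittered_polyline_matches_summation(self, rng):
        pts = np.cumsum(rng.uniform(-1, 1, size=(12, 3)), axis=0)
        pts[0] = 0.0
        expected = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        bb = build_backbone(
            {"peduncle_calyx": pts, "vertical": [[0, 0, 0], [0, 0, 1]],
             "horizontal": [[0, 0, 0], [1, 0, 0]]}
        )
        assert bb.branch_lengths["peduncle_calyx"] == pytest.approx(expected)

    def test_disjoint_junction_rejected(self):
        with pytest.raises(ValueError, match="junction"):
            build_backbone(
                {"peduncle_calyx": [[0, 0, 0], [0, 100, 0]],
                 "vertical": [[5, 0, 0], [5, 0, 100]],
                 "horizontal": [[0, 0, 0], [90, 0, 0]]}
            )

    def test_json_round_trip(self, tmp_path):
        bb = straight_y_backbone()
        p = tmp_path / "bb.json"
        bb.to_json(p)
        back = Backbone.from_json(p)
        assert back.branch_lengths == pytest.approx(bb.branch_lengths)


class TestStandardization:
    def test_two_backbone_average(self):
        a = {"peduncle_calyx": 100.0, "vertical": 100.0, "horizontal": 90.0}
        b = {"peduncle_calyx": 120.0, "vertical": 100.0, "horizontal": 90.0}
        std, scales = standardize_backbones([a, b], spacing_um=20.0)
        assert std.branch_lengths["peduncle_calyx"] == pytest.approx(110.0)
        # first recording's node spacing is stretched by 100/110
        assert scales[0]["peduncle_calyx"] * 20.0 == pytest.approx(100.0 / 110.0 * 20.0)

    def test_single_backbone_idempotent(self):
        bb = straight_y_backbone()
        std, scales = standardize_backbones([bb])
        assert std.branch_lengths == pytest.approx(bb.branch_lengths)
        assert all(s == pytest.approx(1.0) for s in scales[0].values())
        std2, scales2 = standardize_backbones([std.branch_lengths])
        assert std2.branch_lengths == pytest.approx(std.branch_lengths)

    def test_mean_matches_independent_computation(self, rng):
        lengths = rng.uniform(80, 200, size=(6, 3))
        dicts = [
            {"peduncle_calyx": l[0], "vertical": l[1], "horizontal": l[2]}
            for l in lengths
        ]
        std, _ = standardize_backbones(dicts)
        np.testing.assert_allclose(
            [std.branch_lengths[k] for k in ("peduncle_calyx", "vertical", "horizontal")],
            lengths.mean(axis=0),
        )

    def test_mismatched_topology_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            standardize_backbones(
                [{"peduncle_calyx": 1.0, "vertical": 1.0},
                 {"peduncle_calyx": 1.0, "horizontal": 1.0}]
            )

    def test_node_placement_monotone(self):
        bb = straight_y_backbone()
        std, scales = standardize_backbones([bb], spacing_um=20.0)
        nodes = place_nodes(bb, std, scales[0])
        vert = nodes[nodes["branch"].isin(["peduncle_calyx", "vertical"])]
        z_plus_y = vert["z_um"] + (160.0 - vert["y_um"])
        np.testing.assert_allclose(
            z_plus_y, vert["distance_from_calyx_um"], atol=1e-9
        )


# ----------------------------------------------------------- Voronoi
class TestAssignVoxels:
    def test_two_node_bisection(self):
        mask = np.ones((1, 1, 10), dtype=bool)
        nodes = [[0, 0, 1.0], [0, 0, 8.0]]
        seg = assign_voxels(mask, nodes)
        assert seg.labels[0, 0, :5].tolist() == [0] * 5
        assert seg.labels[0, 0, 5:].tolist() == [1] * 5

    def test_tie_goes_to_lower_node(self):
        mask = np.ones((1, 1, 3), dtype=bool)
        seg = assign_voxels(mask, [[0, 0, 0.0], [0, 0, 2.0]])
        assert seg.labels[0, 0, 1] == 0  # voxel 1 equidistant

    def test_anisotropic_voxels(self):
        # voxel (1,0,0) sits at z=10 um when z-voxels are 10 um tall, so it
        # flips to the far node only under the anisotropic scaling
        mask = np.ones((2, 1, 1), dtype=bool)
        nodes = [[0, 0, 0], [12.0, 0, 0]]
        tall = assign_voxels(mask, nodes, voxel_size_um=(10, 1, 1))
        flat = assign_voxels(mask, nodes, voxel_size_um=(1, 1, 1))
        assert tall.labels[1, 0, 0] == 1
        assert flat.labels[1, 0, 0] == 0

    @pytest.mark.parametrize("seed", range(3))
    def test_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(8, 9, 10)) < 0.5
        mask.flat[0] = True
        nodes = rng.uniform(0, 10, size=(5, 3))
        vs = (2.0, 1.0, 1.5)
        seg = assign_voxels(mask, nodes, voxel_size_um=vs)
        for idx in np.argwhere(mask):
            c = idx * np.array(vs)
            d = np.linalg.norm(nodes - c, axis=1)
            assert seg.labels[tuple(idx)] == int(np.argmin(d))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            assign_voxels(np.zeros((2, 2, 2), dtype=bool), [[0, 0, 0]])

    def test_conservation_of_fluorescence(self, rng):
        mask = rng.uniform(size=(6, 6, 6)) < 0.7
        mask.flat[0] = True
        nodes = rng.uniform(0, 6, size=(4, 3))
        seg = assign_voxels(mask, nodes)
        movie = rng.uniform(10, 100, size=(3, 6, 6, 6))
        prof_f = []
        for t in range(3):
            total = sum(
                seg.voxel_counts[i] * movie[t][seg.labels == i].mean()
                for i in range(seg.n_nodes)
                if seg.voxel_counts[i] > 0
            )
            assert total == pytest.approx(movie[t][mask].sum(), rel=1e-9)


# ----------------------------------------------------------- dF/F
def simple_seg(n_nodes=4, size=8):
    mask = np.ones((size, size, size), dtype=bool)
    nodes = [[size / 2, size / 2, (i + 0.5) * size / n_nodes] for i in range(n_nodes)]
    return assign_voxels(mask, nodes)


class TestComputeDff:
    def test_constant_movie_is_zero(self):
        seg = simple_seg()
        movie = np.full((10, 8, 8, 8), 70.0)
        prof = compute_dff(movie, seg, prestim_frames=slice(0, 5), background=20.0)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_doubling_step_gives_unit_dff(self):
        seg = simple_seg()
        movie = np.full((10, 8, 8, 8), 100.0)
        movie[5:] = 200.0
        prof = compute_dff(movie, seg, prestim_frames=slice(0, 5), background=0.0)
        np.testing.assert_allclose(prof.values[5:], 1.0, atol=1e-12)

    def test_background_invariance(self, rng):
        seg = simple_seg()
        movie = rng.uniform(50, 150, size=(12, 8, 8, 8))
        p1 = compute_dff(movie, seg, slice(0, 4), background=10.0)
        p2 = compute_dff(movie + 25.0, seg, slice(0, 4), background=35.0)
        np.testing.assert_allclose(p1.values, p2.values, rtol=1e-9)

    def test_generator_round_trip(self):
        seg = simple_seg(n_nodes=5, size=10)
        rng = np.random.default_rng(4)
        T, pre = 20, 6
        truth = rng.uniform(-0.2, 2.0, size=(T, seg.n_nodes))
        truth[:pre] = 0.0
        movie, info = make_synthetic_movie(seg, truth, f0=100.0, background=50.0)
        prof = compute_dff(movie, seg, slice(0, pre), background=info["background"])
        np.testing.assert_allclose(prof.values, truth, atol=1e-10)

    def test_nonpositive_baseline_masked(self):
        seg = simple_seg()
        movie = np.full((6, 8, 8, 8), 30.0)
        prof = compute_dff(movie, seg, slice(0, 3), background=30.0)
        assert np.isnan(prof.values).all()


class TestSmoothingInterpolation:
    def _profile(self, values, dt=1.0):
        from aplocal.volumetric import DFFProfile

        return DFFProfile(values=np.asarray(values, dtype=float), channel="green",
                          frame_interval_s=dt)

    def test_impulse_boxcar(self):
        v = np.zeros((11, 1))
        v[5, 0] = 5.0
        out = smooth_and_interpolate(self._profile(v), mode="trace_boxcar_5frames")
        np.testing.assert_allclose(out.values[3:8, 0], 1.0)
        assert out.values[:3].sum() == 0.0

    def test_1s_boxcar_width_follows_frame_interval(self):
        v = np.zeros((11, 1))
        v[5, 0] = 3.0
        out = smooth_and_interpolate(self._profile(v, dt=1 / 3), mode="trace_boxcar_1s")
        np.testing.assert_allclose(out.values[4:7, 0], 1.0)

    def test_mode_none_is_identity(self, rng):
        v = rng.normal(size=(15, 3))
        out = smooth_and_interpolate(self._profile(v), mode="none")
        np.testing.assert_array_equal(out.values, v)

    def test_sine_interpolation(self):
        dt = 0.33
        t = np.arange(0, 10, dt)
        v = np.sin(t)[:, None]
        out = smooth_and_interpolate(self._profile(v, dt=dt), mode="none",
                                     frame_time_out=0.2)
        t_out = out.time_axis()
        # linear interpolation error bound: h^2/8 * max|f''|
        assert np.max(np.abs(out.values[:, 0] - np.sin(t_out))) < dt**2 / 8 + 1e-9

    def test_missing_frame_interval_rejected(self):
        prof = self._profile(np.zeros((5, 1)))
        prof.frame_interval_s = 0.0
        with pytest.raises(ValueError):
            smooth_and_interpolate(prof, mode="none")


class TestExclusion:
    def _profile(self, sd_per_node, channel, T=50):
        from aplocal.volumetric import DFFProfile

        rng = np.random.default_rng(0)
        v = rng.normal(0.0, 1.0, size=(T, len(sd_per_node)))
        v = (v - v.mean(axis=0)) / v.std(axis=0) * np.asarray(sd_per_node)
        return DFFProfile(values=v, channel=channel, frame_interval_s=1.0)

    def test_green_threshold(self):
        prof = self._profile([1.2, 0.9], "green")
        out = exclude_noisy_nodes(prof, prestim_frames=slice(None))
        assert np.isnan(out.values[:, 0]).all()
        assert not np.isnan(out.values[:, 1]).any()

    def test_red_threshold_stricter(self):
        prof = self._profile([0.9], "red")
        out = exclude_noisy_nodes(prof, prestim_frames=slice(None))
        assert np.isnan(out.values).all()

    def test_zero_variance_kept(self):
        prof = self._profile([0.5], "green")
        prof.values[:] = 0.0
        out = exclude_noisy_nodes(prof, prestim_frames=slice(None))
        assert not np.isnan(out.values).any()


class TestInhibitoryEffect:
    def _pair(self, odor, drug, dt=1.0):
        from aplocal.volumetric import DFFProfile

        mk = lambda v: DFFProfile(values=np.asarray(v, dtype=float), channel="green",
                                  frame_interval_s=dt)
        return mk(odor), mk(drug)

    def test_identical_profiles_zero(self, rng):
        v = np.abs(rng.normal(1.0, 0.1, size=(20, 3)))
        odor, drug = self._pair(v, v)
        eff = normalized_inhibitory_effect(odor, drug, window_frames=slice(8, 15))
        np.testing.assert_allclose(eff, 0.0, atol=1e-12)

    def test_halved_response(self):
        odor = np.zeros((30, 1))
        odor[10:20] = 2.0  # plateau: peak == window mean
        drug = odor / 2
        o, d = self._pair(odor, drug)
        eff = normalized_inhibitory_effect(o, d, window_frames=slice(12, 18))
        assert eff[0] == pytest.approx(-0.5)

    def test_known_suppression_field_recovered(self):
        seg = simple_seg(n_nodes=6, size=12)
        rng = np.random.default_rng(8)
        T, pre = 25, 5
        t = np.arange(T)
        base = np.clip(np.sin((t - pre) / 6.0), 0, None)
        odor_truth = np.outer(base, rng.uniform(0.5, 2.0, seg.n_nodes))
        suppression = rng.uniform(0.1, 0.9, seg.n_nodes)
        drug_truth = odor_truth * (1 - suppression)
        m_odor, info = make_synthetic_movie(seg, odor_truth, background=40.0)
        m_drug, _ = make_synthetic_movie(seg, drug_truth, background=40.0)
        po = compute_dff(m_odor, seg, slice(0, pre), background=40.0)
        pd_ = compute_dff(m_drug, seg, slice(0, pre), background=40.0)
        window = slice(pre, T)
        eff = normalized_inhibitory_effect(po, pd_, window, peak_smoothing="none")
        expected = -suppression * odor_truth[window].mean(axis=0) / odor_truth.max(axis=0)
        np.testing.assert_allclose(eff, expected, atol=1e-6)

    def test_nonpositive_peak_nan(self):
        odor = np.zeros((10, 1)) - 0.1
        o, d = self._pair(odor, odor)
        eff = normalized_inhibitory_effect(o, d, window_frames=slice(5, 8))
        assert np.isnan(eff[0])


class TestAlignment:
    def test_identical_images(self, rng):
        img = rng.uniform(size=(8, 8, 8))
        offs = align_recordings([img, img.copy()])
        assert offs == [(0, 0, 0), (0, 0, 0)]

    def test_constructed_shift_recovered(self, rng):
        img = rng.uniform(size=(16, 16, 16))
        shifted = np.roll(img, (-2, 1, 0), axis=(0, 1, 2))
        offs = align_recordings([img, shifted], max_shift=5)
        assert offs[1] == (2, -1, 0)
        np.testing.assert_allclose(np.roll(shifted, offs[1], axis=(0, 1, 2)), img)

    def test_noisy_shift_recovered(self, rng):
        img = rng.uniform(size=(16, 16, 16))
        shifted = np.roll(img, (2, -1, 0), axis=(0, 1, 2))
        noisy = shifted + rng.normal(0, 0.1 * img.std(), size=img.shape)
        offs = align_recordings([img, noisy], max_shift=5)
        assert offs[1] == (-2, 1, 0)

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            align_recordings([np.ones((4, 4, 4))])
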