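"""De-striping, segmentation, sphericity, background subtraction, redox maps."""

import numpy as np
import pytest

from ramanld import ld_imaging as ldi
from ramanld import synthetic_data as sd


def sphere_stack(radius, shape=None, background=10.0, contrast=1.0):
    shape = shape or (int(4 * radius),) * 3
    c = [s / 2.0 for s in shape]
    truth = sd.PhantomTruth(
        centers=[c],
        semi_axes=[[radius] * 3],
        background=background,
        droplet_level=background + contrast,
    )
    stack, _ = sd.generate_droplet_stack(truth, shape)
    return stack, truth


class TestDestripe:
    def test_constant_image_stays_constant(self):
        stack = ldi.ImageStack(np.full((8, 32, 32), 3.0))
        out = ldi.destripe_and_smooth(stack, smoothing_sigma=1.0)
        assert np.allclose(out.data, 3.0, atol=1e-10)

    def test_nonpositive_smoothing_rejected(self):
        with pytest.raises(ValueError, match="smoothing"):
            ldi.destripe_and_smooth(ldi.ImageStack(np.zeros((2, 4, 4))), 0.0)

    def test_stripe_power_suppressed_and_clean_preserved(self):
        from ramanld.experiments import stripe_removal

        out = stripe_removal(seed=0)
        assert out["power_reduction_pct"] >= 90.0
        assert out["clean_rel_rms_change"] < 0.02


class TestSegmentation:
    def test_two_disjoint_spheres(self):
        truth = sd.PhantomTruth(
            centers=[[20, 20, 16], [20, 20, 48]], semi_axes=[[6] * 3, [6] * 3]
        )
        stack, _ = sd.generate_droplet_stack(truth, (40, 40, 64))
        droplets = ldi.segment_droplets(stack, threshold=10.5)
        assert len(droplets) == 2

    def test_sphere_volume_recovered_at_snr_10(self):
        truth = sd.PhantomTruth(centers=[[32, 32, 32]], semi_axes=[[8] * 3])
        stack, _ = sd.generate_droplet_stack(truth, (64, 64, 64), noise_sd=0.1, seed=0)
        pre = ldi.destripe_and_smooth(stack, smoothing_sigma=1.0)
        droplets = ldi.segment_droplets(pre)
        assert len(droplets) == 1
        analytic = 4.0 / 3.0 * np.pi * 8**3
        assert droplets[0].volume_voxels == pytest.approx(analytic, rel=0.15)

    def test_threshold_above_max_gives_empty(self):
        stack, _ = sphere_stack(6.0)
        assert ldi.segment_droplets(stack, threshold=1e9) == []

    def test_min_voxel_cutoff_drops_specks(self):
        data = np.zeros((16, 16, 16))
        data[8, 8, 8] = 100.0  # single hot voxel
        droplets = ldi.segment_droplets(ldi.ImageStack(data), threshold=1.0)
        assert droplets == []

    def test_volume_reported_in_both_units(self):
        stack, _ = sphere_stack(6.0)
        stack = ldi.ImageStack(stack.data, voxel_size=(2.0, 0.5, 0.5))
        d = ldi.segment_droplets(stack, threshold=10.5)[0]
        assert d.volume_um3 == pytest.approx(d.volume_voxels * 0.5)


class TestSphericity:
    def test_voxel_sphere_scores_high(self):
        stack, _ = sphere_stack(8.0)
        d = ldi.segment_droplets(stack, threshold=10.5)[0]
        assert d.sphericity >= 0.9

    def test_elongated_ellipsoid_scores_below_sphere(self):
        truth = sd.PhantomTruth(centers=[[20, 20, 30]], semi_axes=[[6, 6, 12]])
        stack, _ = sd.generate_droplet_stack(truth, (40, 40, 60))
        ell = ldi.segment_droplets(stack, threshold=10.5)[0]
        sp_stack, _ = sphere_stack(8.0)
        sph = ldi.segment_droplets(sp_stack, threshold=10.5)[0]
        assert ell.sphericity < sph.sphericity

    def test_single_voxel_convention(self):
        score, flagged = ldi.sphericity(np.array([[3, 3, 3]]))
        assert score == 1.0 and flagged

    def test_scale_invariance_within_discretization(self):
        s1 = ldi.segment_droplets(sphere_stack(6.0)[0], threshold=10.5)[0]
        s2 = ldi.segment_droplets(sphere_stack(12.0)[0], threshold=10.5)[0]
        assert abs(s1.sphericity - s2.sphericity) < 0.05

    def test_score_decreases_with_axis_ratio(self):
        # fixed volume, growing elongation
        vol_r = 8.0
        scores = []
        for ratio in (1.0, 1.5, 2.0, 3.0):
            c = vol_r / ratio ** (1.0 / 3.0)
            a = c * ratio
            shape = (int(2 * a + 16), int(2 * c + 16), int(2 * c + 16))
            truth = sd.PhantomTruth(
                centers=[[s / 2 for s in shape]], semi_axes=[[a, c, c]]
            )
            stack, _ = sd.generate_droplet_stack(truth, shape)
            scores.append(ldi.segment_droplets(stack, threshold=10.5)[0].sphericity)
        assert np.all(np.diff(scores) < 0)


class TestFilterAndSummarize:
    def _droplets(self):
        truth = sd.PhantomTruth(
            centers=[[16, 16, 16], [16, 16, 48], [16, 48, 16], [16, 48, 52]],
            semi_axes=[[6] * 3, [6] * 3, [6] * 3, [3, 3, 11]],
        )
        stack, _ = sd.generate_droplet_stack(truth, (32, 64, 72))
        return ldi.segment_droplets(stack, threshold=10.5)

    def test_zero_threshold_keeps_everything(self):
        droplets = self._droplets()
        summary = ldi.filter_and_summarize(droplets, sphericity_threshold=0.0)[0]
        assert summary.count == 4

    def test_threshold_between_scores_drops_ellipsoid(self):
        droplets = self._droplets()
        scores = sorted(d.sphericity for d in droplets)
        cut = (scores[0] + scores[1]) / 2  # between ellipsoid and spheres
        summary = ldi.filter_and_summarize(droplets, sphericity_threshold=cut)[0]
        assert summary.count == 3

    def test_no_droplets_flagged_undefined(self):
        summary = ldi.filter_and_summarize([], sphericity_threshold=0.5)[0]
        assert summary.count == 0
        assert np.isnan(summary.mean_volume_voxels)

    def test_identical_cells_have_zero_count_spread(self):
        droplets = self._droplets()
        for d in droplets:
            d.cell_id = 1
        clones = [
            ldi.Droplet(
                d.voxels, d.centroid, d.volume_voxels, d.volume_um3, d.sphericity, 2
            )
            for d in droplets
        ]
        summaries = ldi.filter_and_summarize(droplets + clones, 0.0, cell_ids=[1, 2])
        counts = [s.count for s in summaries]
        assert np.std(counts) == 0.0


class TestBackgroundSubtraction:
    def test_flat_image_maps_to_zero(self):
        out = ldi.subtract_image_background(np.full((64, 64), 5.0), radius=20.0)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            ldi.subtract_image_background(np.zeros((32, 32)), radius=64.0)

    def test_gradient_background_removed(self):
        from ramanld.experiments import rolling_ball_gradient

        out = rolling_ball_gradient(shape=(128, 128), radius=30.0, seed=0)
        assert out["reduction_pct"] >= 80.0

    def test_large_radius_approaches_min_subtraction(self):
        # a narrow bump on a flat floor: a huge ball cannot enter the bump,
        # so the background approaches the floor (the image minimum)
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[:64, :64]
        img[(yy - 32) ** 2 + (xx - 32) ** 2 <= 25] = 100.0
        out = ldi.subtract_image_background(img, radius=60.0)
        assert np.allclose(out, img - img.min(), atol=1.0)

    def test_sliding_paraboloid_variant(self):
        img = np.zeros((64, 64))
        img[30:34, 30:34] = 50.0
        out = ldi.subtract_image_background(
            img, method="sliding_paraboloid", radius=20.0
        )
        assert out[32, 32] > 40.0
        assert abs(out[5, 5]) < 1.0


class TestRedoxMap:
    def test_equal_channels_half(self):
        f = np.full((16, 16), 2.0)
        ratio, table = ldi.redox_map(f, f)
        assert np.all(ratio == 0.5)
        assert table.loc[0, "mean_redox"] == 0.5

    def test_zero_nadh_gives_one(self):
        f = np.full((8, 8), 3.0)
        ratio, _ = ldi.redox_map(f, np.zeros_like(f))
        assert np.all(ratio == 1.0)

    def test_per_cell_quarter(self, rng):
        masks = sd.make_cell_masks((64, 64), 2, radius=8.0, rng=rng)
        f, n, m = sd.generate_fluorescence_pair(masks, 1.0, 3.0)
        _, table = ldi.redox_map(f, n, m)
        assert np.allclose(table["mean_redox"], 0.25)

    def test_undefined_outside_support(self):
        f = np.zeros((8, 8))
        ratio, _ = ldi.redox_map(f, f)
        assert np.all(np.isnan(ratio))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ldi.redox_map(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_bounded_where_defined(self, rng):
        f = rng.uniform(0, 5, (32, 32))
        n = rng.uniform(0, 5, (32, 32))
        ratio, _ = ldi.redox_map(f, n)
        ok = ~np.isnan(ratio)
        assert np.all((ratio[ok] >= 0) & (ratio[ok] <= 1))


class TestRegionQuantify:
    def test_constant_image_constant_profile(self):
        prof = ldi.line_profile(np.full((32, 32), 4.0), (2.0, 2.0), (28.0, 25.0))
        assert np.allclose(prof["intensity"], 4.0)

    def test_zero_length_line_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            ldi.line_profile(np.zeros((8, 8)), (2.0, 2.0), (2.0, 2.0))

    def test_mip_localizes_bright_voxel(self):
        data = np.zeros((6, 16, 16))
        data[3, 5, 9] = 7.0
        mip = ldi.max_intensity_projection(ldi.ImageStack(data))
        assert mip[5, 9] == 7.0
        assert mip.sum() == 7.0

    def test_identical_cells_zero_sem(self, rng):
        masks = np.zeros((40, 80), dtype=int)
        masks[10:30, 10:30] = 1
        masks[10:30, 50:70] = 2
        img = np.zeros((40, 80))
        pattern = rng.uniform(0, 1, (20, 20))
        img[10:30, 10:30] = pattern
        img[10:30, 50:70] = pattern
        table = ldi.intensity_histograms(img, masks, bins=16)
        assert np.allclose(table["sem_freq"], 0.0)
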