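"""Segmentation, per-particle measurement, and distribution summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pelletopt import (
    MorphometryError,
    ParticleSet,
    SegmentationConfig,
    SyntheticImageSpec,
    circularity,
    draw_pellet_image,
    filter_particles,
    measure,
    segment,
    summarize,
    uniformity_cu,
)
from pelletopt.morphometry import max_caliper


def render(count=5, seed=0, **kw):
    spec = SyntheticImageSpec(count=count, seed=seed, **kw)
    return draw_pellet_image(spec)


class TestSegment:
    def test_five_disjoint_disks_five_labels(self):
        img, _ = render(count=5, noise_sd=6.0, seed=2)
        labels = segment(img)
        assert labels.max() == 5

    def test_blank_image_warns_and_returns_no_labels(self):
        blank = np.full((64, 64), 200, dtype=np.uint8)
        with pytest.warns(UserWarning, match="constant"):
            labels = segment(blank)
        assert labels.max() == 0

    def test_overlapping_disks_merge_without_declumping(self):
        # two overlapping disks drawn explicitly
        img = np.full((120, 120), 200, dtype=np.uint8)
        yy, xx = np.mgrid[0:120, 0:120]
        img[(yy - 60) ** 2 + (xx - 45) ** 2 <= 400] = 60
        img[(yy - 60) ** 2 + (xx - 75) ** 2 <= 400] = 60
        assert segment(img).max() == 1

    def test_fixed_threshold_and_polarity(self):
        img = np.full((50, 50), 20, dtype=np.uint8)
        img[10:20, 10:20] = 240  # bright object on dark background
        cfg = SegmentationConfig(threshold=128.0, dark_objects=False)
        assert segment(img, cfg).max() == 1

    def test_fill_holes(self):
        img = np.full((60, 60), 200, dtype=np.uint8)
        yy, xx = np.mgrid[0:60, 0:60]
        ring = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 400) & (
            (yy - 30) ** 2 + (xx - 30) ** 2 >= 100
        )
        img[ring] = 60
        ps = measure(segment(img))  # holes filled by default
        assert ps.count == 1
        assert ps.particles[0].area == pytest.approx(np.pi * 400, rel=0.05)

    def test_rejects_rgb_input(self):
        with pytest.raises(MorphometryError, match="2-D"):
            segment(np.zeros((10, 10, 3)))


class TestMeasure:
    def test_digitized_disk_circularity_near_one(self):
        yy, xx = np.mgrid[0:121, 0:121]
        disk = ((yy - 60) ** 2 + (xx - 60) ** 2 <= 50**2).astype(int)
        ps = measure(disk)
        assert 0.90 <= ps.particles[0].circularity <= 1.00

    def test_circularity_formula_closed_forms(self):
        # ideal circle: 4*pi*(pi r^2)/(2 pi r)^2 = 1
        assert circularity(np.pi * 25.0, 2 * np.pi * 5.0) == pytest.approx(1.0)
        # ideal square with polygonal perimeter 4s: pi/4
        assert circularity(9.0, 12.0) == pytest.approx(np.pi / 4)

    def test_single_pixel_convention(self):
        img = np.zeros((5, 5), dtype=int)
        img[2, 2] = 1
        ps = measure(img, scale=0.1)
        p = ps.particles[0]
        assert p.area == pytest.approx(0.01)
        assert p.feret == pytest.approx(0.1)  # one pixel width
        assert p.circularity == 1.0  # clamped

    def test_area_and_feret_scale_with_calibration(self):
        yy, xx = np.mgrid[0:60, 0:60]
        disk = ((yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2).astype(int)
        ps1 = measure(disk, scale=1.0)
        ps2 = measure(disk, scale=0.05)
        assert ps2.particles[0].area == pytest.approx(
            ps1.particles[0].area * 0.05**2
        )
        assert ps2.particles[0].feret == pytest.approx(
            ps1.particles[0].feret * 0.05
        )

    def test_feret_within_2pct_for_radius_10_and_up(self):
        rng = np.random.default_rng(5)
        for r in (10, 15, 25, 50):
            for _ in range(5):
                cy, cx = rng.uniform(r + 3, r + 5, 2)
                n = 2 * r + 10
                yy, xx = np.mgrid[0:n, 0:n]
                disk = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r**2).astype(int)
                feret = measure(disk).particles[0].feret
                assert abs(feret - 2 * r) / (2 * r) < 0.02, r

    def test_translation_and_rotation_invariance(self):
        yy, xx = np.mgrid[0:200, 0:200]
        blob = (((yy - 60) / 30.0) ** 2 + ((xx - 70) / 18.0) ** 2 <= 1).astype(int)
        base = measure(blob).particles[0]
        shifted = measure(np.roll(np.roll(blob, 37, axis=0), 21, axis=1))
        rotated = measure(np.rot90(blob).copy())
        assert shifted.particles[0].feret == pytest.approx(base.feret)
        assert shifted.particles[0].area == pytest.approx(base.area)
        assert rotated.particles[0].feret == pytest.approx(base.feret, rel=0.01)
        assert rotated.particles[0].area == pytest.approx(base.area)

    def test_feret_at_least_equivalent_diameter(self):
        img, _ = render(count=20, seed=4)
        ps = measure(segment(img))
        for p in ps.particles:
            eq_d = 2 * np.sqrt(p.area / np.pi)
            assert p.feret >= eq_d * 0.95

    def test_disks_rounder_than_squares_of_equal_area(self):
        yy, xx = np.mgrid[0:80, 0:80]
        disk = ((yy - 40) ** 2 + (xx - 40) ** 2 <= 20**2).astype(int)
        sq = np.zeros((80, 80), dtype=int)
        side = int(round(np.sqrt(np.pi) * 20))  # equal-area square
        sq[10:10 + side, 10:10 + side] = 1
        assert (
            measure(disk).particles[0].circularity
            > measure(sq).particles[0].circularity
        )

    def test_max_caliper_collinear_pixels(self):
        coords = np.array([[0, 0], [0, 1], [0, 2], [0, 3]])
        assert max_caliper(coords) == pytest.approx(3.0)


class TestFilterParticles:
    def test_speck_removed_at_reference_settings(self):
        img, _ = render(count=3, seed=8, diameter_dist="fixed",
                        diameter_params=(2.0,))
        ps = measure(segment(img), scale=0.05)
        # add a sub-threshold speck: 0.005 mm^2 at 0.05 mm/px is 2 px
        from pelletopt.morphometry import Particle

        speck = Particle(label=99, area=0.005, perimeter=0.3, feret=0.1,
                         circularity=0.9)
        ps = ParticleSet(ps.particles + (speck,), scale=0.05)
        kept = filter_particles(ps, min_size=0.01, roundness_range=(0.1, 1.0))
        assert kept.count == 3
        assert all(p.label != 99 for p in kept.particles)

    def test_wide_open_filter_is_identity(self):
        img, _ = render(count=4, seed=9)
        ps = measure(segment(img), scale=0.05)
        kept = filter_particles(ps, min_size=0.0, roundness_range=(0.0, 1.0))
        assert kept.count == ps.count

    def test_everything_below_min_size_empties_the_set(self):
        img, _ = render(count=4, seed=9)
        ps = measure(segment(img), scale=0.05)
        assert filter_particles(ps, min_size=1e6).count == 0

    def test_square_particles_rejected_by_tight_roundness(self):
        img, _ = render(count=4, seed=10, shape="square")
        ps = measure(segment(img), scale=0.05)
        kept = filter_particles(ps, min_size=0.0, roundness_range=(0.95, 1.0))
        assert kept.count == 0

    def test_inverted_range_rejected(self):
        img, _ = render(count=1, seed=0)
        ps = measure(segment(img), scale=0.05)
        with pytest.raises(MorphometryError, match="inverted"):
            filter_particles(ps, roundness_range=(0.9, 0.1))


class TestUniformityCU:
    def test_equal_diameters_give_one(self):
        assert uniformity_cu([3.3, 3.3, 3.3]) == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        # 1 - (|2-3| + |4-3|) / (2*3)
        assert uniformity_cu([2.0, 4.0]) == pytest.approx(0.6667, abs=5e-5)

    def test_empty_input_rejected(self):
        with pytest.raises(MorphometryError):
            uniformity_cu([])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        data=st.lists(st.floats(0.01, 100), min_size=1, max_size=30),
        c=st.floats(0.01, 100),
    )
    def test_scale_invariant_and_bounded(self, data, c):
        cu = uniformity_cu(data)
        assert cu <= 1.0
        assert uniformity_cu(np.array(data) * c) == pytest.approx(cu, abs=1e-9)
        if len(set(data)) == 1:
            assert cu == pytest.approx(1.0)


class TestSummarize:
    def test_single_particle_degenerate_summary(self):
        img, _ = render(count=1, seed=3)
        ps = measure(segment(img), scale=0.05)
        s = summarize(ps)
        fn = s.five_num
        assert fn["min"] == fn["q1"] == fn["median"] == fn["q3"] == fn["max"]
        assert s.outliers == ()
        assert s.feret_sd == 0.0

    def test_gross_outlier_flagged(self):
        from pelletopt.morphometry import Particle

        particles = tuple(
            Particle(i, 1.0, 3.0, d, 0.9)
            for i, d in enumerate((1.0, 2.0, 3.0, 4.0, 100.0))
        )
        s = summarize(ParticleSet(particles, scale=1.0))
        assert s.outliers == (100.0,)
        # quartile rule: linear interpolation between order statistics
        assert s.five_num["q1"] == pytest.approx(2.0)
        assert s.five_num["q3"] == pytest.approx(4.0)

    def test_empty_set_rejected(self):
        with pytest.raises(MorphometryError):
            summarize(ParticleSet((), scale=1.0))

    def test_five_number_summary_is_ordered(self):
        img, _ = render(count=30, seed=6, noise_sd=5.0)
        s = summarize(measure(segment(img), scale=0.05))
        fn = s.five_num
        assert (fn["min"] <= fn["q1"] <= fn["median"]
                <= fn["q3"] <= fn["max"])


class TestEndToEndRecovery:
    """Round trips through generator -> segmentation -> measurement."""

    def test_five_disk_diameter_recovery(self):
        img, truth = render(count=5, seed=2)
        ps = measure(segment(img), scale=0.05)
        assert ps.count == 5
        measured = np.sort(ps.ferets())
        expected = np.sort(truth["diameter_mm"].to_numpy())
        assert np.allclose(measured, expected, rtol=0.02)

    def test_500_disk_population_recovery(self):
        """Counts exact; mean diameter within 2 SE; CU within 0.02."""
        spec = SyntheticImageSpec(
            shape_px=(2048, 2048), scale=0.05, count=500,
            diameter_params=(2.10, 0.52), noise_sd=6.0, seed=12,
        )
        img, truth = draw_pellet_image(spec)
        ps = measure(segment(img), scale=0.05)
        assert ps.count == 500
        d_true = truth["diameter_mm"].to_numpy()
        d_meas = ps.ferets()
        se = 0.52 / np.sqrt(500)
        assert abs(d_meas.mean() - d_true.mean()) < 2 * se
        assert abs(uniformity_cu(d_meas) - uniformity_cu(d_true)) < 0.02
        # population mean itself is near the generator's target
        assert abs(d_true.mean() - 2.10) < 2 * se
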