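"""Radial deposition-pattern mapping, grid-square fractions, trends."""

import numpy as np
import pandas as pd
import pytest

from conftest import grid_frame_images, records_from_positions
from impsem.deposition_pattern import (SizeBinning, coverage_extent_check,
                                       density_profile,
                                       estimate_impact_center,
                                       fit_deposition_trend,
                                       fit_radial_gaussian,
                                       normalized_radius,
                                       radial_uniformity_test,
                                       square_bin_fractions)
from impsem.errors import InsufficientDataError
from impsem.segmentation import MicrographImage, ParticleRecord
from impsem.synthetic import DepositionModel, deposit_positions

R_ORIFICE = 145.0  # um, 0.29 mm nozzle


def frame(stage_x=0.0, stage_y=0.0, image_id="f0", size=100, ps=1000.0):
    return MicrographImage(pixels=np.full((size, size), 200.0),
                           pixel_size=ps, stage_x=stage_x, stage_y=stage_y,
                           image_id=image_id)


def record(image_id, ecd, cx=50.0, cy=50.0, pid=1):
    return ParticleRecord(particle_id=pid, image_id=image_id,
                          area=np.pi * (ecd / 2) ** 2, ecd=ecd,
                          perimeter=np.pi * ecd, circularity=1.0,
                          aspect_ratio=1.0, centroid_x=cx, centroid_y=cy,
                          touches_border=False)


class TestSizeBinning:
    def test_default_edges(self):
        b = SizeBinning()
        assert b.labels == ["0-80", "80-160", "160-240", ">240"]
        assert list(b.assign([40.0, 100.0, 200.0, 500.0])) == [0, 1, 2, 3]

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            SizeBinning(edges=(0.0, 100.0, 50.0))


class TestImpactCenter:
    def test_all_large_particles_at_one_point(self):
        im = frame(stage_x=30.0, stage_y=-10.0)
        recs = [record("f0", 400.0, pid=i) for i in range(3)]
        x, y = estimate_impact_center(recs, [im])
        assert (x, y) == pytest.approx((30.0, -10.0))

    def test_symmetric_ring_recovers_origin(self):
        rng = np.random.default_rng(0)
        model = DepositionModel()
        pos = deposit_positions(np.full(400, 400.0), model, rng)
        images = grid_frame_images(220.0, 15)
        recs = records_from_positions(pos, images)
        x, y = estimate_impact_center(recs, images)
        assert np.hypot(x, y) < 0.05 * R_ORIFICE

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        pos = deposit_positions(np.full(300, 400.0),
                                DepositionModel(), rng)
        images = grid_frame_images(220.0, 15)
        recs = records_from_positions(pos, images)
        x0, y0 = estimate_impact_center(recs, images)
        shifted = [MicrographImage(pixels=im.pixels,
                                   pixel_size=im.pixel_size,
                                   stage_x=im.stage_x + 37.0,
                                   stage_y=im.stage_y - 12.0,
                                   image_id=im.image_id) for im in images]
        x1, y1 = estimate_impact_center(recs, shifted)
        assert (x1 - x0, y1 - y0) == pytest.approx((37.0, -12.0), abs=1e-9)

    def test_fallback_warns_and_empty_raises(self):
        im = frame()
        with pytest.warns(UserWarning):
            estimate_impact_center([record("f0", 50.0)], [im])
        with pytest.raises(InsufficientDataError):
            estimate_impact_center([], [im])


class TestNormalizedRadius:
    def test_examples(self):
        assert normalized_radius(frame(), (0.0, 0.0), R_ORIFICE) == 0.0
        assert normalized_radius(frame(stage_x=145.0), (0.0, 0.0),
                                 R_ORIFICE) == pytest.approx(1.0)
        assert normalized_radius(frame(stage_x=217.5), (0.0, 0.0),
                                 R_ORIFICE) == pytest.approx(1.5)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            normalized_radius(frame(), (0.0, 0.0), 0.0)


class TestDensityProfile:
    def test_count_over_area(self):
        im = frame()  # 100x100 px at 1000 nm/px -> 100 um x 100 um
        assert im.area_um2 == pytest.approx(10_000.0)
        recs = [record("f0", 100.0, pid=i) for i in range(50)]
        profile = density_profile(recs, [im])
        assert profile.loc[0, "count_80-160"] == 50
        assert profile.loc[0, "density_80-160"] == pytest.approx(50 / 10_000)

    def test_empty_frame_zero_everywhere(self):
        profile = density_profile([], [frame()])
        assert all(profile.loc[0, f"count_{lab}"] == 0
                   for lab in SizeBinning().labels)

    def test_total_count_preserved(self):
        images = grid_frame_images(220.0, 9)
        rng = np.random.default_rng(3)
        pos = deposit_positions(np.full(2000, 120.0),
                                DepositionModel(), rng)
        recs = records_from_positions(pos, images)
        profile = density_profile(recs, images)
        total = sum(profile[f"count_{lab}"].sum()
                    for lab in SizeBinning().labels)
        assert total == len(recs)

    def test_poisson_consistency_of_uniform_field(self):
        # Uniform sub-cutoff deposition: per-image densities fluctuate
        # around the true intensity within Poisson errors.
        rng = np.random.default_rng(4)
        model = DepositionModel(sub_cutoff_fraction=1.0)
        n = 40_000
        pos = deposit_positions(np.full(n, 40.0), model, rng)
        images = grid_frame_images(120.0, 7)  # well inside the 2R disc
        recs = records_from_positions(pos, images)
        profile = density_profile(recs, images)
        rho = n / (np.pi * (2 * model.orifice_radius_um) ** 2)
        mean_density = profile["density_0-80"].mean()
        per_image_expected = rho * images[0].area_um2
        sigma = np.sqrt(per_image_expected / len(images)) / images[0].area_um2
        assert abs(mean_density - rho) < 3 * sigma


class TestSquareFractions:
    def test_fractions_sum_to_one(self):
        images = grid_frame_images(220.0, 9)
        rng = np.random.default_rng(5)
        pos = deposit_positions(np.full(3000, 200.0),
                                DepositionModel(), rng)
        recs = records_from_positions(pos, images)
        profile = density_profile(recs, images, center=(0.0, 0.0),
                                  orifice_radius_um=R_ORIFICE)
        squares = square_bin_fractions(profile)
        assert squares["fraction_160-240"].sum() == pytest.approx(1.0,
                                                                  abs=1e-12)

    def test_single_square_gets_everything(self):
        im1, im2 = frame(0.0, 0.0, "a", size=64, ps=100.0), \
            frame(200.0, 0.0, "b", size=64, ps=100.0)
        recs = [record("a", 100.0, pid=i) for i in range(5)]
        profile = density_profile(recs, [im1, im2], center=(0.0, 0.0),
                                  orifice_radius_um=R_ORIFICE)
        squares = square_bin_fractions(profile)
        fr = squares.sort_values("sq_ix")["fraction_80-160"].to_numpy()
        assert list(fr) == [1.0, 0.0]

    def test_mean_per_square_before_normalizing(self):
        # Square A holds two images (counts 2 and 4), square B one image
        # (count 3): per-square means 3 and 3 give fractions 0.5 / 0.5.
        ims = [frame(0.0, 0.0, "a1", size=64, ps=100.0),
               frame(2.0, 0.0, "a2", size=64, ps=100.0),
               frame(200.0, 0.0, "b1", size=64, ps=100.0)]
        recs = ([record("a1", 100.0, pid=i) for i in range(2)]
                + [record("a2", 100.0, pid=i + 10) for i in range(4)]
                + [record("b1", 100.0, pid=i + 20) for i in range(3)])
        profile = density_profile(recs, ims, center=(0.0, 0.0),
                                  orifice_radius_um=R_ORIFICE)
        squares = square_bin_fractions(profile)
        fr = squares.sort_values("sq_ix")["fraction_80-160"].to_numpy()
        assert fr == pytest.approx([0.5, 0.5])

    def test_unpopulated_bin_is_nan(self):
        ims = [frame(0.0, 0.0, "a", size=64, ps=100.0)]
        recs = [record("a", 100.0)]
        profile = density_profile(recs, ims, center=(0.0, 0.0),
                                  orifice_radius_um=R_ORIFICE)
        squares = square_bin_fractions(profile)
        assert np.isnan(squares["fraction_>240"]).all()


class TestRadialGaussian:
    def test_noise_free_recovery(self):
        r = np.linspace(0.0, 2.0, 25)
        y = 0.4 * np.exp(-((r - 0.8) ** 2) / (2 * 0.3**2))
        fit = fit_radial_gaussian(r, y)
        assert fit.amplitude == pytest.approx(0.4, abs=1e-6)
        assert fit.center == pytest.approx(0.8, abs=1e-6)
        assert fit.width == pytest.approx(0.3, abs=1e-6)
        assert not fit.unconstrained

    def test_flat_profile_flagged_unconstrained(self):
        r = np.linspace(0.0, 1.2, 15)
        fit = fit_radial_gaussian(r, np.full(15, 0.25))
        assert fit.unconstrained

    def test_too_few_squares(self):
        with pytest.raises(InsufficientDataError):
            fit_radial_gaussian([0.1, 0.2], [0.5, 0.5])

    def test_ring_centers_shrink_with_size(self):
        # Aerodynamic focusing: the fitted ring centre moves towards the
        # impact centre as the size bin grows.
        rng = np.random.default_rng(11)
        model = DepositionModel()
        sizes = np.concatenate([np.full(6000, 120.0), np.full(6000, 200.0),
                                np.full(6000, 400.0)])
        pos = deposit_positions(sizes, model, rng)
        images = grid_frame_images(220.0, 15)
        recs = records_from_positions(pos, images)
        profile = density_profile(recs, images, center=(0.0, 0.0),
                                  orifice_radius_um=R_ORIFICE)
        squares = square_bin_fractions(profile)
        trend = fit_deposition_trend(squares)
        centers = [trend[lab].center
                   for lab in ("80-160", "160-240", ">240")]
        assert centers[0] > centers[1] > centers[2]


class TestCoverageExtent:
    def test_pass_at_1p6(self):
        ims = [frame(stage_x=x) for x in (0.0, 120.0, 232.0)]
        out = coverage_extent_check(ims, (0.0, 0.0), R_ORIFICE)
        assert out["complete"]

    def test_flagged_at_1p0(self):
        ims = [frame(stage_x=145.0)]
        out = coverage_extent_check(ims, (0.0, 0.0), R_ORIFICE)
        assert not out["complete"]
        assert "1.5" in out["flag"] or "required" in out["flag"]

    def test_empty_sequence_flagged(self):
        out = coverage_extent_check([], (0.0, 0.0), R_ORIFICE)
        assert not out["complete"]


class TestRadialUniformity:
    def test_uniform_disc_passes(self):
        rng = np.random.default_rng(21)
        radii = 290.0 * np.sqrt(rng.uniform(size=2000))
        assert radial_uniformity_test(radii, 290.0) > 0.01

    def test_ring_rejects(self):
        rng = np.random.default_rng(22)
        radii = np.abs(rng.normal(116.0, 40.0, size=2000))
        assert radial_uniformity_test(radii, 290.0) < 0.01
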