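"""Size distributions: histograms, log->linear rebinning, Ceff correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impsem.errors import CoverageError, SchemaError
from impsem.psd import (SizeDistribution, SmpsScan, apply_ceff, compare_psd,
                        psd_from_images, rebin_linear, rebin_log_to_linear,
                        shape_filtered_psd)
from impsem.segmentation import MicrographImage, ParticleRecord


def make_image(image_id="img", stage=(0.0, 0.0)):
    return MicrographImage(pixels=np.full((64, 64), 200.0),
                           pixel_size=100.0, stage_x=stage[0],
                           stage_y=stage[1], image_id=image_id)


def make_record(ecd, image_id="img", circ=1.0, aspect=1.0, pid=1):
    return ParticleRecord(particle_id=pid, image_id=image_id,
                          area=np.pi * (ecd / 2) ** 2, ecd=ecd,
                          perimeter=np.pi * ecd, circularity=circ,
                          aspect_ratio=aspect, centroid_x=32.0,
                          centroid_y=32.0, touches_border=False)


def flat_scan(value=100.0, d_min=20.0, d_max=500.0, channels=64, scans=1):
    mids = np.geomspace(d_min, d_max, channels)
    return SmpsScan(midpoints=mids,
                    data=np.full((scans, channels), value))


class TestPsdFromImages:
    def test_single_bin_counts_and_sqrt_errors(self):
        recs = [make_record(105.0, pid=i) for i in range(25)]
        dist = psd_from_images(recs, [make_image()], bin_width=10.0)
        k = np.argmax(dist.values)
        assert dist.values[k] == 25
        assert dist.uncertainties[k] == pytest.approx(np.sqrt(25))
        assert dist.total == 25

    def test_no_particles_all_zero(self):
        dist = psd_from_images([], [make_image()], bin_width=10.0)
        assert dist.total == 0

    def test_binomial_mixture_fractions(self):
        rng = np.random.default_rng(0)
        n = 2000
        p = 0.3
        sizes = np.where(rng.uniform(size=n) < p, 60.0, 220.0)
        recs = [make_record(s, pid=i) for i, s in enumerate(sizes)]
        dist = psd_from_images(recs, [make_image()], bin_width=10.0)
        low = dist.values[(dist.midpoints > 50) & (dist.midpoints < 70)].sum()
        assert abs(low / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_detection_limit_flagging(self):
        recs = [make_record(30.0), make_record(150.0, pid=2)]
        dist = psd_from_images(recs, [make_image()], bin_width=10.0,
                               detection_limit_nm=40.0)
        flagged = [f == "highly_uncertain" for f in dist.flags]
        assert any(flagged)
        assert all(m < 40.0 for m, f in zip(dist.midpoints, dist.flags)
                   if f == "highly_uncertain")


class TestRebinLogToLinear:
    def test_total_number_conserved(self):
        scan = flat_scan()
        edges = np.arange(0.0, 600.0, 7.0)
        dist = rebin_log_to_linear(scan, edges)
        expected = np.sum(scan.mean_scan
                          * np.log10(scan.channel_edges[1:]
                                     / scan.channel_edges[:-1]))
        assert dist.total == pytest.approx(expected, rel=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(5, 80), st.floats(1.0, 15.0))
    def test_conservation_over_random_edges(self, n_bins, width):
        scan = flat_scan(value=250.0, d_min=30.0, d_max=400.0, channels=40)
        edges = np.concatenate([[1.0], np.linspace(25.0, 410.0, n_bins)
                                + width, [2000.0]])
        edges = np.unique(edges)
        dist = rebin_log_to_linear(scan, edges)
        total_in = np.sum(scan.mean_scan
                          * np.log10(scan.channel_edges[1:]
                                     / scan.channel_edges[:-1]))
        assert dist.total == pytest.approx(total_in, rel=1e-9)

    def test_single_channel_lands_in_containing_bin(self):
        mids = np.geomspace(50.0, 200.0, 16)
        data = np.zeros((1, 16))
        data[0, 8] = 77.0
        scan = SmpsScan(midpoints=mids, data=data)
        edges = np.array([0.0, 80.0, 130.0, 500.0])  # channel 8 ~ 104 nm
        dist = rebin_log_to_linear(scan, edges)
        ch = scan.channel_edges
        expected = 77.0 * np.log10(ch[9] / ch[8])
        assert dist.values[1] == pytest.approx(expected, rel=1e-12)
        assert dist.values[0] == dist.values[2] == 0.0

    def test_constant_dndlogdp_closed_form(self):
        c = 123.0
        scan = flat_scan(value=c, d_min=20.0, d_max=500.0)
        edges = np.array([50.0, 100.0, 200.0])
        dist = rebin_log_to_linear(scan, edges)
        assert dist.values[0] == pytest.approx(c * np.log10(2.0), rel=1e-9)
        assert dist.values[1] == pytest.approx(c * np.log10(2.0), rel=1e-9)

    def test_disjoint_ranges_raise(self):
        with pytest.raises(CoverageError):
            rebin_log_to_linear(flat_scan(d_min=20.0, d_max=100.0),
                                np.array([500.0, 600.0]))

    def test_non_geometric_channels_rejected(self):
        with pytest.raises(SchemaError):
            SmpsScan(midpoints=np.array([10.0, 20.0, 25.0, 100.0]),
                     data=np.zeros((1, 4)))


class TestApplyCeff:
    def test_near_unity_curve_is_identity(self, reference_curve):
        from impsem.collection_efficiency import EfficiencyCurve
        curve = EfficiencyCurve(cmax=1.0, d50=1e-6, steepness=2.0)
        dist = SizeDistribution(edges=np.array([50.0, 100.0, 200.0]),
                                values=np.array([5.0, 7.0]))
        out = apply_ceff(dist, curve)
        assert out.values == pytest.approx(dist.values, rel=1e-9)

    def test_bin_at_d50_scaled_by_half_cmax(self, reference_curve):
        d50 = reference_curve.d50
        edges = np.array([d50 / 1.1, d50 * 1.1])  # geometric mid = d50
        dist = SizeDistribution(edges=edges, values=np.array([10.0]))
        out = apply_ceff(dist, reference_curve)
        assert out.values[0] == pytest.approx(10.0 * reference_curve.cmax / 2)

    def test_reference_scaling_at_146(self, reference_curve):
        edges = np.array([146.0 / 1.05, 146.0 * 1.05])
        dist = SizeDistribution(edges=edges, values=np.array([1.0]))
        out = apply_ceff(dist, reference_curve)
        assert out.values[0] == pytest.approx(0.509, abs=1e-3)

    def test_never_increases_any_bin(self, reference_curve):
        rng = np.random.default_rng(1)
        edges = np.arange(0.0, 500.0, 10.0)
        dist = SizeDistribution(edges=edges,
                                values=rng.uniform(0, 50,
                                                   edges.size - 1))
        out = apply_ceff(dist, reference_curve)
        assert np.all(out.values <= dist.values + 1e-12)


class TestShapeFiltered:
    def test_wide_open_thresholds_identity(self):
        recs = [make_record(100.0 + 10 * i, circ=0.5 + 0.05 * i, pid=i)
                for i in range(8)]
        full = shape_filtered_psd(recs, circularity_min=0.0)
        assert full.total == 8

    def test_impossible_threshold_empty(self):
        recs = [make_record(100.0)]
        assert shape_filtered_psd(recs, circularity_min=1.01).total == 0

    def test_separates_disks_from_ellipses(self):
        disks = [make_record(150.0, circ=0.95, aspect=1.05, pid=i)
                 for i in range(10)]
        ellipses = [make_record(150.0, circ=0.55, aspect=4.0, pid=i + 10)
                    for i in range(7)]
        out = shape_filtered_psd(disks + ellipses, circularity_min=0.9)
        assert out.total == 10


class TestCompare:
    def test_identical_inputs(self):
        edges = np.arange(0.0, 300.0, 10.0)
        vals = np.exp(-((np.arange(edges.size - 1) - 14) ** 2) / 20.0)
        a = SizeDistribution(edges=edges, values=vals)
        b = SizeDistribution(edges=edges, values=3.0 * vals)
        cmp = compare_psd(a, b, d_min=73.0)
        assert cmp.mode_difference == 0.0
        assert cmp.peak_ratio == pytest.approx(1.0)
        assert cmp.max_fraction_difference == pytest.approx(0.0, abs=1e-12)

    def test_one_bin_shift_detected(self):
        edges = np.arange(0.0, 300.0, 10.0)
        vals = np.exp(-((np.arange(edges.size - 1) - 14) ** 2) / 20.0)
        a = SizeDistribution(edges=edges, values=vals)
        b = SizeDistribution(edges=edges, values=np.roll(vals, 1))
        cmp = compare_psd(a, b, d_min=73.0)
        assert cmp.mode_difference == pytest.approx(10.0, abs=0.5)

    def test_empty_overlap_raises(self):
        edges = np.arange(0.0, 60.0, 10.0)
        a = SizeDistribution(edges=edges, values=np.ones(edges.size - 1))
        with pytest.raises(CoverageError):
            compare_psd(a, a, d_min=500.0)


class TestNormalization:
    def test_unit_sum_idempotent(self):
        dist = SizeDistribution(edges=np.array([0.0, 10.0, 20.0]),
                                values=np.array([3.0, 1.0]))
        once = dist.normalized()
        twice = once.normalized()
        assert once.values == pytest.approx(twice.values)
        assert once.total == pytest.approx(1.0)

    def test_rebin_linear_conserves(self):
        dist = SizeDistribution(edges=np.array([0.0, 10.0, 20.0, 30.0]),
                                values=np.array([3.0, 1.0, 2.0]))
        out = rebin_linear(dist, np.array([0.0, 15.0, 30.0]))
        assert out.total == pytest.approx(dist.total)
        assert out.values[0] == pytest.approx(3.0 + 0.5)
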