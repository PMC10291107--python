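"""Signed geometric variance: sign convention, summaries, region labelling
and repeatability statistics."""

import numpy as np
import pytest

from dmliner import (
    DefectSpec,
    NoiseSpec,
    ProtocolSpec,
    ReferenceSphere,
    SphereFit,
    SurfaceScan,
    fit_reference,
    ground_truth_field,
    label_regions,
    repeatability,
    signed_deviation,
    simulate_scan,
    summarize,
)
from dmliner.deviation import SummaryStats
from dmliner.geometry import rotation_about_z, spherical_to_cartesian


def tiny_scan(side, radii_um_offsets, liner, radius):
    """A 4-trace scan whose points sit at radius + given offsets (um)."""
    azimuths = np.array([0.0, 90.0, 180.0, 270.0])
    pts, tidx = [], []
    offsets = iter(radii_um_offsets)
    for t, az in enumerate(azimuths):
        for polar in (30.0, 60.0):
            r = radius + next(offsets) / 1000.0
            pts.append(spherical_to_cartesian(polar, az, r))
            tidx.append(t)
    return SurfaceScan(
        side=side,
        points=np.array(pts),
        trace_index=np.array(tidx),
        azimuths=azimuths,
        liner=liner,
        protocol=ProtocolSpec(azimuth_step=90.0),
    )


@pytest.fixture()
def unit_reference():
    def make(radius):
        return ReferenceSphere(
            centre=np.zeros(3), radius=radius, rms_residual=0.0,
            max_abs_residual=0.0, n_points=8, n_iterations=0, converged=True,
        )
    return make


class TestSignConvention:
    def test_internal_outward_point_is_penetration(self, liner, unit_reference):
        scan = tiny_scan("internal_concave", [10.0] * 8, liner, liner.internal_radius)
        field = signed_deviation(scan, unit_reference(liner.internal_radius))
        np.testing.assert_allclose(field.dev_um, 10.0, atol=1e-9)

    def test_external_outward_point_is_protrusion(self, liner, unit_reference):
        scan = tiny_scan("external_convex", [10.0] * 8, liner, liner.external_radius)
        field = signed_deviation(scan, unit_reference(liner.external_radius))
        np.testing.assert_allclose(field.dev_um, -10.0, atol=1e-9)

    def test_point_on_reference_is_zero(self, liner, unit_reference):
        scan = tiny_scan("internal_concave", [0.0] * 8, liner, liner.internal_radius)
        field = signed_deviation(scan, unit_reference(liner.internal_radius))
        np.testing.assert_allclose(field.dev_um, 0.0, atol=1e-9)

    @pytest.mark.parametrize("side,expected_sign", [
        ("internal_concave", +1.0), ("external_convex", -1.0),
    ])
    def test_radial_inflation_shifts_deviation_by_delta(self, liner, coarse_protocol,
                                                        unit_reference, side, expected_sign):
        scan = simulate_scan(liner, side, coarse_protocol)
        ref = unit_reference(liner.radius(side))
        base = signed_deviation(scan, ref).dev_um
        delta_um = 7.0
        u = scan.points / np.linalg.norm(scan.points, axis=1, keepdims=True)
        scan.points = scan.points + u * delta_um / 1000.0
        inflated = signed_deviation(scan, ref).dev_um
        np.testing.assert_allclose(inflated - base, expected_sign * delta_um, atol=1e-9)

    def test_invariance_under_joint_rigid_transform(self, liner, coarse_protocol):
        scan = simulate_scan(liner, "internal_concave", coarse_protocol,
                             noise=NoiseSpec(sigma=1.0, seed=9))
        ref = fit_reference(scan)
        base = signed_deviation(scan, ref).dev_um
        rot = rotation_about_z(123.0)
        t = np.array([0.5, -1.0, 2.0])
        scan.points = scan.points @ rot.T + t
        moved_ref = ReferenceSphere(
            centre=rot @ ref.centre + t, radius=ref.radius,
            rms_residual=ref.rms_residual, max_abs_residual=ref.max_abs_residual,
            n_points=ref.n_points, n_iterations=ref.n_iterations, converged=True,
        )
        moved = signed_deviation(scan, moved_ref).dev_um
        np.testing.assert_allclose(moved, base, atol=1e-9)


class TestGroundTruthRecovery:
    def test_noise_free_field_matches_ground_truth(self, liner, coarse_protocol):
        defects = [
            DefectSpec(kind="wear_patch", centre=(45, 60), angular_extent=12, magnitude=100.0),
            DefectSpec(kind="circular_mark", centre=(70, 200), angular_extent=6, magnitude=-40.0),
        ]
        scan = simulate_scan(liner, "internal_concave", coarse_protocol, defects)
        gt = ground_truth_field(scan)
        # reference fitted on the defect-free region only
        est = SphereFit().fit(scan.points[gt == 0.0])
        field = signed_deviation(scan, est.result_)
        np.testing.assert_allclose(field.dev_um, gt, atol=1e-6)

    def test_noisy_recovery_rmse_within_noise_floor(self, liner, coarse_protocol):
        patch = DefectSpec(kind="wear_patch", centre=(45, 60), angular_extent=12, magnitude=100.0)
        scan = simulate_scan(liner, "internal_concave", coarse_protocol, [patch],
                             noise=NoiseSpec(sigma=1.0, seed=21))
        ref = fit_reference(scan, robust=True)
        field = signed_deviation(scan, ref)
        rmse = np.sqrt(np.mean((field.dev_um - ground_truth_field(scan)) ** 2))
        assert rmse <= 1.5


class TestSummaries:
    def test_hand_checked_three_values(self, liner, unit_reference):
        # offsets chosen so the deviation multiset is {-5, 0, 5} um repeated
        offs = [-5.0, 0.0, 5.0, -5.0, 0.0, 5.0, -5.0, 0.0]
        scan = tiny_scan("internal_concave", offs, liner, liner.internal_radius)
        stats = summarize(signed_deviation(scan, unit_reference(liner.internal_radius)))
        assert stats.min == pytest.approx(-5.0)
        assert stats.max == pytest.approx(5.0)
        assert stats.median == pytest.approx(0.0)
        assert stats.mean == pytest.approx(np.mean(offs))

    def test_matches_independent_streaming_recomputation(self, liner, coarse_protocol):
        scan = simulate_scan(liner, "internal_concave", coarse_protocol,
                             noise=NoiseSpec(sigma=2.0, seed=17))
        ref = fit_reference(scan)
        field = signed_deviation(scan, ref)
        stats = summarize(field)
        # naive second pass, no numpy reductions
        vals = sorted(float(v) for v in field.dev_um)
        n = len(vals)
        total = 0.0
        for v in vals:
            total += v
        median = (vals[n // 2 - 1] + vals[n // 2]) / 2 if n % 2 == 0 else vals[n // 2]
        assert stats.mean == pytest.approx(total / n, abs=1e-9)
        assert stats.median == pytest.approx(median, abs=1e-9)
        assert stats.min == pytest.approx(vals[0], abs=1e-12)
        assert stats.max == pytest.approx(vals[-1], abs=1e-12)

    def test_summary_ordering_invariants(self, liner, coarse_protocol):
        scan = simulate_scan(liner, "external_convex", coarse_protocol,
                             noise=NoiseSpec(sigma=1.0, seed=2))
        stats = summarize(signed_deviation(scan, fit_reference(scan)))
        assert stats.min <= stats.median <= stats.max
        assert stats.min <= stats.mean <= stats.max


class TestRegionLabelling:
    def test_unworn_noise_free_has_no_regions(self, liner, coarse_protocol, unit_reference):
        scan = simulate_scan(liner, "internal_concave", coarse_protocol)
        field = signed_deviation(scan, unit_reference(liner.internal_radius))
        assert label_regions(field, threshold=1.0) == []

    def test_single_patch_gives_single_penetrating_region(self, liner, coarse_protocol,
                                                          unit_reference):
        patch = DefectSpec(kind="wear_patch", centre=(45, 60), angular_extent=12, magnitude=100.0)
        scan = simulate_scan(liner, "internal_concave", coarse_protocol, [patch])
        field = signed_deviation(scan, unit_reference(liner.internal_radius))
        regions = label_regions(field, threshold=20.0)
        assert len(regions) == 1
        assert regions[0].polarity == "penetrating"
        assert regions[0].peak_dev_um == pytest.approx(100.0, abs=1.0)

    def test_four_marks_give_four_protruding_regions(self, liner, coarse_protocol,
                                                     unit_reference):
        marks = [
            DefectSpec(kind="circular_mark", centre=(60, az), angular_extent=8, magnitude=-60.0)
            for az in (20, 110, 200, 290)
        ]
        scan = simulate_scan(liner, "external_convex", coarse_protocol, marks)
        field = signed_deviation(scan, unit_reference(liner.external_radius))
        regions = label_regions(field, threshold=20.0)
        assert len(regions) == 4
        assert all(r.polarity == "protruding" for r in regions)

    def test_region_spanning_azimuth_seam_is_single(self, liner, coarse_protocol,
                                                    unit_reference):
        # patch centred at azimuth 0 extends across the 355 deg / 0 deg seam
        patch = DefectSpec(kind="wear_patch", centre=(50, 0), angular_extent=15, magnitude=80.0)
        scan = simulate_scan(liner, "internal_concave", coarse_protocol, [patch])
        field = signed_deviation(scan, unit_reference(liner.internal_radius))
        regions = label_regions(field, threshold=20.0)
        assert len(regions) == 1

    def test_min_points_filter(self, liner, coarse_protocol, unit_reference):
        tiny = DefectSpec(kind="wear_patch", centre=(45, 60), angular_extent=2, magnitude=100.0)
        scan = simulate_scan(liner, "internal_concave", coarse_protocol, [tiny])
        field = signed_deviation(scan, unit_reference(liner.internal_radius))
        n_hot = int((field.dev_um >= 20.0).sum())
        assert label_regions(field, threshold=20.0, min_points=n_hot + 1) == []

    def test_subtle_polar_protrusion_detected_below_20um(self, liner):
        # a 15 um polar protrusion under 1 um noise, found at a 10 um threshold
        bump = DefectSpec(kind="polar_protrusion", centre=(0, 0), angular_extent=6,
                          magnitude=-15.0)
        scan = simulate_scan(liner, "internal_concave", ProtocolSpec(), [bump],
                             noise=NoiseSpec(sigma=1.0, seed=30))
        ref = fit_reference(scan)
        field = signed_deviation(scan, ref)
        regions = label_regions(field, threshold=10.0)
        protruding = [r for r in regions if r.polarity == "protruding"]
        assert len(protruding) >= 1
        # height recovered from rasterised cell means (averages the many
        # co-located pole samples instead of trusting one noisy extreme)
        from dmliner import project, rasterize
        grid = rasterize(project(field))
        height = -np.nanmin(grid.values)
        assert abs(height - 15.0) < 3.0


class TestRepeatability:
    @staticmethod
    def stats(radius_mm, mean=0.0, median=0.0, lo=-1.0, hi=1.0):
        return SummaryStats(mean=mean, median=median, min=lo, max=hi,
                            reference_radius=radius_mm, n_points=100)

    def test_identical_repeats_give_zero_sds(self):
        rep = repeatability([self.stats(14.0)] * 5)
        assert rep.radius_sd_um == 0.0
        assert rep.mean_sd_um == rep.median_sd_um == rep.min_sd_um == rep.max_sd_um == 0.0

    def test_hand_checked_radius_sd(self):
        rep = repeatability([self.stats(14.000), self.stats(14.002), self.stats(14.004)])
        assert rep.radius_sd_um == pytest.approx(2.0, abs=1e-9)

    def test_fewer_than_two_repeats_errors(self):
        with pytest.raises(ValueError, match="2 repeats"):
            repeatability([self.stats(14.0)])

    def test_five_simulated_repeats_stay_within_printed_bounds(self, liner):
        # five repeats, sigma = 1 um, reorientations 0/0/0/90/180 deg
        stats = []
        for i, rot in enumerate([0.0, 0.0, 0.0, 90.0, 180.0]):
            scan = simulate_scan(liner, "internal_concave", ProtocolSpec(),
                                 noise=NoiseSpec(sigma=1.0, seed=1 + i),
                                 rotation=rotation_about_z(rot))
            ref = fit_reference(scan)
            stats.append(summarize(signed_deviation(scan, ref)))
        rep = repeatability(stats)
        assert rep.radius_sd_um <= 2.0
        for sd in (rep.mean_sd_um, rep.median_sd_um, rep.min_sd_um, rep.max_sd_um):
            assert sd <= 2.0
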