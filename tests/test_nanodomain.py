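"""MNND, local density, nanodomain detection, subclustering, PSD topology."""

import numpy as np
import pytest
from shapely.geometry import Point

from nanocoloc.exceptions import DegenerateInputError
from nanocoloc.nanodomain import (
    NanodomainParams,
    detect_nanodomains,
    local_density,
    mean_nearest_neighbor_distance,
    psd_centroid,
    split_nanodomain,
    topology_metrics,
)

from _oracles import brute_local_density, brute_mnnd

PARAMS = NanodomainParams()


class TestMnndAndDensity:
    def test_mnnd_collinear_triplet(self):
        pts = np.array([[0, 0], [1, 0], [3, 0]], dtype=float)
        assert mean_nearest_neighbor_distance(pts) == pytest.approx(4 / 3)

    def test_mnnd_pair(self):
        assert mean_nearest_neighbor_distance([[0, 0], [5, 0]]) == pytest.approx(5.0)

    def test_mnnd_single_point_errors(self):
        with pytest.raises(DegenerateInputError):
            mean_nearest_neighbor_distance([[0, 0]])

    def test_ld_collinear_triplet(self):
        pts = np.array([[0, 0], [10, 0], [20, 0]], dtype=float)
        assert local_density(pts, 10.0).tolist() == [1, 2, 1]

    def test_ld_isolated_point_is_zero(self):
        pts = np.array([[0, 0], [1000, 1000]], dtype=float)
        assert local_density(pts, 10.0).tolist() == [0, 0]

    def test_ld_matches_brute_force(self, rng):
        pts = rng.uniform(0, 500, size=(500, 2))
        assert np.array_equal(local_density(pts, 40.0), brute_local_density(pts, 40.0))

    def test_mnnd_matches_brute_force(self, rng):
        pts = rng.uniform(0, 500, size=(200, 2))
        assert mean_nearest_neighbor_distance(pts) == pytest.approx(
            brute_mnnd(pts), rel=1e-12
        )

    @pytest.mark.parametrize("angle", [0.3, 1.2])
    def test_rigid_motion_invariance(self, rng, angle):
        pts = rng.uniform(0, 500, size=(300, 2))
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + np.array([123.4, -56.7])
        assert mean_nearest_neighbor_distance(moved) == pytest.approx(
            mean_nearest_neighbor_distance(pts), rel=1e-9
        )
        assert np.array_equal(local_density(moved, 40.0), local_density(pts, 40.0))

    def test_mnnd_scales_linearly(self, rng):
        pts = rng.uniform(0, 500, size=(100, 2))
        assert mean_nearest_neighbor_distance(pts * 3.0) == pytest.approx(
            3.0 * mean_nearest_neighbor_distance(pts), rel=1e-9
        )


def two_domain_synapse(rng, centers=((70.0, 150.0), (230.0, 150.0)), n_dom=300, n_bg=100):
    parts = [rng.normal(0, 25.0, size=(n_dom, 2)) + c for c in centers]
    parts.append(rng.uniform(0, 300, size=(n_bg, 2)))
    return np.vstack(parts), np.asarray(centers)


class TestDetection:
    def test_two_gaussian_domains_recovered(self, rng):
        pts, centers = two_domain_synapse(rng)
        nds = detect_nanodomains(pts, PARAMS)
        assert len(nds) == 2
        found = np.array(sorted([nd.center_nm.tolist() for nd in nds]))
        for f, c in zip(found, sorted(centers.tolist())):
            assert np.linalg.norm(np.asarray(f) - np.asarray(c)) < 10.0

    def test_uniform_points_below_threshold_yield_nothing(self, rng):
        pts = rng.uniform(0, 600, size=(200, 2))
        field = local_density(
            pts, PARAMS.density_radius_factor * mean_nearest_neighbor_distance(pts)
        )
        assert field.max() <= 40  # oracle precondition: nothing passes
        assert detect_nanodomains(pts, PARAMS) == []

    def test_small_member_fraction_excluded(self, rng):
        # dense 50-point knot next to a 900-point domain + sparse background:
        # the knot holds <5% of the synapse's localizations
        r = 60 * np.sqrt(rng.uniform(0, 1, 900))
        a = rng.uniform(0, 2 * np.pi, 900)
        big = np.column_stack([r * np.cos(a), r * np.sin(a)])
        knot = rng.normal(0, 3.0, size=(50, 2)) + [400.0, 0.0]
        gx, gy = np.meshgrid(np.arange(10), np.arange(15))
        bg = np.column_stack([gx.ravel() * 30.0 + 100, gy.ravel() * 30.0 - 200])
        pts = np.vstack([big, knot, bg])
        assert 50 / len(pts) < 0.05
        defaults = detect_nanodomains(pts, PARAMS)
        assert sum(
            np.linalg.norm(nd.center_nm - [400.0, 0.0]) < 20 for nd in defaults
        ) == 0
        relaxed = detect_nanodomains(
            pts, NanodomainParams(min_member_fraction=0.03)
        )
        assert sum(
            np.linalg.norm(nd.center_nm - [400.0, 0.0]) < 20 for nd in relaxed
        ) == 1

    def test_small_diameter_excluded(self, rng):
        # Voronoi cells clipped to a 25-nm-diameter ROI: equal-area-circle
        # diameter 25 nm < 30 nm, so the (otherwise dense) cluster is dropped
        knot = rng.normal(0, 3.0, size=(60, 2))
        sparse = np.column_stack([200.0 + 30.0 * np.arange(15), np.zeros(15)])
        pts = np.vstack([knot, sparse])
        roi = Point(0, 0).buffer(12.5, quad_segs=64)
        assert detect_nanodomains(pts, PARAMS, roi=roi) == []
        kept = detect_nanodomains(pts, NanodomainParams(min_diameter_nm=20.0), roi=roi)
        assert len(kept) == 1
        assert kept[0].diameter_nm == pytest.approx(25.0, rel=0.02)

    def test_members_partition_and_lie_in_boundary(self, rng):
        pts, _ = two_domain_synapse(rng)
        nds = detect_nanodomains(pts, PARAMS)
        seen = np.concatenate([nd.members for nd in nds])
        assert len(seen) == len(set(seen))  # no point in two nanodomains
        for nd in nds:
            assert nd.member_fraction >= PARAMS.min_member_fraction
            assert nd.diameter_nm >= PARAMS.min_diameter_nm
            for i in nd.members:
                assert nd.boundary.covers(Point(*pts[i]))

    def test_detection_count_is_rigid_motion_invariant(self, rng):
        pts, _ = two_domain_synapse(rng)
        angle = 0.7
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + 500.0
        assert len(detect_nanodomains(moved, PARAMS)) == len(
            detect_nanodomains(pts, PARAMS)
        )


def ridge_groups(positions_x, ld):
    """Points on the x-axis with prescribed LD values."""
    pts = np.column_stack([positions_x, np.zeros(len(positions_x))])
    return pts, np.asarray(ld, dtype=float)


class TestSubclusterRule:
    # 11 points, two density lobes; LD profile controls the rule directly
    LD_TWO_PEAKS = [100, 85, 60, 40, 25, 20, 25, 40, 60, 85, 90]

    def test_split_when_all_conditions_met(self):
        # peaks at 100% and 90% of max, 100 nm apart, valley at 20%
        pts, ld = ridge_groups(np.arange(11) * 10.0, self.LD_TWO_PEAKS)
        groups = split_nanodomain(pts, ld, PARAMS)
        assert len(groups) == 2
        assert {len(g) for g in groups} == {5, 6}

    def test_no_split_when_peaks_too_close(self):
        # same profile compressed to 60 nm total extent
        pts, ld = ridge_groups(np.arange(11) * 6.0, self.LD_TWO_PEAKS)
        assert len(split_nanodomain(pts, ld, PARAMS)) == 1

    def test_no_split_when_second_peak_too_low(self):
        # second lobe tops out at 70% of the maximum
        ld = [100, 85, 60, 40, 25, 20, 25, 40, 55, 65, 70]
        pts, ld = ridge_groups(np.arange(11) * 10.0, ld)
        assert len(split_nanodomain(pts, ld, PARAMS)) == 1

    def test_no_split_without_valley(self):
        # both peaks high and far apart, but the corridor never dips below 30%
        ld = [100, 95, 90, 85, 80, 78, 80, 85, 90, 95, 98]
        pts, ld = ridge_groups(np.arange(11) * 10.0, ld)
        assert len(split_nanodomain(pts, ld, PARAMS)) == 1

    def test_members_reassigned_to_nearest_peak(self):
        pts, ld = ridge_groups(np.arange(11) * 10.0, self.LD_TWO_PEAKS)
        groups = sorted(split_nanodomain(pts, ld, PARAMS), key=lambda g: g.min())
        assert groups[0].tolist() == [0, 1, 2, 3, 4, 5]  # x <= 50 nearer peak at 0
        assert groups[1].tolist() == [6, 7, 8, 9, 10]


class TestPsdCentroid:
    def test_gaussian_cluster_center_recovered(self, rng):
        mu = np.array([500.0, 300.0])
        pts = np.vstack(
            [rng.normal(0, 60.0, size=(800, 2)) + mu, rng.uniform(-1000, 2000, size=(20, 2))]
        )
        center, area_um2, members = psd_centroid(pts)
        assert np.linalg.norm(center - mu) < 10.0
        assert area_um2 > 0
        assert len(members) >= 800 * 0.95

    def test_symmetric_square(self):
        pts = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        center, _, _ = psd_centroid(pts, eps_nm=20.0, min_pts=2)
        assert center == pytest.approx([5.0, 5.0])

    def test_too_few_points_errors(self):
        with pytest.raises(DegenerateInputError):
            psd_centroid(np.zeros((3, 2)), min_pts=10)


class TestTopology:
    def _domain(self, x, y, channel):
        from nanocoloc.nanodomain import Nanodomain

        return Nanodomain(
            members=np.array([0]),
            center_nm=np.array([x, y], dtype=float),
            boundary=Point(x, y).buffer(20.0),
            diameter_nm=40.0,
            max_extent_nm=40.0,
            member_fraction=0.5,
            channel=channel,
        )

    def test_nearest_cross_channel_distance(self):
        metrics = topology_metrics(
            {"A": [self._domain(0, 0, "A")], "B": [self._domain(50, 0, "B"), self._domain(200, 0, "B")]},
            psd_center_nm=np.zeros(2),
        )
        assert metrics.cross_channel_dist["A"].tolist() == [50.0]

    def test_distance_to_psd_center(self):
        metrics = topology_metrics(
            {"A": [self._domain(30, 40, "A")], "B": []}, psd_center_nm=np.zeros(2)
        )
        assert metrics.dist_to_psd["A"].tolist() == [50.0]

    def test_missing_other_channel_flagged(self):
        metrics = topology_metrics(
            {"A": [self._domain(0, 0, "A")], "B": []}, psd_center_nm=np.zeros(2)
        )
        assert np.isnan(metrics.cross_channel_dist["A"]).all()
        assert any("no_other_channel" in f for f in metrics.flags)
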