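"""Synthetic-data generators: layouts, partition ratios, topography, dimers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtopo import (
    Bump,
    Enrichment,
    Fold,
    InfeasibleLayoutError,
    PartitionSpec,
    build_membrane_map,
    generate_cluster_layout,
    partition_counts,
    sample_partitioned,
    sample_topography,
    simulate_dimers,
    thin_detections,
)


class TestClusterLayout:
    def test_reference_layout_geometry(self):
        layout = generate_cluster_layout(52, 32, 2048, 2048, seed=1)
        assert layout.n_clusters == 52
        c = layout.centers
        assert (c[:, 0] >= 32).all() and (c[:, 0] <= 2016).all()
        assert (c[:, 1] >= 32).all() and (c[:, 1] <= 2016).all()
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert (d > 64).all()  # neither overlap nor touch
        assert layout.area_fraction == pytest.approx(52 * np.pi * 32**2 / 2048**2)

    def test_deterministic_per_seed(self):
        a = generate_cluster_layout(10, 20, 512, 512, seed=5)
        b = generate_cluster_layout(10, 20, 512, 512, seed=5)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_empty_layout(self):
        layout = generate_cluster_layout(0, 32, 512, 512, seed=0)
        assert layout.n_clusters == 0
        assert layout.area_fraction == 0.0
        assert not layout.contains([10.0], [10.0]).any()

    def test_infeasible_packing_raises(self):
        # centers of radius-10 disks in a 20x20 image must all sit at
        # (10, 10): no second disk can ever be placed.
        with pytest.raises(InfeasibleLayoutError):
            generate_cluster_layout(5, 10, 20, 20, seed=0, max_attempts=5000)


class TestPartitionCounts:
    @pytest.mark.parametrize(
        "n, f, ratio, expected_in",
        [
            (10_000, 0.04, 1.0, 400),  # uniform density: f * N
            (10_000, 0.04, 4.0, 1429),  # 10000 * 0.16 / 1.12 = 1428.57
            (10_000, 0.04, 1e9, 10_000),  # limit: everything in-cluster
        ],
    )
    def test_closed_form(self, n, f, ratio, expected_in):
        n_in, n_out = partition_counts(n, f, ratio)
        assert n_in == expected_in
        assert n_in + n_out == n

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            partition_counts(100, 0.04, 0.5)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.floats(1.0, 100.0), st.floats(1.0, 100.0))
    def test_n_in_non_decreasing_in_ratio(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert partition_counts(10_000, 0.04, lo)[0] <= partition_counts(10_000, 0.04, hi)[0]

    def test_realized_ratio_converges(self):
        # in/out density ratio of the returned counts approaches R
        f, R = 0.04, 4.0
        n_in, n_out = partition_counts(10**6, f, R)
        realized = (n_in / f) / (n_out / (1 - f))
        assert realized == pytest.approx(R, rel=0.01)


@pytest.fixture(scope="module")
def layout():
    return generate_cluster_layout(52, 32, 2048, 2048, seed=1)


class TestSamplePartitioned:
    def test_pool_membership_is_exact(self, layout):
        table = sample_partitioned(PartitionSpec(20_000, 4.0, layout), seed=7)
        pools = table.data["pool"]
        assert layout.contains(table.x[pools == "in"], table.y[pools == "in"]).all()
        assert not layout.contains(table.x[pools == "out"], table.y[pools == "out"]).any()

    def test_lower_ratio_is_prefix_of_higher(self, layout):
        hi = sample_partitioned(PartitionSpec(20_000, 4.0, layout), seed=7)
        lo = sample_partitioned(PartitionSpec(20_000, 2.0, layout), seed=7)
        for pool in ("in", "out"):
            a = hi.data[hi.data["pool"] == pool][["x", "y"]].to_numpy()
            b = lo.data[lo.data["pool"] == pool][["x", "y"]].to_numpy()
            k = min(len(a), len(b))
            np.testing.assert_array_equal(a[:k], b[:k])

    def test_ratio_one_in_disk_fraction_is_area_fraction(self, layout):
        table = sample_partitioned(PartitionSpec(50_000, 1.0, layout), seed=3)
        frac = layout.contains(table.x, table.y).mean()
        f = layout.area_fraction
        sd = np.sqrt(f * (1 - f) / 50_000)
        assert abs(frac - f) < 5 * sd

    def test_counts_match_spec(self, layout):
        spec = PartitionSpec(20_000, 4.0, layout)
        n_in, n_out = spec.counts
        table = sample_partitioned(spec, seed=7)
        assert (table.data["pool"] == "in").sum() == n_in
        assert (table.data["pool"] == "out").sum() == n_out


class TestMembraneMap:
    def test_flat_membrane_is_unity(self):
        mmap = build_membrane_map(64, 64)
        np.testing.assert_array_equal(mmap.area_factor, 1.0)

    def test_fold_adds_layers_on_stripe_only(self):
        mmap = build_membrane_map(64, 64, [Fold(10, 20, 0, 64, extra_layers=2)])
        assert (mmap.area_factor[:, 10:20] == 3).all()
        assert (mmap.area_factor[:, :10] == 1).all()
        assert (mmap.area_factor[:, 20:] == 1).all()

    def test_bump_max_slope_factor(self):
        s = 2.0
        mmap = build_membrane_map(256, 256, [Bump(128, 128, 20, max_slope=s)])
        assert mmap.slope.max() == pytest.approx(np.sqrt(1 + s**2), rel=1e-3)
        assert (mmap.slope >= 1).all()

    def test_feature_outside_image_rejected(self):
        with pytest.raises(ValueError):
            build_membrane_map(64, 64, [Fold(60, 70, 0, 64)])


class TestSampleTopography:
    def test_flat_membrane_is_csr_by_quadrat_chi_square(self):
        from scipy.stats import chisquare

        mmap = build_membrane_map(256, 256)
        table = sample_topography(mmap, 10_000, False, seed=2)
        counts, _, _ = np.histogram2d(table.y, table.x, bins=4, range=[[0, 256], [0, 256]])
        assert chisquare(counts.ravel()).pvalue > 0.01

    def test_stripe_weight_arithmetic(self):
        # L = 3 over ~10% of the area -> stripe holds 3*0.1/(3*0.1+0.9) ~ 25%
        w = 512
        stripe = 51  # 51/512 = 9.96 %
        mmap = build_membrane_map(w, w, [Fold(0, stripe, 0, w, extra_layers=2)])
        table = sample_topography(mmap, 100_000, False, seed=5)
        frac = (table.x < stripe).mean()
        p = 3 * (stripe / w) / (3 * (stripe / w) + (1 - stripe / w))
        assert frac == pytest.approx(p, abs=0.01)

    def test_enrichment_affects_protein_mode_only(self):
        mmap = build_membrane_map(256, 256, [Enrichment(128, 128, 40, factor=4.0)])
        inside = mmap.footprints["enrichment_0"]
        area = inside.mean()
        prot = sample_topography(mmap, 50_000, True, seed=6)
        mark = sample_topography(mmap, 50_000, False, seed=6)
        r2 = (prot.x - 128) ** 2 + (prot.y - 128) ** 2
        frac_p = (r2 <= 40**2).mean()
        r2m = (mark.x - 128) ** 2 + (mark.y - 128) ** 2
        frac_m = (r2m <= 40**2).mean()
        assert frac_m == pytest.approx(area, abs=0.01)
        assert frac_p == pytest.approx(4 * area / (4 * area + 1 - area), abs=0.01)

    def test_deterministic_per_seed(self):
        mmap = build_membrane_map(64, 64)
        a = sample_topography(mmap, 1000, False, seed=9)
        b = sample_topography(mmap, 1000, False, seed=9)
        np.testing.assert_array_equal(a.xy, b.xy)


@pytest.fixture(scope="module")
def field():
    return simulate_dimers(4048, 600, 600, seed=11)


class TestDimers:
    def test_counts_and_distinct_black_pixels(self, field):
        assert len(field.black) == len(field.red) == 4048
        flat = field.black[:, 0] * 600 + field.black[:, 1]
        assert len(np.unique(flat)) == 4048

    def test_partner_in_eight_neighbourhood(self, field):
        d = np.linalg.norm(field.black_xy - field.red_xy[field.partner], axis=1)
        assert set(np.round(d, 6)) <= {1.0, round(np.sqrt(2), 6)}

    def test_central_window_count_near_expectation(self, field):
        count = field.black_in_central(512).sum()
        expected = 4048 * (512 / 600) ** 2
        sd = 28  # binomial
        assert abs(count - expected) < 4 * sd

    def test_thinning_counts(self, field):
        thin = thin_detections(field, 0.5, seed=12)
        assert len(thin.red) == 2024
        assert (thin.partner >= 0).sum() <= 2024
        # surviving partner links still point at the right molecules
        has = thin.partner >= 0
        d = np.linalg.norm(
            thin.black_xy[has] - thin.red_xy[thin.partner[has]], axis=1
        )
        assert d.max() <= np.sqrt(2) + 1e-9

    def test_full_detection_is_identity(self, field):
        same = thin_detections(field, 1.0, seed=13)
        np.testing.assert_array_equal(same.red, field.red)
        np.testing.assert_array_equal(same.partner, field.partner)

    def test_invalid_fraction_rejected(self, field):
        with pytest.raises(ValueError):
            thin_detections(field, 0.0, seed=0)

    def test_mean_nn_distance_non_decreasing_as_detection_drops(self):
        from memtopo import nearest_neighbour

        # stochastic monotonicity: averaged over seeds
        means = {d: [] for d in (1.0, 0.7, 0.4)}
        for seed in range(20):
            field = simulate_dimers(1000, 300, 300, seed=seed)
            for d in means:
                f = thin_detections(field, d, seed=1000 + seed)
                nn = nearest_neighbour(
                    f.black_xy, f.red_xy, method="distance_map",
                    grid_shape=(300, 300),
                )
                means[d].append(nn.distances.mean())
        avg = {d: np.mean(v) for d, v in means.items()}
        assert avg[1.0] < avg[0.7] < avg[0.4]

    def test_unpaired_csr_mean_nn_also_grows_when_thinned(self):
        """Thinning an *unpaired* CSR target set likewise inflates the
        mean nearest-neighbour distance (the two designs converge as the
        detected fraction drops)."""
        from scipy.spatial import cKDTree

        means = {d: [] for d in (1.0, 0.7, 0.4)}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            black = rng.uniform(0, 300, (1000, 2))
            red = rng.uniform(0, 300, (1000, 2))
            order = rng.permutation(1000)
            for d in means:
                sub = red[order[: int(round(d * 1000))]]
                dist, _ = cKDTree(sub).query(black)
                means[d].append(dist.mean())
        avg = {d: np.mean(v) for d, v in means.items()}
        assert avg[1.0] < avg[0.7] < avg[0.4]
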