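import numpy as np
import pandas as pd
import pytest

import isoniche as iso
from isoniche import community as cm
from isoniche.ellipses import EllipseFit, GroupKey


def fit_at(x, y, species, size_class="pooled", n=10):
    return EllipseFit(
        GroupKey(species, "R", size_class), n,
        np.array([x, y], float), np.eye(2), np.pi, np.pi * (n - 1) / (n - 2),
    )


class TestCentroid:
    def test_arithmetic_mean_of_centers(self):
        fits = [fit_at(0, 0, "a"), fit_at(2, 0, "b"), fit_at(1, 3, "c")]
        assert np.allclose(iso.community_centroid(fits), [1, 1])

    def test_translation_equivariance(self):
        fits = [fit_at(0, 0, "a"), fit_at(2, 0, "b"), fit_at(1, 3, "c")]
        shifted = [fit_at(f.center[0] + 5.0, f.center[1] - 2.5, f.group.species)
                   for f in fits]
        assert np.allclose(
            iso.community_centroid(shifted),
            iso.community_centroid(fits) + np.array([5.0, -2.5]),
        )

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            iso.community_centroid([fit_at(0, 0, "a"), fit_at(1, 1, "a")])

    def test_recovers_configured_mean_of_means(self):
        # large-n simulated species: centroid within 0.02 permil of the
        # configured mean of the species means
        from isoniche.simulate import drift_community
        specs = drift_community(n_per_group=5000, shift_per_cm=0.0)
        df = iso.simulate_isotopes(specs, seed=3)
        fits = iso.fit_ellipses(df, mode="pooled", d13c_col="d13c_raw")
        truth = np.mean([s.mu for s in specs], axis=0)
        assert np.allclose(iso.community_centroid(fits), truth, atol=0.02)


class TestDistancesToCentroid:
    def test_two_symmetric_species(self):
        fits = [fit_at(0, 0, "a"), fit_at(2, 0, "b")]
        d, mean, se = iso.distances_to_centroid(
            fits, iso.community_centroid(fits))
        assert list(d.values()) == pytest.approx([1.0, 1.0])
        assert mean == 1.0

    def test_group_at_centroid_has_zero_distance(self):
        fits = [fit_at(1, 1, "a"), fit_at(0, 0, "b"), fit_at(2, 2, "c")]
        d, _, _ = iso.distances_to_centroid(fits, np.array([1.0, 1.0]))
        assert d[GroupKey("a", "R", "pooled")] == 0.0

    def test_hand_computed_triangle(self):
        # centers (0,0), (0,3), (4,0): centroid (4/3, 1); distances
        # 5/3, sqrt(52)/3, sqrt(73)/3 -> mean of the three
        fits = [fit_at(0, 0, "a"), fit_at(0, 3, "b"), fit_at(4, 0, "c")]
        centroid = iso.community_centroid(fits)
        assert np.allclose(centroid, [4 / 3, 1.0])
        d, mean, _ = iso.distances_to_centroid(fits, centroid)
        expected = [5 / 3, np.sqrt(52) / 3, np.sqrt(73) / 3]
        assert sorted(d.values()) == pytest.approx(sorted(expected))
        assert mean == pytest.approx(np.mean(expected))
        assert mean == pytest.approx(2.3061, abs=1e-4)


class TestNearestNeighbour:
    def test_two_species_mutual_distance(self):
        fits = [fit_at(0, 0, "a"), fit_at(3, 4, "b")]
        dnn, mean, sd = iso.nearest_neighbour_stats(fits)
        assert all(v == 5.0 for v in dnn.values())
        assert mean == 5.0 and sd == 0.0

    def test_three_on_a_line(self):
        fits = [fit_at(0, 0, "a"), fit_at(1, 0, "b"), fit_at(3, 0, "c")]
        dnn, mean, sd = iso.nearest_neighbour_stats(fits)
        assert sorted(dnn.values()) == [1.0, 1.0, 2.0]
        assert mean == pytest.approx(4 / 3)
        assert sd == pytest.approx(np.sqrt(1 / 3))

    def test_same_species_group_never_its_own_neighbour(self):
        fits = [
            fit_at(0, 0, "a", "small"), fit_at(0.01, 0, "a", "large"),
            fit_at(1, 0, "b"),
        ]
        dnn, _, _ = iso.nearest_neighbour_stats(fits)
        # a's groups must look to species b, not to each other
        assert dnn[GroupKey("a", "R", "small")] == pytest.approx(1.0)
        assert dnn[GroupKey("a", "R", "large")] == pytest.approx(0.99)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            iso.nearest_neighbour_stats([fit_at(0, 0, "a", "small"),
                                         fit_at(1, 1, "a", "large")])

    def test_rigid_motion_invariance_and_scaling(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5, 2))
        fits = [fit_at(x, y, f"s{i}") for i, (x, y) in enumerate(pts)]
        _, mean, sd = iso.nearest_neighbour_stats(fits)
        shifted = [fit_at(x + 3, y - 7, f"s{i}") for i, (x, y) in enumerate(pts)]
        _, mean_s, sd_s = iso.nearest_neighbour_stats(shifted)
        assert mean_s == pytest.approx(mean) and sd_s == pytest.approx(sd)
        scaled = [fit_at(2 * x, 2 * y, f"s{i}") for i, (x, y) in enumerate(pts)]
        _, mean_2, sd_2 = iso.nearest_neighbour_stats(scaled)
        assert mean_2 == pytest.approx(2 * mean) and sd_2 == pytest.approx(2 * sd)


class TestBootstrap:
    def samples(self, rng, n=15, spread=1.0):
        rows = []
        for i, mu in enumerate([(0, 0), (2, 0), (0, 2), (2, 2)]):
            xy = rng.normal(mu, 0.3 * spread, size=(n, 2))
            rows.append(pd.DataFrame({
                "species": f"s{i}", "region": "R", "size_class": "pooled",
                "d13c_norm": xy[:, 0], "d15n": xy[:, 1],
            }))
        return pd.concat(rows, ignore_index=True)

    def test_identical_points_give_zero_width(self):
        rows = []
        for i, mu in enumerate([(0.0, 0.0), (1.0, 0.0)]):
            rows.append(pd.DataFrame({
                "species": f"s{i}", "region": "R", "size_class": "pooled",
                "d13c_norm": [mu[0]] * 5, "d15n": [mu[1]] * 5,
            }))
        cis = iso.bootstrap_dnn(pd.concat(rows), n_boot=200, seed=0)
        lo, hi = cis["ci_mean_dnn"]
        assert lo == hi == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        df = self.samples(np.random.default_rng(1))
        a = iso.bootstrap_dnn(df, n_boot=500, seed=11)
        b = iso.bootstrap_dnn(df, n_boot=500, seed=11)
        assert a == b

    def test_interval_orientation(self):
        df = self.samples(np.random.default_rng(2))
        cis = iso.bootstrap_dnn(df, n_boot=500, seed=3)
        for lo, hi in cis.values():
            assert lo <= hi

    def test_width_shrinks_with_sample_size(self):
        # ~1/sqrt(n): doubling per-group n narrows the interval on
        # average over paired seeds
        widths_small, widths_big = [], []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            small = self.samples(rng, n=10)
            rng = np.random.default_rng(seed)
            big = self.samples(rng, n=40)
            w = iso.bootstrap_dnn(small, n_boot=400, seed=seed)["ci_mean_dnn"]
            widths_small.append(w[1] - w[0])
            w = iso.bootstrap_dnn(big, n_boot=400, seed=seed)["ci_mean_dnn"]
            widths_big.append(w[1] - w[0])
        assert np.mean(widths_big) < np.mean(widths_small)

    def test_small_group_rejected(self):
        df = pd.DataFrame({
            "species": ["a"] * 2 + ["b"] * 5, "region": "R",
            "size_class": "pooled",
            "d13c_norm": np.arange(7.0), "d15n": np.arange(7.0),
        })
        with pytest.raises(ValueError, match="n=2"):
            iso.bootstrap_dnn(df, n_boot=100, seed=0)


class TestMetricsFromCentroids:
    def test_hand_computed_table(self):
        # synthetic centroid table (stand-in for externally supplied
        # ellipse centers): three species on a right triangle
        df = pd.DataFrame({
            "region": "R", "species": ["a", "b", "c"],
            "mu_c": [0.0, 0.0, 4.0], "mu_n": [0.0, 3.0, 0.0],
        })
        out = iso.metrics_from_centroids(df)
        row = out.iloc[0]
        assert row["centroid_c"] == pytest.approx(4 / 3)
        assert row["centroid_n"] == pytest.approx(1.0)
        assert row["mean_cd"] == pytest.approx(
            np.mean([5 / 3, np.sqrt(52) / 3, np.sqrt(73) / 3]))
        # pairwise distances 3, 4, 5 -> DNNs {3, 3, 4}
        assert row["mean_dnn"] == pytest.approx(10 / 3)
        assert row["sd_dnn"] == pytest.approx(np.std([3, 3, 4], ddof=1))

    def test_regions_kept_separate(self):
        df = pd.DataFrame({
            "region": ["R1"] * 2 + ["R2"] * 2,
            "species": ["a", "b", "a", "b"],
            "mu_c": [0.0, 1.0, 0.0, 2.0], "mu_n": [0.0, 0.0, 0.0, 0.0],
        })
        out = iso.metrics_from_centroids(df).set_index("region")
        assert out.loc["R1", "mean_dnn"] == pytest.approx(1.0)
        assert out.loc["R2", "mean_dnn"] == pytest.approx(2.0)


class TestStandardization:
    def test_unit_sd_axes_change_distances_but_not_structure(self):
        fits = [fit_at(0, 0, "a"), fit_at(4, 0, "b"), fit_at(0, 1, "c")]
        raw = cm.region_metrics(fits, fits, "R", "pooled")
        std = cm.region_metrics(fits, fits, "R", "pooled", standardize=True)
        # x-axis spread (SD over centers) is 4x the y-axis spread, so
        # standardizing shrinks x-distances relative to y-distances
        assert std.mean_dnn != pytest.approx(raw.mean_dnn)
        centers_sd = np.std([[0, 0], [4, 0], [0, 1]], axis=0, ddof=1)
        expected_ab = np.hypot(4 / centers_sd[0], 0)
        assert std.dnn[GroupKey("b", "R", "pooled")] == pytest.approx(
            min(expected_ab, np.hypot(4 / centers_sd[0], 1 / centers_sd[1])))

    def test_standardize_incompatible_with_bootstrap(self):
        fits = [fit_at(0, 0, "a"), fit_at(1, 0, "b")]
        with pytest.raises(ValueError, match="standardized"):
            cm.region_metrics(fits, fits, "R", "pooled",
                              samples=pd.DataFrame(), standardize=True)


class TestRegionLengthModel:
    def make(self, rng, length_beta=0.0, n_per=20, noise=0.5):
        rows = []
        for r, off in (("A", 0.0), ("B", 0.6), ("C", -0.4)):
            lengths = rng.uniform(10, 50, n_per)
            rows.append(pd.DataFrame({
                "region": r, "length_cm": lengths,
                "d15n": off + length_beta * lengths
                + rng.normal(0, noise, n_per),
            }))
        return pd.concat(rows, ignore_index=True)

    def test_recovers_length_effect(self):
        rng = np.random.default_rng(5)
        df = self.make(rng, length_beta=0.04, noise=0.2)
        m = iso.fit_region_length_model(df, "d15n")
        assert m.p_value("length") < 0.01
        assert m.params["length"] == pytest.approx(0.04, abs=0.02)

    def test_constant_response_degenerate(self, caplog):
        df = self.make(np.random.default_rng(1))
        df["d15n"] = 7.0
        with caplog.at_level("WARNING"):
            m = iso.fit_region_length_model(df, "d15n")
        assert m.degenerate

    def test_single_region_reduces_to_regression(self, caplog):
        rng = np.random.default_rng(2)
        df = self.make(rng, length_beta=0.05)
        df = df[df["region"] == "A"]
        with caplog.at_level("WARNING"):
            m = iso.fit_region_length_model(df, "d15n")
        assert "simple regression" in caplog.text
        assert "length" in m.params
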