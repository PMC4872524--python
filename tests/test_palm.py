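import numpy as np
import pandas as pd
import pytest

from microtrap.palm import (
    EmitterModel,
    EstimationError,
    cluster_centromeres,
    nn_precision,
    read_localizations,
    render_map,
    simulate_localizations,
    write_localizations,
)


@pytest.fixture(scope="module")
def default_table():
    return simulate_localizations(EmitterModel(sigma_true=12.0), rng_seed=42)


class TestGenerator:
    def test_always_on_emitters_yield_frames_times_emitters_rows(self):
        model = EmitterModel(n_clusters=2, emitters_per_cluster=3, frames=40,
                             activation_probability=1.0, sigma_true=0.0,
                             background_density=0.0)
        df = simulate_localizations(model, rng_seed=0)
        assert len(df) == 40 * 6

    def test_zero_error_localizations_coincide_with_emitters(self):
        model = EmitterModel(n_clusters=3, emitters_per_cluster=5, frames=50,
                             activation_probability=0.3, sigma_true=0.0,
                             background_density=0.0)
        df = simulate_localizations(model, rng_seed=1)
        # every emitter has a single exact position: per-truth-id spread is zero
        spread = df.groupby("truth_id")[["x_nm", "y_nm"]].std().fillna(0)
        assert (spread.to_numpy() < 1e-9).all()

    def test_empirical_scatter_matches_sigma(self):
        model = EmitterModel(n_clusters=1, emitters_per_cluster=4, frames=4000,
                             activation_probability=0.5, on_persistence=0.5,
                             sigma_true=12.0, background_density=0.0)
        df = simulate_localizations(model, rng_seed=2)
        sds = df.groupby("truth_id")[["x_nm", "y_nm"]].std().to_numpy().ravel()
        assert np.allclose(sds, 12.0, rtol=0.1)

    def test_background_rows_marked(self):
        model = EmitterModel(n_clusters=0, emitters_per_cluster=0, frames=200,
                             background_density=1.0)
        df = simulate_localizations(model, rng_seed=3)
        assert len(df) > 0
        assert (df["truth_id"] == -1).all()

    def test_frames_nondecreasing(self, default_table):
        assert (np.diff(default_table["frame"].to_numpy()) >= 0).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            EmitterModel(activation_probability=1.5)


class TestIO:
    def test_roundtrip(self, tmp_path, default_table):
        path = tmp_path / "locs.csv"
        write_localizations(default_table, path)
        again = read_localizations(path)
        assert len(again) == len(default_table)
        assert np.allclose(again["x_nm"], default_table["x_nm"])

    def test_extra_columns_tolerated(self, tmp_path):
        path = tmp_path / "locs.csv"
        pd.DataFrame({"frame": [0, 1], "x_nm": [1.0, 2.0], "y_nm": [3.0, 4.0],
                      "intensity": [9, 9]}).to_csv(path, index=False)
        df = read_localizations(path)
        assert len(df) == 2

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "locs.csv"
        pd.DataFrame({"frame": [0], "x_nm": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            read_localizations(path)


class TestPrecision:
    def test_recovers_generator_sigma(self, default_table):
        est = nn_precision(default_table, rng_seed=0, n_bootstrap=50)
        assert est.sigma_loc == pytest.approx(12.0, rel=0.10)
        assert est.ci_low <= est.sigma_loc <= est.ci_high
        assert est.n_pairs >= 100

    def test_degenerate_zero_sigma(self):
        model = EmitterModel(sigma_true=0.0, background_density=0.0)
        df = simulate_localizations(model, rng_seed=5)
        est = nn_precision(df, bin_width=2.0, rng_seed=0, n_bootstrap=20)
        assert est.sigma_loc < 2.0   # below the binning resolution

    def test_translation_and_rotation_invariance(self, default_table):
        est0 = nn_precision(default_table, rng_seed=0, n_bootstrap=0)
        moved = default_table.copy()
        th = 0.7
        x = moved["x_nm"].to_numpy() + 5000.0
        y = moved["y_nm"].to_numpy() - 3000.0
        moved["x_nm"] = np.cos(th) * x - np.sin(th) * y
        moved["y_nm"] = np.sin(th) * x + np.cos(th) * y
        est1 = nn_precision(moved, rng_seed=0, n_bootstrap=0)
        assert est1.sigma_loc == pytest.approx(est0.sigma_loc, rel=1e-6)

    def test_too_few_pairs_raises(self):
        df = pd.DataFrame({"frame": [0, 1], "x_nm": [0.0, 1.0], "y_nm": [0.0, 1.0]})
        with pytest.raises(EstimationError):
            nn_precision(df)

    def test_single_frame_raises(self):
        df = pd.DataFrame({"frame": [0, 0], "x_nm": [0.0, 1.0], "y_nm": [0.0, 1.0]})
        with pytest.raises(EstimationError):
            nn_precision(df)

    @pytest.mark.parametrize("sigma", [5.0, 12.0, 20.0])
    def test_bias_and_coverage_across_replicates(self, sigma):
        """Bias < 10% and CI coverage >= 80% over 20 seeded replicates."""
        cover = 0
        for rep in range(20):
            df = simulate_localizations(EmitterModel(sigma_true=sigma),
                                        rng_seed=1000 + rep)
            est = nn_precision(df, rng_seed=rep, n_bootstrap=60)
            assert abs(est.sigma_loc - sigma) / sigma < 0.10
            cover += est.ci_low <= sigma <= est.ci_high
        assert cover >= 16


class TestClusters:
    def test_recovers_planted_clusters(self, default_table):
        rep = cluster_centromeres(default_table, radius=50, min_points=10,
                                  sigma_loc=12.0)
        assert rep.n_clusters == 8
        assert np.allclose(rep.diameters, 200.0, rtol=0.15)

    def test_single_emitter_min_points_one(self):
        df = pd.DataFrame({"frame": [0], "x_nm": [100.0], "y_nm": [200.0]})
        rep = cluster_centromeres(df, radius=50, min_points=1)
        assert rep.n_clusters == 1
        assert np.allclose(rep.centroids[0], [100.0, 200.0])

    def test_sparse_background_yields_no_clusters(self):
        model = EmitterModel(n_clusters=0, emitters_per_cluster=0, frames=500,
                             background_density=0.05)
        df = simulate_localizations(model, rng_seed=6)
        rep = cluster_centromeres(df, radius=50, min_points=10)
        assert rep.n_clusters == 0

    def test_order_invariance(self, default_table):
        rep0 = cluster_centromeres(default_table, radius=50, min_points=10)
        shuffled = default_table.sample(frac=1.0, random_state=4)
        rep1 = cluster_centromeres(shuffled, radius=50, min_points=10)
        assert rep1.n_clusters == rep0.n_clusters
        c0 = rep0.centroids[np.lexsort(rep0.centroids.T)]
        c1 = rep1.centroids[np.lexsort(rep1.centroids.T)]
        assert np.allclose(c0, c1)

    def test_empty_table_ok(self):
        df = pd.DataFrame({"frame": [], "x_nm": [], "y_nm": []})
        assert cluster_centromeres(df).n_clusters == 0


class TestRenderMap:
    def test_single_localization_single_pixel(self):
        df = pd.DataFrame({"frame": [0], "x_nm": [55.0], "y_nm": [75.0]})
        img = render_map(df, pixel=10.0)
        assert (img > 0).sum() == 1

    def test_blur_conserves_intensity(self, default_table):
        img0 = render_map(default_table, pixel=20.0)
        img1 = render_map(default_table, pixel=20.0, blur_sigma=1.0)
        assert img1.sum() == pytest.approx(img0.sum(), rel=1e-6)

    def test_two_clusters_two_maxima(self):
        rng = np.random.default_rng(8)
        a = rng.normal([500, 500], 30, (300, 2))
        b = rng.normal([1500, 500], 30, (300, 2))
        xy = np.vstack([a, b])
        df = pd.DataFrame({"frame": np.zeros(600, int),
                           "x_nm": xy[:, 0], "y_nm": xy[:, 1]})
        img = render_map(df, pixel=10.0, blur_sigma=2.0)
        from scipy.ndimage import maximum_filter
        peaks = (img == maximum_filter(img, size=21)) & (img > 0.3 * img.max())
        assert peaks.sum() == 2

    def test_bad_pixel_rejected(self, default_table):
        with pytest.raises(ValueError):
            render_map(default_table, pixel=0.0)
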