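import numpy as np
import pandas as pd
import pytest

from phylodecline.geo import (
    PREDICTOR_ORDER,
    build_predictors,
    climate_means,
    filter_trends,
    harmonize_body_size,
    lat_midpoint,
    range_size,
    resample_nearest,
)
from phylodecline.gridio import read_ascii_grid, write_ascii_grid


def _resample_oracle(fine, factor):
    """Exhaustive nearest-center search with tie-toward-lower-index."""
    nr, nc = fine.shape
    out = np.empty((nr // factor, nc // factor))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            ci = i * factor + (factor - 1) / 2.0
            cj = j * factor + (factor - 1) / 2.0
            best = None
            for r in range(nr):
                for c in range(nc):
                    d = (r - ci) ** 2 + (c - cj) ** 2
                    key = (d, r, c)
                    if best is None or key < best[0]:
                        best = (key, fine[r, c])
            out[i, j] = best[1]
    return out


class TestResampleNearest:
    def test_identity(self):
        g = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(resample_nearest(g, 1), g)

    def test_four_by_four_factor_two_matches_oracle(self):
        g = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(
            resample_nearest(g, 2), _resample_oracle(g, 2)
        )

    @pytest.mark.parametrize("shape,factor", [((6, 6), 2), ((9, 6), 3),
                                              ((12, 8), 4), ((20, 20), 5)])
    def test_matches_oracle_on_random_grids(self, shape, factor):
        rng = np.random.default_rng(shape[0] * factor)
        g = rng.random(shape)
        np.testing.assert_array_equal(
            resample_nearest(g, factor), _resample_oracle(g, factor)
        )

    def test_nodata_propagates(self):
        g = np.arange(16.0).reshape(4, 4)
        g[0, 0] = np.nan
        out = resample_nearest(g, 2)
        assert np.isnan(out[0, 0])

    def test_nondivisible_rejected(self):
        with pytest.raises(ValueError):
            resample_nearest(np.zeros((5, 4)), 2)


class TestSummaries:
    def test_range_size_arithmetic(self):
        assert range_size([(0, 0)] * 6, 10.0) == 60.0
        assert range_size([(1, 2)], 2.5) == 2.5
        assert np.isnan(range_size(None, 10.0))
        with pytest.raises(ValueError):
            range_size([(0, 0)], 0.0)

    def test_lat_midpoint(self, flat_world):
        # rows at latitudes 30, 10, -10, -30
        assert lat_midpoint([(2, 0), (3, 0)], flat_world) == 20.0
        assert lat_midpoint([(1, 0), (2, 0)], flat_world) == 0.0
        assert np.isnan(lat_midpoint([], flat_world))

    def test_climate_means(self, flat_world):
        amt, tar, cmi = climate_means([(0, 0), (0, 2)], flat_world)
        assert amt == 1.0  # mean of 0 and 2
        assert tar == 12.0
        flat_world.layers["amt"][0, 0] = np.nan
        amt2, _, _ = climate_means([(0, 0), (0, 2)], flat_world)
        assert amt2 == 2.0  # NODATA skipped
        assert all(np.isnan(v) for v in climate_means([], flat_world))

    def test_climate_means_match_bruteforce(self, small_world):
        rng = np.random.default_rng(0)
        land = small_world.land_cells()
        for _ in range(20):
            cells = [land[i] for i in rng.choice(len(land), 5, replace=False)]
            got = climate_means(cells, small_world)
            for name, g in zip(("amt", "tar", "cmi"), got):
                vals = [small_world.layers[name][r, c] for r, c in cells]
                vals = [v for v in vals if np.isfinite(v)]
                assert g == pytest.approx(np.mean(vals), rel=1e-12)


class TestHarmonizeBodySize:
    def test_mean_and_flags(self):
        a = pd.Series({"x": 20.0, "y": 250.0, "z": 40.0})
        b = pd.Series({"x": 30.0, "y": 25.0})
        out = harmonize_body_size(a, b)
        assert out.loc["x", "body_size_mm"] == 25.0
        assert not out.loc["x", "incongruent"]
        # order-of-magnitude disagreement: averaged but flagged
        assert out.loc["y", "body_size_mm"] == 137.5
        assert out.loc["y", "incongruent"]
        assert out.loc["z", "body_size_mm"] == 40.0
        assert not out.loc["z", "incongruent"]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            harmonize_body_size(pd.Series({"x": -1.0}), pd.Series({"x": 2.0}))


class TestBuildPredictors:
    def test_scaled_columns_standardized(self, toy_species_table):
        pm = build_predictors(toy_species_table)
        for col in ("abs_lat_mid", "amt_mean", "tar_mean", "cmi_mean",
                    "prev_amt", "prev_cmi"):
            assert abs(pm.data[col].mean()) < 1e-9
            assert abs(pm.data[col].std(ddof=0) - 1) < 1e-9

    def test_log_columns_centered(self, toy_species_table):
        pm = build_predictors(toy_species_table)
        assert abs(pm.data["log_body_size"].mean()) < 1e-9

    def test_log_ratio(self, toy_species_table):
        t = toy_species_table.copy()
        t.loc[t.index[0], "range_size_km2"] = 10.0
        t.loc[t.index[1], "range_size_km2"] = 1000.0
        pm = build_predictors(t)
        diff = pm.data["log_range_size"].iloc[1] - pm.data["log_range_size"].iloc[0]
        assert diff == pytest.approx(np.log(100), abs=1e-9)

    def test_zero_variance_named(self, toy_species_table):
        t = toy_species_table.copy()
        t["amt_mean"] = 5.0
        with pytest.raises(ValueError, match="amt_mean"):
            build_predictors(t)

    def test_roundtrip_inverse(self, toy_species_table):
        pm = build_predictors(toy_species_table)
        back = pm.inverse(pm.data)
        for col in ("body_size_mm", "range_size_km2", "amt_mean", "prev_cmi"):
            np.testing.assert_allclose(
                back[col], toy_species_table[col], rtol=1e-9
            )

    def test_transform_matches_build(self, toy_species_table):
        pm = build_predictors(toy_species_table)
        again = pm.transform(toy_species_table)
        pd.testing.assert_frame_equal(pm.data[PREDICTOR_ORDER], again)


class TestFilterTrends:
    def test_toy_counts(self, toy_species_table):
        out, dropped = filter_trends(toy_species_table)
        assert len(out) == 20
        assert dropped == {"increasing": 1, "unknown": 3, "missing": 0}
        assert set(out["decline"].unique()) <= {0, 1}
        assert (out["decline"] == 1).sum() == 10

    def test_retains_stable_and_decreasing_only(self):
        t = pd.DataFrame(
            {"trend": ["decreasing"] * 10 + ["stable"] * 5
             + ["increasing"] + ["unknown"] * 3}
        )
        out, _ = filter_trends(t)
        assert len(out) == 15

    def test_all_unknown_rejected(self):
        with pytest.raises(ValueError):
            filter_trends(pd.DataFrame({"trend": ["unknown"] * 4}))


def test_ascii_grid_roundtrip(tmp_path):
    g = np.array([[1.5, np.nan], [-3.25, 4.0]])
    path = tmp_path / "g.asc"
    write_ascii_grid(path, g, cellsize=2.0)
    back, header = read_ascii_grid(path)
    np.testing.assert_array_equal(np.isnan(back), np.isnan(g))
    np.testing.assert_array_equal(back[np.isfinite(back)], g[np.isfinite(g)])
    assert header["cellsize"] == 2.0


def test_lat_midpoint_absolute_first_variant(flat_world):
    # rows at latitudes 30, 10, -10, -30: default reading cancels to 0,
    # the absolute-first reading averages the magnitudes
    cells = [(1, 0), (2, 0)]
    assert lat_midpoint(cells, flat_world) == 0.0
    assert lat_midpoint(cells, flat_world, absolute_first=True) == 10.0
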