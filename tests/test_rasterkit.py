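"""Raster model, ASCII I/O, resampling, distance/slope derivation, overlay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cluesim.rasterkit import (
    CLASS_CODES,
    Grid,
    GridParseError,
    LULCMap,
    cross_tabulate,
    euclidean_distance,
    read_ascii_grid,
    resample_categorical,
    resample_continuous,
    slope_from_dem,
    write_ascii_grid,
)

from conftest import make_lulc


# ---------------------------------------------------------------------------
# ASCII grid I/O
# ---------------------------------------------------------------------------

class TestAsciiIO:
    def test_reads_simple_file(self, tmp_path):
        p = tmp_path / "g.asc"
        p.write_text(
            "ncols 2\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 60\n"
            "NODATA_value -9999\n1 2\n3 4\n"
        )
        g = read_ascii_grid(p)
        assert g.cellsize == 60
        np.testing.assert_array_equal(g.values, [[1, 2], [3, 4]])
        assert np.issubdtype(g.values.dtype, np.integer)

    def test_write_read_round_trip_bytes(self, tmp_path):
        g = Grid(
            np.array([[1.5, -9999.0], [0.25, 42.0]]),
            cellsize=60,
            xllcorner=100,
            yllcorner=-50,
        )
        p1, p2 = tmp_path / "a.asc", tmp_path / "b.asc"
        write_ascii_grid(g, p1)
        write_ascii_grid(read_ascii_grid(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_integer_grid_written_without_decimal_point(self, tmp_path):
        m = make_lulc([[5, 5], [5, 5]])
        p = tmp_path / "m.asc"
        write_ascii_grid(m.grid, p)
        body = p.read_text().splitlines()[6:]
        assert body == ["5 5", "5 5"]

    def test_nodata_written_verbatim(self, tmp_path):
        g = Grid(np.array([[1.0, -9999.0]]), cellsize=30)
        p = tmp_path / "n.asc"
        write_ascii_grid(g, p)
        assert "-9999" in p.read_text().splitlines()[-1].split()

    def test_one_by_one_grid(self, tmp_path):
        g = Grid(np.array([[7]], dtype=np.int32), cellsize=10)
        p = tmp_path / "one.asc"
        write_ascii_grid(g, p)
        g2 = read_ascii_grid(p)
        assert g2.values.tolist() == [[7]]

    def test_short_row_error_names_line(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text(
            "ncols 4\nnrows 2\nxllcorner 0\nyllcorner 0\ncellsize 60\n"
            "NODATA_value -9999\n1 2 3 4\n1 2 3\n"
        )
        with pytest.raises(GridParseError, match="line 8"):
            read_ascii_grid(p)

    def test_non_numeric_token_error(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text(
            "ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize 60\n"
            "NODATA_value -9999\n1 x\n"
        )
        with pytest.raises(GridParseError, match="'x'"):
            read_ascii_grid(p)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        nrows=st.integers(1, 6),
        ncols=st.integers(1, 6),
        seed=st.integers(0, 2**20),
    )
    def test_round_trip_identity_property(self, tmp_path_factory, nrows, ncols, seed):
        rng = np.random.default_rng(seed)
        g = Grid(np.round(rng.normal(size=(nrows, ncols)), 4), cellsize=60)
        p = tmp_path_factory.mktemp("rt") / "g.asc"
        write_ascii_grid(g, p)
        g2 = read_ascii_grid(p)
        np.testing.assert_array_equal(g.values, g2.values)
        assert g2.cellsize == g.cellsize


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

class TestResampling:
    def test_uniform_block_keeps_class(self):
        m = make_lulc([[3, 3], [3, 3]])
        out = resample_categorical(m, 2)
        assert out.values.tolist() == [[3]]
        assert out.grid.cellsize == 120

    def test_tie_goes_to_smallest_code(self):
        m = make_lulc([[1, 1], [2, 2]])
        assert resample_categorical(m, 2).values.tolist() == [[1]]

    def test_majority_against_brute_force(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(1, 7, size=(4, 4)).astype(np.int32)
        m = make_lulc(codes)
        out = resample_categorical(m, 2)
        for bi in range(2):
            for bj in range(2):
                block = codes[2 * bi : 2 * bi + 2, 2 * bj : 2 * bj + 2].ravel()
                counts = {c: int((block == c).sum()) for c in CLASS_CODES}
                best = max(CLASS_CODES, key=lambda c: (counts[c], -c))
                assert out.values[bi, bj] == best

    def test_all_nodata_block_stays_nodata(self):
        m = make_lulc([[1, 1], [1, 1], [-9999, -9999], [-9999, -9999]])
        out = resample_categorical(m, 2)
        assert out.values.tolist() == [[1], [-9999]]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), factor=st.integers(1, 3))
    def test_never_invents_a_code(self, seed, factor):
        rng = np.random.default_rng(seed)
        codes = rng.integers(1, 7, size=(5, 7)).astype(np.int32)
        out = resample_categorical(make_lulc(codes), factor)
        assert set(out.values.ravel().tolist()) <= set(codes.ravel().tolist())

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            resample_categorical(make_lulc([[1]]), 0)
        with pytest.raises(ValueError):
            resample_continuous(Grid(np.ones((2, 2)), cellsize=30), 0)

    def test_continuous_constant_preserved(self):
        g = Grid(np.full((4, 4), 3.5), cellsize=30)
        out = resample_continuous(g, 2)
        np.testing.assert_allclose(out.values, 3.5)

    def test_continuous_block_mean(self):
        g = Grid(np.array([[0.0, 0.0], [10.0, 10.0]]), cellsize=30)
        assert resample_continuous(g, 2).values.tolist() == [[5.0]]

    def test_continuous_against_loop_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 6))
        g = Grid(vals, cellsize=30)
        out = resample_continuous(g, 3)
        for bi in range(2):
            for bj in range(2):
                expected = vals[3 * bi : 3 * bi + 3, 3 * bj : 3 * bj + 3].mean()
                assert abs(out.values[bi, bj] - expected) < 1e-12


# ---------------------------------------------------------------------------
# Distance and slope
# ---------------------------------------------------------------------------

class TestDistance:
    def test_feature_cells_are_zero(self):
        mask = np.zeros((5, 5), dtype=np.int32)
        mask[2, 2] = 1
        d = euclidean_distance(Grid(mask, cellsize=60))
        assert d.values[2, 2] == 0

    def test_three_four_five_triangle(self):
        mask = np.zeros((5, 6), dtype=np.int32)
        mask[0, 0] = 1
        d = euclidean_distance(Grid(mask, cellsize=60))
        assert d.values[3, 4] == pytest.approx(300.0)

    def test_against_all_pairs_scan(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((20, 20)) < 0.05).astype(np.int32)
        mask[7, 11] = 1  # guarantee non-empty
        d = euclidean_distance(Grid(mask, cellsize=60))
        feats = np.argwhere(mask == 1)
        for i in range(20):
            for j in range(20):
                expected = 60.0 * np.sqrt(((feats - [i, j]) ** 2).sum(axis=1)).min()
                assert abs(d.values[i, j] - expected) <= 1e-9

    def test_adding_feature_never_increases_distance(self):
        rng = np.random.default_rng(4)
        mask = (rng.random((15, 15)) < 0.04).astype(np.int32)
        mask[3, 3] = 1
        d1 = euclidean_distance(Grid(mask, cellsize=60))
        mask2 = mask.copy()
        mask2[10, 12] = 1
        d2 = euclidean_distance(Grid(mask2, cellsize=60))
        assert (d2.values <= d1.values + 1e-12).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            euclidean_distance(Grid(np.zeros((4, 4), dtype=np.int32), cellsize=60))


class TestSlope:
    def test_flat_dem_gives_zero(self):
        s = slope_from_dem(Grid(np.full((8, 8), 42.0), cellsize=60))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_uniform_plane_closed_form(self):
        cols = np.arange(10, dtype=float)
        dem = Grid(np.tile(cols, (8, 1)), cellsize=60)  # +1 m per cell eastward
        s = slope_from_dem(dem)
        expected = np.degrees(np.arctan(1.0 / 60.0))
        np.testing.assert_allclose(s.values, expected, atol=1e-9)

    def test_against_directly_coded_horn_formula(self):
        rng = np.random.default_rng(5)
        from scipy.ndimage import gaussian_filter

        z = gaussian_filter(rng.normal(size=(12, 12)), 2) * 10 + 40
        dem = Grid(z, cellsize=60)
        s = slope_from_dem(dem)
        for i in range(1, 11):
            for j in range(1, 11):
                dzdx = (
                    (z[i - 1, j + 1] + 2 * z[i, j + 1] + z[i + 1, j + 1])
                    - (z[i - 1, j - 1] + 2 * z[i, j - 1] + z[i + 1, j - 1])
                ) / (8 * 60.0)
                dzdy = (
                    (z[i + 1, j - 1] + 2 * z[i + 1, j] + z[i + 1, j + 1])
                    - (z[i - 1, j - 1] + 2 * z[i - 1, j] + z[i - 1, j + 1])
                ) / (8 * 60.0)
                expected = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
                assert abs(s.values[i, j] - expected) < 1e-9

    def test_small_dem_rejected(self):
        with pytest.raises(ValueError):
            slope_from_dem(Grid(np.ones((2, 5)), cellsize=60))


# ---------------------------------------------------------------------------
# Cross-tabulation
# ---------------------------------------------------------------------------

class TestCrossTabulate:
    def test_identical_maps_diagonal(self):
        m = make_lulc([[1, 2, 3], [4, 5, 6]])
        ct = cross_tabulate(m, m)
        assert np.trace(ct) == 6
        assert ct.sum() == 6

    def test_hand_counted_toy(self):
        a = make_lulc([[1, 1, 2, 2, 3, 4, 5, 6]])
        b = make_lulc([[1, 2, 2, 2, 3, 4, 5, 6]])
        ct = cross_tabulate(a, b)
        assert ct[0, 0] == 1 and ct[0, 1] == 1 and ct[1, 1] == 2

    def test_total_equals_jointly_valid_cells(self):
        a = make_lulc([[1, -9999], [2, 3]])
        b = make_lulc([[1, 2], [-9999, 3]])
        assert cross_tabulate(a, b).sum() == 2

    def test_marginals_match_class_counts(self):
        rng = np.random.default_rng(6)
        a = make_lulc(rng.integers(1, 7, size=(10, 10)))
        b = make_lulc(rng.integers(1, 7, size=(10, 10)))
        ct = cross_tabulate(a, b)
        for i, c in enumerate(CLASS_CODES):
            assert ct[i, :].sum() == a.class_counts()[c]
            assert ct[:, i].sum() == b.class_counts()[c]

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_tabulate(make_lulc([[1]]), make_lulc([[1, 2]]))


def test_lulc_areas_sum_to_total():
    m = make_lulc([[1, 2], [-9999, 5]])
    areas = m.class_areas_ha()
    assert sum(areas.values()) == pytest.approx(3 * 0.36)
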