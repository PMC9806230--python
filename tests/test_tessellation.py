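"""Tessellation, tile typing, grid shifting and the EDI."""

import math

import numpy as np
import pytest

from spathet import (
    BlobField,
    TissueSpec,
    classify_tile,
    edi,
    expression_class_ratio,
    generate_tissue,
    shifted_score,
    tessellate,
    tessellation_scores,
    three_class_ratios,
    tile_entropy,
)
from spathet.tessellation import SparseSampleError, TileRecord

from conftest import make_cells


def make_tile(od_values, row=0, col=0):
    od = np.asarray(od_values, dtype=float)
    return TileRecord(row=row, col=col, cell_indices=np.arange(len(od)), od=od)


class TestTessellate:
    def test_cells_in_one_tile(self):
        cells = make_cells(np.linspace(0, 100, 10), np.linspace(0, 100, 10),
                           np.full(10, 5.0))
        grid = tessellate(cells)
        assert grid.n_tiles == 1
        assert grid.tiles[0].n_cells == 10

    def test_min_cells_filter(self):
        # 4 cells in the first 250 µm tile, 6 in the next
        x = [10, 20, 30, 40] + [260, 270, 280, 290, 300, 310]
        cells = make_cells(x, [0] * 10, [5] * 10)
        grid = tessellate(cells, min_cells=5)
        assert grid.n_tiles == 1
        assert grid.n_dropped == 1
        assert grid.tiles[0].n_cells == 6

    def test_matches_floor_division_oracle(self, rng):
        n = 2000
        cells = make_cells(rng.uniform(0, 1000, n), rng.uniform(0, 1000, n),
                           rng.uniform(0, 30, n))
        grid = tessellate(cells, tile_size=250, min_cells=5)
        # brute-force assignment by floor division of shifted coordinates
        x0, y0 = cells.x.min(), cells.y.min()
        expected = {}
        for i in range(n):
            key = (math.floor((cells.y[i] - y0) / 250), math.floor((cells.x[i] - x0) / 250))
            expected.setdefault(key, []).append(i)
        expected = {k: sorted(v) for k, v in expected.items() if len(v) >= 5}
        got = {(t.row, t.col): sorted(t.cell_indices.tolist()) for t in grid.tiles}
        assert got == expected

    def test_membership_is_partition_before_filtering(self, rng):
        n = 800
        cells = make_cells(rng.uniform(0, 600, n), rng.uniform(0, 600, n),
                           rng.uniform(0, 30, n))
        grid = tessellate(cells, tile_size=250, min_cells=1)
        all_members = np.concatenate([t.cell_indices for t in grid.tiles])
        assert sorted(all_members.tolist()) == list(range(n))

    def test_too_sparse_raises(self):
        cells = make_cells([0, 300, 600], [0, 300, 600], [1, 1, 1])
        with pytest.raises(SparseSampleError):
            tessellate(cells, min_cells=5)


class TestTileEntropy:
    def test_seventy_thirty_matches_heterogeneity_threshold(self):
        assert tile_entropy(0.7) == pytest.approx(0.6109, abs=5e-5)

    def test_maximum_at_half(self):
        assert tile_entropy(0.5) == pytest.approx(math.log(2))

    def test_pure_tile_zero(self):
        assert tile_entropy(1.0) == 0.0
        assert tile_entropy(0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tile_entropy(1.5)


class TestClassifyTile:
    def test_half_half_is_heterogenous(self):
        tile = make_tile([10, 10, 20, 20])  # 50% >= 15
        assert classify_tile(tile, od_threshold=15) == "heterogenous"

    def test_all_positive_high_mean_is_homogenous_high(self):
        tile = make_tile([30, 30, 30, 30])
        assert classify_tile(tile, od_threshold=25) == "homogenous-high"

    def test_mostly_positive_low_mean_is_homogenous_low(self):
        # 3/4 positive at threshold 8: entropy 0.562 < 0.61, mean 6 < 8
        tile = make_tile([8, 8, 8, 0])
        assert tile.entropy(8) == pytest.approx(0.5623, abs=1e-4)
        assert classify_tile(tile, od_threshold=8) == "homogenous-low"

    def test_flips_when_positive_fraction_enters_open_middle_band(self):
        """Heterogenous exactly when the positive fraction is inside (0.3, 0.7)."""
        for n_pos in range(0, 17):
            frac = n_pos / 16  # avoids landing exactly on 0.3 / 0.7
            od = [20.0] * n_pos + [0.0] * (16 - n_pos)
            is_het = classify_tile(make_tile(od), od_threshold=10) == "heterogenous"
            assert is_het == (0.3 < frac < 0.7), f"frac={frac}"


class TestRatios:
    def test_all_low(self):
        cells = make_cells(np.linspace(0, 50, 8), np.zeros(8), np.full(8, 2.0))
        grid = tessellate(cells)
        assert expression_class_ratio(grid, 10) == 0.0

    def test_three_of_four_high(self):
        x = np.concatenate([np.linspace(0, 40, 5) + 260 * i for i in range(4)])
        od = np.concatenate([np.full(5, 20.0)] * 3 + [np.full(5, 2.0)])
        grid = tessellate(make_cells(x, np.zeros(20), od))
        assert grid.n_tiles == 4
        assert expression_class_ratio(grid, 10) == 0.75

    def test_three_class_ratios_one_of_each(self):
        x = np.concatenate([np.linspace(0, 40, 6) + 260 * i for i in range(3)])
        od = np.concatenate([
            np.full(6, 30.0),            # homogenous-high
            np.full(6, 2.0),             # homogenous-low
            [30, 30, 30, 2, 2, 2],       # heterogenous (50/50)
        ])
        grid = tessellate(make_cells(x, np.zeros(18), od))
        het, high, low = three_class_ratios(grid, 15)
        assert (het, high, low) == (pytest.approx(1 / 3),) * 3

    def test_ratios_sum_to_one(self, rng):
        cells = make_cells(rng.uniform(0, 1000, 2000), rng.uniform(0, 1000, 2000),
                           rng.uniform(0, 30, 2000))
        grid = tessellate(cells)
        assert sum(three_class_ratios(grid, 15)) == pytest.approx(1.0, abs=1e-12)


class TestShiftedScore:
    def test_constant_score_fn(self, rng):
        cells = make_cells(rng.uniform(0, 600, 500), rng.uniform(0, 600, 500),
                           rng.uniform(0, 30, 500))
        assert shifted_score(cells, lambda g: 7.5) == 7.5

    def test_equals_mean_of_individually_shifted_grids(self):
        """Tile-count score on a one-tile sample, vs. per-shift brute force."""
        cells = make_cells(np.linspace(5, 245, 20), np.linspace(5, 245, 20),
                           np.full(20, 5.0))
        counts = []
        for off in [(25, 0), (-25, 0), (0, 25), (0, -25)]:
            counts.append(tessellate(cells, offset=off).n_tiles)
        got = shifted_score(cells, lambda g: float(g.n_tiles))
        assert got == pytest.approx(np.mean(counts))

    def test_uniform_sample_shift_stable(self, rng):
        cells = make_cells(rng.uniform(0, 1500, 8000), rng.uniform(0, 1500, 8000),
                           np.where(rng.uniform(0, 1, 8000) < 0.5, 20.0, 2.0))
        unshifted = expression_class_ratio(tessellate(cells), 10)
        shifted = shifted_score(cells, lambda g: expression_class_ratio(g, 10))
        assert shifted == pytest.approx(unshifted, abs=0.02)

    def test_all_offsets_failing_raises(self):
        cells = make_cells([0, 1, 2], [0, 0, 0], [1, 1, 1])
        with pytest.raises(SparseSampleError):
            with pytest.warns(UserWarning):
                shifted_score(cells, lambda g: 0.0)


class TestTileMapExport:
    def test_frame_covers_tiles_with_bounds_and_classes(self, rng):
        from spathet import tile_map_frame, tile_map_geojson

        cells = make_cells(rng.uniform(0, 600, 600), rng.uniform(0, 600, 600),
                           rng.uniform(0, 30, 600))
        grid = tessellate(cells)
        frame = tile_map_frame(grid)
        assert len(frame) == grid.n_tiles
        np.testing.assert_allclose(frame["xmax"] - frame["xmin"], grid.tile_size)
        # bounds actually contain the member cells
        for tile in grid.tiles:
            xmin, ymin, xmax, ymax = grid.tile_bounds(tile)
            assert np.all((cells.x[tile.cell_indices] >= xmin)
                          & (cells.x[tile.cell_indices] < xmax))
            assert np.all((cells.y[tile.cell_indices] >= ymin)
                          & (cells.y[tile.cell_indices] < ymax))
        assert set(frame["class_od15"]) <= {"heterogenous", "homogenous-high",
                                            "homogenous-low"}
        gj = tile_map_geojson(grid, 15)
        assert len(gj["features"]) == grid.n_tiles
        assert gj["features"][0]["geometry"]["type"] == "Polygon"


class TestEdi:
    def test_single_gaussian_gives_one(self, rng):
        values = rng.normal(0, 1, 200)
        assert edi(values, seed=0).n_components == 1

    def test_well_separated_mixture_gives_two(self, rng):
        values = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(5, 0.2, 100)])
        assert edi(values, seed=0).n_components == 2

    def test_constant_vector_is_one_by_definition(self):
        assert edi(np.full(50, 3.3)).n_components == 1

    def test_reproducible(self, rng):
        values = rng.normal(size=120)
        a = edi(values, seed=7)
        b = edi(values, seed=7)
        assert a.n_components == b.n_components
        np.testing.assert_array_equal(a.bic, b.bic)

    def test_few_values_reduce_component_range(self):
        res = edi([1.0, 2.0, 3.0, 4.0])
        assert len(res.bic) <= 2  # floor(4/2)


class TestTessellationScores:
    def test_thirty_seven_named_scores(self, rng):
        cells = make_cells(rng.uniform(0, 1500, 5000), rng.uniform(0, 1500, 5000),
                           rng.uniform(0, 30, 5000))
        scores = tessellation_scores(cells)
        assert len(scores) == 37

    def test_seven_edi_scores_present(self, rng):
        cells = make_cells(rng.uniform(0, 1500, 5000), rng.uniform(0, 1500, 5000),
                           rng.uniform(0, 30, 5000))
        scores = tessellation_scores(cells)
        edi_names = [k for k in scores if k.startswith("edi_")]
        assert len(edi_names) == 7  # 5 entropy EDIs + mean-OD EDI + sd-OD EDI
        assert "edi_mean_od" in edi_names and "edi_sd_od" in edi_names

    def test_homogeneous_low_sample(self):
        spec = TissueSpec(n_cells=3000, window=(1000, 1000),
                          od_field=BlobField(centers=(), radius=1, mu_high=30,
                                             mu_low=3, sigma=0.0), seed=0)
        cells = generate_tissue(spec)
        scores = tessellation_scores(cells)
        for t in (8, 10, 15, 20, 25):
            assert scores[f"frac_low_od{t}"] == 1.0
            assert scores[f"mean_entropy_od{t}"] == 0.0

    def test_untessellable_sample_yields_missing(self):
        cells = make_cells([0, 400, 800], [0, 400, 800], [1, 1, 1])
        with pytest.warns(UserWarning, match="not tessellable"):
            scores = tessellation_scores(cells)
        assert len(scores) == 37
        assert all(math.isnan(v) for v in scores.values())
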