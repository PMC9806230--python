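"""Grid tessellation of tissue and tile-based heterogeneity scores.

The tissue region (bounding box of the convex hull of all cell coordinates)
is overlaid with an axis-aligned square grid, 250 µm tiles by default.  Tiles
with fewer than 5 member cells are discarded.  Per tile, cells are split into
marker-positive and marker-negative by an OD threshold and the Shannon
entropy (in nats) of the class proportions measures local mixing: 0 for a
pure tile, ln 2 for a 50/50 tile.  A decision scheme types each tile as
*heterogenous* (entropy above 0.61, i.e. less than 70% of cells in the
majority class) or as *homogenous-high* / *homogenous-low* by the tile mean
OD against the same threshold.

Per-sample aggregates include the fraction of high-expression tiles (shift-
averaged over four 25 µm grid translations to suppress tiling artefacts),
mean tile entropy, the three tile-class fractions, and the Ecosystem
Diversity Index (EDI): the component count, chosen by BIC among 1-5
component Gaussian mixtures, of a distribution of per-tile statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .data import CellTable

__all__ = [
    "DEFAULT_TILE_SIZE",
    "DEFAULT_MIN_CELLS",
    "DEFAULT_OD_THRESHOLDS",
    "ENTROPY_THRESHOLD",
    "TileRecord",
    "TileGrid",
    "EdiResult",
    "tessellate",
    "tile_entropy",
    "classify_tile",
    "shifted_score",
    "expression_class_ratio",
    "three_class_ratios",
    "edi",
    "tessellation_scores",
    "tile_map_frame",
    "tile_map_geojson",
]

DEFAULT_TILE_SIZE = 250.0  #: µm
DEFAULT_MIN_CELLS = 5
DEFAULT_SHIFT = 25.0  #: µm, 1/10 of the tile size
DEFAULT_OD_THRESHOLDS = (8.0, 10.0, 15.0, 20.0, 25.0)
#: entropy (nats) above which a tile is heterogenous; ln-entropy of a
#: 70/30 split is 0.6109, so this admits at most 70% majority class
ENTROPY_THRESHOLD = 0.61

TILE_CLASSES = ("heterogenous", "homogenous-high", "homogenous-low")


class SparseSampleError(ValueError):
    """Raised when no tile reaches the minimum cell count."""


@dataclass(frozen=True)
class TileRecord:
    """One retained grid tile and the OD values of its member cells."""

    row: int
    col: int
    cell_indices: np.ndarray
    od: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.od)

    @property
    def mean_od(self) -> float:
        return float(np.mean(self.od))

    @property
    def sd_od(self) -> float:
        return float(np.std(self.od, ddof=1)) if self.n_cells > 1 else 0.0

    def pos_fraction(self, threshold: float) -> float:
        """Fraction of member cells with od >= threshold (ties positive)."""
        return float(np.mean(self.od >= threshold))

    def entropy(self, threshold: float) -> float:
        return tile_entropy(self.pos_fraction(threshold))


@dataclass(frozen=True)
class TileGrid:
    """Retained tiles of one tessellation of a sample."""

    tile_size: float
    offset: tuple[float, float]
    min_cells: int
    tiles: list[TileRecord]
    n_dropped: int  #: occupied tiles discarded by the min-cells filter
    origin: tuple[float, float] = (0.0, 0.0)  #: grid anchor in slide µm

    def tile_bounds(self, tile: TileRecord) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of a tile in slide coordinates (µm)."""
        s = self.tile_size
        x0 = self.origin[0] + tile.col * s
        y0 = self.origin[1] + tile.row * s
        return (x0, y0, x0 + s, y0 + s)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def mean_od_per_tile(self) -> np.ndarray:
        return np.array([t.mean_od for t in self.tiles])

    def sd_od_per_tile(self) -> np.ndarray:
        return np.array([t.sd_od for t in self.tiles])

    def entropy_per_tile(self, threshold: float) -> np.ndarray:
        return np.array([t.entropy(threshold) for t in self.tiles])


def tessellate(
    cells: CellTable,
    tile_size: float = DEFAULT_TILE_SIZE,
    offset: tuple[float, float] = (0.0, 0.0),
    min_cells: int = DEFAULT_MIN_CELLS,
) -> TileGrid:
    """Assign cells to square grid tiles and drop under-populated tiles.

    The grid is anchored at the minimum corner of the cell bounding box plus
    ``offset``; a cell belongs to the tile whose half-open interval
    [origin + c*s, origin + (c+1)*s) contains its coordinate on each axis.
    Every cell belongs to exactly one tile before filtering.
    """
    if tile_size <= 0:
        raise ValueError(f"tile_size must be > 0, got {tile_size}")
    ox = float(np.min(cells.x)) + offset[0]
    oy = float(np.min(cells.y)) + offset[1]
    col = np.floor((cells.x - ox) / tile_size).astype(np.int64)
    row = np.floor((cells.y - oy) / tile_size).astype(np.int64)
    tiles: list[TileRecord] = []
    n_dropped = 0
    # group cells by (row, col) via lexsort
    order = np.lexsort((col, row))
    keys = np.column_stack([row[order], col[order]])
    boundaries = np.flatnonzero(np.any(np.diff(keys, axis=0) != 0, axis=1)) + 1
    for idx in np.split(order, boundaries):
        if len(idx) < min_cells:
            n_dropped += 1
            continue
        tiles.append(
            TileRecord(
                row=int(row[idx[0]]),
                col=int(col[idx[0]]),
                cell_indices=idx,
                od=cells.od[idx],
            )
        )
    if not tiles:
        raise SparseSampleError(
            f"sample {cells.sample_id} too sparse for tessellation "
            f"(no tile with >= {min_cells} cells)"
        )
    return TileGrid(
        tile_size=float(tile_size),
        offset=(float(offset[0]), float(offset[1])),
        min_cells=min_cells,
        tiles=tiles,
        n_dropped=n_dropped,
        origin=(ox, oy),
    )


def tile_entropy(pos_fraction: float | np.ndarray) -> float | np.ndarray:
    """Shannon entropy in nats of (p, 1-p), with 0*ln(0) := 0."""
    p = np.asarray(pos_fraction, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pos_fraction must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) - np.where(
            p < 1, (1 - p) * np.log(1 - p), 0.0
        )
    return float(h) if np.isscalar(pos_fraction) else h


def classify_tile(
    tile: TileRecord,
    od_threshold: float,
    entropy_threshold: float = ENTROPY_THRESHOLD,
) -> str:
    """Decision scheme: heterogenous by entropy, else high/low by tile mean OD."""
    if tile.entropy(od_threshold) > entropy_threshold:
        return "heterogenous"
    return "homogenous-high" if tile.mean_od >= od_threshold else "homogenous-low"


def expression_class_ratio(grid: TileGrid, od_threshold: float) -> float:
    """Fraction of retained tiles with mean OD at or above the threshold."""
    means = grid.mean_od_per_tile()
    return float(np.mean(means >= od_threshold))


def three_class_ratios(
    grid: TileGrid,
    od_threshold: float,
    entropy_threshold: float = ENTROPY_THRESHOLD,
) -> tuple[float, float, float]:
    """(heterogenous, homogenous-high, homogenous-low) tile fractions; sum 1."""
    labels = [classify_tile(t, od_threshold, entropy_threshold) for t in grid.tiles]
    n = len(labels)
    return tuple(labels.count(c) / n for c in TILE_CLASSES)  # type: ignore[return-value]


def shifted_score(
    cells: CellTable,
    score_fn: Callable[[TileGrid], float],
    tile_size: float = DEFAULT_TILE_SIZE,
    shift: float = DEFAULT_SHIFT,
    min_cells: int = DEFAULT_MIN_CELLS,
    include_origin: bool = False,
) -> float:
    """Average of ``score_fn`` over grids shifted by ±``shift`` µm in x and y.

    Offsets whose tessellation fails (no surviving tile) are skipped with a
    warning; if every offset fails, :class:`SparseSampleError` is raised.
    """
    offsets = [(shift, 0.0), (-shift, 0.0), (0.0, shift), (0.0, -shift)]
    if include_origin:
        offsets.append((0.0, 0.0))
    values = []
    for off in offsets:
        try:
            grid = tessellate(cells, tile_size=tile_size, offset=off, min_cells=min_cells)
        except SparseSampleError:
            warnings.warn(
                f"sample {cells.sample_id}: tessellation failed at offset {off}; skipped",
                stacklevel=2,
            )
            continue
        values.append(score_fn(grid))
    if not values:
        raise SparseSampleError(
            f"sample {cells.sample_id}: tessellation failed at every grid offset"
        )
    return float(np.mean(values))


def tile_map_frame(
    grid: TileGrid,
    od_thresholds: Sequence[float] = DEFAULT_OD_THRESHOLDS,
    entropy_threshold: float = ENTROPY_THRESHOLD,
):
    """Per-tile spatial map: bounds (µm), OD stats, entropy and class per threshold.

    Returns a pandas DataFrame suitable for CSV export or overlay rendering.
    """
    import pandas as pd

    rows = []
    for tile in grid.tiles:
        xmin, ymin, xmax, ymax = grid.tile_bounds(tile)
        rec = {
            "row": tile.row, "col": tile.col,
            "xmin": xmin, "ymin": ymin, "xmax": xmax, "ymax": ymax,
            "n_cells": tile.n_cells,
            "mean_od": tile.mean_od, "sd_od": tile.sd_od,
        }
        for t in od_thresholds:
            rec[f"entropy_od{t:g}"] = tile.entropy(t)
            rec[f"class_od{t:g}"] = classify_tile(tile, t, entropy_threshold)
        rows.append(rec)
    return pd.DataFrame(rows)


def tile_map_geojson(
    grid: TileGrid,
    od_threshold: float,
    entropy_threshold: float = ENTROPY_THRESHOLD,
) -> dict:
    """GeoJSON-style FeatureCollection of tile polygons with class labels."""
    features = []
    for tile in grid.tiles:
        xmin, ymin, xmax, ymax = grid.tile_bounds(tile)
        ring = [[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax], [xmin, ymin]]
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": {
                "row": tile.row, "col": tile.col, "n_cells": tile.n_cells,
                "mean_od": tile.mean_od,
                "entropy": tile.entropy(od_threshold),
                "tile_class": classify_tile(tile, od_threshold, entropy_threshold),
            },
        })
    return {"type": "FeatureCollection", "features": features}


@dataclass(frozen=True)
class EdiResult:
    """Component count of the BIC-best Gaussian mixture fitted to ``values``."""

    values: np.ndarray
    n_components: int
    bic: np.ndarray  #: BIC per component count 1..max tried


def edi(
    values: Sequence[float] | np.ndarray,
    max_components: int = 5,
    seed: int = 0,
    n_init: int = 10,
) -> EdiResult:
    """Ecosystem Diversity Index of a 1-D distribution.

    Fits Gaussian mixtures with 1..``max_components`` components (EM with
    ``n_init`` restarts, tolerance 1e-4, at most 500 iterations) and returns
    the component count minimizing BIC; ties break toward fewer components.
    With fewer than ``2 * max_components`` observations the component range
    is reduced to floor(n/2), at least 1.  A constant vector has EDI 1 by
    definition.
    """
    vals = np.asarray(values, dtype=float).reshape(-1)
    if len(vals) == 0:
        raise ValueError("edi requires at least one value")
    if np.ptp(vals) == 0.0:
        return EdiResult(values=vals, n_components=1, bic=np.array([-np.inf]))
    k_max = min(max_components, max(1, len(vals) // 2))
    bics = np.full(k_max, np.inf)
    X = vals[:, None]
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            tol=1e-4,
            max_iter=500,
            random_state=seed,
            reg_covar=1e-6,
        )
        try:
            gmm.fit(X)
            bics[k - 1] = gmm.bic(X)
        except ValueError:  # fewer distinct values than components
            bics[k - 1] = np.inf
    # argmin returns the first minimum, i.e. the fewest components on ties
    return EdiResult(values=vals, n_components=int(np.argmin(bics)) + 1, bic=bics)


def tessellation_scores(
    cells: CellTable,
    od_thresholds: Sequence[float] = DEFAULT_OD_THRESHOLDS,
    tile_size: float = DEFAULT_TILE_SIZE,
    shift: float = DEFAULT_SHIFT,
    min_cells: int = DEFAULT_MIN_CELLS,
    entropy_threshold: float = ENTROPY_THRESHOLD,
    seed: int = 0,
) -> dict[str, float]:
    """The tessellation score battery (37 named scores at the default 5 thresholds).

    Per OD threshold t: the shift-averaged high-expression tile ratio
    (``ratio_high_od{t}``), mean tile entropy (``mean_entropy_od{t}``), the
    EDI of per-tile entropies (``edi_entropy_od{t}``), the three tile-class
    fractions (``frac_{hetero,high,low}_od{t}``), and the global fraction of
    marker-positive cells (``pos_frac_od{t}``).  Threshold-independent: the
    EDI of per-tile mean OD (``edi_mean_od``) and of per-tile OD standard
    deviation (``edi_sd_od``).  Degenerate samples yield NaN entries rather
    than errors.
    """
    scores: dict[str, float] = {}
    try:
        base = tessellate(cells, tile_size=tile_size, min_cells=min_cells)
    except SparseSampleError:
        warnings.warn(
            f"sample {cells.sample_id}: not tessellable; tessellation scores missing",
            stacklevel=2,
        )
        base = None
    for t in od_thresholds:
        sfx = f"_od{t:g}"
        if base is None:
            for name in ("ratio_high", "mean_entropy", "edi_entropy",
                         "frac_hetero", "frac_high", "frac_low", "pos_frac"):
                scores[name + sfx] = float("nan")
            continue
        try:
            scores["ratio_high" + sfx] = shifted_score(
                cells,
                lambda g, t=t: expression_class_ratio(g, t),
                tile_size=tile_size,
                shift=shift,
                min_cells=min_cells,
            )
        except SparseSampleError:
            scores["ratio_high" + sfx] = float("nan")
        ent = base.entropy_per_tile(t)
        scores["mean_entropy" + sfx] = float(np.mean(ent))
        scores["edi_entropy" + sfx] = float(edi(ent, seed=seed).n_components)
        het, high, low = three_class_ratios(base, t, entropy_threshold)
        scores["frac_hetero" + sfx] = het
        scores["frac_high" + sfx] = high
        scores["frac_low" + sfx] = low
        scores["pos_frac" + sfx] = float(np.mean(cells.od >= t))
    if base is None:
        scores["edi_mean_od"] = float("nan")
        scores["edi_sd_od"] = float("nan")
    else:
        scores["edi_mean_od"] = float(edi(base.mean_od_per_tile(), seed=seed).n_components)
        scores["edi_sd_od"] = float(edi(base.sd_od_per_tile(), seed=seed).n_components)
    return scores
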