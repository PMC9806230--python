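"""Object-based co-occurrence analysis of marker expression in neighboring cells.

Classical Haralick texture features summarize a gray-level co-occurrence
matrix of neighboring *pixels*.  Here the objects are cells: for every pair
of cells joined by an edge of the neighborhood graph, the pair of their
(integer-mapped) membrane OD levels is accumulated into a 255x255 joint
histogram.  Each undirected edge contributes both ordered pairs, so the
matrix is exactly symmetric.  Four features are computed from the normalized
matrix p(i, j):

* homogeneity        sum 1 / (1 + (i - j)^2) * p(i, j)  — large when neighboring
  cells share similar OD values;
* contrast           sum (i - j)^2 * p(i, j)  — large when neighbors differ;
* correlation        (sum i*j*p(i, j) - mu_x*mu_y) / (sigma_x*sigma_y) — the
  Pearson-type linear dependency of neighboring OD levels;
* angular second moment  sum p(i, j)^2 — overall uniformity.

Correlation is undefined (NaN) when all neighboring cells share one OD level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CellTable
from .graph import NeighborhoodGraph, build_graph

__all__ = [
    "N_LEVELS",
    "DEFAULT_RADII",
    "CooccurrenceMatrix",
    "map_od_to_level",
    "build_cooccurrence",
    "homogeneity",
    "contrast",
    "correlation",
    "angular_second_moment",
    "cooccurrence_scores",
]

#: number of mapped OD levels (matrix is N_LEVELS x N_LEVELS, indices 0..254)
N_LEVELS = 255

#: neighborhood radii (µm) of the default score battery
DEFAULT_RADII = (10.0, 25.0, 50.0, 75.0)

FEATURE_NAMES = ("homogeneity", "contrast", "correlation", "asm")


class EmptyGraphError(ValueError):
    """Raised when a co-occurrence matrix is requested for an edgeless graph."""


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized symmetric joint histogram of neighboring-cell OD levels."""

    p: np.ndarray  #: (255, 255), sums to 1
    n_pairs: int  #: count of contributing ordered pairs (2 x edges)

    @property
    def marginal(self) -> np.ndarray:
        """Row marginal distribution (equals the column marginal by symmetry)."""
        return self.p.sum(axis=1)

    @property
    def mu(self) -> float:
        levels = np.arange(N_LEVELS)
        return float(np.dot(levels, self.marginal))

    @property
    def sigma(self) -> float:
        levels = np.arange(N_LEVELS)
        return float(np.sqrt(np.dot((levels - self.mu) ** 2, self.marginal)))


def map_od_to_level(od: np.ndarray | float) -> np.ndarray | int:
    """Map continuous OD on [0, 255] to integer level 0..254.

    Round-half-up, then clamp to the top level.
    """
    od_arr = np.asarray(od, dtype=float)
    if np.any(od_arr < 0):
        raise ValueError("od must be non-negative")
    levels = np.minimum(np.floor(od_arr + 0.5), N_LEVELS - 1).astype(np.int64)
    return int(levels) if np.isscalar(od) else levels


def build_cooccurrence(cells: CellTable, graph: NeighborhoodGraph) -> CooccurrenceMatrix:
    """2-D histogram of OD-level pairs over all edges of the neighborhood graph.

    Each undirected edge {a, b} adds one count at (level_a, level_b) and one
    at (level_b, level_a).
    """
    if graph.n_cells != cells.n_cells:
        raise ValueError("graph was built on a different number of cells")
    if graph.n_edges == 0:
        raise EmptyGraphError(
            f"empty graph: co-occurrence undefined at radius {graph.radius:g}"
        )
    levels = map_od_to_level(cells.od)
    a = levels[graph.edges[:, 0]]
    b = levels[graph.edges[:, 1]]
    counts = np.zeros((N_LEVELS, N_LEVELS), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    np.add.at(counts, (b, a), 1)
    n_pairs = int(counts.sum())
    return CooccurrenceMatrix(p=counts / n_pairs, n_pairs=n_pairs)


def _offsets() -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(N_LEVELS)
    return i[:, None], i[None, :]


def homogeneity(m: CooccurrenceMatrix) -> float:
    i, j = _offsets()
    return float(np.sum(m.p / (1.0 + (i - j) ** 2)))


def contrast(m: CooccurrenceMatrix) -> float:
    i, j = _offsets()
    return float(np.sum((i - j) ** 2 * m.p))


def correlation(m: CooccurrenceMatrix) -> float:
    """NaN when the marginal variance is zero (single occupied level)."""
    i, j = _offsets()
    mu, sigma = m.mu, m.sigma
    if sigma == 0.0:
        return float("nan")
    num = float(np.sum(i * j * m.p)) - mu * mu
    return num / (sigma * sigma)


def angular_second_moment(m: CooccurrenceMatrix) -> float:
    return float(np.sum(m.p**2))


_FEATURE_FNS = {
    "homogeneity": homogeneity,
    "contrast": contrast,
    "correlation": correlation,
    "asm": angular_second_moment,
}


def cooccurrence_scores(
    cells: CellTable, radii: tuple[float, ...] = DEFAULT_RADII
) -> dict[str, float]:
    """The co-occurrence score battery: 4 features x len(radii) radii.

    Score names encode the feature and radius, e.g. ``homogeneity_r10``.
    Radii whose graph has no edges yield NaN for all four features, with a
    warning; an undefined correlation likewise propagates as NaN.
    """
    scores: dict[str, float] = {}
    for radius in radii:
        suffix = f"_r{radius:g}"
        graph = build_graph(cells, radius)
        if graph.n_edges == 0:
            warnings.warn(
                f"sample {cells.sample_id}: no edges at radius {radius:g} µm; "
                "co-occurrence scores missing",
                stacklevel=2,
            )
            for name in FEATURE_NAMES:
                scores[name + suffix] = float("nan")
            continue
        m = build_cooccurrence(cells, graph)
        for name in FEATURE_NAMES:
            scores[name + suffix] = _FEATURE_FNS[name](m)
    return scores
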