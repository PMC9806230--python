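"""Cell neighborhood graphs under a Euclidean distance threshold.

Cells are nodes; an undirected edge links every pair of cells whose center
distance is at most a chosen radius (closed ball: ties at exactly the radius
are edges).  Construction uses a k-d tree, but the result is identical to the
all-pairs definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .data import CellTable

__all__ = ["NeighborhoodGraph", "build_graph", "degree_summary"]


@dataclass(frozen=True)
class NeighborhoodGraph:
    """Undirected distance-threshold graph over one sample's cells.

    ``edges`` is an (m, 2) integer array of cell-index pairs with
    ``edges[:, 0] < edges[:, 1]`` (unordered pairs, no self-edges).
    """

    n_cells: int
    radius: float
    edges: np.ndarray
    degrees: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_graph(cells: CellTable, radius: float) -> NeighborhoodGraph:
    """Build the neighborhood graph at ``radius`` µm.

    Coincident cells are neighbors at any positive radius; isolated cells
    remain as degree-0 nodes.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    xy = cells.xy
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")  # closed ball
    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=np.int64)
    else:
        pairs = np.sort(pairs, axis=1)
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
    degrees = np.bincount(pairs.ravel(), minlength=cells.n_cells)
    return NeighborhoodGraph(
        n_cells=cells.n_cells, radius=float(radius), edges=pairs, degrees=degrees
    )


def degree_summary(graph: NeighborhoodGraph) -> tuple[float, float]:
    """(median degree, mean degree); median uses midpoint interpolation."""
    deg = graph.degrees
    return float(np.median(deg)), float(np.mean(deg))
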