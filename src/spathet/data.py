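"""Data model and I/O for per-cell tables, score tables, and survival tables.

A *cell table* holds one tissue sample: per segmented tumor cell, the cell
center coordinates in micrometres and the membrane mean optical density (OD)
of the marker stain on a 0-255 scale.  Score tables are plain DataFrames with
one row per sample and one column per named spatial score.  Survival tables
carry per-patient overall-survival time/event plus clinical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "CellTable",
    "SampleSummary",
    "read_cell_table",
    "write_cell_table",
    "read_manifest",
    "validate_survival_table",
    "summarize_sample",
]

#: canonical column names of a cell table
CELL_COLUMNS = ("x", "y", "od")

#: required columns of a survival table
SURVIVAL_COLUMNS = ("sample_id", "os_time", "os_event")

OD_MAX = 255.0


@dataclass(frozen=True)
class CellTable:
    """One tissue sample's segmented cells.

    Parameters
    ----------
    sample_id : str
        Nonempty sample identifier.
    x, y : ndarray
        Cell center coordinates in micrometres (arbitrary slide frame).
    od : ndarray
        Membrane mean optical density per cell on the [0, 255] stain scale.
    """

    sample_id: str
    x: np.ndarray
    y: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if not (x.ndim == y.ndim == od.ndim == 1):
            raise ValueError("x, y, od must be 1-dimensional")
        if not (len(x) == len(y) == len(od)):
            raise ValueError("x, y, od must have equal length")
        if len(x) < 1:
            raise ValueError("cell table must contain at least one cell")
        for name, arr in (("x", x), ("y", y), ("od", od)):
            if not np.all(np.isfinite(arr)):
                bad = np.flatnonzero(~np.isfinite(arr))
                raise ValueError(f"non-finite {name} values at rows {bad.tolist()[:10]}")
        if np.any(od < 0):
            bad = np.flatnonzero(od < 0)
            raise ValueError(f"negative od values at rows {bad.tolist()[:10]}")
        if np.any(od > OD_MAX):
            # OD is accepted as already scaled to [0, 255]; clamp with warning
            warnings.warn(
                f"{int(np.sum(od > OD_MAX))} od values exceed {OD_MAX:g}; clamping",
                stacklevel=2,
            )
            od = np.minimum(od, OD_MAX)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "od", od)

    @property
    def n_cells(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in micrometres."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "od": self.od})


@dataclass(frozen=True)
class SampleSummary:
    n_cells: int
    mean_od: float
    sd_od: float
    tissue_area: float  #: convex-hull area in µm²
    degenerate_hull: bool = False


def read_cell_table(
    path: str | Path,
    sample_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> CellTable:
    """Read a delimited text file into a :class:`CellTable`.

    ``column_map`` maps canonical names (``x``, ``y``, ``od``) to the column
    names used in the file.  Units are assumed µm for coordinates and a
    0-255 scale for OD.

    Raises
    ------
    KeyError
        If a required column is missing (configuration error).
    ValueError
        If any row fails validation; the message names the offending rows.
    """
    path = Path(path)
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    column_map = dict(column_map or {})
    cols = {}
    for canon in CELL_COLUMNS:
        name = column_map.get(canon, canon)
        if name not in df.columns:
            raise KeyError(
                f"{path.name}: required column {name!r} (for {canon!r}) not found; "
                f"available: {list(df.columns)}"
            )
        cols[canon] = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
    bad = ~np.all([np.isfinite(cols[c]) for c in CELL_COLUMNS], axis=0)
    if bad.any():
        rows = np.flatnonzero(bad)
        raise ValueError(
            f"{path.name}: non-numeric or missing values in rows {rows.tolist()[:20]}"
        )
    return CellTable(
        sample_id=sample_id or path.stem,
        x=cols["x"],
        y=cols["y"],
        od=cols["od"],
    )


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    """Write a cell table as CSV with full float precision (round-trip safe)."""
    cells.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV mapping sample_id -> cell-table path."""
    df = pd.read_csv(path)
    for col in ("sample_id", "path"):
        if col not in df.columns:
            raise KeyError(f"manifest requires column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample_id in manifest: {dup}")
    if len(df) == 0:
        raise ValueError("empty manifest")
    return df


def validate_survival_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-patient survival/clinical table.

    Requires ``sample_id``, ``os_time`` (> 0) and ``os_event`` (0/1); passes
    through any clinical covariates (age, gender, grade, pathologist_score,
    avg_expression).
    """
    for col in SURVIVAL_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"survival table requires column {col!r}")
    df = df.copy()
    df["os_time"] = pd.to_numeric(df["os_time"])
    df["os_event"] = pd.to_numeric(df["os_event"])
    if (df["os_time"] <= 0).any():
        raise ValueError("os_time must be > 0")
    if not df["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be 0 or 1")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in survival table")
    return df


def convex_hull_area(xy: np.ndarray) -> tuple[float, bool]:
    """Area of the convex hull of 2-D points; (0, True) when degenerate."""
    if len(xy) < 3:
        return 0.0, True
    try:
        hull = ConvexHull(xy)
    except QhullError:
        return 0.0, True  # collinear / duplicate points
    return float(hull.volume), False  # in 2-D, .volume is the polygon area


def summarize_sample(cells: CellTable) -> SampleSummary:
    """n_cells, mean/sd of OD, and tissue area (convex hull, µm²)."""
    area, degenerate = convex_hull_area(cells.xy)
    if degenerate:
        warnings.warn(
            f"sample {cells.sample_id}: degenerate convex hull, area reported as 0",
            stacklevel=2,
        )
    return SampleSummary(
        n_cells=cells.n_cells,
        mean_od=float(np.mean(cells.od)),
        sd_od=float(np.std(cells.od, ddof=1)) if cells.n_cells > 1 else 0.0,
        tissue_area=area,
        degenerate_hull=degenerate,
    )
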