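"""Digital-pathology features from classified cell tables.

A slide is represented as a table of cell centroids (x, y in pixels) with a
class label (cancer / stromal / lymphocyte).  Cell density around each cell is
estimated from the distance to its Nth nearest neighbour within the same
density-defining population: Sigma_N = N / (pi * d_N^2) in cells per px^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CELL_CLASSES = ("cancer", "stromal", "lymphocyte")
DEFAULT_N = 50
STABILITY_GRID = (40, 45, 50, 55, 60)


@dataclass
class DensitySummary:
    """Slide-level density summary for one cell class."""

    n_cells: int
    median: float
    mean: float
    n_neighbours: int


def _validate_cells(cells: pd.DataFrame) -> None:
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if not np.isfinite(cells[["x", "y"]].to_numpy(float)).all():
        raise ValueError("cell coordinates must be finite")
    bad = set(cells["cell_class"]) - set(CELL_CLASSES)
    if bad:
        raise ValueError(f"unknown cell class(es): {sorted(bad)}")


def _sigma_from_xy(
    xy: np.ndarray, n_neighbours: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-point kNN density Sigma = N / (pi * d_N^2) for an (m, 2) array."""
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=n_neighbours + 1)
    d_n = d[:, n_neighbours]
    if (d_n == 0).any():
        warnings.warn("duplicate coordinates; jittering by machine epsilon")
        rng = rng or np.random.default_rng(0)
        scale = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]), 1.0)
        xy = xy + rng.standard_normal(xy.shape) * np.finfo(float).eps * scale
        d, _ = cKDTree(xy).query(xy, k=n_neighbours + 1)
        d_n = d[:, n_neighbours]
    return n_neighbours / (np.pi * d_n**2)


def knn_density(
    cells: pd.DataFrame,
    target_class: str = "lymphocyte",
    n_neighbours: int = DEFAULT_N,
    rng: np.random.Generator | None = None,
) -> tuple[pd.Series, DensitySummary]:
    """Per-cell kNN density and slide summary for one cell class.

    For each cell of ``target_class``, Sigma = N / (pi * d_N^2) with d_N the
    distance to its Nth nearest same-class neighbour (the cell itself
    excluded).  Needs at least N+1 cells of the class; otherwise per-cell
    values are empty and the summary is missing-valued.  Duplicate
    coordinates that would give d_N = 0 are jittered by machine epsilon.
    """
    _validate_cells(cells)
    pts = cells.loc[cells["cell_class"] == target_class, ["x", "y"]].astype(float)
    if len(pts) < n_neighbours + 1:
        return (
            pd.Series(dtype=float),
            DensitySummary(len(pts), float("nan"), float("nan"), n_neighbours),
        )
    sigma = _sigma_from_xy(pts.to_numpy(), n_neighbours, rng)
    per_cell = pd.Series(sigma, index=pts.index, name="sigma")
    return per_cell, DensitySummary(
        n_cells=len(pts),
        median=float(np.median(sigma)),
        mean=float(np.mean(sigma)),
        n_neighbours=n_neighbours,
    )


def density_stability(
    cells: pd.DataFrame,
    target_class: str = "lymphocyte",
    n_grid: tuple[int, ...] = STABILITY_GRID,
    reference_n: int = DEFAULT_N,
) -> tuple[pd.DataFrame, float]:
    """Density summaries over a grid of N plus the maximum relative deviation
    of the median summary from its value at the reference N."""
    rows = []
    for n in n_grid:
        _, summ = knn_density(cells, target_class, n)
        rows.append({"n_neighbours": n, "median": summ.median, "mean": summ.mean})
    table = pd.DataFrame(rows)
    if reference_n in n_grid:
        ref = float(table.loc[table["n_neighbours"] == reference_n, "median"].iloc[0])
    else:
        ref = float(table["median"].iloc[len(table) // 2])
    if not np.isfinite(ref) or ref == 0:
        return table, float("nan")
    dev = float((table["median"] / ref - 1.0).abs().max())
    return table, dev


def cell_fractions(cells: pd.DataFrame) -> pd.Series:
    """Fraction of cells in each class; fractions sum to 1 exactly."""
    _validate_cells(cells)
    counts = cells["cell_class"].value_counts().reindex(CELL_CLASSES, fill_value=0)
    return counts / counts.sum()


def slide_features(
    cells: pd.DataFrame,
    n_neighbours: int = DEFAULT_N,
    microns_per_pixel: float | None = None,
) -> dict:
    """Tidy per-slide feature dict: class fractions plus lymphocyte density
    (median and mean per-cell Sigma).  Densities optionally converted to
    cells/micron^2 when ``microns_per_pixel`` is given."""
    fracs = cell_fractions(cells)
    _, summ = knn_density(cells, "lymphocyte", n_neighbours)
    scale = 1.0 if microns_per_pixel is None else 1.0 / microns_per_pixel**2
    return {
        "cancer_fraction": float(fracs["cancer"]),
        "stromal_fraction": float(fracs["stromal"]),
        "lymphocyte_fraction": float(fracs["lymphocyte"]),
        "lymphocyte_density_median": summ.median * scale,
        "lymphocyte_density_mean": summ.mean * scale,
    }
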