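"""Quantification of labeled-neuron distributions on flattened cortical maps.

Charted cells (transneuronally labeled neurons plotted in flattened-map
micrometer coordinates) are binned on a regular grid; the densest bins are
those in the upper percentile of occupied-bin counts, and each dense bin is
attributed to the cortical region of the majority of its member cells.
Cerebral (layer-5) maps use 200 x 200 um bins, cerebellar (Purkinje-cell)
maps 200 x 100 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DensityGrid",
    "bin_cells",
    "dense_bins",
    "region_composition",
    "dense_fraction_in_region",
    "default_bin_size",
]

CELL_COLUMNS = ["x_um", "y_um"]


def default_bin_size(cell_class: str):
    """Bin size (width, height) in um selected by cell class."""
    if cell_class == "purkinje_cell":
        return 200.0, 100.0
    return 200.0, 200.0


@dataclass
class DensityGrid:
    """Counts of charted cells in half-open rectangular bins.

    Bin (i, j) covers [x0 + i*w, x0 + (i+1)*w) x [y0 + j*h, y0 + (j+1)*h);
    only occupied bins are stored.  The origin is anchored at the minimum
    coordinate of the binned cells.
    """

    origin: tuple
    bin_w: float
    bin_h: float
    bins: pd.DataFrame        # columns ix, iy, count
    total: int

    def __post_init__(self) -> None:
        if int(self.bins["count"].sum()) != self.total:
            raise ValueError("bin counts must conserve the number of cells")

    def cell_bin_indices(self, cells: pd.DataFrame):
        """Bin indices (ix, iy) for each cell row, under this grid's origin."""
        ix = np.floor((cells["x_um"].to_numpy(float) - self.origin[0]) / self.bin_w)
        iy = np.floor((cells["y_um"].to_numpy(float) - self.origin[1]) / self.bin_h)
        return ix.astype(int), iy.astype(int)


def bin_cells(cells: pd.DataFrame, bin_w: float = 200.0,
              bin_h: float = 200.0) -> DensityGrid:
    """Assign every cell to exactly one half-open bin; counts are conserved.

    A cell lying exactly on a bin boundary belongs to the higher-index bin
    (half-open convention).
    """
    if bin_w <= 0 or bin_h <= 0:
        raise ValueError("bin sizes must be positive")
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("cell coordinates must be finite")
    origin = (float(x.min()), float(y.min()))
    ix = np.floor((x - origin[0]) / bin_w).astype(int)
    iy = np.floor((y - origin[1]) / bin_h).astype(int)
    counts = (pd.DataFrame({"ix": ix, "iy": iy})
              .groupby(["ix", "iy"]).size().rename("count").reset_index()
              .sort_values(["ix", "iy"], ignore_index=True))
    return DensityGrid(origin=origin, bin_w=bin_w, bin_h=bin_h,
                       bins=counts, total=len(cells))


def dense_bins(grid: DensityGrid, percentile: float = 90.0):
    """Occupied bins at or above the given percentile of occupied-bin counts.

    The threshold is the smallest occupied-bin count at or above the
    percentile position (ties included, matching a ">= threshold" rule such
    as the reported "5 or more").  Zero bins are excluded from the percentile:
    on an unbounded flattened map their number is arbitrary.
    """
    counts = grid.bins["count"].to_numpy()
    threshold = float(np.percentile(counts, percentile, method="higher"))
    dense = grid.bins[grid.bins["count"] >= threshold].reset_index(drop=True)
    return dense, threshold


def region_composition(cells: pd.DataFrame,
                       group_map: Optional[Dict[str, str]] = None):
    """Percent of cells per region, and per region group when a map is given.

    Regions absent from ``group_map`` are reported under ``"other"``.
    """
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    per_region = (cells["region"].value_counts(normalize=True) * 100.0)
    per_region = per_region.sort_index()
    if group_map is None:
        return per_region, None
    groups = cells["region"].map(lambda r: group_map.get(r, "other"))
    per_group = (groups.value_counts(normalize=True) * 100.0).sort_index()
    return per_region, per_group


def dense_fraction_in_region(grid: DensityGrid, cells: pd.DataFrame,
                             region: str, percentile: float = 90.0):
    """Percent of dense bins whose modal member-cell region is ``region``.

    Each dense bin is labeled by the most frequent region among its member
    cells; ties are broken lexicographically and flagged.  Returns a dict with
    the percentage, the threshold, per-bin labels and the tie flags; when the
    dense set is empty the percentage is NaN with an explanatory message.
    """
    if len(grid.bins) == 0:
        return {"percent": math.nan, "threshold": math.nan, "n_dense": 0,
                "message": "dense-bin set is empty: grid has no occupied bins"}
    dense, threshold = dense_bins(grid, percentile)
    if len(dense) == 0:
        return {"percent": math.nan, "threshold": threshold, "n_dense": 0,
                "message": "dense-bin set is empty"}
    ix, iy = grid.cell_bin_indices(cells)
    key = pd.DataFrame({"ix": ix, "iy": iy, "region": cells["region"].to_numpy()})
    labels, ties = [], []
    dense_idx = set(zip(dense["ix"], dense["iy"]))
    modal = (key.groupby(["ix", "iy"])["region"]
             .agg(lambda s: _modal_label(s))
             .to_dict())
    for b in dense.itertuples():
        lab, tie = modal[(b.ix, b.iy)]
        labels.append(lab)
        ties.append(tie)
    labels = pd.Series(labels, name="modal_region")
    pct = float((labels == region).mean() * 100.0)
    return {"percent": pct, "threshold": threshold, "n_dense": len(dense),
            "modal_regions": labels, "ties": ties}


def _modal_label(s: pd.Series):
    counts = s.value_counts()
    top = counts[counts == counts.iloc[0]]
    tie = len(top) > 1
    return sorted(top.index)[0], tie
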