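"""Cell-shape and jamming metrics.

The shape index of a cell, p0 = L/sqrt(A) (L perimeter, A area), is a
dimensionless, scale-invariant readout of tissue fluidity: the isoperimetric
inequality bounds it below by 2*sqrt(pi) ~ 3.545 (a circle), a regular
hexagon sits at ~3.722, and a jamming transition has been proposed at the
regular-pentagon value ~3.81 — tissues with mean p0 below it behave
solid-like, above it fluid-like. The standard deviation of p0 across a
field of cells is a second fluidity readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JAMMING_THRESHOLD_P0",
    "CellGeometry",
    "FrameGeometry",
    "shape_index",
    "cell_shape_index",
    "neighbor_levels",
    "field_shape_stats",
    "polygon_class_distribution",
    "regular_polygon_shape_index",
]

#: literature jamming-transition shape index (regular pentagon, 2 d.p.)
JAMMING_THRESHOLD_P0 = 3.81


@dataclass
class CellGeometry:
    """Geometry of one cell in one frame (all lengths in um)."""

    cell_id: int
    polygon_um: np.ndarray  # (n, 2) boundary vertices, x-right / y-down
    area_um2: float
    perimeter_um: float
    centroid_um: np.ndarray
    neighbors: frozenset[int] = frozenset()
    on_border: bool = False

    @property
    def n_sides(self) -> int:
        """Topological side count = number of neighbors (interior cells)."""
        return len(self.neighbors)

    @property
    def shape_index(self) -> float:
        return shape_index(self.perimeter_um, self.area_um2)


@dataclass
class FrameGeometry:
    """Per-cell geometry and the adjacency graph of one frame."""

    cells: dict[int, CellGeometry] = field(default_factory=dict)

    @property
    def adjacency(self) -> set[tuple[int, int]]:
        """Symmetric adjacency as sorted id pairs."""
        pairs = set()
        for cid, cell in self.cells.items():
            for nb in cell.neighbors:
                pairs.add((min(cid, nb), max(cid, nb)))
        return pairs

    def interior_cells(self) -> set[int]:
        return {cid for cid, c in self.cells.items() if not c.on_border}

    def validate(self) -> None:
        for cid, cell in self.cells.items():
            if cid in cell.neighbors:
                raise ValueError(f"cell {cid} adjacent to itself")
            for nb in cell.neighbors:
                if nb in self.cells and cid not in self.cells[nb].neighbors:
                    raise ValueError(f"asymmetric adjacency ({cid}, {nb})")


def shape_index(perimeter: float, area: float) -> float:
    """p0 = L / sqrt(A). Scale-invariant; >= 2*sqrt(pi) for any shape."""
    if perimeter <= 0 or area <= 0:
        raise ValueError("perimeter and area must be positive")
    return perimeter / math.sqrt(area)


def cell_shape_index(cell: CellGeometry) -> float:
    return shape_index(cell.perimeter_um, cell.area_um2)


def regular_polygon_shape_index(n: int) -> float:
    """Closed-form p0 of a regular n-gon: n side / sqrt(n s^2/4 * cot(pi/n))."""
    if n < 3:
        raise ValueError("need n >= 3")
    area = n / (4.0 * math.tan(math.pi / n))  # unit side
    return n / math.sqrt(area)


def neighbor_levels(geometry: FrameGeometry, annotation) -> tuple[set[int], set[int]]:
    """First- and second-level interommatidial neighbors of the cluster.

    First level: cells adjacent to any R-cell (cone cells, being ICs by
    convention, qualify). Second level: cells adjacent to a first-level
    cell, excluding the cluster and the first level itself. Conventionally
    evaluated on the frame of R7 recruitment.
    """
    r_cells = {cid for cid, role in annotation.roles.items() if role.startswith("R")}
    first: set[int] = set()
    for cid in r_cells:
        if cid in geometry.cells:
            first |= set(geometry.cells[cid].neighbors)
    first -= r_cells
    second: set[int] = set()
    for cid in first:
        if cid in geometry.cells:
            second |= set(geometry.cells[cid].neighbors)
    second -= first | r_cells
    return first, second


def field_shape_stats(
    geometry: FrameGeometry,
    annotation,
    levels: tuple[int, ...] = (1, 2),
    exclude_cones: bool = False,
) -> tuple[float, float]:
    """Mean and SD of the shape index over the IC neighborhood of a cluster.

    Pools the first- and/or second-level neighbors (per ``levels``),
    excludes border-truncated cells, and returns (mean p0, SD p0). The SD
    uses the population convention (ddof=0), matching a per-field spread
    readout. Raises if fewer than 3 eligible cells remain.
    """
    first, second = neighbor_levels(geometry, annotation)
    pool: set[int] = set()
    if 1 in levels:
        pool |= first
    if 2 in levels:
        pool |= second
    if exclude_cones:
        pool -= {cid for cid, role in annotation.roles.items() if role == "cone"}
    eligible = [geometry.cells[c] for c in pool
                if c in geometry.cells and not geometry.cells[c].on_border]
    if len(eligible) < 3:
        raise ValueError(f"insufficient data: only {len(eligible)} eligible cells")
    p0 = np.array([cell_shape_index(c) for c in eligible])
    return float(p0.mean()), float(p0.std())


def polygon_class_distribution(geometry: FrameGeometry, cells=None):
    """Histogram of topological side classes 3..9+ over interior cells.

    Returns (counts, fractions) as dicts keyed 3..9, where key 9 pools all
    cells with nine or more sides. Fractions sum to 1.
    """
    ids = set(cells) if cells is not None else geometry.interior_cells()
    ids = {c for c in ids if c in geometry.cells and not geometry.cells[c].on_border}
    if not ids:
        raise ValueError("no interior cells to classify")
    counts = {k: 0 for k in range(3, 10)}
    for cid in ids:
        n = geometry.cells[cid].n_sides
        counts[min(max(n, 3), 9)] += 1
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()}
    return counts, fractions
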