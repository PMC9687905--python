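"""Lattice (cell-list) spatial index for fixed-radius neighbor queries.

Atoms are binned into cubic cells of side ``cell_size``; a query of radius
r <= cell_size only has to examine the 27 cells around the query point's
cell, which makes the all-donors search linear in atom count instead of
quadratic. Larger radii are supported by widening the shell proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np


@dataclass
class SpatialGrid:
    cell_size: float
    cells: dict[tuple[int, int, int], list] = field(default_factory=dict)
    positions: dict[Hashable, np.ndarray] = field(default_factory=dict)

    def cell_of(self, position: Sequence[float]) -> tuple[int, int, int]:
        return (
            math.floor(position[0] / self.cell_size),
            math.floor(position[1] / self.cell_size),
            math.floor(position[2] / self.cell_size),
        )


def build_grid(atoms: Sequence, cell_size: float, position_of=None) -> SpatialGrid:
    """Index ``atoms`` by floor(position / cell_size) per axis.

    ``position_of`` extracts the coordinate triple from each item (default:
    the item's ``position`` attribute).
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    if position_of is None:
        position_of = lambda a: a.position  # noqa: E731
    grid = SpatialGrid(cell_size=cell_size)
    for a in atoms:
        pos = np.asarray(position_of(a), dtype=float)
        grid.cells.setdefault(grid.cell_of(pos), []).append((a, pos))
    return grid


def radius_query(grid: SpatialGrid, center: Sequence[float], r: float) -> list:
    """All indexed atoms within Euclidean distance <= r of ``center``.

    Closed-ball convention: an atom exactly at distance r is included.
    """
    center = np.asarray(center, dtype=float)
    shells = max(1, math.ceil(r / grid.cell_size))
    ci, cj, ck = grid.cell_of(center)
    r2 = r * r
    found = []
    for di in range(-shells, shells + 1):
        for dj in range(-shells, shells + 1):
            for dk in range(-shells, shells + 1):
                bucket = grid.cells.get((ci + di, cj + dj, ck + dk))
                if not bucket:
                    continue
                for a, pos in bucket:
                    d = pos - center
                    if float(d @ d) <= r2:
                        found.append(a)
    return found
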