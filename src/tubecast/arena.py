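"""World representation for the construction lattice.

The arena is a rectangular grid of 1 mm square cells (default 220×140, the
floor of the experimental container).  Each cell is EMPTY, NEST (the central
sawdust block that supplies building material) or BUILT.  Two static fields
live on the grid:

* ``k_field`` — the pheromone-independent site preference.  Cells in a band
  along the container wall get twice the baseline value because a wall-hugging
  ("edging") tube needs roughly half the material of a free-standing one.
* the path-distance field ``d`` — length of the shortest 4-connected route
  from the nest through the existing structure, which discounts attraction far
  from the nest.

Coordinates are (row, col), 0-based, arrays shaped ``(height, width)``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

EMPTY: int = 0
NEST: int = 1
BUILT: int = 2

#: 4-connected (von Neumann) neighbourhood — structural adjacency and paths.
N4: tuple[tuple[int, int], ...] = ((-1, 0), (1, 0), (0, -1), (0, 1))
#: 8-connected (Moore) neighbourhood — pheromone/crowdedness/direction lookups.
N8: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)

#: Marks unreachable cells in distance fields.
UNDEFINED = np.inf


class ConfigError(ValueError):
    """Raised for invalid arena or simulation configuration."""


@dataclass
class Arena:
    """Grid geometry plus the static per-cell fields.

    Attributes
    ----------
    state : (height, width) uint8 array of EMPTY / NEST / BUILT labels.
    k_field : per-cell site preference (1 inside, ``k_edge`` in the wall band).
    blocked : cells permanently excluded from construction (collision rule).
    nest_radius : nominal radius of the nest disc in cells, metadata only —
        the nest itself is defined by exact cell count, see :func:`init_arena`.
    """

    width: int
    height: int
    nest_area: int
    group_size: int
    state: np.ndarray
    k_field: np.ndarray
    blocked: np.ndarray
    band: int
    k_edge: float = 2.0
    cell_size_mm: float = 1.0
    nest_radius: float = 18.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def center(self) -> tuple[float, float]:
        """Arena centre in cell-centre units, (row, col)."""
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)

    def in_bounds(self, r: int, c: int) -> bool:
        return 0 <= r < self.height and 0 <= c < self.width

    def copy(self) -> "Arena":
        return Arena(
            width=self.width, height=self.height, nest_area=self.nest_area,
            group_size=self.group_size, state=self.state.copy(),
            k_field=self.k_field.copy(), blocked=self.blocked.copy(),
            band=self.band, k_edge=self.k_edge, cell_size_mm=self.cell_size_mm,
            nest_radius=self.nest_radius,
        )


def default_band(group_size: int) -> int:
    """Wall-band width in cells: 5 for 400-worker runs, 4 for 50-worker runs.

    Calibrated to the mean width of edging tubes observed at each group size.
    """
    return 5 if group_size >= 400 else 4


def edge_band_mask(height: int, width: int, band: int) -> np.ndarray:
    """Boolean mask of cells strictly within ``band`` cells of the border."""
    rr, cc = np.mgrid[0:height, 0:width]
    border_dist = np.minimum(np.minimum(rr, height - 1 - rr),
                             np.minimum(cc, width - 1 - cc))
    return border_dist < band


def compute_k_field(height: int, width: int, *, k_edge: float = 2.0,
                    band: int | None = None, group_size: int = 400) -> np.ndarray:
    """Site-preference field: ``k_edge`` in the wall band, 1 elsewhere."""
    if k_edge <= 0:
        raise ConfigError(f"k_edge must be positive, got {k_edge}")
    if band is None:
        band = default_band(group_size)
    if band < 0:
        raise ConfigError(f"band must be nonnegative, got {band}")
    k = np.ones((height, width), dtype=float)
    k[edge_band_mask(height, width, band)] = k_edge
    return k


def nest_cells(height: int, width: int, nest_area: int) -> np.ndarray:
    """The ``nest_area`` cells nearest the arena centre, as an (n, 2) index array.

    The nominal disc radius (18) and printed area (1020) cannot both be hit by
    any centre-in-disc rasterisation, so the nest is defined by exact cell
    count: cells ranked by Euclidean distance of their centres from the arena
    centre, ties broken by angle then row-major index.  Deterministic, and the
    area is exact by construction.
    """
    if nest_area < 0 or nest_area > height * width:
        raise ConfigError(
            f"nest_area {nest_area} outside [0, {height * width}]")
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    dy, dx = rr - cy, cc - cx
    dist = np.hypot(dy, dx).ravel()
    ang = np.arctan2(dy, dx).ravel()
    idx = np.arange(dist.size)
    order = np.lexsort((idx, ang, dist))
    chosen = order[:nest_area]
    return np.column_stack(np.unravel_index(chosen, (height, width)))


def init_arena(width: int = 220, height: int = 140, nest_area: int = 1020,
               group_size: int = 400, *, k_edge: float = 2.0,
               band: int | None = None, nest_radius: float = 18.0) -> Arena:
    """Create a fresh arena with the central nest and the wall-preference field.

    Defaults reproduce the study container: 220×140 mm floor with a nest disc
    of 1020 cells (radius ≈ 18 mm) at the centre.
    """
    if width <= 0 or height <= 0:
        raise ConfigError(f"arena dimensions must be positive, got {width}×{height}")
    if nest_area > width * height:
        raise ConfigError("nest_area exceeds arena size")
    if band is None:
        band = default_band(group_size)
    state = np.zeros((height, width), dtype=np.uint8)
    cells = nest_cells(height, width, nest_area)
    state[cells[:, 0], cells[:, 1]] = NEST
    k = compute_k_field(height, width, k_edge=k_edge, band=band,
                        group_size=group_size)
    return Arena(
        width=width, height=height, nest_area=nest_area,
        group_size=group_size, state=state, k_field=k,
        blocked=np.zeros((height, width), dtype=bool), band=band,
        k_edge=k_edge, nest_radius=nest_radius,
    )


def distance_field(arena: Arena) -> np.ndarray:
    """Shortest-route distance from the nest, from scratch.

    Breadth-first search, 4-connected, walking only on NEST ∪ BUILT cells.
    NEST cells are at distance 0; each step costs one cell.  Cells not
    reachable through the structure are ``UNDEFINED`` (inf).  The per-cell
    values agree with the incremental construction-time distances the engine
    stores as long as no two tubes have merged.
    """
    d = np.full(arena.shape, UNDEFINED)
    walkable = arena.state != EMPTY
    seeds = np.argwhere(arena.state == NEST)
    queue: deque[tuple[int, int]] = deque()
    for r, c in seeds:
        d[r, c] = 0.0
        queue.append((int(r), int(c)))
    while queue:
        r, c = queue.popleft()
        nd = d[r, c] + 1.0
        for dr, dc in N4:
            nr, nc = r + dr, c + dc
            if (arena.in_bounds(nr, nc) and walkable[nr, nc]
                    and nd < d[nr, nc]):
                d[nr, nc] = nd
                queue.append((nr, nc))
    return d


def candidate_distance(d: np.ndarray, arena: Arena, cell: tuple[int, int]) -> float:
    """Distance d_i of a vacant candidate: 1 + min d over constructed 4-neighbours."""
    r, c = cell
    best = UNDEFINED
    for dr, dc in N4:
        nr, nc = r + dr, c + dc
        if arena.in_bounds(nr, nc) and arena.state[nr, nc] != EMPTY:
            best = min(best, d[nr, nc])
    return best + 1.0 if np.isfinite(best) else UNDEFINED


def write_pgm(path, grid: np.ndarray) -> None:
    """Write a state grid as binary PGM (P5): 0 empty, 128 nest, 255 built."""
    levels = np.zeros(grid.shape, dtype=np.uint8)
    levels[grid == NEST] = 128
    levels[grid == BUILT] = 255
    header = f"P5\n{grid.shape[1]} {grid.shape[0]}\n255\n".encode()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(levels.tobytes())


def read_pgm(path) -> np.ndarray:
    """Read a P5/P2 PGM written by :func:`write_pgm` back to a state grid."""
    import imageio.v3 as iio

    levels = np.asarray(iio.imread(path))
    grid = np.zeros(levels.shape, dtype=np.uint8)
    grid[levels == 128] = NEST
    grid[levels >= 192] = BUILT
    return grid
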