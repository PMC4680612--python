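"""Per-event construction choice: candidates, attraction, sampling, collisions.

An active worker picks one vacant cell adjacent to the existing structure with
probability proportional to its attraction

    A_i = v_i * (c_i + k_i - b * d_i) ** x

where ``c_i`` is the perceived cement pheromone (max over built 8-neighbours),
``k_i`` the wall-band site preference, ``d_i`` the path distance from the
nest, ``b`` a discount calibrated so the attraction base vanishes once a tube
has run the full container perimeter, and ``x`` the pheromone sensitivity that
sets the strength of positive feedback.  ``v_i`` is a direction memory: each
tube remembers its beginning point, and growth straight away from it is
favoured (v = (1 + cos θ)/2, summed over all built neighbours that could be
the construction's last cell).

Two behavioural rules modulate this. Crowded sites (mean crowdedness of built
neighbours ≥ threshold) are excluded, modelling congestion inside a tube.
When two distinct tubes — cells whose construction-time distances differ by at
least ``collision_d_gap`` — come into contact over at least
``collision_contact`` cells, building near the junction stops for good: an
8×8 window around the last-built cell is permanently blocked.

Scalar functions here are the readable reference; :func:`evaluate_candidates`
is the vectorised kernel the engine uses, and the test-suite checks the two
agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .arena import (BUILT, EMPTY, N4, N8, NEST, UNDEFINED, Arena,
                    edge_band_mask)
from .stigmergy import (CrowdField, PheromoneField, candidate_crowdedness,
                        candidate_pheromone, deposit)


@dataclass
class ChoiceParams:
    """Constants of the site-choice rule and collision handling."""

    x: float = 3.0
    b: float = 1.0 / 360.0
    edge_exit_v: float = 0.0007274
    collision_d_gap: float = 10.0
    collision_contact: int = 8
    collision_block_window: int = 8

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError(f"sensitivity x must be >= 0, got {self.x}")
        if self.b <= 0:
            raise ValueError(f"distance discount b must be > 0, got {self.b}")


@dataclass
class BuildState:
    """Mutable simulation state: arena + fields + tube bookkeeping.

    ``dstore`` holds the construction-time path distance of every cell (0 on
    the nest, assigned once when a cell is built, +inf on vacant cells);
    ``origin_r/origin_c`` hold each built cell's tube beginning point in
    cell-centre coordinates (possibly half-integer after tube merges).
    ``cand_mask`` caches the vacant cells 4-adjacent to the structure.
    """

    arena: Arena
    pher: PheromoneField
    crowd: CrowdField
    dstore: np.ndarray
    origin_r: np.ndarray
    origin_c: np.ndarray
    contact: np.ndarray
    cand_mask: np.ndarray
    band_mask: np.ndarray
    built_count: int = 0

    @classmethod
    def from_arena(cls, arena: Arena, *, q: float = 0.3, r: float = 0.7,
                   crowd_threshold: float = 0.9,
                   crowd_increment: float | None = None) -> "BuildState":
        dstore = np.full(arena.shape, UNDEFINED)
        dstore[arena.state == NEST] = 0.0
        nan = np.full(arena.shape, np.nan)
        structure = arena.state != EMPTY
        adj = ndimage.binary_dilation(
            structure, structure=ndimage.generate_binary_structure(2, 1))
        cand = adj & (arena.state == EMPTY) & ~arena.blocked
        return cls(
            arena=arena,
            pher=PheromoneField.zeros(arena, q=q, r=r),
            crowd=CrowdField.zeros(
                arena, threshold=crowd_threshold,
                increment=q if crowd_increment is None else crowd_increment),
            dstore=dstore,
            origin_r=nan.copy(), origin_c=nan.copy(),
            contact=np.zeros(arena.shape, dtype=bool),
            cand_mask=cand,
            band_mask=edge_band_mask(arena.height, arena.width, arena.band),
        )


def candidate_set(state: BuildState, params: ChoiceParams | None = None,
                  apply_crowd_filter: bool = True) -> set[tuple[int, int]]:
    """Vacant, unblocked cells 4-adjacent to the structure, minus crowded ones.

    Full-grid scan; the engine keeps ``cand_mask`` incrementally instead.
    """
    arena = state.arena
    structure = arena.state != EMPTY
    adj = ndimage.binary_dilation(
        structure, structure=ndimage.generate_binary_structure(2, 1))
    mask = adj & (arena.state == EMPTY) & ~arena.blocked
    cells = {(int(r), int(c)) for r, c in np.argwhere(mask)}
    if apply_crowd_filter:
        cells = {cell for cell in cells
                 if candidate_crowdedness(state.crowd, cell, arena)
                 < state.crowd.threshold}
    return cells


def direction_factor(candidate: tuple[int, int], via: tuple[int, int],
                     state: BuildState, params: ChoiceParams) -> float:
    """(1 + cos θ)/2 for building ``candidate`` as the next cell after ``via``.

    θ is the angle between the vector from the tube's beginning point to
    ``via`` and the vector from ``via`` to ``candidate``: 1 for growth straight
    away from the origin, 0 for growth straight back toward it.  Leaving the
    wall band for the interior is instead given the small empirical constant
    ``edge_exit_v``, so established edging tubes rarely peel off the wall.
    """
    vr, vc = via
    if state.arena.state[vr, vc] != BUILT:
        raise ValueError(f"via cell {via} is not built")
    if state.band_mask[vr, vc] and not state.band_mask[candidate]:
        return params.edge_exit_v
    orr, orc = state.origin_r[vr, vc], state.origin_c[vr, vc]
    if math.isnan(orr):
        return 1.0
    v1r, v1c = vr - orr, vc - orc
    if v1r == 0.0 and v1c == 0.0:
        # via is its own origin: fall back to the outward (nest-centre -> via)
        # direction so first steps of a new tube still prefer moving away.
        cy, cx = state.arena.center
        v1r, v1c = vr - cy, vc - cx
    v2r, v2c = candidate[0] - vr, candidate[1] - vc
    n1 = math.hypot(v1r, v1c)
    n2 = math.hypot(v2r, v2c)
    cos = (v1r * v2r + v1c * v2c) / (n1 * n2)
    return 0.5 + 0.5 * cos


def direction_sum(candidate: tuple[int, int], state: BuildState,
                  params: ChoiceParams) -> float:
    """v_i: sum of direction factors over all built 8-neighbours; 1 if none.

    A candidate with only nest neighbours has no defined construction
    direction — v = 1 so building can start from the nest.
    """
    r, c = candidate
    total = 0.0
    n_built = 0
    for dr, dc in N8:
        nr, nc = r + dr, c + dc
        if state.arena.in_bounds(nr, nc) and state.arena.state[nr, nc] == BUILT:
            total += direction_factor(candidate, (nr, nc), state, params)
            n_built += 1
    return total if n_built else 1.0


def candidate_d(candidate: tuple[int, int], state: BuildState) -> float:
    """d_i of a vacant candidate: 1 + min stored d over constructed 4-neighbours."""
    r, c = candidate
    best = UNDEFINED
    for dr, dc in N4:
        nr, nc = r + dr, c + dc
        if state.arena.in_bounds(nr, nc) and state.arena.state[nr, nc] != EMPTY:
            best = min(best, state.dstore[nr, nc])
    return best + 1.0 if np.isfinite(best) else UNDEFINED


def attraction(candidate: tuple[int, int], state: BuildState,
               params: ChoiceParams) -> float:
    """A_i = v_i * max(0, c_i + k_i - b*d_i)^x; 0 for unreachable or repelled cells.

    The base is clamped at zero before exponentiation so non-integer ``x``
    stays real; a cell the structure cannot reach (undefined d) attracts 0.
    """
    d_i = candidate_d(candidate, state)
    if not np.isfinite(d_i):
        return 0.0
    c_i = candidate_pheromone(state.pher, candidate, state.arena)
    k_i = state.arena.k_field[candidate]
    base = c_i + k_i - params.b * d_i
    if base <= 0.0:
        return 0.0
    return direction_sum(candidate, state, params) * base ** params.x


def choice_distribution(attractions: np.ndarray) -> np.ndarray:
    """Normalise attractions to choice probabilities P_i = A_i / ΣA_j.

    If every attraction is zero the choice falls back to uniform, so a step
    never stalls while vacant adjacent cells exist.
    """
    a = np.asarray(attractions, dtype=float)
    if a.size == 0:
        raise ValueError("empty candidate set")
    total = a.sum()
    if total <= 0.0:
        return np.full(a.size, 1.0 / a.size)
    return a / total


def _new_origin(state: BuildState, cell: tuple[int, int]) -> tuple[float, float]:
    """Beginning point for a just-built cell.

    A cell touching the nest or the container wall starts a new tube at its
    own centre; otherwise the origin is inherited from built neighbours, and a
    junction of tubes with distinct origins takes their mean (midpoint for two).
    """
    r, c = cell
    arena = state.arena
    if r in (0, arena.height - 1) or c in (0, arena.width - 1):
        return float(r), float(c)
    for dr, dc in N4:
        nr, nc = r + dr, c + dc
        if arena.in_bounds(nr, nc) and arena.state[nr, nc] == NEST:
            return float(r), float(c)
    origins: list[tuple[float, float]] = []
    for dr, dc in N8:
        nr, nc = r + dr, c + dc
        if arena.in_bounds(nr, nc) and arena.state[nr, nc] == BUILT:
            o = (float(state.origin_r[nr, nc]), float(state.origin_c[nr, nc]))
            if o not in origins:
                origins.append(o)
    if not origins:
        return float(r), float(c)
    return (sum(o[0] for o in origins) / len(origins),
            sum(o[1] for o in origins) / len(origins))


def build(state: BuildState, cell: tuple[int, int],
          params: ChoiceParams) -> None:
    """Fill ``cell``: material, pheromone deposit, bookkeeping, collision check."""
    r, c = cell
    arena = state.arena
    if arena.state[r, c] != EMPTY or arena.blocked[r, c]:
        raise ValueError(f"cannot build on cell {cell}")
    d_i = candidate_d(cell, state)
    origin = _new_origin(state, cell)
    # a new cell inherits the field values it was perceived to have while
    # vacant (max pheromone / mean crowdedness of constructed neighbours)
    # before the deposit tops them up: accumulation ratchets along a growing
    # tube, which is the positive-feedback loop that localises construction
    inherited_c = candidate_pheromone(state.pher, cell, arena)
    inherited_w = candidate_crowdedness(state.crowd, cell, arena)
    arena.state[r, c] = BUILT
    state.dstore[r, c] = d_i
    state.origin_r[r, c], state.origin_c[r, c] = origin
    state.pher.c[r, c] = inherited_c
    deposit(state.pher, cell, arena)
    state.crowd.w[r, c] = inherited_w + state.crowd.increment
    state.built_count += 1
    state.cand_mask[r, c] = False
    for dr, dc in N4:
        nr, nc = r + dr, c + dc
        if (arena.in_bounds(nr, nc) and arena.state[nr, nc] == EMPTY
                and not arena.blocked[nr, nc]):
            state.cand_mask[nr, nc] = True
    detect_collision(state, cell, params)


def _block_window(shape: tuple[int, int], center: tuple[int, int],
                  window: int) -> tuple[slice, slice]:
    """Index slices of a ``window``×``window`` box centred on ``center``."""
    r, c = center
    lo = window // 2 - (1 if window % 2 == 0 else 0)
    hi = window // 2
    return (slice(max(0, r - lo), min(shape[0], r + hi + 1)),
            slice(max(0, c - lo), min(shape[1], c + hi + 1)))


def detect_collision(state: BuildState, last_built: tuple[int, int],
                     params: ChoiceParams) -> bool:
    """Mark tube-collision contacts and block the junction when large enough.

    Adjacent built cells whose construction-time distances differ by at least
    ``collision_d_gap`` belong to different tubes; both are marked contact
    cells.  Once the 8×8 window centred on the last-built cell holds at least
    ``collision_contact`` contact cells, the window is permanently blocked.
    Returns True when a new block was placed.
    """
    r, c = last_built
    arena = state.arena
    dz = state.dstore[r, c]
    if not np.isfinite(dz):
        return False
    for dr, dc in N8:
        nr, nc = r + dr, c + dc
        if (arena.in_bounds(nr, nc) and arena.state[nr, nc] == BUILT
                and np.isfinite(state.dstore[nr, nc])
                and abs(dz - state.dstore[nr, nc]) >= params.collision_d_gap):
            state.contact[r, c] = True
            state.contact[nr, nc] = True
    if not state.contact[r, c]:
        return False
    win = _block_window(arena.shape, last_built, params.collision_block_window)
    if int(state.contact[win].sum()) >= params.collision_contact:
        arena.blocked[win] = True
        state.cand_mask[win] = False
        return True
    return False


def evaluate_candidates(state: BuildState, params: ChoiceParams):
    """Vectorised attraction for every cached candidate cell.

    Returns ``(rows, cols, attractions, keep)`` where ``keep`` flags the
    candidates that survive the crowding filter.  Semantics match the scalar
    functions above exactly (shared test).
    """
    rows, cols = np.nonzero(state.cand_mask)
    m = rows.size
    if m == 0:
        return rows, cols, np.empty(0), np.empty(0, dtype=bool)
    arena = state.arena
    h, w = arena.shape
    st = arena.state
    cy, cx = arena.center

    cmax = np.zeros(m)
    wsum = np.zeros(m)
    nbuilt = np.zeros(m, dtype=np.int64)
    vsum = np.zeros(m)
    band_cand = state.band_mask[rows, cols]

    for dr, dc in N8:
        nr, nc = rows + dr, cols + dc
        valid = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        nri, nci = np.clip(nr, 0, h - 1), np.clip(nc, 0, w - 1)
        built = valid & (st[nri, nci] == BUILT)
        cmax = np.maximum(cmax, np.where(built, state.pher.c[nri, nci], 0.0))
        wsum += np.where(built, state.crowd.w[nri, nci], 0.0)
        nbuilt += built
        # direction term for this via cell
        orr = np.where(built, state.origin_r[nri, nci], 0.0)
        orc = np.where(built, state.origin_c[nri, nci], 0.0)
        no_origin = np.isnan(orr)
        orr, orc = np.nan_to_num(orr), np.nan_to_num(orc)
        v1r, v1c = nr - orr, nc - orc
        degenerate = (v1r == 0.0) & (v1c == 0.0)
        v1r = np.where(degenerate, nr - cy, v1r)
        v1c = np.where(degenerate, nc - cx, v1c)
        n1 = np.hypot(v1r, v1c)
        n2 = math.hypot(dr, dc)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (v1r * -dr + v1c * -dc) / (n1 * n2)
        term = 0.5 + 0.5 * cos
        term = np.where(no_origin, 1.0, term)
        exit_edge = state.band_mask[nri, nci] & ~band_cand
        term = np.where(exit_edge, params.edge_exit_v, term)
        vsum += np.where(built, term, 0.0)
    v = np.where(nbuilt == 0, 1.0, vsum)

    dmin = np.full(m, UNDEFINED)
    for dr, dc in N4:
        nr, nc = rows + dr, cols + dc
        valid = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        nri, nci = np.clip(nr, 0, h - 1), np.clip(nc, 0, w - 1)
        constructed = valid & (st[nri, nci] != EMPTY)
        dmin = np.minimum(dmin, np.where(constructed,
                                         state.dstore[nri, nci], UNDEFINED))
    d_i = dmin + 1.0
    base = cmax + arena.k_field[rows, cols] - params.b * d_i
    with np.errstate(invalid="ignore"):
        a = np.where(np.isfinite(d_i) & (base > 0.0),
                     v * np.where(base > 0.0, base, 1.0) ** params.x, 0.0)
    wmean = np.where(nbuilt > 0, wsum / np.maximum(nbuilt, 1), 0.0)
    keep = wmean < state.crowd.threshold
    return rows, cols, a, keep
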