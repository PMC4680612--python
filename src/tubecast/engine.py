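"""Time stepping, stopping, snapshots, replication and the parameter sweep.

A run starts from the central nest with ``N`` workers of which a fraction
``alpha`` is active.  Within a time step each active worker in turn picks one
vacant cell by the attraction rule and fills it — sequentially, so later
workers in the same step see earlier deposits and crowding (strict synchrony
would let every worker pick the same cell).  At the end of every step the
pheromone evaporates and crowdedness resets.  A run stops, mid-step if
necessary, exactly when ``stop_count`` cells have been built: 5700 for
400-worker groups and 1350 for 50-worker groups, the mean areas the live
experiment reached in 30 days.

The study's sweep crosses alpha ∈ {0.05..0.25} with the pheromone sensitivity
x ∈ {1..3}, 25 parameter sets, replicated with independently derived seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .arena import Arena, ConfigError, init_arena
from .builder import (BuildState, ChoiceParams, build, evaluate_candidates)
from . import morphometry

DEFAULT_ALPHA_GRID = (0.05, 0.10, 0.15, 0.20, 0.25)
DEFAULT_X_GRID = (1.0, 1.5, 2.0, 2.5, 3.0)

#: Terminal built-cell counts by group size (mean constructed area at 30 days).
DEFAULT_STOP_COUNTS = {400: 5700, 50: 1350}


class StallError(RuntimeError):
    """No worker could build for ``max_stalled_steps`` consecutive steps."""

    def __init__(self, message: str, trajectory: "Trajectory | None" = None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class SimParams:
    """All constants of one simulation run.

    ``stop_count``, ``band`` and ``crowd_increment`` default from the group
    size / deposit amount when left as None.
    """

    group_size: int = 400
    alpha: float = 0.05
    x: float = 3.0
    q: float = 0.3
    r: float = 0.7
    b: float = 1.0 / 360.0
    crowd_threshold: float = 0.9
    crowd_increment: float | None = None
    edge_exit_v: float = 0.0007274
    collision_d_gap: float = 10.0
    collision_contact: int = 8
    collision_block_window: int = 8
    width: int = 220
    height: int = 140
    nest_area: int = 1020
    k_edge: float = 2.0
    band: int | None = None
    stop_count: int | None = None
    snapshot_interval: int = 1000
    seed: int = 0
    max_stalled_steps: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.group_size < 1:
            raise ConfigError(f"group_size must be >= 1, got {self.group_size}")
        if self.band is None:
            self.band = 5 if self.group_size >= 400 else 4
        if self.stop_count is None:
            if self.group_size not in DEFAULT_STOP_COUNTS:
                raise ConfigError(
                    "stop_count must be given explicitly for group sizes "
                    f"other than {sorted(DEFAULT_STOP_COUNTS)}")
            self.stop_count = DEFAULT_STOP_COUNTS[self.group_size]
        if self.stop_count < 1:
            raise ConfigError(f"stop_count must be >= 1, got {self.stop_count}")
        if self.crowd_increment is None:
            self.crowd_increment = self.q

    @property
    def active_count(self) -> int:
        """Workers building per step: round-half-up(alpha*N), at least 1."""
        return max(1, math.floor(self.alpha * self.group_size + 0.5))

    @property
    def choice_params(self) -> ChoiceParams:
        return ChoiceParams(
            x=self.x, b=self.b, edge_exit_v=self.edge_exit_v,
            collision_d_gap=self.collision_d_gap,
            collision_contact=self.collision_contact,
            collision_block_window=self.collision_block_window)

    def make_arena(self) -> Arena:
        return init_arena(self.width, self.height, self.nest_area,
                          self.group_size, k_edge=self.k_edge, band=self.band)

    def make_state(self) -> BuildState:
        return BuildState.from_arena(
            self.make_arena(), q=self.q, r=self.r,
            crowd_threshold=self.crowd_threshold,
            crowd_increment=self.crowd_increment)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Snapshot:
    constructed: int
    grid: np.ndarray
    morphometry: "morphometry.MorphometryResult"


@dataclass
class Trajectory:
    """Ordered snapshots plus final state and run metadata."""

    params: SimParams
    snapshots: list[Snapshot]
    final_grid: np.ndarray
    status: str
    n_steps: int
    seed_key: tuple[int, ...] = ()

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


def sample_build_site(state: BuildState, params: ChoiceParams,
                      rng: np.random.Generator) -> tuple[int, int] | None:
    """Draw one build site from the current choice distribution, or None.

    Uniform fallback when all attractions vanish; None when the crowding
    filter leaves no candidate (the worker skips this step).
    """
    rows, cols, attr, keep = evaluate_candidates(state, params)
    if keep.sum() == 0:
        return None
    rows, cols, attr = rows[keep], cols[keep], attr[keep]
    total = attr.sum()
    if total > 0.0:
        cum = np.cumsum(attr)
        i = int(np.searchsorted(cum, rng.random() * total, side="right"))
        i = min(i, attr.size - 1)
    else:
        i = int(rng.integers(attr.size))
    return int(rows[i]), int(cols[i])


def step(state: BuildState, params: SimParams, rng: np.random.Generator,
         on_build=None) -> int:
    """One time step: each active worker builds once; then fields update.

    Returns the number of cells built.  Stops mid-step once ``stop_count``
    is reached; end-of-step evaporation and crowd reset still run.
    """
    cp = params.choice_params
    built = 0
    for _ in range(params.active_count):
        if state.built_count >= params.stop_count:
            break
        cell = sample_build_site(state, cp, rng)
        if cell is None:
            continue
        build(state, cell, cp)
        built += 1
        if on_build is not None:
            on_build(state)
    state.pher.c *= state.pher.r
    state.crowd.reset()
    return built


def _snap(state: BuildState) -> Snapshot:
    grid = state.arena.state.copy()
    return Snapshot(constructed=state.built_count, grid=grid,
                    morphometry=morphometry.measure_grid(grid))


def run(params: SimParams, rng: np.random.Generator | None = None,
        seed_key: tuple[int, ...] = ()) -> Trajectory:
    """Run one simulation to its stop count; deterministic given the seed."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = params.make_state()
    snapshots: list[Snapshot] = []

    def on_build(s: BuildState) -> None:
        if (s.built_count % params.snapshot_interval == 0
                and s.built_count < params.stop_count):
            snapshots.append(_snap(s))

    n_steps = 0
    stalled = 0
    while state.built_count < params.stop_count:
        n_built = step(state, params, rng, on_build)
        n_steps += 1
        if n_built == 0:
            stalled += 1
            if stalled >= params.max_stalled_steps:
                snapshots.append(_snap(state))
                raise StallError(
                    f"no construction for {stalled} consecutive steps at "
                    f"{state.built_count}/{params.stop_count} cells",
                    Trajectory(params, snapshots, state.arena.state.copy(),
                               "stalled", n_steps, seed_key))
        else:
            stalled = 0
    snapshots.append(_snap(state))
    return Trajectory(params, snapshots, state.arena.state.copy(), "ok",
                      n_steps, seed_key)


def sweep(alpha_grid=None, x_grid=None, reps: int = 100,
          base: SimParams | None = None, keep_grids: bool = False,
          progress: bool = False) -> pd.DataFrame:
    """Cross alpha × x grids with ``reps`` replicates each; tidy results table.

    One row per run × snapshot (snapshots every 1000 built cells plus the
    final state).  Seeds derive from (base seed, alpha index, x index, rep)
    so any single run is reproducible in isolation.
    """
    alpha_grid = tuple(alpha_grid) if alpha_grid is not None else DEFAULT_ALPHA_GRID
    x_grid = tuple(x_grid) if x_grid is not None else DEFAULT_X_GRID
    if not alpha_grid or not x_grid:
        raise ConfigError("parameter grids must be nonempty")
    base = base if base is not None else SimParams()
    rows = []
    grids = {}
    for ai, alpha in enumerate(alpha_grid):
        for xi, x in enumerate(x_grid):
            for rep in range(reps):
                key = (base.seed, ai, xi, rep)
                rng = np.random.default_rng(np.random.SeedSequence(key))
                params = replace(base, alpha=alpha, x=x)
                traj = run(params, rng=rng, seed_key=key)
                if keep_grids:
                    grids[(alpha, x, rep)] = traj.final_grid
                for snap in traj.snapshots:
                    m = snap.morphometry
                    rows.append({
                        "alpha": alpha, "x": x, "rep": rep,
                        "group_size": params.group_size,
                        "seed_key": "-".join(map(str, key)),
                        "constructed": snap.constructed,
                        "is_final": snap.constructed == params.stop_count,
                        "area_mm2": m.area,
                        "perim_total": m.perimeter_total,
                        "perim_edge": m.perimeter_edge,
                        "perim_away": m.perimeter_away,
                    })
            if progress:
                print(f"sweep: alpha={alpha} x={x} done", flush=True)
    df = pd.DataFrame(rows)
    if keep_grids:
        df.attrs["grids"] = grids
    return df
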