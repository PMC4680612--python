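"""Cement-pheromone and crowdedness field dynamics.

Freshly placed material carries cement pheromone: each construction event adds
``q`` to the built cell, and at the end of every time step the whole field
decays by the evaporation rate ``r`` (each cell keeps a fraction ``1 - r``).
A vacant candidate cell reads the pheromone as the *maximum* over its built
8-neighbours, so tube tips with recent deposits dominate site choice — the
positive-feedback loop that turns mats into tubes.

Crowdedness accumulates on built cells in the same way as pheromone (one
increment per construction, default equal to ``q``) but is zeroed at the end
of every step, when workers return to the nest for material.  A candidate
whose built 8-neighbours average at or above the crowding threshold is
excluded from choice: the model's only worker–worker physical interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import BUILT, N8, Arena, ConfigError


@dataclass
class PheromoneField:
    """Per-cell cement pheromone. Meaningful only on BUILT cells."""

    q: float = 0.3
    r: float = 0.7
    c: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ConfigError(f"evaporation rate r must be in [0, 1], got {self.r}")
        if self.q < 0:
            raise ConfigError(f"deposit q must be nonnegative, got {self.q}")

    @classmethod
    def zeros(cls, arena: Arena, q: float = 0.3, r: float = 0.7) -> "PheromoneField":
        return cls(q=q, r=r, c=np.zeros(arena.shape))


@dataclass
class CrowdField:
    """Per-cell crowdedness; reset to zero at the end of every time step."""

    threshold: float = 0.9
    increment: float = 0.3
    w: np.ndarray | None = None

    @classmethod
    def zeros(cls, arena: Arena, threshold: float = 0.9,
              increment: float = 0.3) -> "CrowdField":
        return cls(threshold=threshold, increment=increment, w=np.zeros(arena.shape))

    def reset(self) -> None:
        self.w[...] = 0.0


def deposit(pher: PheromoneField, cell: tuple[int, int], arena: Arena,
            q: float | None = None) -> None:
    """Add ``q`` pheromone to a just-built cell (in place)."""
    r, c = cell
    if arena.state[r, c] != BUILT:
        raise ValueError(f"deposit on non-built cell {cell}")
    pher.c[r, c] += pher.q if q is None else q


def evaporate(pher: PheromoneField, r: float | None = None) -> None:
    """End-of-step evaporation: every cell keeps the fraction ``r``.

    ``r`` is the per-step retention factor (0.7 by default: 30% of the
    pheromone is lost each step).  Retention this high is what lets a tube
    tip keep its pheromone gradient from one step to the next; with most of
    the signal lost per step, localized tube growth cannot persist at low
    active-worker fractions.
    """
    rate = pher.r if r is None else r
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"retention factor must be in [0, 1], got {rate}")
    pher.c *= rate


def candidate_pheromone(pher: PheromoneField, cell: tuple[int, int],
                        arena: Arena) -> float:
    """Pheromone a vacant candidate perceives: max over BUILT 8-neighbours.

    Nest neighbours carry no pheromone; with no built neighbour the value is 0.
    """
    r, c = cell
    best = 0.0
    for dr, dc in N8:
        nr, nc = r + dr, c + dc
        if arena.in_bounds(nr, nc) and arena.state[nr, nc] == BUILT:
            best = max(best, pher.c[nr, nc])
    return best


def candidate_crowdedness(crowd: CrowdField, cell: tuple[int, int],
                          arena: Arena) -> float:
    """Crowdedness a candidate perceives: mean over BUILT 8-neighbours (0 if none)."""
    r, c = cell
    total, n = 0.0, 0
    for dr, dc in N8:
        nr, nc = r + dr, c + dc
        if arena.in_bounds(nr, nc) and arena.state[nr, nc] == BUILT:
            total += crowd.w[nr, nc]
            n += 1
    return total / n if n else 0.0
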