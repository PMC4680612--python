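"""Synthetic test patterns and group tables with known ground truth.

Generates the construction-pattern phenotypes the morphometry pipeline must
tell apart — central mats, radial shelter tubes, wall-hugging edging tubes and
intermediates — plus calibration shapes (square, disc, 1-px snake) whose area
and perimeter are known in closed form, and group-record tables with planted
colony effects for exercising the ANOVA path.  Everything is lattice-native
(no anti-aliasing) and deterministic given a seed, so morphometry checks can
be bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import nest_cells

KINDS = ("square", "disc", "snake", "mat", "radial_tubes", "edging_tubes",
         "intermediate")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic pattern on the 220×140 canvas."""

    kind: str = "mat"
    width: int = 220
    height: int = 140
    side: int = 10              # square
    radius: int = 25            # disc / mat
    length: int = 60            # snake
    n_tubes: int = 5            # radial_tubes
    tube_len: int = 40
    tube_width: int = 3
    band_width: int = 4         # edging_tubes
    nest_area: int = 1020
    n_debris: int = 0           # small (<50 px) noise blobs, for clean() tests
    n_holes: int = 0            # small (<10 px) holes punched into structure
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {KINDS}")


def _canvas(spec: FixtureSpec) -> np.ndarray:
    return np.zeros((spec.height, spec.width), dtype=bool)


def _center(spec: FixtureSpec) -> tuple[float, float]:
    return (spec.height - 1) / 2.0, (spec.width - 1) / 2.0


def _nest_disc(spec: FixtureSpec, white: np.ndarray) -> None:
    cells = nest_cells(spec.height, spec.width, spec.nest_area)
    white[cells[:, 0], cells[:, 1]] = True


def generate_pattern(spec: FixtureSpec) -> tuple[np.ndarray, dict]:
    """Build the pattern and its ground truth.

    Returns ``(white, truth)``; ``truth`` always holds ``area`` (exact cell
    count) and, for rectilinear shapes whose perimeter has a closed form
    (square, snake, full edging ring), the exact ``perimeter_total`` too.
    """
    white = _canvas(spec)
    truth: dict = {"kind": spec.kind}
    cy, cx = _center(spec)
    rng = np.random.default_rng(spec.seed)

    if spec.kind == "square":
        r0 = int(cy - spec.side // 2)
        c0 = int(cx - spec.side // 2)
        white[r0:r0 + spec.side, c0:c0 + spec.side] = True
        truth["perimeter_total"] = 4.0 * spec.side
        truth["perimeter_away"] = 4.0 * spec.side

    elif spec.kind in ("disc", "mat"):
        rr, cc = np.mgrid[0:spec.height, 0:spec.width]
        white |= np.hypot(rr - cy, cc - cx) <= spec.radius

    elif spec.kind == "snake":
        # boustrophedon 1-px path, rows two apart: a simple 4-connected path
        # of L cells with no non-consecutive contacts has perimeter 2L + 2
        run = min(40, spec.width - 20)
        path = [(10, 10)]
        r, c, dc = 10, 10, 1
        while len(path) < spec.length:
            at_end = (dc > 0 and c == 10 + run - 1) or (dc < 0 and c == 10)
            if at_end:  # two-cell downward connector keeps rows 2 apart
                path.append((r + 1, c))
                path.append((r + 2, c))
                r += 2
                dc = -dc
            else:
                c += dc
                path.append((r, c))
        for pr, pc in path[:spec.length]:
            white[pr, pc] = True
        truth["perimeter_total"] = 2.0 * int(white.sum()) + 2.0

    elif spec.kind == "radial_tubes":
        _nest_disc(spec, white)
        nominal_r = math.sqrt(spec.nest_area / math.pi)
        for i in range(spec.n_tubes):
            ang = 2.0 * math.pi * i / spec.n_tubes
            _draw_tube(white, cy, cx, ang, nominal_r, spec.tube_len,
                       spec.tube_width)

    elif spec.kind == "edging_tubes":
        b = spec.band_width
        white[:b, :] = True
        white[-b:, :] = True
        white[:, :b] = True
        white[:, -b:] = True
        truth["perimeter_total"] = 4.0 * (spec.width + spec.height) - 8.0 * b
        truth["perimeter_edge"] = truth["perimeter_total"] if b <= 3 else None
        if truth["perimeter_edge"] is None:
            del truth["perimeter_edge"]

    elif spec.kind == "intermediate":
        _nest_disc(spec, white)
        rr, cc = np.mgrid[0:spec.height, 0:spec.width]
        white |= np.hypot(rr - cy, cc - cx) <= spec.radius
        for i in range(spec.n_tubes):
            ang = 2.0 * math.pi * (i + 0.5) / spec.n_tubes
            _draw_tube(white, cy, cx, ang, spec.radius, spec.tube_len,
                       spec.tube_width)

    structure_area = int(white.sum())
    truth["area"] = float(structure_area)

    if spec.n_holes:
        truth["holes_punched"] = _punch_holes(white, rng, spec.n_holes)
        truth["area"] = float(white.sum())
    if spec.n_debris:
        truth["debris_added"] = _add_debris(white, rng, spec.n_debris)

    return white, truth


def _draw_tube(white: np.ndarray, cy: float, cx: float, angle: float,
               start_r: float, length: int, width: int) -> None:
    """Straight 4-connected tube of given width radiating from the nest rim."""
    h, w = white.shape
    dr, dc = math.sin(angle), math.cos(angle)
    half = width // 2
    for t in range(int(start_r) - 1, int(start_r) + length):
        r, c = int(round(cy + dr * t)), int(round(cx + dc * t))
        for o in range(-half, width - half):
            rr, cc = (r + o, c) if abs(dc) > abs(dr) else (r, c + o)
            if 0 <= rr < h and 0 <= cc < w:
                white[rr, cc] = True


def _punch_holes(white: np.ndarray, rng: np.random.Generator, n: int) -> int:
    """Punch n small (< 10 px) rectangular holes into the structure interior."""
    from scipy import ndimage

    interior = ndimage.binary_erosion(white, iterations=3)
    coords = np.argwhere(interior)
    punched = 0
    for _ in range(n * 10):
        if punched >= n or coords.size == 0:
            break
        r, c = coords[rng.integers(len(coords))]
        hh, ww = rng.choice([(1, 3), (3, 3), (2, 4), (3, 2)])
        if interior[r:r + hh, c:c + ww].all():
            white[r:r + hh, c:c + ww] = False
            punched += 1
    return punched


def _add_debris(white: np.ndarray, rng: np.random.Generator, n: int) -> int:
    """Scatter n small (< 50 px) blobs well away from the structure."""
    from scipy import ndimage

    h, w = white.shape
    forbidden = ndimage.binary_dilation(white, iterations=8)
    added = 0
    for _ in range(n * 20):
        if added >= n:
            break
        hh, ww = rng.choice([(2, 3), (3, 3), (4, 5), (6, 8), (7, 7)])
        r = int(rng.integers(0, h - hh))
        c = int(rng.integers(0, w - ww))
        if not forbidden[r:r + hh + 1, c:c + ww + 1].any():
            white[r:r + hh, c:c + ww] = True
            forbidden[max(0, r - 8):r + hh + 8, max(0, c - 8):c + ww + 8] = True
            added += 1
    return added


COLONIES = "ABCDEFGHIJ"


def generate_group_table(n_colonies: int = 5, reps: int = 5,
                         effect_size: float = 0.0, seed: int = 0,
                         group_size: int = 400, sigma: float = 150.0,
                         baseline: float = 1200.0,
                         n_low_survival: int = 0) -> pd.DataFrame:
    """Group-records table with planted colony effects on the perimeter measures.

    Colony means are shifted by ``effect_size`` (Cohen's d units of the
    within-colony s.d. ``sigma``) using centred, unit-s.d. offsets, so
    effect_size=0 is an exact null.  ``n_low_survival`` extra rows get
    survival ≤ 0.5 for testing the exclusion filter.
    """
    if n_colonies < 2:
        raise ValueError("need at least 2 colonies")
    rng = np.random.default_rng(seed)
    offsets = np.linspace(-1.0, 1.0, n_colonies)
    offsets = offsets / offsets.std()
    rows = []
    for i in range(n_colonies):
        mu = baseline + effect_size * sigma * offsets[i]
        for rep in range(reps):
            perim = rng.normal(mu, sigma)
            edge_frac = rng.uniform(0.3, 0.7)
            rows.append({
                "colony": COLONIES[i], "group_size": group_size,
                "replicate": rep,
                "survival_rate": float(rng.uniform(0.7, 1.0)),
                "area_mm2": float(rng.normal(5700.0 if group_size >= 400
                                             else 1370.0, 300.0)),
                "perim_total": float(perim),
                "perim_edge": float(perim * edge_frac),
                "perim_away": float(perim * (1.0 - edge_frac)),
            })
    df = pd.DataFrame(rows)
    if n_low_survival:
        extra = df.sample(n=min(n_low_survival, len(df)), random_state=seed,
                          replace=True).copy()
        extra["survival_rate"] = rng.uniform(0.0, 0.5, size=len(extra))
        extra["replicate"] = -1
        df = pd.concat([df, extra], ignore_index=True)
    return df
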