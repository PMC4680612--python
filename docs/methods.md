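# Methods

This note documents the model implemented in `tubecast`, the choices made
where the published description of this class of models leaves the mechanism
open, and what the synthetic data used by the test suite does and does not
establish.

## World and state

The arena is a rectangular lattice of square 1 mm cells, default 220×140
(the floor of the experimental container), indexed `(row, col)` from the
top-left with arrays shaped `(height, width)`.  Cells are EMPTY, NEST or
BUILT.  The nest is *defined by exact cell count*: the `nest_area` = 1020
cells whose centres are nearest the arena centre, ties broken by angle and
then index.  No centre-in-disc rasterisation reproduces both a nominal
radius of 18 and an area of 1020 simultaneously, so the count is primary and
the radius is kept as metadata; this makes the initial area exact and the
initialisation deterministic.  The nest never changes and supplies unlimited
material; workers are not tracked spatially — they exist only as a per-step
budget of construction choices, with crowdedness as the sole proxy for
physical interaction.

Connectivity conventions: structural adjacency (what counts as "adjacent to
the structure") and path distance use the 4-connected von Neumann
neighbourhood — tubes grow face-to-face.  Field perception (pheromone max,
crowdedness mean, direction memory) uses the 8-connected Moore
neighbourhood, so a candidate feels diagonal contact.

## Path distance

`d_i` is the length of the shortest route from the nest walking on
NEST ∪ BUILT cells: NEST cells are at 0 and each step costs one cell, so a
candidate adjacent to the nest has `d = 1`.  The engine stores each cell's
distance *at construction time* (`1 + min` over its constructed
4-neighbours) rather than recomputing globally.  The two agree while the
structure is a tree of tubes; after two tubes merge, the global recomputation
would erase the distance discontinuity at the junction — and that
discontinuity is exactly what the collision rule keys on, so the
construction-time value is the meaningful one.  `arena.distance_field` still
provides the from-scratch breadth-first field, and a test pins the agreement
on merge-free structures.

## Site choice

Each active worker chooses among vacant, unblocked cells 4-adjacent to the
structure with probability `P_i = A_i / Σ A_j`,
`A_i = v_i (c_i + k_i − b d_i)^x`:

* `k` (site preference): 2 within the wall band, 1 elsewhere.  The band is
  5 cells for 400-worker runs and 4 cells for 50-worker runs, matching the
  observed mean widths of edging tubes (4.86 and 4.28 mm).
* `b = 1/360`: with `k = 2` at the wall, `k − b·d` reaches 0 when
  `d = 720` — the full container perimeter — so a tube that has circled the
  container stops being attractive.
* the base `c + k − b·d` is clamped at 0 before exponentiation (negative
  bases would go complex at non-integer `x`; a repelled cell simply has no
  attraction).
* if every candidate has zero attraction the choice falls back to uniform
  rather than stalling the step.

Exponent `x ≥ 0` is the pheromone sensitivity.  At `x = 1` attraction is
nearly uniform (the base varies over ≈ [1, 3]) and growth is Eden-like and
compact; at `x = 3` the same variation is cubed and construction locks onto
the pheromone-marked tips.

## Pheromone and crowdedness accumulation

This is the one place the implementation had to commit to a mechanism beyond
the bare equations, and the choice is load-bearing, so it is spelled out.

A vacant cell's perceived pheromone is the **maximum** over its built
8-neighbours; perceived crowdedness is the **mean**.  When a cell is built it
**inherits the value it was perceived to have while vacant** and the deposit
`q = 0.3` (crowd increment likewise `q`) is added on top.  Under the
alternative, minimal reading — each built cell starts from zero and receives
only `+q` — both fields are bounded by `q` everywhere, which has two fatal
consequences: the maximum attraction advantage a hot tube tip can ever have
is `(1.3/1)^3 ≈ 2.2`, far too weak to localise growth among hundreds of
candidates, and the crowdedness exclusion can never fire (a mean of values
≤ 0.3 cannot reach the 0.9 threshold), leaving the model with no mechanism
for the active-worker fraction to matter.  With inheritance, pheromone
ratchets up along a growing tube (the tip always carries its tube's maximum)
and crowdedness climbs by ≈ `q` per same-step extension, so a tube saturates
after about `0.9/0.3 = 3` extensions per step — which is precisely how a
large active fraction ends up spreading construction over many sites.

Evaporation: at the end of every step the pheromone field is multiplied by
the retention factor `r = 0.7` (30 % lost per step).  Read the other way
(30 % *retained*), a tube tip cannot carry its advantage from one step to the
next at low build rates, and tube phenotypes then appear only at *high*
active fractions — inverting the model's signature result.  Retention 0.7
yields persistent tip gradients and the expected phenotype map.  Crowdedness
is instead reset to zero at each step's end: workers return to the nest for
material between steps.

## Direction memory

Every built cell carries the coordinates of its tube's beginning point — set
to the cell itself when it touches the nest ring or the container wall, and
otherwise inherited from its built neighbours (the centroid when neighbours
carry distinct origins, i.e. at tube junctions, so the beginning point can be
half-integer).  For a candidate reached via a built neighbour,
`v = (1 + cos θ)/2` with θ the angle between (origin → via) and
(via → candidate): 1 for continuing straight away from the origin, 0 for
doubling back.  Contributions from all built 8-neighbours are summed.  Two
special cases: a candidate whose only neighbours are nest cells gets `v = 1`
(construction must be able to start), and a via cell that *is* its own origin
uses the nest-centre → via direction as its reference (first step of a new
tube still prefers outward growth).  A move from the wall band into the
interior is scored with the small empirical constant 0.0007274 instead of the
cosine — established edging tubes essentially never peel off the wall.

## Collisions and crowding

Adjacent built cells whose construction-time distances differ by ≥ 10 are
taken to belong to different tubes and are marked contact cells.  (The
opposite inequality — labelling *small* differences as different tubes —
would end construction at every tube's own elbow; the rule exists to stop
construction where independent tubes meet.)  When the 8×8 window centred on
the last-built cell contains ≥ 8 contact cells, the window is blocked
permanently: no cell in it can be chosen again.  The window is centred rather
than cornered on the last build; with an even width this means 3 cells
before and 4 after in each axis.

Candidates whose built neighbours average crowdedness ≥ 0.9 are removed from
the choice set before sampling (no within-step retry is needed — the filter
acts on the set, not on the worker).

## Time stepping and replication

Workers act **sequentially within a step**, each seeing all earlier deposits
and crowd increments of the same step; strict synchrony would let every
worker choose the same cell and would make crowdedness meaningless.  Workers
are interchangeable (they carry no state), so the required random ordering
is realised simply as `round(α·N)` successive draws.  The active count
rounds half-up with a floor of one (α·N is fractional for N = 50 at α = 0.05,
0.15, 0.25).  A run stops mid-step exactly at the terminal count: 5700 cells
for 400 workers, 1350 for 50 — the mean areas built in 30 days by the two
group sizes.  Snapshots (grid plus morphometry) are taken every 1000 built
cells and at the end.

A worker with no admissible candidate skips; a run with 100 consecutive
build-free steps aborts with a `StallError` carrying the partial trajectory.
Sweep seeds derive from `SeedSequence((base_seed, alpha_index, x_index,
rep))`, so any single run is reproducible in isolation; a given seed yields
bit-identical trajectories.

## Morphometry

Area is the white-pixel count (1 px = 1 mm²).  Perimeter is the exact count
of unit edges between white pixels and black pixels or the image border —
lattice-native, identical for simulated grids and rasterised photographs, and
bit-reproducible, which is why no smoothed (e.g. Crofton) estimator is used.
Each edge belongs to its white pixel; edges of pixels strictly within 3 px of
the border count as "along the wall".  For simulation grids NEST ∪ BUILT is
white (the sawdust block is part of the photographed structure) and no
cleaning is applied.  Photograph cleaning removes white 8-connected objects
under 50 px and fills 4-connected holes under 10 px (object/hole connectivity
duality is the standard choice); hole boundaries that survive cleaning
(≥ 10 px) remain part of the perimeter.  Binarisation uses Otsu's threshold
by default (with scikit-image's strictly-greater foreground convention) or a
user-supplied threshold (at-or-above).

## Statistics

Containers with survival ≤ 0.5 are excluded (heavy mortality diverts
material into burying corpses).  Differences among colonies are tested with
ordinary fixed-effects one-way ANOVA — `F = MS_between/MS_within`,
p from the upper F tail — per group size and per measure (perimeter total,
area, perimeter along the wall, perimeter away), with no Welch correction and
no multiple-testing adjustment, matching the analysis this pipeline mirrors.
The ANOVA is delegated to `scipy.stats.f_oneway`; tests cross-check it
against direct sums-of-squares formulas.  The spreadsheet reader matches
column names defensively against synonym lists because the external
workbook's exact layout is not guaranteed.

## Synthetic data

`fixtures` generates the phenotype classes programmatically: central mats,
radial tubes, wall-band edging rings, intermediates, plus calibration shapes
whose morphometry is known in closed form (interior square: perimeter `4s`;
a simple 1-px path of `L` cells: `2L + 2`; full edging ring of width `w`:
`4(W + H) − 8w`).  Group tables plant colony effects of chosen Cohen's d with
normal within-colony noise and an exact null at `d = 0`.  These fixtures are
lattice-native and noise-free by design, so morphometry checks are bit-exact;
they do *not* emulate photographic artefacts (uneven lighting, perspective,
colour), so passing tests validate the measurement definitions, not
photograph acquisition.

## Problem sizes used in the checks

The statistical phenotype check replicates the four corner parameter sets
{α = 0.05, 0.25} × {x = 1, 3} at N = 400 with 30 runs each, at a reduced
terminal count of 2000 built cells — the mat/tube contrast is already fully
expressed there, and the comparison (Mann–Whitney, one-sided, α = 0.05)
is insensitive to the exact scale.  The choice-rule oracle check enumerates
the exact distribution on a 10×10 world and compares 10⁵ sampled draws by
χ² at α = 0.01.  ANOVA calibration uses 10⁴ null simulations.

## Known limitations

* Strictly two-dimensional; no galleries dug inside the nest block, no 3-D
  tube structure, no undertaking/burial behaviour.
* No pheromone diffusion — the field lives on built cells only.
* The inheritance/retention semantics above, while the only readings we
  found that make the crowding rule functional and the phenotype map come
  out right, are a reconstruction; the alternative readings are noted here
  deliberately.
* The collision interface is counted within the blocking window around the
  last-built cell; interfaces wider than 8 cells that accumulate entirely
  outside any single window would trigger slightly late.
* Agents are memoryless between steps; real workers presumably are not.
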