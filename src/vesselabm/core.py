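"""Lattice agent-based model of the vessel-wall cross-section.

The cross-section is a 100x100 site lattice. The wall is initialized as an
annulus (lumen radius 20, outer radius 26 lattice units; one unit is
76.75 um, so the lumen radius is 1.535 mm and the wall is 460.5 um thick)
populated with VSMC and ECM agents in random spatial pattern, one agent
per site. Each tick is one hour. Agents age every tick; a VSMC whose age
is a multiple of its 12 h cycle may divide or (exclusively) undergo
apoptosis, an ECM agent whose age is a multiple of its 4 h cycle may
trigger matrix generation or degradation. Event probabilities come from
the agent's damage index and its sector's biochemical modifiers
(:mod:`vesselabm.biochem`).

New tissue displaces the wall: while the plaque burden is below 40% the
wall grows outward at constant lumen (positive remodeling); at or above
40% it grows inward, narrowing the lumen (negative remodeling). Daughter
agents are placed by pushing the least-displacement chain of cells into
the nearest admissible empty site (exterior when growing outward, lumen
when inward); removal compacts the wall from its outer boundary so the
lumen never re-expands. For a locally thin wall the push reduces to a
radial single-site shift.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .biochem import (
    ConversionParams,
    ETParams,
    MMP9Params,
    NOParams,
    ProbabilityParams,
    et_rate,
    factor_probability,
    mmp9_rate,
    no_rate,
    sector_content,
)
from .damage import DamageParams, attenuate_radial, damage_index
from .hemodynamics import WSSProfile, sample_wss

__all__ = [
    "VSMC",
    "ECM",
    "EMPTY",
    "GeometrySpec",
    "ClockSpec",
    "RemodelingState",
    "Agent",
    "Grid",
    "StepParams",
    "PlacementOverflowError",
    "init_geometry",
    "assign_damage",
    "eligible",
    "attempt_event",
    "plaque_burden",
    "growth_direction",
    "place_daughter",
    "remove_agent",
    "biochem_modifier_fields",
    "step",
]

EMPTY, VSMC, ECM = 0, 1, 2

_EVENTS_BY_KIND = {
    VSMC: ("division", "apoptosis"),
    ECM: ("generation", "degradation"),
}

# 4-neighbourhood, fixed order for deterministic breadth-first search
_NEIGH = ((1, 0), (-1, 0), (0, 1), (0, -1))


class PlacementOverflowError(RuntimeError):
    """Raised when a daughter cannot be placed (wall reached the grid edge)."""


@dataclass(frozen=True)
class GeometrySpec:
    """Lattice geometry of the cross-section.

    ``unit_length`` is um per lattice unit; the defaults give a 1.535 mm
    lumen radius and a 460.5 um thick wall.
    """

    grid_size: int = 100
    center: tuple = (50.0, 50.0)
    lumen_radius: float = 20.0
    outer_radius: float = 26.0
    unit_length: float = 76.75

    def __post_init__(self) -> None:
        if not 0 < self.lumen_radius < self.outer_radius < self.grid_size / 2:
            raise ValueError(
                "require 0 < lumen_radius < outer_radius < grid_size/2"
            )
        if self.unit_length <= 0:
            raise ValueError("unit_length must be strictly positive")


@dataclass(frozen=True)
class ClockSpec:
    """Simulation clock: 1 h ticks, agent cycle lengths, run length."""

    dt: int = 1
    vsmc_cycle: int = 12
    ecm_cycle: int = 4
    total_ticks: int = 800

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.total_ticks < 0:
            raise ValueError("dt must be positive and total_ticks non-negative")
        for name in ("vsmc_cycle", "ecm_cycle"):
            cyc = getattr(self, name)
            if cyc <= 0 or cyc % self.dt != 0:
                raise ValueError(f"{name} must be a positive multiple of dt")

    def cycle_of(self, kind: int) -> int:
        return self.vsmc_cycle if kind == VSMC else self.ecm_cycle


@dataclass
class RemodelingState:
    """Positive/negative remodeling switch at a plaque-burden threshold."""

    burden_threshold: float = 0.40


@dataclass(frozen=True)
class Agent:
    """One lattice occupant (view object; the grid stores arrays)."""

    kind: int
    age: int
    damage: float
    site: tuple

    def __post_init__(self) -> None:
        if self.kind not in (VSMC, ECM):
            raise ValueError("kind must be VSMC or ECM")
        if not 0 <= self.damage <= 1:
            raise ValueError("damage must lie in [0, 1]")


class Grid:
    """Occupancy lattice with per-site agent state and area bookkeeping.

    Arrays indexed ``[x, y]``: ``kind`` (0 empty, 1 VSMC, 2 ECM), ``age``
    (hours), ``damage`` (in [0, 1]), ``ids`` (unique agent id, -1 when
    empty). ``lumen_mask`` flags the empty sites belonging to the lumen;
    it can only shrink. ``pos`` maps agent ids to their current site so
    agents can be followed through displacement.
    """

    def __init__(self, spec: GeometrySpec):
        n = spec.grid_size
        self.spec = spec
        self.kind = np.zeros((n, n), dtype=np.int8)
        self.age = np.zeros((n, n), dtype=np.int64)
        self.damage = np.zeros((n, n), dtype=np.float64)
        self.ids = np.full((n, n), -1, dtype=np.int64)
        self.pos: dict[int, tuple] = {}
        self._next_id = 0
        cx, cy = spec.center
        xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        self.radius = np.hypot(xs - cx, ys - cy)
        self.angle = np.degrees(np.arctan2(ys - cy, xs - cx)) % 360.0
        self.lumen_mask = self.radius < spec.lumen_radius
        self.lumen_area = int(self.lumen_mask.sum())
        self.baseline_wall_area = 0

    # -- bookkeeping helpers -------------------------------------------------

    @property
    def occupied(self) -> np.ndarray:
        return self.kind != EMPTY

    @property
    def wall_area(self) -> int:
        return len(self.pos)

    @property
    def n_vsmc(self) -> int:
        return int(np.count_nonzero(self.kind == VSMC))

    @property
    def n_ecm(self) -> int:
        return int(np.count_nonzero(self.kind == ECM))

    def add_agent(self, site, kind: int, age: int, dmg: float) -> int:
        x, y = site
        if self.kind[x, y] != EMPTY:
            raise ValueError(f"site {site} already occupied")
        aid = self._next_id
        self._next_id += 1
        self.kind[x, y] = kind
        self.age[x, y] = age
        self.damage[x, y] = dmg
        self.ids[x, y] = aid
        self.pos[aid] = (x, y)
        if self.lumen_mask[x, y]:
            self.lumen_mask[x, y] = False
            self.lumen_area -= 1
        return aid

    def move_agent(self, src, dst) -> None:
        sx, sy = src
        dx, dy = dst
        if self.kind[dx, dy] != EMPTY:
            raise ValueError(f"destination {dst} occupied")
        aid = int(self.ids[sx, sy])
        self.kind[dx, dy] = self.kind[sx, sy]
        self.age[dx, dy] = self.age[sx, sy]
        self.damage[dx, dy] = self.damage[sx, sy]
        self.ids[dx, dy] = aid
        self.kind[sx, sy] = EMPTY
        self.age[sx, sy] = 0
        self.damage[sx, sy] = 0.0
        self.ids[sx, sy] = -1
        self.pos[aid] = (dx, dy)
        if self.lumen_mask[dx, dy]:
            self.lumen_mask[dx, dy] = False
            self.lumen_area -= 1

    def delete_agent(self, site) -> None:
        x, y = site
        aid = int(self.ids[x, y])
        if aid < 0:
            raise ValueError(f"no agent at {site}")
        self.kind[x, y] = EMPTY
        self.age[x, y] = 0
        self.damage[x, y] = 0.0
        self.ids[x, y] = -1
        del self.pos[aid]

    def agent_at(self, site) -> Agent:
        x, y = site
        if self.kind[x, y] == EMPTY:
            raise ValueError(f"no agent at {site}")
        return Agent(
            kind=int(self.kind[x, y]),
            age=int(self.age[x, y]),
            damage=float(self.damage[x, y]),
            site=(x, y),
        )

    def layer_of(self, site) -> int:
        """Wall layer index: 0 at the innermost (initial) layer."""
        x, y = site
        return max(int(np.floor(self.radius[x, y] - self.spec.lumen_radius)), 0)


# -- initialization ----------------------------------------------------------


def init_geometry(
    spec: GeometrySpec,
    clocks: ClockSpec = ClockSpec(),
    vsmc_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> Grid:
    """Populate the annulus with randomly patterned, randomly aged agents.

    Every site whose centre distance r from the lattice centre satisfies
    ``lumen_radius <= r < outer_radius`` receives one agent; each is VSMC
    with probability ``vsmc_fraction`` (else ECM) and starts at an integer
    age drawn uniformly on [0, cycle) for its kind.
    """
    if rng is None:
        rng = np.random.default_rng()
    grid = Grid(spec)
    ring = (grid.radius >= spec.lumen_radius) & (grid.radius < spec.outer_radius)
    sites = np.argwhere(ring)  # lexicographic site order: deterministic
    kinds = np.where(rng.random(len(sites)) < vsmc_fraction, VSMC, ECM)
    ages_v = rng.integers(0, clocks.vsmc_cycle, size=len(sites))
    ages_e = rng.integers(0, clocks.ecm_cycle, size=len(sites))
    ages = np.where(kinds == VSMC, ages_v, ages_e)
    for (x, y), kind, age in zip(sites, kinds, ages):
        grid.add_agent((int(x), int(y)), int(kind), int(age), 0.0)
    grid.baseline_wall_area = grid.wall_area
    return grid


def assign_damage(
    grid: Grid, profile: WSSProfile, dparams: DamageParams = DamageParams()
) -> Grid:
    """Hemodynamic initialization: damage field from the WSS profile.

    Innermost-layer agents take ``damage_index`` of the WSS sampled at
    their angle; every other agent takes the damage of the angularly
    nearest innermost agent attenuated by its own layer index.
    """
    occ = np.argwhere(grid.occupied)
    layers = np.maximum(
        np.floor(grid.radius[occ[:, 0], occ[:, 1]] - grid.spec.lumen_radius), 0
    ).astype(int)
    angles = grid.angle[occ[:, 0], occ[:, 1]]
    inner = layers == 0
    inner_angles = angles[inner]
    inner_d = damage_index(sample_wss(profile, inner_angles), dparams)
    order = np.argsort(inner_angles)
    sorted_ang = inner_angles[order]
    sorted_d = np.atleast_1d(inner_d)[order]
    # nearest innermost agent by circular angular distance
    idx = np.searchsorted(sorted_ang, angles)
    cand = np.stack([(idx - 1) % len(sorted_ang), idx % len(sorted_ang)])
    dist = np.abs((sorted_ang[cand] - angles + 180.0) % 360.0 - 180.0)
    nearest = cand[np.argmin(dist, axis=0), np.arange(len(angles))]
    d = attenuate_radial(sorted_d[nearest], layers, dparams)
    grid.damage[occ[:, 0], occ[:, 1]] = d
    return grid


# -- elementary operations ---------------------------------------------------


def eligible(agent: Agent, event: str, clocks: ClockSpec = ClockSpec()) -> bool:
    """True iff the agent's age is a positive multiple of its event cycle."""
    if event not in _EVENTS_BY_KIND[agent.kind]:
        raise ValueError(
            f"event {event!r} does not apply to kind {agent.kind}"
        )
    cycle = clocks.cycle_of(agent.kind)
    return agent.age >= 1 and agent.age % cycle == 0


def attempt_event(p: float, rng: np.random.Generator) -> bool:
    """Bernoulli draw: one uniform variate compared against ``p``."""
    if not 0 <= p <= 1:
        raise ValueError("p must be a probability in [0, 1]")
    return rng.random() < p


def plaque_burden(grid: Grid) -> float:
    """Added wall area over total cross-section area.

    ``PB = (A_wall - A_wall(0)) / (A_wall + A_lumen)``, areas in sites;
    0 at initialization, and monotone in wall growth at fixed lumen.
    """
    total = grid.wall_area + grid.lumen_area
    return (grid.wall_area - grid.baseline_wall_area) / total


def growth_direction(pb: float, state: RemodelingState = RemodelingState()) -> str:
    """``"outward"`` below the burden threshold, ``"inward"`` at or above.

    ``pb`` may be slightly negative when early deaths shrink the wall
    below its baseline area; that still counts as below threshold.
    """
    if not pb < 1:
        raise ValueError("plaque burden must be < 1")
    return "outward" if pb < state.burden_threshold else "inward"


def _admissible_empty(grid: Grid, x: int, y: int, direction: str) -> bool:
    if grid.kind[x, y] != EMPTY:
        return False
    is_lumen = bool(grid.lumen_mask[x, y])
    return is_lumen if direction == "inward" else not is_lumen


def _bfs_to_empty(grid: Grid, start, admissible) -> list | None:
    """Shortest 4-connected path through occupied sites from ``start`` to a
    site adjacent to an admissible empty; returns [start, ..., frontier,
    empty] or None. Ties resolved by fixed neighbour order (first found)."""
    n = grid.spec.grid_size
    sx, sy = start
    prev = {(sx, sy): None}
    q = deque([(sx, sy)])
    while q:
        x, y = q.popleft()
        for ox, oy in _NEIGH:
            nx, ny = x + ox, y + oy
            if not (0 <= nx < n and 0 <= ny < n):
                continue
            if admissible(grid, nx, ny):
                path = [(nx, ny), (x, y)]
                node = prev[(x, y)]
                while node is not None:
                    path.append(node)
                    node = prev[node]
                path.reverse()
                return path
            if grid.kind[nx, ny] != EMPTY and (nx, ny) not in prev:
                prev[(nx, ny)] = (x, y)
                q.append((nx, ny))
    return None


def place_daughter(
    grid: Grid,
    mother_site,
    direction: str,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Insert a daughter agent next to its mother, displacing the wall.

    The chain of cells on the shortest path from the mother to the nearest
    admissible empty site (exterior when ``direction == "outward"``, lumen
    when ``"inward"``) shifts one step into that site; the daughter (age 1,
    damage inherited from the mother) occupies the vacated site adjacent
    to the mother. Exactly one agent per site holds afterwards; inward
    placement shrinks the lumen by exactly one site.

    Returns the daughter's site.
    """
    mx, my = mother_site
    if grid.kind[mx, my] == EMPTY:
        raise ValueError(f"mother site {mother_site} is empty")
    path = _bfs_to_empty(
        grid, (mx, my), lambda g, x, y: _admissible_empty(g, x, y, direction)
    )
    if path is None and direction == "inward":
        # total occlusion: no lumen left to grow into; spill outward
        path = _bfs_to_empty(
            grid, (mx, my), lambda g, x, y: _admissible_empty(g, x, y, "outward")
        )
    if path is None:
        raise PlacementOverflowError(
            f"no admissible empty site reachable from {mother_site} "
            f"({direction}); the wall has filled the grid"
        )
    # path = [mother, p1, ..., pk, empty]; shift pk -> empty, ..., p1 -> p2
    for src, dst in zip(path[-2:0:-1], path[:0:-1]):
        grid.move_agent(src, dst)
    daughter_site = path[1]
    grid.add_agent(daughter_site, int(grid.kind[mx, my]), 1, float(grid.damage[mx, my]))
    return daughter_site


def _is_simple_point(grid: Grid, c) -> bool:
    """True iff vacating ``c`` keeps the occupied set locally 4-connected.

    Local (3x3) sufficient test: every occupied 4-neighbour of ``c`` must
    lie in one 4-connected component of the occupied 8-neighbourhood with
    ``c`` excluded. Conservative: may reject a globally safe cell, never
    accepts an unsafe one.
    """
    x, y = c
    n = grid.spec.grid_size
    occ = [
        (x + ox, y + oy)
        for ox in (-1, 0, 1)
        for oy in (-1, 0, 1)
        if (ox, oy) != (0, 0)
        and 0 <= x + ox < n
        and 0 <= y + oy < n
        and grid.kind[x + ox, y + oy] != EMPTY
    ]
    four = [p for p in occ if abs(p[0] - x) + abs(p[1] - y) == 1]
    if not four:
        return False  # isolated cell: vacating it would drop a component
    comp = {p: i for i, p in enumerate(occ)}

    def find(i):
        while comp_list[i] != i:
            comp_list[i] = comp_list[comp_list[i]]
            i = comp_list[i]
        return i

    comp_list = list(range(len(occ)))
    for i, p in enumerate(occ):
        for j, q in enumerate(occ):
            if j > i and abs(p[0] - q[0]) + abs(p[1] - q[1]) == 1:
                comp_list[find(i)] = find(j)
    roots = {find(comp[p]) for p in four}
    return len(roots) == 1


def remove_agent(grid: Grid, site, direction: str = "outward") -> bool:
    """Remove the agent at ``site`` and compact the wall onto the vacancy.

    The net geometric effect is the vacating of one outer-boundary cell:
    the chain of cells on the shortest occupied path from ``site`` to the
    nearest safely removable boundary cell (adjacent to an exterior empty
    site, and whose deletion keeps the wall locally 4-connected) shifts
    one step toward the vacancy. The wall therefore always retracts from
    its outer boundary, never fragments, and the lumen never re-expands,
    in both remodeling phases. ``direction`` is accepted for interface
    symmetry with :func:`place_daughter` but does not change the
    compaction side.

    Returns True when an agent was removed; False (and no change) in the
    degenerate case where no boundary cell can be vacated safely.
    """
    x, y = site
    if grid.kind[x, y] == EMPTY:
        raise ValueError(f"no agent at {site}")
    n = grid.spec.grid_size

    def boundary(cx, cy):
        return any(
            0 <= cx + ox < n
            and 0 <= cy + oy < n
            and _admissible_empty(grid, cx + ox, cy + oy, "outward")
            for ox, oy in _NEIGH
        )

    # breadth-first over occupied cells from `site` for the nearest cell
    # that is on the outer boundary and safe to vacate
    prev = {(x, y): None}
    queue = deque([(x, y)])
    target = None
    while queue:
        cur = queue.popleft()
        if boundary(*cur) and _is_simple_point(grid, cur):
            target = cur
            break
        cx, cy = cur
        for ox, oy in _NEIGH:
            nxt = (cx + ox, cy + oy)
            if (
                0 <= nxt[0] < n
                and 0 <= nxt[1] < n
                and grid.kind[nxt] != EMPTY
                and nxt not in prev
            ):
                prev[nxt] = cur
                queue.append(nxt)
    if target is None:
        return False
    path = [target]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    path.reverse()  # [site, ..., target]
    grid.delete_agent((x, y))
    for dst, src in zip(path[:-1], path[1:]):
        grid.move_agent(src, dst)
    return True


# -- per-tick scheduling -----------------------------------------------------


@dataclass
class StepParams:
    """Everything :func:`step` needs besides the grid and the RNG.

    ``p_et``, ``p_no``, ``p_mmp9`` are per-site biochemical probability
    modifiers (static fields precomputed from the WSS profile with
    :func:`biochem_modifier_fields`); ``decay`` is the per-tick damage
    recovery factor ``exp(-lambda)``.
    """

    clocks: ClockSpec
    probabilities: ProbabilityParams
    state: RemodelingState
    p_et: np.ndarray
    p_no: np.ndarray
    p_mmp9: np.ndarray
    decay: float


def biochem_modifier_fields(
    grid: Grid,
    profile: WSSProfile,
    et: ETParams = ETParams(),
    no: NOParams = NOParams(),
    mmp9: MMP9Params = MMP9Params(),
    conversion: ConversionParams = ConversionParams(),
    n_ec: float = 1.0,
    dt: float = 1.0,
) -> tuple:
    """Per-site (p_ET, p_NO, p_MMP9) modifier fields from the WSS profile.

    Each site's angular sector hosts ``n_ec`` virtual endothelial cells
    whose per-tick factor production converts to a probability modifier.
    The fields are static because the WSS profile is fixed over a run.
    """
    tau = sample_wss(profile, grid.angle.ravel()).reshape(grid.angle.shape)
    fields = []
    for rate_fn, par in ((et_rate, et), (no_rate, no), (mmp9_rate, mmp9)):
        content = sector_content(rate_fn(tau, par), n_ec, dt)
        fields.append(factor_probability(content, conversion))
    return tuple(fields)


def step(
    grid: Grid, t: int, params: StepParams, rng: np.random.Generator
) -> dict:
    """Advance the model by one one-hour tick; returns per-tick statistics.

    Order of operations: all agents age by one hour; cycle-eligible agents
    are visited in a random order; each draws its creation event first
    (division or generation) and, only if that fails, its destruction
    event (apoptosis or degradation) — at most one event per agent per
    tick. Creation resets the mother's age to 1 and places an age-1
    daughter carrying the mother's damage. After all events, every agent's
    damage decays by the recovery factor.

    RNG consumption contract (relied on by the event-tally oracle): one
    ``shuffle`` of the id-sorted eligible list per tick, then per eligible
    agent one uniform for the creation draw and, if it failed, one uniform
    for the destruction draw; each applied creation consumes one extra
    uniform inside placement only when there are path ties (none here:
    tie-breaks are deterministic).
    """
    occ = grid.occupied
    grid.age[occ] += 1
    kinds = grid.kind
    ages = grid.age
    elig = occ & (
        ((kinds == VSMC) & (ages % params.clocks.vsmc_cycle == 0))
        | ((kinds == ECM) & (ages % params.clocks.ecm_cycle == 0))
    )
    elig_ids = np.sort(grid.ids[elig])
    rng.shuffle(elig_ids)
    pr = params.probabilities
    births = deaths = 0
    for aid in elig_ids:
        x, y = grid.pos[int(aid)]
        d = grid.damage[x, y]
        if grid.kind[x, y] == VSMC:
            if d > 0:
                p_create = min(
                    max(pr.alpha_div * d + params.p_et[x, y] - params.p_no[x, y], 0.0),
                    1.0,
                )
            else:
                p_create = 0.0
            p_destroy = pr.alpha_apop * d
        else:
            p_create = pr.alpha_gen * d
            if d > 0:
                p_destroy = min(pr.alpha_deg * d + params.p_mmp9[x, y], 1.0)
            else:
                p_destroy = 0.0
        if attempt_event(p_create, rng):
            direction = growth_direction(plaque_burden(grid), params.state)
            place_daughter(grid, (x, y), direction, rng)
            grid.age[x, y] = 1
            births += 1
        elif attempt_event(p_destroy, rng):
            direction = growth_direction(plaque_burden(grid), params.state)
            if remove_agent(grid, (x, y), direction):
                deaths += 1
    occ = grid.occupied
    grid.damage[occ] *= params.decay
    n_vsmc, n_ecm = grid.n_vsmc, grid.n_ecm
    return {
        "tick": t,
        "n_vsmc": n_vsmc,
        "n_ecm": n_ecm,
        "ratio": n_vsmc / n_ecm if n_ecm else np.nan,
        "plaque_burden": plaque_burden(grid),
        "lumen_area": grid.lumen_area,
        "wall_area": grid.wall_area,
        "mean_damage": float(grid.damage[occ].mean()) if grid.wall_area else 0.0,
        "births": births,
        "deaths": deaths,
    }
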