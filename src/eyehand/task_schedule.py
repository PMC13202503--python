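"""Radial target layout and balanced episode schedule for the stamping task.

The task presents virtual sheets of paper one at a time on a table, at 21
locations arranged as a radial fan (7 angular sectors x 3 rings, neighbor
spacing 140 mm by default).  A session consists of three rounds; in each
round every location is visited exactly once.  The schedule is randomized
under hard constraints: consecutive papers within a round are never at
adjacent locations, the acting hand is balanced so that every location gets
exactly two right-hand interactions per session (21/12/9 per round), and the
sheet colors (33 violet / 30 orange) are balanced within and between the
left- and right-hand sides of the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

__all__ = [
    "LayoutSpec",
    "Location",
    "Layout",
    "Episode",
    "SessionSchedule",
    "ScheduleError",
    "generate_layout",
    "leftmost_sector_ids",
    "generate_schedule",
    "validate_schedule",
]

VIOLET = "violet"
ORANGE = "orange"
LEFT = "left"
RIGHT = "right"

#: right-hand episode count per round (round 1 is right-hand only)
RIGHT_HAND_PER_ROUND = (21, 12, 9)


class ScheduleError(RuntimeError):
    """Raised when the constraint set cannot be satisfied."""


@dataclass(frozen=True)
class LayoutSpec:
    """Geometry of the 21-location radial layout, in the table frame.

    The table frame has its origin at the table center, +x toward the seated
    user's right, +y away from the user, +z up.  The fan of paper locations
    is centered on the user's mid-sagittal plane and radiates from
    ``fan_origin`` (near the user edge of the table).
    """

    n_sectors: int = 7
    n_rings: int = 3
    spacing: float = 0.140          # m, neighbor spacing within/between rings
    inner_radius: float = 0.35      # m, radius of the innermost ring
    fan_origin: Tuple[float, float, float] = (0.0, -0.40, 0.0)
    ink_pad_positions: Tuple[Tuple[float, float, float], ...] = (
        (-0.10, -0.22, 0.0),        # violet pad
        (0.10, -0.22, 0.0),         # orange pad
    )
    ink_pad_radius: float = 0.06    # m
    paper_size: Tuple[float, float] = (0.148, 0.210)  # A5, width x height, m
    table_extent: Tuple[float, float] = (1.2, 0.8)    # width x depth, m

    def validate(self) -> None:
        if self.n_sectors < 3 or self.n_sectors % 2 == 0:
            raise ValueError(
                "n_sectors must be odd and >= 3 for mirror symmetry, got "
                f"{self.n_sectors}"
            )
        if self.n_rings < 1:
            raise ValueError(f"n_rings must be >= 1, got {self.n_rings}")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if self.inner_radius <= self.spacing / 2:
            raise ValueError("inner_radius too small for the given spacing")
        if len(self.ink_pad_positions) != 2:
            raise ValueError("exactly two ink pads are required")


@dataclass(frozen=True)
class Location:
    sector: int        # 1..n_sectors, 1 = leftmost
    ring: int          # 1..n_rings, 1 = innermost
    position: Tuple[float, float, float]


@dataclass
class Layout:
    """Realized layout: positions, index-space adjacency and mirror pairing."""

    spec: LayoutSpec
    locations: Dict[str, Location]
    adjacency: Dict[str, Set[str]]
    mirror: Dict[str, Optional[str]]

    def position(self, location_id: str) -> np.ndarray:
        return np.asarray(self.locations[location_id].position, dtype=float)

    def sector(self, location_id: str) -> int:
        return self.locations[location_id].sector

    def side_of(self, location_id: str, k_sectors: int = 2) -> str:
        """Lateral class of a location: left (sector <= k), right (mirror
        sectors), or center."""
        sec = self.sector(location_id)
        if sec <= k_sectors:
            return "left"
        if sec > self.spec.n_sectors - k_sectors:
            return "right"
        return "center"


def location_id(sector: int, ring: int) -> str:
    return f"s{sector}r{ring}"


def generate_layout(spec: LayoutSpec = LayoutSpec()) -> Layout:
    """Build the radial layout from its spec.

    Ring radii increase by ``spacing``; within each ring the sector angle is
    chosen so that the chord between angular neighbors equals ``spacing``
    exactly.  Sector 1 is the leftmost; the middle sector lies on the user's
    mid-sagittal plane (x = 0).  Mirror pairs map sector i to
    n_sectors + 1 - i at the same ring; middle-sector locations have no
    mirror.
    """
    spec.validate()
    ox, oy, oz = spec.fan_origin
    center = (spec.n_sectors + 1) / 2.0
    locations: Dict[str, Location] = {}
    for ring in range(1, spec.n_rings + 1):
        radius = spec.inner_radius + (ring - 1) * spec.spacing
        dtheta = 2.0 * np.arcsin(spec.spacing / (2.0 * radius))
        for sector in range(1, spec.n_sectors + 1):
            # yaw-sense angle: positive toward +x (user's right)
            theta = (sector - center) * dtheta
            pos = (
                ox + radius * np.sin(theta),
                oy + radius * np.cos(theta),
                oz,
            )
            locations[location_id(sector, ring)] = Location(sector, ring, pos)

    adjacency: Dict[str, Set[str]] = {lid: set() for lid in locations}
    for lid, loc in locations.items():
        for other_id, other in locations.items():
            if other_id == lid:
                continue
            if abs(other.sector - loc.sector) <= 1 and abs(other.ring - loc.ring) <= 1:
                adjacency[lid].add(other_id)

    mirror: Dict[str, Optional[str]] = {}
    mid = int(center)
    for lid, loc in locations.items():
        if loc.sector == mid:
            mirror[lid] = None
        else:
            mirror[lid] = location_id(spec.n_sectors + 1 - loc.sector, loc.ring)

    return Layout(spec=spec, locations=locations, adjacency=adjacency, mirror=mirror)


def leftmost_sector_ids(layout: Layout, k: int) -> Set[str]:
    """Location ids within the k leftmost sectors (each has a right mirror)."""
    n_sectors = layout.spec.n_sectors
    if not 1 <= k <= n_sectors // 2:
        raise ValueError(f"k must be in [1, {n_sectors // 2}], got {k}")
    return {lid for lid, loc in layout.locations.items() if loc.sector <= k}


@dataclass(frozen=True)
class Episode:
    round: int                 # 1..3
    location_id: str
    color: str                 # violet | orange
    hand: str                  # left | right
    post_stamp_delay: float    # s, uniform in [1, 3]


@dataclass
class SessionSchedule:
    episodes: List[Episode]
    seed: int
    timeout: float = 10.0

    def __len__(self) -> int:
        return len(self.episodes)


def _constrained_order(
    ids: List[str], adjacency: Dict[str, Set[str]], rng: np.random.Generator
) -> Optional[List[str]]:
    """Random order of ids with no two consecutive adjacent locations.

    Randomized backtracking; returns None on a dead end (caller restarts).
    """
    order: List[str] = []
    remaining = list(ids)

    def extend() -> bool:
        if not remaining:
            return True
        candidates = [
            lid
            for lid in remaining
            if not order or lid not in adjacency[order[-1]]
        ]
        idx = rng.permutation(len(candidates))
        for i in idx:
            lid = candidates[i]
            order.append(lid)
            remaining.remove(lid)
            if extend():
                return True
            order.pop()
            remaining.append(lid)
        return False

    return order if extend() else None


def generate_schedule(
    layout: Layout,
    seed: int,
    timeout: float = 10.0,
    max_restarts: int = 1000,
) -> SessionSchedule:
    """Generate a fully balanced, constraint-satisfying 63-episode schedule.

    Deterministic for identical (layout, seed).  Raises :class:`ScheduleError`
    if the constraints cannot be met within ``max_restarts`` (never silently
    relaxes a constraint).
    """
    rng = np.random.default_rng(seed)
    ids = sorted(layout.locations)
    n = len(ids)

    orders: List[List[str]] = []
    for _ in range(3):
        for _attempt in range(max_restarts):
            order = _constrained_order(ids, layout.adjacency, rng)
            if order is not None:
                orders.append(order)
                break
        else:
            raise ScheduleError(
                "could not find a non-adjacent location order "
                f"after {max_restarts} restarts"
            )

    # Hands: round 1 all right; each location gets its second right-hand
    # interaction in round 2 (12 locations) or round 3 (9 locations).
    round2_right = set(rng.choice(ids, size=RIGHT_HAND_PER_ROUND[1], replace=False))
    hand_by_round: List[Dict[str, str]] = [
        {lid: RIGHT for lid in ids},
        {lid: (RIGHT if lid in round2_right else LEFT) for lid in ids},
        {lid: (LEFT if lid in round2_right else RIGHT) for lid in ids},
    ]

    # Colors: balance within and between table sides.  With 7x3 locations the
    # left sectors (1-3) and right sectors (5-7) each host 27 episodes and the
    # middle sector 9; violet/orange per group: 14/13, 14/13 and 5/4, giving
    # the 33/30 session totals.
    mid = (layout.spec.n_sectors + 1) // 2
    groups = {
        "left": [lid for lid in ids if layout.sector(lid) < mid],
        "right": [lid for lid in ids if layout.sector(lid) > mid],
        "center": [lid for lid in ids if layout.sector(lid) == mid],
    }
    episode_slots: Dict[str, List[Tuple[int, str]]] = {g: [] for g in groups}
    for rnd in range(3):
        for g, g_ids in groups.items():
            episode_slots[g].extend((rnd, lid) for lid in g_ids)
    n_violet = {"left": 14, "right": 14, "center": 5}
    color_of: Dict[Tuple[int, str], str] = {}
    for g, slots in episode_slots.items():
        k = n_violet[g]
        perm = rng.permutation(len(slots))
        for j, p in enumerate(perm):
            color_of[slots[p]] = VIOLET if j < k else ORANGE

    delays = rng.uniform(1.0, 3.0, size=3 * n)

    episodes: List[Episode] = []
    for rnd in range(3):
        for lid in orders[rnd]:
            episodes.append(
                Episode(
                    round=rnd + 1,
                    location_id=lid,
                    color=color_of[(rnd, lid)],
                    hand=hand_by_round[rnd][lid],
                    post_stamp_delay=float(delays[len(episodes)]),
                )
            )

    schedule = SessionSchedule(episodes=episodes, seed=seed, timeout=timeout)
    validate_schedule(schedule, layout)
    return schedule


def validate_schedule(schedule: SessionSchedule, layout: Layout) -> None:
    """Brute-force check of every schedule invariant; raises on violation."""
    eps = schedule.episodes
    n_loc = len(layout.locations)
    if len(eps) != 3 * n_loc:
        raise ScheduleError(f"expected {3 * n_loc} episodes, got {len(eps)}")

    for rnd in (1, 2, 3):
        round_eps = [e for e in eps if e.round == rnd]
        visited = [e.location_id for e in round_eps]
        if sorted(visited) != sorted(layout.locations):
            raise ScheduleError(f"round {rnd} does not visit each location once")
        for a, b in zip(visited, visited[1:]):
            if b in layout.adjacency[a]:
                raise ScheduleError(
                    f"round {rnd}: consecutive adjacent locations {a} -> {b}"
                )
        n_right = sum(1 for e in round_eps if e.hand == RIGHT)
        if n_right != RIGHT_HAND_PER_ROUND[rnd - 1]:
            raise ScheduleError(
                f"round {rnd}: {n_right} right-hand episodes, expected "
                f"{RIGHT_HAND_PER_ROUND[rnd - 1]}"
            )

    per_location_right: Dict[str, int] = {}
    for e in eps:
        if e.hand == RIGHT:
            per_location_right[e.location_id] = (
                per_location_right.get(e.location_id, 0) + 1
            )
    if any(per_location_right.get(lid, 0) != 2 for lid in layout.locations):
        raise ScheduleError("each location must get exactly 2 right-hand episodes")

    n_violet = sum(1 for e in eps if e.color == VIOLET)
    n_orange = sum(1 for e in eps if e.color == ORANGE)
    if (n_violet, n_orange) != (33, 30):
        raise ScheduleError(f"color totals {n_violet}/{n_orange}, expected 33/30")

    mid = (layout.spec.n_sectors + 1) // 2
    side_counts = {"left": [0, 0], "right": [0, 0]}
    for e in eps:
        sec = layout.sector(e.location_id)
        side = "left" if sec < mid else ("right" if sec > mid else None)
        if side is not None:
            side_counts[side][0 if e.color == VIOLET else 1] += 1
    lv, lo = side_counts["left"]
    rv, ro = side_counts["right"]
    if abs(lv - rv) > 1 or abs(lo - ro) > 1 or abs(lv - lo) > 1 or abs(rv - ro) > 1:
        raise ScheduleError(
            f"color balance violated: left {lv}/{lo} violet/orange, right {rv}/{ro}"
        )

    for e in eps:
        if not 1.0 <= e.post_stamp_delay <= 3.0:
            raise ScheduleError(f"post-stamp delay {e.post_stamp_delay} outside [1, 3]")
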