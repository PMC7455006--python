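"""Continuous 2D toroidal space: Brownian steps and neighbour queries.

Agents live on a periodic (toroidal) rectangle so that density-dependent
dynamics see no edges. Diffusion follows a cheap Brownian scheme: each step
displaces an agent by ``sqrt(6 * dt * D * p)`` (p uniform on [0, 1]) along a
uniformly random direction, which reproduces the correct mean-squared
displacement per step (3 * dt * D) and, over many steps, a Gaussian
displacement by the central limit theorem.

The :class:`SpatialIndex` here is the module-level reference implementation
(dict-of-buckets uniform grid); the simulation engine uses an equivalent
array-based grid in its jitted kernels, which the test-suite checks against
the brute-force all-pairs scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Tuple

import numpy as np

Position = Tuple[float, float]


def wrap(pos: Position, size_x: float, size_y: float) -> Position:
    """Reduce coordinates modulo the area dimensions into [0, size)."""
    x = pos[0] % size_x
    y = pos[1] % size_y
    # guard against float fold-back onto the upper bound
    if x >= size_x:
        x -= size_x
    if y >= size_y:
        y -= size_y
    return (x, y)


def toroidal_distance(
    p: Position, q: Position, size_x: float, size_y: float
) -> float:
    """Shortest Euclidean distance on the torus."""
    dx = abs(p[0] - q[0])
    if dx > 0.5 * size_x:
        dx = size_x - dx
    dy = abs(p[1] - q[1])
    if dy > 0.5 * size_y:
        dy = size_y - dy
    return math.hypot(dx, dy)


def diffusion_step(
    pos: Position,
    D: float,
    dt: float,
    rng: np.random.Generator,
    size_x: float,
    size_y: float,
) -> Position:
    """One Brownian displacement, wrapped onto the torus.

    Displacement magnitude is ``sqrt(6 * dt * D * p)`` with p ~ U[0, 1] and
    direction uniform on the circle; per-step displacement is therefore
    bounded by ``sqrt(6 * dt * D)`` and has mean square 3 * dt * D.
    """
    if D < 0:
        raise ValueError("diffusion constant must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if D == 0:
        return pos
    p = rng.random()
    theta = 2.0 * math.pi * rng.random()
    r = math.sqrt(6.0 * dt * D * p)
    return wrap((pos[0] + r * math.cos(theta), pos[1] + r * math.sin(theta)),
                size_x, size_y)


@dataclass
class SpatialIndex:
    """Uniform-grid index over a toroidal rectangle.

    The cell size is at least ``min_cell`` (normally the interaction
    radius), so any query at radius <= cell size inspects at most the 3x3
    block of cells around the query point.
    """

    size_x: float
    size_y: float
    min_cell: float
    _ncx: int = field(init=False)
    _ncy: int = field(init=False)
    _buckets: Dict[Tuple[int, int], List[Hashable]] = field(
        init=False, default_factory=dict
    )
    _where: Dict[Hashable, Tuple[Position, Tuple[int, int]]] = field(
        init=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.min_cell <= 0:
            raise ValueError("cell size must be positive")
        self._ncx = max(1, int(self.size_x / self.min_cell))
        self._ncy = max(1, int(self.size_y / self.min_cell))

    def _cell(self, pos: Position) -> Tuple[int, int]:
        cx = min(int(pos[0] / (self.size_x / self._ncx)), self._ncx - 1)
        cy = min(int(pos[1] / (self.size_y / self._ncy)), self._ncy - 1)
        return (cx, cy)

    def __len__(self) -> int:
        return len(self._where)

    def __contains__(self, agent_id: Hashable) -> bool:
        return agent_id in self._where

    def insert(self, agent_id: Hashable, pos: Position) -> None:
        if agent_id in self._where:
            raise KeyError(f"agent {agent_id!r} already indexed")
        cell = self._cell(pos)
        self._buckets.setdefault(cell, []).append(agent_id)
        self._where[agent_id] = (pos, cell)

    def remove(self, agent_id: Hashable) -> None:
        pos, cell = self._where.pop(agent_id)
        self._buckets[cell].remove(agent_id)
        if not self._buckets[cell]:
            del self._buckets[cell]

    def move(self, agent_id: Hashable, pos: Position) -> None:
        self.remove(agent_id)
        self.insert(agent_id, pos)

    def position(self, agent_id: Hashable) -> Position:
        return self._where[agent_id][0]

    def neighbors_within(
        self, agent_id: Hashable, radius: float
    ) -> List[Hashable]:
        """All other agents at toroidal distance strictly below *radius*.

        Order is unspecified; callers that need a random order shuffle the
        result themselves. The query agent is excluded.
        """
        if agent_id not in self._where:
            raise KeyError(f"agent {agent_id!r} is not indexed")
        if radius > self.size_x / self._ncx + 1e-12 or radius > (
            self.size_y / self._ncy + 1e-12
        ):
            raise ValueError("query radius exceeds the grid cell size")
        pos, (cx, cy) = self._where[agent_id]
        out: List[Hashable] = []
        seen_cells = set()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                cell = ((cx + dx) % self._ncx, (cy + dy) % self._ncy)
                if cell in seen_cells:
                    continue
                seen_cells.add(cell)
                for other in self._buckets.get(cell, ()):  # noqa: B905
                    if other == agent_id:
                        continue
                    d = toroidal_distance(
                        pos, self._where[other][0], self.size_x, self.size_y
                    )
                    if d < radius:
                        out.append(other)
        return out
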