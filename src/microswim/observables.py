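"""State descriptions sensed by agents.

An observable condenses the full system state into the limited view a
micro-agent plausibly has: a temporal change in a sensed chemical
concentration (an agent without direction sensing), neighbors within a
finite radius, or its own (normalized) position.  Observables never mutate
the colloid list; any history they keep (previous field values) is updated
explicitly per call and slice-indexed by colloid id.
"""

from __future__ import annotations

import numpy as np

from .engine import Colloid, ConcentrationField, field_value

__all__ = [
    "Observable",
    "ConcentrationChange",
    "NeighborSensing",
    "PositionObservable",
    "MultiSensing",
]


class Observable:
    """Base class: fixed output dimension, one vector per subject colloid."""

    dimension: int = 0

    def compute_observable(
        self, colloids: list[Colloid], all_colloids: list[Colloid] | None = None
    ) -> list[np.ndarray]:
        raise NotImplementedError

    def reset(self) -> None:
        """Clear any per-episode history."""


class ConcentrationChange(Observable):
    """Change in sensed concentration between the current and previous slice.

    Output: the 1-vector ``[scale * (c(x_t) - c(x_{t-1}))]``.  On the first
    call for a given colloid the previous value is initialized to the current
    one, so the first observable is exactly 0 (no spurious signal).
    """

    dimension = 1

    def __init__(self, fld: ConcentrationField, scale: float = 1.0) -> None:
        self.field = fld
        self.scale = scale
        self._prev: dict[int, float] = {}

    def compute_observable(self, colloids, all_colloids=None):
        out = []
        for c in colloids:
            cur = float(field_value(self.field, c.pos))
            prev = self._prev.get(c.id, cur)
            self._prev[c.id] = cur
            out.append(np.array([self.scale * (cur - prev)]))
        return out

    def reset(self) -> None:
        self._prev.clear()


class NeighborSensing(Observable):
    """Neighbors within a finite sensing radius.

    Output per colloid: ``[count, mean_rel_x, ..., mean_rel_d]`` where the
    mean relative position is over neighbors inside the radius (zeros when
    none), normalized by the radius.  Dimension is 1 + d.
    """

    def __init__(self, radius: float, dimension_space: int = 2) -> None:
        if radius <= 0:
            raise ValueError("sensing radius must be positive")
        self.radius = radius
        self.dimension = 1 + dimension_space

    def compute_observable(self, colloids, all_colloids=None):
        env = all_colloids if all_colloids is not None else colloids
        out = []
        for c in colloids:
            rels = [
                o.pos - c.pos
                for o in env
                if o.id != c.id and np.linalg.norm(o.pos - c.pos) <= self.radius
            ]
            if rels:
                mean_rel = np.mean(rels, axis=0) / self.radius
                out.append(np.concatenate([[float(len(rels))], mean_rel]))
            else:
                out.append(np.zeros(self.dimension))
        return out


class PositionObservable(Observable):
    """Own position normalized by the box length (dimension d)."""

    def __init__(self, box: np.ndarray) -> None:
        self.box = np.asarray(box, dtype=float)
        self.dimension = len(self.box)

    def compute_observable(self, colloids, all_colloids=None):
        return [c.pos / self.box for c in colloids]


class MultiSensing(Observable):
    """Concatenation of several observables in declaration order."""

    def __init__(self, observables: list[Observable]) -> None:
        if not observables:
            raise ValueError("MultiSensing requires at least one observable")
        self.observables = list(observables)
        self.dimension = sum(o.dimension for o in observables)

    def compute_observable(self, colloids, all_colloids=None):
        parts = [o.compute_observable(colloids, all_colloids) for o in self.observables]
        return [np.concatenate([p[i] for p in parts]) for i in range(len(colloids))]

    def reset(self) -> None:
        for o in self.observables:
            o.reset()
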