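"""Tasks: per-particle rewards and the kill-switch contract.

A task measures how well the system is doing — large positive rewards mean
the task is being achieved.  Each task also owns a *kill switch*: a latched
boolean that, once True, tells the running engine to stop at the end of the
current slice so the trainer can reset or finish.
"""

from __future__ import annotations

import numpy as np

from .engine import Colloid, ConcentrationField, field_value

__all__ = [
    "Task",
    "GradientClimbing",
    "RodRotation",
    "ConstantTask",
    "TimeLimitTask",
    "Multitasking",
]


class Task:
    """Base class.  ``__call__`` returns one reward per subject colloid."""

    def __init__(self) -> None:
        self._kill = False

    @property
    def kill_switch(self) -> bool:
        return self._kill

    def __call__(
        self, colloids: list[Colloid], all_colloids: list[Colloid] | None = None
    ) -> np.ndarray:
        """One reward per subject colloid.

        ``colloids`` are the controlled subjects; ``all_colloids`` (optional)
        is the full system for tasks that track other objects.
        """
        raise NotImplementedError

    def reset(self) -> None:
        self._kill = False


class GradientClimbing(Task):
    """Chemotaxis reward: positive concentration gain per slice.

    reward_i = scale * max(0, c(x_i, t) − c(x_i, t−1)) with the negative
    branch clipped to 0 by default (positive reinforcement only, as in
    bacterial run-and-tumble chemotaxis); set ``clip_negative=False`` for the
    signed gain.  The first slice yields 0 (history initialized to current).

    A ``threshold`` on the mean sensed concentration latches the kill switch
    once reached.
    """

    def __init__(
        self,
        fld: ConcentrationField,
        scale: float = 1.0,
        clip_negative: bool = True,
        threshold: float | None = None,
    ) -> None:
        super().__init__()
        self.field = fld
        self.scale = scale
        self.clip_negative = clip_negative
        self.threshold = threshold
        self._prev: dict[int, float] = {}

    def __call__(self, colloids, all_colloids=None):
        rewards = np.zeros(len(colloids))
        vals = []
        for i, c in enumerate(colloids):
            cur = float(field_value(self.field, c.pos))
            vals.append(cur)
            prev = self._prev.get(c.id, cur)
            self._prev[c.id] = cur
            gain = cur - prev
            if self.clip_negative:
                gain = max(0.0, gain)
            rewards[i] = self.scale * gain
        if self.threshold is not None and vals and np.mean(vals) >= self.threshold:
            self._kill = True
        return rewards

    def reset(self) -> None:
        super().reset()
        self._prev.clear()


class RodRotation(Task):
    """Reward the signed angular velocity of a rigid rod about its center.

    The rod orientation is measured from the tracked beads (first-to-last
    bead vector); the per-slice reward for every subject colloid is
    ``scale * sense * Δangle / slice_dt`` with the angle difference taken on
    the nearest branch (−π, π].  ``sense=+1`` rewards counterclockwise
    rotation.  First slice yields 0.
    """

    def __init__(
        self,
        rod_type: int,
        scale: float = 1.0,
        sense: int = 1,
        slice_dt: float = 1.0,
    ) -> None:
        super().__init__()
        self.rod_type = rod_type
        self.scale = scale
        self.sense = sense
        self.slice_dt = slice_dt
        self._prev_angle: float | None = None

    @staticmethod
    def _rod_angle(beads: list[Colloid]) -> float:
        beads = sorted(beads, key=lambda c: c.id)
        vec = beads[-1].pos - beads[0].pos
        return float(np.arctan2(vec[1], vec[0]))

    def __call__(self, colloids, all_colloids=None):
        env = all_colloids if all_colloids is not None else colloids
        beads = [c for c in env if c.type == self.rod_type]
        if not beads:
            raise ValueError("no rod beads of the configured type in the system")
        subjects = [c for c in colloids if c.type != self.rod_type]
        angle = self._rod_angle(beads)
        if self._prev_angle is None:
            omega = 0.0
        else:
            dphi = angle - self._prev_angle
            dphi = (dphi + np.pi) % (2.0 * np.pi) - np.pi
            omega = dphi / self.slice_dt
        self._prev_angle = angle
        return np.full(len(subjects), self.scale * self.sense * omega)

    def reset(self) -> None:
        super().reset()
        self._prev_angle = None


class ConstantTask(Task):
    """Fixed reward for every subject; handy for composition and testing."""

    def __init__(self, value: float = 0.0) -> None:
        super().__init__()
        self.value = value

    def __call__(self, colloids, all_colloids=None):
        return np.full(len(colloids), self.value)


class TimeLimitTask(Task):
    """Zero reward; latches the kill switch after ``limit`` calls (slices)."""

    def __init__(self, limit: int) -> None:
        super().__init__()
        if limit < 1:
            raise ValueError("limit must be >= 1")
        self.limit = limit
        self._calls = 0

    def __call__(self, colloids, all_colloids=None):
        self._calls += 1
        if self._calls >= self.limit:
            self._kill = True
        return np.zeros(len(colloids))

    def reset(self) -> None:
        super().reset()
        self._calls = 0


class Multitasking(Task):
    """Elementwise sum of several tasks; kill switch is the OR of the parts.

    Latching is monotone: once any part has fired, the composite stays True.
    """

    def __init__(self, tasks: list[Task]) -> None:
        super().__init__()
        if not tasks:
            raise ValueError("Multitasking requires at least one task")
        self.tasks = list(tasks)

    def __call__(self, colloids, all_colloids=None):
        total = None
        for t in self.tasks:
            r = np.asarray(t(colloids, all_colloids), dtype=float)
            total = r if total is None else total + r
        return total

    @property
    def kill_switch(self) -> bool:
        self._kill = self._kill or any(t.kill_switch for t in self.tasks)
        return self._kill

    def reset(self) -> None:
        super().reset()
        for t in self.tasks:
            t.reset()
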