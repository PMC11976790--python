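"""Control primitives: the Action dataclass and ordered ActionSets.

An Action is what an agent can physically do to a particle: apply a
propulsion force of a given magnitude along its director, apply a steering
torque, or directly override the swimming direction (a sometimes simpler
stand-in for an explicit torque computation).  An ActionSet is an ordered
name -> Action mapping; its order defines the categorical indexing used by
discrete policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = ["Action", "ActionSet", "default_action_set"]


@dataclass(eq=False)  # identity equality: numpy fields are not '==' comparable
class Action:
    """A single control primitive.

    Parameters
    ----------
    force : float
        Propulsion force magnitude (>= 0) applied along the director.
    torque : array-like, shape (3,)
        Steering torque; in 2D only the z (out-of-plane) component acts.
        Positive z torque rotates the director counterclockwise.
    new_direction : array-like or None
        Optional unit vector; when set it overrides the torque update and
        assigns the director directly.
    """

    force: float = 0.0
    torque: np.ndarray = field(default_factory=lambda: np.zeros(3))
    new_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.force < 0:
            raise ValueError("force magnitude must be non-negative")
        self.torque = np.asarray(self.torque, dtype=float)
        if self.torque.shape != (3,):
            raise ValueError("torque must be a length-3 vector")
        if self.new_direction is not None:
            nd = np.asarray(self.new_direction, dtype=float)
            nrm = np.linalg.norm(nd)
            if abs(nrm - 1.0) > 1e-9:
                raise ValueError("new_direction must be a unit vector")
            self.new_direction = nd


class ActionSet:
    """Ordered mapping of action names to Actions.

    The insertion order is frozen and defines the index of each action in
    the policy's categorical output distribution.
    """

    def __init__(self, actions: Mapping[str, Action]) -> None:
        if not actions:
            raise ValueError("ActionSet must not be empty")
        self._names = list(actions.keys())
        self._actions = [actions[n] for n in self._names]

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self) -> Iterator[str]:
        return iter(self._names)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def by_index(self, i: int) -> Action:
        return self._actions[i]

    def by_name(self, name: str) -> Action:
        return self._actions[self._names.index(name)]

    def index_of(self, name: str) -> int:
        return self._names.index(name)

    def index_of_action(self, action: Action) -> int:
        return self._actions.index(action)


def default_action_set(force: float = 10.0, torque: float = 10.0) -> ActionSet:
    """The four-action swimming repertoire: translate, rotate either way, rest.

    ``rotate_counterclockwise`` carries +torque about z (director turns left),
    ``rotate_clockwise`` −torque.
    """
    return ActionSet(
        {
            "translate": Action(force=force),
            "rotate_clockwise": Action(torque=np.array([0.0, 0.0, -torque])),
            "rotate_counterclockwise": Action(torque=np.array([0.0, 0.0, torque])),
            "do_nothing": Action(),
        }
    )
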