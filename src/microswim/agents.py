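"""Agents and the force function: the narrow engine/control interface.

An agent controls one particle type.  Trainable agents sense the world
through an :class:`~microswim.observables.Observable`, run their
actor-critic network, sample a discrete action, and are rewarded by a
:class:`~microswim.tasks.Task`.  Classical agents apply a deterministic
rule.  The :class:`ForceFunction` routes each particle group to its
controlling agent and is the *only* channel through which control code sees
the environment: the engine calls ``calc_action(colloids)`` once per slice
and receives one Action per colloid.

Reward timing follows the s_t, a_t -> s_{t+1}, r_{t+1} convention: the task
reward computed at slice t+1 is attributed to the action chosen at slice t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .actions import Action, ActionSet
from .engine import Colloid, ConcentrationField, field_gradient
from .networks import ActorCriticNet, PolicyOutput, log_softmax, softmax
from .observables import Observable
from .rl import PROB_FLOOR
from .tasks import Task

__all__ = [
    "sample_action",
    "EpisodeBuffer",
    "Agent",
    "ActorCriticAgent",
    "ClassicalAgent",
    "SteerToGradient",
    "ForceFunction",
]


# ---------------------------------------------------------------------------
# action sampling
# ---------------------------------------------------------------------------


def sample_action(
    probs: np.ndarray, rng: np.random.Generator, strategy: str = "categorical"
) -> int:
    """Draw an action index i with probability probs[i].

    ``categorical`` uses the inverse-CDF transform; ``gumbel`` uses the
    Gumbel-max trick argmax_i(log p_i + g_i), g_i ~ Gumbel(0, 1).  The two
    are distribution-equivalent.
    """
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ValueError("invalid probability vector")
    if strategy == "categorical":
        cdf = np.cumsum(p) / p.sum()
        return int(np.searchsorted(cdf, rng.random(), side="right"))
    if strategy == "gumbel":
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        g = -np.log(-np.log(rng.random(p.shape)))
        return int(np.argmax(logp + g))
    raise ValueError(f"unknown sampling strategy {strategy!r}")


# ---------------------------------------------------------------------------
# episode buffer
# ---------------------------------------------------------------------------


@dataclass
class EpisodeBuffer:
    """Per-group time series collected during one episode.

    Each entry is one slice; arrays inside have one row per particle of the
    group.  ``rewards`` lags by one slice (reward r_{t+1} closes step t) and
    is completed by :meth:`ForceFunction.finalize`.
    """

    observables: list = field(default_factory=list)
    action_indices: list = field(default_factory=list)
    log_probs: list = field(default_factory=list)
    values: list = field(default_factory=list)
    rewards: list = field(default_factory=list)
    task_rewards: list = field(default_factory=list)
    intrinsic_rewards: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.action_indices)

    @property
    def complete(self) -> bool:
        return len(self.rewards) == len(self.action_indices)

    def arrays(self) -> dict[str, np.ndarray]:
        """Stack to (T, n_particles[, dim]) arrays; requires completeness."""
        if len(self) == 0:
            raise ValueError("empty episode buffer")
        if not self.complete:
            raise ValueError("episode buffer missing final rewards; call finalize")
        return {
            "observables": np.asarray(self.observables, dtype=float),
            "action_indices": np.asarray(self.action_indices, dtype=int),
            "log_probs": np.asarray(self.log_probs, dtype=float),
            "values": np.asarray(self.values, dtype=float),
            "rewards": np.asarray(self.rewards, dtype=float),
        }

    def clear(self) -> None:
        for lst in (
            self.observables,
            self.action_indices,
            self.log_probs,
            self.values,
            self.rewards,
            self.task_rewards,
            self.intrinsic_rewards,
        ):
            lst.clear()


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------


class Agent:
    """Base agent: controls all colloids of ``particle_type``."""

    particle_type: int
    trainable: bool = False
    task: Task | None = None

    def calc_action_group(
        self, mine: list[Colloid], all_colloids: list[Colloid]
    ) -> list[Action]:
        raise NotImplementedError

    def reset_episode(self, seed: int | None = None) -> None:
        """Clear per-episode history; reseed the sampling streams."""

    def finalize(self, all_colloids: list[Colloid]) -> None:
        """Close the episode (attribute the final reward)."""

    @property
    def kill_switch(self) -> bool:
        return bool(self.task is not None and self.task.kill_switch)


class ActorCriticAgent(Agent):
    """Trainable agent: observable -> policy network -> sampled action.

    Parameters
    ----------
    particle_type
        The particle group this agent controls.
    action_set
        Ordered discrete action repertoire.
    observable, task
        Sensing and reward modules.
    network
        :class:`ActorCriticNet`; ``params`` may be given or initialized from
        ``init_seed``.
    sampling
        ``"categorical"`` or ``"gumbel"``.
    exploration
        Optional :class:`~microswim.exploration.RandomExploration`.
    intrinsic_reward
        Optional RND module; its novelty (times ``intrinsic_weight``) is
        added to the task reward for reaching each new state.
    """

    trainable = True

    def __init__(
        self,
        particle_type: int,
        action_set: ActionSet,
        observable: Observable,
        task: Task,
        network: ActorCriticNet | None = None,
        params: dict | None = None,
        sampling: str = "categorical",
        exploration=None,
        intrinsic_reward=None,
        intrinsic_weight: float = 0.1,
        init_seed: int = 0,
        hidden: tuple[int, ...] = (128, 128),
        architecture: str = "shared",
    ) -> None:
        self.particle_type = particle_type
        self.action_set = action_set
        self.observable = observable
        self.task = task
        if network is None:
            network = ActorCriticNet(
                observable.dimension, len(action_set), hidden=hidden, architecture=architecture
            )
        self.network = network
        if params is None:
            params = network.init_params(np.random.Generator(np.random.PCG64(init_seed)))
        self.params = params
        self.sampling = sampling
        self.exploration = exploration
        self.intrinsic_reward = intrinsic_reward
        self.intrinsic_weight = intrinsic_weight
        self.buffer = EpisodeBuffer()
        self.training = True
        self.greedy = False
        self.rng = np.random.Generator(np.random.PCG64(0))
        self._steps = 0

    # -- episode lifecycle ----------------------------------------------------

    def reset_episode(self, seed: int | None = None) -> None:
        self.buffer.clear()
        self.observable.reset()
        self.task.reset()
        self._steps = 0
        if seed is not None:
            self.rng = np.random.Generator(np.random.PCG64(seed))
        if self.exploration is not None:
            self.exploration.reset()

    def policy(self, obs_vector: np.ndarray) -> PolicyOutput:
        return self.network.policy_output(self.params, obs_vector)

    # -- per-slice control ----------------------------------------------------

    def _slice_reward(self, mine: list[Colloid], all_colloids: list[Colloid]) -> None:
        """Attribute the reward observed now to the previous action."""
        task_r = np.asarray(self.task(mine, all_colloids), dtype=float)
        if self._steps == 0:
            return
        intrinsic = np.zeros_like(task_r)
        if self.intrinsic_reward is not None:
            obs = np.asarray(
                self.observable.compute_observable(mine, all_colloids), dtype=float
            )
            intrinsic = self.intrinsic_weight * np.asarray(
                self.intrinsic_reward.novelty(obs), dtype=float
            )
            self.intrinsic_reward.update(obs)
        self.buffer.task_rewards.append(task_r)
        self.buffer.intrinsic_rewards.append(intrinsic)
        self.buffer.rewards.append(task_r + intrinsic)

    def calc_action_group(self, mine, all_colloids):
        self._slice_reward(mine, all_colloids)
        if self.task.kill_switch:
            return [Action() for _ in mine]
        obs = np.asarray(self.observable.compute_observable(mine, all_colloids), dtype=float)
        logits, values, _ = self.network.forward(self.params, obs)
        probs = softmax(logits)
        logp = log_softmax(logits)
        n = len(mine)
        idx = np.empty(n, dtype=int)
        for i in range(n):
            if self.greedy:
                idx[i] = int(np.argmax(probs[i]))
            else:
                idx[i] = sample_action(probs[i], self.rng, self.sampling)
        if self.exploration is not None and not self.greedy:
            idx = self.exploration.apply(idx, self.rng, len(self.action_set))
        lp_executed = np.log(np.clip(probs[np.arange(n), idx], PROB_FLOOR, 1.0))
        if self.training:
            self.buffer.observables.append(obs)
            self.buffer.action_indices.append(idx.copy())
            self.buffer.log_probs.append(lp_executed)
            self.buffer.values.append(values.copy())
        self._steps += 1
        if self.exploration is not None:
            self.exploration.advance()
        return [self.action_set.by_index(int(i)) for i in idx]

    def finalize(self, all_colloids):
        if self._steps == 0 or self.buffer.complete:
            return
        mine = [c for c in all_colloids if c.type == self.particle_type]
        self._slice_reward(mine, all_colloids)


class ClassicalAgent(Agent):
    """Non-trainable agent applying a deterministic rule per colloid."""

    def __init__(self, particle_type: int, rule, task: Task | None = None) -> None:
        self.particle_type = particle_type
        self.rule = rule
        self.task = task

    def reset_episode(self, seed: int | None = None) -> None:
        if self.task is not None:
            self.task.reset()
        if hasattr(self.rule, "reset"):
            self.rule.reset()

    def calc_action_group(self, mine, all_colloids):
        if self.task is not None:
            self.task(mine, all_colloids)
        return [self.rule(c, all_colloids) for c in mine]


class SteerToGradient:
    """Reference classical rule: turn toward increasing concentration.

    If the director is aligned with the local field gradient within
    ``tolerance`` (radians), translate; otherwise rotate in the sense that
    reduces the misalignment (counterclockwise when the gradient lies to the
    left of the director).  Deterministic; 2D.
    """

    def __init__(
        self, fld: ConcentrationField, action_set: ActionSet, tolerance: float = 0.2
    ) -> None:
        self.field = fld
        self.action_set = action_set
        self.tolerance = tolerance

    def __call__(self, colloid: Colloid, all_colloids=None) -> Action:
        g = field_gradient(self.field, colloid.pos)
        norm = np.linalg.norm(g)
        if norm == 0.0:
            return self.action_set.by_name("translate")
        ghat = g / norm
        e = colloid.director
        cosang = float(np.clip(np.dot(e, ghat), -1.0, 1.0))
        if np.arccos(cosang) <= self.tolerance:
            return self.action_set.by_name("translate")
        cross_z = e[0] * ghat[1] - e[1] * ghat[0]
        if cross_z > 0:
            return self.action_set.by_name("rotate_counterclockwise")
        return self.action_set.by_name("rotate_clockwise")


# ---------------------------------------------------------------------------
# force function
# ---------------------------------------------------------------------------

_ZERO_ACTION = Action()


class ForceFunction:
    """Routes particle groups to their controlling agents.

    ``calc_action`` receives the full colloid list from the engine, returns
    one Action per colloid in the same order, and never mutates its input.
    Types without a registered agent are passive (zero action) unless
    ``strict`` is set.
    """

    def __init__(self, agents: list[Agent], strict: bool = False) -> None:
        self.agents: dict[int, Agent] = {}
        for a in agents:
            if a.particle_type in self.agents:
                raise ValueError(f"particle type {a.particle_type} controlled by two agents")
            self.agents[a.particle_type] = a
        self.strict = strict

    @property
    def kill_switch(self) -> bool:
        return any(a.kill_switch for a in self.agents.values())

    @property
    def trainable_agents(self) -> list[ActorCriticAgent]:
        return [a for a in self.agents.values() if a.trainable]

    def reset_episode(self, seed: int | None = None) -> None:
        for k, a in enumerate(sorted(self.agents, key=int)):
            sub = None if seed is None else int(
                np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)
            )
            self.agents[a].reset_episode(sub)

    def calc_action(self, colloids: list[Colloid]) -> list[Action]:
        by_type: dict[int, list[int]] = {}
        for i, c in enumerate(colloids):
            by_type.setdefault(c.type, []).append(i)
        actions: list[Action] = [_ZERO_ACTION] * len(colloids)
        for t, rows in by_type.items():
            agent = self.agents.get(t)
            if agent is None:
                if self.strict:
                    raise ValueError(f"no agent registered for particle type {t}")
                continue
            mine = [colloids[i] for i in rows]
            acts = agent.calc_action_group(mine, colloids)
            if len(acts) != len(rows):
                raise RuntimeError("agent returned wrong number of actions")
            for i, a in zip(rows, acts):
                actions[i] = a
        return actions

    def finalize(self, colloids: list[Colloid]) -> None:
        for a in self.agents.values():
            a.finalize(colloids)
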