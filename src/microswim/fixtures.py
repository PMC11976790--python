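"""Reproducible test systems: every module is exercisable without data.

Five scenarios are provided.

* ``free-diffusion`` — passive Brownian particles; validates the diffusive
  limit MSD = 2 d D_t t.
* ``abp-gas`` — active Brownian particles with constant propulsion and no
  steering; validates the closed-form active MSD.
* ``chemotaxis-arena`` — a Gaussian chemical source plus trainable agents
  with the four-action swimming repertoire and the positive-gain
  chemotaxis reward.
* ``rod-arena`` — a rigid bead-chain rod plus pusher agents rewarded for
  rotating it.
* ``bandit`` — a two-armed bandit wrapped in the engine interface (the
  particle's x coordinate encodes the last pulled arm); the standard
  oracle for the policy-gradient mathematics.

Fixture generation is pure: the spec plus its seed fully determine the
system.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .actions import Action, ActionSet, default_action_set
from .agents import ActorCriticAgent, ClassicalAgent, ForceFunction
from .engine import (
    Colloid,
    ConcentrationField,
    LangevinEngine,
    RigidRod,
    SystemParams,
    TrajectoryRecord,
)
from .observables import ConcentrationChange, MultiSensing, NeighborSensing, Observable
from .rl import TrainingHyperparams
from .tasks import GradientClimbing, RodRotation, Task

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "analyze_msd",
    "BanditEngine",
    "BanditTask",
    "ConstantObservable",
    "ConstantPropulsion",
]

SCENARIOS = ("free-diffusion", "abp-gas", "chemotaxis-arena", "rod-arena", "bandit")


@dataclass
class FixtureSpec:
    """Fully determines a generated system given its seed."""

    scenario: str
    n: int = 100
    box: float = 100.0
    seed: int = 0
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


# ---------------------------------------------------------------------------
# bandit stub environment
# ---------------------------------------------------------------------------


class ConstantObservable(Observable):
    """Stateless observation (all zeros); the bandit has a single state."""

    def __init__(self, dimension: int = 1) -> None:
        self.dimension = dimension

    def compute_observable(self, colloids, all_colloids=None):
        return [np.zeros(self.dimension) for _ in colloids]


class BanditTask(Task):
    """Reward table lookup keyed on the arm encoded in the particle's x."""

    def __init__(self, reward_table=(1.0, 0.0)) -> None:
        super().__init__()
        self.reward_table = list(reward_table)

    def __call__(self, colloids, all_colloids=None):
        out = np.zeros(len(colloids))
        for i, c in enumerate(colloids):
            arm = int(round(float(c.pos[0])))
            if arm >= 0:
                out[i] = self.reward_table[arm]
        return out


class BanditEngine:
    """Stub engine implementing the two-method environment contract.

    Pulling arm ``i`` (an Action with ``force == i``) moves the single
    particle to x = i; x = −1 means no arm pulled yet.  Rewards are then a
    pure table lookup by the task.
    """

    def __init__(self, n_arms: int = 2, seed: int = 0) -> None:
        self.n_arms = n_arms
        self.pos = np.array([-1.0, 0.0])

    def get_particle_data(self) -> list[Colloid]:
        return [Colloid(0, 0, self.pos.copy(), np.array([1.0, 0.0]))]

    def integrate(self, force_function, n_slices: int, steps_per_slice: int = 1):
        for _ in range(n_slices):
            actions = force_function.calc_action(self.get_particle_data())
            if getattr(force_function, "kill_switch", False):
                break
            self.pos[0] = float(actions[0].force)
        return None


def bandit_action_set(n_arms: int = 2) -> ActionSet:
    return ActionSet({f"arm{i}": Action(force=float(i)) for i in range(n_arms)})


# ---------------------------------------------------------------------------
# classical constant propulsion (ABP gas)
# ---------------------------------------------------------------------------


class ConstantPropulsion:
    """Rule: always swim forward with fixed force, never steer."""

    def __init__(self, force: float) -> None:
        self.action = Action(force=force)

    def __call__(self, colloid, all_colloids=None) -> Action:
        return self.action


# ---------------------------------------------------------------------------
# fixture factory
# ---------------------------------------------------------------------------


def _random_state(rng, n, box, d=2, ptype=0):
    pos = rng.uniform(0, box, size=(n, d))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    return [Colloid(i, ptype, pos[i], dirs[i]) for i in range(n)]


def make_fixture(spec: FixtureSpec) -> dict:
    """Build the engine factory and agent declarations for a scenario.

    Returns a dict with at least ``engine_factory(seed)`` and
    ``force_function``; scenario-specific entries (``field``, ``task``,
    ``hyperparams``, ``action_set``, ...) are included where they exist.
    """
    p = dict(spec.params)
    if spec.scenario == "free-diffusion":
        sys_params = SystemParams(
            dimension=2,
            box_length=spec.box,
            temperature=p.get("temperature", 1.0),
            gamma_t=p.get("gamma_t", 1.0),
            gamma_r=p.get("gamma_r", 1.0),
            dt=p.get("dt", 0.01),
            boundary=p.get("boundary", "open"),
            interaction="none",
        )

        def factory(seed: int) -> LangevinEngine:
            rng = np.random.Generator(np.random.PCG64(spec.seed))
            colloids = _random_state(rng, spec.n, spec.box)
            params = SystemParams(**{**sys_params.to_dict(), "seed": seed})
            return LangevinEngine(colloids, params)

        return {"engine_factory": factory, "force_function": ForceFunction([]), "params": sys_params}

    if spec.scenario == "abp-gas":
        force = p.get("force", 10.0)
        sys_params = SystemParams(
            dimension=2,
            box_length=spec.box,
            temperature=p.get("temperature", 1.0),
            gamma_t=p.get("gamma_t", 1.0),
            gamma_r=p.get("gamma_r", 1.0),
            dt=p.get("dt", 0.002),
            boundary=p.get("boundary", "open"),
            interaction="none",
        )
        ff = ForceFunction([ClassicalAgent(0, ConstantPropulsion(force))])

        def factory(seed: int) -> LangevinEngine:
            rng = np.random.Generator(np.random.PCG64(spec.seed))
            colloids = _random_state(rng, spec.n, spec.box)
            params = SystemParams(**{**sys_params.to_dict(), "seed": seed})
            return LangevinEngine(colloids, params)

        return {
            "engine_factory": factory,
            "force_function": ff,
            "params": sys_params,
            "swim_speed": force / p.get("gamma_t", 1.0),
        }

    if spec.scenario == "chemotaxis-arena":
        return _chemotaxis_fixture(spec, p)

    if spec.scenario == "rod-arena":
        return _rod_fixture(spec, p)

    if spec.scenario == "bandit":
        n_arms = p.get("n_arms", 2)
        table = p.get("reward_table", (1.0, 0.0))
        aset = bandit_action_set(n_arms)
        task = BanditTask(table)
        agent = ActorCriticAgent(
            particle_type=0,
            action_set=aset,
            observable=ConstantObservable(1),
            task=task,
            init_seed=spec.seed,
            hidden=p.get("hidden", (32, 32)),
        )
        ff = ForceFunction([agent])
        algorithm = p.get("algorithm", "vpg")
        # single-sample bandit batches: multi-epoch PPO at the VPG step size
        # over-commits before the critic is calibrated, so PPO runs smaller
        default_lr = 0.05 if algorithm == "vpg" else 0.01
        hp = TrainingHyperparams(
            gamma=1.0,
            lr=p.get("lr", default_lr),
            algorithm=algorithm,
            use_gae=False,
            standardize_advantage=False,
            entropy_coef=0.0,
        )
        return {
            "engine_factory": lambda seed: BanditEngine(n_arms, seed),
            "force_function": ff,
            "agent": agent,
            "task": task,
            "action_set": aset,
            "hyperparams": hp,
            "reward_table": list(table),
        }

    raise ValueError(f"unknown scenario {spec.scenario!r}")


def _chemotaxis_fixture(spec: FixtureSpec, p: dict) -> dict:
    """Gaussian source at the box center; agents start on a ring around it.

    Default physics (reduced units): swim speed 10, slice time 0.1 (so one
    body-length-scale move per slice), rotational diffusion D_r = 0.1, start
    distance ~10 from a source of width σ_c = 8.
    """
    box = spec.box if spec.box != 100.0 else 100.0
    source = np.array(p.get("source", (box / 2, box / 2)))
    fld = ConcentrationField(
        source=source, c0=p.get("c0", 1.0), sigma_c=p.get("sigma_c", 8.0)
    )
    sys_params = SystemParams(
        dimension=2,
        box_length=box,
        temperature=p.get("temperature", 0.1),
        gamma_t=p.get("gamma_t", 1.0),
        gamma_r=p.get("gamma_r", 1.0),
        dt=p.get("dt", 0.01),
        boundary=p.get("boundary", "open"),
        interaction="none",
    )
    aset = default_action_set(force=p.get("force", 10.0), torque=p.get("torque", 5.0))
    observable = ConcentrationChange(fld, scale=p.get("obs_scale", 10.0))
    task = GradientClimbing(fld, scale=p.get("reward_scale", 10.0))
    agent = ActorCriticAgent(
        particle_type=0,
        action_set=aset,
        observable=observable,
        task=task,
        init_seed=spec.seed,
        hidden=p.get("hidden", (128, 128)),
    )
    ff = ForceFunction([agent])
    r0 = p.get("start_radius", 10.0)

    def factory(seed: int) -> LangevinEngine:
        rng = np.random.Generator(np.random.PCG64(spec.seed))
        ang = rng.uniform(0, 2 * np.pi, size=spec.n)
        rad = rng.uniform(0.8 * r0, 1.2 * r0, size=spec.n)
        pos = source + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        th = rng.uniform(0, 2 * np.pi, size=spec.n)
        dirs = np.column_stack([np.cos(th), np.sin(th)])
        colloids = [Colloid(i, 0, pos[i], dirs[i]) for i in range(spec.n)]
        params = SystemParams(**{**sys_params.to_dict(), "seed": seed})
        return LangevinEngine(colloids, params)

    hp = TrainingHyperparams(
        gamma=p.get("gamma", 0.99),
        lam=p.get("lam", 0.95),
        lr=p.get("lr", 1e-3),
        algorithm=p.get("algorithm", "ppo"),
        entropy_coef=p.get("entropy_coef", 0.01),
    )
    return {
        "engine_factory": factory,
        "force_function": ff,
        "field": fld,
        "agent": agent,
        "task": task,
        "action_set": aset,
        "params": sys_params,
        "hyperparams": hp,
    }


def _rod_fixture(spec: FixtureSpec, p: dict) -> dict:
    """Rigid 7-bead rod at the center; n pusher agents around it, WCA on."""
    box = spec.box
    n_beads = p.get("n_beads", 7)
    center = np.array([box / 2, box / 2])
    rod = RigidRod(
        bead_ids=list(range(spec.n, spec.n + n_beads)),
        gamma_t=p.get("rod_gamma_t", 10.0),
        gamma_r=p.get("rod_gamma_r", 50.0),
        center=center,
        spacing=p.get("spacing", 1.2),
    )
    sys_params = SystemParams(
        dimension=2,
        box_length=box,
        temperature=p.get("temperature", 0.05),
        gamma_t=p.get("gamma_t", 1.0),
        gamma_r=p.get("gamma_r", 1.0),
        dt=p.get("dt", 0.005),
        boundary="periodic",
        interaction="wca",
        wca_epsilon=p.get("wca_epsilon", 1.0),
        wca_sigma=p.get("wca_sigma", 1.0),
    )
    slice_dt = sys_params.dt * p.get("steps_per_slice", 10)
    aset = default_action_set(force=p.get("force", 10.0), torque=p.get("torque", 5.0))
    observable = MultiSensing(
        [NeighborSensing(radius=p.get("sensing_radius", 6.0), dimension_space=2)]
    )
    task = RodRotation(rod_type=1, scale=p.get("reward_scale", 10.0), slice_dt=slice_dt)
    agent = ActorCriticAgent(
        particle_type=0,
        action_set=aset,
        observable=observable,
        task=task,
        init_seed=spec.seed,
        hidden=p.get("hidden", (64, 64)),
    )
    ff = ForceFunction([agent])

    def factory(seed: int) -> LangevinEngine:
        rng = np.random.Generator(np.random.PCG64(spec.seed))
        ang = rng.uniform(0, 2 * np.pi, size=spec.n)
        rad = rng.uniform(5.0, 8.0, size=spec.n)
        pos = center + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        th = rng.uniform(0, 2 * np.pi, size=spec.n)
        dirs = np.column_stack([np.cos(th), np.sin(th)])
        colloids = [Colloid(i, 0, pos[i], dirs[i]) for i in range(spec.n)]
        bead_rod = RigidRod(
            bead_ids=list(rod.bead_ids),
            gamma_t=rod.gamma_t,
            gamma_r=rod.gamma_r,
            center=center.copy(),
            spacing=rod.spacing,
        )
        beads = [
            Colloid(bid, 1, bp, np.array([1.0, 0.0]))
            for bid, bp in zip(bead_rod.bead_ids, bead_rod.bead_positions())
        ]
        params = SystemParams(**{**sys_params.to_dict(), "seed": seed})
        return LangevinEngine(colloids + beads, params, rod=bead_rod)

    return {
        "engine_factory": factory,
        "force_function": ff,
        "agent": agent,
        "task": task,
        "rod": rod,
        "params": sys_params,
        "hyperparams": TrainingHyperparams(),
    }


# ---------------------------------------------------------------------------
# MSD analysis
# ---------------------------------------------------------------------------


def analyze_msd(record: TrajectoryRecord, lag_times: np.ndarray) -> dict:
    """Ensemble- and time-origin-averaged mean squared displacement.

    Uses the unwrapped (image-corrected) positions.  For each requested lag
    time the nearest snapshot lag is used; the standard error is computed
    over particles (each particle's origin-averaged MSD is one independent
    sample).

    Returns a dict with ``lag_times`` (actually used), ``msd`` and
    ``stderr`` arrays.
    """
    u = record.unwrapped
    times = record.times
    if u.shape[0] < 2:
        raise ValueError("need at least two snapshots for an MSD")
    dt_snap = times[1] - times[0]
    lags = np.asarray(lag_times, dtype=float)
    lag_idx = np.clip(np.round(lags / dt_snap).astype(int), 1, u.shape[0] - 1)
    msd = np.empty(len(lag_idx))
    err = np.empty(len(lag_idx))
    for k, m in enumerate(lag_idx):
        disp = u[m:] - u[:-m]  # (origins, N, d)
        sq = np.sum(disp**2, axis=-1)
        per_particle = sq.mean(axis=0)  # origin average per particle
        msd[k] = per_particle.mean()
        err[k] = per_particle.std(ddof=1) / np.sqrt(per_particle.size)
    return {"lag_times": lag_idx * dt_snap, "msd": msd, "stderr": err}
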