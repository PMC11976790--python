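"""Training orchestration: episodic, semi-episodic, and continuous loops.

The trainer mediates between the environment (any engine exposing
``integrate``/``get_particle_data``) and the trainable agents routed through
a :class:`~microswim.agents.ForceFunction`.  Per episode it collects the
agents' episode buffers, computes returns and advantages, performs the actor
and critic updates, and logs one metrics row.

Reproducibility model: every stream of randomness in an episode (engine
thermal noise, action sampling, exploration) is seeded from
``SeedSequence([master_seed, episode, stream])``, so a (config, seed) pair
determines the whole run bit-for-bit and a checkpoint only needs to store
network parameters, optimizer state, and the episode index to resume
exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .agents import ActorCriticAgent, ForceFunction
from .networks import Adam
from .rl import (
    TrainingHyperparams,
    actor_loss_and_grad,
    advantage,
    critic_loss_and_grad,
    expected_returns,
    gae,
    standardize,
)

__all__ = [
    "TrainerConfig",
    "train_episodic",
    "train_continuous",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "episode_seed",
]


@dataclass
class TrainerConfig:
    """Schedule of a training run.

    ``mode`` is ``"episodic"`` (environment rebuilt every episode),
    ``"semi-episodic"`` (updates every episode, environment rebuilt every
    ``reset_after`` episodes), or ``"continuous"`` (one persistent
    environment, updates every ``update_every`` slices up to
    ``slice_budget``).
    """

    mode: str = "episodic"
    n_episodes: int = 100
    n_slices: int = 20
    steps_per_slice: int = 10
    reset_after: int = 1
    update_every: int = 10
    slice_budget: int = 1000
    checkpoint_every: int = 0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.mode not in ("episodic", "semi-episodic", "continuous"):
            raise ValueError(f"unknown trainer mode {self.mode!r}")
        if self.n_episodes < 1 or self.n_slices < 1:
            raise ValueError("n_episodes and n_slices must be >= 1")


def episode_seed(master: int, episode: int, stream: int) -> int:
    """Deterministic per-(episode, stream) seed below 2^31."""
    return int(np.random.SeedSequence([master, episode, stream]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# updates
# ---------------------------------------------------------------------------


def _update_agent(
    agent: ActorCriticAgent, optimizer: Adam, hp: TrainingHyperparams
) -> dict[str, float]:
    """One actor+critic update from the agent's episode buffer."""
    data = agent.buffer.arrays()
    rewards = data["rewards"]  # (T, n)
    values = data["values"]
    if hp.team_average_reward:
        rewards = np.broadcast_to(
            rewards.mean(axis=1, keepdims=True), rewards.shape
        ).copy()
    returns = expected_returns(rewards, hp.gamma)
    if hp.use_gae:
        adv = gae(rewards, values, hp.gamma, hp.lam)
    else:
        adv = advantage(returns, values)
    if hp.standardize_advantage:
        adv = standardize(adv)

    t_steps, n_part = rewards.shape
    x = data["observables"].reshape(t_steps * n_part, -1)
    idx = data["action_indices"].reshape(-1)
    lp_old = data["log_probs"].reshape(-1)
    adv_f = adv.reshape(-1)
    ret_f = returns.reshape(-1)

    n_epochs = hp.epochs if hp.algorithm == "ppo" else 1
    actor_loss = critic_l = ent = 0.0
    for _ in range(n_epochs):
        logits, v_pred, cache = agent.network.forward(agent.params, x)
        actor_loss, d_logits, ent = actor_loss_and_grad(logits, idx, adv_f, hp, lp_old)
        critic_l, d_values = critic_loss_and_grad(v_pred, ret_f)
        grads = agent.network.backward(agent.params, cache, d_logits, d_values)
        agent.params = optimizer.step(agent.params, grads)

    intr = agent.buffer.intrinsic_rewards
    return {
        "mean_reward": float(rewards.mean()),
        "actor_loss": float(actor_loss),
        "critic_loss": float(critic_l),
        "entropy": float(ent),
        "mean_intrinsic": float(np.mean(intr)) if intr else 0.0,
    }


def _update_all(ff: ForceFunction, optimizers: dict, hp: TrainingHyperparams) -> dict:
    row: dict[str, float] = {}
    for agent in ff.trainable_agents:
        if len(agent.buffer) == 0:
            continue
        stats = _update_agent(agent, optimizers[agent.particle_type], hp)
        if len(ff.trainable_agents) == 1:
            row.update(stats)
        else:
            row.update({f"{k}_type{agent.particle_type}": v for k, v in stats.items()})
    return row


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------


def train_episodic(
    engine_factory,
    force_function: ForceFunction,
    config: TrainerConfig,
    hp: TrainingHyperparams | None = None,
    checkpoint_path: str | None = None,
    start_episode: int = 0,
    optimizers: dict | None = None,
):
    """Episodic / semi-episodic training.

    ``engine_factory(seed)`` must return a fresh engine.  Returns
    ``(force_function, metrics)`` where metrics is a list of one dict per
    update.  ``start_episode``/``optimizers`` support exact resumption from
    a checkpoint (see :func:`load_checkpoint`).
    """
    hp = hp or TrainingHyperparams()
    ff = force_function
    if optimizers is None:
        optimizers = {a.particle_type: Adam(lr=hp.lr) for a in ff.trainable_agents}
    metrics: list[dict] = []
    engine = None
    factory_calls = 0
    for ep in range(start_episode, config.n_episodes):
        rebuild = (
            engine is None
            or config.mode == "episodic"
            or ff.kill_switch
        )
        if rebuild:
            engine = engine_factory(episode_seed(config.seed, ep, 0))
            factory_calls += 1
        ff.reset_episode(episode_seed(config.seed, ep, 1))
        engine.integrate(ff, config.n_slices, config.steps_per_slice)
        ff.finalize(engine.get_particle_data())
        row = {"episode": ep}
        row.update(_update_all(ff, optimizers, hp))
        metrics.append(row)
        if (
            config.mode == "semi-episodic"
            and config.reset_after > 0
            and (ep + 1 - start_episode) % config.reset_after == 0
        ):
            engine = engine_factory(episode_seed(config.seed, ep, 2))
            factory_calls += 1
        if checkpoint_path and config.checkpoint_every and (ep + 1) % config.checkpoint_every == 0:
            save_checkpoint(checkpoint_path, ff, optimizers, ep + 1, hp, config)
    ff._factory_calls = factory_calls  # exposed for accounting tests
    return ff, metrics


def train_continuous(
    engine,
    force_function: ForceFunction,
    config: TrainerConfig,
    hp: TrainingHyperparams | None = None,
):
    """Continuous training on one persistent engine.

    Runs until ``slice_budget`` slices, updating every ``update_every``
    slices.  A task kill switch *ends* training (no reset); a trailing
    partial chunk is discarded without an update.  Returns
    ``(force_function, metrics, aborted)`` with ``aborted`` True when the
    kill switch fired.
    """
    hp = hp or TrainingHyperparams()
    ff = force_function
    optimizers = {a.particle_type: Adam(lr=hp.lr) for a in ff.trainable_agents}
    ff.reset_episode(episode_seed(config.seed, 0, 1))
    metrics: list[dict] = []
    slices_done = 0
    update_no = 0
    aborted = False
    while slices_done < config.slice_budget:
        chunk = min(config.update_every, config.slice_budget - slices_done)
        for a in ff.trainable_agents:
            a.buffer.clear()
        record = engine.integrate(ff, chunk, config.steps_per_slice)
        done = record.n_slices
        slices_done += done
        if done == chunk and chunk == config.update_every:
            ff.finalize(engine.get_particle_data())
            row = {"update": update_no, "slices": slices_done}
            row.update(_update_all(ff, optimizers, hp))
            metrics.append(row)
            update_no += 1
        if ff.kill_switch:
            aborted = True
            break
    return ff, metrics, aborted


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(
    engine_factory,
    force_function: ForceFunction,
    n_runs: int,
    seed: int,
    n_slices: int = 20,
    steps_per_slice: int = 10,
    metric_fn=None,
    greedy: bool = False,
) -> dict:
    """Frozen-policy rollouts; returns mean ± stderr summary statistics.

    ``metric_fn(colloids) -> float`` is evaluated on the final state of each
    run (e.g. the mean chemical concentration at the agents' positions).
    Episode reward is the per-slice mean task reward summed over slices.
    Deterministic for fixed (agents, seed).
    """
    ff = force_function
    saved = [(a.training, a.greedy) for a in ff.trainable_agents]
    for a in ff.trainable_agents:
        a.training = True  # keep recording so rewards are collected
        a.greedy = greedy
    rewards = np.zeros(n_runs)
    metric_vals = np.zeros(n_runs)
    try:
        for run in range(n_runs):
            engine = engine_factory(episode_seed(seed, run, 10))
            ff.reset_episode(episode_seed(seed, run, 11))
            engine.integrate(ff, n_slices, steps_per_slice)
            final = engine.get_particle_data()
            ff.finalize(final)
            total = 0.0
            for a in ff.trainable_agents:
                if a.buffer.task_rewards:
                    total += float(np.sum([np.mean(r) for r in a.buffer.task_rewards]))
            rewards[run] = total
            if metric_fn is not None:
                metric_vals[run] = float(metric_fn(final))
    finally:
        for a, (tr, gr) in zip(ff.trainable_agents, saved):
            a.training = tr
            a.greedy = gr
    out = {
        "n_runs": n_runs,
        "mean_reward": float(rewards.mean()),
        "stderr_reward": float(rewards.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0,
        "rewards": rewards,
    }
    if metric_fn is not None:
        out["mean_metric"] = float(metric_vals.mean())
        out["stderr_metric"] = (
            float(metric_vals.std(ddof=1) / np.sqrt(n_runs)) if n_runs > 1 else 0.0
        )
        out["metrics"] = metric_vals
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(
    path: str,
    ff: ForceFunction,
    optimizers: dict,
    episode: int,
    hp: TrainingHyperparams,
    config: TrainerConfig | None = None,
) -> None:
    """Flat key→array NPZ checkpoint with config hash and training position."""
    arrays: dict[str, np.ndarray] = {}
    for a in ff.trainable_agents:
        t = a.particle_type
        for k, v in a.params.items():
            arrays[f"agent{t}/params/{k}"] = v
        opt = optimizers[t]
        state = opt.state_dict()
        for k, v in state["m"].items():
            arrays[f"agent{t}/opt_m/{k}"] = v
        for k, v in state["v"].items():
            arrays[f"agent{t}/opt_v/{k}"] = v
        arrays[f"agent{t}/opt_t"] = np.array(state["t"])
        if a.intrinsic_reward is not None:
            for k, v in a.intrinsic_reward.predictor_params.items():
                arrays[f"agent{t}/rnd_pred/{k}"] = v
            for k, v in a.intrinsic_reward.target_params.items():
                arrays[f"agent{t}/rnd_target/{k}"] = v
    meta = {
        "episode": episode,
        "hyperparams": asdict(hp),
        "trainer_config": asdict(config) if config else None,
    }
    arrays["meta"] = np.array(json.dumps(meta, sort_keys=True))
    np.savez(path, **arrays)


def load_checkpoint(path: str, ff: ForceFunction, hp: TrainingHyperparams):
    """Restore params/optimizer state into ``ff``; returns (episode, optimizers)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        optimizers: dict[int, Adam] = {}
        for a in ff.trainable_agents:
            t = a.particle_type
            prefix = f"agent{t}/params/"
            a.params = {
                k[len(prefix):]: data[k].copy() for k in data.files if k.startswith(prefix)
            }
            opt = Adam(lr=hp.lr)
            mp, vp = f"agent{t}/opt_m/", f"agent{t}/opt_v/"
            opt.load_state_dict(
                {
                    "t": int(data[f"agent{t}/opt_t"]),
                    "m": {k[len(mp):]: data[k].copy() for k in data.files if k.startswith(mp)},
                    "v": {k[len(vp):]: data[k].copy() for k in data.files if k.startswith(vp)},
                    "lr": hp.lr,
                    "beta1": opt.beta1,
                    "beta2": opt.beta2,
                    "eps": opt.eps,
                }
            )
            optimizers[t] = opt
            if a.intrinsic_reward is not None:
                pp = f"agent{t}/rnd_pred/"
                tp = f"agent{t}/rnd_target/"
                a.intrinsic_reward.predictor_params = {
                    k[len(pp):]: data[k].copy() for k in data.files if k.startswith(pp)
                }
                a.intrinsic_reward.target_params = {
                    k[len(tp):]: data[k].copy() for k in data.files if k.startswith(tp)
                }
    return int(meta["episode"]), optimizers
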