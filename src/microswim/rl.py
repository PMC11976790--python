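"""Policy-gradient training mathematics.

Discounted returns G_t = Σ_{t'≥t} γ^{t'-t} r_{t'}, the advantage
A_t = G_t − V_t, generalized advantage estimation, the vanilla
policy-gradient surrogate, the PPO clipped surrogate, the critic's
mean-squared-error regression target, and parameter updates.

All losses are written so that *minimizing* them performs gradient ascent
on the RL objective J(π_θ) = ⟨Σ_t log π_θ(a_t|s_t) · A_t⟩.  The gradient
helpers return dL/d(logits) so that the caller can chain them through
:meth:`microswim.networks.ActorCriticNet.backward`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import log_softmax, softmax

__all__ = [
    "TrainingHyperparams",
    "expected_returns",
    "advantage",
    "gae",
    "vpg_loss",
    "ppo_loss",
    "critic_loss",
    "update",
    "standardize",
    "actor_loss_and_grad",
    "critic_loss_and_grad",
    "entropy",
]

PROB_FLOOR = 1e-8  # probabilities are clamped away from 0 before logs


@dataclass
class TrainingHyperparams:
    """Hyperparameters of one actor-critic training run.

    Attributes
    ----------
    gamma : float
        Discount factor in [0, 1]; weights near-term over long-term reward.
    lam : float
        GAE λ in [0, 1]; 0 gives one-step TD, 1 gives Monte-Carlo returns.
    eps_clip : float
        PPO probability-ratio clip half-width.
    lr : float
        Adam learning rate.
    epochs : int
        Gradient epochs per collected batch (PPO re-forwards each epoch).
    entropy_coef : float
        Weight of the entropy bonus added to the actor loss (0 disables).
    algorithm : str
        ``"vpg"`` or ``"ppo"``.
    use_gae : bool
        Use GAE advantages instead of plain G − V.
    standardize_advantage : bool
        Shift/scale advantages to zero mean, unit variance per batch.
    team_average_reward : bool
        Replace each particle's reward with the group mean (cooperative
        team-average setting).
    """

    gamma: float = 0.99
    lam: float = 0.95
    eps_clip: float = 0.2
    lr: float = 1e-3
    epochs: int = 4
    entropy_coef: float = 0.01
    algorithm: str = "ppo"
    use_gae: bool = True
    standardize_advantage: bool = True
    team_average_reward: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if self.eps_clip <= 0:
            raise ValueError("eps_clip must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.entropy_coef < 0:
            raise ValueError("entropy coefficient must be non-negative")
        if self.algorithm not in ("vpg", "ppo"):
            raise ValueError("algorithm must be 'vpg' or 'ppo'")


# ---------------------------------------------------------------------------
# returns and advantages
# ---------------------------------------------------------------------------


def expected_returns(rewards: np.ndarray, gamma: float) -> np.ndarray:
    """Discounted returns G_t = Σ_{t'=t}^{T-1} γ^{t'-t} r_{t'}.

    Computed by the exact backward recursion G_t = r_t + γ G_{t+1}.
    ``rewards`` may be (T,) or (T, n) for n particles sharing a policy.
    """
    r = np.asarray(rewards, dtype=float)
    if r.shape[0] == 0:
        raise ValueError("reward sequence must not be empty")
    g = np.empty_like(r)
    g[-1] = r[-1]
    for t in range(r.shape[0] - 2, -1, -1):
        g[t] = r[t] + gamma * g[t + 1]
    return g


def advantage(returns: np.ndarray, values: np.ndarray) -> np.ndarray:
    """A_t = G_t − V_t."""
    g = np.asarray(returns, dtype=float)
    v = np.asarray(values, dtype=float)
    if g.shape != v.shape:
        raise ValueError("returns and values must have equal shape")
    return g - v


def gae(rewards: np.ndarray, values: np.ndarray, gamma: float, lam: float) -> np.ndarray:
    """Generalized advantage estimation with terminal bootstrap V_T = 0.

    δ_t = r_t + γ V_{t+1} − V_t;  A_t = Σ_{l≥0} (γλ)^l δ_{t+l}.
    At λ=1 this telescopes to G_t − V_t; at λ=0 it is the one-step TD error.
    """
    r = np.asarray(rewards, dtype=float)
    v = np.asarray(values, dtype=float)
    if r.shape != v.shape:
        raise ValueError("rewards and values must have equal shape")
    v_next = np.zeros_like(v)
    v_next[:-1] = v[1:]
    delta = r + gamma * v_next - v
    adv = np.empty_like(delta)
    adv[-1] = delta[-1]
    for t in range(r.shape[0] - 2, -1, -1):
        adv[t] = delta[t] + gamma * lam * adv[t + 1]
    return adv


def standardize(x: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Zero-mean unit-variance rescaling; a constant batch maps to zeros."""
    x = np.asarray(x, dtype=float)
    std = x.std()
    if std < eps:
        return np.zeros_like(x)
    return (x - x.mean()) / std


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def vpg_loss(log_probs: np.ndarray, advantages: np.ndarray) -> float:
    """Vanilla policy-gradient surrogate −Σ_t log π(a_t|s_t) · A_t.

    Advantages are treated as constants (no gradient flows through A).
    """
    lp = np.asarray(log_probs, dtype=float)
    a = np.asarray(advantages, dtype=float)
    if np.isnan(lp).any() or np.isnan(a).any():
        raise ValueError("NaN in loss inputs")
    return float(-(lp * a).sum())


def ppo_loss(
    log_probs_new: np.ndarray,
    log_probs_old: np.ndarray,
    advantages: np.ndarray,
    eps_clip: float = 0.2,
) -> float:
    """Clipped-surrogate PPO loss.

    ρ_t = exp(new − old); loss = −Σ_t min(ρ_t A_t, clip(ρ_t, 1∓ε) A_t).
    The pessimistic min bounds each term by the unclipped surrogate.
    """
    lp_new = np.asarray(log_probs_new, dtype=float)
    lp_old = np.asarray(log_probs_old, dtype=float)
    a = np.asarray(advantages, dtype=float)
    rho = np.exp(lp_new - lp_old)
    if not np.all(np.isfinite(rho)):
        raise ValueError("non-finite probability ratio")
    clipped = np.clip(rho, 1.0 - eps_clip, 1.0 + eps_clip)
    return float(-np.minimum(rho * a, clipped * a).sum())


def critic_loss(values: np.ndarray, returns: np.ndarray) -> float:
    """Mean squared error between predicted values and realized returns."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(returns, dtype=float)
    if v.shape != g.shape:
        raise ValueError("values and returns must have equal shape")
    return float(np.mean((v - g) ** 2))


def update(params, grads, lr: float):
    """Plain gradient-ascent step θ' = θ + η ∇J.

    ``grads`` here are ascent gradients ∇J.  Accepts scalars, arrays, or
    flat dicts of arrays (matched by key).
    """
    if isinstance(params, dict):
        if set(params) != set(grads):
            raise ValueError("parameter/gradient structures do not match")
        return {k: params[k] + lr * grads[k] for k in params}
    p = np.asarray(params, dtype=float)
    g = np.asarray(grads, dtype=float)
    if p.shape != g.shape:
        raise ValueError("parameter/gradient shapes do not match")
    out = p + lr * g
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# gradient helpers (chain into ActorCriticNet.backward)
# ---------------------------------------------------------------------------


def entropy(probs: np.ndarray) -> np.ndarray:
    p = np.clip(probs, PROB_FLOOR, 1.0)
    return -(p * np.log(p)).sum(axis=-1)


def actor_loss_and_grad(
    logits: np.ndarray,
    action_idx: np.ndarray,
    advantages: np.ndarray,
    hp: TrainingHyperparams,
    log_probs_old: np.ndarray | None = None,
) -> tuple[float, np.ndarray, float]:
    """Actor loss, dL/d(logits), and mean policy entropy for one batch.

    For VPG: d/dz of −Σ A log π(a) is −A (1_a − π).  For PPO the unclipped
    branch contributes −A ρ (1_a − π) wherever the min selects it; the
    clipped branch is constant in θ.  The entropy bonus −c H is included.
    """
    logits = np.atleast_2d(logits)
    probs = softmax(logits)
    logp = log_softmax(logits)
    b = logits.shape[0]
    idx = np.asarray(action_idx, dtype=int)
    adv = np.asarray(advantages, dtype=float)
    onehot = np.zeros_like(probs)
    onehot[np.arange(b), idx] = 1.0
    lp_taken = np.log(np.clip(probs[np.arange(b), idx], PROB_FLOOR, 1.0))

    if hp.algorithm == "vpg":
        loss = vpg_loss(lp_taken, adv)
        d_logits = -adv[:, None] * (onehot - probs)
    else:
        lp_old = np.asarray(log_probs_old, dtype=float)
        rho = np.exp(lp_taken - lp_old)
        clipped = np.clip(rho, 1.0 - hp.eps_clip, 1.0 + hp.eps_clip)
        loss = float(-np.minimum(rho * adv, clipped * adv).sum())
        unclipped_active = rho * adv <= clipped * adv
        coeff = np.where(unclipped_active, -adv * rho, 0.0)
        d_logits = coeff[:, None] * (onehot - probs)

    ent = entropy(probs)
    mean_ent = float(ent.mean())
    if hp.entropy_coef > 0:
        # entropy bonus enters the gradient only; the returned loss is the
        # bare surrogate so logs read 0 for a perfectly uninformative batch
        logp_safe = np.log(np.clip(probs, PROB_FLOOR, 1.0))
        d_ent = -probs * (logp_safe + ent[:, None])
        d_logits -= hp.entropy_coef * d_ent
    return float(loss), d_logits, mean_ent


def critic_loss_and_grad(values: np.ndarray, returns: np.ndarray) -> tuple[float, np.ndarray]:
    """MSE critic loss and dL/dV."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(returns, dtype=float)
    loss = critic_loss(v, g)
    d_values = 2.0 * (v - g) / v.size
    return loss, d_values
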