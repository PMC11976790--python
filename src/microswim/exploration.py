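"""Random exploration with exponential decay.

The exploration probability ζ dictates how likely an agent is to take a
uniformly random action instead of the policy's; it decays with simulation
time t over an episode of duration T as

    ζ' = exp(−ε t / T) · ζ

with decay rate ε ≥ 0.  The log-probability recorded for training remains
the *policy's* log-probability of the executed action (configurable
behavior; exploration steps stay in the batch).
"""

from __future__ import annotations

import numpy as np

__all__ = ["explore_decay", "maybe_explore", "RandomExploration"]


def explore_decay(zeta: float, eps: float, t: float, total_time: float) -> float:
    """ζ' = exp(−ε t/T) ζ; exactly ζ at t = 0 or ε = 0."""
    if total_time <= 0:
        raise ValueError("episode duration T must be positive")
    if not 0.0 <= zeta <= 1.0:
        raise ValueError("zeta must be in [0, 1]")
    if eps < 0:
        raise ValueError("decay rate must be non-negative")
    return float(np.exp(-eps * t / total_time) * zeta)


def maybe_explore(
    action_index: int | np.ndarray,
    zeta_prime: float,
    rng: np.random.Generator,
    n_actions: int,
) -> int | np.ndarray:
    """With probability ζ' return a uniform random index, else the policy's.

    Accepts a scalar index or a vector of indices (independent coin flips).
    """
    if not 0.0 <= zeta_prime <= 1.0:
        raise ValueError("zeta' must be in [0, 1]")
    idx = np.asarray(action_index)
    scalar = idx.ndim == 0
    idx = np.atleast_1d(idx).copy()
    explore = rng.random(idx.shape) < zeta_prime
    if explore.any():
        idx[explore] = rng.integers(0, n_actions, size=int(explore.sum()))
    return int(idx[0]) if scalar else idx


class RandomExploration:
    """Stateful per-episode exploration schedule over discrete slices.

    ``episode_slices`` plays the role of the episode duration T; the slice
    counter t advances once per control slice and resets with the episode.
    """

    def __init__(self, zeta: float = 0.5, eps: float = 1.0, episode_slices: int = 100) -> None:
        self.zeta = zeta
        self.eps = eps
        self.episode_slices = episode_slices
        self.t = 0

    @property
    def current_zeta(self) -> float:
        return explore_decay(self.zeta, self.eps, self.t, self.episode_slices)

    def apply(self, idx: np.ndarray, rng: np.random.Generator, n_actions: int) -> np.ndarray:
        return maybe_explore(idx, self.current_zeta, rng, n_actions)

    def advance(self) -> None:
        self.t += 1

    def reset(self) -> None:
        self.t = 0
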