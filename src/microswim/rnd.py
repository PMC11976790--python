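"""Random network distillation (RND) intrinsic reward.

A frozen, randomly initialized *target* network embeds observations; a
*predictor* network of the same shape is trained to reproduce the target's
embedding.  The squared prediction error

    novelty(s) = ‖target(s) − predictor(s)‖²

is large on states unlike anything trained on, so adding it (weighted) to
the task reward pushes agents toward unexplored regions of state space.

Two variants are provided: the memoryless one trains the predictor only on
the current batch; the memory variant keeps a bounded FIFO buffer of past
states and trains on minibatches drawn from it, so novelty stays low on
states seen long ago.
"""

from __future__ import annotations

import numpy as np

from .networks import Adam

__all__ = ["RandomNetworkDistillation"]


def _init_net(rng: np.random.Generator, in_dim: int, hidden: int, out_dim: int) -> dict:
    s0 = np.sqrt(6.0 / (in_dim + hidden))
    s1 = np.sqrt(6.0 / (hidden + out_dim))
    return {
        "W0": rng.uniform(-s0, s0, size=(in_dim, hidden)),
        "b0": np.zeros(hidden),
        "W1": rng.uniform(-s1, s1, size=(hidden, out_dim)),
        "b1": np.zeros(out_dim),
    }


def _forward(params: dict, x: np.ndarray):
    h = np.tanh(x @ params["W0"] + params["b0"])
    return h @ params["W1"] + params["b1"], h


class RandomNetworkDistillation:
    """RND intrinsic-reward module.

    Parameters
    ----------
    input_dim
        Observable dimension.
    embedding_dim, hidden
        Embedding size and hidden width of both networks.
    lr
        Predictor Adam learning rate.
    memory
        Enable the state-memory FIFO buffer variant.
    buffer_size, minibatch
        FIFO capacity and training minibatch size (memory variant).
    train_steps
        Gradient steps per :meth:`update` call.
    """

    def __init__(
        self,
        input_dim: int,
        embedding_dim: int = 16,
        hidden: int = 64,
        lr: float = 1e-3,
        memory: bool = False,
        buffer_size: int = 4096,
        minibatch: int = 128,
        train_steps: int = 1,
        seed: int = 0,
    ) -> None:
        rng = np.random.Generator(np.random.PCG64(seed))
        self.input_dim = input_dim
        self.target_params = _init_net(rng, input_dim, hidden, embedding_dim)
        self.predictor_params = _init_net(rng, input_dim, hidden, embedding_dim)
        self.optimizer = Adam(lr=lr)
        self.memory = memory
        self.buffer_size = buffer_size
        self.minibatch = minibatch
        self.train_steps = train_steps
        self._buffer: list[np.ndarray] = []
        self._rng = np.random.Generator(np.random.PCG64(seed + 1))

    # -- inference ------------------------------------------------------------

    def novelty(self, states: np.ndarray) -> np.ndarray:
        """‖target(s) − predictor(s)‖² per state row."""
        x = np.atleast_2d(np.asarray(states, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"state dimension {x.shape[1]} does not match RND input {self.input_dim}"
            )
        t_out, _ = _forward(self.target_params, x)
        p_out, _ = _forward(self.predictor_params, x)
        return np.sum((t_out - p_out) ** 2, axis=1)

    # -- training -------------------------------------------------------------

    def _grad_step(self, x: np.ndarray) -> None:
        t_out, _ = _forward(self.target_params, x)
        p_out, h = _forward(self.predictor_params, x)
        # mean over batch and embedding of squared error
        diff = 2.0 * (p_out - t_out) / x.shape[0]
        grads = {
            "W1": h.T @ diff,
            "b1": diff.sum(axis=0),
        }
        dh = diff @ self.predictor_params["W1"].T * (1.0 - h**2)
        grads["W0"] = x.T @ dh
        grads["b0"] = dh.sum(axis=0)
        self.predictor_params = self.optimizer.step(self.predictor_params, grads)

    def update(self, states: np.ndarray, steps: int | None = None) -> None:
        """Train the predictor toward the frozen target on a state batch.

        The memory variant first appends the batch to the FIFO buffer and
        trains on minibatches sampled from the whole buffer; the memoryless
        variant trains on the given batch only.
        """
        x = np.atleast_2d(np.asarray(states, dtype=float))
        if x.shape[0] == 0:
            raise ValueError("empty state batch")
        n_steps = self.train_steps if steps is None else steps
        if self.memory:
            for row in x:
                self._buffer.append(row.copy())
            if len(self._buffer) > self.buffer_size:
                self._buffer = self._buffer[-self.buffer_size:]
            pool = np.asarray(self._buffer)
            for _ in range(n_steps):
                take = min(self.minibatch, pool.shape[0])
                sel = self._rng.choice(pool.shape[0], size=take, replace=False)
                self._grad_step(pool[sel])
        else:
            for _ in range(n_steps):
                self._grad_step(x)
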