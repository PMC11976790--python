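"""Dense actor-critic networks with hand-written backpropagation.

No autodiff framework is assumed: the networks here are small multilayer
perceptrons (default 2 hidden layers x 128 tanh units) whose forward pass
caches activations and whose backward pass propagates analytic gradients.
Two parameterizations are supported:

* ``shared``   — one trunk feeding an actor head (|A| logits) and a critic
  head (1 value unit); trunk gradients from both heads are summed.
* ``disjoint`` — independent actor and critic MLPs.

Losses supply the gradient of the objective with respect to the logits and
the value output; :meth:`ActorCriticNet.backward` turns those into parameter
gradients, consumed by the :class:`Adam` optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PolicyOutput", "ActorCriticNet", "Adam", "softmax", "log_softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


@dataclass
class PolicyOutput:
    """Probabilities over the action set plus the critic's state value."""

    probs: np.ndarray
    value: float


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, scale: float = 1.0) -> np.ndarray:
    limit = scale * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class ActorCriticNet:
    """MLP policy/value network operating on flat parameter dictionaries.

    Parameters are plain numpy arrays in a ``dict`` so they can be saved to
    NPZ checkpoints and updated functionally by the optimizer.
    """

    def __init__(
        self,
        input_dim: int,
        n_actions: int,
        hidden: tuple[int, ...] = (128, 128),
        architecture: str = "shared",
    ) -> None:
        if architecture not in ("shared", "disjoint"):
            raise ValueError("architecture must be 'shared' or 'disjoint'")
        self.input_dim = input_dim
        self.n_actions = n_actions
        self.hidden = tuple(hidden)
        self.architecture = architecture

    # -- initialization -------------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        if self.architecture == "shared":
            self._init_mlp(params, "trunk", self.input_dim, self.hidden, rng)
            top = self.hidden[-1]
            params["actor_W"] = _xavier(rng, top, self.n_actions, scale=0.01)
            params["actor_b"] = np.zeros(self.n_actions)
            params["critic_W"] = _xavier(rng, top, 1)
            params["critic_b"] = np.zeros(1)
        else:
            self._init_mlp(params, "atrunk", self.input_dim, self.hidden, rng)
            self._init_mlp(params, "ctrunk", self.input_dim, self.hidden, rng)
            top = self.hidden[-1]
            params["actor_W"] = _xavier(rng, top, self.n_actions, scale=0.01)
            params["actor_b"] = np.zeros(self.n_actions)
            params["critic_W"] = _xavier(rng, top, 1)
            params["critic_b"] = np.zeros(1)
        return params

    @staticmethod
    def _init_mlp(params, prefix, in_dim, hidden, rng) -> None:
        d = in_dim
        for i, h in enumerate(hidden):
            params[f"{prefix}_W{i}"] = _xavier(rng, d, h)
            params[f"{prefix}_b{i}"] = np.zeros(h)
            d = h

    # -- forward --------------------------------------------------------------

    @staticmethod
    def _mlp_forward(params, prefix, x, n_layers):
        caches = []
        h = x
        for i in range(n_layers):
            z = h @ params[f"{prefix}_W{i}"] + params[f"{prefix}_b{i}"]
            out = np.tanh(z)
            caches.append((h, out))
            h = out
        return h, caches

    def forward(
        self, params: dict[str, np.ndarray], x: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Batch forward pass.

        Returns ``(logits (B, A), values (B,), cache)``; the cache is passed
        back to :meth:`backward`.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {x.shape[1]} does not match network input {self.input_dim}"
            )
        nl = len(self.hidden)
        if self.architecture == "shared":
            h, caches = self._mlp_forward(params, "trunk", x, nl)
            logits = h @ params["actor_W"] + params["actor_b"]
            values = (h @ params["critic_W"] + params["critic_b"])[:, 0]
            cache = {"x": x, "trunk": caches, "h": h}
        else:
            ha, ca = self._mlp_forward(params, "atrunk", x, nl)
            hc, cc = self._mlp_forward(params, "ctrunk", x, nl)
            logits = ha @ params["actor_W"] + params["actor_b"]
            values = (hc @ params["critic_W"] + params["critic_b"])[:, 0]
            cache = {"x": x, "atrunk": ca, "ctrunk": cc, "ha": ha, "hc": hc}
        return logits, values, cache

    def policy_output(self, params: dict[str, np.ndarray], x: np.ndarray) -> PolicyOutput:
        """Single-state convenience wrapper returning a :class:`PolicyOutput`."""
        logits, values, _ = self.forward(params, np.atleast_2d(x))
        return PolicyOutput(probs=softmax(logits)[0], value=float(values[0]))

    # -- backward -------------------------------------------------------------

    @staticmethod
    def _mlp_backward(params, prefix, caches, d_out, grads):
        for i in reversed(range(len(caches))):
            h_in, h_out = caches[i]
            dz = d_out * (1.0 - h_out**2)
            grads[f"{prefix}_W{i}"] = h_in.T @ dz
            grads[f"{prefix}_b{i}"] = dz.sum(axis=0)
            d_out = dz @ params[f"{prefix}_W{i}"].T
        return d_out

    def backward(
        self,
        params: dict[str, np.ndarray],
        cache: dict,
        d_logits: np.ndarray,
        d_values: np.ndarray | None = None,
    ) -> dict[str, np.ndarray]:
        """Parameter gradients given objective gradients at the heads."""
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        d_logits = np.atleast_2d(d_logits)
        if d_values is None:
            d_values = np.zeros(d_logits.shape[0])
        d_values = np.asarray(d_values, dtype=float).reshape(-1, 1)
        if self.architecture == "shared":
            h = cache["h"]
            grads["actor_W"] = h.T @ d_logits
            grads["actor_b"] = d_logits.sum(axis=0)
            grads["critic_W"] = h.T @ d_values
            grads["critic_b"] = d_values.sum(axis=0)
            d_h = d_logits @ params["actor_W"].T + d_values @ params["critic_W"].T
            self._mlp_backward(params, "trunk", cache["trunk"], d_h, grads)
        else:
            ha, hc = cache["ha"], cache["hc"]
            grads["actor_W"] = ha.T @ d_logits
            grads["actor_b"] = d_logits.sum(axis=0)
            grads["critic_W"] = hc.T @ d_values
            grads["critic_b"] = d_values.sum(axis=0)
            self._mlp_backward(params, "atrunk", cache["atrunk"], d_logits @ params["actor_W"].T, grads)
            self._mlp_backward(params, "ctrunk", cache["ctrunk"], d_values @ params["critic_W"].T, grads)
        return grads


class Adam:
    """Adam optimizer over flat parameter dictionaries (minimizes the loss)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k]
            m = self.m.get(k, np.zeros_like(p))
            v = self.v.get(k, np.zeros_like(p))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self.m[k] = m
            self.v[k] = v
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out

    # checkpoint support ------------------------------------------------------

    def state_dict(self) -> dict:
        return {"t": self.t, "m": dict(self.m), "v": dict(self.v),
                "lr": self.lr, "beta1": self.beta1, "beta2": self.beta2, "eps": self.eps}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = dict(state["m"])
        self.v = dict(state["v"])
        self.lr = float(state["lr"])
        self.beta1 = float(state["beta1"])
        self.beta2 = float(state["beta2"])
        self.eps = float(state["eps"])
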