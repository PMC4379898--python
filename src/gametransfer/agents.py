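"""Feedforward-network agents and their ex-post best-response learning rule.

Each agent is an 8-50-50-50-2 network: the eight inputs are the eight
payoffs of the current 2x2 game seen from the agent's own perspective, the
three hidden layers apply the *tansig* transfer function (identically
``tanh``: ``2/(1+exp(-2z)) - 1``), and the two output units pass through a
softmax, giving a probability distribution over the agent's two actions.
A stochastic decision rule samples the realized action from that
distribution.

Learning is standard online backpropagation, one step per game played:
after observing the opponent's realized action, the agent computes the
myopic (ex-post) best response to it and takes a single gradient step that
moves the output distribution toward that action.  Only the *identity* of
the best response enters the update — the payoff margin between
best-responding and not best-responding is irrelevant.  The default loss
is squared error on the softmax probabilities against the one-hot target
(the era's standard toolbox objective); its gradient fades as the output
saturates, keeping choice probabilities smoothly graded in the payoffs.
Cross-entropy — whose output-layer error is the classic ``target - p`` —
is available via ``loss="cross_entropy"``.

The :class:`Population` class holds all agents' parameters as stacked
arrays so a whole population can be propagated and updated with a handful
of batched matrix products; :class:`AgentNet` is the single-agent view
used by the scalar API and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .games import Game2x2

__all__ = [
    "LAYER_SIZES",
    "tansig",
    "softmax",
    "AgentNet",
    "Population",
    "encode_perspective",
    "encode_both_roles",
    "sample_action",
    "expost_best_response",
]

#: Fixed architecture: payoff input, three tansig hidden layers, softmax output.
LAYER_SIZES = (8, 50, 50, 50, 2)

#: Default online learning rate.
DEFAULT_ETA = 0.02

#: Half-width of the uniform weight/bias initialization.
DEFAULT_INIT_SCALE = 0.5

_LOSSES = ("cross_entropy", "squared_error")


def tansig(z: np.ndarray) -> np.ndarray:
    """Hyperbolic-tangent sigmoid, ``2/(1+exp(-2z)) - 1`` = ``tanh(z)``."""
    return np.tanh(z)


def softmax(z: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, shifted for numerical stability."""
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Perspective encoding and ex-post rationality
# ---------------------------------------------------------------------------


def encode_perspective(game: Game2x2, role: str) -> np.ndarray:
    """The eight payoffs of ``game`` as seen by one player.

    The agent always perceives itself as the row player: for
    ``role="column"`` the game is transposed (roles swapped) first.  The
    vector is own payoffs at cells (00, 01, 10, 11) followed by the
    opponent's payoffs at the same own-perspective cells.
    """
    if role == "row":
        own, opp = game.row, game.col
    elif role == "column":
        own, opp = game.col.T, game.row.T
    else:
        raise ValueError(f"role must be 'row' or 'column', got {role!r}")
    return np.concatenate([own.ravel(), opp.ravel()])


def encode_both_roles(row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched perspective encodings of games ``(n, 2, 2)``.

    Returns ``(enc_row, enc_col)``, each ``(n, 8)``: the input vector an
    agent sees in the row chair and in the column chair of each game.
    """
    row = np.asarray(row, dtype=float).reshape(-1, 2, 2)
    col = np.asarray(col, dtype=float).reshape(-1, 2, 2)
    n = row.shape[0]
    enc_row = np.concatenate([row.reshape(n, 4), col.reshape(n, 4)], axis=1)
    colT = np.swapaxes(col, 1, 2)
    rowT = np.swapaxes(row, 1, 2)
    enc_col = np.concatenate([colT.reshape(n, 4), rowT.reshape(n, 4)], axis=1)
    return enc_row, enc_col


def sample_action(dist: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an action index from a choice distribution ``(p0, p1)``."""
    return int(rng.random() >= float(dist[0]))


def expost_best_response(
    game: Game2x2, role: str, opp_action: int, realized: int | None = None
) -> int:
    """Myopic best response to the opponent's realized action.

    Returns the own action maximizing the own payoff against
    ``opp_action``.  On an exact payoff tie the agent's realized action is
    kept when it attains the maximum; otherwise action 0 is returned.
    """
    own = game.row if role == "row" else game.col.T
    payoffs = own[:, opp_action]
    if payoffs[0] == payoffs[1]:
        return realized if realized is not None else 0
    return int(payoffs.argmax())


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _init_params(rng: np.random.Generator, n_agents: int, scale: float):
    weights = [
        rng.uniform(-scale, scale, (n_agents, fan_in, fan_out))
        for fan_in, fan_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:])
    ]
    biases = [rng.uniform(-scale, scale, (n_agents, 1, w)) for w in LAYER_SIZES[1:]]
    return weights, biases


class Population:
    """A population of agents with stacked parameters.

    ``weights[l]`` has shape ``(n_agents, fan_in, fan_out)`` and
    ``biases[l]`` shape ``(n_agents, 1, fan_out)``; all forward and
    backward passes run as batched matrix products over the agent axis.
    """

    def __init__(self, weights, biases, eta: float = DEFAULT_ETA, loss: str = "squared_error"):
        if eta <= 0:
            raise ValueError("learning rate must be positive")
        if loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]
        shapes = [w.shape[1:] for w in self.weights]
        if shapes != list(zip(LAYER_SIZES[:-1], LAYER_SIZES[1:])):
            raise ValueError(f"weight shapes {shapes} do not match {LAYER_SIZES}")
        self.eta = float(eta)
        self.loss = loss

    # -- construction ------------------------------------------------------

    @classmethod
    def initialize(
        cls,
        n_agents: int,
        rng: np.random.Generator,
        eta: float = DEFAULT_ETA,
        init_scale: float = DEFAULT_INIT_SCALE,
        loss: str = "squared_error",
    ) -> "Population":
        """Independent uniform(-init_scale, init_scale) parameters per agent."""
        weights, biases = _init_params(rng, n_agents, init_scale)
        return cls(weights, biases, eta=eta, loss=loss)

    @property
    def n_agents(self) -> int:
        return self.weights[0].shape[0]

    def copy(self) -> "Population":
        return Population(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            eta=self.eta,
            loss=self.loss,
        )

    def agent(self, index: int) -> "AgentNet":
        """Single-agent view (copies parameters)."""
        return AgentNet(
            weights=[w[index].copy() for w in self.weights],
            biases=[b[index, 0].copy() for b in self.biases],
            learning_rate=self.eta,
            loss=self.loss,
        )

    def check_finite(self) -> None:
        for w in self.weights + self.biases:
            if not np.isfinite(w).all():
                raise FloatingPointError(
                    "non-finite network parameters: learning has diverged"
                )

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray):
        """One input per agent: ``x`` is ``(n_agents, 8)``.

        Returns ``(probs, cache)`` where ``probs`` is ``(n_agents, 2)``
        and ``cache`` holds the layer activations needed by
        :meth:`update`.
        """
        a = x[:, None, :]
        cache = [a]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
            cache.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        p = softmax(logits)
        cache.append(p)
        return p[:, 0, :], cache

    def forward_games(self, x: np.ndarray) -> np.ndarray:
        """Many inputs per agent: ``x`` is ``(n_agents, n_games, 8)`` or
        ``(n_games, 8)`` (broadcast to every agent).  Returns choice
        probabilities ``(n_agents, n_games, 2)``; no cache is kept."""
        if x.ndim == 2:
            x = np.broadcast_to(x, (self.n_agents,) + x.shape)
        a = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
        return softmax(a @ self.weights[-1] + self.biases[-1])

    # -- learning ----------------------------------------------------------

    def output_delta(self, p: np.ndarray, target_onehot: np.ndarray) -> np.ndarray:
        """Output-layer error signal for the configured loss (gradient of
        the loss with respect to the output pre-activations)."""
        if self.loss == "cross_entropy":
            return p - target_onehot
        # squared error through the softmax Jacobian: J = diag(p) - p p^T
        d = p - target_onehot
        return p * (d - (d * p).sum(axis=-1, keepdims=True))

    def update(self, cache, target: np.ndarray) -> None:
        """One online gradient step per agent toward its target action.

        ``cache`` is the second return of :meth:`forward`; ``target`` is
        an integer array ``(n_agents,)`` of best-response actions.  No
        momentum, no batching: plain steepest descent with step ``eta``.
        """
        p = cache[-1]
        onehot = np.zeros_like(p)
        onehot[np.arange(p.shape[0]), 0, target] = 1.0
        delta = self.output_delta(p, onehot)
        eta = self.eta
        for layer in range(len(self.weights) - 1, -1, -1):
            a_prev = cache[layer]
            grad_w = np.swapaxes(a_prev, 1, 2) @ delta
            if layer > 0:
                # propagate through the pre-update weights, then the
                # tansig derivative 1 - a^2 of the previous activation
                next_delta = (delta @ np.swapaxes(self.weights[layer], 1, 2)) * (
                    1.0 - a_prev**2
                )
            else:
                next_delta = None
            self.weights[layer] -= eta * grad_w
            self.biases[layer] -= eta * delta
            delta = next_delta

    def play_and_learn(self, x: np.ndarray, targets: np.ndarray):
        """Convenience: forward pass plus one update; returns the
        pre-update choice probabilities ``(n_agents, 2)``."""
        p, cache = self.forward(x)
        self.update(cache, targets)
        return p


@dataclass
class AgentNet:
    """A single feedforward agent (scalar counterpart of :class:`Population`).

    ``weights`` are the four matrices 8x50, 50x50, 50x50, 50x2 and
    ``biases`` the four vectors (50, 50, 50, 2); ``learning_rate`` is the
    online gradient step size.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    learning_rate: float = DEFAULT_ETA
    loss: str = "squared_error"
    _pop: Population = field(init=False, repr=False)

    def __post_init__(self):
        self._pop = Population(
            [np.asarray(w, dtype=float)[None] for w in self.weights],
            [np.asarray(b, dtype=float)[None, None] for b in self.biases],
            eta=self.learning_rate,
            loss=self.loss,
        )
        # share storage so in-place updates reflect in both views
        self.weights = [w[0] for w in self._pop.weights]
        self.biases = [b[0, 0] for b in self._pop.biases]

    @classmethod
    def initialize(
        cls,
        rng: np.random.Generator,
        learning_rate: float = DEFAULT_ETA,
        init_scale: float = DEFAULT_INIT_SCALE,
        loss: str = "squared_error",
    ) -> "AgentNet":
        weights, biases = _init_params(rng, 1, init_scale)
        return cls(
            weights=[w[0] for w in weights],
            biases=[b[0, 0] for b in biases],
            learning_rate=learning_rate,
            loss=loss,
        )

    def forward(self, x: np.ndarray):
        """Choice probabilities ``(p0, p1)`` for one 8-vector input, plus
        the activation cache needed by :meth:`backprop_update`."""
        x = np.asarray(x, dtype=float)
        if x.shape != (8,):
            raise ValueError("input must be an 8-vector of payoffs")
        p, cache = self._pop.forward(x[None])
        if not np.isfinite(p).all():
            raise FloatingPointError("non-finite network output")
        return p[0], cache

    def choice_probabilities(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backprop_update(self, x: np.ndarray, target: int, cache=None) -> None:
        """One online backpropagation step toward the one-hot ``target``.

        If ``cache`` (from :meth:`forward` on the same input) is omitted,
        a fresh forward pass supplies it.
        """
        if cache is None:
            _, cache = self.forward(x)
        self._pop.update(cache, np.array([target]))

    def act(self, game: Game2x2, role: str, rng: np.random.Generator) -> int:
        """Encode the game from ``role``'s perspective, forward, sample."""
        p, _ = self.forward(encode_perspective(game, role))
        return sample_action(p, rng)
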