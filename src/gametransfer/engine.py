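"""Population training, frozen evaluation, and the 8x8 training/test grid.

One training session: a population of ``n_agents`` (default 10) networks
plays ``n_training_games`` (default 70,000) randomly drawn games from one
training set — a single game class or the ``ALL`` uniform mixture.  Every
round the population is randomly shuffled into pairs, row/column chairs
are assigned at random within each pair, every pair plays that round's
game, each agent samples an action from its softmax output, observes the
opponent's realized action, and takes one backpropagation step toward its
ex-post best response.  Mean realized payoffs are traced in fixed-size
blocks to document convergence.

Evaluation freezes the trained population (no weight updates) on a test
set of fresh games: each agent's choice probability as row player is
recorded for every game, and joint play is simulated by randomly pairing
agents, optionally repeated several times to shrink Monte-Carlo error.

All randomness flows from a single master seed through named
``SeedSequence`` children (initialization, game draws, matching, choices),
so identical configurations reproduce bit-identical populations, traces
and evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import games as G
from .agents import Population, encode_both_roles

__all__ = [
    "SimulationConfig",
    "TrainingResult",
    "Evaluation",
    "GridResult",
    "run_training",
    "evaluate_frozen",
    "run_grid",
    "save_population",
    "load_population",
]

_CLASS_INDEX = {c: k for k, c in enumerate(G.TRAINING_CLASSES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one training session.

    ``convergence_window`` is the number of games per block of the mean
    realized-payoff convergence trace.  When ``shared_round_game`` is
    true (default) all pairs play the same drawn game each round, so
    ``n_training_games`` counts population-level game presentations.
    """

    training_class: str = G.ALL
    n_agents: int = 10
    n_training_games: int = 70_000
    n_test_games: int = 1_000
    master_seed: int = 0
    eta: float = 0.02
    init_scale: float = 0.5
    loss: str = "squared_error"
    convergence_window: int = 500
    shared_round_game: bool = True

    def __post_init__(self):
        if self.training_class not in G.TRAINING_CLASSES:
            raise ValueError(f"unknown training class {self.training_class!r}")
        if self.n_agents <= 0 or self.n_agents % 2:
            raise ValueError("n_agents must be positive and even (random pairing)")
        if self.n_training_games < 0 or self.n_test_games <= 0:
            raise ValueError("game counts must be non-negative / positive")
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")
        if self.convergence_window <= 0:
            raise ValueError("convergence_window must be positive")


@dataclass
class TrainingResult:
    """Outcome of :func:`run_training`.

    ``trace`` holds mean realized payoffs (over agents) per completed
    block of ``config.convergence_window`` games.  The per-round log
    (actions and pairings; payoffs are recoverable from the games) is kept
    in compact array form and rendered to a tidy frame on demand.
    """

    config: SimulationConfig
    population: Population
    trace: np.ndarray
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)
    actions: np.ndarray = field(repr=False)  # (n_rounds, n_agents) int8
    row_players: np.ndarray = field(repr=False)  # (n_rounds, n_pairs)
    col_players: np.ndarray = field(repr=False)
    game_of_pair: np.ndarray = field(repr=False)  # (n_rounds, n_pairs)

    def match_records(self, start: int = 0, stop: int | None = None) -> pd.DataFrame:
        """Per-pair match log as a DataFrame: round, agents, sampled
        actions, realized payoffs and ex-post best responses."""
        stop = self.actions.shape[0] if stop is None else stop
        sl = slice(start, stop)
        rp, cp = self.row_players[sl], self.col_players[sl]
        n_rounds, n_pairs = rp.shape
        rounds = np.repeat(np.arange(start, stop), n_pairs)
        g = self.game_of_pair[sl].ravel()
        a_row = np.take_along_axis(self.actions[sl], rp, axis=1).ravel()
        a_col = np.take_along_axis(self.actions[sl], cp, axis=1).ravel()
        pay_row = self.rows[g, a_row, a_col]
        pay_col = self.cols[g, a_row, a_col]
        br_row = self.rows.argmax(axis=1)[g, a_col]
        br_col = self.cols.argmax(axis=2)[g, a_row]
        return pd.DataFrame(
            {
                "round": rounds,
                "game": g,
                "row_agent": rp.ravel(),
                "col_agent": cp.ravel(),
                "row_action": a_row,
                "col_action": a_col,
                "row_payoff": pay_row,
                "col_payoff": pay_col,
                "row_best_response": br_row,
                "col_best_response": br_col,
            }
        )


def _seed_streams(master_seed: int, label: str):
    """Named, order-independent child RNGs for one session."""
    root = np.random.SeedSequence([int(master_seed), _CLASS_INDEX[label]])
    init_ss, game_ss, match_ss, choice_ss = root.spawn(4)
    return (
        np.random.default_rng(init_ss),
        np.random.default_rng(game_ss),
        np.random.default_rng(match_ss),
        np.random.default_rng(choice_ss),
    )


def run_training(config: SimulationConfig) -> TrainingResult:
    """Train a fresh population per ``config``; see the module docstring.

    The inner loop is vectorized over agents: one forward/backward pass of
    stacked parameter arrays per round.  Parameters are checked for
    finiteness at every trace block; divergence aborts with the offending
    round in the message.
    """
    m = config.n_agents
    n = config.n_training_games
    pairs = m // 2
    init_rng, game_rng, match_rng, choice_rng = _seed_streams(
        config.master_seed, config.training_class
    )
    pop = Population.initialize(
        m, init_rng, eta=config.eta, init_scale=config.init_scale, loss=config.loss
    )
    if n == 0:
        empty = np.zeros((0, pairs), dtype=np.int64)
        return TrainingResult(
            config, pop, np.zeros(0), np.zeros((0, 2, 2)), np.zeros((0, 2, 2)),
            np.zeros((0, m), dtype=np.int8), empty, empty, empty,
        )

    n_games = n if config.shared_round_game else n * pairs
    rows, cols = G.generate_games(config.training_class, n_games, game_rng)
    if config.shared_round_game:
        game_of_pair = np.broadcast_to(np.arange(n)[:, None], (n, pairs)).copy()
    else:
        game_of_pair = np.arange(n_games).reshape(n, pairs)
    enc_row, enc_col = encode_both_roles(rows, cols)
    br_row = rows.argmax(axis=1).astype(np.int8)  # (g, 2): row BR to col action j
    br_col = cols.argmax(axis=2).astype(np.int8)  # (g, 2): col BR to row action i

    # pre-drawn matching and choice randomness
    perms = match_rng.permuted(
        np.broadcast_to(np.arange(m), (n, m)).copy(), axis=1
    ).reshape(n, pairs, 2)
    swap = match_rng.random((n, pairs)) < 0.5
    row_players = np.where(swap, perms[:, :, 1], perms[:, :, 0])
    col_players = np.where(swap, perms[:, :, 0], perms[:, :, 1])
    is_row = np.zeros((n, m), dtype=bool)
    np.put_along_axis(is_row, row_players, True, axis=1)
    game_of_agent = np.empty((n, m), dtype=np.int64)
    np.put_along_axis(game_of_agent, row_players, game_of_pair, axis=1)
    np.put_along_axis(game_of_agent, col_players, game_of_pair, axis=1)
    opp = np.empty((n, m), dtype=np.int64)
    np.put_along_axis(opp, row_players, col_players, axis=1)
    np.put_along_axis(opp, col_players, row_players, axis=1)
    unif = choice_rng.random((n, m))

    # per-agent perspective inputs and own best-response tables, resolved
    # ahead of the loop so each round is a handful of batched array ops
    x_all = np.where(
        is_row[:, :, None], enc_row[game_of_agent], enc_col[game_of_agent]
    )
    br_own = np.where(
        is_row[:, :, None], br_row[game_of_agent], br_col[game_of_agent]
    )
    agent_ix = np.arange(m)

    actions = np.empty((n, m), dtype=np.int8)
    block = config.convergence_window
    trace = np.zeros((n + block - 1) // block)
    block_sum = 0.0
    for r in range(n):
        p, cache = pop.forward(x_all[r])
        act = (unif[r] >= p[:, 0]).view(np.int8)
        actions[r] = act
        opp_act = act[opp[r]]
        target = br_own[r][agent_ix, opp_act]
        gp = game_of_pair[r]
        a_r = act[row_players[r]]
        a_c = act[col_players[r]]
        block_sum += rows[gp, a_r, a_c].sum() + cols[gp, a_r, a_c].sum()
        pop.update(cache, target)
        if (r + 1) % block == 0:
            trace[r // block] = block_sum / (block * m)
            block_sum = 0.0
            try:
                pop.check_finite()
            except FloatingPointError as err:
                raise FloatingPointError(f"{err} (round {r})") from None
    if n % block:
        trace[-1] = block_sum / ((n % block) * m)
    return TrainingResult(
        config, pop, trace, rows, cols, actions, row_players, col_players, game_of_pair
    )


@dataclass
class Evaluation:
    """Frozen-population behavior on one test set.

    - ``probs_row`` / ``probs_col``: (n_agents, n_games) probability of
      action 0 in the row / column chair;
    - ``row_choices``: (n_reps, n_agents, n_games) actions each agent
      samples as row player (used for choice agreement);
    - joint-play simulation per repetition: ``row_players`` /
      ``col_players`` (n_reps, n_games, n_pairs) agent ids, ``a_row`` /
      ``a_col`` sampled actions, ``pay_row`` / ``pay_col`` realized
      payoffs.
    """

    rows: np.ndarray
    cols: np.ndarray
    probs_row: np.ndarray
    probs_col: np.ndarray
    row_choices: np.ndarray
    row_players: np.ndarray
    col_players: np.ndarray
    a_row: np.ndarray
    a_col: np.ndarray
    pay_row: np.ndarray
    pay_col: np.ndarray

    @property
    def n_games(self) -> int:
        return self.rows.shape[0]

    def annotations(self) -> dict:
        """Equilibrium annotations of the test games (cached)."""
        if not hasattr(self, "_ann"):
            self._ann = G.equilibrium_annotations(self.rows, self.cols)
        return self._ann

    def mean_payoff(self) -> float:
        """Mean realized payoff over both members of every simulated
        pairing, all games, all repetitions."""
        return float((self.pay_row.mean() + self.pay_col.mean()) / 2.0)


def evaluate_frozen(
    population: Population,
    rows: np.ndarray,
    cols: np.ndarray,
    rng: np.random.Generator,
    n_reps: int = 1,
) -> Evaluation:
    """Simulate a frozen population on a test set; no weight updates.

    ``n_reps`` repeats the random pairing / sampling pass to reduce
    Monte-Carlo error of the joint statistics; choice probabilities are
    deterministic given the frozen weights.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    m = population.n_agents
    n = rows.shape[0]
    enc_row, enc_col = encode_both_roles(rows, cols)
    probs_row = population.forward_games(enc_row)[:, :, 0]
    probs_col = population.forward_games(enc_col)[:, :, 0]

    row_choices = (rng.random((n_reps, m, n)) >= probs_row[None]).astype(np.int8)

    pairs = m // 2
    perms = rng.permuted(
        np.broadcast_to(np.arange(m), (n_reps * n, m)).copy(), axis=1
    ).reshape(n_reps, n, pairs, 2)
    swap = rng.random((n_reps, n, pairs)) < 0.5
    row_players = np.where(swap, perms[..., 1], perms[..., 0])
    col_players = np.where(swap, perms[..., 0], perms[..., 1])
    g = np.arange(n)[None, :, None]
    a_row = (rng.random((n_reps, n, pairs)) >= probs_row[row_players, g]).astype(np.int8)
    a_col = (rng.random((n_reps, n, pairs)) >= probs_col[col_players, g]).astype(np.int8)
    pay_row = rows[g, a_row, a_col]
    pay_col = cols[g, a_row, a_col]
    return Evaluation(
        rows, cols, probs_row, probs_col, row_choices,
        row_players, col_players, a_row, a_col, pay_row, pay_col,
    )


@dataclass
class GridResult:
    """All artifacts of one 8x8 (or restricted) grid run."""

    base_config: SimulationConfig
    training_classes: tuple[str, ...]
    test_classes: tuple[str, ...]
    results: dict[str, TrainingResult]
    test_sets: dict[str, tuple[np.ndarray, np.ndarray]]
    evaluations: dict[tuple[str, str], Evaluation]

    def population(self, training_class: str) -> Population:
        return self.results[training_class].population


def run_grid(
    base_config: SimulationConfig,
    training_classes: tuple[str, ...] = G.TRAINING_CLASSES,
    test_classes: tuple[str, ...] = G.TRAINING_CLASSES,
    n_reps: int = 10,
    progress: bool = False,
) -> GridResult:
    """Train one population per training class and evaluate every
    population on every test class.

    Test sets are drawn once per test class from a dedicated seed stream
    and shared across populations, so grid columns are directly
    comparable.  Each training session owns its own seed stream derived
    from ``base_config.master_seed`` and the class label.
    """
    results: dict[str, TrainingResult] = {}
    for label in training_classes:
        cfg = SimulationConfig(**{**asdict(base_config), "training_class": label})
        if progress:  # pragma: no cover - cosmetic
            print(f"[grid seed={base_config.master_seed}] training on {label} ...")
        results[label] = run_training(cfg)

    test_root = np.random.SeedSequence([int(base_config.master_seed), 97, 1])
    test_sets = {}
    for label, ss in zip(test_classes, test_root.spawn(len(test_classes))):
        rng = np.random.default_rng(ss)
        test_sets[label] = G.generate_games(label, base_config.n_test_games, rng)

    eval_root = np.random.SeedSequence([int(base_config.master_seed), 97, 2])
    evaluations = {}
    cells = [(tr, te) for tr in training_classes for te in test_classes]
    for (tr, te), ss in zip(cells, eval_root.spawn(len(cells))):
        rows, cols = test_sets[te]
        evaluations[(tr, te)] = evaluate_frozen(
            results[tr].population, rows, cols, np.random.default_rng(ss), n_reps=n_reps
        )
    return GridResult(
        base_config, tuple(training_classes), tuple(test_classes),
        results, test_sets, evaluations,
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_population(path, result: TrainingResult) -> None:
    """Versioned checkpoint directory: per-layer weight/bias ``.npy``
    files, the convergence trace, and a JSON provenance record (training
    class, seed, games played, learning rate).  Byte-deterministic for a
    given population, so checkpoints participate in manifest checksums."""
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pop = result.population
    for k, (w, b) in enumerate(zip(pop.weights, pop.biases)):
        np.save(path / f"w{k}.npy", w)
        np.save(path / f"b{k}.npy", b)
    np.save(path / "trace.npy", result.trace)
    meta = {
        "version": 1,
        "training_class": result.config.training_class,
        "master_seed": result.config.master_seed,
        "n_training_games": result.config.n_training_games,
        "eta": pop.eta,
        "loss": pop.loss,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_population(path) -> tuple[Population, dict]:
    """Load a checkpoint directory; returns the population and its
    provenance (including the convergence trace)."""
    import json

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    n_layers = len(list(path.glob("w*.npy")))
    pop = Population(
        [np.load(path / f"w{k}.npy") for k in range(n_layers)],
        [np.load(path / f"b{k}.npy") for k in range(n_layers)],
        eta=float(meta["eta"]),
        loss=str(meta["loss"]),
    )
    meta["trace"] = np.load(path / "trace.npy")
    return pop, meta
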