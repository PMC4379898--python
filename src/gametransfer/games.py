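"""2x2 normal-form games: generation, classification, and equilibrium analysis.

This module provides the game-theoretic substrate for the learning
simulations: random generators for seven well-studied classes of generic
2x2 games (zero-sum, Prisoner's dilemma, discoordination / mixed-strategy,
stag hunt, chicken, battle of the sexes, no-conflict), a structural
classifier that inverts the generators, pure- and mixed-strategy Nash
solvers, strict-dominance analysis, Harsanyi-Selten payoff/risk dominance
labels, and the lambda-parameterized loop of games that morphs
PD -> SH -> NC -> CH -> PD in small payoff increments.

Conventions
-----------
A game is a pair of 2x2 payoff arrays ``(row, col)`` with all payoffs in
[-1, 1].  Cell ``(i, j)`` means the row player chose action ``i`` and the
column player action ``j``; both actions are indexed 0 and 1.  Batched
operations act on arrays of shape ``(n, 2, 2)`` and are the fast path used
by the simulation engine; scalar wrappers operate on :class:`Game2x2`.

Generators produce *generic* games: within each player's four payoffs any
two values differ by at least ``GENERIC_MARGIN`` so that every ordinal
comparison used by the classifier is strict.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GAME_CLASSES",
    "ALL",
    "TRAINING_CLASSES",
    "GENERIC_MARGIN",
    "Game2x2",
    "EquilibriumReport",
    "TransformStep",
    "generate_games",
    "generate_game",
    "classify_games",
    "classify_game",
    "pure_nash_mask",
    "pure_nash",
    "mixed_nash",
    "mixed_nash_batch",
    "dominance_analysis",
    "dominance_labels",
    "equilibrium_report",
    "equilibrium_annotations",
    "default_transform_bases",
    "build_transform_loop",
    "save_transform_bases",
    "load_transform_bases",
    "DEFAULT_LAMBDA_GRID",
    "games_to_frame",
    "frame_to_games",
    "save_games_jsonl",
    "load_games_jsonl",
]

#: The seven concrete game classes, in the conventional display order.
GAME_CLASSES = ("ZS", "PD", "MS", "SH", "CH", "BOS", "NC")

#: Pseudo-class: games drawn uniformly from the seven concrete classes.
ALL = "ALL"

#: The eight training conditions.
TRAINING_CLASSES = GAME_CLASSES + (ALL,)

#: Minimum separation between any two payoffs of one player in generated
#: games; guarantees strict ordinal comparisons for the classifier.
GENERIC_MARGIN = 1e-3

_UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Game2x2:
    """A bimatrix 2x2 game with payoffs in [-1, 1].

    Attributes
    ----------
    row, col
        2x2 payoff arrays for the row and column player.  ``row[i, j]`` is
        the row player's payoff when she plays ``i`` and the opponent
        plays ``j``.
    """

    row: np.ndarray
    col: np.ndarray

    def __post_init__(self) -> None:
        row = np.asarray(self.row, dtype=float)
        col = np.asarray(self.col, dtype=float)
        if row.shape != (2, 2) or col.shape != (2, 2):
            raise ValueError("payoff arrays must be exactly 2x2")
        if not (np.isfinite(row).all() and np.isfinite(col).all()):
            raise ValueError("payoffs must be finite")
        if np.abs(row).max() > 1 + 1e-12 or np.abs(col).max() > 1 + 1e-12:
            raise ValueError("payoffs must lie in [-1, 1]")
        object.__setattr__(self, "row", row)
        object.__setattr__(self, "col", col)

    def transpose(self) -> "Game2x2":
        """The same game seen from the column player's chair.

        Roles are swapped: the new row payoff matrix is the old column
        player's matrix transposed, and vice versa.
        """
        return Game2x2(self.col.T.copy(), self.row.T.copy())

    def to_dict(self, label: str | None = None) -> dict:
        d = {"row": self.row.tolist(), "col": self.col.tolist()}
        if label is not None:
            d["class"] = label
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Game2x2":
        return cls(np.array(d["row"], dtype=float), np.array(d["col"], dtype=float))


@dataclass(frozen=True)
class EquilibriumReport:
    """Full equilibrium summary of one game.

    ``psne`` lists pure-strategy Nash profiles ``(i, j)`` in lexicographic
    order.  ``msne`` is the interior mixed equilibrium as probabilities of
    action 0, ``(p_row, p_col)``, or ``None``.  ``payoff_dominant`` and
    ``risk_dominant`` index into ``psne`` and are set only when the game
    has exactly two pure equilibria.
    """

    psne: tuple[tuple[int, int], ...]
    msne: tuple[float, float] | None
    dominance_solvable: bool
    payoff_dominant: int | None = None
    risk_dominant: int | None = None


@dataclass(frozen=True)
class TransformStep:
    """One game of the PD->SH->NC->CH->PD transformation loop."""

    lambda_value: float
    source_class: str
    target_class: str
    game: Game2x2
    label: str = field(default="")  # classifier output for this game


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _quadruples(rng: np.random.Generator, n: int, margin: float) -> np.ndarray:
    """n rows of 4 payoffs, iid uniform on [-1, 1], sorted descending,
    resampled until consecutive gaps are all >= margin."""
    out = np.empty((n, 4))
    pending = np.arange(n)
    while pending.size:
        u = np.sort(rng.uniform(-1.0, 1.0, (pending.size, 4)), axis=1)[:, ::-1]
        ok = (-np.diff(u, axis=1) >= margin).all(axis=1)
        out[pending[ok]] = u[ok]
        pending = pending[~ok]
    return out


def _permuted_rows(rng: np.random.Generator, v: np.ndarray) -> np.ndarray:
    """Independently permute each row of v."""
    idx = np.argsort(rng.random(v.shape), axis=1)
    return np.take_along_axis(v, idx, axis=1)


def _cells(values: Sequence[np.ndarray]) -> np.ndarray:
    """Stack per-cell columns (00, 01, 10, 11) into an (n, 2, 2) array."""
    return np.stack(values, axis=1).reshape(-1, 2, 2)


def _gen_zs(rng, n, margin):
    row = _cells(list(_permuted_rows(rng, _quadruples(rng, n, margin)).T))
    return row, -row


def _gen_pd(rng, n, margin):
    # Ordinal pattern T > R > P > S per player; action 1 = defect.
    v = _quadruples(rng, n, margin)  # v0 > v1 > v2 > v3
    row = _cells([v[:, 1], v[:, 3], v[:, 0], v[:, 2]])  # R, S, T, P
    w = _quadruples(rng, n, margin)
    col = _cells([w[:, 1], w[:, 0], w[:, 3], w[:, 2]])  # R, T, S, P
    return row, col


def _gen_sh(rng, n, margin):
    # Stag hunt: R > T > P > S; both pure equilibria on the diagonal,
    # (0, 0) payoff-dominant.
    v = _quadruples(rng, n, margin)
    row = _cells([v[:, 0], v[:, 3], v[:, 1], v[:, 2]])  # R, S, T, P
    w = _quadruples(rng, n, margin)
    col = _cells([w[:, 0], w[:, 1], w[:, 3], w[:, 2]])
    return row, col


def _gen_ch(rng, n, margin):
    # Chicken: T > R > S > P; pure equilibria off-diagonal.
    v = _quadruples(rng, n, margin)
    row = _cells([v[:, 1], v[:, 2], v[:, 0], v[:, 3]])  # R, S, T, P
    w = _quadruples(rng, n, margin)
    col = _cells([w[:, 1], w[:, 0], w[:, 2], w[:, 3]])
    return row, col


def _gen_bos(rng, n, margin):
    # Battle of the sexes: both prefer coordinating, row favors (0,0),
    # column favors (1,1); the two miscoordination cells are both players'
    # two worst outcomes, in random order.
    v = _quadruples(rng, n, margin)
    lo = _permuted_rows(rng, v[:, 2:])
    row = _cells([v[:, 0], lo[:, 0], lo[:, 1], v[:, 1]])
    w = _quadruples(rng, n, margin)
    lo = _permuted_rows(rng, w[:, 2:])
    col = _cells([w[:, 1], lo[:, 0], lo[:, 1], w[:, 0]])
    return row, col


def _gen_ms(rng, n, margin):
    # Discoordination: one player (drawn at random) wants to match the
    # opponent's action, the other wants to mismatch; no pure equilibrium.
    def matcher_row(values):
        s = _permuted_rows(rng, values)
        a, b = np.maximum(s[:, 0], s[:, 1]), np.minimum(s[:, 0], s[:, 1])
        c, d = np.maximum(s[:, 2], s[:, 3]), np.minimum(s[:, 2], s[:, 3])
        return _cells([a, d, b, c])  # r00 > r10, r11 > r01

    def mismatcher_row(values):
        s = _permuted_rows(rng, values)
        a, b = np.maximum(s[:, 0], s[:, 1]), np.minimum(s[:, 0], s[:, 1])
        c, d = np.maximum(s[:, 2], s[:, 3]), np.minimum(s[:, 2], s[:, 3])
        return _cells([b, c, a, d])  # r10 > r00, r01 > r11

    def matcher_col(values):
        s = _permuted_rows(rng, values)
        a, b = np.maximum(s[:, 0], s[:, 1]), np.minimum(s[:, 0], s[:, 1])
        c, d = np.maximum(s[:, 2], s[:, 3]), np.minimum(s[:, 2], s[:, 3])
        return _cells([a, b, d, c])  # c00 > c01, c11 > c10

    def mismatcher_col(values):
        s = _permuted_rows(rng, values)
        a, b = np.maximum(s[:, 0], s[:, 1]), np.minimum(s[:, 0], s[:, 1])
        c, d = np.maximum(s[:, 2], s[:, 3]), np.minimum(s[:, 2], s[:, 3])
        return _cells([b, a, c, d])  # c01 > c00, c10 > c11

    v, w = _quadruples(rng, n, margin), _quadruples(rng, n, margin)
    row_is_matcher = rng.random(n) < 0.5
    row = np.where(
        row_is_matcher[:, None, None], matcher_row(v), mismatcher_row(v)
    )
    col = np.where(
        row_is_matcher[:, None, None], mismatcher_col(w), matcher_col(w)
    )
    return row, col


def _gen_nc(rng, n, margin):
    # No conflict: both players' maximum payoff sits in the same cell —
    # canonically (0, 0) — and that cell is the unique pure equilibrium.
    # The remaining payoffs are random; draws with a second pure
    # equilibrium are rejected and resampled.
    row = np.empty((n, 2, 2))
    col = np.empty((n, 2, 2))
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        v, w = _quadruples(rng, m, margin), _quadruples(rng, m, margin)
        r = _permuted_rows(rng, v[:, 1:])
        c = _permuted_rows(rng, w[:, 1:])
        rr = np.concatenate([v[:, :1], r], axis=1).reshape(m, 2, 2)
        cc = np.concatenate([w[:, :1], c], axis=1).reshape(m, 2, 2)
        unique = pure_nash_mask(rr, cc).sum(axis=(1, 2)) == 1
        row[pending[unique]] = rr[unique]
        col[pending[unique]] = cc[unique]
        pending = pending[~unique]
    return row, col


_GENERATORS = {
    "ZS": _gen_zs,
    "PD": _gen_pd,
    "MS": _gen_ms,
    "SH": _gen_sh,
    "CH": _gen_ch,
    "BOS": _gen_bos,
    "NC": _gen_nc,
}


def generate_games(
    game_class: str,
    n: int,
    rng: np.random.Generator,
    *,
    margin: float = GENERIC_MARGIN,
    canonical: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` random generic games of one class (batched fast path).

    Parameters
    ----------
    game_class
        One of the seven concrete classes, or ``"ALL"`` for a uniform
        mixture over the seven.
    n
        Number of games.
    rng
        NumPy random generator; the only source of randomness.
    margin
        Minimum payoff separation within each player's four payoffs.
    canonical
        By default every class keeps its canonical ordinal layout, as in
        the classic 2x2 taxonomies: defection is action 1 in every
        Prisoner's dilemma, the payoff-dominant stag-hunt equilibrium and
        the no-conflict optimum sit at (0, 0), chicken's equilibria are
        off-diagonal.  With ``canonical=False`` both players' action
        labels are jointly reversed with probability 1/2 per game — a
        game isomorphism that strips class information from action
        positions (useful for probing whether learned behavior reads
        payoffs or positions) while leaving every equilibrium property
        intact.

    Returns
    -------
    (row, col)
        Arrays of shape ``(n, 2, 2)``.
    """
    if game_class == ALL:
        labels = np.asarray(GAME_CLASSES)[rng.integers(0, len(GAME_CLASSES), n)]
        row = np.empty((n, 2, 2))
        col = np.empty((n, 2, 2))
        for c in GAME_CLASSES:
            idx = np.flatnonzero(labels == c)
            if idx.size:
                row[idx], col[idx] = _GENERATORS[c](rng, idx.size, margin)
    else:
        try:
            gen = _GENERATORS[game_class]
        except KeyError:
            raise ValueError(f"unknown game class: {game_class!r}") from None
        row, col = gen(rng, n, margin)
    if not canonical:
        flip = rng.random(n) < 0.5
        row[flip] = row[flip, ::-1, ::-1]
        col[flip] = col[flip, ::-1, ::-1]
    return row, col


def generate_game(
    game_class: str,
    rng: np.random.Generator,
    *,
    margin: float = GENERIC_MARGIN,
    canonical: bool = True,
) -> Game2x2:
    """Draw a single random game of ``game_class`` (not ``ALL``)."""
    if game_class == ALL:
        raise ValueError("ALL is a training mixture, not a single-game class")
    row, col = generate_games(game_class, 1, rng, margin=margin, canonical=canonical)
    return Game2x2(row[0], col[0])


# ---------------------------------------------------------------------------
# Equilibrium analysis (batched)
# ---------------------------------------------------------------------------


def pure_nash_mask(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Boolean (n, 2, 2) mask of pure-strategy Nash cells.

    Cell (i, j) is marked iff i is a best response to j for the row player
    and j is a best response to i for the column player.  Ties count as
    best responses (irrelevant for generic games).
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    br_row = rows >= rows.max(axis=1, keepdims=True)
    br_col = cols >= cols.max(axis=2, keepdims=True)
    return br_row & br_col


def mixed_nash_batch(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Interior mixed equilibrium per game as an (n, 2) array.

    Column 0 is the row player's probability of action 0 (chosen to make
    the *column* player indifferent), column 1 the column player's
    probability of action 0 (making the *row* player indifferent).  Games
    without an interior mixed equilibrium get NaN in both entries.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (rows[:, 1, 1] - rows[:, 0, 1]) / (
            (rows[:, 0, 0] - rows[:, 1, 0]) + (rows[:, 1, 1] - rows[:, 0, 1])
        )
        p = (cols[:, 1, 1] - cols[:, 1, 0]) / (
            (cols[:, 0, 0] - cols[:, 0, 1]) + (cols[:, 1, 1] - cols[:, 1, 0])
        )
    out = np.stack([p, q], axis=1)
    interior = (out > 0).all(axis=1) & (out < 1).all(axis=1)
    out[~interior] = np.nan
    return out


def _dominant_actions(rows: np.ndarray, cols: np.ndarray):
    """Per-player strictly dominant action (0/1) or -1 if none."""
    rd = np.full(rows.shape[0], -1, dtype=np.int64)
    rd[(rows[:, 0] > rows[:, 1]).all(axis=1)] = 0
    rd[(rows[:, 1] > rows[:, 0]).all(axis=1)] = 1
    cd = np.full(cols.shape[0], -1, dtype=np.int64)
    cd[(cols[:, :, 0] > cols[:, :, 1]).all(axis=1)] = 0
    cd[(cols[:, :, 1] > cols[:, :, 0]).all(axis=1)] = 1
    return rd, cd


def equilibrium_annotations(rows: np.ndarray, cols: np.ndarray) -> dict:
    """Vectorized equilibrium annotation used by the analysis pipeline.

    Returns a dict of aligned arrays over the ``n`` games:

    - ``psne_mask``: (n, 2, 2) bool, pure Nash cells;
    - ``n_psne``: (n,) int, 0..2 for generic games;
    - ``pd_cell`` / ``rd_cell``: (n,) flat cell index (``2*i + j``) of the
      payoff-/risk-dominant equilibrium, or -1 when undefined (fewer than
      two pure equilibria, no Pareto ranking, or an exact Nash-product
      tie).
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    mask = pure_nash_mask(rows, cols)
    n_psne = mask.reshape(-1, 4).sum(axis=1)
    n = rows.shape[0]
    pd_cell = np.full(n, -1, dtype=np.int64)
    rd_cell = np.full(n, -1, dtype=np.int64)

    two = np.flatnonzero(n_psne == 2)
    if two.size:
        flat = mask.reshape(-1, 4)[two]
        cells = np.argsort(~flat, axis=1)[:, :2]  # the two PSNE, ascending
        a, b = cells[:, 0], cells[:, 1]
        ia, ja = a // 2, a % 2
        ib, jb = b // 2, b % 2
        k = np.arange(two.size)
        r = rows[two]
        c = cols[two]
        ra, ca = r[k, ia, ja], c[k, ia, ja]
        rb, cb = r[k, ib, jb], c[k, ib, jb]
        a_pareto = (ra > rb) & (ca > cb)
        b_pareto = (rb > ra) & (cb > ca)
        pd_cell[two[a_pareto]] = a[a_pareto]
        pd_cell[two[b_pareto]] = b[b_pareto]
        # Harsanyi-Selten risk dominance: larger Nash product of
        # unilateral deviation losses.
        prod_a = (ra - r[k, ib, ja]) * (ca - c[k, ia, jb])
        prod_b = (rb - r[k, ia, jb]) * (cb - c[k, ib, ja])
        rd_cell[two[prod_a > prod_b]] = a[prod_a > prod_b]
        rd_cell[two[prod_b > prod_a]] = b[prod_b > prod_a]
    return {"psne_mask": mask, "n_psne": n_psne, "pd_cell": pd_cell, "rd_cell": rd_cell}


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _rank_in_cells(payoffs: np.ndarray, flat_cells: np.ndarray) -> np.ndarray:
    """Ranks (1 = best) of a player's payoffs at the given flat cells."""
    order = np.argsort(np.argsort(-payoffs.reshape(-1, 4), axis=1), axis=1) + 1
    return np.take_along_axis(order, flat_cells, axis=1)


def classify_games(
    rows: np.ndarray,
    cols: np.ndarray,
    *,
    zs_tol: float = 1e-9,
) -> np.ndarray:
    """Classify each game into one of the seven classes or "unclassified".

    The zero-sum test (elementwise payoff-sum identity within ``zs_tol``)
    runs before any ordinal test.  Games with an exact payoff tie within
    either player's four payoffs are degenerate and come back
    "unclassified", as do generic games matching no class signature.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    n = rows.shape[0]
    out = np.full(n, _UNCLASSIFIED, dtype=object)

    # degenerate: a tie inside some best-response comparison
    degenerate = (rows[:, 0, :] == rows[:, 1, :]).any(axis=1) | (
        cols[:, :, 0] == cols[:, :, 1]
    ).any(axis=1)
    zs = (np.abs(rows + cols) <= zs_tol).all(axis=(1, 2)) & ~degenerate
    out[zs] = "ZS"
    todo = ~zs & ~degenerate
    if not todo.any():
        return out

    mask = pure_nash_mask(rows, cols)
    n_psne = mask.reshape(-1, 4).sum(axis=1)
    out[todo & (n_psne == 0)] = "MS"

    one = np.flatnonzero(todo & (n_psne == 1))
    if one.size:
        cell = mask.reshape(-1, 4)[one].argmax(axis=1)
        i, j = cell // 2, cell % 2
        k = np.arange(one.size)
        r, c = rows[one], cols[one]
        # No conflict: both players' maxima in the equilibrium cell.
        nc = (r[k, i, j] == r.reshape(-1, 4).max(axis=1)) & (
            c[k, i, j] == c.reshape(-1, 4).max(axis=1)
        )
        out[one[nc]] = "NC"
        # Prisoner's dilemma: dominant-strategy equilibrium strictly
        # Pareto-dominated by the diagonally opposite cell.
        rd, cd = _dominant_actions(r, c)
        pdil = (
            (rd == i)
            & (cd == j)
            & (r[k, 1 - i, 1 - j] > r[k, i, j])
            & (c[k, 1 - i, 1 - j] > c[k, i, j])
        )
        out[one[pdil & ~nc]] = "PD"

    two = np.flatnonzero(todo & (n_psne == 2))
    if two.size:
        flat = mask.reshape(-1, 4)[two]
        cells = np.argsort(~flat, axis=1)[:, :2]
        a, b = cells[:, 0], cells[:, 1]
        ia, ja = a // 2, a % 2
        ib, jb = b // 2, b % 2
        k = np.arange(two.size)
        r, c = rows[two], cols[two]
        ra, ca = r[k, ia, ja], c[k, ia, ja]
        rb, cb = r[k, ib, jb], c[k, ib, jb]
        pareto = ((ra > rb) & (ca > cb)) | ((rb > ra) & (cb > ca))
        # the BOS/CH rank tests need all four payoffs of each player
        # strictly ordered; tied games stay unclassified here
        strict = ((np.diff(np.sort(r.reshape(-1, 4), axis=1), axis=1) > 0).all(axis=1)
                  & (np.diff(np.sort(c.reshape(-1, 4), axis=1), axis=1) > 0).all(axis=1))
        # Ranks of each player's payoffs at the two equilibrium cells.
        r_ranks = np.sort(_rank_in_cells(r, cells), axis=1)
        c_ranks = np.sort(_rank_in_cells(c, cells), axis=1)
        bos = (r_ranks == [1, 2]).all(axis=1) & (c_ranks == [1, 2]).all(axis=1)
        ch = (r_ranks == [1, 3]).all(axis=1) & (c_ranks == [1, 3]).all(axis=1)
        out[two[pareto]] = "SH"
        out[two[~pareto & bos & strict]] = "BOS"
        out[two[~pareto & ch & strict]] = "CH"
    return out


def classify_game(game: Game2x2) -> str:
    """Classify a single game; see :func:`classify_games`."""
    return str(classify_games(game.row[None], game.col[None])[0])


# ---------------------------------------------------------------------------
# Scalar solver interface
# ---------------------------------------------------------------------------


def pure_nash(game: Game2x2) -> list[tuple[int, int]]:
    """Pure-strategy Nash profiles, lexicographically sorted."""
    mask = pure_nash_mask(game.row[None], game.col[None])[0]
    return [(int(i), int(j)) for i in (0, 1) for j in (0, 1) if mask[i, j]]


def mixed_nash(game: Game2x2) -> tuple[float, float] | None:
    """Interior mixed equilibrium ``(p_row, p_col)`` (probabilities of
    action 0) or ``None`` when the game has no interior mixed equilibrium
    (e.g. dominance-solvable games)."""
    pq = mixed_nash_batch(game.row[None], game.col[None])[0]
    if np.isnan(pq).any():
        return None
    return float(pq[0]), float(pq[1])


@dataclass(frozen=True)
class DominanceReport:
    """Strict-dominance summary: per-player dominant action (or None) and
    whether iterated elimination of strictly dominated actions pins down a
    single cell."""

    row_dominant: int | None
    col_dominant: int | None
    solvable: bool


def dominance_analysis(game: Game2x2) -> DominanceReport:
    """Strict dominance only.  A 2x2 game is dominance solvable iff at
    least one player has a strictly dominant action: after eliminating the
    dominated action, the opponent's unique best response leaves one cell."""
    rd, cd = _dominant_actions(game.row[None], game.col[None])
    return DominanceReport(
        row_dominant=None if rd[0] < 0 else int(rd[0]),
        col_dominant=None if cd[0] < 0 else int(cd[0]),
        solvable=bool(rd[0] >= 0 or cd[0] >= 0),
    )


def dominance_labels(
    game: Game2x2, psne: Sequence[tuple[int, int]]
) -> tuple[int | None, int | None]:
    """Payoff- and risk-dominance labels for a game with two pure equilibria.

    Returns indices into ``psne``: the payoff-dominant equilibrium (strictly
    Pareto-superior for both players; ``None`` if neither dominates, as in
    battle of the sexes) and the risk-dominant one (strictly larger Nash
    product of unilateral deviation losses; ``None`` on an exact tie).
    """
    if len(psne) != 2:
        raise ValueError("dominance labels require exactly two pure equilibria")
    ann = equilibrium_annotations(game.row[None], game.col[None])
    flat = [2 * i + j for i, j in psne]

    def to_index(cell):
        return flat.index(int(cell)) if cell >= 0 else None

    return to_index(ann["pd_cell"][0]), to_index(ann["rd_cell"][0])


def equilibrium_report(game: Game2x2) -> EquilibriumReport:
    """Assemble the full :class:`EquilibriumReport` for one game."""
    psne = pure_nash(game)
    payoff_dom = risk_dom = None
    if len(psne) == 2:
        payoff_dom, risk_dom = dominance_labels(game, psne)
    return EquilibriumReport(
        psne=tuple(psne),
        msne=mixed_nash(game),
        dominance_solvable=dominance_analysis(game).solvable,
        payoff_dominant=payoff_dom,
        risk_dominant=risk_dom,
    )


# ---------------------------------------------------------------------------
# The transformation loop
# ---------------------------------------------------------------------------

#: Default lambda increments within each leg of the loop.
DEFAULT_LAMBDA_GRID = tuple(round(0.01 * k, 2) for k in range(1, 25))

# Symmetric base games (col = row.T), payoff sets {+-0.125, +-0.375}.
# Consecutive bases differ in exactly two row-player cells (hence four of
# the eight payoffs), each by 0.25, and each change shifts the rank of the
# coupled payoffs by exactly one.
_BASE_ROW = {
    "PD": np.array([[0.125, -0.375], [0.375, -0.125]]),
    "SH": np.array([[0.375, -0.375], [0.125, -0.125]]),
    "NC": np.array([[0.375, -0.125], [0.125, -0.375]]),
    "CH": np.array([[0.125, -0.125], [0.375, -0.375]]),
}

#: Class order of the closed loop.
TRANSFORM_ORDER = ("PD", "SH", "NC", "CH")


def default_transform_bases() -> list[Game2x2]:
    """The four symmetric base games of the transformation loop, in loop
    order PD, SH, NC, CH."""
    return [Game2x2(_BASE_ROW[c], _BASE_ROW[c].T) for c in TRANSFORM_ORDER]


def _validate_bases(bases: Sequence[Game2x2]) -> None:
    if len(bases) != 4:
        raise ValueError("the loop needs exactly four base games")
    labels = [classify_game(g) for g in bases]
    if tuple(labels) != TRANSFORM_ORDER:
        raise ValueError(f"base games must classify as {TRANSFORM_ORDER}, got {labels}")
    stack_r = np.stack([g.row for g in bases])
    stack_c = np.stack([g.col for g in bases])
    for k in range(4):
        g, h = bases[k], bases[(k + 1) % 4]
        changed = (g.row != h.row).sum() + (g.col != h.col).sum()
        if changed != 4:
            raise ValueError(
                f"consecutive bases must differ in exactly 4 payoffs, got {changed}"
            )
        for p, q in ((g.row, h.row), (g.col, h.col)):
            rk_p = np.argsort(np.argsort(-p.ravel()))
            rk_q = np.argsort(np.argsort(-q.ravel()))
            if np.abs(rk_p - rk_q).max() > 1:
                raise ValueError("a transformation shifts some payoff rank by > 1")
        vals = np.sort(np.concatenate([g.row.ravel(), g.col.ravel()]))
        if not np.allclose(vals + vals[::-1], 0, atol=1e-12):
            raise ValueError("base-game payoffs must be symmetric about zero")
    span = max(
        (stack_r.max(axis=0) - stack_r.min(axis=0)).max(),
        (stack_c.max(axis=0) - stack_c.min(axis=0)).max(),
    )
    if span > 0.5 + 1e-12:
        raise ValueError(f"per-cell payoff span across the loop is {span} > 0.5")


def build_transform_loop(
    base_games: Sequence[Game2x2] | None = None,
    lambda_grid: Iterable[float] | None = None,
) -> list[TransformStep]:
    """Build the closed PD->SH->NC->CH->PD sequence of games.

    Each leg starts at a base game (lambda = 0) and linearly increments the
    four changing payoffs toward the next base; with the default grid
    (lambda = 0.01 .. 0.24, base spacing 0.25) this yields 4 boundary games
    plus 96 interior games, 100 in total, and the step after the last game
    is the first game again.

    Every game in the sequence is classified and the label recorded, so
    downstream profiles can locate the class boundaries.
    """
    bases = list(base_games) if base_games is not None else default_transform_bases()
    _validate_bases(bases)
    grid = sorted(lambda_grid) if lambda_grid is not None else list(DEFAULT_LAMBDA_GRID)
    if grid and grid[0] <= 0:
        raise ValueError("lambda increments must be positive")
    steps: list[TransformStep] = []
    for k in range(4):
        src, dst = bases[k], bases[(k + 1) % 4]
        gap_r, gap_c = dst.row - src.row, dst.col - src.col
        # direction: +-1 on changing cells, 0 elsewhere; per-cell change
        # magnitude is uniform by construction of the bases.
        scale = np.abs(np.concatenate([gap_r.ravel(), gap_c.ravel()])).max()
        for lam in [0.0] + grid:
            if lam >= scale:
                raise ValueError("lambda grid exceeds the base-game spacing")
            row = src.row + gap_r * (lam / scale)
            col = src.col + gap_c * (lam / scale)
            game = Game2x2(row, col)
            steps.append(
                TransformStep(
                    lambda_value=float(lam),
                    source_class=TRANSFORM_ORDER[k],
                    target_class=TRANSFORM_ORDER[(k + 1) % 4],
                    game=game,
                    label=classify_game(game),
                )
            )
    return steps


def save_transform_bases(
    path,
    bases: Sequence[Game2x2] | None = None,
    lambda_grid: Iterable[float] | None = None,
) -> None:
    """Write the loop's four base games and lambda grid as a JSON fixture."""
    bases = list(bases) if bases is not None else default_transform_bases()
    _validate_bases(bases)
    grid = list(lambda_grid) if lambda_grid is not None else list(DEFAULT_LAMBDA_GRID)
    doc = {
        "classes": list(TRANSFORM_ORDER),
        "bases": [g.to_dict(label) for g, label in zip(bases, TRANSFORM_ORDER)],
        "lambda_grid": grid,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_transform_bases(path) -> tuple[list[Game2x2], list[float]]:
    """Read a loop fixture written by :func:`save_transform_bases`."""
    with open(path) as fh:
        doc = json.load(fh)
    bases = [Game2x2.from_dict(d) for d in doc["bases"]]
    return bases, [float(x) for x in doc["lambda_grid"]]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PAYOFF_COLUMNS = ["r00", "r01", "r10", "r11", "c00", "c01", "c10", "c11"]


def games_to_frame(
    rows: np.ndarray, cols: np.ndarray, labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Batched games as a DataFrame with the eight payoff columns."""
    data = np.concatenate(
        [np.asarray(rows).reshape(-1, 4), np.asarray(cols).reshape(-1, 4)], axis=1
    )
    frame = pd.DataFrame(data, columns=_PAYOFF_COLUMNS)
    if labels is not None:
        frame.insert(0, "class", list(labels))
    return frame


def frame_to_games(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`games_to_frame`."""
    rows = frame[_PAYOFF_COLUMNS[:4]].to_numpy(dtype=float).reshape(-1, 2, 2)
    cols = frame[_PAYOFF_COLUMNS[4:]].to_numpy(dtype=float).reshape(-1, 2, 2)
    return rows, cols


def save_games_jsonl(
    path, rows: np.ndarray, cols: np.ndarray, labels: Sequence[str] | None = None
) -> None:
    """One game per line: {"class": ..., "row": [[..]], "col": [[..]]}."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    with open(path, "w") as fh:
        for k in range(rows.shape[0]):
            d = {"row": rows[k].tolist(), "col": cols[k].tolist()}
            if labels is not None:
                d = {"class": str(labels[k]), **d}
            fh.write(json.dumps(d) + "\n")


def load_games_jsonl(path) -> tuple[np.ndarray, np.ndarray, list[str | None]]:
    """Read a JSON-lines game file; returns (rows, cols, labels)."""
    rows, cols, labels = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            rows.append(d["row"])
            cols.append(d["col"])
            labels.append(d.get("class"))
    return np.array(rows, dtype=float), np.array(cols, dtype=float), labels
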