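"""Game generation, classification, and equilibrium solvers.

Brute-force oracles here enumerate the four cells (or the pairwise
strict-dominance comparisons) directly with scalar loops, independently
of the vectorized implementations they check.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gametransfer import games as G
from gametransfer.games import Game2x2


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_pure_nash(row, col):
    """Exhaustive mutual-best-response enumeration over the 4 cells."""
    out = []
    for i in (0, 1):
        for j in (0, 1):
            if row[i, j] >= row[1 - i, j] and col[i, j] >= col[i, 1 - j]:
                out.append((i, j))
    return out


def brute_dominant(payoffs, player):
    """Strictly dominant action of one player by pairwise comparison."""
    own = payoffs if player == "row" else payoffs.T
    if own[0, 0] > own[1, 0] and own[0, 1] > own[1, 1]:
        return 0
    if own[1, 0] > own[0, 0] and own[1, 1] > own[0, 1]:
        return 1
    return None


def brute_risk_dominant(row, col, eq_a, eq_b):
    """Nash products of unilateral deviation losses, from first principles."""
    (ia, ja), (ib, jb) = eq_a, eq_b
    prod_a = (row[ia, ja] - row[ib, ja]) * (col[ia, ja] - col[ia, jb])
    prod_b = (row[ib, jb] - row[ia, jb]) * (col[ib, jb] - col[ib, ja])
    if prod_a > prod_b:
        return 0
    if prod_b > prod_a:
        return 1
    return None


CANONICAL_PD = Game2x2([[0.5, -1.0], [1.0, -0.5]], [[0.5, 1.0], [-1.0, -0.5]])
MATCHING_PENNIES = Game2x2([[1, -1], [-1, 1]], [[-1, 1], [1, -1]])


# ---------------------------------------------------------------------------
# generators and classifier
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("game_class", G.GAME_CLASSES)
def test_generator_classifier_roundtrip(game_class):
    """Every draw of every class classifies back to its own class."""
    rng = np.random.default_rng(10)
    rows, cols = G.generate_games(game_class, 1000, rng)
    assert (G.classify_games(rows, cols) == game_class).all()
    assert np.abs(rows).max() <= 1 and np.abs(cols).max() <= 1


@pytest.mark.parametrize(
    "game_class, psne_counts, has_msne",
    [
        ("ZS", {0, 1}, None),  # either subtype allowed
        ("PD", {1}, False),
        ("MS", {0}, True),
        ("SH", {2}, True),
        ("CH", {2}, True),
        ("BOS", {2}, True),
        ("NC", {1}, False),
    ],
)
def test_equilibrium_signatures_per_class(game_class, psne_counts, has_msne):
    """Each class carries its defining pure/mixed equilibrium signature."""
    rng = np.random.default_rng(20)
    rows, cols = G.generate_games(game_class, 500, rng)
    n_psne = G.pure_nash_mask(rows, cols).sum(axis=(1, 2))
    assert set(np.unique(n_psne)) <= psne_counts
    msne = G.mixed_nash_batch(rows, cols)
    present = ~np.isnan(msne[:, 0])
    if has_msne is True:
        assert present.all()
    elif has_msne is False:
        assert not present.any()
    else:  # zero-sum: interior mixture exists exactly when there is no PSNE
        assert (present == (n_psne == 0)).all()


def test_zero_sum_conservation():
    rng = np.random.default_rng(30)
    rows, cols = G.generate_games("ZS", 1000, rng)
    assert np.array_equal(rows, -cols)


def test_coordination_geometry_of_draws():
    """CH puts both pure equilibria off-diagonal; SH and BOS require
    coordination (equilibria where actions must be matched)."""
    rng = np.random.default_rng(40)
    for cls, cells in (("CH", {(0, 1), (1, 0)}), ("SH", {(0, 0), (1, 1)}),
                       ("BOS", {(0, 0), (1, 1)})):
        rows, cols = G.generate_games(cls, 300, rng)
        mask = G.pure_nash_mask(rows, cols)
        want = np.zeros((2, 2), dtype=bool)
        for c in cells:
            want[c] = True
        assert (mask == want).all()


def test_pd_draw_structure(rng):
    """In the canonical layout defection (action 1) strictly dominates for
    both players and mutual cooperation Pareto-dominates the equilibrium;
    in the default layout the same holds up to a joint relabeling."""
    g = G.generate_game("PD", rng, canonical=True)
    assert brute_dominant(g.row, "row") == 1
    assert brute_dominant(g.col, "col") == 1
    assert g.row[0, 0] > g.row[1, 1] and g.col[0, 0] > g.col[1, 1]
    for _ in range(10):
        g = G.generate_game("PD", rng)
        d = brute_dominant(g.row, "row")
        assert d is not None and brute_dominant(g.col, "col") == d
        assert g.row[1 - d, 1 - d] > g.row[d, d]
        assert g.col[1 - d, 1 - d] > g.col[d, d]


def test_orientation_relabeling_is_isomorphism(rng):
    """Canonical draws pin the layout (stag-hunt payoff-dominant
    equilibrium at (0, 0), no-conflict optimum at (0, 0)); the optional
    random relabeling moves it without ever changing the class."""
    rows, cols = G.generate_games("SH", 200, rng)
    assert (G.equilibrium_annotations(rows, cols)["pd_cell"] == 0).all()
    rows, cols = G.generate_games("NC", 100, rng)
    assert (rows.reshape(-1, 4).argmax(axis=1) == 0).all()
    assert (cols.reshape(-1, 4).argmax(axis=1) == 0).all()
    rows, cols = G.generate_games("SH", 200, rng, canonical=False)
    assert (G.classify_games(rows, cols) == "SH").all()
    ann = G.equilibrium_annotations(rows, cols)
    # payoff-dominant equilibrium lands on both diagonal cells across draws
    assert set(np.unique(ann["pd_cell"])) == {0, 3}


def test_canonical_examples_classify():
    assert G.classify_game(MATCHING_PENNIES) == "ZS"  # zero-sum test first
    # same discoordination structure but not zero-sum -> MS
    ms = Game2x2([[1, -1], [-1, 1]], [[-0.9, 0.8], [0.7, -0.6]])
    assert G.classify_game(ms) == "MS"
    assert G.classify_game(CANONICAL_PD) == "PD"
    # both players' maximum in the same cell, unique equilibrium -> NC
    nc = Game2x2([[0.9, -0.2], [0.1, -0.6]], [[0.8, 0.3], [-0.1, -0.5]])
    assert G.classify_game(nc) == "NC"


def test_ties_unclassified():
    # exact tie inside a best-response comparison (r00 == r10)
    tied = Game2x2([[0.5, -0.2], [0.5, 0.1]], [[0.1, 0.2], [0.3, 0.4]])
    assert G.classify_game(tied) == "unclassified"


def test_generate_game_rejects_all():
    with pytest.raises(ValueError):
        G.generate_game("ALL", np.random.default_rng(0))


# ---------------------------------------------------------------------------
# solvers vs brute force
# ---------------------------------------------------------------------------


def test_pure_nash_matches_enumeration(random_game_pool):
    rows, cols = random_game_pool
    mask = G.pure_nash_mask(rows, cols)
    for k in range(0, rows.shape[0], 7):  # ~1,500 spot checks of the mask
        expect = brute_pure_nash(rows[k], cols[k])
        got = [(i, j) for i in (0, 1) for j in (0, 1) if mask[k, i, j]]
        assert got == expect
    # scalar interface returns sorted profiles
    assert G.pure_nash(CANONICAL_PD) == [(1, 1)]
    assert G.pure_nash(MATCHING_PENNIES) == []


def test_dominance_matches_brute_force(random_game_pool):
    rows, cols = random_game_pool
    for k in range(0, rows.shape[0], 7):
        g = Game2x2(rows[k], cols[k])
        rep = G.dominance_analysis(g)
        assert rep.row_dominant == brute_dominant(g.row, "row")
        assert rep.col_dominant == brute_dominant(g.col, "col")
        assert rep.solvable == (
            rep.row_dominant is not None or rep.col_dominant is not None
        )
    assert G.dominance_analysis(CANONICAL_PD).solvable
    sh = G.generate_game("SH", np.random.default_rng(3))
    assert not G.dominance_analysis(sh).solvable


def test_mixed_nash_indifference():
    """The mixture makes the opponent exactly indifferent (1e-9)."""
    rng = np.random.default_rng(50)
    for cls in ("SH", "CH", "BOS", "MS"):
        rows, cols = G.generate_games(cls, 300, rng)
        pq = G.mixed_nash_batch(rows, cols)
        p, q = pq[:, 0], pq[:, 1]
        # row indifferent given column mixes q on action 0
        row_diff = (q * rows[:, 0, 0] + (1 - q) * rows[:, 0, 1]) - (
            q * rows[:, 1, 0] + (1 - q) * rows[:, 1, 1]
        )
        col_diff = (p * cols[:, 0, 0] + (1 - p) * cols[:, 1, 0]) - (
            p * cols[:, 0, 1] + (1 - p) * cols[:, 1, 1]
        )
        assert np.abs(row_diff).max() < 1e-9
        assert np.abs(col_diff).max() < 1e-9
    assert G.mixed_nash(MATCHING_PENNIES) == (0.5, 0.5)
    assert G.mixed_nash(CANONICAL_PD) is None


def test_dominance_labels_vs_oracle():
    rng = np.random.default_rng(60)
    rows, cols = G.generate_games("SH", 400, rng)
    for k in range(400):
        g = Game2x2(rows[k], cols[k])
        psne = G.pure_nash(g)
        payoff_dom, risk_dom = G.dominance_labels(g, psne)
        # stag-hunt draws: the payoff-dominant equilibrium gives both
        # players their maximum payoff
        i, j = psne[payoff_dom]
        assert g.row[i, j] == g.row.max() and g.col[i, j] == g.col.max()
        assert risk_dom == brute_risk_dominant(g.row, g.col, *psne)


def test_risk_dominance_tie_absent():
    """A fully symmetric coordination game has equal Nash products."""
    g = Game2x2([[0.6, -0.4], [-0.4, 0.6]], [[0.6, -0.4], [-0.4, 0.6]])
    psne = G.pure_nash(g)
    payoff_dom, risk_dom = G.dominance_labels(g, psne)
    assert payoff_dom is None and risk_dom is None


def test_equilibrium_report_consistency(rng):
    for cls in G.GAME_CLASSES:
        g = G.generate_game(cls, rng)
        rep = G.equilibrium_report(g)
        assert rep.psne == tuple(G.pure_nash(g))
        if rep.msne is not None:
            assert 0 < rep.msne[0] < 1 and 0 < rep.msne[1] < 1
        if len(rep.psne) != 2:
            assert rep.payoff_dominant is None and rep.risk_dominant is None


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.sampled_from(G.GAME_CLASSES))
def test_generated_payoffs_are_generic(seed, cls):
    """Within each player's payoffs every pairwise gap is at least the
    genericity margin, so all ordinal comparisons are strict."""
    g = G.generate_game(cls, np.random.default_rng(seed))
    for p in (g.row, g.col):
        vals = np.sort(p.ravel())
        assert np.diff(vals).min() >= G.GENERIC_MARGIN - 1e-12


# ---------------------------------------------------------------------------
# transformation loop
# ---------------------------------------------------------------------------


def test_transform_loop_structure():
    steps = G.build_transform_loop()
    assert len(steps) == 100  # 4 boundary games + 96 interior
    # lambda = 0 games equal the base games
    bases = G.default_transform_bases()
    for leg in range(4):
        s = steps[25 * leg]
        assert s.lambda_value == 0.0
        assert np.array_equal(s.game.row, bases[leg].row)
        assert s.label == G.TRANSFORM_ORDER[leg]
    # closed loop: one more lambda step from the last game returns to start
    last, first = steps[-1].game, steps[0].game
    assert np.abs(first.row - last.row).max() <= 0.01 + 1e-12
    # per-cell span across the whole loop
    all_rows = np.stack([s.game.row for s in steps])
    span = (all_rows.max(axis=0) - all_rows.min(axis=0)).max()
    assert span <= 0.5 + 1e-12
    # class segments are contiguous runs covering all four classes
    labels = [s.label for s in steps]
    assert set(labels) == set(G.TRANSFORM_ORDER)
    changes = sum(labels[k] != labels[k - 1] for k in range(len(labels)))
    assert changes == 4  # circular sequence crosses exactly four boundaries


def test_transform_bases_differ_in_four_payoffs():
    bases = G.default_transform_bases()
    for k in range(4):
        g, h = bases[k], bases[(k + 1) % 4]
        assert (g.row != h.row).sum() + (g.col != h.col).sum() == 4


def test_transform_fixture_roundtrip(tmp_path):
    path = tmp_path / "loop.json"
    G.save_transform_bases(path)
    bases, grid = G.load_transform_bases(path)
    steps = G.build_transform_loop(bases, grid)
    ref = G.build_transform_loop()
    assert len(steps) == len(ref)
    for a, b in zip(steps, ref):
        assert np.array_equal(a.game.row, b.game.row)
        assert a.label == b.label


def test_transform_loop_validates_bases():
    bad = [G.generate_game("PD", np.random.default_rng(1)) for _ in range(4)]
    with pytest.raises(ValueError):
        G.build_transform_loop(bad)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_jsonl_and_frame_roundtrip(tmp_path, rng):
    rows, cols = G.generate_games("ALL", 50, rng)
    labels = G.classify_games(rows, cols)
    path = tmp_path / "games.jsonl"
    G.save_games_jsonl(path, rows, cols, labels)
    r2, c2, l2 = G.load_games_jsonl(path)
    assert np.allclose(rows, r2) and np.allclose(cols, c2)
    assert list(labels) == l2
    frame = G.games_to_frame(rows, cols, labels)
    assert list(frame.columns) == ["class", "r00", "r01", "r10", "r11",
                                   "c00", "c01", "c10", "c11"]
    r3, c3 = G.frame_to_games(frame)
    assert np.array_equal(rows, r3) and np.array_equal(cols, c3)


def test_game2x2_validation():
    with pytest.raises(ValueError):
        Game2x2([[2.0, 0], [0, 0]], [[0, 0], [0, 0]])
    with pytest.raises(ValueError):
        Game2x2(np.zeros((2, 3)), np.zeros((2, 2)))
    g = Game2x2([[0.1, 0.2], [0.3, 0.4]], [[0.4, 0.3], [0.2, 0.1]])
    t = g.transpose()
    assert np.array_equal(t.row, g.col.T) and np.array_equal(t.col, g.row.T)
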