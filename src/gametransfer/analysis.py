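"""Population-level statistics of trained-agent behavior.

Everything the simulation study reports is computed here from the raw
evaluation artifacts: within-population agent similarity (rank
correlations of choice probabilities and choice agreement),
cross-training-condition behavioral correlations on a shared test set,
mean-payoff tables with the transfer-of-learning dominance audit,
joint pure-Nash attainment split by the equilibrium count of the test
game, risk- vs payoff-dominant equilibrium selection in stag-hunt games,
and the deep-vs-superficial transfer profile along the PD-SH-NC-CH
transformation loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import games as G
from .agents import Population, encode_both_roles
from .engine import Evaluation, GridResult

__all__ = [
    "SimilaritySummary",
    "agent_similarity",
    "cross_training_correlation",
    "payoff_table",
    "dominance_audit",
    "psne_attainment",
    "equilibrium_selection",
    "transform_profile",
    "similarity_table",
]


# ---------------------------------------------------------------------------
# Agent homogeneity
# ---------------------------------------------------------------------------


def _spearman_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rank correlation of the rows of ``vectors``.

    Rank-transform each row, then Pearson-correlate.  Rows with zero
    variance yield NaN against every other row (the correlation is
    undefined), rather than poisoning the whole matrix.
    """
    ranks = stats.rankdata(vectors, axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks)
    return np.atleast_2d(corr)


@dataclass(frozen=True)
class SimilaritySummary:
    """Within-population similarity over all agent pairs.

    ``correlation``: Spearman rank correlation of the two agents' choice
    probabilities (P(action 0) in the row chair) across the test games.
    ``agreement``: percentage of games in which the two agents sampled the
    same action, averaged over simulation repetitions.  ``excluded_pairs``
    counts pairs dropped because one agent's probability vector had zero
    variance (correlation undefined).
    """

    correlation_mean: float
    correlation_min: float
    correlation_max: float
    agreement_mean: float
    agreement_min: float
    agreement_max: float
    excluded_pairs: int
    correlations: np.ndarray
    agreements: np.ndarray


def agent_similarity(evaluation: Evaluation) -> SimilaritySummary:
    """Pairwise similarity of the agents of one frozen population."""
    probs = evaluation.probs_row  # (m, n_games)
    m = probs.shape[0]
    corr = _spearman_matrix(probs)
    iu = np.triu_indices(m, k=1)
    pair_corr = corr[iu]
    excluded = int(np.isnan(pair_corr).sum())
    valid = pair_corr[~np.isnan(pair_corr)]

    choices = evaluation.row_choices  # (reps, m, n_games)
    same = choices[:, :, None, :] == choices[:, None, :, :]
    agree = 100.0 * same.mean(axis=(0, 3))[iu]
    return SimilaritySummary(
        correlation_mean=float(valid.mean()),
        correlation_min=float(valid.min()),
        correlation_max=float(valid.max()),
        agreement_mean=float(agree.mean()),
        agreement_min=float(agree.min()),
        agreement_max=float(agree.max()),
        excluded_pairs=excluded,
        correlations=pair_corr,
        agreements=agree,
    )


def similarity_table(grid: GridResult) -> pd.DataFrame:
    """Diagonal of the grid (same-class test) summarized per training set:
    the agent-heterogeneity table."""
    records = []
    for label in grid.training_classes:
        s = agent_similarity(grid.evaluations[(label, label)])
        records.append(
            {
                "training_class": label,
                "corr_mean": s.correlation_mean,
                "corr_min": s.correlation_min,
                "corr_max": s.correlation_max,
                "agree_mean": s.agreement_mean,
                "agree_min": s.agreement_min,
                "agree_max": s.agreement_max,
            }
        )
    return pd.DataFrame(records).set_index("training_class")


# ---------------------------------------------------------------------------
# Cross-training behavioral correlation
# ---------------------------------------------------------------------------


def cross_training_correlation(
    evaluations: dict[str, Evaluation], per_agent: bool = False
) -> pd.DataFrame:
    """Spearman correlation of behavior between training conditions.

    ``evaluations`` maps each training label to its evaluation on the
    *shared* mixed-class test set.  Behavior per condition is the
    population-mean P(action 0 | row chair) per game (or, with
    ``per_agent``, the pooled per-agent probability vectors).
    """
    labels = list(evaluations)
    games_ref = next(iter(evaluations.values())).rows
    for ev in evaluations.values():
        if not np.array_equal(ev.rows, games_ref):
            raise ValueError("cross-training correlation requires a shared test set")
    if per_agent:
        vectors = [evaluations[c].probs_row.ravel() for c in labels]
    else:
        vectors = [evaluations[c].probs_row.mean(axis=0) for c in labels]
    corr = _spearman_matrix(np.stack(vectors, axis=0))
    return pd.DataFrame(corr, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Payoffs
# ---------------------------------------------------------------------------


def payoff_table(grid: GridResult) -> pd.DataFrame:
    """Mean realized payoff per (training, test) cell, averaged over both
    members of each simulated pairing, all games and repetitions."""
    data = {
        te: [grid.evaluations[(tr, te)].mean_payoff() for tr in grid.training_classes]
        for te in grid.test_classes
    }
    return pd.DataFrame(data, index=list(grid.training_classes))


def dominance_audit(payoffs: pd.DataFrame) -> pd.DataFrame:
    """Transfer-of-learning dominance audit of a payoff table.

    Training class A is dominated if some other training class earns a
    higher mean payoff on each of the seven concrete game-class test sets
    — strictly higher wherever the two differ, and strictly on at least
    one.  (The weak form matters because the zero-sum test column is
    identically zero for every training class by payoff conservation, so
    a strict-everywhere comparison could never fire.)  Returns per
    training class whether it is dominated, by whom, and which classes it
    dominates.
    """
    test_cols = [c for c in payoffs.columns if c != G.ALL]
    dominated_by: dict[str, list[str]] = {a: [] for a in payoffs.index}
    for a in payoffs.index:
        for b in payoffs.index:
            if a == b:
                continue
            pa = payoffs.loc[a, test_cols]
            pb = payoffs.loc[b, test_cols]
            if (pb >= pa).all() and (pb > pa).any():
                dominated_by[a].append(b)
    return pd.DataFrame(
        {
            "dominated": [bool(dominated_by[a]) for a in payoffs.index],
            "dominated_by": [",".join(dominated_by[a]) for a in payoffs.index],
            "dominates": [
                ",".join(b for b in payoffs.index if a in dominated_by[b])
                for a in payoffs.index
            ],
        },
        index=payoffs.index,
    )


# ---------------------------------------------------------------------------
# Nash attainment and equilibrium selection
# ---------------------------------------------------------------------------


def _joint_psne_hits(evaluation: Evaluation) -> tuple[np.ndarray, np.ndarray]:
    """Per simulated play: flat joint-profile index (reps, games, pairs)
    and whether the profile is a pure Nash cell of the game."""
    flat = (2 * evaluation.a_row + evaluation.a_col).astype(np.int64)
    mask = evaluation.annotations()["psne_mask"].reshape(-1, 4)
    g = np.arange(evaluation.n_games)[None, :, None]
    return flat, mask[g, flat]


def psne_attainment(grid: GridResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint probability that a simulated pair plays a pure Nash profile.

    Returns two (training x test) tables: over test games with a unique
    pure equilibrium, and over test games with two pure equilibria (for
    which uniform random play lands on a pure equilibrium at the chance
    rate of 0.5).  Games without a pure equilibrium are excluded.  Cells
    whose test set has no qualifying game are NaN.
    """
    uniq: dict[str, list[float]] = {}
    two: dict[str, list[float]] = {}
    for te in grid.test_classes:
        uniq[te], two[te] = [], []
        for tr in grid.training_classes:
            ev = grid.evaluations[(tr, te)]
            n_psne = ev.annotations()["n_psne"]
            _, hits = _joint_psne_hits(ev)
            for target, count in ((uniq, 1), (two, 2)):
                sel = n_psne == count
                target[te].append(
                    float(hits[:, sel, :].mean()) if sel.any() else np.nan
                )
    index = list(grid.training_classes)
    return (
        pd.DataFrame(uniq, index=index),
        pd.DataFrame(two, index=index),
    )


def equilibrium_selection(
    grid: GridResult, test_class: str = "SH"
) -> pd.DataFrame:
    """Risk- vs payoff-dominant equilibrium selection.

    For each training condition, among simulated plays on stag-hunt test
    games that land on either pure equilibrium, the fraction landing on
    the risk-dominant one.  Only games with distinct, well-defined risk-
    and payoff-dominant equilibria enter; the number of excluded games is
    reported alongside.
    """
    records = []
    for tr in grid.training_classes:
        ev = grid.evaluations[(tr, test_class)]
        ann = ev.annotations()
        usable = (
            (ann["n_psne"] == 2)
            & (ann["pd_cell"] >= 0)
            & (ann["rd_cell"] >= 0)
            & (ann["pd_cell"] != ann["rd_cell"])
        )
        flat, hits = _joint_psne_hits(ev)
        sel = usable[None, :, None] & hits
        on_rd = (flat == ann["rd_cell"][None, :, None]) & sel
        n_eq_plays = int(sel.sum())
        records.append(
            {
                "training_class": tr,
                "p_risk_dominant": float(on_rd.sum() / n_eq_plays)
                if n_eq_plays
                else np.nan,
                "n_equilibrium_plays": n_eq_plays,
                "n_games_used": int(usable.sum()),
                "n_games_excluded": int((~usable).sum()),
            }
        )
    return pd.DataFrame(records).set_index("training_class")


# ---------------------------------------------------------------------------
# Deep vs superficial transfer along the transformation loop
# ---------------------------------------------------------------------------


def transform_profile(
    populations: dict[str, Population],
    steps: list[G.TransformStep] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Choice-probability profile of each population along the game loop.

    Returns ``(profile, scores)``.  ``profile`` is tidy: one row per
    (training condition, loop position) with the population-mean
    P(action 0 | row chair), the lambda value, the leg, and the
    classifier label of the game.  ``scores`` summarizes each profile:
    the overall probability range, the largest within-class-segment range
    (flatness: small means the population ignores class changes), and the
    mean absolute probability difference between games equidistant from
    each class boundary (boundary asymmetry: zero for purely
    payoff-similarity-driven behavior).
    """
    if steps is None:
        steps = G.build_transform_loop()
    rows = np.stack([s.game.row for s in steps])
    cols = np.stack([s.game.col for s in steps])
    enc_row, _ = encode_both_roles(rows, cols)
    labels = [s.label for s in steps]
    n = len(steps)

    profile_records = []
    score_records = []
    # class segments: contiguous runs of equal classifier label (the loop
    # is circular; the last PD run joins the first)
    seg_id = np.zeros(n, dtype=int)
    for k in range(1, n):
        seg_id[k] = seg_id[k - 1] + (labels[k] != labels[k - 1])
    if labels[0] == labels[-1]:
        seg_id[seg_id == seg_id[-1]] = 0
    boundaries = [k for k in range(n) if labels[k] != labels[k - 1]]

    for cond, pop in populations.items():
        p = pop.forward_games(enc_row)[:, :, 0].mean(axis=0)
        for k, s in enumerate(steps):
            profile_records.append(
                {
                    "training_class": cond,
                    "position": k,
                    "lambda": s.lambda_value,
                    "leg": f"{s.source_class}->{s.target_class}",
                    "game_class": s.label,
                    "p_action0_row": p[k],
                }
            )
        seg_ranges = [
            p[seg_id == s].max() - p[seg_id == s].min() for s in np.unique(seg_id)
        ]
        asym = []
        for b in boundaries:
            # compare games equidistant from the boundary between b-1 and b
            for k in range(0, min(8, n // 2)):
                asym.append(abs(p[(b - 1 - k) % n] - p[(b + k) % n]))
        score_records.append(
            {
                "training_class": cond,
                "profile_range": float(p.max() - p.min()),
                "max_segment_range": float(max(seg_ranges)),
                "boundary_asymmetry": float(np.mean(asym)) if asym else 0.0,
            }
        )
    return (
        pd.DataFrame(profile_records),
        pd.DataFrame(score_records).set_index("training_class"),
    )
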