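# Methods

This note documents the model, the synthetic-game generators, the
numerical choices, and the design decisions taken where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

**Agents.**  An agent is a feedforward network with layer sizes
8–50–50–50–2.  The input is the played game's eight payoffs *from the
agent's own perspective*: the agent always perceives itself as the row
player, so for an agent seated in the column chair the game is
transposed and the payoff matrices swapped before encoding.  The input
order is own payoffs at cells (00, 01, 10, 11) followed by the
opponent's payoffs at the same own-perspective cells.  Hidden units
apply the tansig transfer function, `2/(1+exp(-2z)) − 1`, identically
`tanh`; because all payoffs lie in [−1, 1], hidden activations stay
comfortably inside the function's linear-to-saturating range.  The two
output units pass through a softmax and are read as a probability
distribution over the agent's two actions; the realized action is
sampled from it.

**Learning rule.**  After both actions are realized, each agent computes
its ex-post (myopic) best response — the action that would have
maximized its own payoff against the opponent's realized action — and
takes a single step of plain online backpropagation toward that action
as a one-hot target.  There is no momentum, no minibatching, no weight
decay, and no learning-rate schedule.  Crucially the update is
*magnitude-blind*: only the identity of the best response enters; the
payoff margin between best-responding and not best-responding never
does.  On an exact payoff tie the realized action is kept as the target.

**Loss.**  The default output loss is squared error on the softmax
probabilities (the classic choice of the era's neural-network toolboxes,
whose default performance function is mean squared error).  Its gradient
through the softmax, `δ = p ⊙ ((p − t) − ((p − t)·p))`, vanishes as the
output saturates, which keeps logits moderate and leaves choice
probabilities smoothly graded in the payoffs even after long training —
visible downstream as high within-population *rank* correlations
alongside near-perfect choice agreement.  Cross-entropy (output error
exactly `p − t`) is available via `loss="cross_entropy"`; it drives
probabilities much harder toward 0/1, which leaves qualitative results
intact but erases the rank structure of the saturated probabilities.
Both losses are verified against central finite differences at 1e−6
relative error.

**Population protocol.**  A population holds 10 agents.  Each training
round draws one game from the training distribution, shuffles the
population into 5 pairs, assigns row/column chairs uniformly at random
within each pair, and has every pair play that same game (a
`shared_round_game=False` switch gives every pair its own draw; results
are insensitive).  Training runs for 70,000 rounds.  Mean realized
payoff across agents is recorded in 500-game blocks as the convergence
trace.  At test time the population is frozen: choice probabilities are
recorded for every agent on every test game, and joint statistics are
simulated by random pairing; 10 independent pairing passes per game
are used by default to shrink Monte-Carlo error.

## Game generators

All games are generic 2×2 bimatrix games with payoffs in [−1, 1].
Generation is constructive, not rejection-based: for each player four
payoffs are drawn iid uniform on [−1, 1], resampled until all pairwise
gaps are at least 1e−3 (so every ordinal comparison used by the
classifier is strict), sorted, and assigned to cells according to the
class's ordinal pattern:

| class | pattern (row player; T/R/P/S-style ranks) | equilibria |
|---|---|---|
| ZS  | random permutation; column = −row | 0 or 1 PSNE (+1 MSNE iff 0) |
| PD  | T>R>P>S, defect = action 1 | 1 PSNE, dominance solvable |
| MS  | one player matches, the other mismatches (matcher drawn at random) | 0 PSNE, 1 MSNE |
| SH  | R>T>P>S, both-stag = (0,0) | 2 PSNE + 1 MSNE, (0,0) payoff-dominant |
| CH  | T>R>S>P, equilibria off-diagonal | 2 PSNE + 1 MSNE, no payoff-dominant |
| BOS | coordination cells are both players' top two, preferences opposed | 2 PSNE + 1 MSNE, no payoff-dominant |
| NC  | both players' maximum in cell (0,0), unique PSNE (rejection on a second PSNE) | 1 PSNE, 0 MSNE |

The classic `2R > T + S` Prisoner's-dilemma side condition is *not*
imposed: it matters for alternating-move conventions, which random
rematching never produces.  `ALL` draws the class uniformly first.

**Canonical orientation.**  Every class keeps a fixed canonical action
layout (defection is always action 1, the stag-hunt payoff-dominant
equilibrium and the no-conflict optimum always sit at (0,0)), matching
the classic ordinal taxonomies of 2×2 games from which the class
definitions come.  This is substantive, not cosmetic: with canonical
layouts, populations trained on a single class can (and do) converge on
position-based conventions, and cross-class transfer of those
conventions — e.g. a defect-convention population landing on the
no-conflict optimum essentially never — is part of the phenomenon under
study.  A `canonical=False` switch applies a joint action-relabeling
isomorphism with probability 1/2 per game, stripping class information
from positions; it is useful for probing which behaviors are
payoff-driven, but it is not the study's condition.

**Equilibrium machinery.**  Pure equilibria by mutual-best-response
masks; the interior mixed equilibrium in closed form from the opponent's
indifference conditions (absent when the solved probabilities leave
(0, 1)); strict-dominance analysis (a 2×2 game is dominance-solvable iff
some player has a strictly dominant action); payoff dominance as strict
Pareto ranking of the two pure equilibria; risk dominance as the
strictly larger Nash product of unilateral deviation losses, with exact
ties labeled absent and such games excluded from selection statistics.
All solvers are vectorized and cross-checked against brute-force
enumeration oracles in the test suite.

**Transformation loop.**  The deep-vs-superficial probe uses four
symmetric base games (payoff sets {±0.125, ±0.375}, so symmetric about
zero and far from the saturation range) that classify as PD, SH, NC, CH.
Consecutive bases differ in exactly four of the eight payoffs, each by
0.25, and each change shifts the rank of the coupled payoffs by exactly
one.  Each leg linearly increments the four changing payoffs by
λ ∈ {0.01, …, 0.24}; the next base closes the leg, so the loop holds
4 × 25 = 100 games, the last step returns to the start, and no payoff
cell spans more than 0.5 across the whole loop.  The base games are this
package's own construction; every constraint above is re-validated when
the loop is built, so substituting different bases is safe.  Class
boundaries fall at λ = 0.125, between grid points, so no loop game is
degenerate.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| population size | 10 | agents | study design |
| training games | 70,000 | games | study design; convergence occurs by 10–20k |
| test games | 1,000 | games/class | study design |
| η (learning rate) | 0.02 | – | selected by sweep: populations converge within 10–20k presentations and within-population rank correlations stabilize; larger η saturates probabilities into rank noise, and at ~0.1 stag-hunt populations tip toward the risk-dominant convention |
| loss | squared error | – | see above; cross-entropy selectable |
| weight init | U(−0.5, 0.5) | – | small uniform keeps tansig unsaturated at the start |
| convergence block | 500 | games | fine enough to localize convergence within a few thousand games |
| pairing passes (test) | 10 | reps | Monte-Carlo error on joint statistics ≲0.005 |
| genericity margin | 1e−3 | payoff | no classifier ties |

## Seeds and determinism

A single master seed drives everything through named `SeedSequence`
children: per-training-session streams for initialization, game draws,
matching and choice sampling (keyed by master seed and training-class
index), and separate streams for shared test sets and evaluations.  Two
runs with the same configuration are bit-identical — enforced in the
test suite down to manifest checksums.  `scripts/acceptance.py` derives
its three master seeds from the single `--seed` argument.

## What the generators do and do not emulate

The generators reproduce the *strategic* structure of the game classes
(ordinal patterns, equilibrium signatures, dominance properties) with
payoff magnitudes drawn uniformly — there is no standard magnitude
distribution for these classes, so quantities that depend on payoff
scale (mean-payoff tables, and any statistic conditioned on
risk-dominance frequencies) carry wider uncertainty than pure
attainment probabilities.  Synthetic games are
exactly generic (no ties) and exactly bounded; real experimental
payoff matrices are neither.  Passing tests therefore certify the
learning dynamics and the analysis pipeline on this game distribution,
not behavioral predictions for any particular empirical payoff set.

## Numerical choices and degenerate inputs

- Softmax is computed with max-shift stabilization; choice probabilities
  are strictly interior for finite logits.
- Ex-post best-response ties (impossible under the generators, possible
  in hand-made games) resolve toward the agent's realized action.
- Games with a tie inside a best-response comparison are "unclassified"
  and rejected by the classifier rather than raising.
- Zero-variance probability vectors (an agent deterministic across the
  whole test set to machine precision) make Spearman correlations
  undefined; such pairs are excluded and counted.
- The dominance audit uses weak dominance (≥ everywhere, > somewhere)
  because the zero-sum test column is identically zero for every
  training condition by exact payoff conservation.
- Non-finite parameters abort training with the offending round in the
  diagnostic; parameters are checked at every trace block.

## Problem sizes used by the shipped runs

The acceptance script runs the full study design (70,000 training
games, 1,000-game test sets, 10 pairing passes, three master seeds) for
the seven training conditions its statistics need.  The test suite's
replication battery runs the same design for all eight conditions at
three seeds.  The `smoke` replication scale (2,000 training games, 200
test games) exists for quick end-to-end checks of the pipeline, not for
reproducing quantitative results.

## Known limitations

- Chicken-class populations converge to near-uniform mixing: under
  magnitude-blind ex-post-best-response learning with anonymous random
  rematching, the symmetric fixed point of the anti-coordination class
  puts every agent's action frequency at 50/50 regardless of payoffs, so
  chicken-trained populations transfer little structured behavior to
  other classes (their choice *probabilities* do remain payoff-graded
  and strongly correlated across agents under the squared-error loss).
- Discoordination (MS) populations likewise retain no stable
  convention — the expected outcome, since a discoordination game's only
  equilibrium is mixed and best-responding to it earns no premium.
- Stag-hunt populations are bistable: a single-class SH population
  coordinates on either the payoff-dominant (stag) or the risk-dominant
  (hare) convention, and the direction is set by early-training
  stochastics — across seeds roughly three in five populations go stag
  — and is insensitive to the learning rate (the same seeds flip at
  η = 0.02 and 0.01; only much larger rates, ~0.1, bias toward hare).
  Statistics that presuppose a stag-convention SH population (its
  across-class payoffs, the identity of the top-earning training class)
  therefore hold for most but not all master seeds.
- Equilibrium selection by mixture-trained populations in stag-hunt
  games is delicately balanced between the conflict-class components
  (pushing toward the risk-dominant, safe equilibrium) and the
  coordination/no-conflict components (pushing toward the
  payoff-dominant one), and therefore sensitive to the generators'
  payoff-magnitude distributions, which no printed source pins down.
  Under this package's uniform magnitudes the payoff-dominant side wins
  decisively; single-class conflict training (ZS, PD) still produces the
  near-certain risk-dominant selection expected of it.
- Within-population *rank correlations* of choice probabilities are an
  unstable statistic for populations whose conventions saturate the
  softmax (PD, SH, BOS, NC): agents agree on essentially every realized
  choice, but the ranking of their near-0/near-1 probabilities across
  games reflects tail noise.  Choice agreement is the robust
  homogeneity measure for such populations; rank correlation is
  informative for interior-probability populations (ZS, CH, MS, ALL).
- The model is a population of anonymous, randomly rematched learners;
  fixed partners, endogenous matching, and learning that continues
  during test are out of scope.
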