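# gametransfer

Agent-based simulation of **transfer of learning across classes of 2×2
games**, with feedforward-network agents that learn by online
backpropagation toward the ex-post best response.

## The scientific question

When people (or adaptive agents) learn to play one kind of strategic
interaction — pure conflict, a social dilemma, a coordination problem —
what do they carry over to *new* games they have never seen?  Behavioral
game theory observes strong spillovers: experience with coordination
games raises cooperation in a subsequent Prisoner's dilemma; experience
with conflict makes players defensive everywhere.  This package
implements a connectionist population model of that phenomenon:

- **Games.**  Random generic 2×2 bimatrix games with payoffs in [−1, 1],
  drawn from seven classic strategic classes: zero-sum (ZS), Prisoner's
  dilemma (PD), discoordination / mixed-strategy (MS), stag hunt (SH),
  chicken (CH), battle of the sexes (BOS) and no-conflict (NC), plus the
  uniform mixture ALL.
- **Agents.**  Each agent is an 8–50–50–50–2 feedforward network: the
  eight inputs are the game's payoffs from the agent's own perspective,
  hidden layers use the tansig (tanh) transfer function, and the two-unit
  softmax output is a probability distribution over the agent's actions,
  from which the realized action is sampled.
- **Learning.**  After each round the agent observes the opponent's
  realized action a⁻ and computes the myopic best response
  b = argmaxₐ u(a, a⁻).  One step of plain online backpropagation
  (squared error against the one-hot b, step size η = 0.02, no momentum
  or batching) moves the policy toward that best response.  Only the
  identity of the best response matters — payoff margins never enter the
  update.
- **Protocol.**  A population of 10 agents plays 70,000 randomly drawn
  training games, randomly re-paired and re-assigned row/column roles
  every round.  The population is then frozen (no more learning) and
  evaluated on 1,000-game test sets from each class, giving an 8×8
  training × test grid of behavioral, payoff, Nash-attainment and
  equilibrium-selection statistics, plus a 100-game
  PD→SH→NC→CH→PD "transformation loop" that separates deep
  (class-sensitive) from superficial (payoff-similarity) transfer.

## Worked example

`examples/02_train_population.py` trains 10 agents on 5,000 Prisoner's
dilemma games and probes them frozen on 500 fresh ones:

```
mean realized payoff per 500-game block (converges to the
mutual-defection payoff, about -0.2 under uniform sampling):
[-0.197 -0.195 -0.206 -0.21  -0.212 -0.202 -0.196 -0.219 -0.193 -0.189]

mean P(dominant action) on 500 fresh PD games: 0.9967
-> close to 1: every agent defects regardless of payoff details
joint probability of playing the unique equilibrium: 0.9943
```

The block means settle at the mutual-defection payoff (≈ −0.2 for
uniformly sampled PD games) — the population has learned the dominant
action and plays the game's unique equilibrium essentially always.  The
other example scripts cover game generation and equilibrium solving
(`01`), a scaled-down transfer grid (`03`), and the transformation-loop
probe of deep vs. superficial transfer (`04`).

A thin CLI wraps the same library calls:

```bash
gametransfer train --class PD --games 70000 --seed 1 --out runs/
gametransfer test  --ckpt runs/PD.ckpt --class NC --n 1000
gametransfer replicate --seed 1 --scale smoke --out replication/
```

`replicate` runs the whole study at one master seed and writes CSV twins
of every summary table, the convergence traces, the loop profile,
per-population checkpoints and a `manifest.json` with a checksum
inventory (bit-identical across reruns of the same seed).

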