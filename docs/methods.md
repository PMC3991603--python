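# Methods

## Model overview and assumptions

Both learners share one memory architecture. A short-term memory (STM) holds
the `n` most recently observed opponent symbols. Before each trial, every
non-empty subset of the occupied STM slots — bound to the symbols currently
sitting there — is a candidate *context pattern*; a full STM yields
`2^n − 1` candidates. The hypothesis space (HS) maps patterns to records.
Patterns are indexed by backward offset (t−1 = most recent), so a hypothesis
is time-shift invariant: it names a *situation*, not a calendar trial.
Candidates are generated from the partial STM before it fills, so learning
can begin at trial 2.

**ELPH** records, per hypothesis, counts of the symbols that followed its
context. Its reliability score is the *regularised entropy*: append one
phantom count of 1 to the multiset of counts, normalise by `N+1`, and take
the base-2 Shannon entropy. The phantom mass penalises low-evidence
hypotheses — a single observation scores a full bit — and bounds the score
by `log2(m+1)` for an `m`-symbol alphabet (2 bits for RPS). Prediction is a
two-stage sample: a matching hypothesis with weight ∝ `exp(−H)` (so lower
entropy is more probable, smoothly, and `H = 0` is well defined), then a
symbol with probability proportional to its count. The agent plays the
unique counter of the predicted symbol, the only reward-maximising mapping
in RPS. Hypotheses with `H > H_thr` are deleted at the end of every trial.
Within a trial the order is fixed: predict → play → observe → update →
prune → shift STM.

**RELPH** shares the context machinery (the STM still holds *opponent*
symbols, so both learners face the same situations) but records the
cumulative reward of its *own plays* per context (+1 win / 0 tie / −1 loss),
plus a per-hypothesis value `V` updated by the delta rule
`V ← V + α (r − V)`. Choice is a two-stage soft-max with one shared
temperature τ: over hypothesis values, then over the per-action reward
totals within the chosen hypothesis; actions never tried in a context enter
at total 0 so exploration can reach them. `greedy=True` replaces both
stages by strict argmax (ties uniform). Pruning applies the same
regularised entropy to the per-hypothesis win/tie/loss tallies ("outcome
entropy"): hypotheses whose *payoffs* are inconsistent are discarded.

**Opponent.** Three stationary phases of 200 i.i.d. trials each: uniform;
P(rock)=0.5; P(paper)=0.8. Residual mass in the biased phases is split
evenly across the remaining symbols (the minimal assumption; configurable
per phase). The opponent never reacts to the player.

## Parameters

| Parameter | Meaning | Range | Default | Why |
| --- | --- | --- | --- | --- |
| `n` | STM depth (symbols) | 1–6 supported, 1–3 fitted | 2 | modal fitted STM length in both participant-like groups |
| `H_thr` | pruning threshold (bits) | ≥ 0 | ELPH 1.0, RELPH 2.28 | see below |
| `α` | learning rate (unitless) | [0, 1] | 0.27 | healthy-control-like group mean |
| `τ` | soft-max temperature | > 0 | 1.0 | held fixed; only `n`, `H_thr`, `α` are fitted |
| `greedy` | argmax choice | bool | False | "turned-off" soft-max regime |

ELPH's default `H_thr = 1.0` puts the learner in the regime where pruning is
active: a fresh single-observation hypothesis ({1} + phantom → exactly 1.0
bit) survives, while any conflicted prediction-set (≥ ~1.3 bits) is deleted.
This is what makes ELPH a fast exploiter of the heavy bias — stale
hypotheses do not linger. Note that for a 3-symbol alphabet the regularised
entropy cannot exceed `log2 4 = 2` bits, so RELPH's control-like default
`H_thr = 2.28` never prunes; those agents run with an unfiltered hypothesis
space. Cohort presets draw `H_thr` and `α` from normals clipped to their
valid ranges ([0, 3] and [0, 1]) and `n` from the group frequency tables;
preset sizes are 12 (control-like), 10 (greedy/"lesioned" soft-max), 14
(low-threshold / high-α).

## Fitting

Likelihood is computed by *teacher forcing*: the model's memory is driven by
the recorded history (opponent symbols; for RELPH also the rewards implied
by the recorded player choices), and trial `t` contributes
`log P(recorded choice_t | state_t)` — the only tractable per-trial choice
likelihood for a stateful stochastic learner. Because RELPH's hypothesis
values are randomly initialised, per-trial probabilities are averaged over
`reps` seeded replicates (default 5) *before* taking logs, which smooths the
lattice surface. Each per-trial probability is floored at `ε = 1e−10`; the
floor only engages when a greedy model assigns probability 0 to the
recorded choice.

The default lattice is `n ∈ {1,2,3}`, `H_thr ∈ 0.0–3.0` step 0.1,
`α ∈ 0.0–1.0` step 0.05, τ fixed at 1. `AIC = 2k − 2 ln L̂` with `k = 2`
(ELPH) or `3` (RELPH); the Bayes factor `2 ln(k)` uses the maximised
likelihoods as plug-in evidences (marginal-likelihood integration is out of
scope), with values above 10 flagged as very strong evidence.

Two implementation routes compute the same quantity: a reference path that
replays the agent classes point by point, and a production evaluator
vectorised over the `(H_thr, α)` grid for each `n` (state arrays indexed by
an enumeration of all `4^n − 1` patterns). Their exact agreement is pinned
by tests. The vectorised path is what makes the default lattice (1,953
RELPH points × 5 replicates × 600 trials) run in seconds per log.

## Numerical choices

* **Value initialisation.** "Random initial values" are uniform on
  [−0.01, +0.01], drawn as a deterministic hash of (pattern, seed) rather
  than by sequential RNG consumption, so an agent's initial values do not
  depend on the order in which hypotheses happen to be created and the two
  likelihood routes are bit-comparable.
* **Per-trial pruning scans only the hypotheses updated that trial.** A
  record that was not updated cannot have changed entropy since it last
  passed the filter, so this equals the full scan (a property test runs a
  full scan afterwards and checks nothing more is removed).
* **Ties.** Sampling ties are resolved by the seeded RNG through the
  categorical draw itself; greedy argmax ties are split uniformly; lattice
  argmax ties (the surface is exactly flat where a parameter stops
  mattering, e.g. `H_thr ≥ 2`) break toward the lexicographically smallest
  `(n, H_thr, α)`, making fits invariant to grid ordering.
* **Degenerate inputs.** An empty STM yields no candidates and uniform
  play; an empty prediction-set has no entropy (error); `H_thr = 0` deletes
  every hypothesis (the phantom count keeps all entropies positive), which
  is also the reference uniform-play baseline used by the likelihood
  anchor tests. Soft-max computations subtract the maximum before
  exponentiating, so unbounded reward totals cannot overflow.
* **Seeding.** A single master seed spawns independent streams (opponent,
  agent, parameter draws, fit replicates) via `numpy` seed sequences; every
  artifact records it. Identical seeds replay byte-identical logs.

## Synthetic data

All data are generated internally: the deterministic period-3 cycle
(paper, rock, rock) used for bookkeeping checks — phased so that 21
observations give the reference counts 7 / {rock 7, paper 6} / 7 — and
synthetic participants (agents with known parameters playing the scheduled
opponent) whose ground truth travels in a JSON sidecar. Synthetic
participants emulate the *structure* of participant play logs (per-trial
choices against the scheduled opponent), not human behaviour: there are no
reaction times, no lapses or drift, no within-session non-stationarity of
the player, and a synthetic participant is by construction a model agent.
Passing recovery tests therefore show that the fitting machinery identifies
model parameters from model-generated data of realistic length — not that
the models describe human play.

## Design choices where the design was open

* The entropy regularisation (phantom count, `N+1` normalisation) follows
  the "reliable entropy" of the original sequence-learning model; the
  surrounding requirements (low-evidence penalty, reliability ordering of
  the worked-example hypotheses) pin it down.
* Hypothesis selection weight `∝ exp(−H)` (a softmin): smooth, defined at
  `H = 0`, and makes lower entropy more probable.
* RELPH's STM stores opponent symbols, so ELPH and RELPH differ only in
  their prediction target; per-hypothesis values `V` drive stage-1
  selection while prediction-set totals drive stage-2, and both are
  retained in the records so either can be ablated.
* One shared temperature for both soft-max stages keeps the parameter
  count at the fitted three.

## Problem sizes in the test suite

Desk-scale settings keep the full suite in a few minutes: behavioural
contrasts use 50 paired seeds of full 600-trial (or 200-trial stationary)
games; parameter recovery fits the full default lattice to 20 synthetic
600-trial participants with 5 replicates per point; oracle equivalences are
exhaustive where the space is finite (all count multisets with total ≤ 6,
all 9 choice pairs, candidate sets for `n ≤ 6`).

## Known limitations

* Under the regularised entropy, thresholds ≥ 2 bits never prune on a
  3-symbol alphabet, so control-like RELPH (`H_thr = 2.28`) effectively
  runs without pruning.
* Because stage-2 soft-max acts on *unbounded cumulative* reward totals,
  the soft-max learner converges toward argmax behaviour late in a run;
  soft-max-vs-greedy and group-level contrasts are therefore muted at
  cohort scale, and the directional claims are sharpest at matched fixed
  parameters.
* α enters choice only through stage-1 hypothesis selection; its
  teacher-forced likelihood profile peaks at the generating value but is
  shallow (tenths of a nat within ±0.1), so single-log α estimates carry
  substantial variance. STM depth `n` and (below 2 bits) `H_thr` are
  sharply identifiable.
* The opponent is non-reactive i.i.d.-within-phase; adversarial or adaptive
  opponents, eligibility traces, discounting and opponent-modelling hybrids
  are out of scope.
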