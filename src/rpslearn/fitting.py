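"""Maximum-likelihood lattice fitting and model comparison.

These learners have no closed-form input-output mapping, so parameters are
estimated by exhaustive search over a lattice of candidate values.  The
objective is the teacher-forced sequence log-likelihood: the model's internal
state is driven by the *recorded* history (opponent symbols and, for RELPH,
the rewards implied by the recorded player choices), and each trial
contributes the log-probability the model assigns to the choice the player
actually made.  Because RELPH is stochastic (random initial hypothesis
values), per-trial choice probabilities are averaged over ``reps`` seeded
replicates before taking logs.  Models are compared with AIC (2k - 2 ln L)
and the plug-in Bayes factor 2 ln(k) = 2 (ln L_A - ln L_B), with values
above 10 conventionally read as very strong evidence.

For RELPH the lattice is evaluated by a numpy implementation vectorised over
the (H_thr, alpha) grid; its agreement with the per-point agent-based
likelihood is pinned by tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd

from .core import RPS_ALPHABET, ContextPattern
from .elph import ElphParams
from .environment import OUTCOMES, outcome, reward_of
from .experiment import make_agent
from .relph import RelphParams, init_value

EPS_FLOOR = 1e-10
STRONG_EVIDENCE = 10.0  # 2 ln(k) above this reads as very strong

MODEL_K = {"elph": 2, "relph": 3, "relph-greedy": 3}


def _grid(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(float(np.round(lo + i * step, 10)) for i in range(n + 1))


@dataclass(frozen=True)
class Lattice:
    """Parameter grids for the exhaustive search; tau is held fixed."""

    n_values: tuple[int, ...] = (1, 2, 3)
    h_thr_values: tuple[float, ...] = field(default_factory=lambda: _grid(0.0, 3.0, 0.1))
    alpha_values: tuple[float, ...] = field(default_factory=lambda: _grid(0.0, 1.0, 0.05))
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not (self.n_values and self.h_thr_values and self.alpha_values):
            raise ValueError("lattice grids must be non-empty")
        if any(n < 1 for n in self.n_values):
            raise ValueError("n values must be >= 1")
        if any(h < 0 for h in self.h_thr_values):
            raise ValueError("H_thr values must be >= 0")
        if any(not 0 <= a <= 1 for a in self.alpha_values):
            raise ValueError("alpha values must lie in [0, 1]")


def default_lattice() -> Lattice:
    return Lattice()


def playlog_id(log: pd.DataFrame) -> str:
    """Stable fingerprint of the choices in a play log."""
    payload = ";".join(
        f"{p}|{o}" for p, o in zip(log["player_choice"], log["opponent_choice"])
    )
    return hashlib.sha1(payload.encode()).hexdigest()


def aic(k: int, loglik: float) -> float:
    """Akaike information criterion, natural-log likelihood."""
    return 2.0 * k - 2.0 * loglik


def _log_arrays(log: pd.DataFrame, alphabet: tuple[str, ...] = RPS_ALPHABET):
    idx = {s: i for i, s in enumerate(alphabet)}
    opp = np.array([idx[s] for s in log["opponent_choice"]], dtype=np.int64)
    play = np.array([idx[s] for s in log["player_choice"]], dtype=np.int64)
    rew = np.array(
        [reward_of(outcome(p, o)) for p, o in zip(log["player_choice"], log["opponent_choice"])],
        dtype=np.int64,
    )
    oidx = {name: i for i, name in enumerate(OUTCOMES)}
    out = np.array(
        [oidx[outcome(p, o)] for p, o in zip(log["player_choice"], log["opponent_choice"])],
        dtype=np.int64,
    )
    return opp, play, rew, out


def _rep_seeds(seed: int, reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(reps)


def sequence_loglik(
    model: str,
    params: ElphParams | RelphParams,
    log: pd.DataFrame,
    reps: int = 5,
    seed: int = 0,
    eps: float = EPS_FLOOR,
) -> float:
    """Teacher-forced log-likelihood of the recorded choices, in nats.

    Reference (agent-based) implementation: runs the model once per replicate
    with a replicate-specific value-initialisation seed, collecting the
    probability assigned to each recorded choice, then averages the per-trial
    probabilities over replicates before flooring at ``eps`` and summing
    logs.  ELPH's teacher-forced state is deterministic, so a single pass
    suffices regardless of ``reps``.
    """
    alphabet = RPS_ALPHABET
    sym_idx = {s: i for i, s in enumerate(alphabet)}
    T = len(log)
    if model == "elph":
        seeds: Sequence[int] = [0]
    else:
        seeds = [int(s) for s in _rep_seeds(seed, reps)]
    probs = np.zeros((len(seeds), T))
    players = list(log["player_choice"])
    opponents = list(log["opponent_choice"])
    for r, rep_seed in enumerate(seeds):
        if model == "elph":
            agent = make_agent(model, params, seed=0)
        else:
            agent = make_agent(model, params, seed=0, value_seed=rep_seed)
        for t in range(T):
            dist = agent.choice_distribution()
            probs[r, t] = dist[sym_idx[players[t]]]
            if model == "elph":
                agent.observe(opponents[t])
            else:
                agent.observe(players[t], opponents[t])
    pbar = probs.mean(axis=0)
    return float(np.log(np.maximum(pbar, eps)).sum())


# ---------------------------------------------------------------------------
# Vectorised RELPH lattice evaluation
# ---------------------------------------------------------------------------


def _enumerate_patterns(n: int, alphabet: tuple[str, ...] = RPS_ALPHABET):
    """All context patterns over offsets 1..n; returns (patterns, index)."""
    patterns: list[ContextPattern] = []
    for r in range(1, n + 1):
        for offs in combinations(range(1, n + 1), r):
            for syms in product(alphabet, repeat=r):
                patterns.append(ContextPattern(tuple(zip(offs, syms))))
    return patterns, {p: i for i, p in enumerate(patterns)}


def _trial_candidates(opp: np.ndarray, n: int, alphabet: tuple[str, ...]):
    """Candidate pattern ids for each trial, from the recorded history."""
    patterns, index = _enumerate_patterns(n, alphabet)
    cand: list[np.ndarray] = []
    for t in range(len(opp)):
        k = min(t, n)
        ids = []
        for r in range(1, k + 1):
            for offs in combinations(range(1, k + 1), r):
                bindings = tuple((o, alphabet[opp[t - o]]) for o in offs)
                ids.append(index[ContextPattern(bindings)])
        cand.append(np.array(ids, dtype=np.int64))
    return patterns, cand


def _relph_grid_logliks(
    log: pd.DataFrame,
    n: int,
    h_grid: Sequence[float],
    a_grid: Sequence[float],
    tau: float,
    greedy: bool,
    reps: int,
    seed: int,
    eps: float = EPS_FLOOR,
) -> np.ndarray:
    """Teacher-forced log-likelihoods over the (H_thr, alpha) grid.

    Returns an array of shape (len(h_grid) * len(a_grid),) ordered with
    H_thr as the major axis.  State arrays are indexed (grid point,
    pattern id, symbol/outcome); each trial touches only the candidate
    pattern columns, and pruning re-checks only those columns (hypotheses
    not updated this trial cannot have changed entropy).
    """
    alphabet = RPS_ALPHABET
    m = len(alphabet)
    opp, play, rew, outc = _log_arrays(log, alphabet)
    T = len(opp)
    patterns, cand = _trial_candidates(opp, n, alphabet)
    P = len(patterns)
    hh, aa = np.meshgrid(np.asarray(h_grid, float), np.asarray(a_grid, float), indexing="ij")
    Hthr = hh.ravel()
    Alpha = aa.ravel()
    G = Hthr.size
    probs_sum = np.zeros((G, T))
    for rep_seed in _rep_seeds(seed, reps):
        v0 = np.array([init_value(p, int(rep_seed)) for p in patterns])
        present = np.zeros((G, P), dtype=bool)
        tot = np.zeros((G, P, m))
        oc = np.zeros((G, P, m))
        V = np.zeros((G, P))
        for t in range(T):
            cols = cand[t]
            if cols.size == 0:
                probs_sum[:, t] += 1.0 / m
                continue
            pm = present[:, cols]  # (G, k)
            any_p = pm.any(axis=1)
            # stage 1: hypothesis selection by value
            Vc = np.where(pm, V[:, cols], -np.inf)
            if greedy:
                mx = Vc.max(axis=1, keepdims=True)
                w = ((Vc == mx) & pm).astype(float)
            else:
                z = Vc / tau
                mx = z.max(axis=1, keepdims=True)
                mx = np.where(np.isfinite(mx), mx, 0.0)
                w = np.exp(z - mx)
                w[~pm] = 0.0
            wsum = w.sum(axis=1, keepdims=True)
            w = np.divide(w, wsum, out=np.zeros_like(w), where=wsum > 0)
            # stage 2: action selection by cumulative reward totals
            Tc = tot[:, cols, :]  # (G, k, m)
            if greedy:
                mx2 = Tc.max(axis=2, keepdims=True)
                s2 = (Tc == mx2).astype(float)
                s2 /= s2.sum(axis=2, keepdims=True)
            else:
                z2 = Tc / tau
                z2 = z2 - z2.max(axis=2, keepdims=True)
                s2 = np.exp(z2)
                s2 /= s2.sum(axis=2, keepdims=True)
            p_t = (w * s2[:, :, play[t]]).sum(axis=1)
            probs_sum[:, t] += np.where(any_p, p_t, 1.0 / m)
            # update: delta-rule values, reward totals, outcome tallies
            V_old = np.where(present[:, cols], V[:, cols], v0[cols][None, :])
            V[:, cols] = V_old + Alpha[:, None] * (rew[t] - V_old)
            tot[:, cols, play[t]] += rew[t]
            oc[:, cols, outc[t]] += 1.0
            present[:, cols] = True
            # prune updated hypotheses by outcome entropy
            c = oc[:, cols, :]
            Ntot = c.sum(axis=2) + 1.0
            pfrac = c / Ntot[:, :, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(c > 0, pfrac * np.log2(pfrac), 0.0)
            ent = -plogp.sum(axis=2) + np.log2(Ntot) / Ntot
            kill = ent > Hthr[:, None]
            if kill.any():
                gk, kk = np.nonzero(kill)
                pcols = cols[kk]
                present[gk, pcols] = False
                V[gk, pcols] = 0.0
                tot[gk, pcols, :] = 0.0
                oc[gk, pcols, :] = 0.0
        # (loop over trials ends)
    pbar = probs_sum / reps
    return np.log(np.maximum(pbar, eps)).sum(axis=1)


@dataclass
class FitResult:
    """Best lattice point with its likelihood, AIC and the full surface."""

    model: str
    params: dict
    loglik: float
    k: int
    aic: float
    log_id: str
    reps: int
    seed: int
    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "log_id": self.log_id,
            "reps": self.reps,
            "seed": self.seed,
        }

    def save(self, path, lattice_csv=None) -> None:
        d = self.to_json_dict()
        if lattice_csv is not None:
            self.table.to_csv(lattice_csv, index=False)
            d["lattice_csv"] = str(lattice_csv)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def load_fit_result(path) -> FitResult:
    with open(path) as fh:
        d = json.load(fh)
    table = pd.DataFrame()
    if d.get("lattice_csv"):
        try:
            table = pd.read_csv(d["lattice_csv"])
        except OSError:
            pass
    return FitResult(
        model=d["model"], params=d["params"], loglik=d["loglik"], k=d["k"],
        aic=d["aic"], log_id=d["log_id"], reps=d["reps"], seed=d["seed"],
        table=table,
    )


def fit_lattice(
    model: str,
    log: pd.DataFrame,
    lattice: Lattice | None = None,
    reps: int = 5,
    seed: int = 0,
) -> FitResult:
    """Evaluate the likelihood at every lattice point and return the argmax.

    Ties (likelihood surfaces are exactly flat where a parameter stops
    mattering, e.g. pruning thresholds above the maximum attainable entropy)
    are broken toward the lexicographically smallest (n, H_thr, alpha), so
    the result does not depend on grid ordering.
    """
    if model not in MODEL_K:
        raise ValueError(f"unknown model {model!r}")
    if lattice is None:
        lattice = default_lattice()
    rows = []
    if model == "elph":
        for n in lattice.n_values:
            for h in lattice.h_thr_values:
                ll = sequence_loglik(model, ElphParams(n=n, h_thr=h), log, reps=1, seed=seed)
                rows.append((n, h, np.nan, ll))
    else:
        greedy = model == "relph-greedy"
        for n in lattice.n_values:
            lls = _relph_grid_logliks(
                log, n, lattice.h_thr_values, lattice.alpha_values,
                tau=lattice.tau, greedy=greedy, reps=reps, seed=seed,
            )
            i = 0
            for h in lattice.h_thr_values:
                for a in lattice.alpha_values:
                    rows.append((n, h, a, float(lls[i])))
                    i += 1
    table = pd.DataFrame(rows, columns=["n", "h_thr", "alpha", "loglik"])
    table = table.sort_values(["n", "h_thr", "alpha"], na_position="first").reset_index(drop=True)
    best_ll = table["loglik"].max()
    best = table[table["loglik"] == best_ll].iloc[0]
    if model == "elph":
        params = {"n": int(best["n"]), "h_thr": float(best["h_thr"])}
    else:
        params = {
            "n": int(best["n"]),
            "h_thr": float(best["h_thr"]),
            "alpha": float(best["alpha"]),
            "tau": lattice.tau,
            "greedy": model == "relph-greedy",
        }
    k = MODEL_K[model]
    return FitResult(
        model=model, params=params, loglik=float(best_ll), k=k,
        aic=aic(k, float(best_ll)), log_id=playlog_id(log), reps=reps,
        seed=seed, table=table,
    )


def bayes_factor(fit_a: FitResult, fit_b: FitResult) -> float:
    """Plug-in 2 ln(k) favouring model A over model B on the same log."""
    if fit_a.log_id != fit_b.log_id:
        raise ValueError("fits were computed on different play logs")
    return 2.0 * (fit_a.loglik - fit_b.loglik)


def is_strong_evidence(bf: float) -> bool:
    return bf > STRONG_EVIDENCE
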