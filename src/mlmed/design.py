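"""Trial-sequence generation for the within-subject tasting design.

The reference design crosses 3 price-cue levels with 2 payment conditions, 18
repetitions per cell (6 per wine), split into 3 runs of 36 trials.  Sequences
are pseudo-random under adjacency constraints: the same wine never occurs on
two successive trials, and price or payment conditions repeat at most twice in
a row.  Sequences are built by randomized backtracking, which is exact (it
fails only on genuinely infeasible specs) and deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InfeasibleDesignError(ValueError):
    """Raised when the constraint set cannot be satisfied for a spec."""


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design geometry and trial timing.

    Timing mirrors one tasting trial: cue display, jittered ISI, an 8-s swirl
    period whose first ``tasting_duration_s`` seconds are modelled, swallow,
    jittered interval, rating, rinse, swallow, jittered ITI.  Jitters are drawn
    uniformly from their bounds.
    """

    n_price_levels: int = 3
    n_payment_levels: int = 2
    reps_per_condition: int = 18
    n_runs: int = 3
    trials_per_run: int = 36
    n_wines: int = 3
    tasting_duration_s: float = 3.0   # modelled epoch within the 8-s swirl
    TR_s: float = 2.5
    sample_volume_ml: float = 1.25
    # per-trial event durations (seconds)
    cue_s: float = 2.5
    swirl_s: float = 8.0
    swallow_s: float = 2.0
    rating_s: float = 8.0
    rinse_s: float = 3.0
    isi_jitter_s: tuple[float, float] = (6.0, 8.0)
    mid_jitter_s: tuple[float, float] = (6.0, 8.0)
    iti_jitter_s: tuple[float, float] = (7.0, 9.0)

    @property
    def n_conditions(self) -> int:
        return self.n_price_levels * self.n_payment_levels

    @property
    def n_trials(self) -> int:
        return self.n_conditions * self.reps_per_condition

    @property
    def total_volume_ml(self) -> float:
        return self.n_trials * self.sample_volume_ml

    def validate(self) -> None:
        if self.n_trials != self.n_runs * self.trials_per_run:
            raise InfeasibleDesignError(
                "cell counts inconsistent: n_price x n_payment x reps "
                f"({self.n_trials}) != n_runs x trials_per_run "
                f"({self.n_runs * self.trials_per_run})")
        per_run_cell, rem = divmod(self.trials_per_run, self.n_conditions)
        if rem:
            raise InfeasibleDesignError(
                "trials_per_run not divisible by the number of conditions")
        if per_run_cell % self.n_wines:
            raise InfeasibleDesignError(
                "wines cannot appear equally often in every condition within a run")
        if self.n_wines < 2 and self.trials_per_run > 1:
            raise InfeasibleDesignError(
                "no-adjacent-same-wine constraint infeasible with a single wine")
        if self.n_price_levels < 2 and self.trials_per_run > 2:
            raise InfeasibleDesignError(
                "max-two-successive-price constraint infeasible with one price level")
        if self.n_payment_levels < 2 and self.trials_per_run > 2:
            raise InfeasibleDesignError(
                "max-two-successive-payment constraint infeasible with one payment level")


def _sequence_ok(seq: list[tuple[int, int, int]], cand: tuple[int, int, int]) -> bool:
    """Check adjacency constraints for appending `cand` (price, pay, wine)."""
    if seq and seq[-1][2] == cand[2]:
        return False  # same wine as previous trial
    if len(seq) >= 2:
        if seq[-1][0] == seq[-2][0] == cand[0]:
            return False  # three successive identical price levels
        if seq[-1][1] == seq[-2][1] == cand[1]:
            return False  # three successive identical payment conditions
    return True


def _build_run_sequence(spec: DesignSpec, rng: np.random.Generator,
                        max_backtracks: int = 2_000,
                        max_restarts: int = 200) -> list[tuple[int, int, int]]:
    """Randomized DFS with restarts over the per-run trial multiset.

    Backtracking search has a heavy-tailed runtime; capping backtracks per
    attempt and restarting with a fresh shuffle keeps the search fast while
    still failing deterministically on genuinely infeasible specs.
    """
    last_err = None
    for _ in range(max_restarts):
        try:
            return _dfs_attempt(spec, rng, max_backtracks)
        except InfeasibleDesignError as err:
            last_err = err
            if "exhausted search" in str(err):
                raise  # full search space explored: truly infeasible
    raise InfeasibleDesignError(
        f"no valid sequence found after {max_restarts} restarts: {last_err}")


def _dfs_attempt(spec: DesignSpec, rng: np.random.Generator,
                 max_backtracks: int) -> list[tuple[int, int, int]]:
    per_cell = spec.trials_per_run // spec.n_conditions // spec.n_wines
    pool: dict[tuple[int, int, int], int] = {}
    for p in range(1, spec.n_price_levels + 1):
        for pay in range(spec.n_payment_levels):
            for w in range(1, spec.n_wines + 1):
                pool[(p, pay, w)] = per_cell

    seq: list[tuple[int, int, int]] = []
    # stack of shuffled candidate lists, one per depth
    def candidates() -> list[tuple[int, int, int]]:
        opts = [k for k, c in pool.items() if c > 0 and _sequence_ok(seq, k)]
        rng.shuffle(opts)
        return opts

    stack = [candidates()]
    backtracks = 0
    while len(seq) < spec.trials_per_run:
        if stack[-1]:
            choice = stack[-1].pop()
            seq.append(choice)
            pool[choice] -= 1
            stack.append(candidates())
        else:
            stack.pop()
            if not seq:
                raise InfeasibleDesignError(
                    "exhausted search: adjacency constraints are infeasible "
                    "for this spec")
            undone = seq.pop()
            pool[undone] += 1
            backtracks += 1
            if backtracks > max_backtracks:
                raise InfeasibleDesignError(
                    "backtracking limit exceeded; constraint set appears infeasible")
    return seq


def _trial_onsets(spec: DesignSpec, rng: np.random.Generator, n_trials: int) -> np.ndarray:
    """Tasting onsets (s from run start) with jittered intervals."""
    isi = rng.uniform(*spec.isi_jitter_s, size=n_trials)
    mid = rng.uniform(*spec.mid_jitter_s, size=n_trials)
    iti = rng.uniform(*spec.iti_jitter_s, size=n_trials)
    onsets = np.empty(n_trials)
    t = 0.0
    for i in range(n_trials):
        t += spec.cue_s + isi[i]
        onsets[i] = t  # wine delivery / swirl onset
        t += (spec.swirl_s + spec.swallow_s + mid[i] + spec.rating_s
              + spec.rinse_s + spec.swallow_s + iti[i])
    return onsets


def run_duration_s(spec: DesignSpec) -> float:
    """Upper bound on run length (used to size simulated BOLD runs)."""
    per_trial = (spec.cue_s + spec.isi_jitter_s[1] + spec.swirl_s + spec.swallow_s
                 + spec.mid_jitter_s[1] + spec.rating_s + spec.rinse_s
                 + spec.swallow_s + spec.iti_jitter_s[1])
    return spec.trials_per_run * per_trial + 32.0  # cover the HRF tail


def generate_design(spec: DesignSpec = DesignSpec(), seed: int = 0) -> pd.DataFrame:
    """Generate one subject's pseudo-random trial table.

    Returns a DataFrame with one row per trial and columns
    ``trial_index`` (1-based, global), ``run`` (1-based), ``price`` (1..3),
    ``payment`` (0 free / 1 pay), ``wine`` (1..3), ``onset_s`` (tasting onset
    within run) and ``rating``/``included`` placeholders filled downstream.

    Raises :class:`InfeasibleDesignError` when the spec's adjacency or balance
    constraints cannot hold.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    frames = []
    for run in range(1, spec.n_runs + 1):
        seq = _build_run_sequence(spec, rng)
        onsets = _trial_onsets(spec, rng, len(seq))
        price, pay, wine = (np.array(z) for z in zip(*seq))
        frames.append(pd.DataFrame({
            "run": run,
            "price": price,
            "payment": pay,
            "wine": wine,
            "onset_s": onsets,
        }))
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "trial_index", np.arange(1, len(table) + 1))
    table["rating"] = np.nan
    table["included"] = True
    return table


def check_constraints(table: pd.DataFrame, spec: DesignSpec = DesignSpec()) -> dict:
    """Audit a trial table against the design invariants; returns violation counts."""
    bad_wine = bad_price = bad_pay = 0
    for _, run_tab in table.groupby("run"):
        w = run_tab["wine"].to_numpy()
        p = run_tab["price"].to_numpy()
        pay = run_tab["payment"].to_numpy()
        bad_wine += int(np.sum(w[1:] == w[:-1]))
        bad_price += int(np.sum((p[2:] == p[1:-1]) & (p[1:-1] == p[:-2])))
        bad_pay += int(np.sum((pay[2:] == pay[1:-1]) & (pay[1:-1] == pay[:-2])))
    cell_counts = table.groupby(["price", "payment"]).size()
    wine_cell = table.groupby(["price", "payment", "wine"]).size()
    return {
        "adjacent_same_wine": bad_wine,
        "triple_same_price": bad_price,
        "triple_same_payment": bad_pay,
        "cell_count_ok": bool((cell_counts == spec.reps_per_condition).all()),
        "wine_balance_ok": bool((wine_cell == spec.reps_per_condition // spec.n_wines).all()),
    }
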