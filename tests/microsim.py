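"""Individual-level event-driven microsimulation oracle.

Simulates N individuals through the same per-cycle transition matrices the
cohort engine uses, sampling one categorical transition per individual per
cycle and, for NICU/ward exits inside multi-day cycles, the exact day of exit
from the truncated geometric implied by the constant daily hazard.  Returns
per-individual tallies so tests can compare cohort-engine expectations with
microsimulation means at Monte Carlo precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from preterm_bia.cohort import (
    DEAD,
    HOME,
    HOME_INF,
    HOSPITAL_STATES,
    N_STATES,
    N_YEARS,
    PRE,
    REHOSP,
    TRAIN,
    WARD,
    Arm,
    build_time_grid,
    build_transition_matrix,
    stratify,
    to_cycle_prob,
)

HOME_BLOCKS = (HOME, HOME_INF, REHOSP)


@dataclass
class MicrosimResult:
    n: int
    nicu_days: np.ndarray
    hosp_infections: np.ndarray
    ngt_discharges: np.ndarray
    home_infections: np.ndarray
    rehosp_events: np.ndarray
    deaths: np.ndarray

    def mean_and_se(self, name: str) -> tuple[float, float]:
        arr = getattr(self, name)
        return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(self.n))


def _truncated_geometric_days(rng, d: float, length: float, n: int) -> np.ndarray:
    """Day of exit (1..length) conditioned on exiting within the cycle."""
    if length <= 1.0 or d <= 0.0:
        return np.ones(n)
    q = -np.expm1(np.log1p(-d) * length)
    u = rng.random(n)
    days = np.ceil(np.log1p(-u * q) / np.log1p(-d))
    return np.clip(days, 1.0, length)


def microsimulate(ps, arm: Arm, n: int, seed: int, horizon_days: float = 5 * 365) -> MicrosimResult:
    rng = np.random.default_rng(seed)
    grid = build_time_grid(horizon_days)
    split = stratify(ps, arm)
    t0 = ps.value("training_start_day")

    # deterministic largest-remainder allocation of individuals to entry branches
    masses = np.array(
        [split.mass_nns_at_birth, split.mass_train_success, split.mass_train_failure]
    )
    counts = np.floor(masses / masses.sum() * n).astype(int)
    rema = masses / masses.sum() * n - counts
    for i in np.argsort(-rema)[: n - counts.sum()]:
        counts[i] += 1
    state = np.empty(n, dtype=np.int64)
    markov = np.empty(n, dtype=np.int64)
    state[: counts[0]] = TRAIN
    markov[: counts[0]] = 0
    state[counts[0] : counts[0] + counts[1]] = PRE
    markov[counts[0] : counts[0] + counts[1]] = 0
    state[counts[0] + counts[1] :] = PRE
    markov[counts[0] + counts[1] :] = 1

    res = MicrosimResult(
        n=n,
        nicu_days=np.zeros(n),
        hosp_infections=np.zeros(n),
        ngt_discharges=np.zeros(n),
        home_infections=np.zeros(n),
        rehosp_events=np.zeros(n),
        deaths=np.zeros(n),
    )
    p_inf_daily = ps.value("p_infection_hosp_daily")
    matrices: dict[tuple, np.ndarray] = {}
    cdfs: dict[tuple, np.ndarray] = {}

    for i, cyc in enumerate(grid):
        if cyc.start_day >= t0:
            state[state == PRE] = TRAIN
        L = cyc.length
        p_inf_cycle = to_cycle_prob(p_inf_daily, 1.0, L)

        in_hosp = np.isin(state, HOSPITAL_STATES)
        if in_hosp.any():
            res.hosp_infections[in_hosp] += rng.random(int(in_hosp.sum())) < p_inf_cycle

        new_state = state.copy()
        for m in (0, 1):
            key = (m, L, cyc.year_cluster)
            if key not in matrices:
                matrices[key] = build_transition_matrix(ps, arm, m, cyc)
                cdfs[key] = np.cumsum(matrices[key], axis=1)
            M, C = matrices[key], cdfs[key]
            sel_m = markov == m
            for s in np.unique(state[sel_m]):
                if s == DEAD:
                    continue
                idx = np.flatnonzero(sel_m & (state == s))
                nxt = np.searchsorted(C[s], rng.random(idx.size), side="right")
                nxt = np.minimum(nxt, N_STATES - 1)
                new_state[idx] = nxt
                if s in HOSPITAL_STATES:
                    stayed = nxt == s
                    res.nicu_days[idx[stayed]] += L if s != WARD else 0.0
                    exited = idx[~stayed]
                    if exited.size and s != WARD:
                        d = 1.0 - (M[s, s]) ** (1.0 / L) if L > 1 else 1.0 - M[s, s]
                        res.nicu_days[exited] += _truncated_geometric_days(
                            rng, d, L, exited.size
                        )
                # event tallies driven by realized transitions
                if s == TRAIN and m == 1:
                    res.ngt_discharges[idx] += (nxt == WARD) | (
                        (nxt >= HOME) & (nxt < HOME + N_YEARS)
                    )
                if HOME <= s < HOME + N_YEARS:
                    res.home_infections[idx] += (nxt >= HOME_INF) & (nxt < HOME_INF + N_YEARS)
                    res.rehosp_events[idx] += (nxt >= REHOSP) & (nxt < REHOSP + N_YEARS)
                res.deaths[idx] += nxt == DEAD
        state = new_state

        if i + 1 < len(grid) and grid.cycles[i + 1].year_cluster > cyc.year_cluster:
            c = cyc.year_cluster
            for base in HOME_BLOCKS:
                state[state == base + c] = base + c + 1
    return res
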