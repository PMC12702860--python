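"""Uncertainty apparatus: PSA, tornado OWSA, TTD sweep, threshold, subgroups.

The probabilistic sensitivity analysis draws every parameter once per
iteration from its assigned distribution and applies the same draw to both
arms (shared inputs are correlated across arms; arm-specific efficacy inputs
are separate named parameters and therefore vary independently).  Uncertainty
intervals are empirical 2.5th/97.5th percentiles of the per-iteration arm
differences, and the probability of cost saving is the share of iterations in
which the comparator arm costs more than the intervention arm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Arm, run_cohort
from .costing import (
    BudgetImpact,
    CostBreakdown,
    Perspective,
    attach_costs,
    compare,
)
from .parameters import Kind, ParameterError, ParameterSet, perturb, sample

logger = logging.getLogger(__name__)


def base_case(ps: ParameterSet, persp: Perspective) -> BudgetImpact:
    """Deterministic run of both arms under one perspective."""
    breakdowns = {
        arm: attach_costs(run_cohort(ps, arm), ps, persp) for arm in (Arm.PFOS, Arm.SOC)
    }
    return compare(breakdowns[Arm.PFOS], breakdowns[Arm.SOC])


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAResult:
    perspective: Perspective
    n_iterations: int
    master_seed: int
    n_patients: float
    total_pfos: np.ndarray           # (n,) per-iteration arm totals
    total_soc: np.ndarray
    category_diffs: pd.DataFrame     # (n, categories) per-iteration differences
    n_skipped: int = 0

    @property
    def differences(self) -> np.ndarray:
        """Per-iteration total-cost difference, intervention minus comparator."""
        return self.total_pfos - self.total_soc

    @property
    def savings(self) -> np.ndarray:
        return self.total_soc - self.total_pfos

    @property
    def mean_difference(self) -> float:
        return float(self.differences.mean())

    @property
    def uncertainty_interval(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.differences, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def prob_cost_saving(self) -> float:
        return float((self.savings > 0.0).mean())

    def category_ui(self) -> pd.DataFrame:
        q = self.category_diffs.quantile([0.025, 0.5, 0.975])
        out = q.T
        out.columns = ["ui_lower", "median", "ui_upper"]
        out.insert(0, "mean", self.category_diffs.mean())
        return out


def run_psa(
    ps: ParameterSet, persp: Perspective, n_iter: int = 5000, seed: int = 0
) -> PSAResult:
    """Monte Carlo PSA: one joint parameter draw and both arm runs per iteration."""
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    child_seeds = np.random.SeedSequence(seed).spawn(n_iter)
    totals = {Arm.PFOS: [], Arm.SOC: []}
    diff_rows = []
    skipped = 0
    for i in range(n_iter):
        rng = np.random.default_rng(child_seeds[i])
        try:
            drawn = sample(ps, rng)
            row: dict[str, float] = {}
            it_totals = {}
            breakdowns = {}
            for arm in (Arm.PFOS, Arm.SOC):
                breakdowns[arm] = attach_costs(run_cohort(drawn, arm), drawn, persp)
                it_totals[arm] = breakdowns[arm].total
            impact = compare(breakdowns[Arm.PFOS], breakdowns[Arm.SOC])
        except (ParameterError, ValueError, RuntimeError) as exc:
            skipped += 1
            logger.warning("PSA iteration %d skipped: %s", i, exc)
            continue
        totals[Arm.PFOS].append(it_totals[Arm.PFOS])
        totals[Arm.SOC].append(it_totals[Arm.SOC])
        diff_rows.append(impact.categories)
    if skipped > 0.01 * n_iter:
        raise RuntimeError(f"PSA failed: {skipped}/{n_iter} iterations skipped")
    return PSAResult(
        perspective=persp,
        n_iterations=n_iter - skipped,
        master_seed=seed,
        n_patients=ps.n_patients,
        total_pfos=np.asarray(totals[Arm.PFOS]),
        total_soc=np.asarray(totals[Arm.SOC]),
        category_diffs=pd.DataFrame(diff_rows),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# one-way sensitivity analysis (tornado)


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_result: float    # total difference at value * (1 - frac)
    high_result: float   # total difference at value * (1 + frac)
    base_result: float
    clamped: bool
    rank: int = 0

    @property
    def spread(self) -> float:
        return abs(self.high_result - self.low_result)


#: parameters never varied one-way: cohort size is structural scale
OWSA_EXCLUDED = frozenset({"n_patients"})


def run_owsa(
    ps: ParameterSet,
    persp: Perspective,
    frac: float = 0.20,
    top_k: int = 10,
) -> list[TornadoEntry]:
    """Tornado analysis: +/- frac one-way perturbation of every eligible parameter.

    Returns the ``top_k`` entries ranked by descending absolute spread of the
    total-cost difference; zero-spread parameters are dropped.
    """
    base = base_case(ps, persp).total_difference
    entries: list[TornadoEntry] = []
    for name in ps.names():
        if name in OWSA_EXCLUDED:
            continue
        results = []
        clamped = False
        for factor in (1.0 - frac, 1.0 + frac):
            perturbed = perturb(ps, name, factor)
            if not math.isclose(
                perturbed.value(name), ps.value(name) * factor, rel_tol=1e-12, abs_tol=1e-15
            ):
                clamped = True
            results.append(base_case(perturbed, persp).total_difference)
        entries.append(
            TornadoEntry(
                parameter=name,
                low_result=results[0],
                high_result=results[1],
                base_result=base,
                clamped=clamped,
            )
        )
    entries = [e for e in entries if e.spread > 1e-9]
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return [
        TornadoEntry(**{**e.__dict__, "rank": i + 1}) for i, e in enumerate(entries[:top_k])
    ]


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": e.rank,
                "parameter": e.parameter,
                "low_result": e.low_result,
                "high_result": e.high_result,
                "base_result": e.base_result,
                "spread": e.spread,
                "clamped": e.clamped,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# TTD sweep


TTD_GRID = tuple(round(0.5 + 0.1 * i, 1) for i in range(8))  # 0.5 .. 1.2


def ttd_sweep(
    ps: ParameterSet, persp: Perspective = Perspective.payer, grid=TTD_GRID
) -> pd.DataFrame:
    """Deterministic re-run per TTD grid point, everything else at base case."""
    base = base_case(ps, persp).total_difference
    rows = []
    for ttd in grid:
        diff = (
            base
            if math.isclose(ttd, ps.value("ttd"))
            else base_case(ps.with_value("ttd", float(ttd)), persp).total_difference
        )
        rows.append(
            {
                "ttd": float(ttd),
                "total_difference": diff,
                "pct_change_vs_base": 100.0 * (diff - base) / abs(base) if base else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# device-cost threshold analysis


@dataclass(frozen=True)
class ThresholdCurve:
    device_cost_grid: np.ndarray       # cost per patient
    prob_cost_saving: np.ndarray
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "device_cost_per_patient": self.device_cost_grid,
                "prob_cost_saving": self.prob_cost_saving,
            }
        )


DEFAULT_DEVICE_COST_GRID = tuple(range(1000, 20001, 1000))


def threshold_analysis(
    ps: ParameterSet, psa: PSAResult, grid=DEFAULT_DEVICE_COST_GRID
) -> ThresholdCurve:
    """Probability of cost saving as a deterministic per-patient device cost rises.

    Reuses the stored PSA draws: a device cost c consumes c * n_patients of
    each iteration's savings, so the curve is nonincreasing in c and equals
    the PSA's probability of cost saving at c = 0.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("device-cost grid must not be empty")
    savings = psa.savings
    n = ps.n_patients
    probs = np.array([(savings > c * n).mean() for c in grid])
    return ThresholdCurve(
        device_cost_grid=grid, prob_cost_saving=probs, n_iterations=psa.n_iterations
    )


# ---------------------------------------------------------------------------
# GAB subgroup analysis


@dataclass(frozen=True)
class SubgroupResult:
    perspective: Perspective
    subgroups: dict[str, BudgetImpact]
    pooled: BudgetImpact


def subgroup_analysis(
    ps_25_28: ParameterSet,
    ps_29_30: ParameterSet,
    persp: Perspective = Perspective.payer,
    expected_total: float | None = None,
) -> SubgroupResult:
    """Independent per-subgroup runs; pooled impact is the exact category sum."""
    n_total = ps_25_28.n_patients + ps_29_30.n_patients
    if expected_total is not None and abs(n_total - expected_total) > 1e-9:
        raise ValueError(
            f"subgroup cohort sizes sum to {n_total}, expected {expected_total}"
        )
    impacts = {
        ps.label: base_case(ps, persp) for ps in (ps_25_28, ps_29_30)
    }
    keys = [tuple(i.categories) for i in impacts.values()]
    if keys[0] != keys[1]:
        raise ValueError("subgroup category sets differ")
    a, b = impacts.values()
    pooled = BudgetImpact(
        perspective=persp,
        categories={k: a.categories[k] + b.categories[k] for k in a.categories},
        arm_totals={
            arm: a.arm_totals[arm] + b.arm_totals[arm] for arm in a.arm_totals
        },
    )
    return SubgroupResult(perspective=persp, subgroups=impacts, pooled=pooled)
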