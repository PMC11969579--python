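"""Discounting, lifetime aggregation, and incremental cost-utility ratios.

Per-person discounted life-years, QALYs and costs are summed over the cohort
trace with annual discounting at rate r: df(t) = (1+r)^-t, membership valued
at cycle start.  A strategy is cost-effective against its comparator when it
dominates (cheaper and more effective) or when its ICUR -- incremental cost
per QALY gained, computed from full-precision internals -- falls at or below
the willingness-to-pay threshold (default: one-time GDP per capita,
INR 171 498).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace, blindness_incidence
from .params import ParameterSet
from .valuation import UtilityTable

__all__ = [
    "EconResult",
    "IcurResult",
    "discount_factor",
    "aggregate",
    "icur",
    "DOMINANT",
    "DOMINATED",
]

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class EconResult:
    """Discounted per-person lifetime outcomes of one strategy."""

    ly: float
    qaly: float
    cost_hs: float
    cost_oope: float
    blindness_incidence: float

    @property
    def cost_total(self) -> float:
        return self.cost_hs + self.cost_oope

    def __post_init__(self) -> None:
        if self.qaly > self.ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")
        if self.cost_hs < -1e-9 or self.cost_oope < -1e-9:
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class IcurResult:
    """Incremental comparison of a strategy against its comparator."""

    delta_cost: float
    delta_qaly: float
    icur: float | None
    label: str | None  # dominance label when no ratio is defined or relevant
    cost_effective: bool
    wtp: float


def discount_factor(cycle: int | np.ndarray, rate: float) -> float | np.ndarray:
    """(1+rate)^(-cycle) with cycle 0 undiscounted."""
    if np.any(np.asarray(cycle) < 0):
        raise ValueError("cycle must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


def aggregate(
    trace: CohortTrace,
    utilities: UtilityTable,
    params: ParameterSet,
    discount_rate: float | None = None,
) -> EconResult:
    """Discounted lifetime totals per person from one cohort trace.

    ly = sum_t df(t) P(alive, t);  qaly weights occupancy by the utility
    table; costs add the per-cycle cascade and state-cost accruals recorded
    on the trace.
    """
    r = params["economics.discount_rate"] if discount_rate is None else discount_rate
    df = discount_factor(np.arange(trace.n_cycles), r)
    ly = float(df @ trace.alive)
    qaly = float(df @ (trace.occupancy @ utilities.weights_vector()))
    cost_hs = float(df @ trace.cost_hs)
    cost_oope = float(df @ trace.cost_oope)
    return EconResult(
        ly=ly,
        qaly=qaly,
        cost_hs=cost_hs,
        cost_oope=cost_oope,
        blindness_incidence=blindness_incidence(trace),
    )


def icur(
    intervention: EconResult, comparator: EconResult, wtp: float = 171_498.0
) -> IcurResult:
    """Incremental cost-utility ratio with dominance handling.

    dominant:  cheaper and at least as effective (strictly better on one);
    dominated: costlier and at most as effective (strictly worse on one);
    equal deltas or zero QALY difference yield no ratio.
    """
    dc = intervention.cost_total - comparator.cost_total
    dq = intervention.qaly - comparator.qaly

    if dq == 0.0 and dc == 0.0:
        return IcurResult(dc, dq, None, None, False, wtp)
    if dc <= 0.0 and dq >= 0.0:
        return IcurResult(dc, dq, None, DOMINANT, True, wtp)
    if dc >= 0.0 and dq <= 0.0:
        return IcurResult(dc, dq, None, DOMINATED, False, wtp)
    ratio = dc / dq
    cost_effective = dq > 0.0 and ratio <= wtp
    return IcurResult(dc, dq, ratio, None, cost_effective, wtp)


def net_monetary_benefit(result: EconResult, wtp: float) -> float:
    """NMB = wtp * QALY - total cost."""
    return wtp * result.qaly - result.cost_total


def evaluate_strategy(strategy, params: ParameterSet, scenario=None) -> EconResult:
    """Full pipeline for one strategy: cohort run plus discounted aggregation."""
    from .markov import run_cohort  # local import to keep module load order flat

    trace = run_cohort(strategy, params, scenario)
    return aggregate(trace, UtilityTable(params), params)
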