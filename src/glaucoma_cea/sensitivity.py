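"""Sensitivity and scenario machinery.

One-way deterministic sensitivity (tornado input), probabilistic sensitivity
analysis (Monte Carlo over the parameter distributions, 1000 iterations by
default) with cost-effectiveness acceptability curves, the two-way
public-share x medicine-availability scenario grid, and the out-of-pocket
impact comparison.  All randomness flows through one seeded generator, so
results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import Strategy
from .econ import EconResult, IcurResult, evaluate_strategy, icur, net_monetary_benefit
from .params import ParameterSet, SchemaError, dsa_range, psa_distribution
from .valuation import CareScenario

__all__ = [
    "PsaResult",
    "ScenarioGrid",
    "one_way",
    "tornado",
    "run_psa",
    "ceac",
    "scenario_grid",
]


def _comparator_for(strategy: Strategy) -> Strategy:
    return Strategy.usual_care(strategy.population)


def one_way(
    params: ParameterSet, parameter_name: str, strategy: Strategy
) -> tuple[IcurResult, IcurResult]:
    """Re-run the full pipeline at the parameter's DSA range endpoints.

    Returns the ICUR of ``strategy`` versus usual care with the named
    parameter at its low and high value, everything else at base case.
    """
    spec = params.spec(parameter_name)  # raises SchemaError if unknown
    low, high = dsa_range(spec)
    comparator = _comparator_for(strategy)
    out = []
    for v in (low, high):
        p = params.with_values({parameter_name: v})
        out.append(icur(evaluate_strategy(strategy, p), evaluate_strategy(comparator, p),
                        wtp=params["economics.wtp"]))
    return out[0], out[1]


def tornado(
    params: ParameterSet, parameter_names: list[str], strategy: Strategy
) -> pd.DataFrame:
    """One-way results for several parameters, widest ICUR swing first."""
    base = icur(
        evaluate_strategy(strategy, params),
        evaluate_strategy(_comparator_for(strategy), params),
        wtp=params["economics.wtp"],
    )
    rows = []
    for name in parameter_names:
        lo, hi = one_way(params, name, strategy)
        vals = [r.icur for r in (lo, hi) if r.icur is not None]
        swing = (max(vals) - min(vals)) if len(vals) == 2 else np.nan
        rows.append(
            {
                "parameter": name,
                "icur_low": lo.icur,
                "icur_high": hi.icur,
                "icur_base": base.icur,
                "swing": swing,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("swing", ascending=False, na_position="last")
        .reset_index(drop=True)
    )


@dataclass
class PsaResult:
    """Per-draw lifetime outcomes for each strategy on common parameter draws."""

    seed: int
    n_iterations: int
    strategies: list[str]
    results: dict[str, list[EconResult]] = field(repr=False)
    draws: pd.DataFrame = field(repr=False)  # (n_iterations, n_parameters)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def run_psa(
    params: ParameterSet,
    strategies: list[Strategy],
    n: int = 1000,
    seed: int = 0,
) -> PsaResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Each iteration draws every uncertain parameter (beta for probabilities
    and utilities, gamma for costs; draws uncorrelated), then runs all
    strategies and their usual-care comparators on the same draw.
    Demographics, the discount rate and the willingness-to-pay threshold are
    held fixed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    uncertain = sorted(params.uncertain_specs(), key=lambda s: s.name)
    dists = {s.name: psa_distribution(s) for s in uncertain}

    run_set: list[Strategy] = []
    for st in strategies:
        if st not in run_set:
            run_set.append(st)
        comp = _comparator_for(st)
        if comp not in run_set:
            run_set.append(comp)

    names = [s.name for s in run_set]
    results: dict[str, list[EconResult]] = {name: [] for name in names}
    draw_rows = []
    for _ in range(n):
        overrides = {
            name: float(dist.rvs(random_state=rng)) for name, dist in dists.items()
        }
        draw_rows.append(overrides)
        p = params.with_values(overrides)
        for st, name in zip(run_set, names):
            results[name].append(evaluate_strategy(st, p))
    return PsaResult(
        seed=seed,
        n_iterations=n,
        strategies=names,
        results=results,
        draws=pd.DataFrame(draw_rows),
    )


def ceac(
    psa: PsaResult,
    strategy: Strategy | str,
    wtp_grid: np.ndarray,
    comparator: Strategy | str | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay value, the probability that the strategy's
    net monetary benefit exceeds the comparator's across PSA draws.
    """
    s_name = strategy if isinstance(strategy, str) else strategy.name
    if comparator is None:
        comparator = _comparator_for(
            strategy if isinstance(strategy, Strategy) else _strategy_by_name(psa, s_name)
        )
    c_name = comparator if isinstance(comparator, str) else comparator.name
    if s_name not in psa.results or c_name not in psa.results:
        raise KeyError(f"strategy {s_name!r} or comparator {c_name!r} not in PSA draws")
    rows = []
    for wtp in np.asarray(wtp_grid, dtype=float):
        wins = [
            net_monetary_benefit(a, wtp) > net_monetary_benefit(b, wtp)
            for a, b in zip(psa.results[s_name], psa.results[c_name])
        ]
        rows.append({"wtp": wtp, "p_cost_effective": float(np.mean(wins))})
    return pd.DataFrame(rows)


def _strategy_by_name(psa: PsaResult, name: str) -> Strategy:
    from .cascade import strategy_from_name

    return strategy_from_name(name)


@dataclass
class ScenarioGrid:
    """Two-way grid of care-seeking scenarios for one strategy."""

    strategy: str
    cells: pd.DataFrame  # public_share, medicine_availability, icur, ...


def scenario_grid(
    params: ParameterSet,
    strategy: Strategy,
    shares_grid: np.ndarray,
    availability_grid: np.ndarray,
) -> ScenarioGrid:
    """Public-sector strengthening scenarios.

    Each cell sets the public share (applied to both outpatient and
    inpatient care) and the free-medicine availability for the screened
    pathway's post-referral care; the usual-care comparator keeps baseline
    behaviour.  Reports the ICUR and the OOPE and total-cost deltas versus
    usual care per cell.
    """
    shares = np.asarray(shares_grid, dtype=float)
    avails = np.asarray(availability_grid, dtype=float)
    for g in (shares, avails):
        if np.any((g < 0) | (g > 1)):
            raise ValueError("grid values must lie in [0,1]")
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid axes must be strictly increasing")
    comparator = evaluate_strategy(_comparator_for(strategy), params)
    wtp = params["economics.wtp"]
    rows = []
    for share in shares:
        for avail in avails:
            scenario = CareScenario(
                public_share_outpatient=float(share),
                public_share_inpatient=float(share),
                medicine_availability=float(avail),
            )
            res = evaluate_strategy(strategy, params, scenario)
            cmp_res = icur(res, comparator, wtp=wtp)
            rows.append(
                {
                    "public_share": float(share),
                    "medicine_availability": float(avail),
                    "icur": cmp_res.icur,
                    "label": cmp_res.label,
                    "cost_effective": cmp_res.cost_effective,
                    "delta_cost_total": res.cost_total - comparator.cost_total,
                    "delta_oope": res.cost_oope - comparator.cost_oope,
                    "delta_qaly": res.qaly - comparator.qaly,
                }
            )
    return ScenarioGrid(strategy=strategy.name, cells=pd.DataFrame(rows))
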