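"""Costing and utility valuation of health states and cascade events.

Costs (INR, 2022) are split by payer into health-system spending and
out-of-pocket expenditure (OOPE), and weighted over the public/private sector
mix: the public share of outpatient contacts applies to consultations,
diagnostics and medicines, and the public inpatient share to surgery.
Medicines dispensed at public facilities are free only to the extent of the
configured availability fraction; the shortfall is bought out of pocket.
Utilities combine a vision-state utility with a comorbidity utility
multiplicatively; treatment does not change the utility of a given vision
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .params import ParameterSet
from .states import STATE_SPACE, Arm, State, stage_param_key

if TYPE_CHECKING:  # pragma: no cover
    from .cascade import Strategy

__all__ = [
    "CareScenario",
    "CostBreakdown",
    "UtilityTable",
    "combined_utility",
    "state_cost",
    "screening_programme_cost",
    "confirmatory_workup_cost",
    "surgery_cost",
]


@dataclass(frozen=True)
class CareScenario:
    """Care-seeking overrides for scenario analysis of the screened pathway.

    ``None`` fields fall back to the baseline parameter values.
    """

    public_share_outpatient: float | None = None
    public_share_inpatient: float | None = None
    medicine_availability: float | None = None

    def outpatient_share(self, params: ParameterSet) -> float:
        if self.public_share_outpatient is not None:
            return self.public_share_outpatient
        return params["care_seeking.public_share_outpatient"]

    def inpatient_share(self, params: ParameterSet) -> float:
        if self.public_share_inpatient is not None:
            return self.public_share_inpatient
        return params["care_seeking.public_share_inpatient"]

    def availability(self, params: ParameterSet) -> float:
        if self.medicine_availability is not None:
            return self.medicine_availability
        return params["cost.medicine_availability"]


_BASELINE = CareScenario()


@dataclass(frozen=True)
class CostBreakdown:
    """Annual (or one-time) cost split by payer, with named components."""

    health_system: float = 0.0
    oope: float = 0.0
    components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.health_system < -1e-9 or self.oope < -1e-9:
            raise ValueError("costs must be non-negative")
        if self.components:
            total = sum(self.components.values())
            if abs(total - self.total) > 1e-6:
                raise ValueError(
                    f"components sum {total} != health_system+oope {self.total}"
                )

    @property
    def total(self) -> float:
        return self.health_system + self.oope

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        comps = dict(self.components)
        for k, v in other.components.items():
            comps[k] = comps.get(k, 0.0) + v
        return CostBreakdown(self.health_system + other.health_system, self.oope + other.oope, comps)


ZERO_COST = CostBreakdown()


def combined_utility(u_state: float, u_comorbidity: float) -> float:
    """Multiplicative combination of a vision-state and a comorbidity utility."""
    if not (0.0 <= u_state <= 1.0 and 0.0 <= u_comorbidity <= 1.0):
        raise ValueError("utilities must be in [0,1]")
    return u_state * u_comorbidity


class UtilityTable:
    """Per-state QALY weights with the population-average comorbidity mix."""

    def __init__(self, params: ParameterSet):
        self._params = params
        shares = {
            k: params[f"utility.share_{k}"]
            for k in ("none", "hypertension", "diabetes", "both")
        }
        self.comorbidity_multiplier = sum(
            shares[k] * params[f"utility.comorbidity_{k}"] for k in shares
        )
        self._state_utility: dict[State, float] = {}
        for state in STATE_SPACE:
            if state.arm is Arm.DEAD:
                u = 0.0
            elif state.arm is Arm.DISEASE_FREE:
                u = params["utility.disease_free"]
            else:
                u = params[f"utility.{stage_param_key(state.arm, state.stage)}"]
            self._state_utility[state] = u

    def state_utility(self, state: State) -> float:
        return self._state_utility[state]

    def weight(self, state: State) -> float:
        """QALY weight: state utility x average comorbidity utility (0 if dead)."""
        if state.arm is Arm.DEAD:
            return 0.0
        return combined_utility(self._state_utility[state], self.comorbidity_multiplier)

    def weights_vector(self) -> np.ndarray:
        return np.array([self.weight(s) for s in STATE_SPACE])


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------


def screening_programme_cost(strategy: "Strategy", params: ParameterSet) -> float:
    """Programme cost (INR, health-system) per screened person.

    Variable cost per face-to-face screen, plus the AI per-scan fee in AI
    mode, plus training/supervision overheads apportioned over the persons
    screened per primary health centre in one screening round (overheads
    accrue over the full 5-year interval for quinquennial rounds).
    """
    if not strategy.is_screening:
        raise ValueError("screening programme cost undefined for usual care")
    variable = params["cost.screening.variable_f2f"]
    if strategy.mode == "ai_f2f":
        variable += params["cost.screening.ai_scan"]
    n = params["cost.screening.screened_per_phc_year"]
    years = 5.0 if strategy.frequency == "quinquennial" else 1.0
    overhead = params["cost.screening.overhead_per_phc_year"] * years / n if n > 0 else 0.0
    return variable + overhead


def confirmatory_workup_cost(
    params: ParameterSet, scenario: CareScenario | None = None
) -> CostBreakdown:
    """Cost of one confirmatory work-up attendance, sector-weighted."""
    sc = scenario or _BASELINE
    share = sc.outpatient_share(params)
    hs = share * params["cost.workup.public_hs"]
    oope = share * params["cost.workup.public_oope"] + (1.0 - share) * params[
        "cost.workup.private_oope"
    ]
    return CostBreakdown(hs, oope, {"diagnostics": hs + oope})


def surgery_cost(
    arm: Arm, stage: str, params: ParameterSet, scenario: CareScenario | None = None
) -> CostBreakdown:
    """One-time surgical cost at treatment initiation, by arm and stage.

    Angle-closure disease receives laser iridotomy at any stage;
    open-angle disease receives trabeculectomy from the severe stage
    onwards (milder POAG starts on medication only).  Weighted by the
    public inpatient share.
    """
    sc = scenario or _BASELINE
    share = sc.inpatient_share(params)
    if arm is Arm.PACD:
        proc = "iridotomy"
    elif arm is Arm.POAG and stage in ("severe", "unilateral_blind", "bilateral_blind"):
        proc = "trabeculectomy"
    else:
        return ZERO_COST
    hs = share * params[f"cost.surgery.{proc}_public_hs"]
    oope = share * params[f"cost.surgery.{proc}_public_oope"] + (1.0 - share) * params[
        f"cost.surgery.{proc}_private_oope"
    ]
    return CostBreakdown(hs, oope, {"surgery": hs + oope})


def state_cost(
    state: State, params: ParameterSet, scenario: CareScenario | None = None
) -> CostBreakdown:
    """Annual management cost of one person-year spent in a state.

    Only treated states accrue treatment costs (consultations, diagnostics,
    medicines, non-medical travel); undiagnosed and diagnosed-but-untreated
    states cost nothing on an annual basis.  Screening and work-up costs are
    charged by the cascade, and surgery at treatment initiation.
    """
    if not state.alive:
        raise ValueError("state_cost applies to living states only")
    if not (state.diseased and state.treated):
        return ZERO_COST
    sc = scenario or _BASELINE
    share = sc.outpatient_share(params)
    avail = sc.availability(params)

    consult_hs = share * params["cost.annual.consult_public_hs"]
    consult_oope = share * params["cost.annual.consult_public_oope"] + (
        1.0 - share
    ) * params["cost.annual.consult_private_oope"]
    diag_hs = share * params["cost.annual.diagnostics_public_hs"]
    diag_oope = share * params["cost.annual.diagnostics_public_oope"] + (
        1.0 - share
    ) * params["cost.annual.diagnostics_private_oope"]
    med = params["cost.annual.medicines"]
    # public users get the available fraction free; the rest is OOPE
    med_hs = share * avail * med
    med_oope = share * (1.0 - avail) * med + (1.0 - share) * med
    non_medical = params["cost.annual.non_medical"]  # travel etc., always OOPE

    hs = consult_hs + diag_hs + med_hs
    oope = consult_oope + diag_oope + med_oope + non_medical
    return CostBreakdown(
        hs,
        oope,
        {
            "consultation": consult_hs + consult_oope,
            "diagnostics": diag_hs + diag_oope,
            "medicines": med_hs + med_oope,
            "non_medical": non_medical,
        },
    )
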