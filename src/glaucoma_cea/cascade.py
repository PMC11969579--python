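"""Screening-cascade decision tree.

Per cycle and per true health state this module computes the probability of
being screened, flagged positive, referred, confirmed at a higher facility
and started on treatment, together with the expected cascade costs per person
entering the cycle -- for each of the 12 systematic screening strategies and
for opportunistic detection under usual care.

Test-to-state mapping: tonometry detects raised intraocular pressure
(OHT and POAG); fundus imaging detects POAG structural damage (graded by a
human in F2F mode or by a deep-learning algorithm in AI mode, with an
ungradable fraction routed straight to referral); angle closure is screened
by tonometry followed by the oblique flashlight test in series.  Referrals
receive a gold-standard work-up assumed to reveal the true state, so false
positives are confirmed negative, accrue the work-up cost, and return to the
undiagnosed pool within the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterSet
from .states import Arm, State
from . import valuation

__all__ = [
    "Strategy",
    "CascadeResult",
    "NULL_CASCADE",
    "series_test",
    "cascade",
    "usual_care_detection",
    "all_screening_strategies",
    "strategy_from_name",
]

POPULATIONS = ("40-75", "50-75")
RISK_FILTERS = ("universal", "high_risk")
MODES = ("f2f", "ai_f2f", "usual_care")
FREQUENCIES = ("annual", "quinquennial")

_SCREENING_UPPER_AGE = 75


@dataclass(frozen=True)
class Strategy:
    """One screening configuration (or usual care)."""

    population: str = "40-75"
    risk_filter: str = "universal"
    mode: str = "usual_care"
    frequency: str = "annual"

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")
        if self.risk_filter not in RISK_FILTERS:
            raise ValueError(f"risk_filter must be one of {RISK_FILTERS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.frequency not in FREQUENCIES:
            raise ValueError(f"frequency must be one of {FREQUENCIES}")
        if self.is_screening and self.frequency == "quinquennial" and self.population != "40-75":
            raise ValueError("quinquennial screening is only defined for the 40-75 population")

    @property
    def is_screening(self) -> bool:
        return self.mode != "usual_care"

    @property
    def start_age(self) -> int:
        return 40 if self.population == "40-75" else 50

    @property
    def name(self) -> str:
        if not self.is_screening:
            return f"usual_care_{self.population.replace('-', '_')}"
        return "_".join(
            (self.frequency, self.mode, self.risk_filter, self.population.replace("-", "_"))
        )

    @classmethod
    def usual_care(cls, population: str = "40-75") -> "Strategy":
        return cls(population=population, mode="usual_care")

    def screening_due(self, cycle: int, age: int) -> bool:
        """Is organised screening offered in this cycle?"""
        if not self.is_screening or age > _SCREENING_UPPER_AGE:
            return False
        if self.frequency == "quinquennial":
            return cycle % 5 == 0
        return True


def all_screening_strategies() -> list[Strategy]:
    """The 12 configurations: 8 annual (2 populations x 2 filters x 2 modes)
    plus 4 quinquennial (40-75 only)."""
    out = []
    for frequency in FREQUENCIES:
        for population in POPULATIONS:
            if frequency == "quinquennial" and population != "40-75":
                continue
            for risk_filter in RISK_FILTERS:
                for mode in ("f2f", "ai_f2f"):
                    out.append(Strategy(population, risk_filter, mode, frequency))
    return out


def strategy_from_name(name: str) -> Strategy:
    for s in all_screening_strategies() + [Strategy.usual_care(p) for p in POPULATIONS]:
        if s.name == name:
            return s
    valid = sorted(s.name for s in all_screening_strategies()) + [
        Strategy.usual_care(p).name for p in POPULATIONS
    ]
    raise ValueError(f"unknown strategy {name!r}; valid names: {', '.join(valid)}")


@dataclass(frozen=True)
class CascadeResult:
    """Cascade probabilities conditional on one true health state, plus the
    expected cascade cost (INR) per person entering the cycle in that state."""

    p_screened: float = 0.0
    p_test_positive: float = 0.0
    p_referred: float = 0.0
    p_confirmed: float = 0.0
    p_treated: float = 0.0
    expected_cost_hs: float = 0.0
    expected_cost_oope: float = 0.0

    def __post_init__(self) -> None:
        for f in ("p_screened", "p_test_positive", "p_referred", "p_confirmed", "p_treated"):
            v = getattr(self, f)
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{f}={v} outside [0,1]")


NULL_CASCADE = CascadeResult()


def series_test(
    sens1: float, spec1: float, sens2: float, spec2: float
) -> tuple[float, float]:
    """Combined accuracy of two tests in series (second applied to first-test
    positives; overall positive requires both positive).

    sens = sens1*sens2;  spec = spec1 + (1-spec1)*spec2.
    """
    for v in (sens1, spec1, sens2, spec2):
        if not (0.0 <= v <= 1.0):
            raise ValueError("test accuracies must be in [0,1]")
    return sens1 * sens2, spec1 + (1.0 - spec1) * spec2


def _test_positive_prob(state: State, params: ParameterSet, mode: str) -> float:
    """P(flagged positive | screened, true state).

    A person is referred if any channel flags them: tonometry positive
    (pressure channel), fundus image ungradable or graded positive, or the
    tonometry+flashlight series positive (angle channel, counted only for
    angle-closure disease to avoid double-counting tonometry).
    """
    sens_t = params["screening.sens_tonometry"]
    spec_t = params["screening.spec_tonometry"]
    suffix = "ai" if mode == "ai_f2f" else "f2f"
    sens_f = params[f"screening.sens_fundus_{suffix}"]
    spec_f = params[f"screening.spec_fundus_{suffix}"]
    u = params["screening.ungradable_rate"]

    if state.arm is Arm.DISEASE_FREE:
        # not referred <=> tonometry negative AND fundus gradable-and-negative
        return 1.0 - spec_t * (1.0 - u) * spec_f
    if state.arm is Arm.POAG:
        if state.stage == "oht":
            # raised pressure only; structural fundus signs absent
            return 1.0 - (1.0 - sens_t) * (1.0 - u) * spec_f
        return 1.0 - (1.0 - sens_t) * (1.0 - u) * (1.0 - sens_f)
    if state.arm is Arm.PACD:
        sens_series, _ = series_test(
            sens_t,
            spec_t,
            params["screening.sens_flashlight"],
            params["screening.spec_flashlight"],
        )
        return 1.0 - (1.0 - sens_series) * (1.0 - u) * spec_f
    raise ValueError(f"no screening pathway for state {state!r}")


def _risk_filter_eligibility(state: State, params: ParameterSet, strategy: Strategy) -> float:
    """Fraction of persons in this true state reachable by the strategy.

    High-risk strategies screen only the high-risk subgroup.  Because
    glaucoma incidence is elevated in that subgroup (relative risk
    ``epi.high_risk_rr``), diseased persons are over-represented in it; the
    cohort-expectation enrichment is f*rr / (f*rr + 1 - f).
    """
    if strategy.risk_filter == "universal":
        return 1.0
    f = params["epi.high_risk_fraction"]
    rr = params["epi.high_risk_rr"]
    if state.diseased:
        denom = f * rr + (1.0 - f)
        return f * rr / denom if denom > 0 else 0.0
    return f


def cascade(
    strategy: Strategy,
    true_state: State,
    params: ParameterSet,
    cycle: int,
    scenario: "valuation.CareScenario | None" = None,
) -> CascadeResult:
    """Decision-tree expectations for one true state in one cycle.

    Referred persons attend confirmatory diagnosis with probability
    1 - ltfu_diagnosis; the gold standard reveals the true state, so only
    truly diseased attendees are confirmed; confirmed cases initiate
    treatment with probability 1 - ltfu_treatment.
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if not true_state.alive:
        raise ValueError("cascade applies to living states only")
    age = strategy.start_age + cycle
    if not strategy.screening_due(cycle, age):
        return NULL_CASCADE
    coverage = params["screening.coverage"]
    p_screened = coverage * _risk_filter_eligibility(true_state, params, strategy)
    if p_screened == 0.0:
        return NULL_CASCADE
    p_pos = _test_positive_prob(true_state, params, strategy.mode)
    p_referred = p_screened * p_pos
    attend = p_referred * (1.0 - params["screening.ltfu_diagnosis"])
    p_confirmed = attend if true_state.diseased else 0.0
    p_treated = p_confirmed * (1.0 - params["screening.ltfu_treatment"])

    programme = valuation.screening_programme_cost(strategy, params)
    workup = valuation.confirmatory_workup_cost(params, scenario)
    cost_hs = p_screened * programme + attend * workup.health_system
    cost_oope = attend * workup.oope
    return CascadeResult(
        p_screened=p_screened,
        p_test_positive=p_pos,
        p_referred=p_referred,
        p_confirmed=p_confirmed,
        p_treated=p_treated,
        expected_cost_hs=cost_hs,
        expected_cost_oope=cost_oope,
    )


def usual_care_detection(true_state: State, params: ParameterSet) -> CascadeResult:
    """Opportunistic detection: each cycle, an undiagnosed person with
    manifest glaucoma consults an ophthalmologist with probability
    ``usual_care.consult_prob`` (interpreted as an annual hazard) and, once
    confirmed, starts treatment with probability ``usual_care.treat_prob``.

    Asymptomatic precursors (OHT, PACS, PAC) and disease-free persons are
    not detected opportunistically.  Work-up costs accrue at the baseline
    sector mix.
    """
    if not true_state.alive:
        raise ValueError("usual-care detection applies to living states only")
    if not true_state.manifest_glaucoma or true_state.diagnosed:
        return NULL_CASCADE
    p_consult = params["usual_care.consult_prob"]
    p_confirmed = p_consult
    p_treated = p_confirmed * params["usual_care.treat_prob"]
    workup = valuation.confirmatory_workup_cost(params, None)
    return CascadeResult(
        p_screened=0.0,
        p_test_positive=0.0,
        p_referred=p_consult,
        p_confirmed=p_confirmed,
        p_treated=p_treated,
        expected_cost_hs=p_consult * workup.health_system,
        expected_cost_oope=p_consult * workup.oope,
    )
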