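"""Lifetime Markov cohort model of glaucoma natural history.

Annual cycles from the start age to the maximum age.  Each cycle: the
screening cascade and the opportunistic (usual-care) pathway move undiagnosed
mass into diagnosed/treated sub-states; state membership is then valued (no
half-cycle correction); finally the age-specific transition matrix is applied.
Competing risks are resolved death-first -- the age-specific background death
probability (multiplied by 2.34 in blind states, capped at 1) applies first,
and disease progression applies to survivors, so a forward move has
probability (1-q)*p.  Vision loss is irreversible: transitions never move
backwards across severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CascadeResult, Strategy, cascade, usual_care_detection
from .params import ParameterSet, ValidationError
from .states import (
    DEAD_INDEX,
    DISEASE_FREE_INDEX,
    DISEASED_STAGES,
    N_STATES,
    STATE_INDEX,
    STATE_SPACE,
    Arm,
    State,
    next_stage,
    stage_param_key,
)
from .valuation import CareScenario, state_cost, surgery_cost

__all__ = [
    "CohortTrace",
    "death_probability",
    "build_transition_matrix",
    "run_cohort",
    "blindness_incidence",
    "one_cycle_incidence",
    "baseline_occupancy",
]

_PROGRESSION_KEY = {
    (Arm.POAG, "oht"): "oht_to_mild",
    (Arm.POAG, "mild"): "mild_to_moderate",
    (Arm.POAG, "moderate"): "moderate_to_severe",
    (Arm.POAG, "severe"): "severe_to_unilateral",
    (Arm.POAG, "unilateral_blind"): "poag_unilateral_to_bilateral",
    (Arm.PACD, "pacs"): "pacs_to_pac",
    (Arm.PACD, "pac"): "pac_to_pacg",
    (Arm.PACD, "pacg"): "pacg_to_unilateral",
    (Arm.PACD, "unilateral_blind"): "pacd_unilateral_to_bilateral",
}

_BLIND_INDICES = np.array(
    [i for i, s in enumerate(STATE_SPACE) if s.blind], dtype=int
)
_NONBLIND_ALIVE = np.array(
    [i for i, s in enumerate(STATE_SPACE) if s.alive and not s.blind], dtype=int
)


def death_probability(age: float, state: State, params: ParameterSet) -> float:
    """Annual death probability: life-table qx, times the blindness mortality
    multiplier for blind states, capped at 1."""
    q = params.qx(age)
    if state.blind:
        key = (
            "mortality.blindness_multiplier_unilateral"
            if state.stage == "unilateral_blind"
            else "mortality.blindness_multiplier_bilateral"
        )
        return min(1.0, params[key] * q)
    return q


def _progression_probability(state: State, params: ParameterSet) -> float:
    key = _PROGRESSION_KEY.get((state.arm, state.stage))
    if key is None:
        return 0.0
    p = params[f"epi.progression.{key}"]
    if state.treated:
        rr = params[
            "epi.treatment_rr_poag" if state.arm is Arm.POAG else "epi.treatment_rr_pacd"
        ]
        p = min(1.0, p * rr)
    return p


def build_transition_matrix(age: float, params: ParameterSet) -> np.ndarray:
    """Annual transition matrix over the full state space at one age.

    Rows sum to 1 by construction (death-first competing risks); no
    renormalisation is performed.  An incidence or progression bundle whose
    conditional probabilities exceed 1 raises a parameter-inconsistency
    error naming the offending row.
    """
    m = np.zeros((N_STATES, N_STATES))
    inc = {
        "oht": params["epi.incidence_oht"],
        "poag": params["epi.incidence_poag"],
        "pacs": params["epi.incidence_pacs"],
    }
    if sum(inc.values()) > 1.0:
        raise ValidationError("disease_free: incidence probabilities sum above 1")
    i_oht = STATE_INDEX[State(Arm.POAG, "oht")]
    i_mild = STATE_INDEX[State(Arm.POAG, "mild")]
    i_pacs = STATE_INDEX[State(Arm.PACD, "pacs")]
    for i, s in enumerate(STATE_SPACE):
        if not s.alive:
            m[i, DEAD_INDEX] = 1.0
            continue
        q = death_probability(age, s, params)
        m[i, DEAD_INDEX] = q
        surv = 1.0 - q
        if s.arm is Arm.DISEASE_FREE:
            m[i, i_oht] = surv * inc["oht"]
            m[i, i_mild] = surv * inc["poag"]
            m[i, i_pacs] = surv * inc["pacs"]
            m[i, i] = surv * (1.0 - sum(inc.values()))
        else:
            p = _progression_probability(s, params)
            if p > 1.0:
                raise ValidationError(f"{s.label}: progression probability {p} above 1")
            nxt = next_stage(s.arm, s.stage)
            if nxt is None or p == 0.0:
                m[i, i] = surv
            else:
                j = STATE_INDEX[State(s.arm, nxt, s.diagnosed, s.treated)]
                m[i, j] = surv * p
                m[i, i] = surv * (1.0 - p)
    return m


def baseline_occupancy(params: ParameterSet) -> np.ndarray:
    """Initial cohort distribution: configured stage prevalences, all
    undiagnosed, with the disease-free residual."""
    occ = np.zeros(N_STATES)
    for arm, stage in DISEASED_STAGES:
        idx = STATE_INDEX[State(arm, stage)]
        occ[idx] = params[f"epi.prevalence.{stage_param_key(arm, stage)}"]
    occ[DISEASE_FREE_INDEX] = params.disease_free_share
    if occ[DISEASE_FREE_INDEX] < -1e-12:
        raise ValidationError("baseline prevalences exceed 1")
    return occ


@dataclass
class CohortTrace:
    """Cycle-by-cycle occupancy with undiscounted per-cycle accruals.

    ``occupancy[t]`` is the distribution at the start of cycle ``t`` after
    detection has acted; accruals (costs) are totals booked during cycle
    ``t``.  ``blind_entries[t]`` is the probability mass first entering a
    blind state during the cycle-``t`` transition.
    """

    ages: np.ndarray
    occupancy: np.ndarray  # (T, S)
    cost_hs: np.ndarray  # (T,)
    cost_oope: np.ndarray  # (T,)
    blind_entries: np.ndarray  # (T,)
    final: np.ndarray = field(repr=False, default=None)  # (S,) after last cycle

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD_INDEX]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per cycle, one column per state plus age."""
        df = pd.DataFrame(self.occupancy, columns=[s.label for s in STATE_SPACE])
        df.insert(0, "age", self.ages)
        df["cost_hs"] = self.cost_hs
        df["cost_oope"] = self.cost_oope
        df["blind_entries"] = self.blind_entries
        return df


def _apply_detection(
    occ: np.ndarray,
    results: dict[int, CascadeResult],
    params: ParameterSet,
    scenario: CareScenario | None,
) -> tuple[np.ndarray, float, float]:
    """Move undiagnosed mass to diagnosed/treated sub-states; return costs."""
    cost_hs = 0.0
    cost_oope = 0.0
    out = occ.copy()
    for i, res in results.items():
        mass = occ[i]
        if mass == 0.0 or res is None:
            continue
        cost_hs += mass * res.expected_cost_hs
        cost_oope += mass * res.expected_cost_oope
        s = STATE_SPACE[i]
        if not s.diseased or s.diagnosed:
            continue
        treated_flow = mass * res.p_treated
        diagnosed_flow = mass * (res.p_confirmed - res.p_treated)
        if treated_flow > 0.0:
            j = STATE_INDEX[State(s.arm, s.stage, True, True)]
            out[i] -= treated_flow
            out[j] += treated_flow
            surg = surgery_cost(s.arm, s.stage, params, scenario)
            cost_hs += treated_flow * surg.health_system
            cost_oope += treated_flow * surg.oope
        if diagnosed_flow > 0.0:
            j = STATE_INDEX[State(s.arm, s.stage, True, False)]
            out[i] -= diagnosed_flow
            out[j] += diagnosed_flow
    return out, cost_hs, cost_oope


def run_cohort(
    strategy: Strategy,
    params: ParameterSet,
    scenario: CareScenario | None = None,
) -> CohortTrace:
    """Deterministic cohort run of one strategy over the lifetime horizon.

    ``scenario`` overrides the care-seeking sector mix for the screened
    pathway's confirmatory and treatment care (screening strategies only);
    usual care always keeps baseline behaviour.
    """
    start_age = strategy.start_age
    max_age = int(params["demographics.max_age"])
    ages = np.arange(start_age, max_age + 1)
    n = len(ages)
    post_referral_scenario = scenario if strategy.is_screening else None

    occupancy = np.zeros((n, N_STATES))
    cost_hs = np.zeros(n)
    cost_oope = np.zeros(n)
    blind_entries = np.zeros(n)

    # annual state costs per state vector (scenario applies in screening arms)
    annual_hs = np.zeros(N_STATES)
    annual_oope = np.zeros(N_STATES)
    for i, s in enumerate(STATE_SPACE):
        if s.alive:
            cb = state_cost(s, params, post_referral_scenario)
            annual_hs[i] = cb.health_system
            annual_oope[i] = cb.oope

    matrices = {int(age): build_transition_matrix(int(age), params) for age in ages}

    occ = baseline_occupancy(params)
    for t, age in enumerate(ages):
        # organised screening (if due), then the opportunistic pathway,
        # acting on whoever is still undiagnosed
        if strategy.screening_due(t, int(age)):
            results = {
                i: cascade(strategy, STATE_SPACE[i], params, t, post_referral_scenario)
                for i, s in enumerate(STATE_SPACE)
                if s.alive and occ[i] > 0.0 and not (s.diseased and s.diagnosed)
            }
            occ, chs, coope = _apply_detection(occ, results, params, post_referral_scenario)
            cost_hs[t] += chs
            cost_oope[t] += coope
        results = {
            i: usual_care_detection(STATE_SPACE[i], params)
            for i, s in enumerate(STATE_SPACE)
            if s.alive and occ[i] > 0.0 and s.manifest_glaucoma and not s.diagnosed
        }
        occ, chs, coope = _apply_detection(occ, results, params, None)
        cost_hs[t] += chs
        cost_oope[t] += coope

        occupancy[t] = occ
        cost_hs[t] += float(occ @ annual_hs)
        cost_oope[t] += float(occ @ annual_oope)

        m = matrices[int(age)]
        blind_entries[t] = float(
            occ[_NONBLIND_ALIVE] @ m[np.ix_(_NONBLIND_ALIVE, _BLIND_INDICES)].sum(axis=1)
        )
        occ = occ @ m

    return CohortTrace(
        ages=ages,
        occupancy=occupancy,
        cost_hs=cost_hs,
        cost_oope=cost_oope,
        blind_entries=blind_entries,
        final=occ,
    )


def blindness_incidence(trace: CohortTrace) -> float:
    """Per-person lifetime probability of newly entering any blind state."""
    return float(trace.blind_entries.sum())


def one_cycle_incidence(params: ParameterSet) -> dict[str, float]:
    """Annual disease incidence implied by one untreated cycle.

    Runs a single natural-history cycle from an all-healthy cohort at the
    start age and reports new entries into the OHT, POAG and PACS states per
    100 000 persons alive at the end of the cycle -- the denominator used by
    incidence rates in cohort studies.
    """
    start_age = int(params["demographics.start_age"])
    m = build_transition_matrix(start_age, params)
    occ = np.zeros(N_STATES)
    occ[DISEASE_FREE_INDEX] = 1.0
    nxt = occ @ m
    alive = 1.0 - nxt[DEAD_INDEX]
    out = {}
    for label, state in (
        ("oht", State(Arm.POAG, "oht")),
        ("poag", State(Arm.POAG, "mild")),
        ("pacs", State(Arm.PACD, "pacs")),
    ):
        out[label] = 1e5 * nxt[STATE_INDEX[state]] / alive if alive > 0 else 0.0
    return out
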