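"""Markov engine: mortality, transitions, conservation, incidence anchors."""

import numpy as np
import pytest

from glaucoma_cea import (
    Strategy,
    UtilityTable,
    aggregate,
    build_transition_matrix,
    death_probability,
    run_cohort,
)
from glaucoma_cea.markov import (
    baseline_occupancy,
    blindness_incidence,
    one_cycle_incidence,
)
from glaucoma_cea.params import ValidationError
from glaucoma_cea.states import N_STATES, STATE_INDEX, STATE_SPACE, Arm, State
from glaucoma_cea.synthetic import (
    GeneratorConfig,
    random_parameter_set,
    toy_parameter_set,
)


class TestDeathProbability:
    def test_blind_multiplier_applied(self, params):
        age = 40
        q = params.qx(age)
        blind = State(Arm.POAG, "bilateral_blind")
        assert death_probability(age, blind, params) == pytest.approx(2.34 * q)

    def test_capped_at_one(self):
        toy = toy_parameter_set(q=0.5, horizon=5)  # 2.34 * 0.5 > 1
        blind = State(Arm.POAG, "bilateral_blind")
        assert death_probability(40, blind, toy) == 1.0

    def test_non_blind_states_use_raw_qx(self, params):
        for state in (State(Arm.DISEASE_FREE), State(Arm.POAG, "severe")):
            assert death_probability(55, state, params) == params.qx(55)

    def test_age_outside_table_raises(self, params):
        with pytest.raises(ValidationError, match="life-table"):
            death_probability(20, State(Arm.DISEASE_FREE), params)


class TestTransitionMatrix:
    def test_rows_sum_to_one(self, params):
        for age in (40, 60, 80, 100):
            m = build_transition_matrix(age, params)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_dead_is_absorbing(self, params):
        m = build_transition_matrix(50, params)
        i = STATE_INDEX[State(Arm.DEAD)]
        assert m[i, i] == 1.0 and m[i].sum() == 1.0

    def test_null_treatment_rows_identical(self, params):
        p = params.with_values(
            {"epi.treatment_rr_poag": 1.0, "epi.treatment_rr_pacd": 1.0}
        )
        m = build_transition_matrix(50, p)
        for arm, stage in ((Arm.POAG, "mild"), (Arm.PACD, "pacg")):
            untreated = m[STATE_INDEX[State(arm, stage)]]
            treated = m[STATE_INDEX[State(arm, stage, True, True)]]
            # same stage-progression pattern regardless of flags
            u = {STATE_SPACE[j].stage: v for j, v in enumerate(untreated) if v > 0}
            t = {STATE_SPACE[j].stage: v for j, v in enumerate(treated) if v > 0}
            assert u == pytest.approx(t)

    def test_treatment_relative_risk_is_multiplicative(self, params):
        p = params.with_values(
            {"epi.progression.mild_to_moderate": 0.10, "epi.treatment_rr_poag": 0.5}
        )
        m = build_transition_matrix(50, p)
        q = p.qx(50)
        i_untreated = STATE_INDEX[State(Arm.POAG, "mild")]
        i_treated = STATE_INDEX[State(Arm.POAG, "mild", True, True)]
        j_untreated = STATE_INDEX[State(Arm.POAG, "moderate")]
        j_treated = STATE_INDEX[State(Arm.POAG, "moderate", True, True)]
        assert m[i_untreated, j_untreated] == pytest.approx((1 - q) * 0.10)
        assert m[i_treated, j_treated] == pytest.approx((1 - q) * 0.05)

    def test_zero_progression_only_incidence_and_death(self, params):
        zero = {k: 0.0 for k in params.specs if k.startswith("epi.progression.")}
        m = build_transition_matrix(50, params.with_values(zero))
        for i, s in enumerate(STATE_SPACE):
            if s.diseased:
                off = [j for j in range(N_STATES) if m[i, j] > 0 and j != i]
                assert off == [STATE_INDEX[State(Arm.DEAD)]]

    def test_no_backward_transitions(self, params):
        from glaucoma_cea.states import PACD_STAGES, POAG_STAGES

        m = build_transition_matrix(60, params)
        order = {Arm.POAG: POAG_STAGES, Arm.PACD: PACD_STAGES}
        for i, s in enumerate(STATE_SPACE):
            if not s.diseased:
                continue
            rank_i = order[s.arm].index(s.stage)
            for j in np.nonzero(m[i])[0]:
                t = STATE_SPACE[j]
                if t.diseased:
                    assert t.arm is s.arm
                    assert order[t.arm].index(t.stage) >= rank_i

    def test_inconsistent_incidence_bundle_raises(self, params):
        with pytest.raises(ValidationError, match="incidence"):
            build_transition_matrix(
                40, params.with_values({"epi.incidence_oht": 0.9, "epi.incidence_poag": 0.2})
            )


class TestCohortRun:
    def test_occupancy_conserved_on_random_sets(self):
        """Mass conservation and monotone deaths across 50 random sets,
        cycling through every strategy configuration."""
        from glaucoma_cea.cascade import all_screening_strategies

        strategies = all_screening_strategies() + [
            Strategy.usual_care("40-75"),
            Strategy.usual_care("50-75"),
        ]
        for seed in range(50):
            p = random_parameter_set(GeneratorConfig(seed=seed))
            trace = run_cohort(strategies[seed % len(strategies)], p)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            dead = 1.0 - trace.alive
            assert np.all(np.diff(dead) >= -1e-12)

    def test_toy_survival_is_geometric(self):
        toy = toy_parameter_set(q=0.2, horizon=15)
        trace = run_cohort(Strategy.usual_care("40-75"), toy)
        np.testing.assert_allclose(
            trace.alive, (1 - 0.2) ** np.arange(15), atol=1e-12
        )

    def test_disease_free_forever_without_incidence(self):
        toy = toy_parameter_set(q=0.0, horizon=10)
        trace = run_cohort(Strategy.usual_care("40-75"), toy)
        from glaucoma_cea.states import DISEASE_FREE_INDEX

        np.testing.assert_allclose(trace.occupancy[:, DISEASE_FREE_INDEX], 1.0)

    def test_baseline_occupancy_matches_prevalence(self, params):
        occ = baseline_occupancy(params)
        assert occ.sum() == pytest.approx(1.0)
        idx = STATE_INDEX[State(Arm.PACD, "pacs")]
        assert occ[idx] == params["epi.prevalence.pacd_pacs"]


class TestBlindnessIncidence:
    def test_zero_without_progression(self, params):
        zero = {k: 0.0 for k in params.specs if k.startswith("epi.progression.")}
        trace = run_cohort(Strategy.usual_care("40-75"), params.with_values(zero))
        assert blindness_incidence(trace) == 0.0

    def test_single_path_flow_matches_hand_sum(self):
        """Oracle: with one seeded stage and deterministic parameters the
        first-entry flow into blindness can be summed by hand."""
        toy = toy_parameter_set(q=0.0, horizon=4, progression=0.5, prevalence=1.0)
        # chain mild -> moderate -> severe -> unilateral_blind at p=0.5 each
        toy = toy.with_values(
            {
                "epi.progression.moderate_to_severe": 0.5,
                "epi.progression.severe_to_unilateral": 0.5,
                "usual_care.consult_prob": 0.0,  # keep the whole flow undiagnosed
            }
        )
        trace = run_cohort(Strategy.usual_care("40-75"), toy)
        # occupancy of severe at cycle start t, times 0.5, summed over cycles
        i_sev = STATE_INDEX[State(Arm.POAG, "severe")]
        expected = 0.5 * trace.occupancy[:, i_sev].sum()
        assert blindness_incidence(trace) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_progression(self, params, usual_care_40):
        base = blindness_incidence(run_cohort(usual_care_40, params))
        doubled = params.with_values(
            {
                k: min(1.0, 2 * params[k])
                for k in params.specs
                if k.startswith("epi.progression.")
            }
        )
        assert blindness_incidence(run_cohort(usual_care_40, doubled)) >= base


class TestIncidenceAnchors:
    def test_one_cycle_incidence_matches_configured_rates(self, params):
        inc = one_cycle_incidence(params)
        assert inc["oht"] == pytest.approx(370.0, abs=1e-9)
        assert inc["poag"] == pytest.approx(489.0, abs=1e-9)
        assert inc["pacs"] == pytest.approx(530.0, abs=1e-9)
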