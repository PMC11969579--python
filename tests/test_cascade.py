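"""Decision-tree cascade: series testing, worked products, tree simulation."""

import numpy as np
import pytest

from glaucoma_cea import Strategy, cascade, series_test, usual_care_detection
from glaucoma_cea.cascade import all_screening_strategies, strategy_from_name
from glaucoma_cea.states import Arm, State
from glaucoma_cea.synthetic import GeneratorConfig, random_parameter_set

MILD_POAG = State(Arm.POAG, "mild")
PACG = State(Arm.PACD, "pacg")
HEALTHY = State(Arm.DISEASE_FREE)


class TestSeriesTest:
    def test_joint_outcome_enumeration(self):
        """Oracle: enumerate the four joint test outcomes directly."""
        s1, p1, s2, p2 = 0.8, 0.9, 0.7, 0.85
        sens, spec = series_test(s1, p1, s2, p2)
        # diseased flagged only when both tests positive
        assert sens == pytest.approx(s1 * s2) == pytest.approx(0.56)
        # healthy cleared if test1 negative, or test1 false-positive and test2 negative
        assert spec == pytest.approx(p1 + (1 - p1) * p2) == pytest.approx(0.985)

    def test_perfect_sensitivity_preserved(self):
        sens, _ = series_test(1.0, 0.5, 1.0, 0.6)
        assert sens == 1.0

    def test_perfect_first_specificity_blocks_false_positives(self):
        _, spec = series_test(0.7, 1.0, 0.6, 0.2)
        assert spec == 1.0


class TestStrategy:
    def test_twelve_screening_configurations(self):
        names = {s.name for s in all_screening_strategies()}
        assert len(names) == 12

    def test_quinquennial_50_75_rejected(self):
        with pytest.raises(ValueError, match="quinquennial"):
            Strategy("50-75", "universal", "f2f", "quinquennial")

    def test_unknown_name_lists_valid_options(self):
        with pytest.raises(ValueError, match="usual_care_40_75"):
            strategy_from_name("nonsense")

    def test_screening_stops_after_75(self):
        s = Strategy("40-75", "universal", "f2f", "annual")
        assert s.screening_due(cycle=35, age=75)
        assert not s.screening_due(cycle=36, age=76)


class TestCascade:
    def test_printed_cascade_product(self, params, annual_f2f_universal_40):
        """coverage x attendance x treatment uptake = 0.65 x 0.58 x 0.725."""
        p = params.with_values(
            {
                "screening.sens_tonometry": 1.0,
                "screening.spec_tonometry": 1.0,
                "screening.sens_fundus_f2f": 1.0,
                "screening.spec_fundus_f2f": 1.0,
                "screening.ungradable_rate": 0.0,
            }
        )
        res = cascade(annual_f2f_universal_40, MILD_POAG, p, cycle=0)
        assert res.p_treated == pytest.approx(0.65 * 0.58 * 0.725) == pytest.approx(0.273325)

    def test_healthy_referred_only_when_ungradable(self, params, annual_f2f_universal_40):
        p = params.with_values(
            {
                "screening.spec_tonometry": 1.0,
                "screening.spec_fundus_f2f": 1.0,
                "screening.ungradable_rate": 0.22,
            }
        )
        res = cascade(annual_f2f_universal_40, HEALTHY, p, cycle=0)
        assert res.p_referred == pytest.approx(res.p_screened * 0.22)
        assert res.p_confirmed == 0.0  # gold standard clears false positives

    def test_blind_screen_confirms_nobody(self, params, annual_f2f_universal_40):
        p = params.with_values(
            {
                "screening.sens_tonometry": 0.0,
                "screening.sens_fundus_f2f": 0.0,
                "screening.sens_flashlight": 0.0,
                "screening.spec_tonometry": 1.0,
                "screening.spec_fundus_f2f": 1.0,
                "screening.spec_flashlight": 1.0,
                "screening.ungradable_rate": 0.0,
            }
        )
        for state in (MILD_POAG, PACG, State(Arm.POAG, "oht")):
            res = cascade(annual_f2f_universal_40, state, p, cycle=0)
            assert res.p_confirmed == 0.0

    def test_zero_coverage_yields_null_cascade(self, params, annual_f2f_universal_40):
        p = params.with_values({"screening.coverage": 0.0})
        for state in (HEALTHY, MILD_POAG, PACG):
            res = cascade(annual_f2f_universal_40, state, p, cycle=0)
            assert res.p_screened == res.p_referred == res.p_treated == 0.0
            assert res.expected_cost_hs == res.expected_cost_oope == 0.0

    def test_cascade_ordering_invariant(self, params):
        """p_screened >= p_referred >= p_confirmed >= p_treated on diseased states."""
        for seed in range(5):
            p = random_parameter_set(GeneratorConfig(seed=seed))
            for strategy in all_screening_strategies()[:4]:
                res = cascade(strategy, MILD_POAG, p, cycle=0)
                assert (
                    res.p_screened + 1e-12
                    >= res.p_referred + 1e-12
                    >= res.p_confirmed + 1e-12
                    >= res.p_treated
                )

    @pytest.mark.parametrize(
        "name", ["screening.coverage", "screening.sens_fundus_f2f"]
    )
    def test_treatment_probability_monotone(self, params, annual_f2f_universal_40, name):
        rng = np.random.default_rng(7)
        for _ in range(10):
            lo, hi = np.sort(rng.uniform(0.0, 1.0, 2))
            r_lo = cascade(annual_f2f_universal_40, MILD_POAG, params.with_values({name: lo}), 0)
            r_hi = cascade(annual_f2f_universal_40, MILD_POAG, params.with_values({name: hi}), 0)
            assert r_hi.p_treated >= r_lo.p_treated - 1e-12

    def test_ltfu_reduction_increases_treatment(self, params, annual_f2f_universal_40):
        base = cascade(annual_f2f_universal_40, MILD_POAG, params, 0)
        better = cascade(
            annual_f2f_universal_40,
            MILD_POAG,
            params.with_values(
                {"screening.ltfu_diagnosis": 0.2, "screening.ltfu_treatment": 0.1}
            ),
            0,
        )
        assert better.p_treated > base.p_treated

    def test_high_risk_filter_enriches_diseased(self, params):
        s = Strategy("40-75", "high_risk", "f2f", "annual")
        diseased = cascade(s, MILD_POAG, params, 0)
        healthy = cascade(s, HEALTHY, params, 0)
        f = params["epi.high_risk_fraction"]
        rr = params["epi.high_risk_rr"]
        assert healthy.p_screened == pytest.approx(params["screening.coverage"] * f)
        assert diseased.p_screened == pytest.approx(
            params["screening.coverage"] * f * rr / (f * rr + 1 - f)
        )

    def test_monte_carlo_tree_oracle(self, params, annual_f2f_universal_40):
        """Simulate the decision tree person-by-person and compare branch
        frequencies with the analytic expectations (4 MC standard errors)."""
        rng = np.random.default_rng(20260930)
        n = 200_000
        coverage = params["screening.coverage"]
        sens_t = params["screening.sens_tonometry"]
        spec_t = params["screening.spec_tonometry"]
        sens_f = params["screening.sens_fundus_f2f"]
        spec_f = params["screening.spec_fundus_f2f"]
        sens_fl = params["screening.sens_flashlight"]
        u = params["screening.ungradable_rate"]
        ltfu_d = params["screening.ltfu_diagnosis"]
        ltfu_t = params["screening.ltfu_treatment"]

        for state in (HEALTHY, State(Arm.POAG, "oht"), MILD_POAG, PACG):
            screened = rng.random(n) < coverage
            ungradable = rng.random(n) < u
            if state is HEALTHY:
                tono = rng.random(n) < (1 - spec_t)
                fundus = rng.random(n) < (1 - spec_f)
                flagged = tono | ungradable | fundus
            elif state.stage == "oht":
                tono = rng.random(n) < sens_t
                fundus = rng.random(n) < (1 - spec_f)
                flagged = tono | ungradable | fundus
            elif state.arm is Arm.POAG:
                tono = rng.random(n) < sens_t
                fundus = rng.random(n) < sens_f
                flagged = tono | ungradable | fundus
            else:  # angle closure: tonometry then flashlight in series
                tono = rng.random(n) < sens_t
                flash = rng.random(n) < sens_fl
                fundus = rng.random(n) < (1 - spec_f)
                flagged = (tono & flash) | ungradable | fundus
            referred = screened & flagged
            attended = referred & (rng.random(n) < (1 - ltfu_d))
            confirmed = attended if state.diseased else np.zeros(n, bool)
            treated = confirmed & (rng.random(n) < (1 - ltfu_t))

            res = cascade(annual_f2f_universal_40, state, params, cycle=0)
            for flow, expected in (
                (screened, res.p_screened),
                (referred, res.p_referred),
                (confirmed, res.p_confirmed),
                (treated, res.p_treated),
            ):
                observed = flow.mean()
                se = np.sqrt(max(expected * (1 - expected), 1e-12) / n)
                assert abs(observed - expected) < 4 * se + 1e-12, state.label


class TestUsualCare:
    def test_consult_and_treat_product(self, params):
        res = usual_care_detection(MILD_POAG, params)
        assert res.p_confirmed == pytest.approx(0.10)
        assert res.p_treated == pytest.approx(0.08)

    def test_precursors_and_healthy_not_detected(self, params):
        for state in (HEALTHY, State(Arm.POAG, "oht"), State(Arm.PACD, "pacs")):
            res = usual_care_detection(state, params)
            assert res.p_confirmed == 0.0

    def test_zero_consultation_never_detects(self, params):
        p = params.with_values({"usual_care.consult_prob": 0.0})
        res = usual_care_detection(MILD_POAG, p)
        assert res.p_treated == 0.0
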