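"""Perception, treatment selection, the health process, and the full encounter."""

import numpy as np
import pytest
from scipy.stats import chisquare

import lhnabm as L
from lhnabm.encounter import (
    evaluation_error,
    health_step,
    perceive_improvement,
    run_encounter,
    select_treatment,
    select_treatments_many,
    selection_efficiency,
    selection_weights,
)
from lhnabm.knowledge import Commons, Registry
from lhnabm.levels import OWNING, UNAWARE
from lhnabm.population import ClinicianState, PatientState, build_condition_matrix


class TestEvaluation:
    def test_full_praxis_no_error(self):
        assert evaluation_error(1.0, 0.2) == 0.0

    def test_zero_praxis_anchor(self):
        assert evaluation_error(0.0, 0.2) == pytest.approx(0.2)

    def test_perfect_judge_parameter(self):
        assert evaluation_error(0.3, 0.0) == 0.0

    def test_perception_truth_without_error(self, rng):
        assert perceive_improvement(0.1, 0.0, rng) is True
        assert perceive_improvement(-0.1, 0.0, rng) is False
        assert perceive_improvement(0.0, 0.0, rng) is False  # zero counts as not improved

    def test_certain_flip(self, rng):
        assert perceive_improvement(0.1, 1.0, rng) is False

    def test_flip_frequency_matches_bernoulli(self):
        rng = np.random.default_rng(5)
        n = 10_000
        out = perceive_improvement(np.full(n, -0.05), 0.2, rng)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(out.mean() - 0.2) < 3 * se


class TestSelectionEfficiency:
    def test_anchors(self):
        assert selection_efficiency(0.0, 1000.0) == 1.0
        assert selection_efficiency(1.0, 1000.0) == 1000.0

    def test_quadratic_interior_value(self):
        # E = 1 + 999 * 0.5**2
        assert selection_efficiency(0.5, 1000.0) == pytest.approx(250.75)

    def test_monotone_in_both_arguments(self):
        p = np.linspace(0, 1, 11)
        e = selection_efficiency(p, 100.0)
        assert np.all(np.diff(e) >= 0)
        assert np.all(selection_efficiency(0.7, 1000.0) >= selection_efficiency(0.7, 10.0))


class TestSelectTreatment:
    def test_weights_closed_form(self):
        # m=3 candidates, E=4: weights (4, 2, 1)
        assert np.allclose(selection_weights([1, 2, 3], 4.0), [4.0, 2.0, 1.0])

    def test_uniform_at_unit_efficiency(self):
        rng = np.random.default_rng(0)
        n = 50_000
        picks = select_treatments_many(
            np.tile(np.arange(1, 6), (n, 1)), np.full(n, -1), np.ones(n), rng)
        counts = np.bincount(picks, minlength=5)
        assert chisquare(counts).pvalue > 0.001

    def test_limit_case_picks_best(self):
        # best:second weight ratio is E**(1/(m-1)), so the efficiency must be
        # extreme for a near-certain best pick with 5 candidates
        rng = np.random.default_rng(1)
        rank_row = np.array([3, 1, 2, 5, 4])
        picks = [select_treatment(rank_row, None, 1e16, rng) for _ in range(1000)]
        assert np.mean(np.array(picks) == 1) >= 0.999

    def test_rank_weight_probabilities(self):
        # 3 candidates at E=4 -> probabilities (4/7, 2/7, 1/7)
        rng = np.random.default_rng(2)
        n = 50_000
        picks = select_treatments_many(
            np.tile([1, 2, 3], (n, 1)), np.full(n, -1), np.full(n, 4.0), rng)
        freq = np.bincount(picks, minlength=3) / n
        expected = np.array([4, 2, 1]) / 7
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) < 3 * se)

    def test_current_treatment_excluded(self):
        rng = np.random.default_rng(3)
        rank_row = np.array([1, 2, 3, 4])
        picks = [select_treatment(rank_row, 0, 5.0, rng) for _ in range(500)]
        assert 0 not in picks

    def test_scalar_and_vector_paths_agree_in_distribution(self):
        rank_row = np.array([2, 4, 1, 3])
        n = 30_000
        rng1, rng2 = np.random.default_rng(7), np.random.default_rng(8)
        scalar = np.array([select_treatment(rank_row, 1, 6.0, rng1) for _ in range(n)])
        vec = select_treatments_many(np.tile(rank_row, (n, 1)), np.full(n, 1), np.full(n, 6.0), rng2)
        f1 = np.bincount(scalar, minlength=4) / n
        f2 = np.bincount(vec, minlength=4) / n
        assert np.all(np.abs(f1 - f2) < 0.012)


class TestHealthStep:
    def _frozen(self, **kw):
        base = dict(responsiveness_kappa=0.0, natural_history_drift=0.0,
                    relapse_probability=0.0, relapse_magnitude=0.0, variability_sd=0.0)
        base.update(kw)
        return L.ConditionSpec(**base)

    def test_frozen_dynamics_identity(self, rng):
        cond = self._frozen()
        assert health_step(0.42, 0.9, cond, rng) == pytest.approx(0.42)

    def test_one_step_pull_arithmetic(self, rng):
        cond = self._frozen(responsiveness_kappa=0.05)
        assert health_step(0.3, 0.9, cond, rng) == pytest.approx(0.33)

    def test_target_is_fixed_point(self, rng):
        cond = self._frozen(responsiveness_kappa=0.08)
        assert health_step(0.7, 0.7, cond, rng) == pytest.approx(0.7)

    def test_clipped_to_unit_interval(self, rng):
        cond = self._frozen(natural_history_drift=-0.5)
        assert health_step(0.1, 0.5, cond, rng, has_treatment=False) == 0.0

    def test_no_treatment_no_pull(self, rng):
        cond = self._frozen(responsiveness_kappa=0.1)
        assert health_step(0.4, 0.9, cond, rng, has_treatment=False) == pytest.approx(0.4)


class TestRunEncounter:
    def _setup(self, seed=0, **cond_kw):
        rng = np.random.default_rng(seed)
        cond = L.ConditionSpec(**cond_kw)
        eff = build_condition_matrix(cond, rng)
        patient = PatientState(id=0, care_center=0, clinician=0, phenotype=0, health=0.5)
        clinician = ClinicianState(id=0, care_center=0, engagement=OWNING, panel=[0])
        commons = Commons(half_life=100.0, stock=50.0, items_ever_added=50.0)
        registry = Registry(er_level="low")
        return rng, cond, eff, patient, clinician, commons, registry

    def test_first_encounter_always_assigns_treatment(self):
        rng, cond, eff, patient, clinician, commons, registry = self._setup()
        params = L.ModelParams()
        out = run_encounter(patient, clinician, commons, registry, params, cond, rng,
                            effectiveness=eff)
        assert patient.current_treatment is not None
        assert out.old_treatment is None and out.new_treatment == patient.current_treatment

    def test_perceived_improvement_keeps_treatment(self):
        rng, cond, eff, patient, clinician, commons, registry = self._setup()
        params = L.ModelParams(evaluation_accuracy_minimum_praxis=0.0)
        patient.current_treatment = 2
        patient.health = 0.6
        patient.health_at_last_encounter = 0.4   # genuine improvement
        out = run_encounter(patient, clinician, commons, registry, params, cond, rng,
                            effectiveness=eff)
        assert out.perceived_improved and not out.switched
        assert patient.current_treatment == 2

    def test_switch_excludes_current_treatment(self):
        rng, cond, eff, patient, clinician, commons, registry = self._setup()
        params = L.ModelParams(evaluation_accuracy_minimum_praxis=0.0)
        for _ in range(50):
            patient.current_treatment = 1
            patient.health = 0.3
            patient.health_at_last_encounter = 0.5   # decline -> switch
            out = run_encounter(patient, clinician, commons, registry, params, cond, rng,
                                effectiveness=eff)
            assert out.switched and patient.current_treatment != 1

    def test_frozen_encounter_only_reschedules(self):
        rng, cond, eff, patient, clinician, commons, registry = self._setup()
        clinician.engagement = UNAWARE
        commons.stock = 0.0
        params = L.ModelParams(
            encounter_aware_determiner=0.0, patient_activate_determiner=0.0,
            patient_dispirit_determiner=0.0,
            potential_phenotype_response_info_from_sk_unit=0.0,
            patient_response_info_increase_numeric=0.0,
            evaluation_accuracy_minimum_praxis=0.0)
        patient.current_treatment = 3
        patient.health_at_last_encounter = 0.4   # perceived improved -> keep
        before = (patient.engagement, patient.pri, patient.iri, patient.current_treatment)
        out = run_encounter(patient, clinician, commons, registry, params, cond, rng,
                            effectiveness=eff)
        assert (patient.engagement, patient.pri, patient.iri, patient.current_treatment) == before
        assert out.praxis == 0.0
        assert patient.steps_until_next_encounter == params.encounter_period

    def test_registry_records_only_when_automated(self):
        rng, cond, eff, patient, clinician, commons, registry = self._setup()
        params = L.ModelParams()
        run_encounter(patient, clinician, commons, registry, params, cond, rng,
                      effectiveness=eff)
        assert registry.record_count == 0
        reg2 = Registry(er_level="medium")
        run_encounter(patient, clinician, commons, reg2, params, cond, rng,
                      effectiveness=eff)
        assert reg2.record_count == 1
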