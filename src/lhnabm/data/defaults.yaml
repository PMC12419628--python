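# Packaged default scenario: a closed cohort of 4 care centers x 5 clinicians
# x 10 patients simulated for five years at one step per week, with every
# model parameter at the midpoint of its default range.  PVP is unconstrained
# (cap 1.0) and the enhanced-registry pipeline is off in the baseline; the
# factorial experiment varies both.
#
# An empty file (or no file) yields exactly this scenario; override any subset
# of keys.  Unknown keys are rejected.

n_care_centers: 4
clinicians_per_center: 5
patients_per_clinician: 10
horizon_steps: 260
steps_per_year: 52
pvp_level: high
er_level: low
closed_cohort: true
seed: 0
initial_engaged_fraction_patients: 0.05
initial_engaged_fraction_clinicians: 0.30
initial_engaged_level: owning
praxis_pri_weight: 0.5

params:
  encounter_period: 15
  encounter_aware_determiner: 0.5
  patient_activate_determiner: 0.5
  patient_dispirit_determiner: 0.1
  patient_network_edges: 5.0
  clinician_network_edges: 5.0
  patient_influence_across_prop: 0.5
  clinician_influence_across_prop: 0.5
  patient_influence_become_aware_probability: 0.5
  patient_influence_activation_probability: 0.5
  clinician_influence_become_aware_probability: 0.5
  clinician_influence_activation_probability: 0.5
  clinician_dispirit_probability: 0.1
  shared_knowledge_initial: 10.0
  shared_knowledge_half_life: 132.0
  patient_shared_knowledge_contrib_determiner: 0.5
  clinician_shared_knowledge_contrib_determiner: 0.5
  enhanced_registry_initial_per_patient: 5.0
  enhanced_registry_analysis_period: 15
  enhanced_registry_record_per_commons_item: 10.5
  potential_phenotype_response_info_from_sk_unit: 0.001
  phenotype_realization_numeric: 0.5
  patient_response_info_half_life: 132.0
  patient_response_info_increase_numeric: 0.5
  patient_response_info_acceleration_from_sk_unit: 0.0005
  maximal_patient_response_info_acceleration_from_sk: 1.0
  selection_efficiency_maximum: 505.0
  evaluation_accuracy_minimum_praxis: 0.2505
  patient_engagement_degree_participating: 0.5
  clinician_engagement_degree_participating: 0.5

condition:
  n_phenotypes: 4
  n_treatments: 8
  responsiveness_kappa: 0.08
  natural_history_drift: -0.0215
  relapse_probability: 0.004
  relapse_magnitude: 0.4
  variability_sd: 0.03
  best_target: 0.95
  worst_target: 0.05
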