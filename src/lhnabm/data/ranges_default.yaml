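# Default sampling ranges for the 30 model parameters.
#
# Probabilities and fractions span [0, 1]; half-lives span one month to the
# full five-year horizon in weekly steps; the selection-efficiency maximum and
# the minimum-evaluation-accuracy (reversed) axis span the values used in the
# simulated intervention experiment.  Every range is overridable by passing a
# custom ranges file.  Entries may be [lower, upper] (uniform) or a mapping
# with lower/upper/dist/mode (dist: uniform | triangle).

encounter_period: [4, 26]
encounter_aware_determiner: [0, 1]
patient_activate_determiner: [0, 1]
patient_dispirit_determiner: [0, 0.2]
patient_network_edges: [0, 10]
clinician_network_edges: [0, 10]
patient_influence_across_prop: [0, 1]
clinician_influence_across_prop: [0, 1]
patient_influence_become_aware_probability: [0, 1]
patient_influence_activation_probability: [0, 1]
clinician_influence_become_aware_probability: [0, 1]
clinician_influence_activation_probability: [0, 1]
clinician_dispirit_probability: [0, 0.2]
shared_knowledge_initial: [0, 20]
shared_knowledge_half_life: [4, 260]
patient_shared_knowledge_contrib_determiner: [0, 1]
clinician_shared_knowledge_contrib_determiner: [0, 1]
enhanced_registry_initial_per_patient: [0, 10]
enhanced_registry_analysis_period: [4, 26]
enhanced_registry_record_per_commons_item: [1, 20]
potential_phenotype_response_info_from_sk_unit: [0, 0.002]
phenotype_realization_numeric: [0, 1]
patient_response_info_half_life: [4, 260]
patient_response_info_increase_numeric: [0, 1]
patient_response_info_acceleration_from_sk_unit: [0, 0.001]
maximal_patient_response_info_acceleration_from_sk: [0, 2]
selection_efficiency_maximum: [10, 1000]
evaluation_accuracy_minimum_praxis: [0.001, 0.5]
patient_engagement_degree_participating: [0, 1]
clinician_engagement_degree_participating: [0, 1]
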