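"""The clinical encounter: perceive, decide, select, and the health process.

At each scheduled visit the patient and clinician judge whether health has
improved since the previous visit (with praxis-dependent evaluation
accuracy), keep the current treatment if it is perceived to be working, and
otherwise pick an alternative with a praxis-dependent bias toward the truly
best-ranked treatment for the patient's phenotype.  Between and during
visits, health relaxes toward the current treatment's target while the
condition's natural history, variability, and relapses push back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engagement import encounter_engagement_update_many
from .knowledge import (
    Commons,
    Registry,
    access_fraction,
    compute_praxis,
    effective_pvp_cap,
    er_encounter_boost,
    pvp_cap,
    update_iri_encounter,
    update_pri,
)
from .params import ConditionSpec, ModelParams

__all__ = [
    "EncounterOutcome",
    "evaluation_error",
    "perceive_improvement",
    "selection_efficiency",
    "selection_weights",
    "select_treatment",
    "select_treatments_many",
    "health_step",
    "run_encounter",
]


@dataclass
class EncounterOutcome:
    patient_id: int
    step: int
    praxis: float
    perceived_improved: bool
    switched: bool
    old_treatment: Optional[int]
    new_treatment: Optional[int]
    # commons contributions happen per time step at the population level, not
    # inside the encounter; these stay for log compatibility and are always 0
    patient_contributed: int = 0
    clinician_contributed: int = 0


def evaluation_error(praxis, e0):
    """Misjudgment probability: e0 at zero praxis, linearly down to 0 at praxis 1.

    ``e0`` is the reversed minimum-evaluation-accuracy axis — larger means
    worse judgment of whether the treatment is working.
    """
    return e0 * (1.0 - np.asarray(praxis))


def perceive_improvement(true_delta, error_p, rng: np.random.Generator):
    """The truth (delta > 0), flipped with the evaluation-error probability.

    A zero delta counts as not improved, triggering a switch attempt.
    Vectorized.
    """
    truth = np.asarray(true_delta) > 0
    flip = rng.random(truth.shape) < error_p
    out = truth ^ flip
    return bool(out) if out.ndim == 0 else out


def selection_efficiency(praxis, e_max, praxis_exponent: float = 2.0):
    """Interpolation from no skill (E = 1) to the praxis-1 maximum.

    The praxis response is convex (quadratic by default): low levels of
    applied knowledge buy little selection skill, and the full maximum is
    only realized near praxis 1.  E = 1 + (E_max - 1) * praxis**exponent,
    so E ranges over [1, E_max] for praxis in [0, 1].
    """
    return 1.0 + (np.asarray(e_max) - 1.0) * np.asarray(praxis) ** praxis_exponent


def selection_weights(ranks, efficiency):
    """Geometric rank weights: the rank-r candidate of m gets E**((m-r)/(m-1)).

    The best candidate gets weight E, the worst weight 1; E = 1 is uniform
    and E -> infinity is a point mass on the best.  ``ranks`` are 1..m.
    """
    ranks = np.asarray(ranks, dtype=float)
    m = ranks.size
    if m == 1:
        return np.ones(1)
    expo = (m - ranks) / (m - 1.0)
    return float(efficiency) ** expo


def select_treatment(rank_row, current, efficiency, rng: np.random.Generator) -> int:
    """Pick a treatment for one patient, biased toward the best-ranked.

    ``rank_row`` ranks every treatment for the patient's phenotype (1 = best).
    At the first encounter (``current`` is None) all treatments are
    candidates; at a switch the current one is excluded.
    """
    rank_row = np.asarray(rank_row)
    n_t = rank_row.size
    candidates = np.arange(n_t)
    ranks = rank_row.astype(float)
    if current is not None:
        candidates = candidates[candidates != current]
        if candidates.size == 0:
            raise ValueError("no alternative treatments available")
        ranks = rank_row[candidates].astype(float)
        # compress ranks to 1..m after removing the current treatment
        ranks = ranks - (rank_row[candidates] > rank_row[current])
    w = selection_weights(ranks, efficiency)
    p = w / w.sum()
    return int(rng.choice(candidates, p=p))


def select_treatments_many(
    rank_rows: np.ndarray,
    current: np.ndarray,
    efficiency: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized treatment selection for many patients at once.

    ``rank_rows`` is (k, n_treatments) with ranks 1..n; ``current`` holds the
    treatment to exclude, or -1 for a first encounter.
    """
    rank_rows = np.asarray(rank_rows, dtype=np.int64)
    current = np.asarray(current, dtype=np.int64)
    eff = np.asarray(efficiency, dtype=float)
    k, n_t = rank_rows.shape
    has_current = current >= 0
    cur_rank = np.where(has_current, np.take_along_axis(
        rank_rows, np.clip(current, 0, n_t - 1)[:, None], axis=1)[:, 0], n_t + 1)
    # rank among candidates after excluding the current treatment
    ranks = rank_rows - (rank_rows > cur_rank[:, None]).astype(np.int64)
    m = np.where(has_current, n_t - 1, n_t).astype(float)
    denom = np.maximum(m - 1.0, 1.0)
    expo = (m[:, None] - ranks) / denom[:, None]
    w = eff[:, None] ** expo
    if np.any(has_current):
        rows = np.flatnonzero(has_current)
        w[rows, current[rows]] = 0.0
    cum = np.cumsum(w, axis=1)
    u = rng.random(k) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1).astype(np.int64)


def health_step(h, target, condition: ConditionSpec, rng: np.random.Generator, has_treatment=True):
    """One step of the bounded health process.

    h' = clip(h + kappa*(target - h) + drift + N(0, sd) - relapse*magnitude).
    Patients without an assigned treatment feel no pull toward a target.
    Vectorized.
    """
    h = np.asarray(h, dtype=float)
    pull = np.where(has_treatment,
                    condition.responsiveness_kappa * (np.asarray(target, dtype=float) - h),
                    0.0)
    noise = rng.normal(0.0, condition.variability_sd, size=h.shape) \
        if condition.variability_sd > 0 else 0.0
    relapse = (rng.random(h.shape) < condition.relapse_probability) \
        if condition.relapse_probability > 0 else np.zeros(h.shape, dtype=bool)
    out = np.clip(h + pull + condition.natural_history_drift + noise
                  - relapse * condition.relapse_magnitude, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def run_encounter(
    patient,
    clinician,
    commons: Commons,
    registry: Registry,
    params: ModelParams,
    condition: ConditionSpec,
    rng: np.random.Generator,
    *,
    effectiveness,
    pvp_level: str = "high",
    pri_weight: float = 0.5,
    step: int = 0,
) -> EncounterOutcome:
    """One full clinical encounter for a single patient (mutates the states).

    Stages: engagement update; knowledge access (PRI/IRI with any real-time
    registry boost); praxis; perception of the health change since the last
    visit; treatment keep/switch; registry record; scheduling bookkeeping.
    (Commons contributions are a per-step population process, not an
    encounter stage.)
    """
    stock = commons.stock

    # 1. engagement
    patient.engagement = int(encounter_engagement_update_many(
        np.array([patient.engagement]), np.array([clinician.engagement]),
        params.encounter_aware_determiner, params.patient_activate_determiner,
        params.patient_dispirit_determiner, rng)[0])

    # 2. knowledge access
    a_p = access_fraction(patient.engagement, params.patient_engagement_degree_participating)
    a_c = access_fraction(clinician.engagement, params.clinician_engagement_degree_participating)
    a_c = er_encounter_boost(registry.er_level == "high", a_c,
                             params.clinician_engagement_degree_participating)
    patient.pri = float(update_pri(
        patient.pri, stock, params.phenotype_realization_numeric,
        params.potential_phenotype_response_info_from_sk_unit, a_c))
    patient.iri = float(update_iri_encounter(
        patient.iri, params.patient_response_info_increase_numeric,
        params.patient_response_info_acceleration_from_sk_unit,
        params.maximal_patient_response_info_acceleration_from_sk, stock))

    # 3. praxis
    cap = effective_pvp_cap(pvp_cap(pvp_level), registry.er_level == "high")
    praxis = compute_praxis(patient.pri, patient.iri, a_p, a_c, cap, pri_weight)

    # 4. perception
    err = float(evaluation_error(praxis, params.evaluation_accuracy_minimum_praxis))
    delta = patient.health - patient.health_at_last_encounter
    perceived = bool(perceive_improvement(delta, err, rng))

    # 5. treatment decision
    old_tx = patient.current_treatment
    switched = False
    if old_tx is None or not perceived:
        eff = float(selection_efficiency(praxis, params.selection_efficiency_maximum))
        rank_row = effectiveness.rank[patient.phenotype]
        new_tx = select_treatment(rank_row, old_tx, eff, rng)
        switched = old_tx is not None and new_tx != old_tx
        patient.current_treatment = new_tx
    else:
        new_tx = old_tx

    # 6. registry record
    if registry.automated:
        registry.record_count += 1
        registry.records_since_last_analysis += 1

    # 7. bookkeeping
    patient.health_at_last_encounter = patient.health
    patient.steps_until_next_encounter = params.encounter_period
    patient.last_praxis = float(praxis)

    return EncounterOutcome(
        patient_id=getattr(patient, "id", -1), step=step, praxis=float(praxis),
        perceived_improved=perceived, switched=switched,
        old_treatment=old_tx, new_treatment=new_tx)
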