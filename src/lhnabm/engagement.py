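"""Engagement transitions: encounter effects, peer influence, burnout.

Engagement moves one rung at a time on the unaware -> aware -> participating
-> contributing -> owning ladder.  Encounters let a more-engaged clinician
pull a patient up (or a less-engaged one drag them down); influence edges let
the more-engaged peer pull the less-engaged one up (never down); clinicians
additionally face burnout.  Peer-influence and burnout probabilities are
quoted per year and converted to per-step rates so that compounding over one
year reproduces the annual probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .levels import AWARE, CONTRIBUTING, OWNING, UNAWARE

__all__ = [
    "EngagementTransition",
    "annual_to_step_probability",
    "encounter_engagement_update",
    "encounter_engagement_update_many",
    "influence_step",
    "clinician_burnout_step",
]


@dataclass
class EngagementTransition:
    agent_id: int
    step: int
    old_level: int
    new_level: int
    cause: str  # encounter_aware | encounter_activate | encounter_dispirit |
                # influence_aware | influence_activate | burnout


def annual_to_step_probability(p_annual: float, steps_per_year: int) -> float:
    """Per-step probability whose compounding over a year gives ``p_annual``.

    p_step = 1 - (1 - p_annual)^(1/steps_per_year); p_annual = 1 maps to 1.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be in [0, 1], got {p_annual}")
    if p_annual >= 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (1.0 / steps_per_year)


def encounter_engagement_update_many(
    patient_levels: np.ndarray,
    clinician_levels: np.ndarray,
    aware_determiner: float,
    activate_determiner: float,
    dispirit_determiner: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized encounter-driven engagement update; one transition at most.

    Unaware patient + engaged clinician: become aware with the awareness
    determiner.  Otherwise the patient moves one rung toward the clinician's
    level, up with the activation determiner or down with the dispirit
    determiner.  Equal levels leave the patient unchanged.
    """
    pl = np.asarray(patient_levels, dtype=np.int64)
    cl = np.asarray(clinician_levels, dtype=np.int64)
    r = rng.random(pl.shape)
    aware_case = (pl == UNAWARE) & (cl >= AWARE)
    up_case = (~aware_case) & (cl > pl)
    down_case = (~aware_case) & (cl < pl)
    delta = np.zeros_like(pl)
    delta[aware_case & (r < aware_determiner)] = 1
    delta[up_case & (r < activate_determiner)] = 1
    delta[down_case & (r < dispirit_determiner)] = -1
    return np.clip(pl + delta, UNAWARE, OWNING)


def encounter_engagement_update(
    patient_level: int,
    clinician_level: int,
    params,
    rng: np.random.Generator,
) -> int:
    """Scalar wrapper over the vectorized encounter engagement rule."""
    out = encounter_engagement_update_many(
        np.array([patient_level]), np.array([clinician_level]),
        params.encounter_aware_determiner,
        params.patient_activate_determiner,
        params.patient_dispirit_determiner,
        rng)
    return int(out[0])


def _max_neighbor_level(edges: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """For each agent, the highest engagement level among its neighbors."""
    mx = np.full(len(levels), -1, dtype=np.int64)
    if len(edges):
        np.maximum.at(mx, edges[:, 0], levels[edges[:, 1]])
        np.maximum.at(mx, edges[:, 1], levels[edges[:, 0]])
    return mx


def influence_step(
    edges: np.ndarray,
    levels: np.ndarray,
    become_aware_p_step: float,
    activation_p_step: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One step of peer-influence contagion; returns the new level array.

    Transitions are resolved against the step-start snapshot (no cascades
    within a step).  An agent with at least one strictly more engaged
    neighbor gets a single Bernoulli trial — multiple qualifying neighbors do
    not stack, so degree does not mechanically multiply transition rates.
    Influence is upward only.
    """
    levels = np.asarray(levels, dtype=np.int64)
    mx = _max_neighbor_level(np.asarray(edges, dtype=np.int64).reshape(-1, 2), levels)
    r = rng.random(levels.shape)
    rise_aware = (levels == UNAWARE) & (mx >= AWARE) & (r < become_aware_p_step)
    rise_up = (levels >= AWARE) & (levels <= CONTRIBUTING) & (mx > levels) & (r < activation_p_step)
    return levels + rise_aware.astype(np.int64) + rise_up.astype(np.int64)


def clinician_burnout_step(
    levels: np.ndarray,
    dispirit_p_step: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Each engaged clinician independently drops one rung with the step rate."""
    levels = np.asarray(levels, dtype=np.int64)
    r = rng.random(levels.shape)
    drop = (levels > UNAWARE) & (r < dispirit_p_step)
    return levels - drop.astype(np.int64)
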