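"""The knowledge commons, enhanced registry, information stocks, and praxis.

The commons is a pool of exchangeable knowledge items whose usefulness halves
every ``shared_knowledge_half_life`` steps; the *effective stock* S(t) is the
sum of every item's decayed weight, so items age out of the commons rather
than accumulating forever.  Patients and clinicians at the contributing rung
or above may add an item at each time step; care centers with an enhanced
registry (medium/high) also convert encounter records into items at periodic
analyses.

Two engagement-gated information stocks feed praxis at the encounter:

* phenotype response information (PRI) — what is known about how patients of
  this phenotype respond to the treatments, drawn from the commons and
  accessed by the clinician;
* individual response information (IRI) — what this patient knows about their
  own response, accrued at encounters, decaying between them, and brought to
  the encounter by the patient.

Praxis, the knowledge actually applied to the treatment decision, is a
weighted mean of the two stocks after engagement gating and the pre-visit-
planning cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .levels import CONTRIBUTING, OWNING, UNAWARE
from .params import PVP_CAPS

__all__ = [
    "Commons",
    "Registry",
    "pvp_cap",
    "decay_stock",
    "contribute_knowledge",
    "contribution_step",
    "registry_step",
    "access_fraction",
    "er_encounter_boost",
    "effective_pvp_cap",
    "update_pri",
    "update_iri_decay",
    "update_iri_encounter",
    "compute_praxis",
]


@dataclass
class Commons:
    """Shared knowledge pool with exponential item decay.

    ``stock`` is maintained incrementally: each step it is multiplied by
    ``2**(-1/half_life)`` and fresh items enter at weight 1.  This equals the
    brute-force sum of per-item decays exactly (each item's weight is
    ``2**(-age/half_life)``).
    """

    half_life: float
    stock: float = 0.0
    items_ever_added: float = 0.0

    def decay(self, dt: float = 1.0) -> None:
        self.stock = decay_stock(self.stock, self.half_life, dt)

    def add(self, n_items: float) -> None:
        if n_items < 0:
            raise ValueError("cannot remove items from the commons")
        self.stock += n_items
        self.items_ever_added += n_items


@dataclass
class Registry:
    """Per-care-center enhanced-registry state."""

    er_level: str
    record_count: float = 0.0
    records_since_last_analysis: float = 0.0

    @property
    def automated(self) -> bool:
        return self.er_level in ("medium", "high")


def pvp_cap(pvp_level: str) -> float:
    """Maximum usable fraction of PRI/IRI under a pre-visit-planning level."""
    try:
        return PVP_CAPS[pvp_level]
    except KeyError:
        raise ValueError(f"unknown PVP level {pvp_level!r}; expected low/medium/high") from None


def decay_stock(stock: float, half_life: float, dt: float = 1.0):
    """Exponential decay: S' = S * 2**(-dt/half_life)."""
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be >= 0")
    return stock * 2.0 ** (-dt / half_life)


def contribute_knowledge(level: int, contrib_determiner: float, rng: np.random.Generator) -> int:
    """One Bernoulli contribution opportunity for one agent.

    Agents contribute to the commons at each time step, independent of the
    encounter schedule; only agents at the contributing rung or above can add
    an item.
    """
    if level >= CONTRIBUTING and rng.random() < contrib_determiner:
        return 1
    return 0


def contribution_step(patient_levels, clinician_levels, patient_determiner,
                      clinician_determiner, rng: np.random.Generator) -> int:
    """Per-step commons contributions from every sufficiently engaged agent."""
    patient_levels = np.asarray(patient_levels)
    clinician_levels = np.asarray(clinician_levels)
    n_p = int(((patient_levels >= CONTRIBUTING) &
               (rng.random(patient_levels.shape) < patient_determiner)).sum())
    n_c = int(((clinician_levels >= CONTRIBUTING) &
               (rng.random(clinician_levels.shape) < clinician_determiner)).sum())
    return n_p + n_c


def registry_step(
    registry: Registry,
    encounters_this_step: int,
    analysis_due: bool,
    record_per_commons_item: float,
) -> int:
    """Accumulate encounter records; at analyses, convert records to items.

    Low-level registries capture nothing.  Medium/high registries add one
    record per encounter; every analysis period the records accrued since the
    last analysis are distilled into
    ``floor(records / record_per_commons_item)`` commons items.
    """
    if not registry.automated:
        return 0
    registry.record_count += encounters_this_step
    registry.records_since_last_analysis += encounters_this_step
    if not analysis_due:
        return 0
    items = int(registry.records_since_last_analysis // record_per_commons_item)
    registry.records_since_last_analysis = 0.0
    return items


def access_fraction(level, degree_participating):
    """Fraction of available information an agent at a given rung can access.

    Anchored at the participating rung (access = the engagement-degree
    parameter ``d``): unaware 0, aware 0.25*d, participating d, contributing
    min(1, 1.5*d), owning min(1, 2*d).  Vectorized over ``level``.
    """
    level = np.asarray(level)
    d = degree_participating
    mult = np.choose(np.clip(level, UNAWARE, OWNING), [0.0, 0.25, 1.0, 1.5, 2.0])
    out = np.minimum(1.0, mult * d)
    return float(out) if out.ndim == 0 else out


def er_encounter_boost(er_level_high, clinician_access, degree_participating):
    """Real-time registry availability floors the clinician's access.

    At a high-ER care center the encounter has registry data on screen, which
    substitutes for engagement-gated retrieval: effective clinician access is
    at least the participating-level degree.  Vectorized.

    Real-time availability also supplies pre-visit-planning capability; see
    :func:`effective_pvp_cap`.
    """
    boosted = np.maximum(clinician_access, degree_participating)
    out = np.where(er_level_high, boosted, clinician_access)
    return float(out) if np.ndim(out) == 0 else out


def effective_pvp_cap(pvp_cap_value, er_level_high):
    """The usable-information cap at the encounter.

    A high-ER care center has registry data available in real time at the
    encounter, which supplies the pre-visit-planning capability directly: the
    effective cap is lifted to the unconstrained level regardless of the
    center's own PVP sophistication.  Vectorized.
    """
    out = np.where(er_level_high, np.maximum(pvp_cap_value, PVP_CAPS["high"]),
                   pvp_cap_value)
    return float(out) if np.ndim(out) == 0 else out


def update_pri(pri, stock, phenotype_realization, info_rate, clinician_access):
    """Saturating PRI gain from the accessible share of the commons.

    Accessible knowledge A = S * phenotype_realization * clinician_access
    (the clinician retrieves phenotype-level knowledge from the commons);
    gain g = 1 - exp(-info_rate * A); PRI' = 1 - (1 - PRI)(1 - g).
    Monotone, bounded in [PRI, 1], and PRI has no intrinsic decay — phenotype
    knowledge ages only through the commons stock itself.
    """
    a = stock * phenotype_realization * clinician_access
    gain = 1.0 - np.exp(-info_rate * np.maximum(a, 0.0))
    return 1.0 - (1.0 - pri) * (1.0 - gain)


def update_iri_decay(iri, half_life, dt: float = 1.0):
    """Between encounters a patient's own response knowledge goes stale."""
    return decay_stock(iri, half_life, dt)


def update_iri_encounter(iri, increase, accel_per_sk_unit, accel_cap, stock):
    """At an encounter IRI rises by a fixed increment, accelerated by the commons.

    IRI' = min(1, IRI + increase * (1 + a)) with
    a = min(accel_cap, accel_per_sk_unit * S).
    """
    a = np.minimum(accel_cap, accel_per_sk_unit * stock)
    return np.minimum(1.0, iri + increase * (1.0 + a))


def compute_praxis(pri, iri, patient_access, clinician_access, cap, pri_weight: float = 0.5):
    """Knowledge applied to the treatment decision, in [0, 1].

    The clinician brings the phenotype-level knowledge (PRI gated by
    clinician access), the patient brings their own response knowledge (IRI
    gated by patient access); pre-visit planning caps how much of either is
    usable in the encounter.  Vectorized.
    """
    pri_eff = np.minimum(pri * clinician_access, cap)
    iri_eff = np.minimum(iri * patient_access, cap)
    out = np.clip(pri_weight * pri_eff + (1.0 - pri_weight) * iri_eff, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out
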