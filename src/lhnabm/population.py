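"""Cohort construction: care centers, panels, phenotypes, influence networks.

A population is stored column-wise in numpy arrays (one entry per patient or
clinician) so that the engine can update every agent of a kind in a single
vectorized pass.  Influence edges are undirected (i, j) pairs generated
configuration-model style: the expected number of edges per agent is a
parameter, and each drawn edge crosses care centers with a configurable
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .levels import level_code
from .params import ConditionSpec, ScenarioConfig, validate_params

__all__ = [
    "PatientState",
    "ClinicianState",
    "EffectivenessMatrix",
    "InfluenceNetwork",
    "Population",
    "build_condition_matrix",
    "build_influence_network",
    "build_population",
]


@dataclass
class PatientState:
    """Mutable state of a single patient (scalar encounter path and tests).

    The engine keeps the same fields column-wise in numpy arrays.
    """

    id: int
    care_center: int
    clinician: int
    phenotype: int
    health: float
    engagement: int = 0
    iri: float = 0.0
    pri: float = 0.0
    current_treatment: Optional[int] = None
    health_at_last_encounter: float = 0.0
    steps_until_next_encounter: int = 0
    last_praxis: float = 0.0
    active: bool = True

    def __post_init__(self):
        if self.health_at_last_encounter == 0.0:
            self.health_at_last_encounter = self.health


@dataclass
class ClinicianState:
    """Mutable state of a single clinician."""

    id: int
    care_center: int
    engagement: int = 0
    panel: list = field(default_factory=list)


@dataclass
class EffectivenessMatrix:
    """Per-phenotype health targets for each treatment.

    ``target[p, t]`` is the health level treatment ``t`` pulls a phenotype-``p``
    patient toward; ``rank[p, t]`` ranks treatments within a phenotype row
    (1 = best).  Within a row the targets are an evenly spaced grid from
    ``best_target`` down to ``worst_target`` assigned to treatments by an
    independent random permutation, so every phenotype has exactly one best
    treatment and the ranking is total.
    """

    target: np.ndarray  # (n_phenotypes, n_treatments)
    rank: np.ndarray    # (n_phenotypes, n_treatments), 1 = best

    @property
    def n_phenotypes(self) -> int:
        return self.target.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.target.shape[1]


@dataclass
class InfluenceNetwork:
    """Undirected influence edges over one agent kind."""

    edges: np.ndarray        # (n_edges, 2) agent indices, i < j
    across: np.ndarray       # (n_edges,) bool, True if endpoints span care centers

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_condition_matrix(condition: ConditionSpec, rng: np.random.Generator) -> EffectivenessMatrix:
    """Draw the phenotype-by-treatment effectiveness structure."""
    n_p, n_t = condition.n_phenotypes, condition.n_treatments
    if n_t < 2:
        raise ValueError("need at least 2 treatments")
    grid = np.linspace(condition.best_target, condition.worst_target, n_t)
    target = np.empty((n_p, n_t))
    rank = np.empty((n_p, n_t), dtype=np.int64)
    for p in range(n_p):
        perm = rng.permutation(n_t)
        target[p, perm] = grid           # grid[k] -> treatment perm[k]
        rank[p, perm] = np.arange(1, n_t + 1)
    return EffectivenessMatrix(target=target, rank=rank)


def build_influence_network(
    center_of: np.ndarray,
    edges_per_agent: float,
    across_prop: float,
    rng: np.random.Generator,
) -> InfluenceNetwork:
    """Draw an undirected influence network by repeated random pair draws.

    ``n_agents * edges_per_agent / 2`` edges are attempted (each edge touches
    two agents); each is an across-center pair with probability
    ``across_prop``, otherwise a within-center pair.  Self-loops and duplicate
    edges are rejected and redrawn (bounded retries); degenerate requests
    (across-center edge in a single-center population, within-center edge in
    a singleton center) fall back to the feasible kind.
    """
    center_of = np.asarray(center_of)
    n = len(center_of)
    n_centers = center_of.max() + 1 if n else 0
    n_edges = int(round(n * edges_per_agent / 2.0))
    if n < 2 or n_edges == 0:
        return InfluenceNetwork(edges=np.empty((0, 2), dtype=np.int64),
                                across=np.empty(0, dtype=bool))
    members = [np.flatnonzero(center_of == c) for c in range(n_centers)]
    multi_center = n_centers > 1
    seen: set[tuple[int, int]] = set()
    out = []
    out_across = []
    max_tries = 50 * n_edges + 1000
    tries = 0
    while len(out) < n_edges and tries < max_tries:
        tries += 1
        want_across = multi_center and rng.random() < across_prop
        if want_across:
            i = int(rng.integers(n))
            c = center_of[i]
            other = np.flatnonzero(center_of != c)
            j = int(other[rng.integers(len(other))])
        else:
            # pick a center able to host a within edge, weighted by size
            i = int(rng.integers(n))
            mem = members[center_of[i]]
            if len(mem) < 2:
                # singleton center: fall back to an across edge if possible
                if not multi_center:
                    continue
                other = np.flatnonzero(center_of != center_of[i])
                j = int(other[rng.integers(len(other))])
                want_across = True
            else:
                j = int(mem[rng.integers(len(mem))])
                if j == i:
                    continue
        a, b = (i, j) if i < j else (j, i)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        out.append((a, b))
        out_across.append(center_of[a] != center_of[b])
    edges = np.array(out, dtype=np.int64).reshape(-1, 2)
    return InfluenceNetwork(edges=edges, across=np.array(out_across, dtype=bool))


@dataclass
class Population:
    """Initial state of every agent, column-wise."""

    # patients
    patient_center: np.ndarray       # (n_patients,) care-center index
    patient_clinician: np.ndarray    # (n_patients,) clinician index
    phenotype: np.ndarray            # (n_patients,)
    health0: np.ndarray              # (n_patients,) initial health
    patient_engagement0: np.ndarray  # (n_patients,) engagement code
    first_encounter_offset: np.ndarray  # (n_patients,) in [0, encounter_period)
    # clinicians
    clinician_center: np.ndarray     # (n_clinicians,)
    clinician_engagement0: np.ndarray
    # structure
    effectiveness: EffectivenessMatrix
    patient_network: InfluenceNetwork
    clinician_network: InfluenceNetwork

    @property
    def n_patients(self) -> int:
        return len(self.patient_center)

    @property
    def n_clinicians(self) -> int:
        return len(self.clinician_center)

    def to_frame(self) -> pd.DataFrame:
        """One row per agent, for debugging/regression dumps."""
        pats = pd.DataFrame({
            "id": np.arange(self.n_patients), "kind": "patient",
            "center": self.patient_center, "clinician": self.patient_clinician,
            "phenotype": self.phenotype, "health0": self.health0,
            "engagement0": self.patient_engagement0,
        })
        clins = pd.DataFrame({
            "id": np.arange(self.n_clinicians), "kind": "clinician",
            "center": self.clinician_center, "clinician": -1,
            "phenotype": -1, "health0": np.nan,
            "engagement0": self.clinician_engagement0,
        })
        return pd.concat([pats, clins], ignore_index=True)


def _seed_engagement(n: int, fraction: float, level: int, rng: np.random.Generator) -> np.ndarray:
    eng = np.zeros(n, dtype=np.int64)
    k = int(round(n * fraction))
    if k > 0:
        idx = rng.choice(n, size=min(k, n), replace=False)
        eng[idx] = level
    return eng


def build_population(scenario: ScenarioConfig, rng: np.random.Generator) -> Population:
    """Construct the full cohort for a validated scenario."""
    validate_params(scenario.params, scenario.condition)
    n_centers = scenario.n_care_centers
    n_clin = scenario.n_clinicians
    n_pat = scenario.n_patients

    clinician_center = np.repeat(np.arange(n_centers), scenario.clinicians_per_center)
    patient_clinician = np.repeat(np.arange(n_clin), scenario.patients_per_clinician)
    patient_center = clinician_center[patient_clinician]

    effectiveness = build_condition_matrix(scenario.condition, rng)
    phenotype = rng.integers(0, scenario.condition.n_phenotypes, size=n_pat)
    health0 = rng.uniform(0.3, 0.7, size=n_pat)

    lvl = level_code(scenario.initial_engaged_level)
    patient_eng = _seed_engagement(n_pat, scenario.initial_engaged_fraction_patients, lvl, rng)
    clinician_eng = _seed_engagement(n_clin, scenario.initial_engaged_fraction_clinicians, lvl, rng)

    offsets = rng.integers(0, scenario.params.encounter_period, size=n_pat)

    p = scenario.params
    patient_net = build_influence_network(
        patient_center, p.patient_network_edges, p.patient_influence_across_prop, rng)
    clinician_net = build_influence_network(
        clinician_center, p.clinician_network_edges, p.clinician_influence_across_prop, rng)

    return Population(
        patient_center=patient_center,
        patient_clinician=patient_clinician,
        phenotype=phenotype,
        health0=health0,
        patient_engagement0=patient_eng,
        first_encounter_offset=offsets,
        clinician_center=clinician_center,
        clinician_engagement0=clinician_eng,
        effectiveness=effectiveness,
        patient_network=patient_net,
        clinician_network=clinician_net,
    )
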