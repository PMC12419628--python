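"""Output writing and miniature diagnostic fixtures.

All outputs are plain CSV/JSON with dot decimals and UTF-8 so downstream
analysis works in any stack (including recomputing the PRCCs in R).  Run
directories get a manifest with SHA-256 checksums of every file written.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from .engine import RunMetrics, RunOutcomes
from .params import ScenarioConfig, scenario_to_dict, scenario_to_yaml

__all__ = ["write_run_outputs", "write_manifest", "make_fixtures", "FIXTURE_KINDS"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, scenario: ScenarioConfig, seed, files) -> Path:
    from . import __version__
    manifest = {
        "tool": "lhnabm",
        "version": __version__,
        "seed": seed,
        "written_at": datetime.now(timezone.utc).isoformat(),
        "scenario": scenario_to_dict(scenario),
        "files": {f.name: _sha256(f) for f in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float))
    return path


def write_run_outputs(outdir, metrics: RunMetrics, outcomes: RunOutcomes) -> list:
    """Write timeseries.csv, outcomes.json, and manifest.json for one run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ts = outdir / "timeseries.csv"
    metrics.frame.to_csv(ts, index=False, lineterminator="\n")
    oc = outdir / "outcomes.json"
    oc.write_text(json.dumps(outcomes.as_dict(), indent=2))
    man = write_manifest(outdir, metrics.scenario, metrics.seed, [ts, oc])
    return [ts, oc, man]


# ---------------------------------------------------------------------------
# Fixtures: miniature scenarios exercising a single mechanism each.

FIXTURE_KINDS = ("frozen", "two-patient", "contagion-star", "commons-only")

_FROZEN_PARAMS = dict(
    encounter_aware_determiner=0.0, patient_activate_determiner=0.0,
    patient_dispirit_determiner=0.0,
    patient_influence_become_aware_probability=0.0,
    patient_influence_activation_probability=0.0,
    clinician_influence_become_aware_probability=0.0,
    clinician_influence_activation_probability=0.0,
    clinician_dispirit_probability=0.0,
    shared_knowledge_initial=0.0,
    patient_shared_knowledge_contrib_determiner=0.0,
    clinician_shared_knowledge_contrib_determiner=0.0,
    enhanced_registry_initial_per_patient=0.0,
    potential_phenotype_response_info_from_sk_unit=0.0,
    patient_response_info_increase_numeric=0.0,
    patient_response_info_acceleration_from_sk_unit=0.0,
)

_FROZEN_CONDITION = dict(
    responsiveness_kappa=0.0, natural_history_drift=0.0,
    relapse_probability=0.0, relapse_magnitude=0.0, variability_sd=0.0,
)


def make_fixture_scenario(kind: str, seed: int = 0) -> ScenarioConfig:
    """A miniature scenario in which exactly one mechanism is live."""
    base = ScenarioConfig(seed=seed)
    if kind == "frozen":
        # Nothing moves: engagement, health, knowledge all constant.
        return base.replace(
            n_care_centers=1, clinicians_per_center=2, patients_per_clinician=5,
            initial_engaged_fraction_patients=0.0,
            initial_engaged_fraction_clinicians=0.0,
            params=base.params.replace(**_FROZEN_PARAMS),
            condition=base.condition.replace(**_FROZEN_CONDITION))
    if kind == "two-patient":
        # Smallest legal cohort with live encounters; for replay-style checks.
        return base.replace(
            n_care_centers=1, clinicians_per_center=1, patients_per_clinician=2,
            horizon_steps=52,
            initial_engaged_fraction_patients=0.0,
            initial_engaged_fraction_clinicians=1.0,
            initial_engaged_level="owning")
    if kind == "contagion-star":
        # Peer influence only: all encounter-side and knowledge dynamics off.
        frozen = dict(_FROZEN_PARAMS)
        frozen.update(
            patient_influence_become_aware_probability=0.5,
            patient_influence_activation_probability=0.5,
            patient_network_edges=2.0, clinician_network_edges=0.0)
        return base.replace(
            n_care_centers=1, clinicians_per_center=1, patients_per_clinician=51,
            horizon_steps=52,
            initial_engaged_fraction_patients=0.02,
            initial_engaged_fraction_clinicians=0.0,
            initial_engaged_level="owning",
            params=base.params.replace(**frozen),
            condition=base.condition.replace(**_FROZEN_CONDITION))
    if kind == "commons-only":
        # Contributions are the only live mechanism: knowledge = Bernoulli sum.
        frozen = dict(_FROZEN_PARAMS)
        frozen.update(
            patient_shared_knowledge_contrib_determiner=0.4,
            clinician_shared_knowledge_contrib_determiner=0.4,
            shared_knowledge_half_life=1e9)  # effectively no decay
        return base.replace(
            n_care_centers=1, clinicians_per_center=2, patients_per_clinician=5,
            horizon_steps=52,
            initial_engaged_fraction_patients=1.0,
            initial_engaged_fraction_clinicians=1.0,
            initial_engaged_level="owning",
            params=base.params.replace(**frozen),
            condition=base.condition.replace(**_FROZEN_CONDITION))
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")


def make_fixtures(outdir, kinds=FIXTURE_KINDS, seed: int = 0) -> list:
    """Write the fixture scenario YAMLs to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for kind in kinds:
        path = outdir / f"{kind.replace('-', '_')}.yaml"
        path.write_text(scenario_to_yaml(make_fixture_scenario(kind, seed)))
        written.append(path)
    return written
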