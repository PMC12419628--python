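"""Model parameters, condition description, scenario configuration, ranges.

The thirty named model parameters (:class:`ModelParams`) are the levers a
learning-health-network leadership team could in principle move: encounter
cadence, engagement-contagion probabilities, network density, commons decay,
registry throughput, information-access degrees, and the praxis-driven
selection/evaluation maxima.  Everything describing the *disease* rather than
the network lives in :class:`ConditionSpec` and is held constant in the
sensitivity analysis.  A :class:`ScenarioConfig` bundles both with the cohort
layout, intervention levels, horizon and seed, and is the single input to a
simulation run.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import yaml

from .levels import LEVEL_NAMES, level_code

__all__ = [
    "ModelParams",
    "ConditionSpec",
    "ScenarioConfig",
    "ParamRange",
    "ParamValidationError",
    "ConfigError",
    "validate_params",
    "midpoint_params",
    "load_scenario",
    "load_ranges",
    "default_ranges",
    "scenario_to_yaml",
    "PVP_CAPS",
    "ER_LEVELS",
]

# Pre-visit-planning cap on usable response information, by intervention level.
PVP_CAPS = {"low": 0.2, "medium": 0.5, "high": 1.0}
ER_LEVELS = ("low", "medium", "high")

# Fields that must be integral.
_INT_FIELDS = {"encounter_period", "enhanced_registry_analysis_period"}
# Per-encounter or per-step probabilities / fractions, must lie in [0, 1].
_PROB_FIELDS = {
    "encounter_aware_determiner",
    "patient_activate_determiner",
    "patient_dispirit_determiner",
    "patient_influence_across_prop",
    "clinician_influence_across_prop",
    "patient_influence_become_aware_probability",
    "patient_influence_activation_probability",
    "clinician_influence_become_aware_probability",
    "clinician_influence_activation_probability",
    "clinician_dispirit_probability",
    "patient_shared_knowledge_contrib_determiner",
    "clinician_shared_knowledge_contrib_determiner",
    "phenotype_realization_numeric",
    "patient_response_info_increase_numeric",
    "evaluation_accuracy_minimum_praxis",
    "patient_engagement_degree_participating",
    "clinician_engagement_degree_participating",
}
_POSITIVE_FIELDS = {"shared_knowledge_half_life", "patient_response_info_half_life",
                    "enhanced_registry_record_per_commons_item"}
_NONNEG_FIELDS = {
    "patient_network_edges",
    "clinician_network_edges",
    "shared_knowledge_initial",
    "enhanced_registry_initial_per_patient",
    "potential_phenotype_response_info_from_sk_unit",
    "patient_response_info_acceleration_from_sk_unit",
    "maximal_patient_response_info_acceleration_from_sk",
}


@dataclass
class ModelParams:
    """The 30 network-level model parameters.

    Defaults are the midpoints of the packaged default ranges, so that an
    all-defaults scenario coincides with the "all other parameters held at
    their midpoints" setting used by the grid and factorial experiments.
    """

    # Encounter cadence and encounter-driven engagement change
    encounter_period: int = 15                       # steps between scheduled visits
    encounter_aware_determiner: float = 0.5          # P(unaware -> aware | encounter)
    patient_activate_determiner: float = 0.5         # P(step up | clinician more engaged)
    patient_dispirit_determiner: float = 0.1         # P(step down | clinician less engaged)
    # Influence networks
    patient_network_edges: float = 5.0               # expected edges per patient
    clinician_network_edges: float = 5.0
    patient_influence_across_prop: float = 0.5       # fraction of edges across centers
    clinician_influence_across_prop: float = 0.5
    # Peer-influence probabilities (ANNUAL; converted to per-step inside the engine)
    patient_influence_become_aware_probability: float = 0.5
    patient_influence_activation_probability: float = 0.5
    clinician_influence_become_aware_probability: float = 0.5
    clinician_influence_activation_probability: float = 0.5
    clinician_dispirit_probability: float = 0.1      # annual burnout probability
    # Knowledge commons
    shared_knowledge_initial: float = 10.0           # items present at t = 0
    shared_knowledge_half_life: float = 132.0        # steps
    patient_shared_knowledge_contrib_determiner: float = 0.5
    clinician_shared_knowledge_contrib_determiner: float = 0.5
    # Enhanced registry pipeline
    enhanced_registry_initial_per_patient: float = 5.0
    enhanced_registry_analysis_period: int = 15      # steps between analyses
    enhanced_registry_record_per_commons_item: float = 10.5
    # Phenotype response information (PRI)
    potential_phenotype_response_info_from_sk_unit: float = 0.001
    phenotype_realization_numeric: float = 0.5       # share of commons relevant to one phenotype
    # Individual response information (IRI)
    patient_response_info_half_life: float = 132.0   # steps
    patient_response_info_increase_numeric: float = 0.5
    patient_response_info_acceleration_from_sk_unit: float = 0.0005
    maximal_patient_response_info_acceleration_from_sk: float = 1.0
    # Praxis-driven decision quality
    selection_efficiency_maximum: float = 505.0      # selection efficiency at praxis 1
    evaluation_accuracy_minimum_praxis: float = 0.2505  # misjudgment prob at praxis 0 (reversed axis)
    # Engagement-gated information access
    patient_engagement_degree_participating: float = 0.5
    clinician_engagement_degree_participating: float = 0.5

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)


PARAM_NAMES = tuple(f.name for f in fields(ModelParams))
assert len(PARAM_NAMES) == 30


@dataclass
class ConditionSpec:
    """Description of the simulated chronic condition.

    Held constant across the sensitivity analysis; the values below were
    calibrated once so that the low / medium / high network-functioning
    regimes produce declining / stable / improving cohort health (see
    docs/methods.md).
    """

    n_phenotypes: int = 4
    n_treatments: int = 8
    responsiveness_kappa: float = 0.08      # per-step pull of health toward the treatment target
    natural_history_drift: float = -0.0215   # per-step untreated drift (progressive condition)
    relapse_probability: float = 0.004      # per-step probability of an acute setback
    relapse_magnitude: float = 0.4          # health lost in a relapse
    variability_sd: float = 0.03            # per-step health noise SD
    best_target: float = 0.95               # health target of the best-matched treatment
    worst_target: float = 0.05

    def replace(self, **kw) -> "ConditionSpec":
        return dataclasses.replace(self, **kw)


_SCENARIO_SIMPLE_FIELDS = {
    "n_care_centers", "clinicians_per_center", "patients_per_clinician",
    "horizon_steps", "steps_per_year", "pvp_level", "er_level",
    "closed_cohort", "seed",
    "initial_engaged_fraction_patients", "initial_engaged_fraction_clinicians",
    "initial_engaged_level",
    "exit_health_high", "exit_health_low", "exit_consecutive_steps",
    "exit_ageout_annual_probability",
    "praxis_pri_weight",
}


@dataclass
class ScenarioConfig:
    """Everything needed to run one simulation."""

    params: ModelParams = field(default_factory=ModelParams)
    condition: ConditionSpec = field(default_factory=ConditionSpec)
    n_care_centers: int = 4
    clinicians_per_center: int = 5
    patients_per_clinician: int = 10
    horizon_steps: int = 260                # five years at one step per week
    steps_per_year: int = 52
    pvp_level: Union[str, list] = "high"    # one level, or one per care center
    er_level: Union[str, list] = "low"
    closed_cohort: bool = True
    seed: int = 0
    # Engagement seeding: contagion needs a nonzero seed population, and the
    # population's top engagement rung can never rise above the highest seed
    # (peer influence and encounters only pull agents up toward someone
    # already more engaged), so seeds sit at the owning rung.
    initial_engaged_fraction_patients: float = 0.05
    initial_engaged_fraction_clinicians: float = 0.30
    initial_engaged_level: str = "owning"
    # Cohort-exit rules; only consulted when closed_cohort is False.
    exit_health_high: float = 0.95
    exit_health_low: float = 0.05
    exit_consecutive_steps: int = 8
    exit_ageout_annual_probability: float = 0.0
    # Relative weight of PRI vs IRI in praxis (equal by default).
    praxis_pri_weight: float = 0.5

    @property
    def n_clinicians(self) -> int:
        return self.n_care_centers * self.clinicians_per_center

    @property
    def n_patients(self) -> int:
        return self.n_clinicians * self.patients_per_clinician

    def center_levels(self, which: str) -> list:
        """Per-center intervention levels, expanding a scalar to all centers."""
        raw = self.pvp_level if which == "pvp" else self.er_level
        if isinstance(raw, str):
            return [raw] * self.n_care_centers
        lv = list(raw)
        if len(lv) != self.n_care_centers:
            raise ConfigError(
                f"{which}_level list has {len(lv)} entries for "
                f"{self.n_care_centers} care centers")
        return lv

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


class ParamValidationError(ValueError):
    """Raised with the full list of violated invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid parameters:\n  " + "\n  ".join(self.violations))


class ConfigError(ValueError):
    """Malformed scenario/ranges configuration."""


def validate_params(params: ModelParams, condition: Optional[ConditionSpec] = None) -> ModelParams:
    """Check every field invariant; report *all* violations, not just the first."""
    bad: list[str] = []
    for name in PARAM_NAMES:
        v = getattr(params, name)
        if not isinstance(v, (int, float, np.integer, np.floating)) or not math.isfinite(float(v)):
            bad.append(f"{name}: non-numeric or non-finite value {v!r}")
            continue
        v = float(v)
        if name in _INT_FIELDS:
            if v != int(v):
                bad.append(f"{name}: must be an integer, got {v}")
            if v < 1:
                bad.append(f"{name}: must be >= 1, got {v}")
        if name in _PROB_FIELDS and not (0.0 <= v <= 1.0):
            bad.append(f"{name}: must be in [0, 1], got {v}")
        if name in _POSITIVE_FIELDS and not v > 0:
            bad.append(f"{name}: must be > 0, got {v}")
        if name in _NONNEG_FIELDS and v < 0:
            bad.append(f"{name}: must be >= 0, got {v}")
    if params.selection_efficiency_maximum < 1:
        bad.append("selection_efficiency_maximum: must be >= 1, got "
                   f"{params.selection_efficiency_maximum}")
    if condition is not None:
        c = condition
        if c.n_phenotypes < 1:
            bad.append(f"n_phenotypes: must be >= 1, got {c.n_phenotypes}")
        if c.n_treatments < 2:
            bad.append(f"n_treatments: must be >= 2, got {c.n_treatments}")
        # kappa = 0 is allowed: frozen-dynamics diagnostic scenarios rely on it
        if not (0.0 <= c.responsiveness_kappa <= 1.0):
            bad.append(f"responsiveness_kappa: must be in [0, 1], got {c.responsiveness_kappa}")
        if not (0.0 <= c.relapse_probability <= 1.0):
            bad.append(f"relapse_probability: must be in [0, 1], got {c.relapse_probability}")
        if not (0.0 <= c.relapse_magnitude <= 1.0):
            bad.append(f"relapse_magnitude: must be in [0, 1], got {c.relapse_magnitude}")
        if c.variability_sd < 0:
            bad.append(f"variability_sd: must be >= 0, got {c.variability_sd}")
        for t in ("best_target", "worst_target"):
            tv = getattr(c, t)
            if not (0.0 <= tv <= 1.0):
                bad.append(f"{t}: must be in [0, 1], got {tv}")
        if not c.best_target > c.worst_target:
            bad.append(f"best_target ({c.best_target}) must exceed worst_target ({c.worst_target})")
    if bad:
        raise ParamValidationError(bad)
    return params


@dataclass
class ParamRange:
    """Sampling range for one parameter (uniform or triangle marginal)."""

    name: str
    lower: float
    upper: float
    dist: str = "uniform"
    mode: Optional[float] = None

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ConfigError(f"{self.name}: lower ({self.lower}) must be < upper ({self.upper})")
        if self.dist not in ("uniform", "triangle"):
            raise ConfigError(f"{self.name}: unknown distribution {self.dist!r}")
        if self.dist == "triangle":
            if self.mode is None:
                self.mode = 0.5 * (self.lower + self.upper)
            if not (self.lower <= self.mode <= self.upper):
                raise ConfigError(
                    f"{self.name}: triangle mode {self.mode} outside [{self.lower}, {self.upper}]")

    def midpoint(self) -> float:
        # "Midpoint" of the parameter, not of the distribution: (lower+upper)/2
        # for triangle ranges too.
        return 0.5 * (self.lower + self.upper)

    def ppf(self, q):
        """Inverse CDF, vectorized over q."""
        q = np.asarray(q, dtype=float)
        lo, up = self.lower, self.upper
        if self.dist == "uniform":
            return lo + q * (up - lo)
        m = self.mode
        fc = (m - lo) / (up - lo)
        left = lo + np.sqrt(np.clip(q, 0, 1) * (up - lo) * (m - lo))
        right = up - np.sqrt(np.clip(1 - q, 0, 1) * (up - lo) * (up - m))
        return np.where(q < fc, left, right)


def midpoint_params(ranges: Iterable[ParamRange]) -> ModelParams:
    """All parameters at the midpoints of their ranges (integers rounded)."""
    rlist = list(ranges)
    names = [r.name for r in rlist]
    dup = {n for n in names if names.count(n) > 1}
    if dup:
        raise ConfigError(f"duplicate parameter ranges: {sorted(dup)}")
    unknown = set(names) - set(PARAM_NAMES)
    if unknown:
        raise ConfigError(f"ranges for unknown parameters: {sorted(unknown)}")
    missing = set(PARAM_NAMES) - set(names)
    if missing:
        raise ConfigError(f"missing ranges for parameters: {sorted(missing)}")
    kw = {}
    for r in rlist:
        v = r.midpoint()
        if r.name in _INT_FIELDS:
            v = int(round(v))
        kw[r.name] = v
    return ModelParams(**kw)


# ---------------------------------------------------------------------------
# Configuration file handling


def _coerce(value, template, path):
    """Coerce a YAML scalar to the type of the default it overrides."""
    if isinstance(template, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected a boolean, got {value!r}")
        return value
    if isinstance(template, int) and not isinstance(template, bool):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected a number, got {value!r}")
        if float(value) != int(value):
            raise ConfigError(f"{path}: expected an integer, got {value!r}")
        return int(value)
    if isinstance(template, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected a number, got {value!r}")
        return float(value)
    if isinstance(template, str):
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected a string, got {value!r}")
        return value
    return value


def _apply_section(obj, overrides: dict, section: str):
    valid = {f.name for f in fields(obj)}
    kw = {}
    for key, val in overrides.items():
        if key not in valid:
            raise ConfigError(f"unknown key {section}{key!r}")
        kw[key] = _coerce(val, getattr(obj, key), f"{section}{key}")
    return dataclasses.replace(obj, **kw)


def load_scenario(source) -> ScenarioConfig:
    """Load a scenario from YAML/JSON text, a path, or a mapping.

    Unspecified fields take packaged defaults; unknown keys are rejected.
    """
    if isinstance(source, dict) or source is None:
        data = source or {}
    else:
        text = Path(source).read_text() if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
        ) else str(source)
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"scenario config must be a mapping, got {type(data).__name__}")

    scenario = ScenarioConfig()
    params_over = data.pop("params", {}) or {}
    cond_over = data.pop("condition", {}) or {}
    if not isinstance(params_over, dict):
        raise ConfigError("params: expected a mapping")
    if not isinstance(cond_over, dict):
        raise ConfigError("condition: expected a mapping")
    params = _apply_section(scenario.params, params_over, "params.")
    condition = _apply_section(scenario.condition, cond_over, "condition.")

    kw = {}
    for key, val in data.items():
        if key not in _SCENARIO_SIMPLE_FIELDS:
            raise ConfigError(f"unknown key {key!r}")
        if key in ("pvp_level", "er_level"):
            levels = [val] if isinstance(val, str) else list(val)
            for lv in levels:
                if lv not in PVP_CAPS:
                    raise ConfigError(f"{key}: unknown level {lv!r}; expected low/medium/high")
            kw[key] = val
        else:
            kw[key] = _coerce(val, getattr(scenario, key), key)
    scenario = dataclasses.replace(scenario, params=params, condition=condition, **kw)

    # Scenario-level invariants
    if scenario.horizon_steps < 0:
        raise ConfigError(f"horizon_steps: must be >= 0, got {scenario.horizon_steps}")
    if scenario.steps_per_year < 1:
        raise ConfigError(f"steps_per_year: must be >= 1, got {scenario.steps_per_year}")
    for key in ("n_care_centers", "clinicians_per_center", "patients_per_clinician"):
        if getattr(scenario, key) < 1:
            raise ConfigError(f"{key}: must be >= 1, got {getattr(scenario, key)}")
    if scenario.initial_engaged_level not in LEVEL_NAMES:
        raise ConfigError(f"initial_engaged_level: unknown level {scenario.initial_engaged_level!r}")
    for key in ("initial_engaged_fraction_patients", "initial_engaged_fraction_clinicians",
                "praxis_pri_weight"):
        v = getattr(scenario, key)
        if not (0.0 <= v <= 1.0):
            raise ConfigError(f"{key}: must be in [0, 1], got {v}")
    scenario.center_levels("pvp")
    scenario.center_levels("er")
    validate_params(scenario.params, scenario.condition)
    return scenario


def scenario_to_dict(scenario: ScenarioConfig) -> dict:
    d = {f.name: getattr(scenario, f.name) for f in fields(scenario)
         if f.name not in ("params", "condition")}
    d["params"] = dataclasses.asdict(scenario.params)
    d["condition"] = dataclasses.asdict(scenario.condition)
    return d


def scenario_to_yaml(scenario: ScenarioConfig) -> str:
    return yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False)


def load_ranges(source=None) -> list[ParamRange]:
    """Load parameter ranges from YAML (defaults to the packaged ranges file)."""
    if source is None:
        text = resources.files("lhnabm.data").joinpath("ranges_default.yaml").read_text()
    elif isinstance(source, (str, Path)) and (
            isinstance(source, Path) or source.endswith((".yaml", ".yml", ".json"))):
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("ranges file must be a mapping of parameter name -> range")
    out = []
    for name, spec in data.items():
        if name not in PARAM_NAMES:
            raise ConfigError(f"range for unknown parameter {name!r}")
        if isinstance(spec, (list, tuple)):
            if len(spec) != 2:
                raise ConfigError(f"{name}: a list range must be [lower, upper]")
            out.append(ParamRange(name, float(spec[0]), float(spec[1])))
        elif isinstance(spec, dict):
            extra = set(spec) - {"lower", "upper", "dist", "mode"}
            if extra:
                raise ConfigError(f"{name}: unknown range keys {sorted(extra)}")
            out.append(ParamRange(
                name, float(spec["lower"]), float(spec["upper"]),
                dist=spec.get("dist", "uniform"),
                mode=float(spec["mode"]) if spec.get("mode") is not None else None))
        else:
            raise ConfigError(f"{name}: range must be [lower, upper] or a mapping")
    return out


def default_ranges() -> list[ParamRange]:
    return load_ranges(None)


def default_scenario() -> ScenarioConfig:
    """The packaged default scenario."""
    text = resources.files("lhnabm.data").joinpath("defaults.yaml").read_text()
    return load_scenario(text)
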