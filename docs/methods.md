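# Methods

`lhnabm` simulates a collaborative learning health network (LHN): a set of
care centers whose patients and clinicians coproduce the knowledge used in
treatment decisions.  This note documents the model, its parameters, the
functional forms chosen where the conceptual description leaves them open,
the synthetic study conditions, and the known limitations.

## Model overview

Time advances in discrete weekly steps (52 steps/year; the reference horizon
is five years = 260 steps) over a closed cohort.  Agents are patients
(assigned to a clinician within a care center) and clinicians (each with a
panel of patients).  Both carry an ordinal engagement state —
unaware → aware → participating → contributing → owning — that gates every
knowledge flow in the model.

Each step executes a fixed stage order:

1. exponential decay of the knowledge commons and of each patient's
   individual response information (IRI), then one step of the health
   process for every patient;
2. the clinical encounters due this step;
3. commons contributions from every agent at the contributing rung or above;
4. peer influence over the patient and clinician networks;
5. clinician burnout;
6. registry analysis, when due;
7. metrics collection.

A run is a deterministic function of (scenario, seed): one PCG64 stream
drives population construction and all subsequent stochasticity, and
identical seeds give byte-identical output.

### Health process

Patient health h ∈ [0, 1] follows a bounded pull-toward-target process.
With κ the per-step responsiveness, T the health target of the current
treatment for the patient's phenotype, δ the natural-history drift, σ the
per-step variability, and relapses of magnitude M arriving with per-step
probability ρ:

    h' = clip( h + κ·(T − h) + δ + N(0, σ²) − 1{relapse}·M , 0, 1 )

Patients not yet on a treatment feel no pull.  A pull-toward-target form
(rather than additive treatment effects) keeps health bounded and produces
sustained decline under poor matching and sustained improvement under good
matching.

### Phenotypes and treatments

Each patient has one of `n_phenotypes` phenotypes.  For each phenotype the
`n_treatments` treatments are assigned health targets on an evenly spaced
grid from `best_target` down to `worst_target`, permuted independently per
phenotype — so every phenotype has exactly one best treatment and a total
ranking, but which treatment is best differs across phenotypes.

### The clinical encounter

Each patient has an encounter every `encounter_period` steps (first visits
are staggered uniformly over one period).  An encounter runs:

1. **Engagement**: an unaware patient meeting an engaged clinician becomes
   aware with probability `encounter_aware_determiner`; otherwise the
   patient moves one rung toward the clinician's level (up with
   `patient_activate_determiner`, down with `patient_dispirit_determiner`).
2. **Knowledge access**: engagement gates the fraction of available
   information an agent can use — unaware 0, aware 0.25·d, participating d,
   contributing min(1, 1.5·d), owning min(1, 2·d), where d is the agent
   kind's `*_engagement_degree_participating` parameter.  The clinician
   retrieves phenotype response information (PRI) from the commons; the
   patient brings their own individual response information (IRI).
   PRI grows by a saturating exponential in the accessible stock:
   g = 1 − exp(−u·S·r·a_c), PRI' = 1 − (1 − PRI)(1 − g), with u the
   per-stock-unit information rate, S the commons stock, r the phenotype
   realization fraction and a_c the clinician access.  IRI gains a fixed
   increment Δ·(1 + a) with a = min(a_max, a_rate·S), capped at 1, and
   decays between encounters with its own half-life.  PRI has no intrinsic
   decay: phenotype knowledge ages only through the commons.
3. **Praxis** — the knowledge actually applied to the decision:
   praxis = w·min(PRI·a_c, c) + (1 − w)·min(IRI·a_p, c), with w = 0.5 by
   default and c the effective pre-visit-planning cap (below).
4. **Perception**: the pair judges whether health improved since the last
   visit.  The misjudgment probability is e₀·(1 − praxis), where e₀ is the
   reversed minimum-evaluation-accuracy parameter; the verdict is the truth
   (Δh > 0; a zero change counts as not improved) flipped with that
   probability.
5. **Treatment decision**: at a first visit a treatment is always chosen;
   otherwise the current treatment is kept iff perceived improving.  A
   switch draws from all treatments excluding the current one, with the
   rank-r candidate of m weighted E^((m−r)/(m−1)) — uniform at E = 1, a
   point mass on the best as E → ∞.  Selection efficiency is
   E = 1 + (E_max − 1)·praxis², a convex praxis response: low levels of
   applied knowledge buy little selection skill (see "Design choices").
6. **Registry record**: automated registries (ER medium/high) log one
   record per encounter.

### Knowledge commons and registry

The commons is a pool of exchangeable items whose usefulness halves every
`shared_knowledge_half_life` steps; the effective stock S(t) is the sum of
per-item decayed weights, maintained incrementally (exactly equal to the
brute-force per-item sum).  Every agent at contributing or above adds an
item each step with its kind's contribution determiner.  Registries at ER
medium/high accumulate encounter records and, every
`enhanced_registry_analysis_period` steps, distill
floor(records / `enhanced_registry_record_per_commons_item`) new items into
the commons.

The **knowledge outcome** of a run is the change in the decayed effective
stock S(final) − S(0): knowledge that has gone out of date no longer counts.
The cumulative items-ever-added counter is tracked separately and is, by
construction, independent of the half-life when engagement is frozen.

### Interventions

*Pre-visit planning* (PVP) is a care-center capability that caps the usable
fraction of PRI and IRI at the encounter: low 0.2, medium 0.5, high 1.0.
*Enhanced registry* (ER) is the center's data pipeline: low — no automated
capture; medium — automated record capture feeding periodic analyses;
high — additionally the data are on screen at the encounter, which (a)
floors the clinician's effective access at the participating-level degree
and (b) lifts the effective PVP cap to the unconstrained level, because
real-time availability of registry data at the encounter *is* pre-visit
planning capability.  (b) is what produces the characteristic jump of
low-PVP/high-ER cells in the factorial experiment.

### Engagement dynamics

Peer influence runs over undirected networks (drawn configuration-model
style with an expected `*_network_edges` per agent; each edge crosses care
centers with probability `*_influence_across_prop`).  Per step, an agent
with at least one strictly more engaged neighbour gets a single Bernoulli
trial to rise one rung (unaware→aware uses the become-aware rate, higher
rungs the activation rate); multiple qualifying neighbours do not stack, so
degree does not mechanically multiply transition rates, and transitions
resolve against the step-start snapshot (no within-step cascades).
Influence probabilities and clinician burnout are quoted per year and
converted by p_step = 1 − (1 − p_annual)^(1/52), so compounding over a year
reproduces the annual probability.  Burnout independently drops each
engaged clinician one rung at the converted per-step rate (a continuous
hazard rather than an annual batch, avoiding synchronization artifacts).

A structural property worth knowing: the population's top engagement rung
can never rise, because every upward transition requires an already more
engaged partner while burnout and dispiriting pull down.  Engagement
therefore has to be *seeded*: by default 5% of patients and 30% of
clinicians start at the owning rung (all others unaware).  Seeding below
the owning rung would permanently lock the contributing/owning rungs out of
reach and silence the commons entirely.

## Parameters

The 30 network-level parameters (Latin-hypercube ranges in
`lhnabm/data/ranges_default.yaml`, defaults = range midpoints):

| group | parameters | default range |
|---|---|---|
| encounter cadence | encounter_period (steps) | [4, 26] |
| encounter engagement | encounter_aware / patient_activate / patient_dispirit determiners | [0,1]; dispirit [0, 0.2] |
| networks | patient/clinician_network_edges; across-center fractions | [0, 10]; [0, 1] |
| peer influence (annual) | become-aware and activation probabilities, both kinds | [0, 1] |
| burnout (annual) | clinician_dispirit_probability | [0, 0.2] |
| commons | shared_knowledge_initial [0, 20]; half-life [4, 260] steps; contribution determiners [0, 1] | |
| registry | initial records/patient [0, 10]; analysis period [4, 26]; records per item [1, 20] | |
| PRI | info rate u [0, 0.002] per stock unit; phenotype realization [0, 1] | |
| IRI | half-life [4, 260]; increment Δ [0, 1]; acceleration rate [0, 0.001]; cap [0, 2] | |
| decision quality | selection_efficiency_maximum [10, 1000]; evaluation_accuracy_minimum_praxis [0.001, 0.5] | |
| access degrees | patient/clinician_engagement_degree_participating | [0, 1] |

The erosion parameters (burnout, dispirit) span [0, 0.2] rather than [0, 1]:
a full-rung drop is an occasional event, not an even-odds one, and wider
spans make engagement erosion swamp every other mechanism.  The two
stock-coupled rates (u and the IRI acceleration) are scaled to the O(10³)
commons stock that per-step contributions produce.  The
evaluation-accuracy axis runs to 0.5 — a completely uninformative verdict —
its natural worst case.

Condition constants (held fixed in the sensitivity analysis) describe a
progressive relapsing condition: 4 phenotypes, 8 treatments with targets
spanning 0.95–0.05, κ = 0.08/step, drift −0.0215/step, relapses of 0.4
health units at 0.004/step, noise SD 0.03/step.  They were calibrated once,
by a coarse grid search, so that the three network-functioning settings
(selection maximum / reversed evaluation accuracy = 10/0.20, 200/0.10,
1000/0.001, all other parameters at midpoints) produce declining, stable,
and improving cohort health respectively; after calibration they were not
revisited.

## Design choices where the design was open

* **Quadratic praxis response of selection efficiency.**  With a linear
  response, the medium (E_max = 200) and high (E_max = 1000) functioning
  settings are indistinguishable at realistic ambient praxis — both sit in
  the near-certain-best-pick regime.  E = 1 + (E_max − 1)·praxis² keeps E
  in its sensitive range and preserves the anchors E(0) = 1, E(1) = E_max.
  The exponent is an argument of `selection_efficiency`.
* **Geometric rank weights** for treatment choice: the simplest
  one-parameter family that is uniform at E = 1 and degenerate as E → ∞.
  Note the best:second odds are E^(1/(m−1)), so "near-certain best" needs
  E ≫ 1000 when m is large.
* **PRI gated by clinician access, IRI by patient access** (rather than a
  common mean): the clinician is the conduit for phenotype-level knowledge,
  the patient for self-knowledge.  This is also what makes the two
  engagement-degree parameters the leading praxis drivers, with the
  clinician degree acting through PRI and the patient degree through IRI.
* **Encounters read the step-start commons snapshot**, making within-step
  encounter order irrelevant; no per-step shuffle is needed for fairness
  and determinism is carried entirely by the seed.
* **Outcome definitions**: health and praxis outcomes are the change from
  baseline of the patient-mean trajectories; knowledge is the change in the
  decayed stock (and can be negative if an initial stock decays faster than
  contributions replace it).  The factorial experiment reports the ensemble
  median of per-run median final health.
* **Cohort exit** (health persistently above 0.95 / below 0.05 for 8
  consecutive steps, plus an optional annual age-out hazard) is implemented
  but inactive in every closed-cohort reference experiment.

## Experiment harnesses and problem sizes

* **Sensitivity**: Latin hypercube sampling (stratified-permuted inverse
  CDF per column; uniform or triangle marginals), 1000 rows by default, one
  seeded run per row (seed = design seed + row), then PRCC per parameter
  and outcome.  PRCC is computed by double residualization on ranks
  (average ranks for ties): rank-transform every column and the outcome,
  regress each on all other columns, and correlate the residuals.
  Degenerate columns yield NaN with a warning, never a silent 0.
  Percentile bootstrap CIs (100 row resamples by default) at a
  Bonferroni-corrected level 1 − 0.05/30.
* **Grid explorer**: two parameters on an evenly spaced grid (41 increments
  → 1,681 cells for the reference plots), all others at range midpoints
  ("midpoint" = (lower+upper)/2 for triangle ranges too), a small shared
  replicate set per cell (default 3, common random numbers across cells).
* **Factorial**: 3×3×3 of network functioning × PVP × ER, 30 replicates
  per cell with shared seeds, two named presets of the
  functioning-level settings: `accurate-eval` (the default), which keeps
  evaluation accuracy near-perfect at every functioning level, and
  `graded-eval`, which degrades evaluation accuracy as functioning drops
  (the parameterization the anchor regimes use).

The default cohort is 4 centers × 5 clinicians × 10 patients = 200
patients; a five-year run takes ~0.1 s, so the full 1000-row sensitivity
completes in a few minutes on one core.  The test suite exercises reduced
cohorts (20–50 patients) for unit-level checks and the full default scale
for the reproduction tests.

## What the synthetic conditions do and do not capture

The generator emulates: engagement contagion from a seeded core, a commons
that must be actively replenished, engagement-gated information flows, and
treatment matching under imperfect perception.  It does not emulate:
patient demographics or payor mix, condition heterogeneity beyond the
phenotype→target structure, content or quality differences between
knowledge items, assortative or scale-free network topology, open-cohort
enrollment growth, or any empirically calibrated parameter values.  Passing
reproduction tests therefore demonstrates internal consistency of the
mechanisms at the declared study conditions, not predictive validity for
any real network.

## Known limitations

* The keep-if-improving rule is itself a powerful bandit-style learning
  mechanism: even a zero-skill network retains treatments that happen to
  work, which lifts the low-functioning regime; conversely, near steady
  state health changes are noise-dominated, so even perfect evaluators
  churn off the best treatment.  Together these bound the achievable spread
  between the worst and best functioning regimes at roughly 0.14 health
  units under these mechanics — the improving-regime benchmark of +0.15 is
  reproduced in sign and ordering but not in magnitude (≈ +0.06–0.08), and
  the low-functioning slab of the factorial shows a residual intervention
  effect (≈ 0.11) rather than complete flatness.
* The praxis→health chain carries the praxis drivers (engagement degrees,
  clinician-side contagion) into the health sensitivity ranking alongside
  the decision-quality maxima.
* PRCC assumes monotone parameter–outcome relationships; it is reported
  as-is for all 30 parameters without monotonicity screening.
* Bootstrap percentile CIs slightly undercover at small designs (n ≲ 150).
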