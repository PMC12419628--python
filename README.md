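# lhnabm

Agent-based simulation of collaborative **learning health networks** (LHNs)
— healthcare delivery networks in which patients and clinicians coproduce
the knowledge used in treatment decisions through a shared, decaying
knowledge commons.  The package is aimed at health-systems researchers and
network leaders who want to reason quantitatively about which levers
(engagement, knowledge sharing, pre-visit planning, registries) matter for
population health, and at modelers who want a fast, fully seeded ABM with
its analysis harnesses included.

## The model in brief

A closed cohort of patients, each assigned to a clinician within a care
center, is simulated in weekly steps over five years.  Patient health
h ∈ [0, 1] follows a bounded pull toward the current treatment's target:

    h' = clip( h + κ(T − h) + δ + N(0, σ²) − 1{relapse}·M , 0, 1 )

where the target T depends on how well the treatment matches the patient's
phenotype.  At each scheduled encounter the patient–clinician pair judges
whether health improved since the last visit (misjudging with probability
e₀(1 − praxis)), keeps a treatment perceived to be working, and otherwise
switches: the rank-r of m candidate treatments is chosen with weight
E^((m−r)/(m−1)), where the selection efficiency E = 1 + (E_max − 1)·praxis²
rises with praxis — the knowledge actually applied to the decision.

Praxis combines two engagement-gated information stocks: phenotype response
information, retrieved by the clinician from the commons, and the patient's
individual response information, accrued at encounters and decaying between
them.  The commons is replenished each step by agents engaged enough to
contribute and drained by exponential decay (knowledge goes out of date);
engagement itself spreads by contagion over influence networks and through
encounters, and erodes through clinician burnout.  Two care-center
interventions modulate the flows: pre-visit planning (PVP) caps the usable
fraction of both stocks (low 0.2 / medium 0.5 / high 1.0) and an enhanced
registry (ER) captures encounter records, distills them into commons items,
and — at its highest level — puts registry data on screen at the encounter,
substituting for PVP.

Three experiment harnesses ship with the model:

* **`run_sensitivity`** — Latin hypercube sampling over the 30 network
  parameters with partial rank correlation coefficients (PRCC, via double
  residualization on ranks) and Bonferroni-corrected bootstrap CIs;
* **`grid_explore`** — two-parameter solution-space grids (41 × 41 = 1,681
  cells in the reference layout), all other parameters at range midpoints;
* **`factorial_experiment`** — a 3×3×3 factorial of network functioning ×
  PVP × ER with paired-seed replicate ensembles.

See `docs/methods.md` for the full model description, parameter tables,
and design rationale.

## Worked example

Run the packaged default scenario (4 care centers × 5 clinicians × 10
patients, five years, all 30 parameters at their range midpoints):

```
$ lhn run --seed 42 --out demo_run
run start: seed=42 horizon=260 patients=200
run done: health=+0.0619 praxis=+0.7190 knowledge=+8694.0 -> demo_run
```

`health=+0.0619` is the cumulative average change in health status: mean
patient health rose by about 0.06 (on the 0–1 health scale) from baseline
over five years.  `praxis=+0.7190` says the knowledge applied at encounters
climbed from zero to a high level as engagement spread and the commons
filled; `knowledge=+8694.0` is the net growth of the decayed effective
commons stock (items contributed minus knowledge gone stale).

`demo_run/` contains `timeseries.csv` (one row per step: mean/median
health, mean praxis, commons stock, engagement-level counts),
`outcomes.json`, and a `manifest.json` with the scenario echo, seed, and
file checksums:

```json
{
  "health": 0.061878901672946185,
  "praxis": 0.7190261776397839,
  "knowledge": 8693.978114732816,
  "median_final_health": 0.5795740507530383
}
```

Every run is a deterministic function of (scenario, seed): the same
command produces byte-identical CSVs.  Scenario YAML files override any
subset of the packaged defaults (`lhnabm/data/defaults.yaml`); unknown keys
are rejected.  The other subcommands are `lhn ensemble`, `lhn sensitivity`,
`lhn grid`, `lhn factorial`, and `lhn fixtures`.

From Python:

```python
import lhnabm as L

scenario = L.default_scenario().replace(seed=42)
metrics = L.simulate(scenario)
print(L.compute_outcomes(metrics))

sens = L.run_sensitivity(L.default_ranges(), n_samples=200,
                         template=scenario, seed=0)
print(sens.prcc["health"].to_frame().sort_values("coefficient"))
```

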