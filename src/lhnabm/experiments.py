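"""The three experiment harnesses: LHS–PRCC sensitivity, grid exploration,
and the 3×3×3 factorial intervention experiment.

The sensitivity analysis draws a Latin hypercube sample over the 30 model
parameters, runs one seeded simulation per row, and summarizes each
parameter's influence on each outcome with a partial rank correlation
coefficient (PRCC): the correlation between the rank-transformed parameter
and outcome after removing, by linear regression on ranks, the effect of all
other parameters.  Confidence intervals come from a row bootstrap with a
Bonferroni-corrected level.

The grid explorer sweeps two parameters over an evenly spaced grid with all
others at their range midpoints; the factorial harness crosses pre-visit
planning and enhanced-registry levels with three network-functioning
presets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .engine import compute_outcomes, simulate
from .params import ModelParams, ParamRange, ScenarioConfig, _INT_FIELDS, midpoint_params

__all__ = [
    "LHSDesign",
    "PRCCResult",
    "SensitivityResult",
    "GridResult",
    "FactorialResult",
    "LHN_PRESETS",
    "lhs_sample",
    "prcc",
    "prcc_bootstrap_ci",
    "run_sensitivity",
    "grid_explore",
    "factorial_experiment",
]

OUTCOME_NAMES = ("health", "praxis", "knowledge")

# Network-functioning presets for the factorial experiment:
# (selection_efficiency_maximum, evaluation_accuracy_minimum_praxis) per level.
LHN_PRESETS = {
    "accurate-eval": {"low": (10.0, 0.001), "medium": (100.0, 0.01), "high": (1000.0, 0.01)},
    "graded-eval": {"low": (10.0, 0.20), "medium": (200.0, 0.10), "high": (1000.0, 0.001)},
}


# ---------------------------------------------------------------------------
# Latin hypercube sampling


@dataclass
class LHSDesign:
    """A stratified-permuted sample: one draw per equal-probability stratum."""

    values: pd.DataFrame          # n_samples x n_params
    ranges: list                  # per-column ParamRange provenance
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.values)


def lhs_sample(ranges: Sequence[ParamRange], n: int, seed: int) -> LHSDesign:
    """Latin hypercube sample of ``n`` rows over the given ranges.

    Column j takes values F_j^{-1}((pi_j(i) - u_ij)/n): a seeded permutation
    of the n strata, jittered uniformly within each stratum, pushed through
    the column's (uniform or triangle) inverse CDF.
    """
    if n < 2:
        raise ValueError("need n >= 2 LHS samples")
    rng = np.random.default_rng(seed)
    cols = {}
    for r in ranges:
        perm = rng.permutation(n) + 1            # strata 1..n
        u = rng.random(n)
        q = (perm - u) / n
        cols[r.name] = r.ppf(q)
    return LHSDesign(values=pd.DataFrame(cols), ranges=list(ranges), seed=seed)


# ---------------------------------------------------------------------------
# Partial rank correlation


def _residuals(design: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each target column on the design (with intercept)."""
    a = np.column_stack([np.ones(len(design)), design])
    coef, *_ = np.linalg.lstsq(a, targets, rcond=None)
    return targets - a @ coef


def prcc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial rank correlation of each column of ``x`` with ``y``.

    Every column and the outcome are rank-transformed (average ranks for
    ties); for parameter j the coefficient is the Pearson correlation between
    the residuals of rank(x_j) and of rank(y), each regressed on the ranks of
    all the other parameters.  Degenerate columns or singular regressions
    yield NaN with a warning rather than a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if len(y) != n:
        raise ValueError("x and y disagree on the number of rows")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for {p} parameters, got {n}")
    rx = rankdata(x, axis=0)
    ry = rankdata(y)
    out = np.full(p, np.nan)
    if ry.std() == 0:
        warnings.warn("outcome is constant; all PRCCs undefined", stacklevel=2)
        return out
    for j in range(p):
        if rx[:, j].std() == 0:
            warnings.warn(f"column {j} is constant; PRCC undefined", stacklevel=2)
            continue
        others = np.delete(rx, j, axis=1)
        res = _residuals(others, np.column_stack([rx[:, j], ry]))
        sx, sy = res[:, 0].std(), res[:, 1].std()
        if sx == 0 or sy == 0:
            warnings.warn(f"residual regression singular for column {j}", stacklevel=2)
            continue
        out[j] = float(np.dot(res[:, 0] - res[:, 0].mean(),
                              res[:, 1] - res[:, 1].mean()) / (n * sx * sy))
    return np.clip(out, -1.0, 1.0)


@dataclass
class PRCCResult:
    """Coefficients with bootstrap CIs for one outcome."""

    outcome: str
    parameters: list
    coefficients: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_boot: int
    alpha: float                 # after Bonferroni correction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameters, "outcome": self.outcome,
            "coefficient": self.coefficients,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
        })

    def top(self, k: int = 2) -> list:
        order = np.argsort(-np.abs(np.nan_to_num(self.coefficients)))
        return [self.parameters[i] for i in order[:k]]


def prcc_bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 100,
    family_size: Optional[int] = None,
    base_alpha: float = 0.05,
    seed: int = 0,
    outcome: str = "outcome",
    parameters: Optional[Sequence[str]] = None,
    max_redraws: int = 50,
) -> PRCCResult:
    """Row-bootstrap percentile CIs at a Bonferroni-corrected level.

    Replicates whose resample degenerates (a constant column) are redrawn up
    to ``max_redraws`` times each.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    family = family_size if family_size is not None else p
    alpha = base_alpha / family
    point = prcc(x, y)
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, p), np.nan)
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            xb, yb = x[idx], y[idx]
            if yb.std() == 0 or np.any(xb.std(axis=0) == 0):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                boots[b] = prcc(xb, yb)
            break
    lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0)
    # percentile intervals are widened, if necessary, to contain the point estimate
    lo = np.fmin(lo, point)
    hi = np.fmax(hi, point)
    names = list(parameters) if parameters is not None else [f"x{j}" for j in range(p)]
    return PRCCResult(outcome=outcome, parameters=names, coefficients=point,
                      ci_lo=lo, ci_hi=hi, n_boot=n_boot, alpha=alpha)


# ---------------------------------------------------------------------------
# Sensitivity experiment


@dataclass
class SensitivityResult:
    design: pd.DataFrame                  # LHS values + outcome columns + seed
    prcc: dict                            # outcome name -> PRCCResult
    n_failed: int = 0

    def prcc_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.prcc.values()], ignore_index=True)


def _params_from_row(row: pd.Series) -> ModelParams:
    kw = {}
    for name, v in row.items():
        kw[name] = int(round(v)) if name in _INT_FIELDS else float(v)
    return ModelParams(**kw)


def run_sensitivity(
    ranges: Sequence[ParamRange],
    n_samples: int = 1000,
    template: Optional[ScenarioConfig] = None,
    seed: int = 0,
    n_boot: int = 100,
) -> SensitivityResult:
    """LHS design, one seeded run per row, PRCC + CIs per outcome."""
    template = template if template is not None else ScenarioConfig()
    design = lhs_sample(ranges, n_samples, seed)
    values = design.values
    names = list(values.columns)
    outs = {name: np.full(n_samples, np.nan) for name in OUTCOME_NAMES}
    ok = np.ones(n_samples, dtype=bool)
    for i in range(n_samples):
        try:
            params = _params_from_row(values.iloc[i])
            scenario = template.replace(params=params, seed=seed + i + 1)
            oc = compute_outcomes(simulate(scenario))
        except Exception as exc:  # noqa: BLE001 — a failed row is flagged, not fatal
            warnings.warn(f"simulation failed on design row {i}: {exc}", stacklevel=2)
            ok[i] = False
            continue
        for name in OUTCOME_NAMES:
            outs[name][i] = getattr(oc, name)
    table = values.copy()
    for name in OUTCOME_NAMES:
        table[name] = outs[name]
    table["row_seed"] = seed + 1 + np.arange(n_samples)
    table["ok"] = ok

    x = values.to_numpy()[ok]
    results = {}
    for name in OUTCOME_NAMES:
        results[name] = prcc_bootstrap_ci(
            x, outs[name][ok], n_boot=n_boot, family_size=len(names),
            seed=seed + 10_000, outcome=name, parameters=names)
    return SensitivityResult(design=table, prcc=results, n_failed=int((~ok).sum()))


# ---------------------------------------------------------------------------
# Grid exploration


@dataclass
class GridResult:
    x_param: str
    y_param: str
    x_values: np.ndarray
    y_values: np.ndarray
    outcome: str
    mean: np.ndarray             # (len(y_values), len(x_values))
    sd: np.ndarray
    n_replicates: int
    midpoints: ModelParams = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for iy, yv in enumerate(self.y_values):
            for ix, xv in enumerate(self.x_values):
                recs.append({self.x_param: xv, self.y_param: yv,
                             "mean": self.mean[iy, ix], "sd": self.sd[iy, ix],
                             "n": self.n_replicates})
        return pd.DataFrame(recs)


def grid_explore(
    x_param: str,
    y_param: str,
    ranges: Sequence[ParamRange],
    n_increments: int = 41,
    outcome: str = "health",
    template: Optional[ScenarioConfig] = None,
    seed: int = 0,
    replicates_per_cell: int = 3,
) -> GridResult:
    """Sweep two parameters over an even grid, all others at range midpoints.

    Cell (ix, iy) is the mean outcome over ``replicates_per_cell`` seeded
    runs; replicate seeds are shared across cells (common random numbers) so
    that between-cell contrasts are paired.
    """
    if x_param == y_param:
        raise ValueError("x and y must be different parameters")
    if outcome not in OUTCOME_NAMES + ("median_final_health",):
        raise ValueError(f"unknown outcome {outcome!r}")
    by_name = {r.name: r for r in ranges}
    for name in (x_param, y_param):
        if name not in by_name:
            raise ValueError(f"no range for parameter {name!r}")
    template = template if template is not None else ScenarioConfig()
    mid = midpoint_params(ranges)
    xr, yr = by_name[x_param], by_name[y_param]
    xs = np.linspace(xr.lower, xr.upper, n_increments)
    ys = np.linspace(yr.lower, yr.upper, n_increments)
    mean = np.empty((n_increments, n_increments))
    sd = np.empty_like(mean)
    for iy, yv in enumerate(ys):
        for ix, xv in enumerate(xs):
            kw = {x_param: int(round(xv)) if x_param in _INT_FIELDS else float(xv),
                  y_param: int(round(yv)) if y_param in _INT_FIELDS else float(yv)}
            params = mid.replace(**kw)
            vals = []
            for r in range(replicates_per_cell):
                scenario = template.replace(params=params, seed=seed + r)
                oc = compute_outcomes(simulate(scenario))
                vals.append(getattr(oc, outcome))
            mean[iy, ix] = float(np.mean(vals))
            sd[iy, ix] = float(np.std(vals, ddof=1)) if replicates_per_cell > 1 else 0.0
    return GridResult(x_param=x_param, y_param=y_param, x_values=xs, y_values=ys,
                      outcome=outcome, mean=mean, sd=sd,
                      n_replicates=replicates_per_cell, midpoints=mid)


# ---------------------------------------------------------------------------
# Factorial intervention experiment


@dataclass
class FactorialResult:
    table: pd.DataFrame          # 27 rows: lhn, pvp, er, median_health, sd, n
    preset: str

    def cell(self, lhn: str, pvp: str, er: str) -> pd.Series:
        t = self.table
        m = t[(t.lhn == lhn) & (t.pvp == pvp) & (t.er == er)]
        return m.iloc[0]


def factorial_experiment(
    template: Optional[ScenarioConfig] = None,
    preset: str = "accurate-eval",
    levels: Optional[dict] = None,
    n_replicates: int = 30,
    seed: int = 0,
) -> FactorialResult:
    """3×3×3 factorial of network functioning × PVP × ER.

    Each cell runs ``n_replicates`` seeded five-year simulations (replicate
    seeds shared across cells, so contrasts are paired) and reports the
    ensemble median of the per-run median final health, with the ensemble SD.
    """
    template = template if template is not None else ScenarioConfig()
    lhn_levels = levels if levels is not None else LHN_PRESETS.get(preset)
    if lhn_levels is None:
        raise ValueError(f"unknown preset {preset!r}; expected one of {list(LHN_PRESETS)}")
    for lv in ("low", "medium", "high"):
        if lv not in lhn_levels:
            raise ValueError(f"missing network-functioning level {lv!r}")
    recs = []
    for lhn, pvp, er in itertools.product(("low", "medium", "high"), repeat=3):
        sel, e0 = lhn_levels[lhn]
        params = template.params.replace(
            selection_efficiency_maximum=float(sel),
            evaluation_accuracy_minimum_praxis=float(e0))
        scenario = template.replace(params=params, pvp_level=pvp, er_level=er)
        vals = []
        for r in range(n_replicates):
            oc = compute_outcomes(simulate(scenario.replace(seed=seed + r)))
            vals.append(oc.median_final_health)
        recs.append({"lhn": lhn, "pvp": pvp, "er": er,
                     "median_health": float(np.median(vals)),
                     "mean_health": float(np.mean(vals)),
                     "sd": float(np.std(vals, ddof=1)) if n_replicates > 1 else 0.0,
                     "n": n_replicates})
    return FactorialResult(table=pd.DataFrame(recs), preset=preset)
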