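"""Two-layer Monte Carlo scenario engine.

Layer 1 (scenario generation) perturbs the case-mix of the conditioned
digital-twin cohort by stratified resampling: rows are drawn with
replacement *within* strata of the perturbed variable, so the target
marginal is hit while all within-stratum joint structure is preserved.
Five scenarios are supported:

* ``baseline`` — straight resampling of the conditioned cohort;
* ``doac70`` — treatment marginal forced to 70% DOAC / 30% VKA;
* ``cancer_plus50`` — active-cancer prevalence raised by 50% relative;
* ``cvt40`` — cerebral venous thrombosis raised to 40% of all cases;
* ``ttr100`` — every VKA record reassigned to the perfect-control stratum
  (a deterministic TTR edit, not resampling).

Layer 2 (outcome simulation) scores each resampled profile with the
fitted logistic models and draws the simulated outcome from a Bernoulli
with that probability; per-arm event rates are averaged within each
iteration.  Each scenario runs R independent iterations (default 500),
each with a fresh case-mix and fresh outcome draws under a deterministic
seed ladder (master seed → scenario → iteration).  Aggregates are mean
rates with empirical percentile 95% CIs, Monte Carlo standard errors
(MCSE, absolute and relative), coefficients of variation, convergence
flags (MCSE < 5%, CV < 10%) and directionality-preservation fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from usvtwin.cohort import Cohort

__all__ = [
    "SCENARIO_IDS",
    "ScenarioSpec",
    "SimulationResult",
    "build_scenario_casemix",
    "simulate_iteration",
    "run_simulation",
    "directionality",
    "sensitivity_suite",
    "default_scenarios",
]

SCENARIO_IDS = ("baseline", "doac70", "cancer_plus50", "cvt40", "ttr100")
ARMS = ("VKA", "DOAC")


class ScenarioInfeasibleError(ValueError):
    """A perturbation requires a stratum that is empty in the twin cohort."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One what-if scenario for the Monte Carlo engine."""

    id: str
    resample_size: int = 4000  # per-iteration case-mix size M
    iterations: int = 500  # R
    doac_share: float = 0.70
    cancer_multiplier: float = 1.5
    cvt_share: float = 0.40
    scheme: str = "stratified"  # or "weighted" (sensitivity alternative)

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario {self.id!r}; expected one of {SCENARIO_IDS}")
        if self.iterations < 1 or self.resample_size < 1:
            raise ValueError("iterations and resample_size must be >= 1")
        if self.scheme not in ("stratified", "weighted"):
            raise ValueError(f"unknown resampling scheme {self.scheme!r}")


def default_scenarios(
    resample_size: int = 4000, iterations: int = 500
) -> list[ScenarioSpec]:
    return [
        ScenarioSpec(i, resample_size=resample_size, iterations=iterations)
        for i in SCENARIO_IDS
    ]


def _strata_for(spec: ScenarioSpec, df: pd.DataFrame):
    """(stratum masks, target shares) for the perturbed variable."""
    if spec.id == "doac70":
        masks = {"DOAC": df["treatment"] == "DOAC", "VKA": df["treatment"] == "VKA"}
        shares = {"DOAC": spec.doac_share, "VKA": 1.0 - spec.doac_share}
    elif spec.id == "cancer_plus50":
        prev = float(df["active_cancer"].mean())
        target = min(1.0, spec.cancer_multiplier * prev)
        masks = {"cancer": df["active_cancer"] == 1, "no_cancer": df["active_cancer"] == 0}
        shares = {"cancer": target, "no_cancer": 1.0 - target}
    elif spec.id == "cvt40":
        masks = {"CVT": df["usvt_site"] == "CVT", "non_CVT": df["usvt_site"] != "CVT"}
        shares = {"CVT": spec.cvt_share, "non_CVT": 1.0 - spec.cvt_share}
    else:
        return None, None
    return masks, shares


def build_scenario_casemix(
    dt_cohort: Cohort | pd.DataFrame,
    spec: ScenarioSpec,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Layer 1: one resampled case-mix of size ``spec.resample_size``.

    Stratified scheme: exact stratum counts at the target shares, rows
    drawn with replacement within stratum.  Weighted scheme (sensitivity
    alternative): a single weighted draw over all rows with weights chosen
    so the target marginal is hit in expectation.
    """
    df = (dt_cohort.df if isinstance(dt_cohort, Cohort) else dt_cohort).reset_index(drop=True)
    if len(df) == 0:
        raise ScenarioInfeasibleError("empty twin cohort")
    rng = np.random.default_rng(seed)
    m = spec.resample_size
    masks, shares = _strata_for(spec, df)
    if masks is None:  # baseline and ttr100 keep the empirical case-mix
        out = df.iloc[rng.integers(0, len(df), m)].reset_index(drop=True)
    else:
        for name, mask in masks.items():
            if shares[name] > 0 and not mask.any():
                raise ScenarioInfeasibleError(
                    f"scenario {spec.id!r} requires rows in empty stratum {name!r}"
                )
        if spec.scheme == "stratified":
            parts = []
            names = list(masks)
            counts = [int(round(shares[n] * m)) for n in names]
            counts[-1] = m - sum(counts[:-1])
            for name, count in zip(names, counts):
                idx = np.flatnonzero(masks[name])
                if count > 0:
                    parts.append(df.iloc[idx[rng.integers(0, len(idx), count)]])
            out = pd.concat(parts, ignore_index=True)
        else:
            weights = np.zeros(len(df))
            for name, mask in masks.items():
                p_emp = mask.mean()
                if p_emp > 0:
                    weights[mask.to_numpy()] = shares[name] / p_emp
            weights = weights / weights.sum()
            out = df.iloc[rng.choice(len(df), m, replace=True, p=weights)].reset_index(
                drop=True
            )
    if spec.id == "ttr100":
        vka = (out["treatment"] == "VKA").to_numpy()
        ttr = out["ttr"].to_numpy(dtype=float)
        ttr[vka] = 100.0
        out = out.copy()
        out["ttr"] = ttr
    return out


def simulate_iteration(
    casemix: pd.DataFrame,
    models: Mapping[str, object],
    seed: int | np.random.SeedSequence | None = None,
) -> dict[str, dict[str, float]]:
    """Layer 2: Bernoulli outcome draws and per-arm rates for one iteration.

    Returns ``{endpoint: {arm: rate}}``; an arm absent from the case-mix
    yields NaN for that arm.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    arm_masks = {arm: (casemix["treatment"] == arm).to_numpy() for arm in ARMS}
    result: dict[str, dict[str, float]] = {}
    for endpoint, model in models.items():
        p = np.asarray(model.predict_risk(casemix), dtype=float)
        draws = (rng.random(len(casemix)) < p).astype(float)
        result[endpoint] = {
            arm: float(draws[mask].mean()) if mask.any() else float("nan")
            for arm, mask in arm_masks.items()
        }
    return result


@dataclass
class SimulationResult:
    """Aggregated Monte Carlo output plus the iteration-level trace."""

    summary: pd.DataFrame  # scenario × endpoint × arm rows
    iteration_rates: dict[str, np.ndarray]  # scenario -> (R, n_endpoints, 2) fractions
    endpoints: tuple[str, ...]
    scenarios: tuple[str, ...]
    master_seed: int

    def scenario_table(self, scenario: str) -> pd.DataFrame:
        return self.summary[self.summary["scenario"] == scenario]

    @property
    def all_converged(self) -> bool:
        return bool((self.summary["mcse_ok"] & self.summary["cv_ok"]).all())


def _iteration_seed(master: int, scen_idx: int, iteration: int) -> np.random.SeedSequence:
    # documented seed ladder: master -> scenario -> iteration
    return np.random.SeedSequence([master, scen_idx, iteration])


def run_simulation(
    dt_cohort: Cohort | pd.DataFrame,
    models: Mapping[str, object],
    specs: Sequence[ScenarioSpec],
    master_seed: int = 0,
) -> SimulationResult:
    """Run every scenario: R iterations each, fresh case-mix and outcome
    draws per iteration, deterministic under ``master_seed``."""
    endpoints = tuple(models)
    rows = []
    traces: dict[str, np.ndarray] = {}
    for scen_idx, spec in enumerate(specs):
        r = spec.iterations
        rates = np.full((r, len(endpoints), 2), np.nan)
        for it in range(r):
            ss = _iteration_seed(master_seed, scen_idx, it)
            child_mix, child_draw = ss.spawn(2)
            casemix = build_scenario_casemix(dt_cohort, spec, child_mix)
            result = simulate_iteration(casemix, models, child_draw)
            for e_idx, endpoint in enumerate(endpoints):
                for a_idx, arm in enumerate(ARMS):
                    rates[it, e_idx, a_idx] = result[endpoint][arm]
        traces[spec.id] = rates
        for e_idx, endpoint in enumerate(endpoints):
            for a_idx, arm in enumerate(ARMS):
                vals = rates[:, e_idx, a_idx] * 100.0
                ok = np.isfinite(vals)
                vals = vals[ok]
                mean = float(vals.mean()) if len(vals) else float("nan")
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                lo, hi = (
                    (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
                    if len(vals)
                    else (float("nan"), float("nan"))
                )
                mcse_abs = sd / np.sqrt(max(len(vals), 1))
                mcse_pct = 100.0 * mcse_abs / mean if mean else float("inf")
                cv_pct = 100.0 * sd / mean if mean else float("inf")
                rows.append(
                    {
                        "scenario": spec.id,
                        "endpoint": endpoint,
                        "arm": arm,
                        "mean": mean,
                        "ci_lo": lo,
                        "ci_hi": hi,
                        "sd": sd,
                        "mcse_abs": mcse_abs,
                        "mcse_pct": mcse_pct,
                        "cv_pct": cv_pct,
                        "mcse_ok": mcse_pct < 5.0,
                        "cv_ok": cv_pct < 10.0,
                        "n_iterations": int(len(vals)),
                    }
                )
    return SimulationResult(
        summary=pd.DataFrame(rows),
        iteration_rates=traces,
        endpoints=endpoints,
        scenarios=tuple(s.id for s in specs),
        master_seed=master_seed,
    )


def directionality(
    result: SimulationResult,
    reference_signs: Mapping[str, int],
    scenario: str = "baseline",
) -> dict[str, float]:
    """Fraction of iterations whose DOAC−VKA difference keeps the reference
    sign, per endpoint plus a pooled entry.  Exact zero differences count
    as non-preserving (conservative)."""
    rates = result.iteration_rates[scenario]
    out: dict[str, float] = {}
    total_hits = 0
    total_n = 0
    for e_idx, endpoint in enumerate(result.endpoints):
        diff = rates[:, e_idx, 1] - rates[:, e_idx, 0]  # DOAC − VKA
        ok = np.isfinite(diff)
        signs = np.sign(diff[ok])
        hits = int(np.sum(signs == np.sign(reference_signs[endpoint])))
        out[endpoint] = hits / max(len(signs), 1)
        total_hits += hits
        total_n += len(signs)
    out["pooled"] = total_hits / max(total_n, 1)
    return out


def sensitivity_suite(
    dt_cohort: Cohort | pd.DataFrame,
    models: Mapping[str, object],
    spec: ScenarioSpec,
    r_values: Sequence[int] = (100, 250, 500, 1000),
    master_seed: int = 0,
) -> pd.DataFrame:
    """Robustness checks: rerun one scenario at several iteration counts and
    under the alternative (weighted) resampling scheme; report the maximum
    absolute deviation of mean rates from the reference configuration."""
    reference = run_simulation(dt_cohort, models, [spec], master_seed)
    ref_means = reference.summary.set_index(["endpoint", "arm"])["mean"]
    rows = []
    variants: list[tuple[str, ScenarioSpec, int]] = [
        (f"R={r}", replace(spec, iterations=r), master_seed + 1 + i)
        for i, r in enumerate(r_values)
    ]
    variants.append(("weighted", replace(spec, scheme="weighted"), master_seed + 101))
    for label, variant, seed in variants:
        res = run_simulation(dt_cohort, models, [variant], seed)
        means = res.summary.set_index(["endpoint", "arm"])["mean"]
        dev = (means - ref_means).abs()
        mcse = res.summary.set_index(["endpoint", "arm"])["mcse_abs"]
        ref_mcse = reference.summary.set_index(["endpoint", "arm"])["mcse_abs"]
        combined = np.sqrt(mcse**2 + ref_mcse**2)
        rows.append(
            {
                "variant": label,
                "iterations": variant.iterations,
                "scheme": variant.scheme,
                "max_abs_deviation": float(dev.max()),
                "max_deviation_in_mcse_units": float((dev / combined).max()),
            }
        )
    return pd.DataFrame(rows)
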