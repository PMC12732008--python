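"""End-to-end orchestration: source → twins → fidelity → conditioning →
outcome models → Monte Carlo, from a single config with one master seed.

Every random draw is attributable to a seed recorded in the manifest
(master seed plus fixed per-stage offsets), so re-running from the
manifest reproduces all artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from usvtwin import fidelity as fid
from usvtwin import gan, matching, mc, models as om
from usvtwin.gan import DAGSpec, GANConfig, default_dag
from usvtwin.cohort import Cohort, render_summary_text, summarize_cohort, write_cohort
from usvtwin.source import SourceConfig, sample_cohort

logger = logging.getLogger("usvtwin")

__all__ = ["PipelineConfig", "run_pipeline", "render_simulation_table", "reference_signs"]

# fixed per-stage seed offsets from the master seed (recorded in the manifest)
STAGE_OFFSETS = {
    "source": 0,
    "gan": 1_000,
    "matching": 2_000,
    "bootstrap": 3_000,
    "mc": 4_000,
    "fidelity": 5_000,
}


@dataclass
class PipelineConfig:
    source: SourceConfig = field(default_factory=SourceConfig)
    gan: GANConfig = field(default_factory=GANConfig)
    dag: DAGSpec = field(default_factory=default_dag)
    n_replicas: int = 10
    caliper: float = 0.2
    predictors: tuple[str, ...] = om.DEFAULT_PREDICTORS
    site_ridge: float = 1.0
    ttr_threshold: float = 70.0
    n_boot: int = 1000
    resample_size: int = 4000
    iterations: int = 500
    scenarios: tuple[str, ...] = mc.SCENARIO_IDS
    output_dir: str = "usvtwin-output"
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        if "source" in kwargs:
            kwargs["source"] = SourceConfig(**kwargs["source"])
        if "gan" in kwargs:
            kwargs["gan"] = GANConfig(**kwargs["gan"])
        if "dag" in kwargs:
            d = kwargs["dag"]
            kwargs["dag"] = DAGSpec(
                tuple(d["nodes"]),
                tuple((p, c) for p, c in d["edges"]),
                tuple(d["terminal_outcomes"]),
            )
        for key in ("predictors", "scenarios"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def reference_signs(source: Cohort) -> dict[str, int]:
    """Observed DOAC−VKA direction of each endpoint in the source cohort."""
    df = source.df
    signs = {}
    for endpoint in om.ENDPOINTS:
        observed, y = om.endpoint_values(df, endpoint)
        rates = {
            arm: y[observed & (df["treatment"] == arm).to_numpy()].mean()
            for arm in ("VKA", "DOAC")
        }
        signs[endpoint] = int(np.sign(rates["DOAC"] - rates["VKA"])) or 1
    return signs


def render_simulation_table(result: mc.SimulationResult) -> pd.DataFrame:
    """Scenario × outcome table: per-arm mean rates with empirical 95% CIs
    and the DOAC − VKA difference in percentage points."""
    rows = []
    for scenario in result.scenarios:
        sub = result.scenario_table(scenario)
        for endpoint in result.endpoints:
            e = sub[sub["endpoint"] == endpoint].set_index("arm")
            vka, doac = e.loc["VKA"], e.loc["DOAC"]
            rows.append(
                {
                    "scenario": scenario,
                    "outcome": endpoint,
                    "vka_mean": vka["mean"],
                    "vka_ci_lo": vka["ci_lo"],
                    "vka_ci_hi": vka["ci_hi"],
                    "doac_mean": doac["mean"],
                    "doac_ci_lo": doac["ci_lo"],
                    "doac_ci_hi": doac["ci_hi"],
                    "difference_pp": doac["mean"] - vka["mean"],
                }
            )
    return pd.DataFrame(rows)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return decorator


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run the full workflow and write all artifacts under
    ``config.output_dir``.  Returns the in-memory artifact bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = config.master_seed
    bundle: dict[str, object] = {}

    @_stage("source")
    def stage_source():
        cohort = sample_cohort(config.source, seed=master + STAGE_OFFSETS["source"])
        write_cohort(cohort, out / "source_cohort.csv")
        summary = summarize_cohort(cohort)
        summary.to_csv(out / "baseline_summary.csv", index=False)
        (out / "baseline_summary.txt").write_text(render_summary_text(summary) + "\n")
        return cohort

    source = stage_source()
    bundle["source"] = source

    @_stage("twins")
    def stage_twins():
        replicas = gan.replicate_twins(
            source,
            config.dag,
            config.gan,
            n_replicas=config.n_replicas,
            seed_base=master + STAGE_OFFSETS["gan"],
        )
        reports = []
        for i, twin in enumerate(replicas):
            write_cohort(twin, out / f"twin_replica_{i}.csv")
            reports.append(
                fid.fidelity_report(source, twin, seed=master + STAGE_OFFSETS["fidelity"] + i)
            )
        per_replica = pd.DataFrame(
            {
                "replica": range(len(replicas)),
                "masmd": [r.masmd[0] for r in reports],
                "masmd_sd": [r.masmd[1] for r in reports],
                "mmd2": [r.mmd2 for r in reports],
                "mmd_p": [r.mmd_pvalue for r in reports],
                "corr_similarity": [r.corr_similarity for r in reports],
                "acceptable": [r.acceptable for r in reports],
            }
        )
        per_replica.to_csv(out / "fidelity_replicas.csv", index=False)
        reports[0].to_frame().to_csv(out / "fidelity_variables.csv", index=False)
        return replicas, reports

    replicas, reports = stage_twins()
    bundle["twins"] = replicas
    bundle["fidelity"] = reports

    @_stage("conditioning")
    def stage_condition():
        conditioned, matched, prop = matching.condition_cohort(
            replicas[0], caliper=config.caliper, seed=master + STAGE_OFFSETS["matching"]
        )
        write_cohort(conditioned, out / "conditioned_cohort.csv")
        if len(matched.balance):
            matched.balance.to_csv(out / "balance_table.csv", index=False)
        pd.DataFrame(matched.pairs, columns=["doac_row", "vka_row"]).to_csv(
            out / "matched_pairs.csv", index=False
        )
        return conditioned, matched, prop

    conditioned, matched, prop = stage_condition()
    bundle["conditioned"] = conditioned
    bundle["matched"] = matched

    @_stage("models")
    def stage_models():
        fitted = {}
        rows = []
        for endpoint in om.ENDPOINTS:
            model = om.fit_outcome_model(
                conditioned,
                endpoint,
                config.predictors,
                site_ridge=config.site_ridge,
                ttr_threshold=config.ttr_threshold,
            )
            fitted[endpoint] = model
            rates = om.marginal_rates(
                model,
                conditioned,
                n_boot=config.n_boot,
                seed=master + STAGE_OFFSETS["bootstrap"],
            )
            rows.append(
                {
                    "outcome": endpoint,
                    "vka_pct": rates.vka,
                    "vka_ci_lo": rates.vka_ci[0],
                    "vka_ci_hi": rates.vka_ci[1],
                    "doac_pct": rates.doac,
                    "doac_ci_lo": rates.doac_ci[0],
                    "doac_ci_hi": rates.doac_ci[1],
                    "difference_pp": rates.difference,
                    "brier": om.brier_score(model, conditioned),
                }
            )
        rates_table = pd.DataFrame(rows)
        rates_table.to_csv(out / "marginal_rates_table.csv", index=False)
        return fitted, rates_table

    fitted, rates_table = stage_models()
    bundle["models"] = fitted
    bundle["marginal_rates_table"] = rates_table

    if config.scenarios:

        @_stage("monte-carlo")
        def stage_mc():
            specs = [
                mc.ScenarioSpec(
                    s, resample_size=config.resample_size, iterations=config.iterations
                )
                for s in config.scenarios
            ]
            result = mc.run_simulation(
                conditioned, fitted, specs, master_seed=master + STAGE_OFFSETS["mc"]
            )
            sim_table = render_simulation_table(result)
            sim_table.to_csv(out / "simulation_table.csv", index=False)
            signs = reference_signs(source)
            direction = {
                scenario: mc.directionality(result, signs, scenario)
                for scenario in result.scenarios
            }
            with open(out / "directionality.json", "w") as fh:
                json.dump({"reference_signs": signs, "fractions": direction}, fh, indent=2)
            return result, sim_table, direction

        result, sim_table, direction = stage_mc()
        bundle["simulation"] = result
        bundle["simulation_table"] = sim_table
        bundle["directionality"] = direction

        @_stage("figures")
        def stage_figures():
            _figures(out, source, replicas[0], result)

        stage_figures()

    manifest = {
        "master_seed": master,
        "stage_seeds": {k: master + v for k, v in STAGE_OFFSETS.items()},
        "config": _as_jsonable(config),
        "config_hash": config.config_hash(),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    bundle["manifest"] = manifest
    return bundle


def _figures(out: Path, source: Cohort, twin: Cohort, result: mc.SimulationResult) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    corr_vars = [
        "age",
        "sex",
        "usvt_site",
        "treatment",
        "active_cancer",
        "recurrence",
        "major_bleed",
    ]
    ca, cb, _, _ = fid.correlation_similarity(source, twin, corr_vars)
    mask = (ca - cb).abs() > 0.1
    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))
    for ax, (mat, title) in zip(
        axes,
        [(ca, "source cohort"), (cb, "digital twin"), (mask.astype(float), "|Δρ| > 0.1")],
    ):
        im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(mat)), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat)), mat.columns, fontsize=7)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out / "correlation_heatmaps.png", dpi=120)
    plt.close(fig)

    # iteration distributions for the baseline scenario with the source
    # cohort's observed rates overlaid
    rates = result.iteration_rates.get("baseline")
    if rates is None:
        return
    signs_df = source.df
    fig, axes = plt.subplots(1, len(result.endpoints), figsize=(4 * len(result.endpoints), 4))
    axes = np.atleast_1d(axes)
    for e_idx, (ax, endpoint) in enumerate(zip(axes, result.endpoints)):
        data = [rates[:, e_idx, a] * 100 for a in range(2)]
        ax.boxplot(data, tick_labels=["VKA", "DOAC"])
        observed, y = om.endpoint_values(signs_df, endpoint)
        for a, arm in enumerate(("VKA", "DOAC")):
            mask_arm = observed & (signs_df["treatment"] == arm).to_numpy()
            if mask_arm.any():
                ax.plot(a + 1, 100 * y[mask_arm].mean(), "ro", zorder=3)
        ax.set_title(endpoint)
        ax.set_ylabel("event rate (%)")
    fig.tight_layout()
    fig.savefig(out / "simulation_distributions.png", dpi=120)
    plt.close(fig)
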