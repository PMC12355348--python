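"""End-to-end orchestration: ingest -> harmonise -> log-ratios -> fit ->
evaluate -> source densities -> report.

Runs either on an archived compilation (CSV paths) or on the bundled
synthetic generator.  Every output carries the master seed and a hash of
the configuration; reruns with the same config are draw-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from bluecarbon import compilation as cio
from bluecarbon.attribution import bootstrap_density, pooled_source_stats
from bluecarbon.evaluation import (
    compare_elpd,
    pit_residuals,
    pointwise_loglik,
    posterior_predictive,
    ppc_pvalue,
    psis_loo,
)
from bluecarbon.logratio import batch_logratios
from bluecarbon.model import (
    ModelSpec,
    bayes_r2,
    fit_mcmc,
    model_data,
    summarize_fold_variation,
)
from bluecarbon.synthetic import (
    GeneratorConfig,
    generate_compilation,
    generate_source_table,
)

log = logging.getLogger("bluecarbon")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one input mode (paths or synthetic)."""

    compilation_path: str | None = None
    contributions_path: str | None = None
    synthetic: GeneratorConfig | None = None
    n_draws: int = 1_000_000
    model: ModelSpec = field(default_factory=ModelSpec)
    run_loo: bool = True
    run_ppc: bool = True
    run_residuals: bool = True
    run_densities: bool = True
    density_n_boot: int = 1000
    output_dir: str = "results"
    seed: int = 0
    save_draws: bool = False

    def __post_init__(self):
        has_path = self.compilation_path is not None
        has_synth = self.synthetic is not None
        if has_path == has_synth:
            raise ValueError("exactly one of compilation_path or synthetic required")

    def hash(self) -> str:
        def default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    outputs: dict[str, str]
    summary: dict[str, object]
    warnings: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and return a report of outputs and key results."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    outputs: dict[str, str] = {}
    caught: list[str] = []
    t0 = time.time()

    def stage(name: str):
        log.info("stage %-12s %6.1fs", name, time.time() - t0)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # ingest
        source_rows = None
        if config.synthetic is not None:
            records, truth = generate_compilation(config.synthetic, seed=config.seed)
            source_rows = generate_source_table(config.synthetic, seed=config.seed + 1)
        else:
            records = cio.read_compilation(
                config.compilation_path, config.contributions_path
            )
            truth = None
        stage("ingest")
        log.info("%d records, %d studies", len(records), len({r.study_id for r in records}))

        # harmonise + Monte-Carlo log-ratios
        adjusted = batch_logratios(
            records, n_draws=config.n_draws, master_seed=config.seed
        )
        adj = cio.adjusted_frame(adjusted)
        adj["n_draws"] = config.n_draws
        adj["seed"] = config.seed
        adj["config_hash"] = chash
        adj.to_csv(out / "adjusted.csv", index=False)
        outputs["adjusted"] = str(out / "adjusted.csv")
        stage("logratios")

        # fit full and null models
        full_spec = replace(config.model, seed=config.seed)
        null_spec = replace(full_spec, fixed_effects=())
        data_full = model_data(adjusted, full_spec)
        data_null = model_data(adjusted, null_spec)
        draws_full = fit_mcmc(data_full, full_spec)
        draws_null = fit_mcmc(data_null, null_spec)
        stage("fit")

        summary_df = draws_full.diagnostics()
        summary_df["config_hash"] = chash
        summary_df["seed"] = config.seed
        summary_df.to_csv(out / "summary.csv", index=False)
        outputs["summary"] = str(out / "summary.csv")
        if config.save_draws:
            draws_full.to_frame().to_csv(out / "draws.csv", index=False)
            outputs["draws"] = str(out / "draws.csv")

        sb = draws_full.sigma_between.reshape(-1)
        summary: dict[str, object] = {
            "n_estimates": len(adjusted),
            "n_studies": data_full.design.n_groups,
            "sigma_between": {
                "median": float(np.median(sb)),
                "q2.5": float(np.quantile(sb, 0.025)),
                "q97.5": float(np.quantile(sb, 0.975)),
            },
            "fold_variation": summarize_fold_variation(sb),
            "fixed_effects": {
                name: {
                    "median": float(np.median(draws_full.beta[:, :, j])),
                    "q2.5": float(np.quantile(draws_full.beta[:, :, j], 0.025)),
                    "q97.5": float(np.quantile(draws_full.beta[:, :, j], 0.975)),
                }
                for j, name in enumerate(draws_full.column_names)
            },
        }
        r2 = bayes_r2(draws_full, data_full)
        summary["bayes_r2"] = {k: r2[k] for k in ("median", "q2.5", "q97.5")}

        # evaluation
        if config.run_loo:
            ll_full = pointwise_loglik(draws_full, data_full)
            ll_null = pointwise_loglik(draws_null, data_null)
            loo_full = psis_loo(ll_full)
            loo_null = psis_loo(ll_null)
            diff, diff_se = compare_elpd(loo_full, loo_null)
            pd.DataFrame(
                {
                    "observation": np.arange(loo_full.pointwise.size),
                    "elpd_i": loo_full.pointwise,
                    "pareto_k": loo_full.pareto_k,
                }
            ).to_csv(out / "loo.csv", index=False)
            outputs["loo"] = str(out / "loo.csv")
            comparison = {
                "elpd_full": loo_full.elpd,
                "elpd_null": loo_null.elpd,
                "elpd_diff": diff,
                "diff_se": diff_se,
                "n_bad_pareto_k": loo_full.n_bad_k,
            }
            (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
            outputs["comparison"] = str(out / "comparison.json")
            summary["loo"] = comparison
        if config.run_ppc:
            rep = posterior_predictive(
                draws_full, data_full, n_rep=1000, seed=config.seed + 17
            )
            summary["ppc"] = {
                stat: ppc_pvalue(rep[f"rep_{stat}"], rep["observed"][stat])
                for stat in ("mean", "sd", "min", "max")
            }
        if config.run_residuals:
            pit = pit_residuals(draws_full, data_full, seed=config.seed + 29)
            pd.DataFrame({"observation": np.arange(pit.size), "pit": pit}).to_csv(
                out / "pit.csv", index=False
            )
            outputs["pit"] = str(out / "pit.csv")
        stage("evaluate")

        # source densities
        if config.run_densities and (source_rows or config.contributions_path):
            if source_rows is None:
                cdf = cio.read_contributions(config.contributions_path)
                groups = {}
                hab_of = {r.estimate_id: r.habitat for r in records}
                for _, row in cdf.iterrows():
                    key = (hab_of.get(row["estimate_id"]), row["source_name"])
                    groups.setdefault(key, []).append(
                        cio.SourceContribution(
                            source_name=row["source_name"],
                            mean_pct=float(row["mean_pct"]),
                            sd_pct=float(row["sd_pct"]),
                            n_estimates=int(row["n_estimates"]),
                        )
                    )
            else:
                groups = {}
                for r in source_rows:
                    groups.setdefault((r.habitat, r.contribution.source_name), []).append(
                        r.contribution
                    )
            dens_rows, stat_rows = [], []
            for (habitat, source), contribs in sorted(groups.items()):
                mean, sd, n_ds = pooled_source_stats(contribs)
                stat_rows.append(
                    {"habitat": habitat, "source": source, "mean": mean, "sd": sd, "n_datasets": n_ds}
                )
                dens = bootstrap_density(
                    contribs,
                    n_boot=config.density_n_boot,
                    seed=config.seed + 31,
                    habitat=habitat,
                    source_name=source,
                )
                for x, d in zip(dens.grid, dens.density):
                    dens_rows.append(
                        {"habitat": habitat, "source": source, "grid_point": x, "density": d}
                    )
            pd.DataFrame(stat_rows).to_csv(out / "source_summary.csv", index=False)
            pd.DataFrame(dens_rows).to_csv(out / "densities.csv", index=False)
            outputs["source_summary"] = str(out / "source_summary.csv")
            outputs["densities"] = str(out / "densities.csv")
            summary["pooled_sources"] = stat_rows
        stage("densities")

        caught = [str(w.message) for w in wlist]

    report = RunReport(
        config_hash=chash,
        seed=config.seed,
        outputs=outputs,
        summary=summary,
        warnings=caught,
    )
    report.to_json(out / "report.json")
    return report
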