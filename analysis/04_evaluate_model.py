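"""Model comparison and checking for the fitted meta-regression.

Refits the full and null (intercept-only) models, compares them by
PSIS-LOO, runs posterior predictive checks on mean/SD/min/max, and writes
PIT residuals.  Outputs: results/loo.csv, results/comparison.json,
results/pit.csv.
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from bluecarbon.cli import _read_adjusted
from bluecarbon.evaluation import (
    compare_elpd,
    pit_residuals,
    pointwise_loglik,
    posterior_predictive,
    ppc_pvalue,
    psis_loo,
)
from bluecarbon.model import ModelSpec, fit_mcmc, model_data


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--adjusted", type=Path, default=Path("results/adjusted.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    parser.add_argument("--chains", type=int, default=4)
    parser.add_argument("--iter", type=int, default=10_000)
    parser.add_argument("--warmup", type=int, default=5_000)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    estimates = _read_adjusted(args.adjusted)
    full_spec = ModelSpec(chains=args.chains, iterations=args.iter,
                          warmup=args.warmup, seed=args.seed)
    null_spec = replace(full_spec, fixed_effects=())
    data_full = model_data(estimates, full_spec)
    data_null = model_data(estimates, null_spec)
    draws_full = fit_mcmc(data_full, full_spec)
    draws_null = fit_mcmc(data_null, null_spec)

    loo_full = psis_loo(pointwise_loglik(draws_full, data_full))
    loo_null = psis_loo(pointwise_loglik(draws_null, data_null))
    diff, diff_se = compare_elpd(loo_full, loo_null)
    pd.DataFrame(
        {
            "observation": np.arange(loo_full.pointwise.size),
            "elpd_i": loo_full.pointwise,
            "pareto_k": loo_full.pareto_k,
        }
    ).to_csv(args.out_dir / "loo.csv", index=False)
    comparison = {
        "elpd_full": loo_full.elpd,
        "elpd_null": loo_null.elpd,
        "elpd_diff": diff,
        "diff_se": diff_se,
        "n_bad_pareto_k": loo_full.n_bad_k,
    }
    (args.out_dir / "comparison.json").write_text(json.dumps(comparison, indent=2))

    rep = posterior_predictive(draws_full, data_full, n_rep=1000, seed=args.seed + 17)
    ppc = {s: ppc_pvalue(rep[f"rep_{s}"], rep["observed"][s])
           for s in ("mean", "sd", "min", "max")}

    pit = pit_residuals(draws_full, data_full, seed=args.seed + 29)
    pd.DataFrame({"observation": np.arange(pit.size), "pit": pit}).to_csv(
        args.out_dir / "pit.csv", index=False
    )
    ks = stats.kstest(pit, "uniform")

    print(f"elpd (full) {loo_full.elpd:.1f}, elpd (null) {loo_null.elpd:.1f}")
    print(f"elpd difference {diff:.1f} +- {diff_se:.1f} "
          f"({'favors the full model' if diff > 2 * diff_se else 'inconclusive'})")
    print(f"Pareto-k > 0.7: {loo_full.n_bad_k} of {loo_full.pointwise.size}")
    print("posterior predictive p-values: "
          + ", ".join(f"{k}={v:.2f}" for k, v in ppc.items()))
    print(f"PIT uniformity: KS statistic {ks.statistic:.3f}, p = {ks.pvalue:.2f}")


if __name__ == "__main__":
    main()
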