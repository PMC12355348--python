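"""Pool per-source contribution estimates and build bootstrap densities.

For every habitat x carbon-source cell in the contribution table, computes
the unweighted pooled mean/SD across datasets and a 1000-draw-per-dataset
truncated-normal bootstrap density on [0, 100]%.  Also demonstrates the
two-source isotope mixing computation used where studies reported only
delta-13C signatures.  Outputs: results/source_summary.csv,
results/densities.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from bluecarbon.attribution import (
    IsotopeSignature,
    bootstrap_density,
    pooled_source_stats,
    two_source_mixing,
)
from bluecarbon.compilation import SourceContribution, read_contributions


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--contributions", type=Path,
                        default=Path("results/synthetic/contributions.csv"))
    parser.add_argument("--habitats", type=Path,
                        default=Path("results/synthetic/compilation.csv"))
    parser.add_argument("--n-boot", type=int, default=1000)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cdf = read_contributions(args.contributions)
    if "habitat" not in cdf.columns:
        habs = pd.read_csv(args.habitats)[["estimate_id", "habitat"]]
        cdf = cdf.merge(habs, on="estimate_id")

    stat_rows, dens_rows = [], []
    for (habitat, source), grp in sorted(cdf.groupby(["habitat", "source_name"])):
        contribs = [
            SourceContribution(source_name=source, mean_pct=r.mean_pct,
                               sd_pct=r.sd_pct, n_estimates=int(r.n_estimates))
            for r in grp.itertuples(index=False)
        ]
        mean, sd, n_ds = pooled_source_stats(contribs)
        stat_rows.append({"habitat": habitat, "source": source,
                          "mean": mean, "sd": sd, "n_datasets": n_ds})
        dens = bootstrap_density(contribs, n_boot=args.n_boot, seed=args.seed,
                                 habitat=habitat, source_name=source)
        for x, d in zip(dens.grid, dens.density):
            dens_rows.append({"habitat": habitat, "source": source,
                              "grid_point": x, "density": d})

    summary = pd.DataFrame(stat_rows)
    summary.to_csv(args.out_dir / "source_summary.csv", index=False)
    pd.DataFrame(dens_rows).to_csv(args.out_dir / "densities.csv", index=False)

    print(summary.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    cross = summary[(summary["habitat"] != summary["source"])]
    top = cross.sort_values("mean", ascending=False).head(3)
    print("\nlargest cross-habitat subsidies:")
    for r in top.itertuples(index=False):
        print(f"  {r.source} -> {r.habitat} soils: {r.mean:.0f}% (n={r.n_datasets})")

    # two-source mixing example: mixture between mangrove-like and
    # SPOM-like delta-13C end-members
    f1, se, _ = two_source_mixing(
        IsotopeSignature(-26.0, 1.2, 10),
        IsotopeSignature(-28.5, 1.0, 12),
        IsotopeSignature(-22.0, 1.5, 8),
    )
    print(f"\ntwo-source mixing example: f(mangrove) = {f1:.2f} +- {se:.2f}")


if __name__ == "__main__":
    main()
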