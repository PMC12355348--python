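"""Harmonise reported variability measures and build log-ratio effect sizes.

Reads the compilation, converts every reported SE / 95% CI / variance to an
adjusted SD, then Monte-Carlo samples 10^6 truncated-normal draws per record
to obtain the mean and SD of ln(autochthonous% / allochthonous%).  Writes
results/adjusted.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from bluecarbon.compilation import adjusted_frame, read_compilation
from bluecarbon.logratio import batch_logratios


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--draws", type=int, default=1_000_000)
    parser.add_argument("--compilation", type=Path,
                        default=Path("results/synthetic/compilation.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/adjusted.csv"))
    args = parser.parse_args()

    records = read_compilation(args.compilation)
    adjusted = batch_logratios(records, n_draws=args.draws, master_seed=args.seed)
    frame = adjusted_frame(adjusted)
    frame["n_draws"] = args.draws
    frame["seed"] = args.seed
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False)

    lr = frame["logratio_mean"]
    print(f"wrote {len(frame)} adjusted estimates to {args.out}")
    print(f"log-ratio mean {lr.mean():.3f} (negative = predominantly allochthonous)")
    print(f"fraction of estimates below auto:allo parity: {np.mean(lr < 0):.2f}")


if __name__ == "__main__":
    main()
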