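#!/usr/bin/env python
"""Generate the synthetic study datasets.

Emulates both experiments: a pouch-and-wick seedling root screen (7 runs of
768 plant positions, 32 genotypes x 24 individuals per run, ~29% attrition)
and the polytunnel ionomics experiment (432 genotypes x 5 replicate blocks
= 2,160 pots; 2,096 leaf solutions in 14 ICP-MS runs and 1,986 seed
solutions in 4 runs, with operational blanks, interleaved reference
material, within-run drift and near-LOD censoring).

Writes CSV tables under results/data/.
"""

import argparse
import logging
from pathlib import Path

from napus_phenomics import config as cfgmod
from napus_phenomics.stages import stage_simulate

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    parser.add_argument("--root-runs", type=int, default=7,
                        help="pouch runs to simulate (768 plants each)")
    args = parser.parse_args()

    cfg = cfgmod.load_config()
    cfg["pouch"]["n_runs"] = args.root_runs
    paths = stage_simulate(cfg, args.seed, args.out)
    for name, path in paths.items():
        print(f"{name}: {path}")


if __name__ == "__main__":
    main()
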