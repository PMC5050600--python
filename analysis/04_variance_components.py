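#!/usr/bin/env python
"""REML variance-component decomposition.

Root traits use [(run/frame/column/tray/paper-side) + habit + seed size +
genotype]; leaf and seed element concentrations use [habit + genotype +
polytunnel + polytunnel/replicate + polytunnel/replicate/sub-block].
Percents of total variance are written in a Table-style layout (genotype,
habit, experimental, seed diameter, residual).
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from napus_phenomics import defaults
from napus_phenomics.stages import stage_varcomp

logging.basicConfig(level=logging.WARNING)

COMPOSITION_EXAMPLES = {
    "leaf": ["S", "Ca", "Mo", "Se", "K"],
    "seed": ["S", "Mo", "Ca"],
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    print("root traits (percent of total variance):")
    table = stage_varcomp(args.results / "root_traits.csv",
                          list(defaults.ROOT_TRAITS), "root",
                          args.results, out_name="varcomp_root.csv")
    print(table.to_string(index=False))

    pots = pd.read_csv(args.results / "data" / "pots.csv")
    design = pots[["pot_id", "habit", "polytunnel", "replicate", "sub_block"]]
    for tissue, elements in COMPOSITION_EXAMPLES.items():
        conc = pd.read_csv(args.results / f"{tissue}_conc.csv")
        conc = conc[conc["genotype_id"].notna()].merge(design, on="pot_id")
        merged_path = args.results / f"_tmp_{tissue}.csv"
        conc.to_csv(merged_path, index=False)
        print(f"\n{tissue} composition traits:")
        table = stage_varcomp(merged_path, elements, "composition",
                              args.results,
                              out_name=f"varcomp_{tissue}.csv")
        print(table.to_string(index=False))
        merged_path.unlink()


if __name__ == "__main__":
    main()
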