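#!/usr/bin/env python
"""Element-pair translocation ratios.

For the pairs S:Mo, Ca:Sr, K:Rb and Zn:Cd (shared transport/assimilation
pathways), computes per-genotype leaf and seed concentration ratios and the
translocation index (seed ratio / leaf ratio); an index below 1 means
relatively greater net seed accumulation of the second element.
"""

import argparse
import logging
from pathlib import Path

from napus_phenomics.stages import stage_ratios

logging.basicConfig(level=logging.WARNING)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    ratios = stage_ratios(args.results / "genotype_means.csv", args.results)
    summary = (ratios.groupby("pair")
               .agg(median_leaf_ratio=("leaf_ratio", "median"),
                    median_index=("translocation_index", "median")))
    print(summary.round(3).to_string())


if __name__ == "__main__":
    main()
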