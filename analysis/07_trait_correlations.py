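#!/usr/bin/env python
"""Pairwise correlations of all genotype-mean traits.

Pearson r over pairwise-complete genotypes for every pair of the 44 traits
(946 pairs), plus the symmetric matrix in the fixed heat-map ordering.
"""

import argparse
import logging
from pathlib import Path

from napus_phenomics.stages import stage_correlate

logging.basicConfig(level=logging.WARNING)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    long = stage_correlate(args.results / "genotype_means.csv", args.results)
    strongest = long.dropna().reindex(
        long["r"].abs().sort_values(ascending=False).index).head(8)
    print(f"{len(long)} trait pairs; strongest correlations:")
    print(strongest[["trait_i", "trait_j", "r", "n"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
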