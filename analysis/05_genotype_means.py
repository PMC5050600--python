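#!/usr/bin/env python
"""Genotype x trait mean matrix.

Root and leaf traits use generalised least squares means with genotype
fixed and the design terms random at their REML variances; seed element
concentrations and the seed-weight traits use arithmetic per-genotype
means.  The 44-trait matrix feeds the ratio, correlation and discriminant
stages.
"""

import argparse
import logging
from pathlib import Path

from napus_phenomics.stages import stage_genotype_means

logging.basicConfig(level=logging.WARNING)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    matrix = stage_genotype_means(
        root_csv=args.results / "root_traits.csv",
        leaf_csv=args.results / "leaf_conc.csv",
        seed_csv=args.results / "seed_conc.csv",
        pots_csv=args.results / "data" / "pots.csv",
        outdir=args.results,
    )
    n_traits = matrix.shape[1] - 2  # genotype_id + habit
    print(f"{matrix.shape[0]} genotypes x {n_traits} traits "
          f"-> {args.results / 'genotype_means.csv'}")


if __name__ == "__main__":
    main()
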