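#!/usr/bin/env python
"""Stepwise discriminant analysis of crop habit.

Wilks' Lambda forward selection over the combined 44-trait variate set
(and each single-tissue set), recording per-step Lambda and per-habit
specificity, plus canonical-variate scores for the two-dimensional
discrimination plot.
"""

import argparse
import logging
from pathlib import Path

from napus_phenomics.stages import stage_discriminate

logging.basicConfig(level=logging.WARNING)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--max-steps", type=int, default=20)
    args = parser.parse_args()

    means_csv = args.results / "genotype_means.csv"
    for variate_set in ("root", "leaf", "seed", "seed_weight", "combined"):
        table = stage_discriminate(means_csv, variate_set, args.results,
                                   max_steps=args.max_steps)
        if table.empty:
            continue
        last = table.iloc[-1]
        spec_cols = [c for c in table.columns if c.startswith("specificity_")]
        mean_spec = last[spec_cols].mean()
        print(f"{variate_set}: {len(table)} steps, final Lambda "
              f"{last['wilks_lambda']:.4f}, mean specificity "
              f"{mean_spec:.2f}")
    combined = args.results / "discriminant_combined_steps.csv"
    print(f"step details in {combined}")


if __name__ == "__main__":
    main()
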