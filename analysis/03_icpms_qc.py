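#!/usr/bin/env python
"""ICP-MS quality control for leaf and seed run tables.

Stage order: blank subtraction -> drift normalisation against interleaved
reference material -> unit conversion to mg/kg dry tissue -> LOD estimation
(3 x blank SD at the notional dry mass) -> element retention -> half-LOD
substitution of censored values -> one-sided 5-SD outlier screen.
"""

import argparse
import logging
from pathlib import Path

from napus_phenomics.stages import stage_icpms_qc

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    for tissue in ("leaf", "seed"):
        result, _ = stage_icpms_qc(args.data / f"icpms_{tissue}.csv",
                                   tissue, args.out)
        retained = list(result.matrix.values.columns)
        print(f"{tissue}: {result.n_raw_cells} raw values, "
              f"{len(retained)} elements retained, "
              f"{result.n_outliers_removed} outlier cells removed")


if __name__ == "__main__":
    main()
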