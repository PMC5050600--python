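#!/usr/bin/env python
"""Seedling quality control and root-trait derivation.

Applies the exclusion rules (failed germination, failed emergence, deformed
radicle, stunted radicle < 3 cm), derives TRL / MLRL / LRD from the
measured components, and reports the attrition fraction by reason.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from napus_phenomics.stages import stage_root_traits

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--records", type=Path,
                        default=Path("results/data/root_records.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    paths = stage_root_traits(args.records, args.out)
    attrition = pd.read_csv(paths["attrition"])
    total = attrition.set_index("reason").loc["total"]
    print(f"excluded {int(total['n'])} seedlings "
          f"({100 * total['fraction']:.1f}% attrition)")
    print(attrition.to_string(index=False))


if __name__ == "__main__":
    main()
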