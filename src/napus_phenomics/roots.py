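"""Seedling QC and root-trait derivation.

Measured components per seedling are primary root length (PRL, cm), total
lateral root length (LRL, cm) and lateral root number (LRN).  Derived
traits: TRL = PRL + LRL, MLRL = LRL / LRN (missing when LRN = 0) and
LRD = LRN / PRL.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .defaults import MIN_RADICLE_CM
from .io import log_filter

EXCLUSION_REASONS = ("non_germination", "non_emergence", "deformed", "stunted")


def qc_seedling(record: pd.Series, min_radicle_cm: float = MIN_RADICLE_CM) -> str | None:
    """Return the exclusion reason for one seedling, or None to keep it.

    Excluded: failed germination; shoot failed to emerge; deformed radicle;
    stunted with a radicle strictly shorter than 3 cm (a 3.0 cm radicle is
    kept).
    """
    if not bool(record["germinated"]):
        return "non_germination"
    if not bool(record["emerged"]):
        return "non_emergence"
    if bool(record["deformed"]):
        return "deformed"
    if float(record["prl"]) < min_radicle_cm:
        return "stunted"
    return None


def qc_seedlings(
    records: pd.DataFrame, min_radicle_cm: float = MIN_RADICLE_CM
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised QC over a record table.

    Returns (kept records, exclusion log with plant_id and reason); the
    first matching rule in the order non-germination > non-emergence >
    deformed > stunted is the recorded reason.
    """
    reason = pd.Series(pd.NA, index=records.index, dtype="string")
    stunted = records["prl"].astype(float) < min_radicle_cm
    reason[stunted] = "stunted"
    reason[records["deformed"].astype(bool)] = "deformed"
    reason[~records["emerged"].astype(bool)] = "non_emergence"
    reason[~records["germinated"].astype(bool)] = "non_germination"
    kept = records[reason.isna()].copy()
    exclusions = pd.DataFrame({
        "plant_id": records.loc[reason.notna(), "plant_id"],
        "reason": reason.dropna(),
    })
    log_filter("seedling QC", "germination/emergence/deformity/stunting",
               len(records), len(exclusions))
    return kept, exclusions


def derive_root_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Add TRL, MLRL, LRD to QC-passed records.

    MLRL is missing (not zero) when a seedling has no laterals; LRD never
    divides by zero because QC guarantees PRL >= 3 cm.
    """
    if (records["prl"].astype(float) <= 0).any():
        raise ValueError("derive_root_traits requires QC-passed records "
                         "(prl > 0); run qc_seedlings first")
    out = records.copy()
    prl = out["prl"].astype(float)
    lrl = out["lrl"].astype(float)
    lrn = out["lrn"].astype(float)
    out["trl"] = prl + lrl
    out["mlrl"] = np.where(lrn > 0, lrl / lrn.replace(0, np.nan), np.nan)
    out["lrd"] = lrn / prl
    return out


def attrition_report(
    records: pd.DataFrame, exclusions: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of seedlings excluded, overall and per reason."""
    n = len(records)
    rows = [{"reason": "total", "n": len(exclusions),
             "fraction": len(exclusions) / n if n else 0.0}]
    for reason in EXCLUSION_REASONS:
        k = int((exclusions["reason"] == reason).sum()) if len(exclusions) else 0
        rows.append({"reason": reason, "n": k, "fraction": k / n if n else 0.0})
    return pd.DataFrame(rows)
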