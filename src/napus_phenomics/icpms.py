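"""ICP-MS quality control: raw solution readings to QC'd tissue concentrations.

Fixed stage order, each step logged:
blank subtraction -> drift normalisation -> unit conversion -> LOD ->
element retention -> half-LOD substitution -> 5-SD outlier screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import icpms_element_columns, log_filter

log = logging.getLogger("napus_phenomics")


class QcError(ValueError):
    pass


@dataclass
class ElementPanel:
    """Monitored and excluded element lists for one tissue.

    `excluded` need not be a subset of `monitored` (the seed exclusion list
    carries Cr and Pb, never monitored in seed); retained is the ordered set
    difference.
    """

    tissue: str
    monitored: tuple[str, ...]
    excluded: tuple[str, ...] = ()

    @property
    def retained(self) -> list[str]:
        return [e for e in self.monitored if e not in self.excluded]


@dataclass
class LodTable:
    tissue: str
    notional_mass_g: float
    lod: dict[str, float]  # mg/kg

    def __post_init__(self) -> None:
        if self.notional_mass_g <= 0:
            raise ValueError("notional mass must be > 0")
        bad = {e: v for e, v in self.lod.items() if v < 0}
        if bad:
            raise ValueError(f"negative LODs: {bad}")


# Cell-level QC flags (a cell carries at most one terminal flag)
FLAG_RAW = "raw"
FLAG_BLANK = "blank_corrected"
FLAG_DRIFT = "drift_corrected"
FLAG_HALF_LOD = "half_lod_substituted"
FLAG_OUTLIER = "outlier_removed"


@dataclass
class TissueConcMatrix:
    """Samples x retained elements, mg element per kg dry tissue."""

    tissue: str
    values: pd.DataFrame   # index: sample ids; columns: elements
    flags: pd.DataFrame    # same shape, QC flag strings
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def subtract_blanks(runs: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-run, per-element mean operational blank reading from
    every non-blank row.  Negative corrected readings are retained (the
    censoring rule deals with them later)."""
    elements = icpms_element_columns(runs)
    out = runs.copy()
    for run_id, idx in runs.groupby("run_id").groups.items():
        sub = runs.loc[idx]
        blanks = sub[sub["role"] == "blank"]
        if blanks.empty:
            raise QcError(f"run {run_id} has no operational blanks")
        means = blanks[elements].mean()
        target = sub.index[sub["role"] != "blank"]
        out.loc[target, elements] = sub.loc[target, elements] - means
    return out


def drift_correct(runs: pd.DataFrame) -> pd.DataFrame:
    """Normalise within-run drift against interleaved reference readings.

    For each run and element, a piecewise-linear factor is interpolated
    between bracketing reference readings (normalised to the run-mean
    reference reading); sample readings are divided by the local factor.
    Samples outside the reference bracket use the nearest factor.  Runs with
    fewer than two references are left uncorrected (logged warning).
    """
    elements = icpms_element_columns(runs)
    out = runs.copy()
    for run_id, idx in runs.groupby("run_id").groups.items():
        sub = runs.loc[idx]
        refs = sub[sub["role"] == "reference"].sort_values("position")
        if len(refs) < 2:
            log.warning("drift correction skipped for run %s: %d reference "
                        "row(s)", run_id, len(refs))
            continue
        ref_pos = refs["position"].to_numpy(dtype=float)
        target = sub.index[sub["role"].isin(["sample", "reference"])]
        pos = sub.loc[target, "position"].to_numpy(dtype=float)
        for el in elements:
            ref_vals = refs[el].to_numpy(dtype=float)
            mean_ref = ref_vals.mean()
            if mean_ref == 0:
                continue
            factor = np.interp(pos, ref_pos, ref_vals) / mean_ref
            with np.errstate(divide="ignore", invalid="ignore"):
                out.loc[target, el] = sub.loc[target, el].to_numpy() / factor
    return out


def to_tissue_concentration(
    reading_ugl: float | np.ndarray | pd.Series,
    dilution: float | np.ndarray | pd.Series,
    digest_volume_l: float | np.ndarray | pd.Series,
    dry_mass_g: float | np.ndarray | pd.Series,
) -> float | np.ndarray | pd.Series:
    """Solution ug/L -> tissue mg/kg: reading x dilution x volume / dry mass.

    ug/L x L = ug in the digest; ug / g dry mass = ug/g = mg/kg.
    """
    mass = np.asarray(dry_mass_g, dtype=float)
    if np.any(mass <= 0):
        raise QcError("dry mass must be > 0")
    return reading_ugl * dilution * digest_volume_l / dry_mass_g


def compute_lod(
    blank_readings: pd.DataFrame,
    dilution: float,
    digest_volume_l: float,
    notional_mass_g: float,
    tissue: str = "leaf",
) -> LodTable:
    """LOD per element: 3 x SD of operational blank solution readings,
    converted to mg/kg with the notional starting dry mass."""
    lods: dict[str, float] = {}
    for el in blank_readings.columns:
        vals = blank_readings[el].dropna()
        if len(vals) < 2:
            raise QcError(f"element {el}: need >= 2 blank readings for an SD")
        lod_solution = 3.0 * vals.std(ddof=1)
        lods[el] = float(to_tissue_concentration(
            lod_solution, dilution, digest_volume_l, notional_mass_g))
    return LodTable(tissue=tissue, notional_mass_g=notional_mass_g, lod=lods)


def retain_elements(panel: ElementPanel) -> list[str]:
    """Monitored minus excluded, in monitored order."""
    return panel.retained


def auto_exclude(
    matrix: pd.DataFrame, lods: LodTable, k: float = 2.0
) -> list[str]:
    """Automatic at-or-near-LOD rule: exclude elements whose global mean
    concentration is below k x LOD (the printed exclusion lists are the
    defaults for the study-scale retention counts)."""
    out = []
    for el in matrix.columns:
        if el in lods.lod and matrix[el].mean() < k * lods.lod[el]:
            out.append(el)
    return out


def substitute_half_lod(
    matrix: TissueConcMatrix, lods: LodTable
) -> TissueConcMatrix:
    """Replace cells strictly below the element LOD with LOD/2 (left-censor
    convention); cells at or above the LOD are unchanged."""
    values = matrix.values.copy()
    flags = matrix.flags.copy()
    n_sub = 0
    for el in values.columns:
        if el not in lods.lod:
            raise QcError(f"no LOD available for retained element {el}")
        lod = lods.lod[el]
        below = values[el].notna() & (values[el] < lod)
        values.loc[below, el] = lod / 2.0
        flags.loc[below, el] = FLAG_HALF_LOD
        n_sub += int(below.sum())
    log_filter(f"{matrix.tissue} half-LOD", "value < LOD -> LOD/2",
               int(values.size), n_sub)
    return TissueConcMatrix(matrix.tissue, values, flags, matrix.meta)


def remove_outliers(matrix: TissueConcMatrix) -> tuple[TissueConcMatrix, int]:
    """One-sided, non-iterative 5-SD screen: per element, cells strictly
    above mean + 5 x SD (global arithmetic mean/SD over non-missing cells)
    are set missing as suspected contamination."""
    values = matrix.values.copy()
    flags = matrix.flags.copy()
    n_removed = 0
    for el in values.columns:
        col = values[el]
        ok = col.dropna()
        if len(ok) < 2:
            continue
        threshold = ok.mean() + 5.0 * ok.std(ddof=1)
        high = col.notna() & (col > threshold)
        values.loc[high, el] = np.nan
        flags.loc[high, el] = FLAG_OUTLIER
        n_removed += int(high.sum())
    log_filter(f"{matrix.tissue} outlier screen", "> mean + 5 SD removed",
               int(values.size), n_removed)
    return TissueConcMatrix(matrix.tissue, values, flags, matrix.meta), n_removed


def crm_recovery(
    measured: pd.Series | dict[str, float],
    certified: pd.Series | dict[str, float],
) -> pd.Series:
    """Per-element recovery percentage: 100 x measured / certified."""
    measured = pd.Series(measured, dtype=float)
    certified = pd.Series(certified, dtype=float)
    if (certified <= 0).any():
        bad = list(certified.index[certified <= 0])
        raise QcError(f"certified values must be > 0: {bad}")
    return 100.0 * measured / certified.reindex(measured.index)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class QcResult:
    matrix: TissueConcMatrix
    lods: LodTable
    report: pd.DataFrame       # per element QC summary
    n_outliers_removed: int
    n_raw_cells: int
    n_excluded_element_cells: int


def process_tissue(
    runs: pd.DataFrame,
    panel: ElementPanel,
    notional_mass_g: float,
    apply_drift_correction: bool = True,
) -> QcResult:
    """Run the full QC chain on one tissue's raw ICP-MS run tables."""
    elements = [e for e in icpms_element_columns(runs) if e in panel.monitored]
    n_samples = int((runs["role"] == "sample").sum())
    n_raw_cells = n_samples * len(elements)

    corrected = subtract_blanks(runs)
    if apply_drift_correction:
        corrected = drift_correct(corrected)

    samples = corrected[corrected["role"] == "sample"].copy()
    sample_ids = samples["pot_id"].fillna(samples["run_id"].astype(str)
                                          + ":" + samples["position"].astype(str))
    conc = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for el in elements:
        conc[el] = to_tissue_concentration(
            samples[el].to_numpy(dtype=float),
            samples["dilution"].to_numpy(dtype=float),
            samples["digest_volume_l"].to_numpy(dtype=float),
            samples["dry_mass_g"].to_numpy(dtype=float),
        )

    blanks = corrected[corrected["role"] == "blank"]
    lods = compute_lod(
        blanks[elements],
        dilution=float(samples["dilution"].iloc[0]),
        digest_volume_l=float(samples["digest_volume_l"].iloc[0]),
        notional_mass_g=notional_mass_g,
        tissue=panel.tissue,
    )

    retained_els = retain_elements(panel)
    n_excluded_cells = n_samples * (len(elements) - len(retained_els))
    log_filter(f"{panel.tissue} element retention",
               "at-or-near-LOD exclusion list",
               len(elements), len(elements) - len(retained_els))

    flag = FLAG_DRIFT if apply_drift_correction else FLAG_BLANK
    matrix = TissueConcMatrix(
        tissue=panel.tissue,
        values=conc[retained_els],
        flags=pd.DataFrame(flag, index=conc.index, columns=retained_els),
        meta=samples[["run_id", "position", "genotype_id", "pot_id"]]
        .set_index(conc.index),
    )
    below = {
        el: int((matrix.values[el] < lods.lod[el]).sum()) for el in retained_els
    }
    matrix = substitute_half_lod(matrix, lods)
    matrix, n_outliers = remove_outliers(matrix)

    report = pd.DataFrame({
        "element": retained_els,
        "n": [int(matrix.values[el].notna().sum()) for el in retained_els],
        "mean": [matrix.values[el].mean() for el in retained_els],
        "sd": [matrix.values[el].std(ddof=1) for el in retained_els],
        "lod": [lods.lod[el] for el in retained_els],
        "n_below_lod": [below[el] for el in retained_els],
        "n_outliers_removed": [
            int((matrix.flags[el] == FLAG_OUTLIER).sum()) for el in retained_els
        ],
    })
    return QcResult(
        matrix=matrix, lods=lods, report=report,
        n_outliers_removed=n_outliers, n_raw_cells=n_raw_cells,
        n_excluded_element_cells=n_excluded_cells,
    )
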