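"""Element-pair translocation ratios and all-pairs trait correlations
on genotype means.

The translocation index for an element pair (A, B) is
(seed [A]/[B]) / (leaf [A]/[B]); values below 1 indicate relatively
greater net seed accumulation of B than A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("napus_phenomics")


@dataclass(frozen=True)
class RatioSpec:
    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("element pair must be two distinct elements")

    @property
    def label(self) -> str:
        return f"{self.numerator}:{self.denominator}"


def translocation_ratio(
    means: pd.DataFrame, spec: RatioSpec
) -> pd.DataFrame:
    """Per-genotype leaf ratio, seed ratio and translocation index.

    `means` is a genotype x trait matrix holding leaf_<El> and seed_<El>
    columns.  Genotypes with any missing or non-positive concentration among
    the four inputs yield missing results with a recorded reason.
    """
    cols = {
        "leaf_num": f"leaf_{spec.numerator}",
        "leaf_den": f"leaf_{spec.denominator}",
        "seed_num": f"seed_{spec.numerator}",
        "seed_den": f"seed_{spec.denominator}",
    }
    for c in cols.values():
        if c not in means.columns:
            raise KeyError(f"trait column '{c}' not in genotype means")
    out = pd.DataFrame(index=means.index)
    out["pair"] = spec.label
    ln, ld = means[cols["leaf_num"]], means[cols["leaf_den"]]
    sn, sd = means[cols["seed_num"]], means[cols["seed_den"]]
    missing = ln.isna() | ld.isna() | sn.isna() | sd.isna()
    nonpos = (~missing) & ((ln <= 0) | (ld <= 0) | (sn <= 0) | (sd <= 0))
    ok = ~(missing | nonpos)
    out["leaf_ratio"] = np.where(ok, ln / ld, np.nan)
    out["seed_ratio"] = np.where(ok, sn / sd, np.nan)
    out["translocation_index"] = np.where(
        ok, (sn / sd) / (ln / ld), np.nan)
    out["reason"] = ""
    out.loc[missing, "reason"] = "missing concentration"
    out.loc[nonpos, "reason"] = "nonpositive denominator"
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("ratio %s: %d genotype(s) skipped", spec.label, n_bad)
    return out


def habit_ratio_summary(
    ratios: pd.DataFrame, habits: pd.Series
) -> pd.DataFrame:
    """Box-plot summaries of the translocation index per habit: median, mid
    quartiles, 95% whiskers and extremes."""
    df = ratios.join(habits.rename("habit"))
    rows = []
    for (pair, habit), sub in df.groupby(["pair", "habit"]):
        vals = sub["translocation_index"].dropna()
        if vals.empty:
            continue
        rows.append({
            "pair": pair, "habit": habit, "n": len(vals),
            "median": vals.median(),
            "q1": vals.quantile(0.25), "q3": vals.quantile(0.75),
            "lo95": vals.quantile(0.025), "hi95": vals.quantile(0.975),
            "min": vals.min(), "max": vals.max(),
        })
    return pd.DataFrame(rows)


def correlation_matrix(
    means: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Pearson correlations over all trait pairs of a genotype x trait matrix.

    Pairwise-complete over genotypes; two-sided p-values from the t
    transform.  Returns long format (trait_i, trait_j, r, n, p) for i < j;
    pairs with fewer than `min_n` complete observations or a constant trait
    are missing.
    """
    traits = list(means.columns)
    rows = []
    values = means.to_numpy(dtype=float)
    for i in range(len(traits)):
        for j in range(i + 1, len(traits)):
            x, y = values[:, i], values[:, j]
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            r = p = np.nan
            if n >= min_n and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append({"trait_i": traits[i], "trait_j": traits[j],
                         "r": r, "n": n, "p": p})
    out = pd.DataFrame(rows)
    n_missing = int(out["r"].isna().sum())
    if n_missing:
        log.info("correlation matrix: %d pair(s) not estimable", n_missing)
    return out


def correlation_square(long: pd.DataFrame, order: list[str]) -> pd.DataFrame:
    """Symmetric unit-diagonal matrix in a fixed trait ordering
    (heat-map layout)."""
    mat = pd.DataFrame(np.eye(len(order)), index=order, columns=order)
    for _, row in long.iterrows():
        i, j = row["trait_i"], row["trait_j"]
        if i in mat.index and j in mat.columns:
            mat.loc[i, j] = mat.loc[j, i] = row["r"]
    return mat
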