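"""Forward-selection stepwise discriminant analysis of crop habit.

At each step the candidate trait minimising Wilks' Lambda
(Lambda = det(W)/det(T), within-group over total scatter) of the augmented
selected set is added; per-step specificity is the fraction of each habit's
genotypes correctly re-allocated by the linear discriminant rule (pooled
within-group covariance, equal priors by default).  Canonical variates for
the two-dimensional discrimination plot come from the generalised
eigen-decomposition of between- against within-group scatter, scaled to
unit within-group variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.spatial import ConvexHull, QhullError

log = logging.getLogger("napus_phenomics")


class SingularScatterError(np.linalg.LinAlgError):
    pass


def _complete(data: pd.DataFrame, groups: pd.Series, traits: list[str]):
    """Listwise-complete rows for the active trait set (count logged)."""
    sub = data[traits]
    ok = sub.notna().all(axis=1) & groups.notna()
    dropped = int((~ok).sum())
    if dropped:
        log.info("discriminant: %d observation(s) dropped listwise for "
                 "traits %s", dropped, traits)
    return sub[ok].to_numpy(dtype=float), np.asarray(groups[ok])


def _scatter(X: np.ndarray, g: np.ndarray):
    """Within-group (W) and total (T) cross-product matrices."""
    grand = X.mean(axis=0)
    Tm = (X - grand).T @ (X - grand)
    Wm = np.zeros_like(Tm)
    for level in pd.unique(g):
        sub = X[g == level]
        dev = sub - sub.mean(axis=0)
        Wm += dev.T @ dev
    return Wm, Tm


def wilks_lambda(
    data: pd.DataFrame, groups: pd.Series, traits: list[str]
) -> float:
    """Wilks' Lambda = det(W)/det(T) on the selected traits."""
    X, g = _complete(data, groups, traits)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if X.shape[0] <= len(traits) + len(levels):
        raise ValueError("need n > n_traits + n_groups observations")
    Wm, Tm = _scatter(X, g)
    sign_w, logdet_w = np.linalg.slogdet(Wm)
    sign_t, logdet_t = np.linalg.slogdet(Tm)
    if sign_w <= 0 or sign_t <= 0 or not np.isfinite(logdet_w + logdet_t):
        raise SingularScatterError(
            f"singular scatter matrix for traits {traits}; remove a "
            f"collinear or constant trait"
        )
    return float(np.exp(logdet_w - logdet_t))


def allocate(
    data: pd.DataFrame,
    groups: pd.Series,
    traits: list[str],
    priors: str = "equal",
) -> tuple[pd.Series, dict[str, float]]:
    """Resubstitution allocation by maximum linear discriminant score.

    Scores use the pooled within-group covariance; ties go to the group
    first seen in the input.  Returns per-observation predictions (indexed
    like the complete rows) and per-group specificity (fraction of the
    group's members allocated back to it).
    """
    sub = data[traits]
    ok = sub.notna().all(axis=1) & groups.notna()
    X = sub[ok].to_numpy(dtype=float)
    g = np.asarray(groups[ok])
    levels = list(pd.unique(g))
    Wm, _ = _scatter(X, g)
    pooled = Wm / (len(X) - len(levels))
    try:
        Sinv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise SingularScatterError(
            f"singular pooled covariance for traits {traits}") from exc
    if priors == "equal":
        log_prior = {lv: 0.0 for lv in levels}
    elif priors == "proportional":
        counts = pd.Series(g).value_counts()
        log_prior = {lv: float(np.log(counts[lv] / len(g))) for lv in levels}
    else:
        raise ValueError("priors must be 'equal' or 'proportional'")
    scores = np.empty((len(X), len(levels)))
    for j, lv in enumerate(levels):
        mu = X[g == lv].mean(axis=0)
        a = Sinv @ mu
        scores[:, j] = X @ a - 0.5 * mu @ a + log_prior[lv]
    # argmax takes the first maximum: tie-break by input group order
    pred = np.asarray(levels, dtype=object)[np.argmax(scores, axis=1)]
    specificity = {
        lv: float(np.mean(pred[g == lv] == lv)) for lv in levels
    }
    return pd.Series(pred, index=sub.index[ok], name="predicted"), specificity


@dataclass
class DiscriminantStep:
    step: int
    trait: str
    wilks_lambda: float
    specificity: dict[str, float]


def forward_select(
    data: pd.DataFrame,
    groups: pd.Series,
    candidates: list[str],
    max_steps: int | None = None,
    priors: str = "equal",
) -> list[DiscriminantStep]:
    """Wilks' Lambda forward selection.

    At each step add the candidate whose inclusion minimises Lambda (ties
    broken by candidate input order); stop at `max_steps`, candidate
    exhaustion, or when every remaining candidate yields a singular scatter.
    """
    if not candidates:
        raise ValueError("no candidate traits")
    selected: list[str] = []
    steps: list[DiscriminantStep] = []
    remaining = list(candidates)
    limit = max_steps if max_steps is not None else len(candidates)
    while remaining and len(steps) < limit:
        best: tuple[float, str] | None = None
        for trait in remaining:
            try:
                lam = wilks_lambda(data, groups, selected + [trait])
            except (SingularScatterError, ValueError):
                continue
            if best is None or lam < best[0] - 1e-15:
                best = (lam, trait)
        if best is None:
            break
        lam, trait = best
        selected.append(trait)
        remaining.remove(trait)
        _, spec = allocate(data, groups, selected, priors=priors)
        steps.append(DiscriminantStep(
            step=len(steps) + 1, trait=trait, wilks_lambda=lam,
            specificity=spec,
        ))
    return steps


@dataclass
class CanonicalProjection:
    scores: pd.DataFrame          # cv1, cv2 (+ group) per observation
    group_means: pd.DataFrame
    circle_radius: dict[str, float]
    polygons: dict[str, np.ndarray]
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def canonical_projection(
    data: pd.DataFrame, groups: pd.Series, traits: list[str]
) -> CanonicalProjection:
    """Project observations on the first two canonical variates.

    Scores are scaled to unit pooled within-group variance, so the 95%
    confidence circle for a group mean has radius
    sqrt(chi2(2 df, 0.95) / n_group); polygons are the convex hulls of each
    group's scores.
    """
    sub = data[traits]
    ok = sub.notna().all(axis=1) & groups.notna()
    X = sub[ok].to_numpy(dtype=float)
    g = np.asarray(groups[ok])
    levels = list(pd.unique(g))
    if len(levels) < 3:
        log.warning("canonical projection with %d groups: only one "
                    "discriminant axis exists", len(levels))
    Wm, Tm = _scatter(X, g)
    Bm = Tm - Wm
    pooled = Wm / (len(X) - len(levels))
    eigvals, eigvecs = linalg.eigh(Bm, pooled)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(2, len(order))
    A = eigvecs[:, order[:n_axes]]
    # eigh(B, pooled) returns vectors with a' pooled a = 1: unit
    # within-group variance on each canonical axis already
    Y = (X - X.mean(axis=0)) @ A
    if n_axes < 2:
        Y = np.column_stack([Y, np.zeros(len(Y))])
    scores = pd.DataFrame(Y, columns=["cv1", "cv2"], index=sub.index[ok])
    scores["group"] = g
    gm = scores.groupby("group")[["cv1", "cv2"]].mean()
    chi2_95 = stats.chi2.ppf(0.95, df=2)
    radius = {
        lv: float(np.sqrt(chi2_95 / (g == lv).sum())) for lv in levels
    }
    polygons: dict[str, np.ndarray] = {}
    for lv in levels:
        pts = Y[g == lv]
        if len(pts) >= 3:
            try:
                hull = ConvexHull(pts)
                polygons[lv] = pts[hull.vertices]
            except QhullError:
                polygons[lv] = pts
        else:
            polygons[lv] = pts
    return CanonicalProjection(
        scores=scores, group_means=gm, circle_radius=radius,
        polygons=polygons, eigenvalues=np.sort(eigvals)[::-1],
    )


def steps_frame(steps: list[DiscriminantStep]) -> pd.DataFrame:
    """Steps as a flat table (step, trait, lambda, specificity per habit)."""
    rows = []
    for s in steps:
        row = {"step": s.step, "trait": s.trait,
               "wilks_lambda": s.wilks_lambda}
        for habit, frac in s.specificity.items():
            row[f"specificity_{habit}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)
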