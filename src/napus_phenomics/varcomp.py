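"""REML variance-component decomposition and genotype means.

Random-effects models of the form

    y = mu + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I)

with crossed and nested categorical terms (nesting written 'a/b/c' expands
to a, a.b, a.b.c).  Estimation is residual maximum likelihood via
Henderson's mixed-model equations: expectation-maximisation warm-up
followed by average-information updates, with EM fallback whenever an AI
step would leave the parameter space.  Negative components are truncated at
zero (the term is effectively removed and the rest refitted; logged).

Genotype means are either arithmetic per-genotype means or generalised
least squares means with genotype fixed and the remaining terms random at
their REML variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger("napus_phenomics")


class RemlError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {"genotype": "genotype_id", "seed_size": "seed_diameter"}


@dataclass
class VarianceModelSpec:
    """Response plus ordered random terms; nesting via '/'.

    term_groups maps expanded term labels to report groups (e.g. all pouch
    design terms to 'experimental'); unmapped terms report under their own
    label.
    """

    response: str
    random_terms: list[str]
    term_groups: dict[str, str] = field(default_factory=dict)

    def expanded_terms(self) -> list[tuple[str, tuple[str, ...]]]:
        out: list[tuple[str, tuple[str, ...]]] = []
        for term in self.random_terms:
            parts = [p.strip() for p in term.split("/")]
            for depth in range(len(parts)):
                label = ".".join(parts[: depth + 1])
                cols = tuple(
                    _COLUMN_ALIASES.get(p, p) for p in parts[: depth + 1]
                )
                out.append((label, cols))
        return out


def root_model_spec(response: str) -> VarianceModelSpec:
    """The seedling screen model:
    (run/frame/column/tray/paper-side) + habit + seed size + genotype."""
    chain = "run/frame/column/tray/paper_side"
    groups = {}
    parts = chain.split("/")
    for depth in range(len(parts)):
        groups[".".join(parts[: depth + 1])] = "experimental"
    return VarianceModelSpec(
        response=response,
        random_terms=[chain, "habit", "seed_size", "genotype"],
        term_groups={**groups, "habit": "habit", "seed_size": "seed_diameter",
                     "genotype": "genotype"},
    )


def composition_model_spec(response: str) -> VarianceModelSpec:
    """The ionomics model:
    habit + genotype + polytunnel + polytunnel/replicate +
    polytunnel/replicate/sub-block."""
    groups = {"polytunnel": "experimental",
              "polytunnel.replicate": "experimental",
              "polytunnel.replicate.sub_block": "experimental",
              "habit": "habit", "genotype": "genotype"}
    return VarianceModelSpec(
        response=response,
        random_terms=["habit", "genotype",
                      "polytunnel/replicate/sub_block"],
        term_groups=groups,
    )


@dataclass
class VarianceDecomposition:
    trait: str
    components: dict[str, float]       # term label -> variance (>= 0)
    residual: float
    n_iter: int
    converged: bool
    truncated: list[str] = field(default_factory=list)
    term_groups: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.components.values()) + self.residual

    def percents(self) -> dict[str, float]:
        """Percent of total variance per term, residual included."""
        total = self.total
        out = {k: 100.0 * v / total for k, v in self.components.items()}
        out["residual"] = 100.0 * self.residual / total
        return out

    def grouped_percents(self) -> dict[str, float]:
        """Percents aggregated to report groups (Table-style layout)."""
        out: dict[str, float] = {}
        for label, pct in self.percents().items():
            group = self.term_groups.get(label, label)
            out[group] = out.get(group, 0.0) + pct
        return out


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def _factor_codes(data: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"factor column '{c}' not in data")
    if len(cols) == 1:
        codes, _ = pd.factorize(data[cols[0]])
    else:
        codes, _ = pd.factorize(pd.MultiIndex.from_frame(data[list(cols)]))
    if (codes < 0).any():
        raise ValueError(f"missing values in factor columns {cols}")
    return codes


def _indicator(codes: np.ndarray) -> sp.csr_matrix:
    n = len(codes)
    q = int(codes.max()) + 1
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q)
    )


def reml_fit(
    y: np.ndarray,
    factors: list[tuple[str, np.ndarray]],
    max_iter: int = 500,
    tol: float = 1e-8,
    n_em_warmup: int = 5,
) -> dict:
    """EM + average-information REML for independent random factors.

    `factors` is a list of (label, integer level codes).  Returns variance
    components, BLUPs, iteration count and convergence flag.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    labels = [lab for lab, _ in factors]
    Zs = [_indicator(codes) for _, codes in factors]
    qs = [Z.shape[1] for Z in Zs]
    for lab, q in zip(labels, qs):
        if q < 2:
            raise RemlError(f"term '{lab}' has fewer than 2 levels")
    K = len(Zs)
    p = 1  # intercept-only fixed part
    Zall = sp.hstack(Zs, format="csr")
    qtot = Zall.shape[1]
    d = p + qtot

    slices = [slice(p + int(np.sum(qs[:k])), p + int(np.sum(qs[: k + 1])))
              for k in range(K)]

    # Normal-equation blocks (constant across iterations)
    A = np.zeros((d, d))
    A[0, 0] = n
    colsum = np.asarray(Zall.sum(axis=0)).ravel()
    A[0, 1:] = colsum
    A[1:, 0] = colsum
    A[1:, 1:] = (Zall.T @ Zall).toarray()
    r = np.empty(d)
    r[0] = y.sum()
    r[1:] = Zall.T @ y
    yy = float(y @ y)

    var_y = float(np.var(y)) or 1.0
    floor = 1e-10 * var_y
    sig = np.full(K, var_y / (2 * max(K, 1)))
    sig_e = var_y / 2.0
    truncated: set[str] = set()

    def mme_inverse(sig, sig_e):
        M = A.copy()
        for k in range(K):
            lam = sig_e / max(sig[k], floor)
            idx = np.arange(slices[k].start, slices[k].stop)
            M[idx, idx] += lam
        try:
            C = np.linalg.inv(M)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RemlError("singular mixed-model equations; terms may be "
                            "confounded") from exc
        return C

    def w_dot(v):
        """[X Z] @ v for the d-vector v."""
        return v[0] + Zall @ v[1:]

    def wt_dot(f):
        """[X Z]' @ f for an n-vector f."""
        out = np.empty(d)
        out[0] = f.sum()
        out[1:] = Zall.T @ f
        return out

    converged = False
    it = 0
    active = np.ones(K, dtype=bool)   # components not truncated at zero
    decreasing = np.zeros(K, dtype=int)
    hist: list[np.ndarray] = []       # recent updates, for Aitken jumps
    theta = np.append(sig, sig_e)
    for it in range(1, max_iter + 1):
        C = mme_inverse(sig, sig_e)
        sol = C @ r
        resid = y - w_dot(sol)
        sse = float(resid @ resid)
        uu = np.array([float(sol[slices[k]] @ sol[slices[k]]) for k in range(K)])
        trC = np.array([float(np.trace(C[slices[k], slices[k]]))
                        for k in range(K)])
        lam = sig_e / np.maximum(sig, floor)

        new_sig = sig.copy()
        em_sig = (uu + sig_e * trC) / np.array(qs)
        em_sig_e = (yy - float(r @ sol)) / (n - p)
        act = np.where(active)[0]
        new_sig[act] = np.maximum(em_sig[act], floor)
        new_sig_e = em_sig_e
        if it > n_em_warmup and len(act):
            # Average-information step over the active components + residual;
            # element-wise EM fallback where AI would leave the parameter
            # space (standard near-boundary practice).
            s = np.empty(len(act) + 1)
            tr_p_g = (np.array(qs) - lam * trC) / np.maximum(sig, floor)
            s[:-1] = -0.5 * (tr_p_g[act] - uu[act] / np.maximum(sig[act], floor) ** 2)
            tr_p = (n - p - np.sum(np.array(qs) - lam * trC)) / sig_e
            s[-1] = -0.5 * (tr_p - sse / sig_e**2)
            F = np.empty((n, len(act) + 1))
            for j, k in enumerate(act):
                F[:, j] = Zs[k] @ (sol[slices[k]] / max(sig[k], floor))
            F[:, -1] = resid / sig_e
            PF = np.empty_like(F)
            for j in range(F.shape[1]):
                f = F[:, j]
                solf = C @ wt_dot(f)
                PF[:, j] = (f - w_dot(solf)) / sig_e
            AI = 0.5 * (F.T @ PF)
            try:
                delta = np.linalg.solve(AI, s)
                cand = np.append(sig[act], sig_e) + delta
                for j, k in enumerate(act):
                    if cand[j] > floor:
                        new_sig[k] = cand[j]
                if cand[-1] > floor:
                    new_sig_e = float(cand[-1])
            except np.linalg.LinAlgError:
                pass  # keep the EM update

        # EM converges linearly; periodically extrapolate each component's
        # geometric tail (Aitken) so near-boundary terms do not crawl.
        hist.append(new_sig.copy())
        if len(hist) > 3:
            hist.pop(0)
        if it > n_em_warmup and it % 4 == 0 and len(hist) == 3:
            s0, s1, s2 = hist
            for k in act:
                d1, d2 = s1[k] - s0[k], s2[k] - s1[k]
                if d1 != 0 and d2 != 0 and np.sign(d1) == np.sign(d2):
                    ratio = d2 / d1
                    if 0.0 < ratio < 0.999:
                        new_sig[k] = max(s2[k] + d2 * ratio / (1 - ratio),
                                         floor)
            hist.clear()

        # Truncation at the zero boundary: pin the component and refit the
        # remaining terms with it effectively removed.  A component is
        # boundary-bound when it is negligible (< 1e-6 of the trait
        # variance) or when it shrinks monotonically while already below
        # 0.3% of the trait variance (the slow geometric EM tail towards
        # zero; well below the integer-percent reporting precision).
        for k in act:
            shrinking = new_sig[k] < sig[k] and new_sig[k] < 3e-3 * var_y
            decreasing[k] = decreasing[k] + 1 if shrinking else 0
            if new_sig[k] <= max(2 * floor, 1e-6 * var_y) or decreasing[k] >= 10:
                new_sig[k] = floor
                active[k] = False
                if labels[k] not in truncated:
                    truncated.add(labels[k])
                    log.info("variance component '%s' truncated at zero",
                             labels[k])
        new_theta = np.append(new_sig, new_sig_e)
        # Convergence is judged on components large enough to matter for the
        # decomposition (> 0.01% of the trait variance) plus the residual.
        moved = np.append(active & (new_sig > 1e-4 * var_y), True)
        change = np.max(np.abs(new_theta[moved] - theta[moved])
                        / (np.abs(theta[moved]) + 1e-8 * var_y))
        sig, sig_e, theta = new_sig, float(new_sig_e), new_theta
        if change < tol:
            converged = True
            break

    if not converged:
        raise RemlError(
            f"REML did not converge in {max_iter} iterations "
            f"(last components {dict(zip(labels, sig))}, "
            f"residual {sig_e:.6g})"
        )
    sig = np.where(sig <= 2 * floor, 0.0, sig)
    C = mme_inverse(np.maximum(sig, floor), sig_e)
    sol = C @ r
    blups = {labels[k]: sol[slices[k]].copy() for k in range(K)}
    return {
        "components": dict(zip(labels, map(float, sig))),
        "residual": float(sig_e),
        "n_iter": it,
        "converged": converged,
        "truncated": sorted(truncated),
        "blups": blups,
        "intercept": float(sol[0]),
    }


def fit_varcomp(
    data: pd.DataFrame,
    spec: VarianceModelSpec,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VarianceDecomposition:
    """Fit the REML decomposition of `spec.response` over `data`."""
    sub = data.dropna(subset=[spec.response])
    y = sub[spec.response].to_numpy(dtype=float)
    factors = [(label, _factor_codes(sub, cols))
               for label, cols in spec.expanded_terms()]
    fit = reml_fit(y, factors, max_iter=max_iter, tol=tol)
    return VarianceDecomposition(
        trait=spec.response,
        components=fit["components"],
        residual=fit["residual"],
        n_iter=fit["n_iter"],
        converged=fit["converged"],
        truncated=fit["truncated"],
        term_groups=dict(spec.term_groups),
    )


# ---------------------------------------------------------------------------
# Genotype means
# ---------------------------------------------------------------------------

def genotype_means(
    data: pd.DataFrame,
    spec: VarianceModelSpec,
    method: str = "fixed_genotype_model",
) -> pd.Series:
    """Per-genotype means for one trait.

    'arithmetic_mean': plain means ignoring design.  'fixed_genotype_model':
    genotype enters as a fixed factor and the remaining random terms keep
    their REML variances (generalised least squares means).
    """
    sub = data.dropna(subset=[spec.response])
    geno_col = "genotype_id" if "genotype_id" in sub.columns else "genotype"
    if method == "arithmetic_mean":
        means = sub.groupby(geno_col)[spec.response].mean()
        means.index.name = "genotype_id"
        return means
    if method != "fixed_genotype_model":
        raise ValueError(f"unknown method '{method}'")

    fit = fit_varcomp(sub, spec)
    y = sub[spec.response].to_numpy(dtype=float)
    n = len(y)
    g_codes, g_levels = pd.factorize(sub[geno_col])
    G = len(g_levels)
    X = _indicator(g_codes)  # cell-means coding, no intercept

    terms = [(label, cols) for label, cols in spec.expanded_terms()
             if "genotype" not in label.split(".")]
    Zs, lams, qs = [], [], []
    var_y = float(np.var(y)) or 1.0
    for label, cols in terms:
        variance = fit.components.get(label, 0.0)
        if variance <= 1e-10 * var_y:
            continue  # truncated terms drop out of the GLS structure
        codes = _factor_codes(sub, cols)
        Zs.append(_indicator(codes))
        qs.append(Zs[-1].shape[1])
        lams.append(fit.residual / variance)

    if not Zs:
        means = sub.groupby(geno_col)[spec.response].mean()
        means.index.name = "genotype_id"
        return means

    W = sp.hstack([X] + Zs, format="csr")
    M = (W.T @ W).toarray()
    offset = G
    for lam, q in zip(lams, qs):
        idx = np.arange(offset, offset + q)
        M[idx, idx] += lam
        offset += q
    rhs = W.T @ y
    sol = np.linalg.solve(M, rhs)
    means = pd.Series(sol[:G], index=pd.Index(g_levels, name="genotype_id"),
                      name=spec.response)
    return means.sort_index()
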