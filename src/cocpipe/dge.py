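"""Pseudo-bulk negative-binomial differential expression and shared tests.

The centerpiece is a gene-wise NB generalized linear model with a log link
and size-factor offsets, fitted by iteratively reweighted least squares and
tested with two-tailed Wald statistics. It is a deliberately simplified
scheme — no outlier replacement, no independent filtering, a single
moderation step for dispersions — aimed at calibrated calls on pseudo-bulk
replicates rather than bit-compatibility with any particular package.

Dispersion: a residual method-of-moments estimate from a Poisson pre-fit
(df = samples - parameters), floored and then shrunk halfway toward a fitted
a0 + a1/mean trend across genes. This works for any full-rank design,
including designs with per-mouse covariates where no two samples share a
design row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, renormalized to geometric mean 1.

    Genes with any zero count are excluded from the median. If no gene is
    positive in all samples, fall back to total-count ratios (with a warning).
    """
    values = cm.values if isinstance(cm, CountMatrix) else cm
    v = values.to_numpy(float)
    if v.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    allpos = (v > 0).all(axis=1)
    if allpos.any():
        logs = np.log(v[allpos])
        geo_mean = np.exp(logs.mean(axis=1))
        sf = np.median(v[allpos] / geo_mean[:, None], axis=0)
    else:
        warnings.warn("no gene positive in all samples; using total-count size factors")
        totals = v.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = totals / totals.mean()
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=values.columns, name="size_factor")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Age x treatment interaction design built from sample conditions.

    Columns: intercept, age_old, treat_super, age_old:treat_super. Default
    contrasts express superovulation within young (the treatment coefficient),
    superovulation within old (treatment + interaction), aging within natural
    (the age coefficient), and the interaction itself.
    """

    matrix: pd.DataFrame
    contrasts: dict[str, np.ndarray]

    @classmethod
    def from_conditions(cls, conditions: pd.Series) -> "DesignSpec":
        cond = conditions.astype(str)
        bad = set(cond) - {"NY", "SY", "NO", "SO"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        old = cond.isin(("NO", "SO")).astype(float)
        sup = cond.isin(("SY", "SO")).astype(float)
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "age_old": old,
                "treat_super": sup,
                "age_old:treat_super": old * sup,
            },
            index=cond.index,
        )
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("design not full rank on provided samples")
        contrasts = {
            "super_young": np.array([0.0, 0.0, 1.0, 0.0]),
            "super_old": np.array([0.0, 0.0, 1.0, 1.0]),
            "aging_natural": np.array([0.0, 1.0, 0.0, 0.0]),
            "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
        }
        return cls(X, contrasts)

    @classmethod
    def two_group(cls, groups: pd.Series, contrast_name: str = "group") -> "DesignSpec":
        """Plain two-group design (intercept + group indicator)."""
        levels = sorted(groups.astype(str).unique())
        if len(levels) != 2:
            raise ValueError("exactly two group levels required")
        X = pd.DataFrame(
            {"intercept": 1.0, "group": (groups.astype(str) == levels[1]).astype(float)},
            index=groups.index,
        )
        return cls(X, {contrast_name: np.array([0.0, 1.0])})


def design_with_covariate(
    groups: pd.Series, covariate: pd.Series, contrast_name: str = "group"
) -> DesignSpec:
    """Two-group design plus a categorical covariate (e.g. mouse of origin).

    Covariate dummy columns that would make the design rank-deficient are
    dropped. The contrast tests the group coefficient.
    """
    levels = sorted(groups.astype(str).unique())
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    X = pd.DataFrame({"intercept": 1.0, "group": (groups.astype(str) == levels[1]).astype(float)},
                     index=groups.index)
    dummies = pd.get_dummies(covariate.astype(str), prefix="cov", drop_first=True).astype(float)
    for col in dummies.columns:
        cand = pd.concat([X, dummies[[col]]], axis=1)
        if np.linalg.matrix_rank(cand.to_numpy()) == cand.shape[1]:
            X = cand
    c = np.zeros(X.shape[1])
    c[list(X.columns).index("group")] = 1.0
    return DesignSpec(X, {contrast_name: c})


# ---------------------------------------------------------------------------
# NB GLM via batched IRLS
# ---------------------------------------------------------------------------

def _irls(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
    max_iter: int = 50, tol: float = 1e-8, ridge: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-link NB GLMs for all genes at once.

    Returns (beta, covariance, converged) with shapes (G, p), (G, p, p), (G,).
    ``alpha`` is the per-gene dispersion (0 = Poisson).
    """
    G, n = Y.shape
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    z0 = np.log(np.maximum(Y, 0) + 0.5) - offset[None, :]
    beta = z0 @ pinv.T
    eye = ridge * np.eye(p)
    converged = np.zeros(G, bool)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
        XtWz = np.einsum("np,gn,gn->gp", X, W, z, optimize=True)
        new = np.linalg.solve(XtWX + eye[None], XtWz[..., None])[..., 0]
        step = np.abs(new - beta).max(axis=1)
        beta = new
        converged = step < tol
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("np,gn,nq->gpq", X, W, X, optimize=True)
    cov = np.linalg.inv(XtWX + eye[None])
    return beta, cov, converged


def _dispersion_trend(disp: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Fit disp ~ a0 + a1/mean by non-negative least squares across genes."""
    ok = (base_mean > 0) & np.isfinite(disp)
    if ok.sum() < 10:
        med = float(np.median(disp[ok])) if ok.any() else 0.1
        return np.full_like(disp, max(med, 1e-8))
    A = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    coef, _ = optimize.nnls(A, disp[ok])
    trend = coef[0] + coef[1] / np.maximum(base_mean, 1e-8)
    return np.maximum(trend, 1e-8)


def nb_wald(
    cm: CountMatrix | pd.DataFrame,
    design: DesignSpec,
    sf: pd.Series | None = None,
    dispersion_floor: float = 1e-8,
    moderation_weight: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Gene-wise NB Wald tests for every contrast of ``design``.

    Returns one DataFrame per contrast with columns baseMean, log2FC, lfcSE,
    stat, pvalue, padj (Benjamini-Hochberg within the contrast, NA p values
    dropped from the denominator) and a ``flag`` column marking degenerate or
    non-converged genes.
    """
    values = cm.values if isinstance(cm, CountMatrix) else cm
    X = design.matrix.loc[values.columns].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than samples")
    Y = values.to_numpy(float)
    if sf is None:
        sf = size_factors(values)
    sfv = sf.loc[values.columns].to_numpy(float)
    offset = np.log(sfv)
    norm = Y / sfv[None, :]
    base_mean = norm.mean(axis=1)

    nonzero = Y.sum(axis=1) > 0
    constant = np.array([len(np.unique(row)) == 1 for row in Y])
    fit_mask = nonzero & ~constant

    G = Y.shape[0]
    lfc = np.full((G, len(design.contrasts)), 0.0)
    se = np.full((G, len(design.contrasts)), np.nan)
    stat = np.full((G, len(design.contrasts)), np.nan)
    pval = np.full((G, len(design.contrasts)), np.nan)
    flag = np.where(constant, "degenerate", np.where(~nonzero, "all_zero", ""))
    flag = flag.astype(object)
    pval[constant & nonzero] = 1.0

    if fit_mask.any():
        Yf = Y[fit_mask]
        # Poisson pre-fit for residual-based dispersion
        beta0, _, _ = _irls(Yf, X, offset, np.zeros(fit_mask.sum()))
        mu0 = np.exp(np.clip(beta0 @ X.T + offset[None, :], -30, 30))
        resid = ((Yf - mu0) ** 2 - mu0) / mu0**2
        disp_raw = np.maximum(resid.sum(axis=1) / (n - p), dispersion_floor)
        trend = _dispersion_trend(disp_raw, base_mean[fit_mask])
        disp = np.maximum(
            moderation_weight * disp_raw + (1 - moderation_weight) * trend, dispersion_floor
        )
        beta, cov, converged = _irls(Yf, X, offset, disp)
        for k, (name, c) in enumerate(design.contrasts.items()):
            est = beta @ c
            var = np.einsum("p,gpq,q->g", c, cov, c)
            s = np.sqrt(np.maximum(var, 1e-300))
            z = est / s
            lfc[fit_mask, k] = est / _LN2
            se[fit_mask, k] = s / _LN2
            stat[fit_mask, k] = z
            pval[fit_mask, k] = 2.0 * stats.norm.sf(np.abs(z))
        pval[fit_mask] = np.where(converged[:, None], pval[fit_mask], np.nan)
        idx = np.flatnonzero(fit_mask)
        for i in idx[~converged]:
            flag[i] = "not_converged"

    out = {}
    for k, name in enumerate(design.contrasts):
        df = pd.DataFrame(
            {
                "baseMean": base_mean,
                "log2FC": lfc[:, k],
                "lfcSE": se[:, k],
                "stat": stat[:, k],
                "pvalue": pval[:, k],
                "padj": adjust_bh(pval[:, k]),
                "flag": flag,
            },
            index=values.index,
        )
        out[name] = df
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def _adjust(p, method: str) -> np.ndarray:
    arr = np.asarray(p, float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method=method)[1]
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaNs propagate and shrink the family size."""
    return _adjust(p, "fdr_bh")


def adjust_holm(p) -> np.ndarray:
    """Holm step-down; NaNs propagate and shrink the family size."""
    return _adjust(p, "holm")


# ---------------------------------------------------------------------------
# over-representation and rank tests
# ---------------------------------------------------------------------------

def ora(hits: set, universe: set, pathway: set) -> dict:
    """Upper-tail hypergeometric over-representation of ``pathway`` in ``hits``."""
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & set(universe)
    pathway = set(pathway) & set(universe)
    overlap = len(hits & pathway)
    N, K, n = len(universe), len(pathway), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    return {"overlap": overlap, "pathway_size": K, "hits": n, "universe": N, "p": min(p, 1.0)}


def rank_test_two_sided(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact distribution when n + m <= 20 and there are no ties; otherwise the
    normal approximation with tie correction. Degenerate all-identical input
    gives p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 20) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
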