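"""Developmental marker selection and principal-curve embryo pseudotime.

Marker genes are selected from a staged pre-implantation reference (2-cell to
blastocyst) by three criteria: membership in the highly variable set, a
strong Spearman correlation with stage, and large same-direction fold changes
across the 8-cell-to-morula and morula-to-blastocyst transitions. Embryos are
then ordered by projecting them onto a principal curve fitted in PCA space of
the marker panel; pseudotime is the normalized arc-length position, oriented
so the earliest reference stage maps near 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ccc import pca_embed
from .dge import adjust_bh, rank_test_two_sided

STAGES = ("2cell", "4cell", "8cell", "morula", "blastocyst")
STAGE_SCORE = {s: i + 1 for i, s in enumerate(STAGES)}


@dataclass
class DevGenePanel:
    table: pd.DataFrame  # gene, rho, padj, lfc_8cell_morula, lfc_morula_blastocyst, direction

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def select_dev_genes(
    ref_expr: pd.DataFrame,
    stages: pd.Series,
    hvg_frac: float = 0.3,
    rho_min: float = 0.85,
    padj_max: float = 0.01,
    lfc_min: float = 1.0,
) -> DevGenePanel:
    """Select monotone stage-marker genes from the staged reference.

    ``ref_expr`` is log-normalized expression (genes x embryos); ``stages``
    holds each embryo's stage label. Criteria: (i) the gene is within the top
    ``hvg_frac`` most variable genes, (ii) |Spearman rho| between expression
    and the ordinal stage exceeds ``rho_min`` at BH-adjusted p below
    ``padj_max``, (iii) the 8-cell-to-morula and morula-to-blastocyst log2
    fold changes both exceed ``lfc_min`` in magnitude and share the sign of
    rho.
    """
    stages = stages.loc[ref_expr.columns].astype(str)
    score = stages.map(STAGE_SCORE)
    if score.isna().any():
        raise ValueError("unknown stage labels")
    if (stages.value_counts().reindex(STAGES).fillna(0) < 2).any():
        raise ValueError("need >= 2 embryos per stage")

    variances = ref_expr.var(axis=1)
    n_hvg = max(1, int(round(hvg_frac * len(variances))))
    hvg = set(variances.sort_values(ascending=False).index[:n_hvg])

    v = ref_expr.to_numpy(float)
    rho = np.zeros(v.shape[0])
    pval = np.ones(v.shape[0])
    sc = score.to_numpy(float)
    for i in range(v.shape[0]):
        if np.unique(v[i]).size == 1:
            rho[i], pval[i] = 0.0, 1.0
        else:
            r, p = stats.spearmanr(v[i], sc)
            rho[i], pval[i] = r, p
    padj = adjust_bh(pval)

    means = {s: ref_expr[stages.index[stages == s]].mean(axis=1) for s in STAGES}
    lfc1 = (means["morula"] - means["8cell"]).to_numpy()
    lfc2 = (means["blastocyst"] - means["morula"]).to_numpy()

    keep = []
    for i, g in enumerate(ref_expr.index):
        if g not in hvg:
            continue
        if not (abs(rho[i]) > rho_min and padj[i] < padj_max):
            continue
        if not (abs(lfc1[i]) > lfc_min and abs(lfc2[i]) > lfc_min):
            continue
        s = np.sign(rho[i])
        if not (np.sign(lfc1[i]) == s and np.sign(lfc2[i]) == s):
            continue
        keep.append(i)
    if not keep:
        raise ValueError("no genes pass the developmental selection criteria")
    table = pd.DataFrame(
        {
            "rho": rho[keep],
            "padj": padj[keep],
            "lfc_8cell_morula": lfc1[keep],
            "lfc_morula_blastocyst": lfc2[keep],
            "direction": np.where(rho[keep] > 0, "up", "down"),
        },
        index=ref_expr.index[keep],
    )
    return DevGenePanel(table)


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series        # per embryo, in [0, 1]
    curve: np.ndarray            # curve control points in PC space
    pc_scores: pd.DataFrame
    converged: bool


def _smooth_against_arclength(coord: np.ndarray, order: np.ndarray, span: float) -> np.ndarray:
    """Local-averaging smoother with a fixed span along the current ordering."""
    n = len(coord)
    half = max(1, int(round(span * n / 2)))
    sm = np.empty(n)
    for k in range(n):
        lo, hi = max(0, k - half), min(n, k + half + 1)
        sm[k] = coord[order[lo:hi]].mean()
    return sm


def _project_to_polyline(points: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; return arc-length positions and distances.

    The first and last segments are extended linearly (as spanned-smoother
    principal curves do), so points beyond the smoothed endpoints keep exact
    positions instead of piling up at the ends.
    """
    seg = np.diff(curve, axis=0)                       # (m-1, d)
    seg_len = np.linalg.norm(seg, axis=1)
    seg_len2 = np.maximum((seg**2).sum(axis=1), 1e-300)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # t of the projection of every point on every segment
    diff = points[:, None, :] - curve[None, :-1, :]    # (n, m-1, d)
    t = (diff * seg[None]).sum(axis=2) / seg_len2[None]
    lo = np.zeros(len(seg))
    hi = np.ones(len(seg))
    lo[0], hi[-1] = -1e12, 1e12
    t = np.clip(t, lo[None, :], hi[None, :])
    proj = curve[None, :-1, :] + t[..., None] * seg[None]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    n = len(points)
    lam = cum[best] + t[np.arange(n), best] * seg_len[best]
    dist = np.sqrt(d2[np.arange(n), best])
    return lam, dist


def principal_curve_pseudotime(
    X: pd.DataFrame,
    n_pcs: int = 3,
    ref_stages: pd.Series | None = None,
    span: float = 0.6,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> PseudotimeResult:
    """Fit an iterative principal curve in PCA space and order embryos on it.

    ``X`` is embryos x panel-gene expression. The curve is initialized at the
    first principal component, then alternates projecting points to the
    current curve and smoothing each PC coordinate against the arc-length
    ordering (local averaging, fixed span) until the mean projection distance
    changes by less than ``tol`` or ``max_iter`` iterations. For collinear
    data the smoothed curve stays on the line, so pseudotime reduces exactly
    to the least-squares line projection. Orientation: if reference stages
    are supplied, pseudotime is flipped so the earliest stage has the lower
    mean; otherwise the orientation of PC1 is kept.
    """
    if X.shape[0] < 5:
        raise ValueError("need at least 5 embryos")
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    scores, _, _ = pca_embed(X, n_pcs=n_pcs)
    Z = scores.to_numpy(float)
    lam = Z[:, 0].copy()
    prev_dist = np.inf
    converged = False
    curve = None
    for _ in range(max_iter):
        order = np.argsort(lam, kind="stable")
        curve = np.column_stack(
            [_smooth_against_arclength(Z[:, j], order, span) for j in range(Z.shape[1])]
        )
        lam, dist = _project_to_polyline(Z, curve)
        mean_dist = float(dist.mean())
        if abs(prev_dist - mean_dist) < tol:
            converged = True
            break
        prev_dist = mean_dist
    rng = lam.max() - lam.min()
    pt = (lam - lam.min()) / rng if rng > 0 else np.zeros_like(lam)
    pt_series = pd.Series(pt, index=X.index, name="pseudotime")
    if ref_stages is not None:
        labeled = ref_stages.dropna()
        labeled = labeled[labeled.astype(str).isin(STAGES)]
        early = labeled.index[labeled.astype(str) == STAGES[0]]
        late = labeled.index[labeled.astype(str) == STAGES[-1]]
        if len(early) and len(late):
            if pt_series[early].mean() > pt_series[late].mean():
                pt_series = 1.0 - pt_series
    return PseudotimeResult(pt_series, curve, scores, converged)


def compare_groups(pt: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided rank tests on pseudotime between groups.

    Returns one row per unordered group pair with both medians and the p value.
    """
    groups = groups.loc[pt.index].astype(str)
    levels = list(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    counts = groups.value_counts()
    if (counts < 3).any():
        raise ValueError("each group needs >= 3 members")
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            xa = pt[groups.index[groups == a]].to_numpy()
            xb = pt[groups.index[groups == b]].to_numpy()
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                    "p": rank_test_two_sided(xa, xb),
                }
            )
    return pd.DataFrame(rows)
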