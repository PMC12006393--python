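"""Expression-variability (Shannon entropy) analysis and the
aging x superovulation non-additivity decomposition.

Per-gene variability is a normalized Shannon entropy of the expression values
binned into equal-width bins over the observed range: 0 means all samples in
one bin (no variability), 1 means uniform occupancy of all bins. Differential
entropy (dShE) between two conditions is tested by label permutation.

The non-additivity decomposition projects old samples onto a PCA fitted on
young samples restricted to superovulation-responsive genes; group mean
positions on PC1 define the superovulation shifts within young and old and
their difference — the interaction effect. Confidence intervals come from a
mouse-level bootstrap, treating samples from one animal as replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._random import stream
from .dge import adjust_bh

logger = logging.getLogger(__name__)


def _bin_indices(values: np.ndarray, n_bins: int,
                 lo: np.ndarray | None = None, hi: np.ndarray | None = None) -> np.ndarray:
    """Equal-width bin index per entry; rows with zero width map to bin 0."""
    if lo is None:
        lo = values.min(axis=1, keepdims=True)
    if hi is None:
        hi = values.max(axis=1, keepdims=True)
    width = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.floor((values - lo) / np.where(width > 0, width, 1.0) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _entropy_from_indices(idx: np.ndarray, n_bins: int) -> np.ndarray:
    G, n = idx.shape
    counts = np.zeros((G, n_bins))
    rows = np.repeat(np.arange(G), n)
    np.add.at(counts, (rows, idx.ravel()), 1.0)
    p = counts / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1) / np.log2(n_bins)


def _entropy_rows(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Normalized Shannon entropy per row of a (genes x samples) block."""
    flat = values.max(axis=1) - values.min(axis=1) <= 0
    ent = _entropy_from_indices(_bin_indices(values, n_bins), n_bins)
    ent[flat] = 0.0
    return ent


def gene_entropy(values, n_bins: int = 10) -> float:
    """Normalized Shannon entropy of one gene's expression values.

    Equal-width bins over [min, max] (bins track the range, so the measure is
    invariant to affine transforms); all-identical values give 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.asarray(values, float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    return float(_entropy_rows(v[None, :], n_bins)[0])


def diff_entropy(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    n_bins: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    shared_bins: bool = True,
) -> pd.DataFrame:
    """Per-gene differential Shannon entropy dShE = ShE_A - ShE_B.

    With ``shared_bins`` (default) both conditions are binned on one
    equal-width grid spanning the pooled range of the gene, so a condition
    with wider spread occupies more bins and scores higher — the property
    that makes dShE a variability difference rather than a shape-only
    difference. With ``shared_bins=False`` each condition tracks its own
    range (affine-invariant per condition).

    P values come from a label-permutation null of |dShE| (the pooled bin
    grid is permutation-invariant, so binning is done once), BH-adjusted
    across genes. Genes that are all-zero in both conditions are excluded
    (logged).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = expr_a.index.intersection(expr_b.index)
    A = expr_a.loc[genes].to_numpy(float)
    B = expr_b.loc[genes].to_numpy(float)
    if A.shape[1] < 5 or B.shape[1] < 5:
        raise ValueError("each condition needs >= 5 samples")
    nonzero = ~((A == 0).all(axis=1) & (B == 0).all(axis=1))
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("diff_entropy: %d all-zero genes excluded", dropped)
    A, B = A[nonzero], B[nonzero]
    genes = genes[nonzero]
    na = A.shape[1]
    pooled = np.concatenate([A, B], axis=1)

    if shared_bins:
        lo = pooled.min(axis=1, keepdims=True)
        hi = pooled.max(axis=1, keepdims=True)
        idx = _bin_indices(pooled, n_bins, lo, hi)

        def dshe(cols_a: np.ndarray, cols_b: np.ndarray) -> np.ndarray:
            return (_entropy_from_indices(idx[:, cols_a], n_bins)
                    - _entropy_from_indices(idx[:, cols_b], n_bins))
    else:

        def dshe(cols_a: np.ndarray, cols_b: np.ndarray) -> np.ndarray:
            return (_entropy_rows(pooled[:, cols_a], n_bins)
                    - _entropy_rows(pooled[:, cols_b], n_bins))

    cols = np.arange(pooled.shape[1])
    obs = dshe(cols[:na], cols[na:])
    flat = pooled.max(axis=1) - pooled.min(axis=1) <= 0
    obs[flat] = 0.0
    she_a = _entropy_rows(A, n_bins) if not shared_bins else _entropy_from_indices(idx[:, :na], n_bins)
    she_b = _entropy_rows(B, n_bins) if not shared_bins else _entropy_from_indices(idx[:, na:], n_bins)

    rng = stream(seed, "diff_entropy")
    exceed = np.zeros(len(genes))
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[1])
        exceed += np.abs(dshe(perm[:na], perm[na:])) >= np.abs(obs) - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    out = pd.DataFrame(
        {"ShE_A": she_a, "ShE_B": she_b, "dShE": obs, "p": p},
        index=genes,
    )
    out["padj"] = adjust_bh(out["p"].to_numpy())
    return out


@dataclass
class ShiftDecomposition:
    """Group mean PC1 positions and the derived effects with bootstrap CIs.

    ``effects`` holds super_young = SY - NY, super_old = SO - NO,
    aging_natural = NO - NY, aging_super = SO - SY and
    interaction = super_old - super_young (the non-additivity of aging and
    superovulation); the identity holds exactly by construction.
    """

    loadings: pd.Series
    group_means: dict[str, float]
    effects: dict[str, float]
    ci: dict[str, tuple[float, float]] | None
    n_boot: int


def fit_projection(
    expr: pd.DataFrame,
    de_genes: list[str],
    meta: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ShiftDecomposition:
    """Project all four condition groups onto young superovulation-responsive PC1.

    PCA is fitted on the young samples (NY, SY) restricted to ``de_genes``
    (centered on young means); all samples are projected with the same
    centering and loadings. PC1 is oriented so mean(SY) > mean(NY). Bootstrap
    resamples mice within each condition with replacement; if any condition
    has fewer than 2 mice the CIs are omitted.
    """
    meta = meta.loc[expr.columns]
    missing = [g for g in de_genes if g not in expr.index]
    if missing:
        raise ValueError(f"{len(missing)} de_genes absent from expression matrix")
    for cond in ("NY", "SY", "NO", "SO"):
        if not (meta.condition == cond).any():
            raise ValueError(f"condition {cond} missing")

    sub = expr.loc[de_genes]
    young_cols = meta.index[meta.condition.isin(("NY", "SY"))]
    young = sub[young_cols].to_numpy(float)
    center = young.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd((young - center).T, full_matrices=False)
    pc1 = Vt[0]

    scores = pd.Series(((sub.to_numpy(float) - center).T @ pc1), index=expr.columns)
    if scores[meta.index[meta.condition == "SY"]].mean() < scores[
        meta.index[meta.condition == "NY"]
    ].mean():
        pc1 = -pc1
        scores = -scores

    def effects_from_means(gm: dict[str, float]) -> dict[str, float]:
        return {
            "super_young": gm["SY"] - gm["NY"],
            "super_old": gm["SO"] - gm["NO"],
            "aging_natural": gm["NO"] - gm["NY"],
            "aging_super": gm["SO"] - gm["SY"],
            "interaction": (gm["SO"] - gm["NO"]) - (gm["SY"] - gm["NY"]),
        }

    group_means = {c: float(scores[meta.index[meta.condition == c]].mean())
                   for c in ("NY", "SY", "NO", "SO")}
    effects = effects_from_means(group_means)

    # mouse-level bootstrap on the fixed projection
    mice_by_cond = {
        c: meta.loc[meta.condition == c, "mouse_id"].unique() for c in ("NY", "SY", "NO", "SO")
    }
    if any(len(m) < 2 for m in mice_by_cond.values()) or n_boot <= 0:
        ci = None
        n_boot_used = 0
    else:
        rng = stream(seed, "projection_bootstrap")
        mouse_mean = scores.groupby(meta["mouse_id"]).mean()
        boot_effects: dict[str, np.ndarray] = {k: np.empty(n_boot) for k in effects}
        cond_means = np.empty((n_boot, 4))
        for ci_idx, cond in enumerate(("NY", "SY", "NO", "SO")):
            mice = mice_by_cond[cond]
            vals = mouse_mean.loc[mice].to_numpy()
            draw = rng.integers(0, len(mice), size=(n_boot, len(mice)))
            cond_means[:, ci_idx] = vals[draw].mean(axis=1)
        gm_boot = {c: cond_means[:, i] for i, c in enumerate(("NY", "SY", "NO", "SO"))}
        for k in effects:
            boot_effects[k] = effects_from_means(gm_boot)[k]
        a = (1 - ci_level) / 2
        ci = {
            k: (float(np.quantile(v, a)), float(np.quantile(v, 1 - a)))
            for k, v in boot_effects.items()
        }
        n_boot_used = n_boot

    return ShiftDecomposition(
        loadings=pd.Series(pc1, index=de_genes),
        group_means=group_means,
        effects=effects,
        ci=ci,
        n_boot=n_boot_used,
    )
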