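"""Ligand-receptor cell-cell communication scoring within paired COCs.

A communication score for a ligand-receptor pair is the product of the
ligand's expression in the sender cell and the receptor's expression in the
receiver cell; for multi-subunit receptors only the least expressed subunit
counts. Each COC contributes one oocyte expression vector and one granulosa
vector, and communication is scored in four directions: oocyte-to-granulosa,
granulosa-to-oocyte, and the two autocrine directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .dge import adjust_holm

logger = logging.getLogger(__name__)

DIRECTIONS = ("OC->GC", "GC->OC", "GC->GC", "OC->OC")


@dataclass(frozen=True)
class LRPair:
    pair_id: str
    ligand: str
    receptor_subunits: tuple[str, ...]
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.receptor_subunits:
            raise ValueError(f"pair {self.pair_id}: empty subunit list")


def load_lr_table(table: pd.DataFrame) -> list[LRPair]:
    """Parse a pair table with semicolon-separated receptor subunits."""
    pairs = []
    for _, row in table.iterrows():
        pairs.append(
            LRPair(
                pair_id=str(row.get("pair_id", f"{row['ligand']}->{row['receptor_subunits']}")),
                ligand=str(row["ligand"]),
                receptor_subunits=tuple(str(row["receptor_subunits"]).split(";")),
                annotation=str(row.get("annotation", "")),
            )
        )
    return pairs


def top_expressed_lr(
    db: list[LRPair],
    ligand_expr_mean: pd.Series,
    receptor_expr_mean: pd.Series,
    k: int = 100,
) -> list[LRPair]:
    """Keep pairs whose ligand and receptor rank in the top-k expressed genes.

    Ligand genes are ranked by mean expression in the sender cell type and
    receptor genes by mean expression in the receiver cell type, each within
    the genes that actually play that role in ``db``. A multi-subunit
    receptor is represented by its least expressed subunit. Ties break by
    gene id (lexicographic), so the filter is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    usable = [
        p for p in db
        if p.ligand in ligand_expr_mean.index
        and all(s in receptor_expr_mean.index for s in p.receptor_subunits)
    ]
    skipped = len(db) - len(usable)
    if skipped:
        logger.info("top_expressed_lr: %d pairs skipped (genes missing)", skipped)

    ligands = sorted({p.ligand for p in usable})
    rep = {p.pair_id: min(p.receptor_subunits, key=lambda s: (receptor_expr_mean[s], s))
           for p in usable}
    receptors = sorted(set(rep.values()))

    def topk(genes: list[str], expr: pd.Series) -> set[str]:
        expressed = [g for g in genes if expr[g] > 0]  # never-expressed genes cannot rank
        ranked = sorted(expressed, key=lambda g: (-expr[g], g))
        return set(ranked[:k])

    lig_top = topk(ligands, ligand_expr_mean)
    rec_top = topk(receptors, receptor_expr_mean)
    return [p for p in usable if p.ligand in lig_top and rep[p.pair_id] in rec_top]


def interaction_score(
    sender_expr: pd.Series, receiver_expr: pd.Series, pair: LRPair
) -> float:
    """Ligand expression (sender) x least-expressed-subunit expression (receiver)."""
    if pair.ligand not in sender_expr.index or any(
        s not in receiver_expr.index for s in pair.receptor_subunits
    ):
        logger.info("interaction_score: missing genes for pair %s", pair.pair_id)
        return float("nan")
    lig = float(sender_expr[pair.ligand])
    rec = min(float(receiver_expr[s]) for s in pair.receptor_subunits)
    return lig * rec


def interaction_profiles(
    oc_expr: pd.DataFrame,
    gc_expr: pd.DataFrame,
    pairing: pd.DataFrame,
    db: list[LRPair],
) -> pd.DataFrame:
    """Per-COC interaction scores for every pair x direction.

    ``pairing`` maps coc_id to the oocyte and granulosa sample columns
    (columns: coc_id, oc_sample, gc_sample). Returns a DataFrame indexed by
    (pair_id, direction) with one column per COC. Scores are >= 0 and exactly
    0 whenever ligand or effective receptor expression is 0.
    """
    rows = []
    index = []
    sender_of = {"OC->GC": "oc", "GC->OC": "gc", "GC->GC": "gc", "OC->OC": "oc"}
    receiver_of = {"OC->GC": "gc", "GC->OC": "oc", "GC->GC": "gc", "OC->OC": "oc"}
    for pair in db:
        lig_ok_oc = pair.ligand in oc_expr.index
        if not (lig_ok_oc and pair.ligand in gc_expr.index
                and all(s in oc_expr.index and s in gc_expr.index for s in pair.receptor_subunits)):
            logger.info("interaction_profiles: pair %s skipped (genes missing)", pair.pair_id)
            continue
        for direction in DIRECTIONS:
            scores = []
            for _, row in pairing.iterrows():
                sexpr = oc_expr[row.oc_sample] if sender_of[direction] == "oc" else gc_expr[row.gc_sample]
                rexpr = oc_expr[row.oc_sample] if receiver_of[direction] == "oc" else gc_expr[row.gc_sample]
                lig = float(sexpr[pair.ligand])
                rec = min(float(rexpr[s]) for s in pair.receptor_subunits)
                scores.append(lig * rec)
            rows.append(scores)
            index.append((pair.pair_id, direction))
    if not rows:
        return pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["pair_id", "direction"]),
            columns=list(pairing.coc_id),
        )
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["pair_id", "direction"]),
        columns=list(pairing.coc_id),
    )


def screen_pairs(profiles: pd.DataFrame, labels: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis across cluster labels per pair x direction, Holm-adjusted.

    The Holm family is all tests in one screen. Constant scores give p = 1.
    """
    labels = labels.loc[profiles.columns]
    groups = labels.unique()
    if len(groups) < 2 or (labels.value_counts() < 2).any():
        raise ValueError("need >= 2 clusters with >= 2 members each")
    stats_out = []
    for idx, row in profiles.iterrows():
        samples = [row[labels.index[labels == g]].to_numpy(float) for g in groups]
        if np.unique(np.concatenate(samples)).size == 1:
            stats_out.append((np.nan, 1.0))
            continue
        h, p = stats.kruskal(*samples)
        stats_out.append((float(h), float(p)))
    out = pd.DataFrame(stats_out, index=profiles.index, columns=["statistic", "pvalue"])
    out["padj"] = adjust_holm(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] < alpha
    return out


def zscale_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-scale each pair x direction score vector across COCs (constant rows -> 0)."""
    v = profiles.to_numpy(float)
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=profiles.index, columns=profiles.columns)


def cluster_profiles(
    profiles: pd.DataFrame, k: int, z_scale_rows: bool = True
) -> tuple[np.ndarray, pd.Series]:
    """Complete-linkage Euclidean clustering of COC communication profiles.

    Returns the scipy linkage matrix and the flat labels at the ``k`` cut.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least two profiles")
    data = zscale_rows(profiles) if z_scale_rows else profiles
    X = data.to_numpy(float).T  # COCs as observations
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=profiles.columns, name="cluster")


def pca_embed(
    X: pd.DataFrame, n_pcs: int = 2, scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA by SVD of the column-centered matrix (rows = observations).

    Each component is oriented so its largest-|loading| feature has a positive
    loading. Returns (scores, loadings, variance fractions).
    """
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 observations")
    V = X.to_numpy(float)
    V = V - V.mean(axis=0, keepdims=True)
    if scale:
        sd = V.std(axis=0, keepdims=True)
        V = V / np.where(sd > 0, sd, 1.0)
    if not np.any(V):
        raise ValueError("zero-variance input")
    U, s, Vt = np.linalg.svd(V, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = U[:, :n_pcs] * s[:n_pcs]
    loadings = Vt[:n_pcs].T
    for j in range(n_pcs):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    varfrac = (s**2 / (s**2).sum())[:n_pcs]
    cols = [f"PC{i+1}" for i in range(n_pcs)]
    return (
        pd.DataFrame(scores, index=X.index, columns=cols),
        pd.DataFrame(loadings, index=X.columns, columns=cols),
        varfrac,
    )
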