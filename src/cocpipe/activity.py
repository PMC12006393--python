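"""Recovery-curve (AUC) activity scoring for regulons and pathway gene sets.

A sample's activity for a gene set is the area under the set's recovery curve
within the top ``top_frac`` of the sample's expression ranking, normalized by
the maximal possible area (all members at the very top). The score is purely
rank-based, lies in [0, 1], equals 1 iff the set occupies the top positions
and 0 iff no member makes the top fraction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._random import stream
from .dge import adjust_bh


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: frozenset

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("regulon with empty target set")
        if self.tf in self.targets:
            warnings.warn(f"regulon {self.tf}: TF removed from its own target set")
            object.__setattr__(self, "targets", self.targets - {self.tf})


def load_regulon_table(table: pd.DataFrame) -> dict[str, Regulon]:
    """Parse a regulon table with semicolon-separated targets."""
    out = {}
    for _, row in table.iterrows():
        out[str(row["regulon_id"])] = Regulon(
            tf=str(row["tf"]), targets=frozenset(str(row["targets"]).split(";"))
        )
    return out


def activity_score(expr_sample: pd.Series, gene_set, top_frac: float = 0.2) -> float:
    """Normalized recovery-curve area of ``gene_set`` in one sample's ranking.

    Genes are ranked by descending expression with ties broken by gene id
    (stable, deterministic). With cutoff T = ceil(top_frac * G) and recovery
    curve r(i) = members among the top i, the score is
    sum_{i=1..T} r(i) / sum_{i=1..T} min(i, |set|).
    """
    G = len(expr_sample)
    if G < 5:
        raise ValueError("need at least 5 genes")
    members = set(gene_set) & set(expr_sample.index)
    if not members:
        warnings.warn("gene set has no overlap with expression universe")
        return float("nan")
    order = sorted(expr_sample.index, key=lambda g: (-expr_sample[g], g))
    cutoff = math.ceil(top_frac * G)
    hits = np.fromiter((g in members for g in order[:cutoff]), bool, cutoff)
    recovery = np.cumsum(hits)
    max_area = np.minimum(np.arange(1, cutoff + 1), len(members)).sum()
    return float(recovery.sum() / max_area)


def activity_matrix(
    expr: pd.DataFrame, gene_sets: dict, top_frac: float = 0.2
) -> pd.DataFrame:
    """Set x sample activity scores (vectorized over samples).

    ``gene_sets`` maps a name to an iterable of gene ids (or a Regulon, whose
    targets are used).
    """
    G = expr.shape[0]
    if G < 5:
        raise ValueError("need at least 5 genes")
    cutoff = math.ceil(0.2 * G) if top_frac is None else math.ceil(top_frac * G)
    # ranking per sample: descending expression, ties by gene id
    gene_order = np.argsort(expr.index.to_numpy())  # lexicographic tiebreak
    v = expr.to_numpy(float)[gene_order]
    ids = expr.index.to_numpy()[gene_order]
    rank_idx = np.argsort(-v, axis=0, kind="stable")  # (G, S)
    out = {}
    for name, gs in gene_sets.items():
        genes = gs.targets if isinstance(gs, Regulon) else gs
        members = set(genes) & set(expr.index)
        if not members:
            warnings.warn(f"gene set {name}: no overlap with universe")
            out[name] = np.full(expr.shape[1], np.nan)
            continue
        is_member = np.isin(ids, list(members))
        hits = is_member[rank_idx[:cutoff]]  # (cutoff, S)
        recovery = np.cumsum(hits, axis=0)
        max_area = np.minimum(np.arange(1, cutoff + 1), len(members)).sum()
        out[name] = recovery.sum(axis=0) / max_area
    return pd.DataFrame(out, index=expr.columns).T


def regulon_pathway_assoc(
    regulon: Regulon, pathways: dict[str, set], universe: set
) -> pd.DataFrame:
    """Jaccard overlap and upper-tail hypergeometric p per pathway, BH-adjusted."""
    A = set(regulon.targets) & set(universe)
    rows = []
    for name, genes in pathways.items():
        B = set(genes) & set(universe)
        inter = len(A & B)
        union = len(A | B)
        jac = inter / union if union else 0.0
        if not A or not B:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(inter - 1, len(universe), len(B), len(A)))
        rows.append({"pathway": name, "jaccard": jac, "overlap": inter, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("pathway")
    out["padj"] = adjust_bh(out["p"].to_numpy())
    return out


def perm_test_activity(
    scores: pd.Series,
    labels: pd.Series,
    blocks: pd.Series | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    exact_limit: int = 50_000,
) -> dict:
    """Two-tailed permutation test on the difference of group mean activity.

    Labels are permuted at the block level when ``blocks`` is given (each
    block, e.g. a mouse, must be label-homogeneous), so technical replicates
    from one animal move together. When the number of distinct assignments is
    at most ``exact_limit`` the null is enumerated exhaustively and
    p = #{|perm| >= |obs|} / #assignments; otherwise p uses ``n_perm``
    Monte-Carlo draws with the add-one correction
    (1 + #{|perm| >= |obs|}) / (1 + n_perm).
    """
    labels = labels.loc[scores.index]
    levels = sorted(labels.astype(str).unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if (labels.value_counts() < 3).any():
        raise ValueError("each group needs >= 3 samples")
    if blocks is None:
        units = pd.Series(scores.index, index=scores.index)
    else:
        units = blocks.loc[scores.index].astype(str)
        per_block = labels.groupby(units).nunique()
        if (per_block > 1).any():
            # blocks straddle the two groups (e.g. one mouse contributing
            # COCs to both subgroups): permute labels within each block,
            # preserving its label counts, instead of permuting whole blocks
            return _perm_test_within_blocks(scores, labels, units, levels, n_perm, seed)

    uniq = units.unique()
    unit_label = labels.groupby(units).first().loc[uniq]
    unit_sum = np.array([scores[units.index[units == u]].sum() for u in uniq], float)
    unit_n = np.array([(units == u).sum() for u in uniq], float)
    n1 = int((unit_label == levels[1]).sum())
    n_units = len(uniq)
    tot_sum, tot_n = unit_sum.sum(), unit_n.sum()

    def deltas(masks: np.ndarray) -> np.ndarray:
        s1 = masks @ unit_sum
        c1 = masks @ unit_n
        return s1 / c1 - (tot_sum - s1) / (tot_n - c1)

    obs_mask = (unit_label == levels[1]).to_numpy()
    observed = float(deltas(obs_mask[None, :])[0])

    total = math.comb(n_units, n1)
    if total <= exact_limit:
        masks = np.zeros((total, n_units), float)
        for i, combo in enumerate(itertools.combinations(range(n_units), n1)):
            masks[i, list(combo)] = 1.0
        p = float(np.mean(np.abs(deltas(masks)) >= abs(observed) - 1e-12))
        used = total
        exact = True
    else:
        rng = stream(seed, "perm_test")
        idx = np.argsort(rng.random((n_perm, n_units)), axis=1)[:, :n1]
        masks = np.zeros((n_perm, n_units), float)
        np.put_along_axis(masks, idx, 1.0, axis=1)
        count = int(np.sum(np.abs(deltas(masks)) >= abs(observed) - 1e-12))
        p = (1 + count) / (1 + n_perm)
        used = n_perm
        exact = False
    return {"delta": observed, "p": float(min(p, 1.0)), "n_perm": used, "exact": exact,
            "group_high": levels[1]}


def _perm_test_within_blocks(
    scores: pd.Series, labels: pd.Series, units: pd.Series,
    levels: list, n_perm: int, seed: int,
) -> dict:
    """Restricted permutation: shuffle labels inside each block only."""
    s = scores.to_numpy(float)
    is1 = (labels == levels[1]).to_numpy()
    n1 = int(is1.sum())
    observed = float(s[is1].mean() - s[~is1].mean())
    block_pos = [np.flatnonzero((units == u).to_numpy()) for u in units.unique()]
    rng = stream(seed, "perm_test_blocked")
    count = 0
    mask = is1.copy()
    for _ in range(n_perm):
        for pos in block_pos:
            mask[pos] = mask[pos][rng.permutation(len(pos))]
        d = s[mask].mean() - s[~mask].mean()
        if abs(d) >= abs(observed) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"delta": observed, "p": float(min(p, 1.0)), "n_perm": n_perm,
            "exact": False, "group_high": levels[1]}


def differential_activity(
    act: pd.DataFrame,
    labels: pd.Series,
    blocks: pd.Series | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-regulon permutation test with BH adjustment across regulons."""
    rows = {}
    for i, (name, scores) in enumerate(act.iterrows()):
        res = perm_test_activity(
            scores, labels, blocks=blocks, n_perm=n_perm, seed=seed + i
        )
        rows[name] = {"delta": res["delta"], "p": res["p"]}
    out = pd.DataFrame(rows).T
    out["padj"] = adjust_bh(out["p"].to_numpy())
    out["significant"] = out["padj"] < alpha
    return out
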