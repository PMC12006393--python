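"""Ligand-receptor scoring, pair screening, clustering and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

import cocpipe as cp
from cocpipe.ccc import LRPair, zscale_rows


def _series(d):
    return pd.Series(d)


# ---------------------------------------------------------------------------
# interaction score
# ---------------------------------------------------------------------------

def test_interaction_score_product_and_min_subunit_rule():
    sender = _series({"L": 2.0, "x": 1.0})
    receiver = _series({"R1": 3.0, "R2": 1.0})
    single = LRPair("p1", "L", ("R1",))
    multi = LRPair("p2", "L", ("R1", "R2"))
    assert cp.interaction_score(sender, receiver, single) == 6.0
    # least expressed subunit carries the complex
    assert cp.interaction_score(sender, receiver, multi) == 2.0
    assert cp.interaction_score(_series({"L": 0.0}), receiver, single) == 0.0


def test_interaction_score_homogeneous_in_sender(rng):
    sender = _series({"L": float(rng.uniform(1, 5))})
    receiver = _series({"R1": float(rng.uniform(1, 5)), "R2": float(rng.uniform(1, 5))})
    pair = LRPair("p", "L", ("R1", "R2"))
    s1 = cp.interaction_score(sender, receiver, pair)
    s2 = cp.interaction_score(sender * 3.0, receiver, pair)
    assert s2 == pytest.approx(3.0 * s1)


def test_interaction_score_missing_gene_is_nan():
    pair = LRPair("p", "L", ("R1",))
    assert np.isnan(cp.interaction_score(_series({"x": 1.0}), _series({"R1": 1.0}), pair))


# ---------------------------------------------------------------------------
# top-expressed filter
# ---------------------------------------------------------------------------

def _twelve_gene_fixture():
    ligands = {f"L{i}": float(10 - i) for i in range(6)}     # L0 highest
    receptors = {f"R{i}": float(10 - i) for i in range(6)}
    db = [LRPair(f"p{i}", f"L{i}", (f"R{i}",)) for i in range(6)]
    return db, _series(ligands), _series(receptors)


def test_top_expressed_keeps_hand_ranked_pairs():
    db, lig, rec = _twelve_gene_fixture()
    kept = cp.top_expressed_lr(db, lig, rec, k=3)
    assert [p.pair_id for p in kept] == ["p0", "p1", "p2"]


def test_top_expressed_large_k_keeps_everything():
    db, lig, rec = _twelve_gene_fixture()
    assert len(cp.top_expressed_lr(db, lig, rec, k=100)) == len(db)


def test_top_expressed_drops_silent_ligand():
    db, lig, rec = _twelve_gene_fixture()
    lig["L0"] = 0.0
    kept = cp.top_expressed_lr(db, lig, rec, k=100)
    assert "p0" not in [p.pair_id for p in kept]


def test_top_expressed_invalid_k():
    db, lig, rec = _twelve_gene_fixture()
    with pytest.raises(ValueError):
        cp.top_expressed_lr(db, lig, rec, k=0)


# ---------------------------------------------------------------------------
# Kruskal-Wallis screening
# ---------------------------------------------------------------------------

def _profiles(rows: dict, cocs: list) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(list(rows), names=["pair_id", "direction"])
    return pd.DataFrame(list(rows.values()), index=idx, columns=cocs)


def test_kw_statistic_matches_rank_formula():
    # clusters A: {1,2}, B: {3,4}, C: {5,6}; ranks 1..6
    # H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 12/42 * (9/2+49/2+121/2) - 21 = 32/7
    prof = _profiles({("p", "OC->GC"): [1, 2, 3, 4, 5, 6]}, list("abcdef"))
    labels = pd.Series(["A", "A", "B", "B", "C", "C"], index=list("abcdef"))
    out = cp.screen_pairs(prof, labels)
    assert out.iloc[0]["statistic"] == pytest.approx(32 / 7, abs=1e-10)


def test_screen_constant_scores_give_p_one_and_identical_distributions_ns(rng):
    cocs = [f"c{i}" for i in range(15)]
    labels = pd.Series(np.repeat(["A", "B", "C"], 5), index=cocs)
    rows = {("p0", "OC->GC"): [1.0] * 15}
    for i in range(1, 6):
        rows[(f"p{i}", "OC->GC")] = rng.normal(0, 1, 15)  # same distribution everywhere
    out = cp.screen_pairs(_profiles(rows, cocs), labels)
    assert out.loc[("p0", "OC->GC"), "pvalue"] == 1.0
    assert not out["significant"].any()


def test_screen_disjoint_supports_significant(rng):
    cocs = [f"c{i}" for i in range(15)]
    labels = pd.Series(np.repeat(["A", "B", "C"], 5), index=cocs)
    rows = {("hit", "OC->GC"): np.concatenate([rng.uniform(0, 1, 5),
                                               rng.uniform(10, 11, 5),
                                               rng.uniform(20, 21, 5)])}
    for i in range(5):
        rows[(f"null{i}", "OC->GC")] = rng.normal(0, 1, 15)
    out = cp.screen_pairs(_profiles(rows, cocs), labels)
    assert bool(out.loc[("hit", "OC->GC"), "significant"])
    # Holm-significant set is a subset of the unadjusted-significant set
    assert (out["padj"] >= out["pvalue"] - 1e-12).all()


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_cluster_recovers_separated_blobs(rng):
    a = rng.normal(0, 1, size=(6, 20))
    b = rng.normal(10, 1, size=(6, 20))
    prof = pd.DataFrame(np.vstack([a, b]).T, columns=[f"c{i}" for i in range(12)])
    _, labels = cp.cluster_profiles(prof, k=2, z_scale_rows=False)
    assert labels.iloc[:6].nunique() == 1 and labels.iloc[6:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[-1]


def test_duplicated_profile_merges_first():
    prof = pd.DataFrame(
        {"c0": [1.0, 2.0, 5.0], "c1": [1.0, 2.0, 5.0], "c2": [8.0, 1.0, 0.0],
         "c3": [4.0, 9.0, 2.0], "c4": [0.0, 0.0, 7.0]},
    )
    Z, _ = cp.cluster_profiles(prof, k=2, z_scale_rows=False)
    assert Z[0, 2] == 0.0                       # first merge at height 0
    assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}


def test_merge_heights_match_bruteforce_complete_linkage(rng):
    prof = pd.DataFrame(rng.normal(0, 1, size=(3, 5)), columns=[f"c{i}" for i in range(5)])
    Z, _ = cp.cluster_profiles(prof, k=2, z_scale_rows=False)
    # naive O(n^3) complete-linkage oracle
    pts = [prof[c].to_numpy() for c in prof.columns]
    clusters = {i: [i] for i in range(5)}
    heights = []
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i < j:
                    d = max(
                        np.linalg.norm(pts[p] - pts[q])
                        for p in clusters[i] for q in clusters[j]
                    )
                    if best is None or d < best[0]:
                        best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters.pop(i) + clusters.pop(j)
        clusters[5 + len(heights)] = merged
    assert np.allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-10)


def test_cluster_requires_two_profiles():
    with pytest.raises(ValueError):
        cp.cluster_profiles(pd.DataFrame({"only": [1.0, 2.0]}), k=1)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_data():
    base = np.outer(np.arange(5, dtype=float), [1.0, 2.0, 3.0])
    scores, loadings, varfrac = cp.pca_embed(pd.DataFrame(base), n_pcs=2)
    assert varfrac[0] == pytest.approx(1.0)


def test_pca_variance_fractions_rotation_invariant(rng):
    X = rng.normal(0, 1, size=(8, 4))
    Q, _ = np.linalg.qr(rng.normal(0, 1, size=(4, 4)))
    _, _, v1 = cp.pca_embed(pd.DataFrame(X), n_pcs=3)
    _, _, v2 = cp.pca_embed(pd.DataFrame(X @ Q), n_pcs=3)
    assert np.allclose(v1, v2, atol=1e-10)


def test_pca_matches_eigendecomposition_oracle(rng):
    X = rng.normal(0, 1, size=(6, 4))
    scores, loadings, varfrac = cp.pca_embed(pd.DataFrame(X), n_pcs=3)
    C = np.cov((X - X.mean(0)).T, bias=True)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    for j in range(3):
        v = V[:, order[j]]
        got = loadings.iloc[:, j].to_numpy()
        assert np.allclose(np.abs(got), np.abs(v), atol=1e-8)  # up to sign
    # sign convention: dominant loading positive
    for j in range(3):
        col = loadings.iloc[:, j].to_numpy()
        assert col[np.argmax(np.abs(col))] > 0


def test_pca_zero_variance_rejected():
    with pytest.raises(ValueError):
        cp.pca_embed(pd.DataFrame(np.ones((4, 3))))
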