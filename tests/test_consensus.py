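"""Consensus labeling, feature selection and the dual SVM classifier."""

import numpy as np
import pandas as pd
import pytest

import cocpipe as cp
from cocpipe.consensus import _LinearModel


# ---------------------------------------------------------------------------
# consensus clusters
# ---------------------------------------------------------------------------

def test_consensus_agreement_and_disagreement():
    idx = [f"c{i}" for i in range(8)]
    a = pd.Series(["N", "N", "S_N", "S_N", "S", "S", "S_N", "S"], index=idx)
    same = cp.consensus_clusters(a, a)
    assert (same.labels == a).all()
    flipped = a.map({"N": "S", "S_N": "N", "S": "S_N"})
    none = cp.consensus_clusters(a, flipped)
    assert (none.labels == "excluded").all()
    # exactly the two planted disagreements are excluded
    b = a.copy()
    b.iloc[[2, 5]] = ["S", "N"]
    mixed = cp.consensus_clusters(a, b)
    assert list(mixed.labels[mixed.labels == "excluded"].index) == ["c2", "c5"]
    assert (mixed.labels.drop(["c2", "c5"]) == a.drop(["c2", "c5"])).all()


def test_align_clusters_maps_by_natural_fraction_and_centroid():
    idx = [f"c{i}" for i in range(9)]
    labels = pd.Series([1, 1, 1, 2, 2, 2, 3, 3, 3], index=idx)
    feats = pd.DataFrame(
        {"f": [0.0, 0.1, -0.1, 1.0, 1.1, 0.9, 5.0, 5.1, 4.9]}, index=idx
    )
    natural = pd.Series([True] * 3 + [False] * 6, index=idx)
    mapped = cp.align_clusters(labels, feats, natural)
    assert (mapped.iloc[:3] == "N").all()
    assert (mapped.iloc[3:6] == "S_N").all()   # centroid 1.0 closer to N than 5.0
    assert (mapped.iloc[6:] == "S").all()


def test_align_clusters_tie_raises():
    idx = [f"c{i}" for i in range(6)]
    labels = pd.Series([1, 1, 2, 2, 3, 3], index=idx)
    feats = pd.DataFrame({"f": [0.0, 0.0, 1.0, 1.0, -1.0, -1.0]}, index=idx)
    natural = pd.Series([True, True, False, False, False, False], index=idx)
    with pytest.raises(ValueError, match="tie"):
        cp.align_clusters(labels, feats, natural)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _dge_table(base_mean, padj, lfc, genes):
    return pd.DataFrame({"baseMean": base_mean, "padj": padj, "log2FC": lfc}, index=genes)


def test_select_features_base_mean_gate():
    genes = ["g_low", "g_ok"]
    dge = _dge_table([49.0, 200.0], [1e-6, 1e-6], [2.0, 2.0], genes)
    expr = pd.DataFrame(
        np.array([[1, 2, 8, 9], [1, 2, 8, 9.0]]), index=genes,
        columns=[f"s{i}" for i in range(4)],
    )
    kept = cp.select_features_dge(dge, expr)
    # baseMean 49 excluded regardless of its p value
    assert kept == ["g_ok"]


def test_select_features_no_passers_raises():
    dge = _dge_table([10.0], [0.5], [0.1], ["g"])
    expr = pd.DataFrame(np.ones((1, 4)), index=["g"])
    with pytest.raises(ValueError, match="threshold"):
        cp.select_features_dge(dge, expr)


def test_select_features_recovers_planted_separators(rng):
    n_sep, n_null, n_samp = 40, 960, 20
    genes = [f"sep{i}" for i in range(n_sep)] + [f"null{i}" for i in range(n_null)]
    y = np.array([0] * 10 + [1] * 10)
    expr = rng.normal(8, 1, size=(n_sep + n_null, n_samp))
    expr[:n_sep] += np.outer(rng.choice([-2.0, 2.0], n_sep), y)
    expr_df = pd.DataFrame(expr, index=genes, columns=[f"s{i}" for i in range(n_samp)])
    padj = np.concatenate([np.full(n_sep, 1e-5), rng.uniform(0.2, 1, n_null)])
    dge = _dge_table(np.full(len(genes), 100.0), padj,
                     np.concatenate([np.full(n_sep, 2.0), rng.normal(0, 0.1, n_null)]),
                     genes)
    kept = cp.select_features_dge(dge, expr_df)
    assert sum(1 for g in kept if g.startswith("sep")) >= 30


def test_prune_features_removes_planted_defects(rng):
    n = 40
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    X = pd.DataFrame(
        {
            "x1": x1,
            "x2": x2,
            "const": np.full(n, 3.0),
            "dup": x1.copy(),
            "combo": x1 + x2,
            "indep": rng.normal(0, 1, n),
        }
    )
    kept = cp.prune_features(X)
    assert "const" not in kept
    assert not ({"x1", "dup"} <= set(kept))     # one of the pair dropped
    assert not ({"x1", "x2", "combo"} <= set(kept))  # dependency broken
    assert "indep" in kept


def test_ga_select_finds_informative_feature(rng):
    n = 30
    y = pd.Series(["a"] * 15 + ["b"] * 15, index=[f"s{i}" for i in range(n)])
    X = pd.DataFrame(
        rng.normal(0, 1, size=(n, 8)), index=y.index,
        columns=[f"f{i}" for i in range(8)],
    )
    X["signal"] = np.where(y == "b", 3.0, -3.0) + rng.normal(0, 0.3, n)
    found = 0
    for seed in range(10):
        sel = cp.ga_select(X, y, pop=20, gens=6, seed=seed)
        assert len(sel) >= 1                        # never empty
        found += "signal" in sel
    assert found >= 9


def test_ga_select_degenerate_inputs():
    X = pd.DataFrame(np.ones((6, 3)), columns=list("abc"))
    y_one = pd.Series(["a"] * 6, index=X.index)
    with pytest.raises(ValueError):
        cp.ga_select(X, y_one)
    # pop=1, gens=0 returns the single (repaired) random chromosome, reproducibly
    y = pd.Series(["a", "a", "a", "b", "b", "b"], index=X.index)
    s1 = cp.ga_select(X, y, pop=1, gens=0, seed=5)
    s2 = cp.ga_select(X, y, pop=1, gens=0, seed=5)
    assert s1 == s2 and len(s1) >= 1


# ---------------------------------------------------------------------------
# dual classifier
# ---------------------------------------------------------------------------

def _toy_views(rng, n=16):
    idx = [f"s{i}" for i in range(n)]
    y = pd.Series(["S_N"] * (n // 2) + ["S"] * (n // 2), index=idx)
    sep = np.where(y == "S", 2.0, -2.0)
    X_tf = pd.DataFrame({"a": sep + rng.normal(0, 0.1, n), "b": rng.normal(0, 1, n)}, index=idx)
    X_dge = pd.DataFrame({"g1": sep + rng.normal(0, 0.1, n), "g2": rng.normal(0, 1, n)}, index=idx)
    return X_tf, X_dge, y


def test_train_dual_separable_views_perfect_cv(rng):
    X_tf, X_dge, y = _toy_views(rng)
    clf = cp.train_dual(X_tf, X_dge, y, seed=0)
    assert clf.model_tf.cv_accuracy == 1.0
    assert clf.model_dge.cv_accuracy == 1.0
    pred = cp.predict_consensus_frame(clf, X_tf, X_dge)
    assert (pred == y).all()


def test_train_dual_label_permutation_near_chance(rng):
    X_tf, X_dge, y = _toy_views(rng, n=20)
    y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    clf = cp.train_dual(X_tf, X_dge, y_perm, seed=0)
    assert 0.5 - 0.25 <= clf.model_tf.cv_accuracy <= 0.5 + 0.25


def test_train_dual_requires_four_per_class(rng):
    X_tf, X_dge, y = _toy_views(rng, n=6)
    with pytest.raises(ValueError):
        cp.train_dual(X_tf, X_dge, y)


def test_predict_consensus_na_on_disagreement():
    m1 = _LinearModel(["f"], np.zeros(1), np.ones(1), np.array([1.0]), 0.0, 1.0,
                      ["S_N", "S"], 1.0)
    m2 = _LinearModel(["f"], np.zeros(1), np.ones(1), np.array([-1.0]), 0.0, 1.0,
                      ["S_N", "S"], 1.0)
    clf = cp.DualClassifier(m1, m2, seed=0)
    x = pd.Series({"f": 2.0})
    assert cp.predict_consensus(clf, x, x) == "NA"
    agree = cp.DualClassifier(m1, m1, seed=0)
    assert cp.predict_consensus(agree, x, x) == "S"
    with pytest.raises(KeyError, match="missing"):
        cp.predict_consensus(clf, pd.Series({"other": 1.0}), x)


def test_classifier_roundtrip_serialization(tmp_path, rng):
    X_tf, X_dge, y = _toy_views(rng)
    clf = cp.train_dual(X_tf, X_dge, y, seed=0)
    clf.save(tmp_path / "clf.json")
    back = cp.DualClassifier.load(tmp_path / "clf.json")
    pred1 = cp.predict_consensus_frame(clf, X_tf, X_dge)
    pred2 = cp.predict_consensus_frame(back, X_tf, X_dge)
    assert (pred1 == pred2).all()
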