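"""Recovery-curve activity scores, set association and permutation tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from scipy.stats import hypergeom

import cocpipe as cp
from cocpipe.activity import Regulon


def _expr(values: dict) -> pd.Series:
    return pd.Series(values, dtype=float)


# ---------------------------------------------------------------------------
# activity score
# ---------------------------------------------------------------------------

def test_activity_score_extremes():
    expr = _expr({f"g{i}": 10.0 - i for i in range(10)})  # g0 top
    top2 = {"g0", "g1"}
    bottom = {"g8", "g9"}
    assert cp.activity_score(expr, top2, top_frac=0.2) == 1.0
    assert cp.activity_score(expr, bottom, top_frac=0.2) == 0.0


def test_activity_score_matches_hand_recovery_curve():
    # G=10, cutoff 2; members at ranks {1, 3}: r(1)=1, r(2)=1 -> area 2;
    # best case r = (1, 2) -> area 3; score 2/3
    expr = _expr({f"g{i}": 10.0 - i for i in range(10)})
    members = {"g0", "g2"}
    assert cp.activity_score(expr, members, top_frac=0.2) == pytest.approx(2 / 3, abs=1e-10)


def test_activity_score_rank_invariance(rng):
    expr = _expr({f"g{i}": float(v) for i, v in enumerate(rng.uniform(1, 5, 20))})
    members = {"g3", "g7", "g11"}
    s1 = cp.activity_score(expr, members)
    s2 = cp.activity_score(np.exp(expr), members)       # monotone transform
    s3 = cp.activity_score(expr * 100 + 7, members)
    assert s1 == s2 == s3


def test_activity_score_empty_overlap_warns_nan():
    expr = _expr({f"g{i}": float(i) for i in range(10)})
    with pytest.warns(UserWarning):
        assert np.isnan(cp.activity_score(expr, {"absent"}))


def test_activity_matrix_agrees_with_scalar_scores(rng):
    expr = pd.DataFrame(
        rng.uniform(0, 9, size=(15, 4)),
        index=[f"g{i:02d}" for i in range(15)], columns=list("abcd"),
    )
    sets = {"s1": {"g00", "g05", "g09"}, "s2": {"g01", "g14"}}
    mat = cp.activity_matrix(expr, sets, top_frac=0.3)
    for name, genes in sets.items():
        for c in expr.columns:
            assert mat.loc[name, c] == pytest.approx(
                cp.activity_score(expr[c], genes, top_frac=0.3), abs=1e-12
            )


# ---------------------------------------------------------------------------
# regulon-pathway association
# ---------------------------------------------------------------------------

def test_regulon_pathway_jaccard_extremes():
    universe = {f"g{i}" for i in range(30)}
    reg = Regulon("tf", frozenset({"g0", "g1", "g2"}))
    out = cp.regulon_pathway_assoc(
        reg, {"same": {"g0", "g1", "g2"}, "disjoint": {"g10", "g11"}}, universe
    )
    assert out.loc["same", "jaccard"] == 1.0
    assert out.loc["disjoint", "jaccard"] == 0.0


def test_regulon_pathway_p_matches_enumeration():
    # |A|=4, |B|=6, overlap 3, universe 50: P(X >= 3) hypergeometric
    universe = {f"g{i}" for i in range(50)}
    A = {"g0", "g1", "g2", "g10"}
    B = {"g0", "g1", "g2", "g20", "g21", "g22"}
    expected = sum(
        comb(6, k) * comb(44, 4 - k) for k in (3, 4)
    ) / comb(50, 4)
    out = cp.regulon_pathway_assoc(Regulon("tf", frozenset(A)), {"b": B}, universe)
    assert out.loc["b", "p"] == pytest.approx(expected, abs=1e-10)
    assert out.loc["b", "p"] == pytest.approx(hypergeom.sf(2, 50, 6, 4), abs=1e-12)


def test_regulon_tf_removed_from_targets():
    with pytest.warns(UserWarning):
        reg = Regulon("tf", frozenset({"tf", "a", "b"}))
    assert "tf" not in reg.targets


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_perm_test_exhaustive_matches_manual_enumeration():
    scores = pd.Series([0.0, 0.0, 0.0, 1.0, 1.0, 1.0], index=list("abcdef"))
    labels = pd.Series(["x", "x", "x", "y", "y", "y"], index=list("abcdef"))
    res = cp.perm_test_activity(scores, labels)
    assert res["exact"] and res["n_perm"] == 20
    # manual: of C(6,3)=20 splits, only the observed and its mirror give |delta|=1
    assert res["p"] == pytest.approx(2 / 20, abs=1e-12)


def test_perm_test_agrees_with_bruteforce_for_5v5(rng):
    scores = pd.Series(rng.normal(0, 1, 10), index=[f"s{i}" for i in range(10)])
    labels = pd.Series(["a"] * 5 + ["b"] * 5, index=scores.index)
    res = cp.perm_test_activity(scores, labels)
    # independent brute force over all C(10,5) label assignments
    vals = scores.to_numpy()
    obs = vals[5:].mean() - vals[:5].mean()
    count = 0
    total = 0
    for combo in itertools.combinations(range(10), 5):
        mask = np.zeros(10, bool)
        mask[list(combo)] = True
        d = vals[mask].mean() - vals[~mask].mean()
        total += 1
        if abs(d) >= abs(obs) - 1e-12:
            count += 1
    assert res["exact"]
    assert res["p"] == pytest.approx(count / total, abs=1e-12)


def test_perm_test_identical_groups_near_one(rng):
    scores = pd.Series(np.tile([0.3, 0.5, 0.7], 2), index=[f"s{i}" for i in range(6)])
    labels = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
    assert cp.perm_test_activity(scores, labels)["p"] > 0.9


def test_perm_test_blocked_permutes_mice_not_samples():
    # two samples per mouse; block permutation has C(4,2)=6 assignments
    idx = [f"s{i}" for i in range(8)]
    scores = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=idx, dtype=float)
    labels = pd.Series(["a"] * 4 + ["b"] * 4, index=idx)
    blocks = pd.Series(["m0", "m0", "m1", "m1", "m2", "m2", "m3", "m3"], index=idx)
    res = cp.perm_test_activity(scores, labels, blocks=blocks)
    assert res["exact"] and res["n_perm"] == 6
    assert res["p"] == pytest.approx(2 / 6, abs=1e-12)


def test_perm_test_planted_difference_detected(rng):
    hits = 0
    for s in range(10):
        r = np.random.default_rng(s)
        scores = pd.Series(
            np.concatenate([r.normal(0.3, 0.05, 10), r.normal(0.6, 0.05, 10)]),
            index=[f"s{i}" for i in range(20)],
        )
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=scores.index)
        res = cp.perm_test_activity(scores, labels, n_perm=2000, seed=s)
        hits += res["p"] < 0.01
    assert hits >= 9


def test_differential_activity_sensitivity_and_fdr(rng):
    # 12 regulons: 6 with a planted 0.4 shift, 6 null
    n = 10
    idx = [f"s{i}" for i in range(2 * n)]
    labels = pd.Series(["a"] * n + ["b"] * n, index=idx)
    act = {}
    for r in range(6):
        act[f"hit{r}"] = np.concatenate([rng.normal(0.3, 0.05, n), rng.normal(0.7, 0.05, n)])
    for r in range(6):
        act[f"null{r}"] = rng.normal(0.5, 0.05, 2 * n)
    out = cp.differential_activity(pd.DataFrame(act, index=idx).T, labels, n_perm=2000, seed=1)
    sig = set(out.index[out["significant"]])
    assert all(f"hit{r}" in sig for r in range(6))
    assert sum(1 for s in sig if s.startswith("null")) <= 1
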