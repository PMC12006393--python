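"""Size factors, NB Wald GLM, multiple testing and rank/ORA primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb

import cocpipe as cp
from cocpipe import CountMatrix
from cocpipe.dge import DesignSpec


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def test_size_factors_identical_columns_are_one():
    v = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2], "c": [5, 9, 2]},
                     index=["g1", "g2", "g3"])
    sf = cp.size_factors(CountMatrix(v))
    assert np.allclose(sf, 1.0)


def test_size_factors_scale_equivariance():
    v = pd.DataFrame({"a": [5, 9, 2], "b": [10, 18, 4]}, index=["g1", "g2", "g3"])
    sf = cp.size_factors(CountMatrix(v))
    assert sf["b"] / sf["a"] == pytest.approx(2.0)


def test_size_factors_match_bruteforce_formula(rng):
    v = pd.DataFrame(rng.integers(1, 500, size=(10, 4)),
                     index=[f"g{i}" for i in range(10)], columns=list("abcd"))
    sf = cp.size_factors(CountMatrix(v))
    # definitional oracle: median over genes of count / geometric mean, then
    # renormalize to geometric mean one
    logs = np.log(v.to_numpy(float))
    ratios = np.exp(logs - logs.mean(axis=1, keepdims=True))
    expected = np.median(ratios, axis=0)
    expected /= np.exp(np.mean(np.log(expected)))
    assert np.allclose(sf.to_numpy(), expected, atol=1e-10)


def test_size_factors_fallback_without_allpositive_genes():
    v = pd.DataFrame({"a": [0, 10], "b": [10, 0]}, index=["g1", "g2"])
    with pytest.warns(UserWarning, match="total-count"):
        sf = cp.size_factors(CountMatrix(v))
    assert np.allclose(sf, 1.0)  # equal totals


# ---------------------------------------------------------------------------
# multiple testing vs definitional enumeration
# ---------------------------------------------------------------------------

def _bh_bruteforce(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def _holm_bruteforce(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
def test_bh_and_holm_match_bruteforce(pvals):
    assert np.allclose(cp.adjust_bh(pvals), _bh_bruteforce(pvals), atol=1e-10)
    assert np.allclose(cp.adjust_holm(pvals), _holm_bruteforce(pvals), atol=1e-10)


def test_bh_hand_example_and_na_handling():
    assert np.allclose(cp.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    out = cp.adjust_bh([0.01, np.nan, 0.02])
    assert np.isnan(out[1])
    # NA excluded from the family size: m = 2
    assert np.allclose(out[[0, 2]], [0.02, 0.02])
    assert cp.adjust_holm([0.04])[0] == pytest.approx(0.04)


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def test_ora_degenerate_cases():
    universe = {f"g{i}" for i in range(20)}
    assert cp.ora(set(list(universe)[:5]), universe, universe)["p"] == pytest.approx(1.0)
    assert cp.ora({"g0"}, universe, {"g1", "g2"})["p"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cp.ora({"g0"}, set(), {"g1"})


def test_ora_matches_exact_enumeration():
    # universe 20, pathway 5, hits 5, overlap 4: P(X >= 4) by counting draws
    universe = {f"g{i}" for i in range(20)}
    pathway = {f"g{i}" for i in range(5)}
    hits = {"g0", "g1", "g2", "g3", "g10"}
    expected = (comb(5, 4) * comb(15, 1) + comb(5, 5) * comb(15, 0)) / comb(20, 5)
    assert cp.ora(hits, universe, pathway)["p"] == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# rank test
# ---------------------------------------------------------------------------

def test_rank_test_degenerate_and_exact():
    assert cp.rank_test_two_sided([1, 1, 1], [1, 1, 1]) == 1.0
    # all 20 rank assignments: only 1 as extreme per tail -> 2/20
    assert cp.rank_test_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_rank_test_large_shift_significant(rng):
    x = rng.normal(0, 1, 300)
    y = rng.normal(3, 1, 300)
    assert cp.rank_test_two_sided(x, y) < 1e-6


# ---------------------------------------------------------------------------
# NB Wald
# ---------------------------------------------------------------------------

def _two_group_counts(rng, n_genes=300, n=4, lfc=0.0, disp=0.1, mu=100.0, n_de=50):
    """NB counts with ``n_de`` genes shifted by ``lfc`` in group B, rest null."""
    r = 1.0 / disp
    shift = np.zeros(n_genes)
    # balanced up/down shifts so depth normalization stays identifiable
    shift[: n_de // 2] = lfc
    shift[n_de // 2 : n_de] = -lfc
    mu_a = np.full((n_genes, n), mu)
    mu_b = mu_a * 2.0 ** shift[:, None]
    y = np.concatenate(
        [rng.negative_binomial(r, r / (r + mu_a)), rng.negative_binomial(r, r / (r + mu_b))],
        axis=1,
    )
    cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    cm = CountMatrix(pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)], columns=cols))
    groups = pd.Series(["A"] * n + ["B"] * n, index=cols)
    return cm, DesignSpec.two_group(groups), [f"g{i}" for i in range(n_de)]


def test_nb_wald_degenerate_gene_flagged():
    v = pd.DataFrame(
        {"a0": [5, 10], "a1": [5, 12], "b0": [5, 30], "b1": [5, 33]},
        index=["const", "var"],
    )
    groups = pd.Series(["A", "A", "B", "B"], index=v.columns)
    res = cp.nb_wald(CountMatrix(v), DesignSpec.two_group(groups))["group"]
    assert res.loc["const", "flag"] == "degenerate"
    assert res.loc["const", "log2FC"] == 0.0
    assert res.loc["const", "pvalue"] == 1.0


def test_nb_wald_column_order_invariance(rng):
    cm, design, _ = _two_group_counts(rng, n_genes=100, lfc=1.0)
    res1 = cp.nb_wald(cm, design)["group"]
    perm = list(cm.sample_ids)[::-1]
    res2 = cp.nb_wald(cm.subset_samples(perm), design)["group"]
    assert np.allclose(res1["log2FC"], res2["log2FC"], atol=1e-8)
    assert np.allclose(res1["pvalue"], res2["pvalue"], atol=1e-8)


def test_nb_wald_recovers_planted_lfc(rng):
    cm, design, de = _two_group_counts(rng, n_genes=400, lfc=2.0, disp=0.1, n_de=100)
    res = cp.nb_wald(cm, design)["group"]
    planted = pd.Series([2.0] * 50 + [-2.0] * 50, index=de)
    err = res.loc[de, "log2FC"] - planted
    # sampling floor: sd(log2FC) = sqrt(2 (disp + 1/mu) / n) / ln2 = 0.34, so
    # ~87% of genes land within +/-0.5 even for a perfect estimator
    assert err.abs().median() < 0.3
    assert (err.abs() < 0.5).mean() >= 0.8
    assert abs(err.mean()) < 0.1  # unbiased


def test_nb_wald_power_monotone_in_effect_size(rng):
    sig = []
    for lfc in (0.5, 1.0, 2.0):
        cm, design, de = _two_group_counts(rng, n_genes=300, lfc=lfc)
        res = cp.nb_wald(cm, design)["group"]
        sig.append((res.loc[de, "padj"] < 0.05).mean())
    assert sig[0] < sig[1] <= sig[2]


def test_interaction_design_contrasts():
    cond = pd.Series(["NY", "NY", "SY", "SY", "NO", "NO", "SO", "SO"],
                     index=[f"s{i}" for i in range(8)])
    design = DesignSpec.from_conditions(cond)
    assert list(design.matrix.columns) == [
        "intercept", "age_old", "treat_super", "age_old:treat_super"
    ]
    # superovulation-in-old contrast includes the interaction term
    assert design.contrasts["super_old"].tolist() == [0, 0, 1, 1]
    with pytest.raises(ValueError):
        DesignSpec.from_conditions(cond.iloc[:4])  # rank-deficient (young only)
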