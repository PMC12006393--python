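"""Generator determinism, planted-effect structure and conservation."""

import numpy as np
import pandas as pd
import pytest

import cocpipe as cp
from cocpipe.simulate import ConfigurationError, tail_capture


def test_identical_seed_gives_identical_cohort(small_config):
    a, _ = cp.generate_paired_cohort(small_config)
    b, _ = cp.generate_paired_cohort(small_config)
    pd.testing.assert_frame_equal(a.oc_counts.values, b.oc_counts.values)
    pd.testing.assert_frame_equal(a.gc_counts.values, b.gc_counts.values)


def test_new_seed_resamples_counts_but_keeps_planted_effects(small_config):
    import dataclasses

    a, ta = cp.generate_paired_cohort(small_config)
    cfg2 = dataclasses.replace(small_config, seed=2)
    b, tb = cp.generate_paired_cohort(cfg2)
    assert not a.oc_counts.values.equals(b.oc_counts.values)
    pd.testing.assert_series_equal(ta.lfc_super, tb.lfc_super)
    pd.testing.assert_series_equal(ta.lfc_aging, tb.lfc_aging)


def test_zero_effect_config_has_no_group_differences():
    cfg = cp.SimConfig(
        n_mice_per_condition=4, cocs_per_mouse=8, n_genes=800, seed=3,
        n_lr_pairs=0, n_regulons=0, n_entropy_genes=0, n_de_super=0, n_de_aging=0,
        superovulation_lfc_scale=0.0, aging_lfc_scale=0.0,
    )
    cohort, truth = cp.generate_paired_cohort(cfg)
    assert (truth.lfc_super == 0).all() and (truth.lfc_aging == 0).all()
    expr = cp.cpm(cohort.oc_counts)
    meta = cohort.meta[cohort.meta.cell_type == "oocyte"]
    means = {c: expr[list(meta.index[meta.condition == c])].mean(axis=1) for c in cp.CONDITIONS}
    lfc = np.log2((means["SY"] + 1) / (means["NY"] + 1))
    # no planted effect: group log-ratios are centered on zero
    assert abs(lfc.mean()) < 0.05
    assert lfc.abs().quantile(0.95) < 0.5


def test_full_attenuation_is_additive(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, interaction_attenuation=1.0)
    _, truth = cp.generate_paired_cohort(cfg)
    assert (truth.lfc_interaction == 0).all()


def test_library_size_conservation(small_config):
    cohort, _ = cp.generate_paired_cohort(small_config)
    lo, hi = small_config.lib_size_range
    totals = np.concatenate(
        [cohort.oc_counts.values.sum(axis=0), cohort.gc_counts.values.sum(axis=0)]
    )
    # expected totals equal library size x the per-mouse depth multiplier
    # (log-normal, sd 0.1), so samples stay within a loose band and the
    # Monte-Carlo mean over all samples is within 10% of the drawn mean
    assert (totals > lo * 0.6).all() and (totals < hi * 1.5).all()
    assert abs(totals.mean() / ((lo + hi) / 2) - 1) < 0.1


def test_naive_lfc_recovers_planted_effects():
    from cocpipe.evaluation import lfc_recovery

    assert lfc_recovery(seed=1)["pearson_r"] >= 0.9


def test_impossible_config_rejected():
    with pytest.raises(ConfigurationError):
        cp.SimConfig(n_genes=100).validate()
    with pytest.raises(ConfigurationError):
        cp.SimConfig(sn_fraction=1.5).validate()
    with pytest.raises(ConfigurationError):
        cp.SimConfig(n_regulons=2, targets_per_regulon=0).validate()


def test_lr_database_structure(small_config):
    import dataclasses

    db = cp.generate_lr_database(small_config)
    cohort, _ = cp.generate_paired_cohort(small_config)
    genes = set(cohort.gene_meta.gene_id)
    for row in db.itertuples():
        assert row.ligand in genes
        assert all(s in genes for s in row.receptor_subunits.split(";"))
    single = cp.generate_lr_database(
        dataclasses.replace(small_config, frac_multisubunit_receptors=0.0)
    )
    assert (single.receptor_subunits.str.split(";").str.len() == 1).all()
    empty = cp.generate_lr_database(dataclasses.replace(small_config, n_lr_pairs=0))
    assert empty.empty


def test_regulons_disjoint_and_expression_tracks_activity(small_config):
    regs = cp.generate_regulons(small_config)
    target_sets = [set(t.split(";")) for t in regs.targets]
    for i in range(len(target_sets)):
        for j in range(i + 1, len(target_sets)):
            assert not (target_sets[i] & target_sets[j])
    cohort, truth = cp.generate_paired_cohort(small_config)
    act = truth.regulon_activity
    gc_meta = cohort.meta[cohort.meta.cell_type == "granulosa"]
    expr = cp.normalize_logcpm(cohort.gc_counts)
    # granulosa samples with high true activity express the targets higher
    for rid in act.index[:5]:
        a = act.loc[rid, gc_meta.index]
        hi = a.nlargest(8).index
        lo = a.nsmallest(8).index
        if a[hi].mean() - a[lo].mean() < 0.2:
            continue  # unaffected regulon: no contrast to check
        targets = set(regs.set_index("regulon_id").loc[rid, "targets"].split(";"))
        t_expr = expr.loc[sorted(targets)]
        assert t_expr[hi].mean(axis=1).mean() > t_expr[lo].mean(axis=1).mean()


def test_dual_protocol_expectations(small_config):
    polya, total, tails, truth = cp.generate_dual_protocol_oocytes(small_config)
    classes = truth.tail_truth.set_index("gene")["remodeling_class"]
    cap = lambda t: tail_capture(t, small_config.tail_capture_midpoint)
    tt = truth.tail_truth.set_index("gene")
    re = tt[classes == "repolyadenylated"]
    # re-polyadenylated genes: capture strictly better in mature cells
    assert (cap(re.tail_mii.to_numpy()) > cap(re.tail_gv.to_numpy())).all()
    # degraded genes lose abundance: mature mean counts well below immature
    dg = classes.index[classes == "deadenylated_degraded"]
    mat = [c for c in total.sample_ids if c.startswith("mat")]
    imm = [c for c in total.sample_ids if c.startswith("imm")]
    ratio = total.values.loc[dg, mat].mean(axis=1) / total.values.loc[dg, imm].mean(axis=1)
    assert (ratio < 1).mean() > 0.99
    # pooled Monte-Carlo ratio tracks the planted abundance loss
    pooled = total.values.loc[dg, mat].to_numpy().sum() / total.values.loc[dg, imm].to_numpy().sum()
    reads = tails.set_index("gene").loc[dg]
    expected = float(
        (reads.reads_gv * np.exp(tt.loc[dg, "ln_read_ratio"])).sum() / reads.reads_gv.sum()
    )
    assert pooled == pytest.approx(expected, rel=0.5)


def test_embryo_series_monotone_genes_and_group_order(small_config):
    cm, meta, truth = cp.generate_embryo_series(small_config)
    logexp = cp.normalize_logcpm(cm)
    score = truth.embryo_meta["stage_score"]
    ref = meta.index[meta.role == "reference"]
    dev = truth.dev_gene_slopes[truth.dev_gene_slopes != 0].index
    from scipy.stats import spearmanr

    rhos = np.array(
        [abs(spearmanr(logexp.loc[g, ref], score.loc[ref]).statistic) for g in dev]
    )
    assert (rhos > 0.85).mean() >= 0.95
    grp = truth.embryo_meta[truth.embryo_meta.role == "test"].groupby("group")["stage_score"].mean()
    assert grp["NY"] > grp["S_N"] > grp["S"]
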