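"""End-to-end recovery experiments on synthetic cohorts.

Each function generates data with :mod:`cocpipe.simulate`, runs the relevant
analysis stages, and measures how well the planted structure is recovered.
They back both the acceptance test suite and ``scripts/acceptance.py``; the
problem sizes are chosen so the full battery runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import (
    SimConfig,
    activity_matrix,
    align_clusters,
    classify_table,
    cluster_profiles,
    compare_groups,
    concordance_test,
    consensus_clusters,
    cpm,
    design_with_covariate,
    diff_entropy,
    differential_activity,
    fit_projection,
    ga_select,
    generate_dual_protocol_oocytes,
    generate_embryo_series,
    generate_lr_database,
    generate_paired_cohort,
    generate_regulons,
    interaction_profiles,
    length_normalize,
    load_lr_table,
    load_regulon_table,
    nb_wald,
    normalize_logcpm,
    per_sample_log2fc,
    predict_consensus_frame,
    principal_curve_pseudotime,
    prune_features,
    pseudobulk,
    select_dev_genes,
    select_features_dge,
    train_dual,
)
from ._random import substream_seed
from .dge import DesignSpec
from .simulate import GroundTruth, PairedCohort


# ---------------------------------------------------------------------------
# shared young-cohort pipeline
# ---------------------------------------------------------------------------

def _young_config(seed: int, **overrides) -> SimConfig:
    """Three balanced clusters of ~10 young COCs (N subsampled to 10)."""
    kw = dict(n_mice_per_condition=5, cocs_per_mouse=4, sn_fraction=0.5, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


def young_cohort_analysis(cfg: SimConfig) -> dict:
    """Communication + activity clustering and consensus labels on young COCs.

    Returns profiles, activity matrix, aligned labelings, consensus labels and
    the planted truth, all indexed by coc_id.
    """
    cohort, gt = generate_paired_cohort(cfg)
    meta = cohort.meta
    young = meta[meta.condition.isin(("NY", "SY"))]
    ny_cocs = sorted(young.loc[young.condition == "NY", "coc_id"].unique())[:10]
    cocs = ny_cocs + sorted(young.loc[young.condition == "SY", "coc_id"].unique())
    sub = meta[meta.coc_id.isin(cocs)]

    oc_expr = length_normalize(cohort.oc_counts)
    gc_expr = length_normalize(cohort.gc_counts)
    oc = sub[sub.cell_type == "oocyte"][["coc_id", "sample_id"]].rename(
        columns={"sample_id": "oc_sample"}
    )
    gc = sub[sub.cell_type == "granulosa"][["coc_id", "sample_id"]].rename(
        columns={"sample_id": "gc_sample"}
    )
    pairing = oc.merge(gc, on="coc_id")
    db = load_lr_table(generate_lr_database(cfg))
    profiles = np.log1p(interaction_profiles(oc_expr, gc_expr, pairing, db))
    _, lab_cci = cluster_profiles(profiles, k=3)

    regulons = load_regulon_table(generate_regulons(cfg))
    gc_cols = list(sub.loc[sub.cell_type == "granulosa", "sample_id"])
    act = activity_matrix(normalize_logcpm(cohort.gc_counts.subset_samples(gc_cols)), regulons)
    act.columns = [sub.loc[c, "coc_id"] for c in act.columns]
    _, lab_tf = cluster_profiles(act, k=3)

    truth = pd.Series(
        {c: ("N" if c.startswith("NY") else gt.subgroup[c]) for c in profiles.columns},
        name="truth",
    )
    natural = pd.Series({c: c.startswith("NY") for c in profiles.columns})
    aligned_cci = align_clusters(lab_cci.loc[truth.index], profiles.T, natural)
    aligned_tf = align_clusters(lab_tf.loc[truth.index], act.T.loc[truth.index], natural)
    consensus = consensus_clusters(aligned_cci, aligned_tf)
    return {
        "cohort": cohort,
        "truth_obj": gt,
        "profiles": profiles,
        "activity": act,
        "labels_cci": aligned_cci,
        "labels_tf": aligned_tf,
        "consensus": consensus,
        "truth": truth,
        "meta": sub,
        "regulons": regulons,
    }


def consensus_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """ARI of consensus labels (with 'excluded' as its own category) vs truth."""
    aris = []
    for i in range(n_seeds):
        res = young_cohort_analysis(_young_config(substream_seed(base_seed, f"consensus{i}")))
        aris.append(
            adjusted_rand_score(res["truth"], res["consensus"].labels.loc[res["truth"].index])
        )
    aris = np.asarray(aris)
    return {
        "ari": aris.tolist(),
        "median_ari": float(np.median(aris)),
        "frac_ari_ge_0.8": float((aris >= 0.8).mean()),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# differential expression calibration and recovery
# ---------------------------------------------------------------------------

def _null_config(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed, n_genes=1000, n_lr_pairs=0, n_regulons=0, n_entropy_genes=0,
        n_de_super=0, n_de_aging=0, superovulation_lfc_scale=0.0, aging_lfc_scale=0.0,
    )


def nb_wald_type1(seed: int = 0, n_reps: int = 10) -> dict:
    """Empirical type-I error of the NB Wald test at nominal 0.05.

    Null cohorts (no planted effects), oocyte pseudo-bulk, 4 NY vs 4 SY mice,
    1000 genes per replicate; the mean over replicates estimates the rate.
    """
    rates = []
    for i in range(n_reps):
        cfg = _null_config(substream_seed(seed, f"type1-{i}"))
        cohort, _ = generate_paired_cohort(cfg)
        pb, _ = pseudobulk(cohort.oc_counts, cohort.meta)
        cols = [c for c in pb.sample_ids if c.startswith(("NY", "SY"))]
        cond = pd.Series([c.split("-")[0] for c in cols], index=cols)
        res = nb_wald(pb.subset_samples(cols), DesignSpec.two_group(cond))["group"]
        rates.append(float((res["pvalue"] < 0.05).mean()))
    return {"type1_error": float(np.mean(rates)), "per_rep": rates, "n_genes": 1000 * n_reps}


def lfc_recovery(seed: int = 0) -> dict:
    """Pearson r between naive group-mean log2 ratios and planted log2FCs."""
    cfg = SimConfig(seed=substream_seed(seed, "lfc_recovery"))
    cohort, gt = generate_paired_cohort(cfg)
    meta = cohort.meta
    gc_meta = meta[meta.cell_type == "granulosa"]
    expr = cpm(cohort.gc_counts)
    ny = gc_meta.index[gc_meta.condition == "NY"]
    s_cocs = set(gt.subgroup[gt.subgroup == "S"].index)
    sy_s = [i for i in gc_meta.index[gc_meta.condition == "SY"] if gc_meta.loc[i, "coc_id"] in s_cocs]
    naive = np.log2((expr[sy_s].mean(axis=1) + 1) / (expr[list(ny)].mean(axis=1) + 1))
    de = gt.de_flags["super"]
    r = float(np.corrcoef(naive[de], gt.lfc_super[de])[0, 1])
    return {"pearson_r": r, "n_de_genes": int(de.sum())}


# ---------------------------------------------------------------------------
# dual classifier
# ---------------------------------------------------------------------------

def _classifier_features(
    cohort: PairedCohort, gt: GroundTruth, cfg: SimConfig, labels: pd.Series,
    regulons: dict, seed: int, ga_pop: int, ga_gens: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Activity-view and expression-view training features for labeled GC samples.

    ``labels`` maps coc_id -> S_N/S for the training COCs.
    """
    meta = cohort.meta
    gc_meta = meta[(meta.cell_type == "granulosa") & meta.coc_id.isin(labels.index)]
    gc_cols = list(gc_meta.sample_id)
    counts = cohort.gc_counts.subset_samples(gc_cols)
    logexp = normalize_logcpm(counts)
    y = pd.Series(labels.loc[gc_meta.coc_id].to_numpy(), index=gc_cols)
    mice = gc_meta["mouse_id"]

    # activity view: regulons with significantly different activity
    act = activity_matrix(logexp, regulons)
    diff = differential_activity(act, y, blocks=mice, n_perm=2000,
                                 seed=substream_seed(seed, "perm"))
    sig = diff.index[diff["significant"]]
    if len(sig) == 0:  # fall back to the strongest shift rather than fail
        sig = diff["p"].sort_values().index[:1]
    X_tf = act.loc[sig].T

    # expression view: thresholded DGE with mouse covariate, PC1 filter, prune, GA
    design = design_with_covariate(y, mice.set_axis(gc_cols))
    dge_res = nb_wald(counts, design)["group"]
    genes = select_features_dge(dge_res, logexp)
    X = logexp.loc[genes].T
    kept = prune_features(X)
    selected = ga_select(
        X[kept], y, pop=ga_pop, gens=ga_gens, seed=substream_seed(seed, "ga")
    )
    return X_tf, X[selected]


def classifier_experiment(
    seed: int = 0,
    sn_effect_fraction: float = 0.3,
    ga_pop: int = 24,
    ga_gens: int = 8,
) -> dict:
    """Train the dual classifier end-to-end and evaluate on a fresh cohort.

    Training labels come from the consensus clustering of a training cohort;
    the classifier then predicts S_N/S for the superovulated granulosa samples
    of an independent test cohort, scored against the planted subgroups.
    Accuracy is over assigned (non-NA) predictions.
    """
    cfg_train = _young_config(substream_seed(seed, "clf_train"),
                              sn_effect_fraction=sn_effect_fraction)
    res = young_cohort_analysis(cfg_train)
    cons = res["consensus"].labels
    train_labels = cons[cons.isin(("S_N", "S"))]
    counts = train_labels.value_counts()
    if len(counts) < 2 or (counts < 4).any():
        # consensus failed to define trainable subgroups: classifier abstains
        return {"accuracy": float("nan"), "na_rate": 1.0, "trainable": False}

    regulons = res["regulons"]
    X_tf, X_dge = _classifier_features(
        res["cohort"], res["truth_obj"], cfg_train, train_labels, regulons,
        seed, ga_pop, ga_gens,
    )
    y = pd.Series(
        train_labels.loc[
            res["cohort"].meta.loc[X_tf.index, "coc_id"]
        ].to_numpy(),
        index=X_tf.index,
    )
    clf = train_dual(X_tf, X_dge.loc[X_tf.index], y, seed=substream_seed(seed, "svm"))

    # independent test cohort, same study conditions
    cfg_test = _young_config(substream_seed(seed, "clf_test"),
                             sn_effect_fraction=sn_effect_fraction)
    cohort_t, gt_t = generate_paired_cohort(cfg_test)
    meta_t = cohort_t.meta
    gc_t = meta_t[(meta_t.cell_type == "granulosa") & (meta_t.condition == "SY")]
    logexp_t = normalize_logcpm(cohort_t.gc_counts.subset_samples(list(gc_t.sample_id)))
    act_t = activity_matrix(logexp_t, regulons).T
    expr_t = logexp_t.T
    pred = predict_consensus_frame(
        clf, act_t[clf.model_tf.features], expr_t[clf.model_dge.features]
    )
    truth = gt_t.subgroup.loc[gc_t.loc[pred.index, "coc_id"]].set_axis(pred.index)
    assigned = pred != "NA"
    acc = float((pred[assigned] == truth[assigned]).mean()) if assigned.any() else float("nan")
    return {
        "accuracy": acc,
        "na_rate": float((~assigned).mean()),
        "n_test": int(len(pred)),
        "n_features_tf": len(clf.model_tf.features),
        "n_features_dge": len(clf.model_dge.features),
        "trainable": True,
    }


def na_monotonicity(seed: int = 0, separations=(0.0, 0.15, 0.3)) -> dict:
    """NA rate of the end-to-end classifier as subgroup separation grows.

    The separation knob positions S_N between N (separation 0.3, the default
    study condition: S_N at 30% of the full shift, well apart from S) and S
    itself (separation 0: S_N carries the full shift and is indistinguishable
    from S, so consensus training labels and the two views degrade into
    disagreement). Concretely sn_effect_fraction = 1 - separation/0.3 * 0.7.
    """
    out = {}
    for sep in separations:
        frac = 1.0 - (sep / 0.3) * 0.7
        r = classifier_experiment(seed=seed, sn_effect_fraction=frac)
        out[sep] = r["na_rate"]
    return {"na_rate_by_separation": out}


# ---------------------------------------------------------------------------
# remodeling
# ---------------------------------------------------------------------------

def remodeling_recovery(seed: int = 0) -> dict:
    """Per-class recovery of planted remodeling classes + concordance verdicts."""
    cfg = SimConfig(seed=substream_seed(seed, "remodel"))
    polya, total, tails, gt = generate_dual_protocol_oocytes(cfg)
    called = classify_table(tails)
    truth = gt.tail_truth.set_index("gene")["remodeling_class"]
    per_class = {}
    for cls in truth.unique():
        genes = truth.index[truth == cls]
        per_class[cls] = float((called.loc[genes] == cls).mean())

    groups = gt.dual_meta["maturity"]
    disrupted = list(gt.dual_meta.index[groups == "immature"])
    lfc_p = per_sample_log2fc(cpm(polya), groups)
    lfc_t = per_sample_log2fc(cpm(total), groups)
    conc = concordance_test(lfc_p, lfc_t, truth, disrupted)
    return {
        "per_class_accuracy": per_class,
        "min_class_accuracy": float(min(per_class.values())),
        "verdicts": conc["verdict"].to_dict(),
        "n_consistent": int((conc["verdict"] == "consistent").sum()),
    }


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

def pseudotime_recovery(seed: int = 0) -> dict:
    """Stage recovery on the reference series + group ordering on test embryos."""
    cfg = SimConfig(seed=substream_seed(seed, "embryo"))
    cm, meta, gt = generate_embryo_series(cfg)
    logexp = normalize_logcpm(cm)
    ref = meta.index[meta.role == "reference"]
    stages = meta.loc[ref, "stage"]
    panel = select_dev_genes(logexp[list(ref)], stages)
    pt = principal_curve_pseudotime(
        logexp.loc[panel.genes].T, ref_stages=meta["stage"].where(meta.role == "reference")
    )
    truth = gt.embryo_meta["stage_score"]
    rho_ref = float(
        stats.spearmanr(pt.pseudotime.loc[ref], truth.loc[ref]).statistic
    )
    test = meta.index[meta.role == "test"]
    comp = compare_groups(pt.pseudotime.loc[test], meta.loc[test, "group"])
    pair_p = {
        f"{r.group_a}|{r.group_b}": float(r.p) for r in comp.itertuples()
    }
    medians = {
        g: float(pt.pseudotime.loc[test][meta.loc[test, "group"] == g].median())
        for g in ("NY", "S_N", "S")
    }
    return {
        "spearman_ref": abs(rho_ref),
        "panel_size": len(panel.genes),
        "group_medians": medians,
        "pairwise_p": pair_p,
    }


# ---------------------------------------------------------------------------
# interaction decomposition
# ---------------------------------------------------------------------------

def _interaction_run(seed: int, attenuation: float) -> tuple[float, tuple[float, float]]:
    cfg = SimConfig(
        seed=seed, n_genes=800, n_lr_pairs=0, n_regulons=0, n_entropy_genes=0,
        n_de_super=150, n_de_aging=100, cocs_per_mouse=4,
        interaction_attenuation=attenuation,
    )
    cohort, gt = generate_paired_cohort(cfg)
    meta = cohort.meta
    gc_meta = meta[meta.cell_type == "granulosa"]
    expr = normalize_logcpm(cohort.gc_counts)
    de_genes = list(gt.de_flags.index[gt.de_flags["super"]])
    dec = fit_projection(expr[list(gc_meta.index)], de_genes, gc_meta,
                         n_boot=1000, seed=seed)
    return dec.effects["interaction"], dec.ci["interaction"]


def interaction_calibration(seed: int = 0, n_runs: int = 50) -> dict:
    """CI coverage under additivity and sign recovery under attenuation 0.2."""
    cover = 0
    for i in range(n_runs):
        _, ci = _interaction_run(substream_seed(seed, f"addtv{i}"), attenuation=1.0)
        cover += ci[0] <= 0.0 <= ci[1]
    neg = 0
    for i in range(n_runs):
        est, _ = _interaction_run(substream_seed(seed, f"atten{i}"), attenuation=0.2)
        neg += est < 0
    return {
        "ci_coverage_additive": cover / n_runs,
        "negative_sign_rate_attenuated": neg / n_runs,
        "n_runs": n_runs,
    }


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def entropy_detection(seed: int = 0) -> dict:
    """Fraction of variance-inflated genes with dShE > 0 (SY vs NY oocytes)."""
    cfg = SimConfig(seed=substream_seed(seed, "entropy_eval"))
    cohort, gt = generate_paired_cohort(cfg)
    meta = cohort.meta
    oc = meta[meta.cell_type == "oocyte"]
    expr = normalize_logcpm(cohort.oc_counts)
    sy = expr[list(oc.index[oc.condition == "SY"])]
    ny = expr[list(oc.index[oc.condition == "NY"])]
    res = diff_entropy(sy, ny, n_perm=50, seed=seed)
    hit = res.loc[gt.entropy_genes, "dShE"] > 0
    return {"detection_rate": float(hit.mean()), "n_inflated_genes": int(len(hit))}
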