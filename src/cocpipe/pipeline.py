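"""End-to-end pipeline: simulate -> QC -> DGE -> communication -> activity ->
consensus/classifier -> remodeling -> pseudotime -> entropy -> interaction.

Every stage reads its inputs from and writes its outputs to a run directory
in plain-text formats (MatrixMarket + TSV sidecars, TSV tables, JSON), so
stages can be run individually from the CLI after ``simulate``, and a rerun
with the same configuration reproduces every output bit-for-bit. A manifest
records the configuration, seeds and SHA-256 digests of all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._random import substream_seed
from .activity import activity_matrix, differential_activity, load_regulon_table
from .ccc import cluster_profiles, interaction_profiles, load_lr_table, screen_pairs, top_expressed_lr
from .consensus import (
    align_clusters,
    consensus_clusters,
    ga_select,
    predict_consensus_frame,
    prune_features,
    select_features_dge,
    train_dual,
)
from .dge import DesignSpec, design_with_covariate, nb_wald, ora, adjust_bh
from .matrix import CountMatrix
from .qc import QCThresholds, cpm, length_normalize, normalize_logcpm, pseudobulk, qc_filter
from .remodeling import classify_table, concordance_test, per_sample_log2fc
from .simulate import (
    SimConfig,
    generate_dual_protocol_oocytes,
    generate_embryo_series,
    generate_lr_database,
    generate_paired_cohort,
    generate_regulons,
)
from .trajectory import compare_groups, principal_curve_pseudotime, select_dev_genes
from .variability import diff_entropy, fit_projection

STAGES = (
    "simulate", "qc", "dge", "ccc", "activity", "classify",
    "remodel", "trajectory", "entropy", "interaction",
)

_KNOWN_KEYS = {"seed", "stages", "sim", "qc", "ccc", "activity", "classify", "entropy",
               "interaction", "dge"}


class PipelineConfig:
    """Validated pipeline configuration (strict: unknown keys rejected)."""

    def __init__(self, raw: dict | None = None):
        raw = dict(raw or {})
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.stages = list(raw.get("stages", STAGES))
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        self.sim = dict(raw.get("sim", {}))
        self.qc = dict(raw.get("qc", {}))
        self.ccc = dict(raw.get("ccc", {}))
        self.activity = dict(raw.get("activity", {}))
        self.classify = dict(raw.get("classify", {}))
        self.entropy = dict(raw.get("entropy", {}))
        self.interaction = dict(raw.get("interaction", {}))
        self.dge = dict(raw.get("dge", {}))
        self.raw = raw

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=substream_seed(self.seed, "simulate"), **self.sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """A run directory with helpers to load stage inputs back from disk."""

    def __init__(self, outdir: str | Path, config: PipelineConfig):
        self.dir = Path(outdir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config

    # -- loaders ------------------------------------------------------------
    def counts(self, name: str) -> CountMatrix:
        return CountMatrix.from_mtx_dir(self.dir / name)

    def meta(self) -> pd.DataFrame:
        df = pd.read_csv(self.dir / "meta.tsv", sep="\t").set_index("sample_id", drop=False)
        df.index.name = None
        return df

    def gene_meta(self) -> pd.DataFrame:
        df = pd.read_csv(self.dir / "gene_meta.tsv", sep="\t").set_index("gene_id", drop=False)
        df.index.name = None
        return df

    def gene_lengths(self) -> pd.Series:
        gm = self.gene_meta()
        return pd.Series(gm["length_bp"].to_numpy(), index=gm.index)

    def subgroups(self) -> pd.Series:
        df = pd.read_csv(self.dir / "subgroups.tsv", sep="\t", index_col=0)
        return df["subgroup"]

    # -- stages -------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.sim_config()
        cohort, truth = generate_paired_cohort(cfg)
        cohort.oc_counts.to_mtx_dir(self.dir / "oc_counts")
        cohort.gc_counts.to_mtx_dir(self.dir / "gc_counts")
        cohort.meta.to_csv(self.dir / "meta.tsv", sep="\t", index=False)
        cohort.gene_meta.to_csv(self.dir / "gene_meta.tsv", sep="\t", index=False)
        truth.subgroup.rename("subgroup").to_csv(self.dir / "subgroups.tsv", sep="\t")
        truth.to_json(self.dir / "ground_truth.json")
        generate_lr_database(cfg).to_csv(self.dir / "lr_db.tsv", sep="\t", index=False)
        generate_regulons(cfg).to_csv(self.dir / "regulons.tsv", sep="\t", index=False)
        polya, total, tails, dual_truth = generate_dual_protocol_oocytes(cfg)
        polya.to_tsv(self.dir / "dual_polya.tsv")
        total.to_tsv(self.dir / "dual_total.tsv")
        tails.to_csv(self.dir / "tails.tsv", sep="\t", index=False)
        dual_truth.dual_meta.to_csv(self.dir / "dual_meta.tsv", sep="\t", index=False)
        emb, emb_meta, emb_truth = generate_embryo_series(cfg)
        emb.to_tsv(self.dir / "embryo_counts.tsv")
        emb_meta.to_csv(self.dir / "embryo_meta.tsv", sep="\t", index=False)

    def stage_qc(self) -> None:
        gm = self.gene_meta()
        thresholds = QCThresholds(**self.config.qc) if self.config.qc else QCThresholds()
        report = {}
        for name in ("oc_counts", "gc_counts"):
            filtered, rep = qc_filter(self.counts(name), gm, thresholds)
            filtered.to_mtx_dir(self.dir / f"{name}_qc")
            report[name] = rep.to_dict()
        (self.dir / "qc_report.json").write_text(json.dumps(report, indent=1))

    def stage_dge(self) -> None:
        meta = self.meta()
        regulons = pd.read_csv(self.dir / "regulons.tsv", sep="\t")
        pathway_sets = {
            r.regulon_id: set(str(r.targets).split(";")) for r in regulons.itertuples()
        }
        for name, ct in (("oc", "oc_counts_qc"), ("gc", "gc_counts_qc")):
            cm = self.counts(ct)
            pb, prov = pseudobulk(cm, meta, group_keys=("mouse_id",))
            cond = pd.Series(
                [c.split("-m")[0] for c in pb.sample_ids], index=pb.sample_ids
            )
            design = DesignSpec.from_conditions(cond)
            results = nb_wald(pb, design)
            for contrast, table in results.items():
                table.to_csv(self.dir / f"dge_{name}_{contrast}.tsv", sep="\t",
                             index_label="gene_id")
            # over-representation of regulon-target sets in superovulation hits
            res = results["super_young"]
            hits = set(res.index[(res["padj"] < 0.05).fillna(False)])
            universe = set(res.index)
            rows = []
            for pname, genes in pathway_sets.items():
                r = ora(hits, universe, genes)
                r["pathway"] = pname
                rows.append(r)
            ora_df = pd.DataFrame(rows).set_index("pathway")
            ora_df["padj"] = adjust_bh(ora_df["p"].to_numpy())
            ora_df.to_csv(self.dir / f"ora_{name}_super_young.tsv", sep="\t")

    def _young_pairing(self, meta: pd.DataFrame) -> pd.DataFrame:
        young = meta[meta.condition.isin(("NY", "SY"))]
        oc = young[young.cell_type == "oocyte"][["coc_id", "sample_id"]].rename(
            columns={"sample_id": "oc_sample"}
        )
        gc = young[young.cell_type == "granulosa"][["coc_id", "sample_id"]].rename(
            columns={"sample_id": "gc_sample"}
        )
        return oc.merge(gc, on="coc_id")

    def stage_ccc(self) -> None:
        meta = self.meta()
        lengths = self.gene_lengths()
        oc = self.counts("oc_counts_qc")
        gc = self.counts("gc_counts_qc")
        oc_expr = length_normalize(oc, lengths)
        gc_expr = length_normalize(gc, lengths)
        pairing = self._young_pairing(meta)
        pairing = pairing[
            pairing.oc_sample.isin(oc.sample_ids) & pairing.gc_sample.isin(gc.sample_ids)
        ]
        db = load_lr_table(pd.read_csv(self.dir / "lr_db.tsv", sep="\t"))
        k = int(self.config.ccc.get("top_k", 100))
        lig_mean = oc_expr[pairing.oc_sample].mean(axis=1)
        rec_mean = gc_expr[pairing.gc_sample].mean(axis=1)
        db = top_expressed_lr(db, lig_mean, rec_mean, k=k)
        profiles = np.log1p(interaction_profiles(oc_expr, gc_expr, pairing, db))
        profiles.to_csv(self.dir / "ccc_profiles.tsv", sep="\t")
        _, labels = cluster_profiles(profiles, k=3)
        screen = screen_pairs(profiles, labels)
        screen.to_csv(self.dir / "ccc_screen.tsv", sep="\t")
        labels.rename("cluster").to_csv(self.dir / "ccc_clusters.tsv", sep="\t")

    def stage_activity(self) -> None:
        meta = self.meta()
        gc = self.counts("gc_counts_qc")
        young_gc = meta[
            (meta.cell_type == "granulosa") & meta.condition.isin(("NY", "SY"))
            & meta.sample_id.isin(gc.sample_ids)
        ]
        logexp = normalize_logcpm(gc.subset_samples(list(young_gc.sample_id)))
        regulons = load_regulon_table(pd.read_csv(self.dir / "regulons.tsv", sep="\t"))
        act = activity_matrix(logexp, regulons,
                              top_frac=float(self.config.activity.get("top_frac", 0.2)))
        act.to_csv(self.dir / "activity.tsv", sep="\t")
        labels = pd.Series(young_gc.condition.to_numpy(), index=act.columns)
        diff = differential_activity(
            act, labels, blocks=young_gc["mouse_id"].set_axis(act.columns),
            n_perm=int(self.config.activity.get("n_perm", 2000)),
            seed=substream_seed(self.config.seed, "activity"),
        )
        diff.to_csv(self.dir / "activity_diff.tsv", sep="\t")
        act_by_coc = act.copy()
        act_by_coc.columns = young_gc.loc[act.columns, "coc_id"]
        _, clusters = cluster_profiles(act_by_coc, k=3)
        clusters.rename("cluster").to_csv(self.dir / "activity_clusters.tsv", sep="\t")

    def stage_classify(self) -> None:
        meta = self.meta()
        profiles = pd.read_csv(self.dir / "ccc_profiles.tsv", sep="\t",
                               index_col=[0, 1])
        cci_clusters = pd.read_csv(self.dir / "ccc_clusters.tsv", sep="\t", index_col=0)["cluster"]
        act = pd.read_csv(self.dir / "activity.tsv", sep="\t", index_col=0)
        tf_clusters = pd.read_csv(self.dir / "activity_clusters.tsv", sep="\t", index_col=0)["cluster"]
        gc = self.counts("gc_counts_qc")
        young_gc = meta[(meta.cell_type == "granulosa") & meta.condition.isin(("NY", "SY"))]
        coc_of = young_gc.set_index("sample_id")["coc_id"]
        act_by_coc = act.copy()
        act_by_coc.columns = [coc_of[c] for c in act.columns]

        cocs = [c for c in profiles.columns if c in act_by_coc.columns]
        natural = pd.Series({c: c.startswith("NY") for c in cocs})
        aligned_cci = align_clusters(cci_clusters.loc[cocs], profiles[cocs].T, natural)
        aligned_tf = align_clusters(tf_clusters.loc[cocs], act_by_coc[cocs].T, natural)
        cons = consensus_clusters(aligned_cci, aligned_tf)
        cons.labels.to_csv(self.dir / "consensus_labels.tsv", sep="\t")

        train = cons.labels[cons.labels.isin(("S_N", "S"))]
        counts_ok = train.value_counts()
        seed = substream_seed(self.config.seed, "classify")
        if len(counts_ok) < 2 or (counts_ok < 4).any():
            (self.dir / "classifier_report.json").write_text(
                json.dumps({"trained": False, "reason": "too few consensus samples"})
            )
            return
        gc_meta = meta[(meta.cell_type == "granulosa") & meta.coc_id.isin(train.index)]
        gc_cols = list(gc_meta.sample_id)
        counts = gc.subset_samples(gc_cols)
        logexp = normalize_logcpm(counts)
        y = pd.Series(train.loc[gc_meta.coc_id].to_numpy(), index=gc_cols)
        mice = gc_meta["mouse_id"].set_axis(gc_cols)

        regulons = load_regulon_table(pd.read_csv(self.dir / "regulons.tsv", sep="\t"))
        act_train = activity_matrix(logexp, regulons)
        diff = differential_activity(act_train, y, blocks=mice, n_perm=2000,
                                     seed=substream_seed(seed, "perm"))
        sig = diff.index[diff["significant"]]
        if len(sig) == 0:
            sig = diff["p"].sort_values().index[:1]
        X_tf = act_train.loc[sig].T

        design = design_with_covariate(y, mice)
        dge_res = nb_wald(counts, design)["group"]
        genes = select_features_dge(dge_res, logexp)
        X = logexp.loc[genes].T
        kept = prune_features(X)
        selected = ga_select(
            X[kept], y,
            pop=int(self.config.classify.get("ga_pop", 24)),
            gens=int(self.config.classify.get("ga_gens", 8)),
            seed=substream_seed(seed, "ga"),
        )
        clf = train_dual(X_tf, X[selected], y, seed=substream_seed(seed, "svm"))
        clf.save(self.dir / "classifier.json")

        # predict superovulated-old granulosa samples
        so_gc = meta[(meta.cell_type == "granulosa") & (meta.condition == "SO")
                     & meta.sample_id.isin(gc.sample_ids)]
        logexp_so = normalize_logcpm(gc.subset_samples(list(so_gc.sample_id)))
        act_so = activity_matrix(logexp_so, regulons).T
        pred = predict_consensus_frame(
            clf, act_so[clf.model_tf.features], logexp_so.T[clf.model_dge.features]
        )
        pred.to_csv(self.dir / "classifier_predictions.tsv", sep="\t")
        report = {
            "trained": True,
            "n_train": int(len(y)),
            "cv_accuracy_tf": clf.model_tf.cv_accuracy,
            "cv_accuracy_dge": clf.model_dge.cv_accuracy,
            "n_features_tf": len(clf.model_tf.features),
            "n_features_dge": len(clf.model_dge.features),
            "na_rate_so": float((pred == "NA").mean()),
        }
        (self.dir / "classifier_report.json").write_text(json.dumps(report, indent=1))

    def stage_remodel(self) -> None:
        tails = pd.read_csv(self.dir / "tails.tsv", sep="\t")
        classes = classify_table(tails)
        classes.rename("remodeling_class").to_csv(self.dir / "remodel_classes.tsv", sep="\t")
        polya = CountMatrix.from_tsv(self.dir / "dual_polya.tsv")
        total = CountMatrix.from_tsv(self.dir / "dual_total.tsv")
        dual_meta = pd.read_csv(self.dir / "dual_meta.tsv", sep="\t").set_index("sample_id")
        groups = dual_meta["maturity"]
        disrupted = list(dual_meta.index[groups == "immature"])
        conc = concordance_test(
            per_sample_log2fc(cpm(polya), groups),
            per_sample_log2fc(cpm(total), groups),
            classes, disrupted,
        )
        conc.to_csv(self.dir / "remodel_concordance.tsv", sep="\t")

    def stage_trajectory(self) -> None:
        cm = CountMatrix.from_tsv(self.dir / "embryo_counts.tsv")
        emb_meta = pd.read_csv(self.dir / "embryo_meta.tsv", sep="\t").set_index(
            "sample_id", drop=False
        )
        emb_meta.index.name = None
        logexp = normalize_logcpm(cm)
        ref = emb_meta.index[emb_meta.role == "reference"]
        panel = select_dev_genes(logexp[list(ref)], emb_meta.loc[ref, "stage"])
        panel.table.to_csv(self.dir / "dev_panel.tsv", sep="\t", index_label="gene_id")
        pt = principal_curve_pseudotime(
            logexp.loc[panel.genes].T,
            ref_stages=emb_meta["stage"].where(emb_meta.role == "reference"),
        )
        out = pd.DataFrame({"pseudotime": pt.pseudotime, "group": emb_meta["group"]})
        out.to_csv(self.dir / "pseudotime.tsv", sep="\t", index_label="sample_id")
        test = emb_meta.index[emb_meta.role == "test"]
        comp = compare_groups(pt.pseudotime.loc[test], emb_meta.loc[test, "group"])
        comp.to_csv(self.dir / "pseudotime_group_tests.tsv", sep="\t", index=False)

    def stage_entropy(self) -> None:
        meta = self.meta()
        oc = self.counts("oc_counts_qc")
        oc_meta = meta[(meta.cell_type == "oocyte") & meta.sample_id.isin(oc.sample_ids)]
        expr = normalize_logcpm(oc)
        sy = expr[list(oc_meta.index[oc_meta.condition == "SY"])]
        ny = expr[list(oc_meta.index[oc_meta.condition == "NY"])]
        res = diff_entropy(
            sy, ny,
            n_perm=int(self.config.entropy.get("n_perm", 200)),
            seed=substream_seed(self.config.seed, "entropy"),
        )
        res.to_csv(self.dir / "entropy_sy_vs_ny.tsv", sep="\t", index_label="gene_id")

    def stage_interaction(self) -> None:
        meta = self.meta()
        gc = self.counts("gc_counts_qc")
        gc_meta = meta[(meta.cell_type == "granulosa") & meta.sample_id.isin(gc.sample_ids)]
        expr = normalize_logcpm(gc)
        dge = pd.read_csv(self.dir / "dge_gc_super_young.tsv", sep="\t", index_col=0)
        de_genes = list(dge.index[(dge["padj"] < 0.05).fillna(False)])
        if len(de_genes) < 2:
            de_genes = list(dge["pvalue"].sort_values().index[:50])
        dec = fit_projection(
            expr[list(gc_meta.index)], de_genes, gc_meta,
            n_boot=int(self.config.interaction.get("n_boot", 1000)),
            seed=substream_seed(self.config.seed, "interaction"),
        )
        out = {
            "group_means_pc1": dec.group_means,
            "effects": dec.effects,
            "ci95": dec.ci,
            "n_boot": dec.n_boot,
            "n_de_genes": len(de_genes),
        }
        (self.dir / "interaction_decomposition.json").write_text(json.dumps(out, indent=1))

    # -- orchestration ------------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        stages = stages or self.config.stages
        for s in stages:
            try:
                getattr(self, f"stage_{s}")()
            except Exception as e:  # abort with stage name per contract
                raise RuntimeError(f"pipeline stage '{s}' failed: {e}") from e
        return self.write_manifest(stages)

    def write_manifest(self, stages: list[str]) -> dict:
        outputs = {}
        for p in sorted(self.dir.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                outputs[str(p.relative_to(self.dir))] = _sha256(p)
        manifest = {
            "package_version": __version__,
            "seed": self.config.seed,
            "stages": stages,
            "config": self.config.raw,
            "outputs": outputs,
        }
        (self.dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest


def run_pipeline(
    config: PipelineConfig | dict | str | Path | None,
    outdir: str | Path,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Run the pipeline into ``outdir`` and return the manifest."""
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig(config)
    if seed is not None:
        config.seed = int(seed)
        config.raw["seed"] = int(seed)
    return PipelineRun(outdir, config).run(stages)
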