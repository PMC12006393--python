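"""Synthetic paired cumulus-oocyte-complex (COC) cohort generator.

Emulates the statistical structure of a superovulation/aging study in mice:

* four condition groups — naturally ovulated young (NY), superovulated young
  (SY), naturally ovulated old (NO), superovulated old (SO) — with mouse-level
  replication and one oocyte sample plus one granulosa bulk per COC;
* negative-binomial counts with a global dispersion and per-mouse baseline
  variation;
* a latent split of superovulated COCs into S_N (attenuated superovulation
  response, resembling natural ovulation) and S (full response);
* attenuation of the superovulation effect in old animals (the aging x
  superovulation interaction);
* ligand-receptor co-expression within a COC, with condition-dependent
  communication shifts on a subset of pairs;
* regulon-driven target expression scaled by a per-sample true activity;
* a designated gene subset with inflated expression variability;
* a dual-protocol (poly-A-selected vs total RNA) oocyte maturation experiment
  driven by per-gene poly(A)-tail remodeling classes; and
* a staged pre-implantation embryo series with monotone stage-marker genes.

Every generator returns the ground truth needed for recovery-based testing.
All randomness flows from ``SimConfig.seed`` through named streams, so a
configuration is a complete, reproducible description of a synthetic study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._random import stream
from .matrix import CountMatrix

CONDITIONS = ("NY", "SY", "NO", "SO")
STAGES = ("2cell", "4cell", "8cell", "morula", "blastocyst")
REMODEL_CLASSES = (
    "repolyadenylated",
    "deadenylated_stable",
    "deadenylated_degraded",
    "unclassified",
)


class ConfigurationError(ValueError):
    """Raised when a SimConfig cannot be realized."""


@dataclass
class SimConfig:
    """Study-design and effect-size parameters for all synthetic generators.

    The defaults describe a modest paired cohort: 4 mice per condition with
    8 COCs each, a 2000-gene universe, a two-fold (log2 = 2) superovulation
    shift on 200 genes, a one-fold aging shift on 150 genes, 50% attenuation
    of the superovulation response in old mice, and an S_N subgroup that
    receives 30% of the full superovulation shift.
    """

    # cohort design
    n_mice_per_condition: int = 4
    cocs_per_mouse: int = 8          # one oocyte + one granulosa bulk per COC
    n_genes: int = 2000
    # ligand-receptor communication
    n_lr_pairs: int = 60
    frac_multisubunit_receptors: float = 0.3
    frac_lr_affected: float = 0.8
    lr_shift_scale: float = 3.0      # log2 communication shift in S COCs
    lr_coexpr_sd: float = 0.2        # per-COC shared log2 noise on a pair
    lr_abundance_boost: float = 8.0  # baseline multiplier for LR genes
    # regulons
    n_regulons: int = 20
    targets_per_regulon: int = 40
    frac_regulons_affected: float = 0.8
    regulon_base_activity: float = 0.2
    regulon_activity_shift: float = 0.6
    activity_lfc_scale: float = 4.0  # log2 target shift per unit activity
    # planted condition effects
    n_de_super: int = 200
    n_de_aging: int = 150
    superovulation_lfc_scale: float = 2.0
    aging_lfc_scale: float = 1.0
    interaction_attenuation: float = 0.5  # multiplier on the SO response
    sn_fraction: float = 0.5
    sn_effect_fraction: float = 0.3
    # noise model
    nb_dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (50_000, 100_000)
    mouse_effect_sd: float = 0.1     # per-mouse log-normal baseline sd
    mito_mass_fraction: float = 0.02
    # expression variability
    n_entropy_genes: int = 100
    entropy_inflation: float = 4.0   # variance multiplier in SY/SO oocytes
    # dual-protocol maturation experiment
    tail_capture_midpoint: float = 25.0  # nt at which capture efficiency = 0.5
    dual_samples_per_group: int = 16
    frac_repoly: float = 0.08
    frac_dead_stable: float = 0.08
    frac_dead_degraded: float = 0.08
    # embryo series
    embryos_per_stage: int = 6
    n_dev_genes: int = 150
    dev_noise_sd: float = 0.1
    embryo_dispersion: float = 0.02
    embryo_group_sizes: tuple[int, int, int] = (22, 17, 21)   # NY, S_N, S
    embryo_group_stage_means: tuple[float, float, float] = (4.2, 3.6, 3.0)
    embryo_stage_sd: float = 0.3
    seed: int = 0
    # the planted biology (gene allocation, baselines, effect sizes, which
    # pairs/regulons respond) is drawn from its own seed, so varying `seed`
    # resamples mice/counts from the SAME underlying study
    biology_seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_multisubunit_receptors": self.frac_multisubunit_receptors,
            "frac_lr_affected": self.frac_lr_affected,
            "frac_regulons_affected": self.frac_regulons_affected,
            "interaction_attenuation": self.interaction_attenuation,
            "sn_fraction": self.sn_fraction,
            "sn_effect_fraction": self.sn_effect_fraction,
            "frac_repoly": self.frac_repoly,
            "frac_dead_stable": self.frac_dead_stable,
            "frac_dead_degraded": self.frac_dead_degraded,
            "mito_mass_fraction": self.mito_mass_fraction,
        }
        for name, f in fracs.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError(f"{name}={f} outside [0, 1]")
        if self.n_genes < 2 * (self.n_lr_pairs + self.n_regulons * self.targets_per_regulon):
            raise ConfigurationError(
                "n_genes must be at least twice the number of ligand-receptor "
                "and regulon-target genes"
            )
        if self.lib_size_range[0] < 1 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise ConfigurationError("invalid lib_size_range")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.n_regulons > 0 and self.targets_per_regulon <= 0:
            raise ConfigurationError("targets_per_regulon must be positive")
        # a hard count check: every special gene needs its own slot
        n_special = (
            self.n_lr_pairs * 4  # ligand + up to 3 subunits
            + self.n_regulons * (1 + self.targets_per_regulon)
            + self.n_entropy_genes
            + self.n_de_super
            + self.n_de_aging
        )
        if n_special > self.n_genes:
            raise ConfigurationError(
                f"{n_special} special genes exceed n_genes={self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Planted effects backing recovery-based tests.

    Only the fields produced by the generator that built the object are
    populated; the rest stay ``None``.
    """

    sample_meta: pd.DataFrame | None = None       # sample_id, coc_id, mouse_id, condition, cell_type
    subgroup: pd.Series | None = None             # per superovulated coc_id: S_N or S
    lfc_super: pd.Series | None = None
    lfc_aging: pd.Series | None = None
    lfc_interaction: pd.Series | None = None
    de_flags: pd.DataFrame | None = None          # gene x {super, aging, interaction}
    lr_truth: pd.DataFrame | None = None          # pair_id, affected, sign
    regulon_activity: pd.DataFrame | None = None  # regulon x sample in [0, 1]
    entropy_genes: list[str] | None = None
    tail_truth: pd.DataFrame | None = None        # gene, true class, tails, ln read ratio
    dual_meta: pd.DataFrame | None = None
    embryo_meta: pd.DataFrame | None = None       # sample_id, role, group, stage, stage_score
    dev_gene_slopes: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        blob: dict = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            if isinstance(v, pd.DataFrame):
                blob[k] = {"__frame__": v.reset_index().to_dict(orient="list")}
            elif isinstance(v, pd.Series):
                blob[k] = {"__series__": {"index": list(v.index), "values": v.tolist()}}
            else:
                blob[k] = v
        Path(path).write_text(json.dumps(blob, indent=1))


@dataclass
class PairedCohort:
    """Oocyte and granulosa count matrices with COC-level pairing metadata."""

    oc_counts: CountMatrix
    gc_counts: CountMatrix
    meta: pd.DataFrame        # indexed by sample_id
    gene_meta: pd.DataFrame   # gene_id, length_bp, is_mito

    def __post_init__(self) -> None:
        oc = set(self.meta.loc[self.meta.cell_type == "oocyte", "coc_id"])
        gc = set(self.meta.loc[self.meta.cell_type == "granulosa", "coc_id"])
        if oc != gc:
            raise ValueError("every COC must have exactly one oocyte and one granulosa sample")


# ---------------------------------------------------------------------------
# gene universe allocation
# ---------------------------------------------------------------------------

@dataclass
class _GeneAllocation:
    gene_ids: pd.Index
    lengths: np.ndarray
    is_mito: np.ndarray
    ligand_idx: np.ndarray                 # (n_lr,)
    subunit_idx: list[np.ndarray]          # per pair, 1-3 gene indices
    tf_idx: np.ndarray                     # (n_regulons,)
    target_idx: list[np.ndarray]           # per regulon
    entropy_idx: np.ndarray
    super_idx: np.ndarray
    aging_idx: np.ndarray


def _allocate_genes(cfg: SimConfig) -> _GeneAllocation:
    rng = stream(cfg.biology_seed, "genes")
    G = cfg.n_genes
    n_mito = max(5, G // 100)
    ids = [f"g{i:04d}" for i in range(G - n_mito)] + [f"mt-g{i:04d}" for i in range(n_mito)]
    is_mito = np.zeros(G, bool)
    is_mito[G - n_mito:] = True
    lengths = np.round(np.exp(rng.normal(7.5, 0.6, size=G))).astype(int).clip(200, None)

    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = np.arange(cursor, cursor + n)
        cursor += n
        return out

    ligand_idx = take(cfg.n_lr_pairs)
    n_sub = np.ones(cfg.n_lr_pairs, int)
    multi = rng.random(cfg.n_lr_pairs) < cfg.frac_multisubunit_receptors
    n_sub[multi] = rng.integers(2, 4, size=multi.sum())
    subunit_idx = [take(k) for k in n_sub]
    tf_idx = take(cfg.n_regulons)
    target_idx = [take(cfg.targets_per_regulon) for _ in range(cfg.n_regulons)]
    entropy_idx = take(cfg.n_entropy_genes)
    super_idx = take(cfg.n_de_super)
    aging_idx = take(cfg.n_de_aging)
    if cursor > G - n_mito:
        raise ConfigurationError("special genes exceed the non-mitochondrial gene pool")
    return _GeneAllocation(
        pd.Index(ids, name="gene_id"), lengths, is_mito, ligand_idx, subunit_idx,
        tf_idx, target_idx, entropy_idx, super_idx, aging_idx,
    )


def _signed_lfc(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Non-zero planted log2 fold changes: random sign, |lfc| in [scale/2, scale]."""
    if scale == 0:
        return np.zeros(n)
    mag = rng.uniform(0.5 * scale, scale, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * mag


# ---------------------------------------------------------------------------
# sample table + subgroups
# ---------------------------------------------------------------------------

def _sample_table(cfg: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """COC-level metadata for both cell types plus the latent S_N/S split."""
    rng = stream(cfg.seed, "subgroups")
    rows = []
    subgroup: dict[str, str] = {}
    for cond in CONDITIONS:
        cocs = [
            f"{cond}-m{m}-c{c}"
            for m in range(cfg.n_mice_per_condition)
            for c in range(cfg.cocs_per_mouse)
        ]
        if cond in ("SY", "SO"):
            order = rng.permutation(len(cocs))
            k = int(round(cfg.sn_fraction * len(cocs)))
            sn = set(np.asarray(cocs)[order[:k]])
            for c in cocs:
                subgroup[c] = "S_N" if c in sn else "S"
        for coc in cocs:
            mouse = coc.rsplit("-c", 1)[0]
            for ct, tag in (("oocyte", "oc"), ("granulosa", "gc")):
                rows.append(
                    {
                        "sample_id": f"{coc}-{tag}",
                        "coc_id": coc,
                        "mouse_id": mouse,
                        "condition": cond,
                        "cell_type": ct,
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    meta.index.name = None
    return meta, pd.Series(subgroup, name="subgroup")


def _treatment_multiplier(meta: pd.DataFrame, subgroup: pd.Series, cfg: SimConfig) -> np.ndarray:
    """Per-sample multiplier on the superovulation effect (0 for natural COCs)."""
    e = np.zeros(len(meta))
    is_super = meta.condition.isin(("SY", "SO")).to_numpy()
    sub = meta.coc_id.map(subgroup).to_numpy(dtype=object)
    frac = np.where(sub == "S_N", cfg.sn_effect_fraction, 1.0)
    old_atten = np.where(meta.condition.to_numpy() == "SO", cfg.interaction_attenuation, 1.0)
    e[is_super] = (frac * old_atten)[is_super]
    return e


def _bimodal_delta(cfg: SimConfig) -> float:
    """log2 half-separation of the mean-preserving bimodal shift that
    multiplies a gene's total variance by ``entropy_inflation``.

    With a per-sample factor m = 2**(+/-delta) / cosh(delta*ln2) (so E[m] = 1)
    on an NB(mu, d) gene, the large-mu variance multiplier is
    (E[m^2]*(1+d) - 1)/d; solving for delta gives the closed form below.
    """
    d = cfg.nb_dispersion
    t = (1.0 + cfg.entropy_inflation * d) / (1.0 + d)  # required E[m^2]
    if t >= 2.0:  # unreachable with a two-point mixture; saturate
        t = 1.999
    x = np.arccosh(np.sqrt(1.0 / (2.0 - t)))  # delta * ln 2
    return float(x / np.log(2.0))


# ---------------------------------------------------------------------------
# paired cohort
# ---------------------------------------------------------------------------

def generate_paired_cohort(cfg: SimConfig) -> tuple[PairedCohort, GroundTruth]:
    """Draw the four-condition paired oocyte/granulosa cohort.

    Counts are NB(mean, dispersion) with mean = library size x baseline
    relative abundance x 2**(planted shifts), renormalized per sample so the
    expected total equals the drawn library size.
    """
    cfg.validate()
    alloc = _allocate_genes(cfg)
    meta, subgroup = _sample_table(cfg)
    G, S = cfg.n_genes, len(meta)

    rng_base = stream(cfg.biology_seed, "baseline")
    rng_fx = stream(cfg.biology_seed, "effects")
    rng_struct = stream(cfg.biology_seed, "structure")
    rng_mouse = stream(cfg.seed, "mouse")
    rng_lib = stream(cfg.seed, "libsize")
    rng_cnt = stream(cfg.seed, "counts")
    rng_comm = stream(cfg.seed, "communication")
    rng_act = stream(cfg.seed, "activity")
    rng_ent = stream(cfg.seed, "entropy")

    # baseline relative abundance; mitochondrial genes pinned to a fixed mass share
    base = np.exp(rng_base.normal(0.0, 1.2, size=G))
    # ligand/receptor genes are robustly expressed (the top-k communication
    # filter presumes this), so their baseline is boosted
    lr_genes = np.concatenate([alloc.ligand_idx, *alloc.subunit_idx]).astype(int)
    if lr_genes.size:
        base[lr_genes] *= cfg.lr_abundance_boost
    # variability-inflated genes are drawn from robustly detected genes: a
    # handful of reads per sample cannot carry a spread signal
    if alloc.entropy_idx.size:
        base[alloc.entropy_idx] = np.maximum(base[alloc.entropy_idx], 1.0)
    mito = alloc.is_mito
    base[mito] = cfg.mito_mass_fraction / (1 - cfg.mito_mass_fraction) * base[~mito].sum() / mito.sum()

    # planted condition effects
    s_lfc = np.zeros(G)
    a_lfc = np.zeros(G)
    s_lfc[alloc.super_idx] = _signed_lfc(rng_fx, len(alloc.super_idx), cfg.superovulation_lfc_scale)
    a_lfc[alloc.aging_idx] = _signed_lfc(rng_fx, len(alloc.aging_idx), cfg.aging_lfc_scale)
    i_lfc = (cfg.interaction_attenuation - 1.0) * s_lfc

    e_treat = _treatment_multiplier(meta, subgroup, cfg)
    is_old = meta.condition.isin(("NO", "SO")).to_numpy().astype(float)
    shift = np.outer(s_lfc, e_treat) + np.outer(a_lfc, is_old)

    # per-mouse log-normal baseline multiplier, shared by a mouse's two cell
    # types: scales every gene alike, i.e. a depth-style replicate effect
    mice = meta.mouse_id.unique()
    mouse_fx = {m: float(np.exp(rng_mouse.normal(0.0, cfg.mouse_effect_sd))) for m in mice}
    mouse_mult = np.array([mouse_fx[m] for m in meta.mouse_id])

    # ligand-receptor co-expression within each COC
    cocs = meta.coc_id.unique()
    coc_pos = {c: np.flatnonzero((meta.coc_id == c).to_numpy()) for c in cocs}
    oc_col = {c: p[meta.cell_type.iloc[p].to_numpy() == "oocyte"][0] for c, p in coc_pos.items()}
    gc_col = {c: p[meta.cell_type.iloc[p].to_numpy() == "granulosa"][0] for c, p in coc_pos.items()}
    n_aff = int(round(cfg.frac_lr_affected * cfg.n_lr_pairs))
    affected = np.zeros(cfg.n_lr_pairs, bool)
    affected[rng_struct.permutation(cfg.n_lr_pairs)[:n_aff]] = True
    # communication intensifies with the superovulation response (co-elevation)
    pair_sign = np.ones(cfg.n_lr_pairs)
    e_coc = {c: e_treat[oc_col[c]] for c in cocs}  # same for both cell types
    for p in range(cfg.n_lr_pairs):
        eta = rng_comm.normal(0.0, cfg.lr_coexpr_sd, size=len(cocs))
        for j, c in enumerate(cocs):
            comm = eta[j]
            if affected[p]:
                comm += cfg.lr_shift_scale * pair_sign[p] * e_coc[c]
            # the whole ligand-receptor axis is co-elevated in both
            # compartments of the COC, so every signaling direction carries it
            cols = [oc_col[c], gc_col[c]]
            shift[alloc.ligand_idx[p], cols] += comm
            shift[np.ix_(alloc.subunit_idx[p], cols)] += comm

    # regulon-driven target expression (granulosa samples carry the program)
    n_reg_aff = int(round(cfg.frac_regulons_affected * cfg.n_regulons))
    reg_affected = np.zeros(cfg.n_regulons, bool)
    if cfg.n_regulons:
        reg_affected[rng_struct.permutation(cfg.n_regulons)[:n_reg_aff]] = True
    activity = np.zeros((cfg.n_regulons, S))
    is_gc = (meta.cell_type == "granulosa").to_numpy()
    for r in range(cfg.n_regulons):
        alpha = cfg.regulon_base_activity + rng_act.normal(0.0, 0.03, size=S)
        if reg_affected[r]:
            alpha = alpha + cfg.regulon_activity_shift * e_treat
        alpha = np.clip(alpha, 0.0, 1.0)
        activity[r] = alpha
        d_act = cfg.activity_lfc_scale * (alpha - cfg.regulon_base_activity)
        shift[alloc.target_idx[r][:, None], np.flatnonzero(is_gc)] += d_act[is_gc]
        shift[alloc.tf_idx[r], is_gc] += 0.5 * d_act[is_gc]

    # variance-inflated genes in superovulated oocytes (bimodal sub-states)
    if cfg.n_entropy_genes and cfg.entropy_inflation > 1.0:
        delta = _bimodal_delta(cfg)
        centering = np.log2(np.cosh(delta * np.log(2)))
        inflate_cols = np.flatnonzero(
            (meta.cell_type == "oocyte").to_numpy() & meta.condition.isin(("SY", "SO")).to_numpy()
        )
        signs = rng_ent.choice([-1.0, 1.0], size=(cfg.n_entropy_genes, inflate_cols.size))
        shift[alloc.entropy_idx[:, None], inflate_cols] += signs * delta - centering

    # compose NB means and draw
    lib = rng_lib.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1, size=S)
    weights = base[:, None] * np.exp2(shift)
    mean = weights / weights.sum(axis=0, keepdims=True) * (lib * mouse_mult)[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng_cnt.negative_binomial(r, r / (r + mean))

    values = pd.DataFrame(counts, index=alloc.gene_ids, columns=meta.sample_id)
    gene_meta = pd.DataFrame(
        {"gene_id": alloc.gene_ids, "length_bp": alloc.lengths, "is_mito": alloc.is_mito}
    ).set_index("gene_id", drop=False)
    gene_meta.index.name = None
    lengths = pd.Series(alloc.lengths, index=alloc.gene_ids)
    oc_cols = meta.index[meta.cell_type == "oocyte"]
    gc_cols = meta.index[meta.cell_type == "granulosa"]
    cohort = PairedCohort(
        oc_counts=CountMatrix(values[oc_cols], lengths),
        gc_counts=CountMatrix(values[gc_cols], lengths),
        meta=meta,
        gene_meta=gene_meta,
    )
    lr_truth = pd.DataFrame(
        {
            "pair_id": [f"lr{p:03d}" for p in range(cfg.n_lr_pairs)],
            "affected": affected,
            "sign": pair_sign,
        }
    )
    truth = GroundTruth(
        sample_meta=meta,
        subgroup=subgroup,
        lfc_super=pd.Series(s_lfc, index=alloc.gene_ids, name="lfc_super"),
        lfc_aging=pd.Series(a_lfc, index=alloc.gene_ids, name="lfc_aging"),
        lfc_interaction=pd.Series(i_lfc, index=alloc.gene_ids, name="lfc_interaction"),
        de_flags=pd.DataFrame(
            {"super": s_lfc != 0, "aging": a_lfc != 0, "interaction": i_lfc != 0},
            index=alloc.gene_ids,
        ),
        lr_truth=lr_truth,
        regulon_activity=pd.DataFrame(
            activity, index=[f"reg{r:02d}" for r in range(cfg.n_regulons)], columns=meta.sample_id
        ),
        entropy_genes=list(alloc.gene_ids[alloc.entropy_idx]),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# ligand-receptor database / regulon tables
# ---------------------------------------------------------------------------

def generate_lr_database(cfg: SimConfig) -> pd.DataFrame:
    """Ligand-receptor pair table over the cohort's gene universe.

    ``frac_multisubunit_receptors`` of the receptors have 2-3 subunits; the
    receptor column lists subunit gene ids separated by semicolons.
    """
    cfg.validate()
    alloc = _allocate_genes(cfg)
    rows = [
        {
            "pair_id": f"lr{p:03d}",
            "ligand": alloc.gene_ids[alloc.ligand_idx[p]],
            "receptor_subunits": ";".join(alloc.gene_ids[alloc.subunit_idx[p]]),
            "annotation": "synthetic",
        }
        for p in range(cfg.n_lr_pairs)
    ]
    return pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor_subunits", "annotation"])


def generate_regulons(cfg: SimConfig) -> pd.DataFrame:
    """Regulon (TF -> targets) table; target sets are disjoint by construction."""
    cfg.validate()
    if cfg.n_regulons > 0 and cfg.targets_per_regulon <= 0:
        raise ConfigurationError("targets_per_regulon must be positive")
    alloc = _allocate_genes(cfg)
    rows = [
        {
            "regulon_id": f"reg{r:02d}",
            "tf": alloc.gene_ids[alloc.tf_idx[r]],
            "targets": ";".join(alloc.gene_ids[alloc.target_idx[r]]),
        }
        for r in range(cfg.n_regulons)
    ]
    return pd.DataFrame(rows, columns=["regulon_id", "tf", "targets"])


# ---------------------------------------------------------------------------
# dual-protocol oocyte maturation experiment
# ---------------------------------------------------------------------------

def tail_capture(tail_nt: np.ndarray | float, midpoint: float) -> np.ndarray | float:
    """Saturating poly-A capture efficiency: tail / (tail + midpoint)."""
    return np.asarray(tail_nt, float) / (np.asarray(tail_nt, float) + midpoint)


def generate_dual_protocol_oocytes(
    cfg: SimConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame, GroundTruth]:
    """Poly-A-selected and total-RNA count matrices for mature vs immature oocytes.

    Genes carry one of four maternal-transcriptome remodeling classes. A gene's
    abundance follows its class across maturation (degraded genes lose
    transcripts in mature cells, all other classes retain them) and its
    expected poly-A-protocol counts are additionally weighted by the saturating
    capture efficiency of its current tail length. Immature ("disrupted")
    samples retain the germinal-vesicle tail and abundance state. Planted tail
    tables sit well beyond every classification threshold: tail changes are at
    least twice the 20-nt gate, adjusted p values at most half of 0.001, read
    maxima at least twice the 50-read gate, and degraded log read ratios at
    most -4 (twice the -2 gate).
    """
    cfg.validate()
    rng = stream(cfg.biology_seed, "tails")
    rng_cnt = stream(cfg.seed, "dual_counts")
    G = cfg.n_genes
    n_re = int(round(cfg.frac_repoly * G))
    n_st = int(round(cfg.frac_dead_stable * G))
    n_dg = int(round(cfg.frac_dead_degraded * G))
    classes = np.array(
        ["repolyadenylated"] * n_re
        + ["deadenylated_stable"] * n_st
        + ["deadenylated_degraded"] * n_dg
        + ["unclassified"] * (G - n_re - n_st - n_dg)
    )
    classes = classes[rng.permutation(G)]
    gene_ids = pd.Index([f"t{i:04d}" for i in range(G)], name="gene_id")

    tail_gv = np.empty(G)
    tail_mii = np.empty(G)
    padj = np.empty(G)
    ln_ratio = np.zeros(G)
    reads_gv = np.empty(G)
    m_re = classes == "repolyadenylated"
    m_st = classes == "deadenylated_stable"
    m_dg = classes == "deadenylated_degraded"
    m_un = classes == "unclassified"

    tail_gv[m_re] = rng.uniform(5, 15, m_re.sum())
    tail_mii[m_re] = rng.uniform(100, 150, m_re.sum())
    dead = m_st | m_dg
    tail_gv[dead] = rng.uniform(100, 150, dead.sum())
    tail_mii[dead] = rng.uniform(5, 15, dead.sum())
    tail_gv[m_un] = rng.uniform(40, 80, m_un.sum())
    tail_mii[m_un] = tail_gv[m_un] + rng.uniform(-9, 9, m_un.sum())
    padj[~m_un] = rng.uniform(1e-8, 5e-4, (~m_un).sum())
    padj[m_un] = rng.uniform(0.1, 1.0, m_un.sum())
    ln_ratio[m_st] = rng.uniform(0.02, 0.1, m_st.sum())
    ln_ratio[m_dg] = -rng.uniform(4.0, 5.0, m_dg.sum())
    reads_gv[m_re | m_st | m_un] = rng.uniform(100, 1000, (m_re | m_st | m_un).sum())
    # degraded genes kept modest in abundance so their loss in mature cells
    # does not dominate the per-sample composition
    reads_gv[m_dg] = rng.uniform(100, 400, m_dg.sum())
    reads_mii = reads_gv * np.exp(ln_ratio)

    tails = pd.DataFrame(
        {
            "gene": gene_ids,
            "tail_gv": np.round(tail_gv, 2),
            "tail_mii": np.round(tail_mii, 2),
            "padj": padj,
            "reads_gv": np.round(reads_gv).astype(int),
            "reads_mii": np.round(reads_mii).astype(int),
        }
    )

    # expression matrices: columns = mature then immature samples
    n = cfg.dual_samples_per_group
    sample_ids = [f"mat-{i:02d}" for i in range(n)] + [f"imm-{i:02d}" for i in range(n)]
    maturity = np.array(["mature"] * n + ["immature"] * n)
    abund = np.column_stack(
        [reads_mii if m == "mature" else reads_gv for m in maturity]
    )
    tail_state = np.column_stack(
        [tail_mii if m == "mature" else tail_gv for m in maturity]
    )
    depth = np.exp(rng_cnt.normal(0.0, 0.2, size=2 * n))
    mean_total = abund * depth[None, :] * 0.3
    mean_polya = abund * tail_capture(tail_state, cfg.tail_capture_midpoint) * depth[None, :] * 0.3
    r = 1.0 / cfg.nb_dispersion
    total = rng_cnt.negative_binomial(r, r / (r + np.maximum(mean_total, 1e-9)))
    polya = rng_cnt.negative_binomial(r, r / (r + np.maximum(mean_polya, 1e-9)))

    dual_meta = pd.DataFrame({"sample_id": sample_ids, "maturity": maturity}).set_index(
        "sample_id", drop=False
    )
    dual_meta.index.name = None
    truth = GroundTruth(
        tail_truth=pd.DataFrame(
            {
                "gene": gene_ids,
                "remodeling_class": classes,
                "tail_gv": tail_gv,
                "tail_mii": tail_mii,
                "ln_read_ratio": ln_ratio,
            }
        ),
        dual_meta=dual_meta,
    )
    polya_cm = CountMatrix(pd.DataFrame(polya, index=gene_ids, columns=sample_ids))
    total_cm = CountMatrix(pd.DataFrame(total, index=gene_ids, columns=sample_ids))
    return polya_cm, total_cm, tails, truth


# ---------------------------------------------------------------------------
# embryo series
# ---------------------------------------------------------------------------

def generate_embryo_series(
    cfg: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Staged reference embryos plus test embryos with planted group offsets.

    Reference embryos span 2-cell to blastocyst (stage scores 1..5) with
    ``embryos_per_stage`` embryos per stage. A designated monotone gene panel
    has log2 expression linear in the stage score (|slope| in [1, 2] log2 per
    stage, Gaussian log-noise ``dev_noise_sd``). Test embryos carry group
    labels NY, S_N and S with decreasing mean stage scores (NY most advanced).
    """
    cfg.validate()
    rng_bio = stream(cfg.biology_seed, "embryo_genes")
    rng = stream(cfg.seed, "embryo")
    rng_cnt = stream(cfg.seed, "embryo_counts")
    G = cfg.n_genes
    n_dev = min(cfg.n_dev_genes, G)
    gene_ids = pd.Index([f"e{i:04d}" for i in range(G)], name="gene_id")
    slope = np.zeros(G)
    # slopes clear the downstream |lfc| > 1 selection gate with margin, so a
    # marker's recovery is not a coin flip against estimation noise
    slope[:n_dev] = rng_bio.choice([-1.0, 1.0], n_dev) * rng_bio.uniform(1.2, 2.2, n_dev)
    base = rng_bio.uniform(4.0, 7.0, G)

    rows = []
    scores = []
    for s, stage in enumerate(STAGES, start=1):
        for i in range(cfg.embryos_per_stage):
            rows.append(
                {"sample_id": f"ref-{stage}-{i:02d}", "role": "reference",
                 "group": "reference", "stage": stage}
            )
            scores.append(float(s))
    for group, size, mu in zip(
        ("NY", "S_N", "S"), cfg.embryo_group_sizes, cfg.embryo_group_stage_means
    ):
        sc = np.clip(rng.normal(mu, cfg.embryo_stage_sd, size=size), 1.0, 5.0)
        for i in range(size):
            rows.append(
                {"sample_id": f"test-{group}-{i:02d}", "role": "test",
                 "group": group, "stage": ""}
            )
            scores.append(float(sc[i]))
    meta = pd.DataFrame(rows).set_index("sample_id", drop=False)
    meta.index.name = None
    score = np.asarray(scores)

    log2mu = base[:, None] + slope[:, None] * (score[None, :] - 3.0)
    log2mu = log2mu + rng_cnt.normal(0.0, cfg.dev_noise_sd, size=log2mu.shape)
    mean = np.exp2(log2mu)
    r = 1.0 / cfg.embryo_dispersion
    counts = rng_cnt.negative_binomial(r, r / (r + mean))
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=meta.sample_id))
    truth = GroundTruth(
        embryo_meta=meta.assign(stage_score=score),
        dev_gene_slopes=pd.Series(slope, index=gene_ids, name="slope"),
    )
    return cm, meta, truth
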