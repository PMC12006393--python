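"""Maternal-transcriptome remodeling classes from poly(A)-tail data.

During oocyte maturation (germinal vesicle, GV, to metaphase II, MII)
maternal transcripts are re-poly-adenylated (tail lengthens, abundance kept),
de-adenylated but stable (tail shortens, abundance kept) or de-adenylated and
degraded (tail shortens, transcripts lost). The class of a gene is decided
from its tail-length change, its significance, and the log ratio of read
counts between the stages. The dual-protocol concordance test then checks
whether expression differences between mature and maturation-disrupted
oocytes follow the pattern each class predicts under a poly-A-biased versus
an unbiased sequencing protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dge import adjust_bh

CLASS_GATE_DELTA_NT = 20.0
CLASS_GATE_PADJ = 0.001
CLASS_GATE_FRAC_OF_MAX = 0.7
CLASS_GATE_MIN_READS = 50
DEGRADED_LN_RATIO = -2.0


@dataclass(frozen=True)
class TailRecord:
    gene: str
    tail_gv: float
    tail_mii: float
    padj: float
    reads_gv: float
    reads_mii: float

    def __post_init__(self) -> None:
        if self.tail_gv < 0 or self.tail_mii < 0 or self.reads_gv < 0 or self.reads_mii < 0:
            raise ValueError(f"{self.gene}: negative tail length or read count")
        if not (0 <= self.padj <= 1):
            raise ValueError(f"{self.gene}: padj outside [0, 1]")


def classify_gene(r: TailRecord) -> str:
    """Assign one remodeling class to a tail record.

    Gate: |tail change| > 20 nt, adjusted p < 0.001, change at least 70% of
    the larger of the two tail lengths, and at least 50 reads in the more
    expressed stage. Gated genes with lengthening tails are re-poly-adenylated;
    shortening tails split by the natural-log read ratio MII/GV: > 0 stable,
    < -2 degraded, in between unclassified.
    """
    delta = r.tail_mii - r.tail_gv
    gate = (
        abs(delta) > CLASS_GATE_DELTA_NT
        and r.padj < CLASS_GATE_PADJ
        and abs(delta) >= CLASS_GATE_FRAC_OF_MAX * max(r.tail_gv, r.tail_mii)
        and max(r.reads_gv, r.reads_mii) >= CLASS_GATE_MIN_READS
    )
    if not gate:
        return "unclassified"
    if delta > 0:
        return "repolyadenylated"
    gv, mii = r.reads_gv, r.reads_mii
    if gv == 0:
        warnings.warn(f"{r.gene}: zero GV reads, using pseudocount 1 in log ratio")
        gv = 1.0
        mii = mii + 1.0
    ln_ratio = np.log(max(mii, 1e-300) / gv)
    if ln_ratio > 0:
        return "deadenylated_stable"
    if ln_ratio < DEGRADED_LN_RATIO:
        return "deadenylated_degraded"
    return "unclassified"


def classify_table(tails: pd.DataFrame) -> pd.Series:
    """Classify every row of a tail table (columns gene, tail_gv, tail_mii,
    padj, reads_gv, reads_mii); deterministic and order-independent."""
    out = {}
    for _, row in tails.iterrows():
        rec = TailRecord(
            gene=str(row["gene"]), tail_gv=float(row["tail_gv"]),
            tail_mii=float(row["tail_mii"]), padj=float(row["padj"]),
            reads_gv=float(row["reads_gv"]), reads_mii=float(row["reads_mii"]),
        )
        out[rec.gene] = classify_gene(rec)
    return pd.Series(out, name="remodeling_class")


def per_sample_log2fc(
    expr: pd.DataFrame, groups: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-sample log2 fold change against the mean of the other group.

    For sample i in group A, lfc_gi = log2((x_gi + pc) / (mean_B(x_g) + pc)),
    and symmetrically for group B. ``expr`` should be depth-normalized linear
    expression.
    """
    groups = groups.loc[expr.columns].astype(str)
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    means = {g: expr[groups.index[groups == g]].mean(axis=1) for g in levels}
    other = {levels[0]: levels[1], levels[1]: levels[0]}
    out = {}
    for sid in expr.columns:
        ref = means[other[groups[sid]]]
        out[sid] = np.log2((expr[sid] + pseudocount) / (ref + pseudocount))
    return pd.DataFrame(out)


# expectation patterns for the disrupted (immature-like) group's fold change
_EXPECTATIONS = {
    "repolyadenylated": {"polya": "down", "total": "none"},
    "deadenylated_stable": {"polya": "up", "total": "none"},
    "deadenylated_degraded": {"polya": "same", "total": "same"},
}


def concordance_test(
    lfc_polya: pd.DataFrame,
    lfc_total: pd.DataFrame,
    classes: pd.Series,
    disrupted_samples: list[str],
    alpha: float = 0.05,
    min_genes: int = 5,
    min_effect: float = 0.25,
) -> pd.DataFrame:
    """Test the per-class dual-protocol expression expectations.

    For each remodeling class, the per-sample median fold change of the
    disrupted group across the class's genes is tested against zero with a
    two-sided one-sample Wilcoxon signed-rank test, separately per protocol;
    p values are BH-adjusted within the whole family. A protocol shows a
    change only when the adjusted p is below ``alpha`` AND the |median| fold
    change is at least ``min_effect`` (a significant but negligible shift —
    e.g. a depth-normalization composition artifact — does not count).

    Verdicts: re-poly-adenylated genes must drop in the poly-A protocol only;
    de-adenylated stable genes must rise in the poly-A protocol only;
    degraded genes must shift in the same direction in both protocols.
    Classes with fewer than ``min_genes`` genes are 'underpowered'.
    """
    classes = classes.dropna()
    shared = lfc_polya.index.intersection(lfc_total.index).intersection(classes.index)
    classes = classes.loc[shared]
    rows = []
    stats_rows = []
    for cls in _EXPECTATIONS:
        genes = classes.index[classes == cls]
        for proto, lfc in (("polya", lfc_polya), ("total", lfc_total)):
            if len(genes) == 0:
                med, p = np.nan, np.nan
            else:
                per_sample = lfc.loc[genes, disrupted_samples].median(axis=0)
                med = float(per_sample.median())
                if np.allclose(per_sample, 0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(per_sample.to_numpy()).pvalue)
            stats_rows.append({"class": cls, "protocol": proto, "n_genes": len(genes),
                               "median_lfc": med, "p": p})
    fam = pd.DataFrame(stats_rows)
    fam["padj"] = adjust_bh(fam["p"].to_numpy())

    for cls, expect in _EXPECTATIONS.items():
        sub = fam[fam["class"] == cls].set_index("protocol")
        n_genes = int(sub["n_genes"].iloc[0])
        if n_genes < min_genes:
            verdict = "underpowered"
        else:
            def state(proto: str) -> str:
                p = sub.loc[proto, "padj"]
                m = sub.loc[proto, "median_lfc"]
                if np.isfinite(p) and p < alpha and abs(m) >= min_effect:
                    return "up" if m > 0 else "down"
                return "none"

            sp, st = state("polya"), state("total")
            ok = True
            for proto, want in expect.items():
                got = sp if proto == "polya" else st
                if want == "same":
                    ok = ok and got != "none"
                else:
                    ok = ok and got == want
            if expect["polya"] == "same":  # degraded: directions must agree
                ok = ok and sp == st
            verdict = "consistent" if ok else "inconsistent"
        rows.append(
            {
                "class": cls,
                "n_genes": n_genes,
                "median_lfc_polya": sub.loc["polya", "median_lfc"],
                "median_lfc_total": sub.loc["total", "median_lfc"],
                "padj_polya": sub.loc["polya", "padj"],
                "padj_total": sub.loc["total", "padj"],
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows).set_index("class")
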