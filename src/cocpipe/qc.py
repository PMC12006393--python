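"""Sample quality control, pseudo-bulk aggregation and normalization.

QC mirrors the fixed exclusion rules used for single oocyte / granulosa
libraries: a sample is kept only if it has at least ``min_reads`` total reads,
at least ``min_genes`` detected genes and a mitochondrial read fraction of at
most ``max_mito_frac``. Depth normalization is log2 counts-per-million;
length normalization scales counts by gene length in kb before per-sample
depth scaling (a transcripts-per-million-style quantity), which is what the
ligand-receptor scoring expects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix


@dataclass
class QCThresholds:
    min_reads: int = 5000
    min_genes: int = 1000
    max_mito_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.min_reads <= 0:
            raise ValueError("min_reads must be positive")
        if not (0 < self.max_mito_frac <= 1):
            raise ValueError("max_mito_frac must be in (0, 1]")


@dataclass
class QCReport:
    retained: list[str]
    excluded: dict[str, list[str]]  # sample -> failed criteria among reads/genes/mito
    mito_checked: bool
    thresholds: QCThresholds

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "excluded": self.excluded,
            "mito_checked": self.mito_checked,
            "thresholds": {
                "min_reads": self.thresholds.min_reads,
                "min_genes": self.thresholds.min_genes,
                "max_mito_frac": self.thresholds.max_mito_frac,
            },
        }


def _mito_mask(cm: CountMatrix, gene_meta: pd.DataFrame | None) -> np.ndarray | None:
    if gene_meta is not None and "is_mito" in gene_meta.columns:
        return gene_meta["is_mito"].reindex(cm.gene_ids).fillna(False).to_numpy(bool)
    prefix = cm.gene_ids.str.lower().str.startswith("mt-")
    if prefix.any():
        return np.asarray(prefix)
    return None


def qc_filter(
    cm: CountMatrix,
    gene_meta: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Drop samples failing any fixed QC criterion; report every exclusion.

    The retained set is a pure per-sample predicate, so the operation is
    idempotent and independent of sample order. If no mitochondrial flags are
    available (neither ``gene_meta.is_mito`` nor an ``mt-`` id prefix), the
    mitochondrial criterion is skipped with a warning and recorded as such.
    """
    t = thresholds or QCThresholds()
    v = cm.values.to_numpy()
    totals = v.sum(axis=0)
    detected = (v > 0).sum(axis=0)
    mito = _mito_mask(cm, gene_meta)
    mito_checked = mito is not None
    if not mito_checked:
        warnings.warn("no mitochondrial gene flags found; mito criterion skipped")
        mito_frac = np.zeros(cm.shape[1])
    else:
        with np.errstate(invalid="ignore"):
            mito_frac = np.where(totals > 0, v[mito].sum(axis=0) / np.maximum(totals, 1), 1.0)

    excluded: dict[str, list[str]] = {}
    retained: list[str] = []
    for j, sid in enumerate(cm.sample_ids):
        reasons = []
        if totals[j] < t.min_reads:
            reasons.append("reads")
        if detected[j] < t.min_genes:
            reasons.append("genes")
        if mito_checked and mito_frac[j] > t.max_mito_frac:
            reasons.append("mito")
        if reasons:
            excluded[sid] = reasons
        else:
            retained.append(sid)
    report = QCReport(retained=retained, excluded=excluded, mito_checked=mito_checked, thresholds=t)
    return cm.subset_samples(retained), report


def pseudobulk(
    cm: CountMatrix,
    meta: pd.DataFrame,
    group_keys: tuple[str, ...] = ("mouse_id", "cell_type"),
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sum counts over samples sharing all ``group_keys``.

    Returns the aggregated matrix (one column per key combination, named by
    joining the key values with ``"|"``) and a provenance table listing the
    member samples of each column. Total counts are conserved.
    """
    missing = [k for k in group_keys if k not in meta.columns]
    if missing:
        raise ValueError(f"meta lacks group keys: {missing}")
    sub = meta.loc[list(cm.sample_ids)]
    labels = sub[list(group_keys)].astype(str).agg("|".join, axis=1)
    out = {}
    prov = []
    for name in labels.unique():
        members = labels.index[labels == name]
        out[name] = cm.values[members].sum(axis=1)
        row = dict(zip(group_keys, name.split("|")))
        row.update({"column": name, "n_samples": len(members), "samples": ";".join(members)})
        prov.append(row)
    agg = CountMatrix(pd.DataFrame(out, index=cm.gene_ids), cm.gene_lengths)
    return agg, pd.DataFrame(prov)


def _check_totals(values: pd.DataFrame) -> np.ndarray:
    totals = values.sum(axis=0).to_numpy(float)
    if (totals <= 0).any():
        bad = list(values.columns[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    return totals


def normalize_logcpm(cm: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(pseudocount + counts-per-million); scale-invariant per sample."""
    totals = _check_totals(cm.values)
    cpm = cm.values.to_numpy(float) / totals[None, :] * 1e6
    return pd.DataFrame(np.log2(pseudocount + cpm), index=cm.gene_ids, columns=cm.sample_ids)


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Linear counts-per-million."""
    totals = _check_totals(cm.values)
    return pd.DataFrame(
        cm.values.to_numpy(float) / totals[None, :] * 1e6,
        index=cm.gene_ids, columns=cm.sample_ids,
    )


def length_normalize(cm: CountMatrix, gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Length-scaled, depth-scaled expression (TPM-style).

    Counts are divided by gene length in kb, then each sample is scaled so its
    rates sum to 1e6. Zeros stay the minimal value of each sample.
    """
    lengths = gene_lengths if gene_lengths is not None else cm.gene_lengths
    if lengths is None:
        raise ValueError("gene lengths required for length normalization")
    lengths = lengths.reindex(cm.gene_ids)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for all genes")
    rate = cm.values.to_numpy(float) / (lengths.to_numpy(float)[:, None] / 1e3)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = list(cm.sample_ids[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    return pd.DataFrame(rate / totals[None, :] * 1e6, index=cm.gene_ids, columns=cm.sample_ids)
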