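"""Consensus N / S_N / S subgrouping and the dual granulosa-cell classifier.

Superovulated COCs split into two transcriptional subgroups: S_N, which
resembles naturally ovulated COCs, and S, which carries the full
superovulation response. Cluster labels derived independently from the
communication profiles and from regulon activities are aligned to
{N, S_N, S} and intersected: samples on which the two labelings agree form
the consensus; the rest are excluded.

The classifier is a pair of linear soft-margin SVMs — one on regulon-activity
features, one on selected gene-expression features — trained on the consensus
S_N/S samples. A new sample is labeled only when both models agree; otherwise
it is 'not assigned' (NA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._random import stream, substream_seed
from .ccc import pca_embed

NA_LABEL = "NA"


# ---------------------------------------------------------------------------
# consensus clusters
# ---------------------------------------------------------------------------

def align_clusters(
    labels: pd.Series, features: pd.DataFrame, natural_mask: pd.Series
) -> pd.Series:
    """Map arbitrary 3-cluster ids to {N, S_N, S}.

    N is the cluster most dominated by naturally ovulated samples; among the
    other two, S_N is the one whose centroid (in ``features`` space, samples
    as rows) is closer to the N centroid. A tie in centroid distances raises.
    """
    labels = labels.loc[features.index]
    natural_mask = natural_mask.loc[features.index].astype(bool)
    ids = list(pd.unique(labels))
    if len(ids) != 3:
        raise ValueError("exactly three clusters required")
    nat_frac = {c: float(natural_mask[labels == c].mean()) for c in ids}
    n_cluster = max(sorted(ids, key=str), key=lambda c: nat_frac[c])
    rest = [c for c in ids if c != n_cluster]
    cents = {c: features.loc[labels.index[labels == c]].mean(axis=0).to_numpy() for c in ids}
    d = {c: float(np.linalg.norm(cents[c] - cents[n_cluster])) for c in rest}
    if np.isclose(d[rest[0]], d[rest[1]]):
        raise ValueError("centroid-distance tie; manual cluster mapping required")
    sn = min(rest, key=lambda c: d[c])
    mapping = {n_cluster: "N", sn: "S_N", [c for c in rest if c != sn][0]: "S"}
    return labels.map(mapping)


@dataclass
class ConsensusLabels:
    labels: pd.Series                    # N, S_N, S or excluded
    provenance: pd.DataFrame             # per sample: cci and tf labels

    @property
    def agreeing(self) -> pd.Index:
        return self.labels.index[self.labels != "excluded"]


def consensus_clusters(labels_cci: pd.Series, labels_tf: pd.Series) -> ConsensusLabels:
    """Intersect two aligned labelings; disagreeing samples become 'excluded'."""
    if set(labels_cci.index) != set(labels_tf.index):
        raise ValueError("labelings cover different sample sets")
    tf = labels_tf.loc[labels_cci.index]
    agree = labels_cci == tf
    labels = labels_cci.where(agree, "excluded")
    prov = pd.DataFrame({"cci": labels_cci, "tf": tf})
    return ConsensusLabels(labels.rename("consensus"), prov)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features_dge(
    dge_result: pd.DataFrame,
    expr: pd.DataFrame,
    base_mean_min: float = 50.0,
    padj_max: float = 0.01,
    lfc_min: float = 0.7,
    loading_min: float = 0.09,
) -> list[str]:
    """Threshold differential genes, then keep the genes driving PC1.

    Genes must pass baseMean > ``base_mean_min``, adjusted p < ``padj_max``
    and |log2FC| > ``lfc_min``; a PCA on the passing genes (samples as rows)
    then retains genes whose unit-norm PC1 loading exceeds ``loading_min`` in
    magnitude.
    """
    passing = dge_result.index[
        (dge_result["baseMean"] > base_mean_min)
        & (dge_result["padj"] < padj_max)
        & (dge_result["log2FC"].abs() > lfc_min)
    ]
    passing = [g for g in passing if g in expr.index]
    if not passing:
        raise ValueError("no genes pass the thresholds; consider relaxing them")
    _, loadings, _ = pca_embed(expr.loc[passing].T, n_pcs=1)
    keep = loadings.index[loadings["PC1"].abs() > loading_min]
    if len(keep) == 0:
        raise ValueError("no genes pass the PC1 loading threshold")
    return list(keep)


def prune_features(X: pd.DataFrame, corr_max: float = 0.9) -> list[str]:
    """Remove near-zero-variance, highly correlated and linearly dependent features.

    Near-zero variance: variance < 1e-8, or the two most common values have a
    frequency ratio above 19 with under 10% distinct values. Correlation:
    greedily drop one of each |Pearson r| > ``corr_max`` pair (the one with
    the larger mean absolute correlation). Linear dependence: exact linear
    combinations found by rank-revealing QR are dropped.
    """
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features")
    keep = []
    for col in X.columns:
        v = X[col].to_numpy(float)
        if np.var(v) < 1e-8:
            continue
        counts = pd.Series(v).value_counts()
        distinct_frac = len(counts) / len(v)
        freq_ratio = counts.iloc[0] / counts.iloc[1] if len(counts) > 1 else np.inf
        if freq_ratio > 19 and distinct_frac < 0.1:
            continue
        keep.append(col)
    if not keep:
        raise ValueError("all features removed by near-zero-variance filter")

    # greedy correlation pruning (caret-style)
    sub = X[keep]
    corr = sub.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    active = list(range(len(keep)))
    while True:
        sub_corr = corr[np.ix_(active, active)]
        i, j = np.unravel_index(np.argmax(sub_corr), sub_corr.shape)
        if sub_corr[i, j] <= corr_max:
            break
        mean_i = sub_corr[i].mean()
        mean_j = sub_corr[j].mean()
        drop = active[i] if mean_i >= mean_j else active[j]
        active.remove(drop)
        if len(active) < 2:
            break
    keep = [keep[i] for i in active]

    # exact linear combinations via rank-revealing QR
    from scipy.linalg import qr

    M = X[keep].to_numpy(float)
    M = M - M.mean(axis=0, keepdims=True)
    if M.shape[1] >= 2:
        _, R, piv = qr(M, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = max(M.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        rank = int((diag > tol).sum())
        dependent = set(piv[rank:])
        keep = [f for i, f in enumerate(keep) if i not in dependent]
    if not keep:
        raise ValueError("all features removed")
    return keep


def ga_select(
    X: pd.DataFrame,
    y: pd.Series,
    cv_folds: int = 5,
    pop: int = 50,
    gens: int = 20,
    seed: int = 0,
    size_penalty: float = 0.001,
    base_cost: float = 1.0,
) -> list[str]:
    """Genetic-algorithm feature selection maximizing CV accuracy.

    Chromosomes are feature-inclusion bitmasks; fitness is the mean stratified
    CV accuracy of a linear SVM minus ``size_penalty`` x subset size.
    Tournament selection (k = 3), uniform crossover (p = 0.5), bit-flip
    mutation (p = 1/n_features), elitism of 1. Deterministic given the seed,
    and never returns an empty subset (empty chromosomes are repaired by
    setting one random bit).
    """
    if y.nunique() < 2:
        raise ValueError("labels are degenerate (single class)")
    rng = stream(seed, "ga_select")
    n = X.shape[1]
    Xv = X.to_numpy(float)
    yv = y.loc[X.index].to_numpy()
    folds = min(cv_folds, int(pd.Series(yv).value_counts().min()))
    folds = max(folds, 2)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        if not mask.any():
            return -np.inf
        key = mask.tobytes()
        if key not in cache:
            clf = Pipeline(
                [("scale", StandardScaler()),
                 ("svm", SVC(kernel="linear", C=base_cost))]
            )
            cv = StratifiedKFold(n_splits=folds, shuffle=True,
                                 random_state=substream_seed(seed, "ga_cv"))
            acc = cross_val_score(clf, Xv[:, mask], yv, cv=cv).mean()
            cache[key] = float(acc) - size_penalty * int(mask.sum())
        return cache[key]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(0, n)] = True
        return mask

    popu = [repair(rng.random(n) < 0.5) for _ in range(pop)]
    fits = [fitness(m) for m in popu]
    for _ in range(gens):
        best_i = int(np.argmax(fits))
        nxt = [popu[best_i].copy()]  # elitism
        while len(nxt) < pop:
            def pick() -> np.ndarray:
                idx = rng.integers(0, pop, size=3)
                return popu[max(idx, key=lambda i: fits[i])]

            a, b = pick(), pick()
            cross = rng.random(n) < 0.5
            child = np.where(cross, a, b)
            flip = rng.random(n) < 1.0 / n
            child = repair(child ^ flip)
            nxt.append(child)
        popu = nxt
        fits = [fitness(m) for m in popu]
    best = popu[int(np.argmax(fits))]
    return list(X.columns[best])


# ---------------------------------------------------------------------------
# dual classifier
# ---------------------------------------------------------------------------

@dataclass
class _LinearModel:
    features: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    weights: np.ndarray
    intercept: float
    cost: float
    classes: list[str]
    cv_accuracy: float

    def predict(self, x: pd.Series) -> str:
        missing = [f for f in self.features if f not in x.index]
        if missing:
            raise KeyError(f"missing features: {missing}")
        v = (x[self.features].to_numpy(float) - self.scaler_mean) / self.scaler_scale
        score = float(v @ self.weights + self.intercept)
        return self.classes[1] if score > 0 else self.classes[0]

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "cost": self.cost,
            "classes": self.classes,
            "cv_accuracy": self.cv_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_LinearModel":
        return cls(
            features=list(d["features"]),
            scaler_mean=np.asarray(d["scaler_mean"], float),
            scaler_scale=np.asarray(d["scaler_scale"], float),
            weights=np.asarray(d["weights"], float),
            intercept=float(d["intercept"]),
            cost=float(d["cost"]),
            classes=list(d["classes"]),
            cv_accuracy=float(d["cv_accuracy"]),
        )


@dataclass
class DualClassifier:
    model_tf: _LinearModel
    model_dge: _LinearModel
    seed: int

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"model_tf": self.model_tf.to_dict(), "model_dge": self.model_dge.to_dict(),
                 "seed": self.seed},
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "DualClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            _LinearModel.from_dict(d["model_tf"]),
            _LinearModel.from_dict(d["model_dge"]),
            int(d["seed"]),
        )


def _train_linear_svm(
    X: pd.DataFrame, y: pd.Series, cost_grid, cv_folds: int, seed: int
) -> _LinearModel:
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("binary labels required")
    if (y.value_counts() < 4).any():
        raise ValueError("need >= 4 samples per class")
    yv = (y == classes[1]).astype(int).to_numpy()
    Xv = X.to_numpy(float)
    folds = max(2, min(cv_folds, int(pd.Series(yv).value_counts().min())))
    best = None
    for cost in cost_grid:
        clf = Pipeline(
            [("scale", StandardScaler()), ("svm", SVC(kernel="linear", C=cost))]
        )
        cv = StratifiedKFold(n_splits=folds, shuffle=True,
                             random_state=substream_seed(seed, "svm_cv"))
        acc = float(cross_val_score(clf, Xv, yv, cv=cv).mean())
        if best is None or acc > best[0] + 1e-12:
            best = (acc, cost)
    acc, cost = best
    scaler = StandardScaler().fit(Xv)
    svm = SVC(kernel="linear", C=cost).fit(scaler.transform(Xv), yv)
    return _LinearModel(
        features=list(X.columns),
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        weights=svm.coef_.ravel(),
        intercept=float(svm.intercept_[0]),
        cost=float(cost),
        classes=classes,
        cv_accuracy=acc,
    )


def train_dual(
    X_tf: pd.DataFrame,
    X_dge: pd.DataFrame,
    y: pd.Series,
    cost_grid=(0.01, 0.1, 1.0, 10.0),
    cv_folds: int = 5,
    seed: int = 0,
) -> DualClassifier:
    """Train the two linear SVMs (activity view, expression view) independently.

    The cost hyperparameter is tuned by exhaustive stratified grid CV per
    view; ties prefer the smaller cost.
    """
    y_tf = y.loc[X_tf.index]
    y_dge = y.loc[X_dge.index]
    model_tf = _train_linear_svm(X_tf, y_tf, cost_grid, cv_folds, seed)
    model_dge = _train_linear_svm(X_dge, y_dge, cost_grid, cv_folds, seed)
    return DualClassifier(model_tf, model_dge, seed)


def predict_consensus(clf: DualClassifier, x_tf: pd.Series, x_dge: pd.Series) -> str:
    """Shared label of the two models, or NA when they disagree."""
    a = clf.model_tf.predict(x_tf)
    b = clf.model_dge.predict(x_dge)
    return a if a == b else NA_LABEL


def predict_consensus_frame(
    clf: DualClassifier, X_tf: pd.DataFrame, X_dge: pd.DataFrame
) -> pd.Series:
    """Vectorized consensus prediction over aligned sample frames."""
    out = {}
    for sid in X_tf.index:
        out[sid] = predict_consensus(clf, X_tf.loc[sid], X_dge.loc[sid])
    return pd.Series(out, name="predicted")
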