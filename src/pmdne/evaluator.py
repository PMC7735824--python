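"""Link-prediction evaluation of the learned embeddings.

Known associations are the positive class; an equal number of unconnected
(u, v) pairs, sampled uniformly without replacement, forms the negative
class.  Pairs are featurized from the two endpoint embeddings (Hadamard
product by default) and scored by a supervised classifier under stratified
k-fold cross-validation (default k = 5, i.e. a 4:1 train/test split per
fold).  Reported metrics: ROC-AUC (trapezoidal integral of the ROC curve),
PR-AUC (average-precision step integration), and precision / accuracy / F1
/ recall with the confusion counts TP, FN, FP, TN at probability threshold
0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, average_precision_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .embedder import EmbeddingModel, Hyperparams, embed_network
from .net_io import BipartiteNetwork, SimilarityNetwork

__all__ = [
    "LabeledEdgeSet",
    "EvaluationReport",
    "sample_negative_edges",
    "edge_features",
    "compute_metrics",
    "cross_validate",
    "ablation_report",
    "make_classifier",
]

METRIC_NAMES = ("roc_auc", "pr_auc", "precision", "accuracy", "f1", "recall")
_COMBINERS = ("hadamard", "concat", "average", "l1", "l2")


@dataclass
class LabeledEdgeSet:
    """Candidate pairs with binary labels and fold assignments."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    fold_ids: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.pairs) == len(self.labels) == len(self.fold_ids)):
            raise ValueError("pairs, labels and fold_ids must have equal length")


@dataclass
class EvaluationReport:
    """Per-fold metric rows plus their mean and standard deviation."""

    folds: list[dict]
    mean: dict = field(init=False)
    sd: dict = field(init=False)

    def __post_init__(self) -> None:
        frame = pd.DataFrame(self.folds)
        numeric = frame[[c for c in frame.columns if c != "fold"]]
        self.mean = numeric.mean().to_dict()
        self.sd = numeric.std(ddof=1).to_dict() if len(frame) > 1 else dict.fromkeys(numeric, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            {"folds": self.folds, "mean": self.mean, "sd": self.sd}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def __str__(self) -> str:
        lines = [
            "metric     mean      sd",
            *(
                f"{m:<10} {self.mean[m]:.4f}    {self.sd[m]:.4f}"
                for m in METRIC_NAMES
            ),
        ]
        return "\n".join(lines)


def sample_negative_edges(
    bn: BipartiteNetwork, n: int, rng_seed=0
) -> list[tuple[str, str]]:
    """Sample ``n`` distinct non-edges uniformly without replacement."""
    present = np.zeros((bn.n_u, bn.n_v), dtype=bool)
    u_index = {u: i for i, u in enumerate(bn.u_nodes)}
    v_index = {v: j for j, v in enumerate(bn.v_nodes)}
    for u, v in bn.edges:
        present[u_index[u], v_index[v]] = True
    absent_flat = np.flatnonzero(~present.ravel())
    if n > absent_flat.size:
        raise ValueError(f"requested {n} negatives but only {absent_flat.size} non-edges exist")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(absent_flat, size=n, replace=False)
    return [(bn.u_nodes[k // bn.n_v], bn.v_nodes[k % bn.n_v]) for k in chosen]


def edge_features(
    model: EmbeddingModel, pairs, combiner: str = "hadamard"
) -> np.ndarray:
    """Featurize (u, v) pairs from the endpoint embeddings.

    hadamard: u*v; concat: [u, v]; average: (u+v)/2; l1: |u-v|;
    l2: (u-v)**2.
    """
    if combiner not in _COMBINERS:
        raise ValueError(f"unknown combiner {combiner!r}; choose from {_COMBINERS}")
    try:
        ui = np.array([model.u_index[u] for u, _ in pairs])
        vj = np.array([model.v_index[v] for _, v in pairs])
    except KeyError as err:
        raise KeyError(f"node {err.args[0]!r} missing from model") from None
    a, b = model.u_emb[ui], model.v_emb[vj]
    if combiner == "hadamard":
        return a * b
    if combiner == "concat":
        return np.hstack([a, b])
    if combiner == "average":
        return (a + b) / 2.0
    if combiner == "l1":
        return np.abs(a - b)
    return (a - b) ** 2


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Metric suite for one set of scored pairs.

    Returns ROC-AUC, PR-AUC, threshold metrics (precision, accuracy, f1,
    recall defined from TP/(TP+FP), (TP+TN)/n, etc.) and the confusion
    counts.  Both classes must be present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUCs are undefined with a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    preds = scores >= threshold
    tp = int(np.sum(preds & (labels == 1)))
    fn = int(np.sum(~preds & (labels == 1)))
    fp = int(np.sum(preds & (labels == 0)))
    tn = int(np.sum(~preds & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "roc_auc": float(auc(fpr, tpr)),
        "pr_auc": float(average_precision_score(labels, scores)),
        "precision": precision,
        "accuracy": (tp + tn) / labels.size,
        "f1": f1,
        "recall": recall,
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
    }


def make_classifier(name: str, random_state: int):
    """Instantiate one of the supported classifiers with library defaults."""
    if name == "RF":
        return RandomForestClassifier(random_state=random_state)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "ADBC":
        return AdaBoostClassifier(random_state=random_state)
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=random_state)
    if name == "GBC":
        return GradientBoostingClassifier(random_state=random_state)
    if name == "SVM":
        return SVC(probability=True, random_state=random_state)
    raise ValueError(f"unknown classifier {name!r}; choose RF, KNN, ADBC, LR, GBC or SVM")


def _assign_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    ids = np.arange(n) % k
    rng.shuffle(ids)
    return ids


def build_labeled_edges(
    bn: BipartiteNetwork, k: int, rng_seed=0
) -> LabeledEdgeSet:
    """Balanced labeled pair set: all positives plus an equal number of
    sampled negatives, each split into k folds."""
    positives = list(bn.edges)
    negatives = sample_negative_edges(bn, len(positives), rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    pos_folds = _assign_folds(len(positives), k, rng)
    neg_folds = _assign_folds(len(negatives), k, rng)
    return LabeledEdgeSet(
        pairs=positives + negatives,
        labels=np.concatenate([np.ones(len(positives), dtype=int), np.zeros(len(negatives), dtype=int)]),
        fold_ids=np.concatenate([pos_folds, neg_folds]),
    )


def cross_validate(
    bn: BipartiteNetwork,
    sims: tuple[SimilarityNetwork | None, SimilarityNetwork | None] = (None, None),
    hp: Hyperparams | None = None,
    k: int = 5,
    classifier: str = "RF",
    rng_seed: int = 0,
    combiner: str = "hadamard",
    strict: bool = False,
    model: EmbeddingModel | None = None,
) -> EvaluationReport:
    """k-fold cross-validated link prediction.

    By default embeddings are trained once on the full network and the
    cross-validation operates at the feature/classifier level; with
    ``strict=True`` embeddings are retrained per fold with the test fold's
    positive edges removed from the network (slower, leakage-proof).  A
    pre-trained ``model`` may be supplied to skip embedding.  ``sims`` is
    (miRNA-side, disease-side).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    hp = hp if hp is not None else Hyperparams()
    sim_u, sim_v = sims
    labeled = build_labeled_edges(bn, k, rng_seed=rng_seed)
    if model is None and not strict:
        model = embed_network(bn, sim_u, sim_v, hp)

    features = None
    if not strict:
        features = edge_features(model, labeled.pairs, combiner=combiner)

    folds = []
    for fold in range(k):
        test_mask = labeled.fold_ids == fold
        if strict:
            held_out = {
                p for p, lab, m in zip(labeled.pairs, labeled.labels, test_mask)
                if m and lab == 1
            }
            fold_bn = BipartiteNetwork(
                u_nodes=list(bn.u_nodes),
                v_nodes=list(bn.v_nodes),
                edges={e: w for e, w in bn.edges.items() if e not in held_out},
            )
            fold_model = embed_network(fold_bn, sim_u, sim_v, hp)
            feats = edge_features(fold_model, labeled.pairs, combiner=combiner)
        else:
            feats = features
        clf = make_classifier(classifier, random_state=rng_seed + fold)
        clf.fit(feats[~test_mask], labeled.labels[~test_mask])
        scores = clf.predict_proba(feats[test_mask])[:, 1]
        row = compute_metrics(labeled.labels[test_mask], scores)
        row["fold"] = fold
        folds.append(row)
    return EvaluationReport(folds=folds)


def ablation_report(
    bn: BipartiteNetwork,
    sims: tuple[SimilarityNetwork | None, SimilarityNetwork | None],
    hp: Hyperparams | None = None,
    k: int = 5,
    rng_seed: int = 0,
    classifier: str = "RF",
) -> pd.DataFrame:
    """Four-arm similarity ablation.

    Arm 1 uses both similarity networks, arm 2 neither, arm 3 the
    disease-side network only, arm 4 the miRNA-side network only —
    implemented by zeroing the similarity coefficients e (miRNA) and/or c
    (disease).  Returns one row of mean metrics per arm.
    """
    hp = hp if hp is not None else Hyperparams()
    arms = [
        (1, "both similarity networks", hp.c, hp.e),
        (2, "no similarity network", 0.0, 0.0),
        (3, "disease similarity only", hp.c, 0.0),
        (4, "miRNA similarity only", 0.0, hp.e),
    ]
    rows = []
    for arm_id, desc, c, e in arms:
        report = cross_validate(
            bn,
            sims,
            replace(hp, c=c, e=e),
            k=k,
            classifier=classifier,
            rng_seed=rng_seed,
        )
        row = {"arm": arm_id, "config": desc, "c": c, "e": e}
        row.update({m: report.mean[m] for m in METRIC_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
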