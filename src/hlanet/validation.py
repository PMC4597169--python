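"""Leave-one-out and repeated k-fold validation of edge-label prediction.

Folds are drawn over EDGES (binding records), not nodes: in k-fold
cross-validation the edge set is split into near-equal folds and each fold is
predicted from the network formed by the others.  Training networks keep the
full node index with held-out entries zeroed, and the predictor never reads
the queried pair's own entry; k = n_edges therefore traverses exactly the
same arithmetic as leave-one-out.

AUC is computed by the rank (Mann-Whitney) formulation with midranks for tied
scores, so it equals the probability that a random positive outscores a
random negative (ties counting half).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from hlanet.nebula import (
    DEFAULT_CONFIG,
    NebulaConfig,
    POSITIVE,
    predict,
)
from hlanet.network import BipartiteNetwork


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


def confusion_metrics(
    calls: Sequence, labels: Sequence
) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy of categorical calls.

    ``calls`` and ``labels`` are equal-length sequences of booleans or of the
    strings "positive"/"negative"; positive means binder.
    """
    c = np.asarray([x == POSITIVE if isinstance(x, str) else bool(x) for x in calls])
    y = np.asarray([x == POSITIVE if isinstance(x, str) else bool(x) for x in labels])
    if c.shape != y.shape:
        raise ValueError("calls and labels differ in length")
    tp = int((c & y).sum())
    tn = int((~c & ~y).sum())
    fp = int((c & ~y).sum())
    fn = int((~c & y).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(c)
    return sens, spec, acc


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve by the midrank Mann-Whitney formulation."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray([x == POSITIVE if isinstance(x, str) else bool(x) for x in labels])
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # midranks for ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """(false positive rate, true positive rate) points for plotting."""
    from sklearn.metrics import roc_curve

    y = np.asarray([x == POSITIVE if isinstance(x, str) else bool(x) for x in labels])
    fpr, tpr, _ = roc_curve(y.astype(int), np.asarray(scores, dtype=float))
    return fpr, tpr


@dataclass
class ValidationReport:
    """Per-edge predictions plus aggregate classification metrics."""

    edges: list[tuple[str, str]]
    true_labels: list[str]
    scores: list[float]
    calls: list[str]
    fallbacks: list[str]
    sensitivity: float
    specificity: float
    accuracy: float
    auc: Optional[float]
    scheme: str = "loo"
    iteration: Optional[int] = None
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def fallback_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for f in self.fallbacks:
            counts[f] = counts.get(f, 0) + 1
        return counts

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_edges": self.n_edges,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "fallbacks": self.fallback_counts,
            "iteration": self.iteration,
            "seed": self.seed,
        }

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hla\tpeptide\ttrue_label\tF\tC\tfallback\n")
            for (h, p), t, s, c, f in zip(
                self.edges, self.true_labels, self.scores, self.calls, self.fallbacks
            ):
                fh.write(f"{h}\t{p}\t{t}\t{s:.6f}\t{c}\t{f}\n")


def _make_report(edges, truths, results, scheme, iteration=None, seed=None) -> ValidationReport:
    scores = [r.F for r in results]
    calls = [r.C for r in results]
    fallbacks = [r.fallback_used for r in results]
    sens, spec, acc = confusion_metrics(calls, truths)
    try:
        auc = roc_auc(scores, truths)
    except UndefinedAUCError:
        auc = None
    return ValidationReport(
        edges=list(edges),
        true_labels=list(truths),
        scores=scores,
        calls=calls,
        fallbacks=fallbacks,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        scheme=scheme,
        iteration=iteration,
        seed=seed,
    )


def leave_one_out(
    network: BipartiteNetwork,
    config: NebulaConfig = DEFAULT_CONFIG,
) -> ValidationReport:
    """Predict every edge from the network with that edge removed.

    The predictor's exclusion is structural (the queried entry is never
    read), so no network copies are made.
    """
    edges = network.edges()
    pairs = [(h, p) for h, p, _ in edges]
    truths = [POSITIVE if w == 2.0 else "negative" for _, _, w in edges]
    results = [predict(network, h, p, config) for h, p in pairs]
    return _make_report(pairs, truths, results, scheme="loo")


def repeated_kfold(
    network: BipartiteNetwork,
    k: int = 2,
    iterations: int = 100,
    base_seed: int = 0,
    config: NebulaConfig = DEFAULT_CONFIG,
) -> list[ValidationReport]:
    """Repeated k-fold cross-validation over edges.

    Per iteration the edges are shuffled (seed ``base_seed + iteration``) and
    split into k folds whose sizes differ by at most one; each fold is
    predicted from the union of the others and the per-edge predictions are
    pooled into one report per iteration.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ii, jj, ww = network.edge_arrays()
    n = len(ww)
    if n < k:
        raise ValueError("fewer edges than folds")
    reports = []
    for it in range(iterations):
        seed = base_seed + it
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        pairs, truths, results = [], [], []
        for fold in folds:
            W_train = network.W.copy()
            W_train[ii[fold], jj[fold]] = 0.0
            train_net = BipartiteNetwork(network.hla_names, network.peptide_names, W_train)
            for e in fold:
                h, p = network.hla_names[ii[e]], network.peptide_names[jj[e]]
                pairs.append((h, p))
                truths.append(POSITIVE if ww[e] == 2.0 else "negative")
                results.append(predict(train_net, h, p, config))
        reports.append(
            _make_report(pairs, truths, results, scheme=f"{k}-fold", iteration=it, seed=seed)
        )
    return reports


def summarize_reports(reports: Sequence[ValidationReport]) -> dict:
    """Mean and standard deviation of each metric across iterations."""
    def stat(values):
        v = np.asarray([x for x in values if x is not None], dtype=float)
        return {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        }

    return {
        "iterations": len(reports),
        "sensitivity": stat([r.sensitivity for r in reports]),
        "specificity": stat([r.specificity for r in reports]),
        "accuracy": stat([r.accuracy for r in reports]),
        "auc": stat([r.auc for r in reports]),
    }
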