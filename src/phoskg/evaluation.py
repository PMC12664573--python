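"""Evaluation: ROC-AUC / PR-AUC with fixed tie handling, percentile
bootstrap confidence intervals, the similar-kinase easy-test filter, and
the random-embedding control experiment.

The metric implementations are deliberately self-contained (mean-rank ties
for ROC, average-precision stepping for PR) so results are bit-stable and
independent of any particular library version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .classifier import ClassifierTrainConfig, predict, train_classifier
from .dataset import ClassificationSample, DatasetBundle
from .kg import KnowledgeGraph
from .kge import EmbeddingTable


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, float).ravel()
    y = np.asarray(labels, int).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if len(s) == 0:
        raise ValueError("empty input")
    return s, y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(random positive outscores random negative), ties counted half."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision: sum over thresholds of delta-recall x precision."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC needs at least one positive")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    # collapse tied scores into threshold blocks
    distinct = np.concatenate([np.nonzero(np.diff(s))[0], [len(s) - 1]])
    tp = np.cumsum(y)[distinct]
    fp = (distinct + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def bootstrap_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    metric: Callable[[Sequence[float], Sequence[int]], float],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap over (score, label) pairs; degenerate resamples
    (a single class) are redrawn."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    s, y = _validate(scores, labels)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    n = len(s)
    for i in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            yy = y[idx]
            if 0 < yy.sum() < n:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        stats[i] = metric(s[idx], yy)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    roc_auc: float
    pr_auc: float
    roc_ci: tuple[float, float]
    pr_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    n_bootstrap: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "roc_ci_low": self.roc_ci[0],
            "roc_ci_high": self.roc_ci[1],
            "pr_ci_low": self.pr_ci[0],
            "pr_ci_high": self.pr_ci[1],
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EvalReport:
    s, y = _validate(scores, labels)
    return EvalReport(
        roc_auc=roc_auc(s, y),
        pr_auc=pr_auc(s, y),
        roc_ci=bootstrap_ci(s, y, roc_auc, n_bootstrap, seed),
        pr_ci=bootstrap_ci(s, y, pr_auc, n_bootstrap, seed),
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Easy-test filtering
# ---------------------------------------------------------------------------

class SimilarKinasePairs:
    """Symmetric, irreflexive set of kinase pairs sharing a family or domain."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[frozenset] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        if a == b:
            return
        self._pairs.add(frozenset((a, b)))

    def partners(self, kinase: str) -> set[str]:
        out = set()
        for pair in self._pairs:
            if kinase in pair:
                out |= pair - {kinase}
        return out

    def __contains__(self, pair) -> bool:
        a, b = pair
        return frozenset((a, b)) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        for pair in self._pairs:
            yield tuple(sorted(pair))


def find_similar_kinases(kg: KnowledgeGraph) -> SimilarKinasePairs:
    """Pair kinases that share at least one family or one domain entity."""
    groups: dict[str, set[str]] = {}
    for t in kg:
        if t.relation in ("belongs_to_family", "has_domain"):
            groups.setdefault(t.tail, set()).add(t.head)
    pairs = SimilarKinasePairs()
    for members in groups.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pairs.add(a, b)
    return pairs


def filter_easy_tests(
    train: Sequence[ClassificationSample],
    test: Sequence[ClassificationSample],
    similar: SimilarKinasePairs,
) -> tuple[list[ClassificationSample], int]:
    """Drop test samples answerable from a similar kinase's single-label
    (kinase, motif) record in training; ambiguous (both-label) records keep
    the sample."""
    train_labels: dict[tuple[str, str], set[int]] = {}
    for s in train:
        train_labels.setdefault((s.kinase, s.motif), set()).add(s.label)
    partner_cache: dict[str, set[str]] = {}
    kept: list[ClassificationSample] = []
    removed = 0
    for s in test:
        if s.kinase not in partner_cache:
            partner_cache[s.kinase] = similar.partners(s.kinase)
        easy = False
        for k2 in partner_cache[s.kinase]:
            labels = train_labels.get((k2, s.motif))
            if labels is not None and labels == {s.label}:
                easy = True
                break
        if easy:
            removed += 1
        else:
            kept.append(s)
    return kept, removed


# ---------------------------------------------------------------------------
# Random-embedding control
# ---------------------------------------------------------------------------

def random_embedding_control(
    bundle: DatasetBundle,
    dim: int = 100,
    config: ClassifierTrainConfig | None = None,
    seed: int = 0,
    n_bootstrap: int = 1000,
) -> dict[str, EvalReport]:
    """Train the classifier on independent standard-normal embeddings and
    evaluate on test1 (balanced) and test2 (natural ratio)."""
    entities = sorted(
        {x.kinase for part in (bundle.train, bundle.test1, bundle.test2) for x in part}
        | {x.substrate for part in (bundle.train, bundle.test1, bundle.test2) for x in part}
        | {x.motif for part in (bundle.train, bundle.test1, bundle.test2) for x in part}
    )
    emb = EmbeddingTable.random(entities, [], dim=dim, seed=seed)
    config = config or ClassifierTrainConfig(seed=seed)
    params, _ = train_classifier(bundle, emb, config)
    reports = {}
    for name in ("test1", "test2"):
        samples = getattr(bundle, name)
        probs = predict(params, emb, samples)
        labels = [s.label for s in samples]
        reports[name] = evaluate_scores(probs, labels, n_bootstrap=n_bootstrap, seed=seed)
    return reports
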