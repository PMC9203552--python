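"""Permutation inference and scan-2 biotype consistency.

Classification metrics are assigned significance by label permutation:
case/control labels are shuffled independently within each split
(preserving split sizes and case fractions), the metric is recomputed on
each permuted dataset, and the add-one p-value
``(1 + #{null >= observed}) / (n_perm + 1)`` is reported, so p is never
zero and its minimum at 200 permutations is 1/201.

Biotype-score robustness is checked on the second scan of the same
subjects: for each retained biotype, the one-vs-rest AUC of that
biotype's membership score among cases, summarized as the
cluster-size-weighted mean AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from biotypeflow.classifier import ClassifierModel, auc
from biotypeflow.clustering import OMITTED, BiotypeSolution


@dataclass(frozen=True)
class PermutationResult:
    """Observed metric, its permutation null, and the add-one p-value."""

    observed: float
    null_values: np.ndarray
    n_perm: int
    seed: int

    @property
    def p_value(self) -> float:
        return (1.0 + float(np.sum(self.null_values >= self.observed))) / (self.n_perm + 1.0)


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-biotype one-vs-rest AUCs on scan 2 and their weighted mean."""

    biotype_aucs: dict[int, float]
    biotype_sizes: dict[int, int]
    weighted_auc: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.biotype_sizes[b] for b in self.biotype_aucs)
        weighted = sum(
            self.biotype_sizes[b] * self.biotype_aucs[b] for b in self.biotype_aucs
        ) / total
        object.__setattr__(self, "weighted_auc", float(weighted))


def weighted_auc(aucs: dict[int, float], sizes: dict[int, int]) -> float:
    """Cluster-size-weighted mean of per-biotype AUCs."""
    return ConsistencyReport(biotype_aucs=aucs, biotype_sizes=sizes).weighted_auc


def permute_labels_within_splits(
    labels: np.ndarray, split: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle labels independently inside each split (fractions preserved)."""
    labels = np.asarray(labels)
    out = labels.copy()
    for s in np.unique(split):
        idx = np.flatnonzero(split == s)
        out[idx] = labels[idx[rng.permutation(len(idx))]]
    return out


def permutation_test(
    metric_fn: Callable[[np.ndarray, np.random.Generator], float],
    labels: np.ndarray,
    split: np.ndarray | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of any label-dependent metric.

    ``metric_fn(labels, rng)`` must recompute the metric from scratch for
    a given label vector (retraining whatever it needs); it is called
    once with the observed labels and once per permutation.  Labels are
    permuted within splits when ``split`` is given.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    labels = np.asarray(labels)
    if split is None:
        split = np.zeros(len(labels), dtype=int)
    rng = np.random.default_rng(seed)
    observed = float(metric_fn(labels, np.random.default_rng(rng.integers(2**31))))
    null = np.empty(n_perm)
    for i in range(n_perm):
        permuted = permute_labels_within_splits(labels, split, rng)
        null[i] = metric_fn(permuted, np.random.default_rng(rng.integers(2**31)))
    return PermutationResult(observed=observed, null_values=null, n_perm=n_perm, seed=seed)


def scan2_consistency(
    model: ClassifierModel,
    scan2_fc: np.ndarray,
    solution: BiotypeSolution,
) -> ConsistencyReport:
    """One-vs-rest biotype AUCs on scan-2 FC of the clustered cases.

    ``scan2_fc`` must already be residualized with the training-split
    covariate model.  Rows align with ``solution.labels`` (the clustered
    case subjects); omitted-cluster subjects are excluded.
    """
    labels = solution.labels
    retained = labels != OMITTED
    scores = model.predict(np.asarray(scan2_fc, dtype=float)[retained])["biotype_scores"]
    labs = labels[retained]
    biotype_ids = list(model.provenance.get("biotype_ids", [])) or sorted(
        np.unique(labs).tolist()
    )
    aucs: dict[int, float] = {}
    sizes: dict[int, int] = {}
    for j, b in enumerate(biotype_ids):
        members = labs == b
        if members.sum() == 0 or members.all():
            warnings.warn(f"biotype {b} absent (or alone) in scan-2 data; skipped",
                          stacklevel=2)
            continue
        aucs[b] = auc(scores[:, j], members.astype(int))
        sizes[b] = int(members.sum())
    if not aucs:
        raise ValueError("no biotype could be evaluated on scan 2")
    return ConsistencyReport(biotype_aucs=aucs, biotype_sizes=sizes)
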