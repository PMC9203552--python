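"""Biotype discovery: dimension reduction, clustering, model selection.

Case subjects' selected FC features are embedded into 2/3/4 dimensions
(UMAP by default; the reducer is a pluggable contract so any
proximity-preserving embedding can stand in), clustered by K-means and
Ward hierarchical clustering, with the cluster count k in {2, 3, 4}
chosen by the Variance Ratio Criterion (the Calinski–Harabasz
statistic).  The full grid of three screening alphas times three
embedding dimensions yields nine candidate biotyping solutions; the
winner is picked downstream by validation classification AUC.  Clusters
too small to power subsequent analyses are flagged *omitted*: their
subjects drop out of biotype-level analyses but remain cases for the
overall case-control classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

OMITTED = -1  #: label marking subjects of an omitted (undersized) cluster

DEFAULT_DIMS = (2, 3, 4)
DEFAULT_K_CANDIDATES = (2, 3, 4)
DEFAULT_MIN_CLUSTER_SIZE = 20


@dataclass(frozen=True)
class Embedding:
    """Low-dimensional coordinates of case subjects plus provenance."""

    coords: np.ndarray  # n_subjects x d
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("embedding contains non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def n_subjects(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class BiotypeSolution:
    """One clustering solution: labels, k, method, VRC and provenance.

    ``labels`` holds 1..k for retained clusters and :data:`OMITTED` for
    subjects of omitted clusters.
    """

    labels: np.ndarray
    k: int
    method: str
    vrc_score: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def retained_labels(self) -> np.ndarray:
        return np.unique(self.labels[self.labels != OMITTED])

    def cluster_sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))


def reduce(
    fc_selected: np.ndarray,
    d: int,
    seed: int,
    reducer: str = "umap",
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> Embedding:
    """Embed selected FC features of case subjects into ``d`` dimensions.

    ``reducer='umap'`` is the production path; ``reducer='pca'``
    fulfils the same proximity-preserving contract deterministically and
    cheaply, which is useful in tests of downstream stages.
    Deterministic under a fixed ``seed``.
    """
    x = np.asarray(fc_selected, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in the feature matrix")
    if d not in (2, 3, 4):
        raise ValueError("embedding dimension must be 2, 3 or 4")
    if x.shape[0] < d + 1:
        raise ValueError(f"need at least {d + 1} subjects for a {d}-D embedding")
    provenance = {"reducer": reducer, "d": d, "seed": seed}
    if reducer == "umap":
        import umap  # deferred: numba compilation is expensive at import

        n_neighbors = min(n_neighbors, x.shape[0] - 1)
        provenance.update({"n_neighbors": n_neighbors, "min_dist": min_dist})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = umap.UMAP(
                n_components=d,
                n_neighbors=n_neighbors,
                min_dist=min_dist,
                random_state=seed,
                metric="euclidean",
            )
            coords = model.fit_transform(x)
    elif reducer == "pca":
        coords = PCA(n_components=min(d, min(x.shape)), random_state=seed).fit_transform(x)
        if coords.shape[1] < d:  # degenerate rank: pad with zeros
            coords = np.column_stack([coords, np.zeros((x.shape[0], d - coords.shape[1]))])
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    return Embedding(coords=np.asarray(coords, dtype=float), provenance=provenance)


def cluster(
    emb: Embedding, k: int, method: str = "kmeans", seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Cluster an embedding into ``k`` groups; labels are 1..k.

    K-means runs ``n_restarts`` seeded restarts keeping the best
    inertia; hierarchical clustering is Ward linkage cut at ``k``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > emb.n_subjects:
        raise ValueError(f"k={k} exceeds the number of subjects {emb.n_subjects}")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(emb.coords)
    elif method == "hierarchical":
        z = linkage(emb.coords, method="ward")
        labels = fcluster(z, t=k, criterion="maxclust") - 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return labels.astype(int) + 1


def vrc(emb: Embedding, labels: np.ndarray) -> float:
    """Variance Ratio Criterion (Calinski–Harabasz statistic).

    [trace(B)/(k-1)] / [trace(W)/(n-k)] with B, W the between- and
    within-cluster dispersion matrices.  A partition with zero
    within-cluster dispersion returns +inf.
    """
    x = emb.coords
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("VRC requires at least 2 non-empty clusters")
    n, k = x.shape[0], len(uniq)
    overall = x.mean(axis=0)
    between = 0.0
    within = 0.0
    for lab in uniq:
        grp = x[labels == lab]
        centroid = grp.mean(axis=0)
        between += len(grp) * np.sum((centroid - overall) ** 2)
        within += np.sum((grp - centroid) ** 2)
    if within == 0.0:
        warnings.warn("zero within-cluster dispersion; VRC is infinite", stacklevel=2)
        return float("inf")
    return float((between / (k - 1)) / (within / (n - k)))


def select_k(
    emb: Embedding,
    candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
    method: str = "kmeans",
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose k among ``candidates`` by maximal VRC (ties -> smaller k)."""
    best: tuple[float, int, np.ndarray] | None = None
    for k in sorted(candidates):
        labels = cluster(emb, k, method=method, seed=seed)
        score = vrc(emb, labels)
        if best is None or score > best[0]:
            best = (score, k, labels)
    assert best is not None
    return best[1], best[2]


def omit_small_clusters(
    solution: BiotypeSolution, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> BiotypeSolution:
    """Flag clusters smaller than ``min_cluster_size`` as omitted.

    Omitted subjects keep their case status for overall classification
    but are excluded from biotype-level analyses.  Retained clusters are
    relabelled 1..k' in order of their original labels.
    """
    labels = solution.labels.copy()
    uniq, counts = np.unique(labels[labels != OMITTED], return_counts=True)
    retained = uniq[counts >= min_cluster_size]
    if len(retained) == 0:
        raise ValueError("all clusters fall below min_cluster_size")
    new_labels = np.full_like(labels, OMITTED)
    for new, old in enumerate(retained, start=1):
        new_labels[labels == old] = new
    return replace(
        solution,
        labels=new_labels,
        k=len(retained),
        provenance={**solution.provenance, "min_cluster_size": min_cluster_size,
                    "omitted_sizes": counts[counts < min_cluster_size].tolist()},
    )


def solution_grid(
    fc: np.ndarray,
    masks: dict[float, np.ndarray],
    dims: Sequence[int] = DEFAULT_DIMS,
    seed: int = 0,
    methods: Sequence[str] = ("kmeans", "hierarchical"),
    k_candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    reducer: str = "umap",
) -> list[BiotypeSolution]:
    """Enumerate the (alpha x dimension) grid of biotyping solutions.

    For each feature mask (one per alpha) and each embedding dimension,
    embed the case subjects, run every clustering method, keep the
    method with the larger VRC at its selected k, then omit undersized
    clusters.  Cells with an empty mask are skipped with a warning.
    The caller selects among solutions by validation AUC.
    """
    solutions: list[BiotypeSolution] = []
    for alpha in sorted(masks, reverse=True):
        mask = np.asarray(masks[alpha], dtype=bool)
        if mask.sum() == 0:
            warnings.warn(f"empty feature mask at alpha={alpha}; cell skipped", stacklevel=2)
            continue
        sub = fc[:, mask]
        for d in dims:
            emb = reduce(sub, d=d, seed=seed, reducer=reducer)
            best: BiotypeSolution | None = None
            for method in methods:
                k, labels = select_k(emb, candidates=k_candidates, method=method, seed=seed)
                score = vrc(emb, labels)
                cand = BiotypeSolution(
                    labels=labels,
                    k=k,
                    method=method,
                    vrc_score=score,
                    provenance={"alpha": alpha, "d": d, "seed": seed,
                                "n_features": int(mask.sum()), **emb.provenance},
                )
                if best is None or cand.vrc_score > best.vrc_score:
                    best = cand
            assert best is not None
            solutions.append(omit_small_clusters(best, min_cluster_size))
    return solutions
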