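"""Offline phase: fragment genomes, cluster signatures, tag marker clusters.

Reference genomes are split into fixed-length fragments (1,000 bp by
default), each fragment is reduced to its tetranucleotide signature, and the
signatures are clustered by k-means under the Manhattan (L1) metric.  A set
of reference marker sequences (e.g. 16S rDNA from a curated database) is then
assigned to nearest clusters; clusters picked by many references are tagged
as "probable marker clusters".  The centroids, cluster sizes and tagged id
set form the entire offline product consumed by the online classifier.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DimensionMismatchError,
    EmptyReferenceError,
    InfeasibleClusteringError,
    NoTaggedClustersError,
)
from .features import DEFAULT_SPEC, FeatureSpec, FeatureVector, tetra_vector

logger = logging.getLogger(__name__)

MODEL_FORMAT = "irdna-model/1"

#: Tagging threshold used at reference scale: clusters picked by at least
#: 10,000 of the 63,325 reference 16S sequences.  The fractional form makes
#: the same rule applicable to reference sets of any size.
REFERENCE_PICK_COUNT = 10_000
REFERENCE_SET_SIZE = 63_325


@dataclass(frozen=True)
class FragmentationParams:
    fragment_length: int = 1000
    drop_partial: bool = True

    def __post_init__(self) -> None:
        if self.fragment_length < 1:
            raise ValueError("fragment_length must be positive")


@dataclass(frozen=True)
class Fragment:
    """One genome window and its signature; coordinates 0-based half-open."""

    source_id: str
    start: int
    end: int
    vector: FeatureVector


@dataclass(frozen=True)
class ClusteringParams:
    n_clusters: int = 16
    max_iterations: int = 100
    convergence_tolerance: float = 1e-6
    random_seed: int = 0
    spread_init: bool = False  # k-means++-style spreading; plain seeded choice by default

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


@dataclass(frozen=True)
class TaggingParams:
    """Threshold for tagging probable marker clusters.

    Exactly one of ``min_pick_count`` / ``min_pick_fraction`` governs a run.
    The default fraction reproduces the absolute reference-scale rule
    (10,000 picks out of 63,325 references) for reference sets of any size.
    """

    min_pick_count: int | None = None
    min_pick_fraction: float | None = REFERENCE_PICK_COUNT / REFERENCE_SET_SIZE

    def __post_init__(self) -> None:
        if (self.min_pick_count is None) == (self.min_pick_fraction is None):
            raise ValueError(
                "exactly one of min_pick_count / min_pick_fraction must be set"
            )

    def threshold(self, n_markers: int) -> float:
        if self.min_pick_count is not None:
            return float(self.min_pick_count)
        return self.min_pick_fraction * n_markers


@dataclass
class ClusterModel:
    """The offline product: centroids, sizes, tagged cluster ids, provenance."""

    spec: FeatureSpec
    centroids: np.ndarray  # (n_clusters, dimension)
    sizes: np.ndarray  # (n_clusters,) fragment counts
    tagged_cluster_ids: set[int] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != self.spec.dimension:
            raise DimensionMismatchError(
                f"centroids must be (k, {self.spec.dimension}), got {self.centroids.shape}"
            )
        if len(self.sizes) != len(self.centroids):
            raise ValueError("sizes and centroids disagree in cluster count")
        bad = set(self.tagged_cluster_ids) - set(range(len(self.centroids)))
        if bad:
            raise ValueError(f"tagged ids outside cluster range: {sorted(bad)}")

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def total_fragments(self) -> int:
        return int(self.sizes.sum())

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.centroids).tobytes())
        h.update(np.ascontiguousarray(self.sizes).tobytes())
        h.update(",".join(map(str, sorted(self.tagged_cluster_ids))).encode())
        return h.hexdigest()


def fragment_genome(
    seq: str,
    source_id: str,
    params: FragmentationParams = FragmentationParams(),
    spec: FeatureSpec = DEFAULT_SPEC,
) -> list[Fragment]:
    """Split a genome into consecutive non-overlapping windows and vectorize.

    The trailing partial window is discarded when ``drop_partial``; a genome
    shorter than one fragment yields an empty list (warning logged).
    """
    L = params.fragment_length
    out: list[Fragment] = []
    n_full = len(seq) // L
    if n_full == 0 and params.drop_partial:
        logger.warning(
            "genome %s (%d bp) shorter than fragment_length=%d: no fragments",
            source_id, len(seq), L,
        )
    stops = n_full * L if params.drop_partial else len(seq)
    for start in range(0, stops, L):
        end = min(start + L, len(seq))
        if end - start < spec.k:
            continue
        out.append(Fragment(source_id, start, end, tetra_vector(seq[start:end], spec)))
    return out


def _as_matrix(vectors: Sequence[FeatureVector]) -> np.ndarray:
    return np.stack([v.values for v in vectors])


def kmeans_cluster(
    vectors: Sequence[FeatureVector] | np.ndarray,
    params: ClusteringParams,
    objective_history: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lloyd iteration with L1 assignment and mean centroid update.

    Returns (assignments, centroids, sizes).  Initial centroids are k
    distinct input vectors chosen by the seeded generator (optionally with
    greedy farthest-point spreading).  Empty clusters are re-seeded from the
    point farthest (L1) from its current centroid.  Deterministic given
    ``params.random_seed``.  When ``objective_history`` is a list, a pair
    (objective before reassignment under the current centroids, objective
    after reassignment) is appended per iteration, witnessing that the
    assignment step never increases the objective.
    """
    X = vectors if isinstance(vectors, np.ndarray) else _as_matrix(vectors)
    n, k = len(X), params.n_clusters
    if n < k:
        raise InfeasibleClusteringError(f"{n} vectors cannot form {k} clusters")
    rng = np.random.default_rng(params.random_seed)
    if params.spread_init:
        idx = [int(rng.integers(n))]
        d_min = np.abs(X - X[idx[0]]).sum(axis=1)
        for _ in range(k - 1):
            idx.append(int(d_min.argmax()))
            d_min = np.minimum(d_min, np.abs(X - X[idx[-1]]).sum(axis=1))
        centroids = X[idx].copy()
    else:
        centroids = X[rng.choice(n, size=k, replace=False)].copy()

    assign = np.zeros(n, dtype=np.int64)
    for it in range(params.max_iterations):
        D = cdist(X, centroids, metric="cityblock")
        if objective_history is not None and it > 0:
            pre = float(D[np.arange(n), assign].sum())
        assign_new = D.argmin(axis=1)  # argmin takes the lowest id on ties
        point_dist = D[np.arange(n), assign_new]
        if objective_history is not None and it > 0:
            objective_history.append((pre, float(point_dist.sum())))
        assign = assign_new
        new_centroids = centroids.copy()
        for j in range(k):
            members = assign == j
            if members.any():
                new_centroids[j] = X[members].mean(axis=0)
            else:
                far = int(point_dist.argmax())
                new_centroids[j] = X[far]
                point_dist[far] = -1.0  # a point reseeds at most one cluster
        moved = np.abs(new_centroids - centroids).sum(axis=1).max()
        centroids = new_centroids
        if moved < params.convergence_tolerance:
            break
    D = cdist(X, centroids, metric="cityblock")
    assign = D.argmin(axis=1)
    sizes = np.bincount(assign, minlength=k)
    return assign, centroids, sizes


def kmeans_objective(X: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    """Sum of L1 distances from each point to its assigned centroid."""
    return float(np.abs(X - centroids[assign]).sum())


def nearest_cluster(v: FeatureVector, model: ClusterModel) -> int:
    """Index of the centroid closest under L1; ties broken by lowest id."""
    if v.values.shape[0] != model.centroids.shape[1]:
        raise DimensionMismatchError(
            f"vector dim {v.values.shape[0]} vs model dim {model.centroids.shape[1]}"
        )
    return int(np.abs(model.centroids - v.values).sum(axis=1).argmin())


def tag_marker_clusters(
    marker_vectors: Sequence[FeatureVector],
    model: ClusterModel,
    params: TaggingParams = TaggingParams(),
) -> set[int]:
    """Tag clusters picked (nearest-cluster) by enough marker references.

    Stores the result into ``model.tagged_cluster_ids`` and returns it.
    """
    if len(marker_vectors) == 0:
        raise EmptyReferenceError("marker reference set is empty")
    picks = np.array([nearest_cluster(v, model) for v in marker_vectors])
    counts = np.bincount(picks, minlength=model.n_clusters)
    thr = params.threshold(len(marker_vectors))
    tagged = {int(c) for c in np.flatnonzero(counts >= thr)}
    model.tagged_cluster_ids = tagged
    model.provenance.setdefault("tagging", {})
    model.provenance["tagging"].update(
        {
            "n_markers": len(marker_vectors),
            "threshold": thr,
            "pick_counts": {int(c): int(n) for c, n in enumerate(counts) if n},
        }
    )
    return tagged


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_model(
    genomes: str | Path,
    markers: str | Path,
    frag: FragmentationParams = FragmentationParams(),
    clus: ClusteringParams = ClusteringParams(),
    tag: TaggingParams = TaggingParams(),
    spec: FeatureSpec = DEFAULT_SPEC,
) -> ClusterModel:
    """Compose the full offline phase from two FASTA files.

    fragment -> vectorize -> k-means (L1) -> tag probable marker clusters.
    Refuses to emit a model whose tagged set is empty.
    """
    from .io import read_fasta  # local import to avoid a cycle

    fragments: list[Fragment] = []
    for rec_id, seq in read_fasta(genomes):
        fragments.extend(fragment_genome(seq, rec_id, frag, spec))
    if len(fragments) < clus.n_clusters:
        raise InfeasibleClusteringError(
            f"{len(fragments)} fragments cannot form {clus.n_clusters} clusters"
        )
    X = np.stack([f.vector.values for f in fragments])
    assign, centroids, sizes = kmeans_cluster(X, clus)
    model = ClusterModel(
        spec=spec,
        centroids=centroids,
        sizes=sizes,
        provenance={
            "format": MODEL_FORMAT,
            "fragmentation": {"fragment_length": frag.fragment_length,
                              "drop_partial": frag.drop_partial},
            "clustering": {"n_clusters": clus.n_clusters,
                           "max_iterations": clus.max_iterations,
                           "convergence_tolerance": clus.convergence_tolerance,
                           "random_seed": clus.random_seed,
                           "spread_init": clus.spread_init},
            "inputs": {"genomes_sha256": _sha256_file(genomes),
                       "markers_sha256": _sha256_file(markers)},
            "n_fragments": len(fragments),
            "empty_clusters": [int(c) for c in np.flatnonzero(sizes == 0)],
        },
    )
    marker_vectors = [tetra_vector(seq, spec) for _, seq in read_fasta(markers)]
    tagged = tag_marker_clusters(marker_vectors, model, tag)
    if not tagged:
        logger.error("no cluster reached the marker pick threshold")
        raise NoTaggedClustersError(
            "zero probable marker clusters: reference set does not localize"
        )
    logger.info(
        "built model: %d fragments, %d clusters, %d tagged",
        len(fragments), model.n_clusters, len(tagged),
    )
    return model
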