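"""Online phase: flag reads whose closest clusters overlap the tagged set.

For each query read the classifier (i) computes its tetranucleotide vector
(both orientations by default, keeping the one closer to its nearest
centroid, since metagenomic reads are unoriented), (ii) walks clusters in
ascending L1 distance, accumulating their fragment counts until the
cumulative-sequence-count budget is reached, and (iii) calls the read a
"probable marker fragment" when the percentage of selected clusters that are
tagged meets the overlap threshold.  Runtime per read is O(n_clusters * 256)
with no dependence on dataset size, which is what makes the pre-screen cheap
relative to a per-read HMM scan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateSelectionError, DegenerateSequenceError, DimensionMismatchError
from .features import FeatureVector, reverse_complement, tetra_vector
from .model import ClusterModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierParams:
    """The two runtime thresholds plus strand handling.

    The budget can be given three ways; exactly one must be active.
    ``cumulative_sequence_count`` is the absolute budget of summed cluster
    sizes.  ``budget_fraction`` expresses it as a fraction of the model's
    total fragment count.  ``budget_from_tagged`` resolves it to the
    cumulative size of the model's tagged clusters: a marker-like query can
    then exhaust the tagged set without dragging in background clusters,
    and the resolved value scales with the model (for a full-scale reference
    model this lands in the tens-of-thousands range that the tuning grid
    sweeps).
    """

    cumulative_sequence_count: int | None = None
    budget_fraction: float | None = None
    budget_from_tagged: bool = False
    overlap_threshold_percent: float = 50.0
    both_strands: bool = True

    def __post_init__(self) -> None:
        n_modes = (
            (self.cumulative_sequence_count is not None)
            + (self.budget_fraction is not None)
            + bool(self.budget_from_tagged)
        )
        if n_modes != 1:
            raise ValueError(
                "exactly one of cumulative_sequence_count / budget_fraction / "
                "budget_from_tagged must be set"
            )
        if self.cumulative_sequence_count is not None and self.cumulative_sequence_count < 1:
            raise ValueError("cumulative_sequence_count must be >= 1")
        if not 0.0 <= self.overlap_threshold_percent <= 100.0:
            raise ValueError("overlap_threshold_percent must lie in [0, 100]")

    def resolve_budget(self, model: ClusterModel) -> int:
        """Absolute cumulative-sequence-count budget for a given model."""
        if self.cumulative_sequence_count is not None:
            return self.cumulative_sequence_count
        if self.budget_fraction is not None:
            return max(1, int(round(self.budget_fraction * model.total_fragments)))
        tagged_total = int(model.sizes[sorted(model.tagged_cluster_ids)].sum())
        return max(1, tagged_total)


#: Read-length presets named after the sequencing technologies whose typical
#: lengths they target (Sanger ~800 bp, 454-Titanium ~400, 454-Standard ~250,
#: Roche-GS20 ~100).  All resolve the budget from the model's tagged-cluster
#: mass and use a 50% overlap threshold; tune_grid exists to refit the
#: thresholds to a particular model.
PROFILES: dict[str, ClassifierParams] = {
    "sanger-800": ClassifierParams(budget_from_tagged=True, overlap_threshold_percent=50.0),
    "454-400": ClassifierParams(budget_from_tagged=True, overlap_threshold_percent=50.0),
    "454-250": ClassifierParams(budget_from_tagged=True, overlap_threshold_percent=50.0),
    "454-100": ClassifierParams(budget_from_tagged=True, overlap_threshold_percent=50.0),
}


@dataclass(frozen=True)
class Prediction:
    read_id: str
    is_probable_marker: bool
    overlap_percent: float
    n_closest_clusters: int
    orientation_used: str  # "forward" | "reverse" | "n/a"


def select_closest_clusters(
    v: FeatureVector, model: ClusterModel, budget: int
) -> list[int]:
    """Clusters in ascending L1 order until their sizes first reach budget.

    The cluster that crosses the budget is included, so budget=1 selects
    exactly the nearest non-empty cluster.  Ties in distance break toward
    the lower cluster id.
    """
    if v.values.shape[0] != model.centroids.shape[1]:
        raise DimensionMismatchError(
            f"vector dim {v.values.shape[0]} vs model dim {model.centroids.shape[1]}"
        )
    if budget < 1:
        raise ValueError("budget must be >= 1")
    dist = np.abs(model.centroids - v.values).sum(axis=1)
    order = np.argsort(dist, kind="stable")  # stable sort => lowest id on ties
    selected: list[int] = []
    running = 0
    for cid in order:
        selected.append(int(cid))
        running += int(model.sizes[cid])
        if running >= budget:
            break
    return selected


def overlap_percent(closest: Iterable[int], tagged: set[int]) -> float:
    """100 * |closest ∩ tagged| / |closest|."""
    closest = set(closest)
    if not closest:
        raise DegenerateSelectionError("closest-cluster set is empty")
    return 100.0 * len(closest & tagged) / len(closest)


def _oriented_vector(
    seq: str, model: ClusterModel, both_strands: bool
) -> tuple[FeatureVector, str]:
    fwd = tetra_vector(seq, model.spec)
    if not both_strands:
        return fwd, "forward"
    try:
        rev = tetra_vector(reverse_complement(seq), model.spec)
    except DegenerateSequenceError:
        return fwd, "forward"
    d_fwd = np.abs(model.centroids - fwd.values).sum(axis=1).min()
    d_rev = np.abs(model.centroids - rev.values).sum(axis=1).min()
    return (fwd, "forward") if d_fwd <= d_rev else (rev, "reverse")


def classify_read(
    seq: str, model: ClusterModel, params: ClassifierParams, read_id: str = ""
) -> Prediction:
    """Classify one read; unvectorizable reads yield a negative verdict."""
    try:
        v, orientation = _oriented_vector(seq, model, params.both_strands)
    except DegenerateSequenceError:
        logger.warning("read %s has no ambiguity-free window: skipped", read_id)
        return Prediction(read_id, False, 0.0, 0, "n/a")
    budget = params.resolve_budget(model)
    closest = select_closest_clusters(v, model, budget)
    pct = overlap_percent(closest, model.tagged_cluster_ids)
    return Prediction(
        read_id=read_id,
        is_probable_marker=pct >= params.overlap_threshold_percent,
        overlap_percent=pct,
        n_closest_clusters=len(closest),
        orientation_used=orientation,
    )


@dataclass(frozen=True)
class ScreenSummary:
    total_reads: int  # X
    probable_reads: int  # Y
    params: ClassifierParams
    model_digest: str

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "X": self.total_reads,
                "Y": self.probable_reads,
                "params": {
                    "cumulative_sequence_count": p.cumulative_sequence_count,
                    "budget_fraction": p.budget_fraction,
                    "overlap_threshold_percent": p.overlap_threshold_percent,
                    "both_strands": p.both_strands,
                },
                "model_digest": self.model_digest,
            },
            indent=2,
        )


PREDICTIONS_HEADER = "read_id\toverlap_percent\tn_closest_clusters\tverdict\torientation"


def iter_predictions(
    reads: Iterable[tuple[str, str]], model: ClusterModel, params: ClassifierParams
) -> Iterator[tuple[Prediction, str]]:
    """Stream (prediction, sequence) pairs over (id, seq) records."""
    for read_id, seq in reads:
        yield classify_read(seq, model, params, read_id=read_id), seq


def screen_dataset(
    reads: str | Path,
    model: ClusterModel,
    params: ClassifierParams,
    out_prefix: str | Path | None = None,
) -> tuple[list[Prediction], ScreenSummary]:
    """Screen a FASTA file; optionally write candidates/predictions/summary.

    Streams records (memory independent of dataset size).  When
    ``out_prefix`` is given, writes ``<prefix>.candidates.fasta`` (probable
    reads verbatim), ``<prefix>.predictions.tsv`` and ``<prefix>.summary.json``.
    """
    from .io import read_fasta, write_fasta_record

    predictions: list[Prediction] = []
    n_probable = 0
    cand_fh = pred_fh = None
    try:
        if out_prefix is not None:
            out_prefix = Path(out_prefix)
            out_prefix.parent.mkdir(parents=True, exist_ok=True)
            cand_fh = open(f"{out_prefix}.candidates.fasta", "w")
            pred_fh = open(f"{out_prefix}.predictions.tsv", "w")
            pred_fh.write(PREDICTIONS_HEADER + "\n")
        for pred, seq in iter_predictions(read_fasta(reads), model, params):
            predictions.append(pred)
            if pred.is_probable_marker:
                n_probable += 1
                if cand_fh is not None:
                    write_fasta_record(cand_fh, pred.read_id, seq)
            if pred_fh is not None:
                pred_fh.write(
                    f"{pred.read_id}\t{pred.overlap_percent:.4f}\t"
                    f"{pred.n_closest_clusters}\t"
                    f"{int(pred.is_probable_marker)}\t{pred.orientation_used}\n"
                )
    finally:
        for fh in (cand_fh, pred_fh):
            if fh is not None:
                fh.close()
    summary = ScreenSummary(
        total_reads=len(predictions),
        probable_reads=n_probable,
        params=params,
        model_digest=model.digest(),
    )
    if out_prefix is not None:
        with open(f"{out_prefix}.summary.json", "w") as fh:
            fh.write(summary.to_json() + "\n")
    logger.info("screened %d reads: %d probable", summary.total_reads, n_probable)
    return predictions, summary


def overlap_percent_matrix(
    vectors: np.ndarray, model: ClusterModel, budget: int
) -> np.ndarray:
    """Vectorized overlap percentages for many query vectors at one budget.

    Equivalent to running select_closest_clusters + overlap_percent per row;
    used by the tuning grid where the same distances serve many thresholds.
    """
    D = cdist(vectors, model.centroids, metric="cityblock")
    order = np.argsort(D, axis=1, kind="stable")
    sizes_sorted = model.sizes[order]
    csum = np.cumsum(sizes_sorted, axis=1)
    # first index where the running sum reaches the budget (inclusive crossing)
    n_sel = (csum < budget).sum(axis=1) + 1
    n_sel = np.minimum(n_sel, model.n_clusters)
    tagged_mask = np.zeros(model.n_clusters, dtype=bool)
    tagged_mask[list(model.tagged_cluster_ids)] = True
    tagged_sorted = tagged_mask[order]
    tag_csum = np.cumsum(tagged_sorted, axis=1)
    rows = np.arange(len(vectors))
    return 100.0 * tag_csum[rows, n_sel - 1] / n_sel
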