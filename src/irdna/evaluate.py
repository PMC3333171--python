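"""Evaluation machinery: screening metrics, tuning grid, ROC, clade holdout.

The screening quality of the pre-screen on a dataset of X reads is summarised
by four counts: Y reads flagged probable, A reference-confirmed marker reads,
and B confirmed marker reads among the flagged ones.  From these,

    detection sensitivity = B * 100 / A
    fold reduction in search space = X / Y

The tuning grid sweeps the two runtime thresholds (cumulative sequence count
budget x overlap percentage) on a labelled dataset, recording per cell the
percentage of reads flagged (A_pct), the percentage of true marker reads
captured (B_pct = TPR) and the false-positive rate, from which ROC points
follow.  The leave-one-clade-out protocol removes all marker references of
one taxon before tagging and measures sensitivity on reads drawn from the
removed taxon's markers, emulating screening of genuinely novel organisms.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import ClassifierParams, Prediction, classify_read, overlap_percent_matrix
from .errors import UndefinedMetricError, UnknownCladeError
from .features import tetra_vector
from .model import ClusterModel, TaggingParams, tag_marker_clusters
from .simulate import RANKS

logger = logging.getLogger(__name__)


def sensitivity(A: int, B: int) -> float:
    """Detection sensitivity B*100/A, to one decimal."""
    if A == 0:
        raise UndefinedMetricError("sensitivity undefined for A=0")
    if not 0 <= B <= A:
        raise ValueError(f"need 0 <= B <= A, got A={A}, B={B}")
    return round(B * 100.0 / A, 1)


def fold_reduction(X: int, Y: int) -> float:
    """Search-space fold reduction X/Y, to one decimal."""
    if Y == 0:
        raise UndefinedMetricError("fold reduction undefined for Y=0")
    if X < Y:
        raise ValueError(f"need X >= Y, got X={X}, Y={Y}")
    return round(X / Y, 1)


@dataclass(frozen=True)
class EvalReport:
    """One screened dataset's counts and derived metrics."""

    X: int  # total reads screened
    Y: int  # reads predicted probable
    A: int  # reference-positive reads
    B: int  # reference positives within the predicted set

    def __post_init__(self) -> None:
        if not (self.B <= self.A and self.B <= self.Y <= self.X):
            raise ValueError(f"inconsistent counts X={self.X} Y={self.Y} A={self.A} B={self.B}")

    @property
    def sensitivity_percent(self) -> float:
        return sensitivity(self.A, self.B)

    @property
    def fold_reduction(self) -> float:
        return fold_reduction(self.X, self.Y)

    def as_dict(self) -> dict:
        return {
            "X": self.X, "Y": self.Y, "A": self.A, "B": self.B,
            "sensitivity_percent": self.sensitivity_percent,
            "fold_reduction": self.fold_reduction,
        }


def report_from_predictions(
    predictions: Sequence[Prediction], labels: Mapping[str, bool]
) -> EvalReport:
    """Cross predictions with ground-truth labels into an EvalReport."""
    missing = [p.read_id for p in predictions if p.read_id not in labels]
    if missing:
        raise KeyError(f"{len(missing)} reads lack labels, e.g. {missing[0]!r}")
    X = len(predictions)
    Y = sum(p.is_probable_marker for p in predictions)
    A = sum(bool(labels[p.read_id]) for p in predictions)
    B = sum(p.is_probable_marker and bool(labels[p.read_id]) for p in predictions)
    return EvalReport(X=X, Y=Y, A=A, B=B)


def profile_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Taxon counts -> percent of the profile total, to one decimal.

    The arithmetic behind comparing taxonomic profiles built from two
    marker-detection routes: each taxon's share of all classified marker
    sequences.
    """
    total = sum(counts.values())
    if total == 0:
        raise UndefinedMetricError("empty taxonomic profile")
    return {taxon: round(100.0 * n / total, 1) for taxon, n in counts.items()}


@dataclass(frozen=True)
class GridCell:
    budget: int
    overlap: float
    A_pct: float  # percent of dataset flagged probable
    B_pct: float  # percent of true marker reads captured (== TPR)
    tpr: float
    fpr: float


def tune_grid(
    reads: Iterable[tuple[str, str]],
    labels: Mapping[str, bool],
    model: ClusterModel,
    budgets: Sequence[int],
    overlaps: Sequence[float],
    both_strands: bool = True,
) -> list[GridCell]:
    """Sweep (budget, overlap) thresholds over a labelled read set.

    Reads are vectorized once; each budget reuses the same distance matrix
    across all overlap thresholds, so the full grid costs little more than a
    single screen.
    """
    if not budgets or not overlaps:
        raise ValueError("budget and overlap grids must be non-empty")
    from .classify import _oriented_vector

    ids, vectors = [], []
    for read_id, seq in reads:
        v, _ = _oriented_vector(seq, model, both_strands)
        ids.append(read_id)
        vectors.append(v.values)
    if not ids:
        raise UndefinedMetricError("empty read set")
    V = np.stack(vectors)
    y = np.array([bool(labels[i]) for i in ids])
    X, A = len(ids), int(y.sum())
    if A == 0:
        raise UndefinedMetricError("dataset has no positive reads; grid undefined")

    cells: list[GridCell] = []
    for budget in budgets:
        pct = overlap_percent_matrix(V, model, int(budget))
        for overlap in overlaps:
            flagged = pct >= overlap
            Y = int(flagged.sum())
            B = int((flagged & y).sum())
            a_pct = 100.0 * Y / X
            b_pct = 100.0 * B / A
            fpr = 100.0 * (Y - B) / (X - A) if X > A else 0.0
            cells.append(GridCell(int(budget), float(overlap), a_pct, b_pct, b_pct, fpr))
    return cells


def select_optimal(cells: Sequence[GridCell], a_pct_cap: float = 20.0) -> GridCell:
    """The cell maximizing captured positives subject to a flagged-fraction cap.

    Among cells with A_pct <= cap, pick max B_pct (ties: lower A_pct, then
    lower budget).  If no cell meets the cap, the cell with the lowest A_pct
    is returned as the least-bad compromise.
    """
    if not cells:
        raise ValueError("empty grid")
    eligible = [c for c in cells if c.A_pct <= a_pct_cap]
    if not eligible:
        logger.warning("no grid cell under A_pct cap %.1f; relaxing", a_pct_cap)
        return min(cells, key=lambda c: (c.A_pct, -c.B_pct, c.budget))
    return max(eligible, key=lambda c: (c.B_pct, -c.A_pct, -c.budget))


def roc_points(cells: Sequence[GridCell]) -> list[tuple[float, float]]:
    """Deduplicated (FPR, TPR) points sorted by FPR, with (0,0) and (100,100)."""
    if not cells:
        raise ValueError("empty grid")
    pts = {(round(c.fpr, 6), round(c.tpr, 6)) for c in cells}
    pts.add((0.0, 0.0))
    pts.add((100.0, 100.0))
    return sorted(pts)


@dataclass(frozen=True)
class CladeHoldout:
    """Per-read-length sensitivity after excluding one clade from tagging."""

    level: str
    held_out_clade: str
    sensitivity_by_length: dict[int, float] = field(default_factory=dict)


def leave_clade_out(
    markers: Mapping[str, str],
    taxonomy: Mapping[str, Mapping[str, str]],
    model: ClusterModel,
    level: str,
    clade: str,
    params: ClassifierParams,
    tag_params: TaggingParams = TaggingParams(),
    read_lengths: Sequence[int] = (100, 250, 400, 800),
    reads_per_marker: int = 50,
    seed: int = 0,
) -> CladeHoldout:
    """Re-tag the model without one clade's markers; screen that clade's reads.

    The cluster geometry is untouched (the offline clustering never saw the
    marker references); only the tagged set is recomputed from the retained
    references.  Reads are drawn uniformly from the held-out markers at each
    requested length and sensitivity (percent flagged) is reported per length.
    """
    if level not in RANKS:
        raise UnknownCladeError(f"unknown rank {level!r}; expected one of {RANKS}")
    uncovered = [m for m in markers if m not in taxonomy]
    if uncovered:
        raise UnknownCladeError(f"taxonomy does not cover markers, e.g. {uncovered[0]!r}")
    held = {m for m in markers if taxonomy[m][level] == clade}
    if not held:
        raise UnknownCladeError(f"no marker belongs to {level}={clade!r}")
    retained = [m for m in markers if m not in held]

    holdout_model = copy.deepcopy(model)
    retained_vectors = [tetra_vector(markers[m], model.spec) for m in retained]
    tag_marker_clusters(retained_vectors, holdout_model, tag_params)  # may be empty -> 0% sens
    if not holdout_model.tagged_cluster_ids:
        logger.warning("holdout %s=%s left no tagged clusters", level, clade)

    rng = np.random.default_rng(seed)
    sens: dict[int, float] = {}
    for L in read_lengths:
        n_hit = n_tot = 0
        for mid in sorted(held):
            seq = markers[mid]
            if len(seq) < L:
                continue
            starts = rng.integers(0, max(1, len(seq) - L + 1), size=reads_per_marker)
            for s in map(int, starts):
                pred = classify_read(seq[s : s + L], holdout_model, params,
                                     read_id=f"{mid}|L{L}")
                n_tot += 1
                n_hit += pred.is_probable_marker
        if n_tot == 0:
            raise UndefinedMetricError(f"no held-out marker is >= {L} bp")
        sens[int(L)] = round(100.0 * n_hit / n_tot, 1)
    return CladeHoldout(level=level, held_out_clade=clade, sensitivity_by_length=sens)


def holdout_trend(
    markers: Mapping[str, str],
    taxonomy: Mapping[str, Mapping[str, str]],
    model: ClusterModel,
    focus_species: str,
    params: ClassifierParams,
    read_lengths: Sequence[int] = (100, 250, 400, 800),
    reads_per_marker: int = 100,
    seed: int = 0,
) -> dict[str, CladeHoldout]:
    """Nested clade holdouts around one species, compared on identical reads.

    For each rank, the clade containing ``focus_species`` is withheld from
    tagging; sensitivity is always measured on the same reads, drawn from the
    focus species' markers (which lie inside every withheld clade, since
    clades nest).  Two choices make the rank-to-rank comparison exact rather
    than a sampling artefact: the tagging threshold is the absolute pick
    count implied by the *full* reference set (so removing more references
    can only shrink the tagged set), and the cluster budget is resolved once
    against the base model.  Under those conditions sensitivity is provably
    non-increasing from species to phylum, mirroring how screening degrades
    as a query's relatives vanish from the reference database.
    """
    import math as _math

    focus = [m for m in markers if taxonomy.get(m, {}).get("species") == focus_species]
    if not focus:
        raise UnknownCladeError(f"no marker belongs to species={focus_species!r}")

    base_tag = TaggingParams(min_pick_fraction=None,
                             min_pick_count=max(1, _math.ceil(
                                 TaggingParams().min_pick_fraction * len(markers))))
    fixed_params = ClassifierParams(
        cumulative_sequence_count=params.resolve_budget(model),
        overlap_threshold_percent=params.overlap_threshold_percent,
        both_strands=params.both_strands,
    )

    rng = np.random.default_rng(seed)
    reads: dict[int, list[str]] = {}
    for L in read_lengths:
        pool = []
        for mid in sorted(focus):
            seq = markers[mid]
            if len(seq) < L:
                continue
            starts = rng.integers(0, len(seq) - L + 1, size=reads_per_marker)
            pool.extend(seq[s : s + L] for s in map(int, starts))
        if not pool:
            raise UndefinedMetricError(f"no focus marker is >= {L} bp")
        reads[int(L)] = pool

    out: dict[str, CladeHoldout] = {}
    for level in RANKS:
        clade = taxonomy[focus[0]][level]
        held = {m for m in markers if taxonomy[m][level] == clade}
        retained_vectors = [
            tetra_vector(markers[m], model.spec) for m in markers if m not in held
        ]
        holdout_model = copy.deepcopy(model)
        tag_marker_clusters(retained_vectors, holdout_model, base_tag)
        sens = {
            L: round(
                100.0
                * sum(
                    classify_read(seq, holdout_model, fixed_params).is_probable_marker
                    for seq in pool
                )
                / len(pool),
                1,
            )
            for L, pool in reads.items()
        }
        out[level] = CladeHoldout(level=level, held_out_clade=clade,
                                  sensitivity_by_length=sens)
    return out
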