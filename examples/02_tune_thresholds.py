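"""Sweep the two runtime thresholds and pick an operating point.

The classifier has two knobs: the cumulative-sequence-count budget (how many
closest clusters to consider, expressed through their summed fragment
counts) and the overlap percentage threshold.  On a labelled read set,
tune_grid measures per cell the fraction of reads flagged (A%), the fraction
of true marker reads captured (B% = TPR) and the false positive rate; the
preferred cell captures the most positives while flagging few reads.
"""

import tempfile
from pathlib import Path

from irdna import (
    CommunitySpec,
    build_model,
    make_community,
    roc_points,
    select_optimal,
    tune_grid,
    write_community,
)

community = make_community(CommunitySpec(seed=42))
paths = write_community(community, Path(tempfile.mkdtemp()))
model = build_model(paths["genomes"], paths["markers"])

reads = [(r.read_id, r.sequence) for r in community.reads]
cells = tune_grid(
    reads, community.labels(), model,
    budgets=[1, 5, 10, 20, 40, 80, 160, model.total_fragments],
    overlaps=[20, 30, 40, 50, 60, 70, 80],
)
print(f"swept {len(cells)} (budget, overlap) cells on {len(reads)} labelled reads")

best = select_optimal(cells, a_pct_cap=20.0)
print(f"optimal cell: budget={best.budget} overlap={best.overlap:g}% -> "
      f"captures {best.B_pct:.1f}% of marker reads while flagging "
      f"{best.A_pct:.1f}% of the dataset (FPR {best.fpr:.1f}%)")

pts = roc_points(cells)
print(f"ROC curve over the grid ({len(pts)} points), first/last: "
      f"{pts[0]} ... {pts[-1]}")
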