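"""Leave-one-clade-out: how well are truly novel organisms screened?

Marker references of one clade (species up to phylum) are withheld while
tagging probable marker clusters; reads from the withheld clade's marker
then emulate sequences of an organism absent from the reference database.
Sensitivity should fall as the withheld clade widens (less related reference
material remains) and rise with read length (stronger composition signal).
"""

import tempfile
from pathlib import Path

from irdna import (
    ClusteringParams,
    CommunitySpec,
    PROFILES,
    build_model,
    holdout_trend,
    make_community,
    write_community,
)

community = make_community(CommunitySpec(seed=42))
paths = write_community(community, Path(tempfile.mkdtemp()))

# finer clustering than the screening default, so the marker family spans
# several clusters and withholding references can actually untag some
model = build_model(
    paths["genomes"], paths["markers"],
    clus=ClusteringParams(n_clusters=96, random_seed=0),
)

trend = holdout_trend(
    community.markers, community.taxonomy, model,
    focus_species="species_0", params=PROFILES["454-250"],
    reads_per_marker=50, seed=0,
)
print("sensitivity (%) on reads from the withheld clade's marker:")
print(f"{'withheld rank':<14}" + "".join(f"{L:>8}" for L in (100, 250, 400, 800)))
for level, result in trend.items():
    row = "".join(f"{result.sensitivity_by_length[L]:>8}" for L in (100, 250, 400, 800))
    print(f"{level:<14}{row}")
print("each row withholds the clade of that rank containing species_0;")
print("columns are read lengths in bp — sensitivity may only fall downwards.")
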