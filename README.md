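# irdna — alignment-free pre-screening of 16S rDNA fragments in metagenomes

Shotgun metagenomic data sets contain a tiny fraction (typically < 0.2%) of
reads that overlap the 16S rRNA gene, yet those reads carry most of the
taxonomic information. Finding them with a profile-HMM scan is accurate but
costs tens of milliseconds per read — days of compute for data sets of
millions of reads. `irdna` implements a composition-based pre-screen: a fast
filter that flags a small candidate subset ("probable 16S rDNA fragments")
to hand to the HMM step, cutting the search space several-fold with little
loss of sensitivity.

The package targets bioinformaticians building rRNA-detection pipelines, and
anyone studying alignment-free, k-mer-signature classification of marker
genes.

## Method

Every sequence is summarised by its tetranucleotide signature: the vector
**f** ∈ ℝ²⁵⁶ of overlapping 4-mer frequencies (windows containing ambiguous
bases are skipped; counts are normalised by the number of valid windows).
Distances are Manhattan, d(**f**, **g**) = Σᵢ |fᵢ − gᵢ|.

**Offline phase.** Reference genomes are split into non-overlapping 1,000 bp
fragments; fragment signatures are clustered by k-means under the L1 metric
(mean centroid update, seeded initialisation, empty clusters re-seeded from
the farthest point). Each reference 16S rDNA sequence is then assigned to
its nearest centroid; clusters picked by at least a threshold number (or
fraction) of references are tagged as *probable marker clusters*. Because
the 16S gene is compositionally conserved across bacteria and archaea, the
marker family concentrates in few clusters regardless of taxonomic origin.

**Online phase.** For a query read (both orientations; the one closer to its
nearest centroid is used), clusters are walked in ascending distance,
accumulating their fragment counts until a *cumulative sequence count*
budget is reached. The read is flagged when

  overlap% = 100 · |selected ∩ tagged| / |selected| ≥ threshold.

Screening is O(k·256) per read, independent of data set size.

**Evaluation.** For a screened data set of X reads with Y flagged, A
reference-confirmed marker reads and B confirmed reads among the flagged:
detection sensitivity = B·100/A, and fold reduction in search space = X/Y.
A (budget × overlap) tuning grid with TPR/FPR per cell, ROC points, and a
leave-one-clade-out protocol (withhold a taxon's references from tagging,
screen reads from that taxon) round out the machinery.

A synthetic-community generator (`irdna.simulate`) provides labelled
fixtures: per-genome order-2 Markov backgrounds, a conserved marker family
diverged along a six-rank taxonomy, and reads at the 100/250/400/800 bp
length classes of common sequencing technologies.

## Worked example

`python examples/01_build_and_screen.py` builds everything from scratch:

```
community written under /tmp/tmppdrfejsy: 8 genomes, 6400 labelled reads
model: 400 fragments in 16 clusters, tagged marker clusters: [13]
X=6400 reads screened, Y=159 flagged as probable marker
detection sensitivity 81.8% (flagged 157 of 192 true marker reads)
search space handed to HMM confirmation shrank 40.3x
```

Eight 50 kb genomes with one embedded 1.5 kb marker each yield 400
fragments; the 8 reference marker sequences all pick cluster 13, which
becomes the tagged set. Screening all 6,400 labelled reads flags 159
candidates that contain 157 of the 192 true marker reads — the downstream
HMM step now inspects 2.5% of the data. `examples/02_tune_thresholds.py`
sweeps the two runtime thresholds and prints the preferred operating point;
`examples/03_clade_holdout.py` shows sensitivity degrading as ever-wider
clades are withheld from the reference set (novel-phylum screening is the
hard case, especially at 100 bp).

The same pipeline is scriptable from a shell:

```sh
irdna simulate --out data
irdna build --genomes data/genomes.fasta --markers data/markers.fasta \
      --clusters 16 --seed 0 --out model.irdna
irdna screen --model model.irdna --reads data/reads.fasta \
      --profile 454-250 --out-prefix run
irdna evaluate --predictions run.predictions.tsv --labels data/labels.tsv \
      --out report.json
```

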