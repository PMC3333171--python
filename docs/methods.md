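# Methods

## The model

The pre-screen rests on one empirical premise: the 16S rRNA gene is
compositionally conserved across bacteria and archaea, so genome fragments
that harbour it occupy a small, dense region of tetranucleotide-signature
space, while bulk genomic background spreads out by genome-specific
oligonucleotide usage. Clustering fragment signatures therefore localises
the marker family into few clusters, and membership of a query's
compositional neighbourhood in those clusters is a cheap proxy for "probably
contains 16S sequence".

The signature of a sequence is the 256-vector of overlapping 4-mer
frequencies. Coordinates follow base-4 encoding (A=0, C=1, G=2, T=3, most
significant digit first). Windows containing any non-ACGT symbol are skipped
rather than the sequence rejected — real reads contain Ns — and counts are
divided by the number of valid windows so fragments, full-length reference
genes and short reads live on a common simplex. Reverse complements are
distinct coordinates (no canonicalisation); instead the classifier
vectorizes both orientations of a read and keeps the one closer to its
nearest centroid, since shotgun reads are unoriented. RNA-alphabet input (U)
is rejected; converting U→T is the caller's duty.

## Offline phase

* **Fragmentation**: consecutive non-overlapping windows of
  `fragment_length` (default 1,000 bp, 0-based half-open coordinates); the
  trailing partial window is discarded so all fragments are homogeneous.
  Multi-record FASTA genomes are fragmented per record.
* **Clustering**: Lloyd k-means with L1 assignment. The centroid update is
  the coordinate-wise mean (not the L1-optimal median): the mean pairs
  naturally with the "cluster centroid" object the method stores, converges
  quickly, and in practice the assignment metric dominates behaviour.
  Initialisation picks k distinct fragment vectors with a seeded generator
  (an optional farthest-point spreading flag exists, off by default). Empty
  clusters are re-seeded from the point farthest from its centroid, each
  point re-seeding at most one cluster per iteration. Iteration stops at
  `max_iterations` (100) or when no centroid moves ≥ `convergence_tolerance`
  (1e-6, L1). The assignment step never increases the objective
  Σᵢ d(vᵢ, c(aᵢ)); this is asserted in the test suite via the recorded
  per-iteration objective pairs.
* **Cluster count k** is data-dependent and deliberately a required choice:
  800 is a sensible order of magnitude for a full-scale model built from a
  few hundred genomes (~10⁶ fragments), 16 for the 400-fragment desk-scale
  fixture. The contract only needs the tagged set to be a small plural
  subset of all clusters.
* **Tagging**: each reference marker sequence picks its nearest cluster;
  clusters with pick count ≥ `min_pick_count` (reference-scale rule: 10,000
  picks out of 63,325 references) or pick fraction ≥ `min_pick_fraction`
  (default 10000/63325 ≈ 0.158, usable with reference sets of any size) are
  tagged. A model with an empty tagged set is refused — it cannot screen.

## Online phase

Clusters are pre-sorted by distance to the query (ties to the lower id) and
taken until their cumulative fragment count first reaches the
cumulative-sequence-count budget; the crossing cluster is included, so
budget 1 degenerates to nearest-cluster search. The score is the percentage
of *selected* clusters that are tagged; the selected set normalises the
score because the tagged set is a fixed property of the model. The verdict
uses ≥, so grid values like 50% are attainable exactly.

The shipped read-length presets (`sanger-800`, `454-400`, `454-250`,
`454-100`) resolve the budget to the cumulative fragment mass of the
model's tagged clusters (`ClassifierParams.budget_from_tagged`) with a 50%
overlap threshold. This form is scale-free: a marker-like query can exhaust
the tagged set exactly, without the score depending on how the remaining
mass happens to be chopped into clusters. On a full-scale model the
resolved value lands in the tens of thousands of sequences — the range the
tuning grid sweeps — while a fixed absolute budget in that range would
select *every* cluster of a desk-scale model and make the score degenerate.
Absolute budgets and total-fraction budgets remain available, and
`tune_grid`/`select_optimal` exist precisely to re-derive operating points
for a particular model (maximise captured positives B% subject to a cap on
the flagged fraction A%, default cap 20%).

## Evaluation machinery

Sensitivity (B·100/A) and fold reduction (X/Y) are reported to one decimal.
The tuning grid records per (budget, overlap) cell: A% = 100·Y/X,
B% = TPR = 100·B/A, FPR = 100·(Y−B)/(X−A) — the standard false-positive
rate, documented here as this package's reconstruction. ROC points are the
deduplicated (FPR, TPR) pairs plus the (0,0) and (100,100) endpoints.

Two ground-truth modes exist: a read-id → 0/1 label table (synthetic data)
or a file of externally confirmed positive ids (e.g. HMM-scan calls on real
data).

`leave_clade_out` withholds one clade's marker references from tagging —
the cluster geometry is untouched, since the offline clustering never saw
the references — and measures sensitivity on reads drawn from the withheld
clade's markers at each length class. `holdout_trend` compares the nested
holdouts around one focus species *on the same reads*, with the tagging
threshold fixed at the absolute pick count implied by the full reference set
and the budget resolved once against the base model. Under those two
conditions, widening the withheld clade can only shrink the tagged set, so
the species ≥ genus ≥ … ≥ phylum sensitivity ordering is a theorem rather
than a sampling observation; the observed magnitudes (and the 800 bp vs
100 bp gap) remain empirical. The trend experiment is run on a
finer-grained model (k = 96 on the desk-scale fixture) because the protocol
only measures something when the marker family spans more than one cluster.

## Synthetic communities

`make_community` emulates the statistical structure the method assumes, not
any particular organism:

* **Background**: per-genome random Markov chain of order 2 (configurable)
  with Dirichlet(1) transition rows — every genome gets its own stable
  oligonucleotide signature, the analogue of real genome signatures.
* **Marker family**: one master sequence (uniform random, default 1,500 bp —
  a typical 16S length) diverged along a balanced six-rank taxonomy. Each
  of the six tree edges substitutes at rate r with (1−r)⁶ = 1 − d, so the
  root-to-leaf substitution probability equals `marker_divergence`
  (default 0.1) while taxonomic neighbours stay compositionally closer than
  distant clades — this is what gives the holdout protocol its signal. One
  copy per genome is written over the background at a recorded position.
* **Reads**: uniform starts, error-free by default (a uniform substitution
  rate flag exists); lengths 100/250/400/800 bp, 200 reads per genome per
  length over 8 genomes of 50 kb in the default spec. A read is labelled
  positive when ≥ 50% of its bases lie inside a marker region.
* **Taxonomy**: genome-index divisors that are powers of two, so clades
  nest properly; 8 genomes span 2 phyla.

What the generator does **not** emulate: sequencing-error models, clone
coverage profiles, paralogous rRNA operons, horizontal transfer, real
community abundance distributions, or the absolute scale of reference
databases. Passing tests on this fixture therefore demonstrate the
machinery and its scaling behaviour, not field performance on real
metagenomes; full-scale behaviour depends on curated genome and 16S
reference sets that the caller supplies.

## Numerical and degenerate-input choices

* Distance ties (assignment, selection) break toward the lower cluster id;
  sorting is stable throughout, so runs are bit-reproducible from the seeds.
* Signature entries sum to 1 within 1e-9 for any vectorizable sequence;
  unvectorizable reads (no ambiguity-free window) are flagged negative and
  logged, never fatal, during screening.
* The model archive stores the centroid matrix raw (float64) with a SHA-256
  digest and a format-version string; truncation, tampering or version
  drift fails loading loudly.
* An empty FASTA yields an empty screen (X = Y = 0); non-FASTA content is a
  format error.
* Problem sizes in the test suite and acceptance script (8 × 50 kb
  community, k = 16/96, 6,400 reads, 49-cell grid) were chosen so a full
  from-scratch run of everything completes in well under a minute on one
  core while keeping every statistical margin wide.

## Known limitations

* The 4-mer signature of a 100 bp read carries ~97 windows of information;
  nearest-cluster noise dominates and sensitivity at 100 bp is genuinely
  poor on the desk-scale fixture (~30–50%). This mirrors the method's
  intrinsic short-read weakness; a full-scale reference model narrows but
  does not remove it.
* The overlap score's denominator (the selected set) is this package's
  choice among the definitions consistent with the method's description;
  alternatives (e.g. normalising by the tagged set) would make the score
  budget-dependent in a degenerate way.
* k-means under L1 with mean updates has no monotone-convergence guarantee
  across full iterations (only the assignment step is monotone); in
  practice convergence is fast and the tolerance/iteration caps bound the
  work.
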