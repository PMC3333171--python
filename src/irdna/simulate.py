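"""Synthetic communities with the structure the pre-screen relies on.

Each simulated genome is a genome-specific random Markov background (order 2
by default, Dirichlet-distributed transition rows), which gives every genome
its own oligonucleotide signature the way real prokaryotic genomes have one.
Into each genome a copy of a compositionally conserved marker family
(emulating 16S rDNA, default 1,500 bp) is embedded at a recorded position.
Marker copies descend from a single master sequence by substitution along a
balanced six-rank taxonomy (phylum -> ... -> species), so taxonomic distance
between genomes translates into compositional distance between their marker
copies — the structure the leave-one-clade-out protocol probes.

Reads of the four technology length classes (100/250/400/800 bp) are drawn
uniformly from each genome and labelled positive when at least half of the
read lies inside a marker region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SpecError
from .features import ALPHABET

RANKS = ("species", "genus", "family", "order", "class", "phylum")

READ_LENGTH_CLASSES = (100, 250, 400, 800)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic community."""

    n_genomes: int = 8
    genome_length: int = 50_000
    marker_length: int = 1500
    markers_per_genome: int = 1
    marker_divergence: float = 0.1
    background_order: int = 2
    read_lengths: tuple[int, ...] = READ_LENGTH_CLASSES
    reads_per_genome: int = 200
    error_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.marker_divergence <= 1.0:
            raise SpecError("marker_divergence must lie in [0, 1]")
        if self.marker_length >= self.genome_length:
            raise SpecError("marker_length must be smaller than genome_length")
        if self.markers_per_genome * self.marker_length * 2 > self.genome_length:
            raise SpecError("markers do not fit in the genome with spacing")
        if self.n_genomes < 1 or self.reads_per_genome < 0:
            raise SpecError("n_genomes must be >= 1 and reads_per_genome >= 0")


@dataclass(frozen=True)
class LabeledRead:
    read_id: str
    sequence: str
    source_genome: str
    start: int
    end: int  # half-open on the source genome
    is_marker: bool
    length_class: int


@dataclass
class Community:
    """In-memory product of :func:`make_community`."""

    spec: CommunitySpec
    genomes: dict[str, str]
    markers: dict[str, str]  # marker id -> sequence
    marker_regions: dict[str, list[tuple[int, int]]]  # genome id -> [(start, end)]
    reads: list[LabeledRead]
    taxonomy: dict[str, dict[str, str]]  # sequence id -> rank -> clade name

    def labels(self) -> dict[str, bool]:
        return {r.read_id: r.is_marker for r in self.reads}


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def _str_to_codes(seq: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate(ALPHABET)}
    return np.array([lut[c] for c in seq], dtype=np.int64)


def make_master_marker(length: int, seed: int) -> str:
    """Uniform random ACGT string; the ancestral marker sequence."""
    if length < 4:
        raise SpecError("marker length must be >= 4")
    rng = np.random.default_rng(seed)
    return _codes_to_str(rng.integers(0, 4, size=length))


def mutate_marker(
    master: str, divergence: float, seed: int | np.random.Generator
) -> str:
    """Substitute each base independently with probability ``divergence``.

    A substituted base becomes one of the three other bases, uniformly.
    """
    if not 0.0 <= divergence <= 1.0:
        raise SpecError("divergence must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _str_to_codes(master)
    hit = rng.random(len(codes)) < divergence
    shift = rng.integers(1, 4, size=len(codes))
    codes[hit] = (codes[hit] + shift[hit]) % 4
    return _codes_to_str(codes)


def _markov_background(rng: np.random.Generator, length: int, order: int) -> np.ndarray:
    """Genome background from a random Markov chain with Dirichlet(1) rows."""
    if order == 0:
        probs = rng.dirichlet(np.ones(4))
        return rng.choice(4, size=length, p=probs)
    n_ctx = 4**order
    rows = rng.dirichlet(np.ones(4), size=n_ctx)
    # cumulative rows let the whole chain run on pre-drawn uniforms
    cum = rows.cumsum(axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[:order] = rng.integers(0, 4, size=order)
    ctx = 0
    for i in range(order):
        ctx = ctx * 4 + int(out[i])
    ctx_mod = 4 ** (order - 1)
    for i in range(order, length):
        out[i] = np.searchsorted(cum[ctx], u[i], side="right")
        ctx = (ctx % ctx_mod) * 4 + int(out[i])
    return out


def rank_divisors(n_genomes: int) -> dict[str, int]:
    """Genome-index divisors defining a nested balanced taxonomy.

    Finer ranks use smaller divisors; dividing genome index by the divisor
    gives the clade index at that rank.  Divisors are powers of two, so
    clades nest properly (each genus lies inside exactly one family, etc.).
    """
    if n_genomes < 2:
        return {rank: 1 for rank in RANKS}
    halvings = max(1, math.ceil(math.log2(n_genomes)) - 1)
    return {
        rank: 2 ** math.floor(r * halvings / (len(RANKS) - 1))
        for r, rank in enumerate(RANKS)
    }


def taxonomy_for(n_genomes: int) -> dict[str, dict[str, str]]:
    """Balanced six-rank taxonomy over genome ids g0..g{n-1}."""
    div = rank_divisors(n_genomes)
    return {
        f"g{g}": {rank: f"{rank}_{g // div[rank]}" for rank in RANKS}
        for g in range(n_genomes)
    }


def _clade_markers(
    master: str, n_genomes: int, divergence: float, rng: np.random.Generator
) -> list[str]:
    """One marker per genome, mutated from the master along the taxonomy.

    Each of the six edges from the master down through phylum ... species
    substitutes at rate r with (1-r)^6 = 1 - divergence, so the total
    root-to-leaf substitution probability is ``divergence`` while taxonomic
    neighbours stay compositionally closer than distant clades.
    """
    div = rank_divisors(n_genomes)
    per_level = 1.0 - (1.0 - divergence) ** (1.0 / len(RANKS))
    ancestors: dict[tuple[str, int], str] = {}
    for rank in reversed(RANKS):  # phylum (coarsest) first
        coarser_idx = RANKS.index(rank) + 1
        for clade in sorted({g // div[rank] for g in range(n_genomes)}):
            if coarser_idx >= len(RANKS):
                parent = master
            else:
                coarser = RANKS[coarser_idx]
                any_g = clade * div[rank]  # a genome inside this clade
                parent = ancestors[(coarser, any_g // div[coarser])]
            ancestors[(rank, clade)] = mutate_marker(parent, per_level, rng)
    return [ancestors[("species", g // div["species"])] for g in range(n_genomes)]


def make_community(spec: CommunitySpec = CommunitySpec()) -> Community:
    """Generate genomes, markers, labelled reads and taxonomy for one spec.

    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    master = make_master_marker(spec.marker_length, int(rng.integers(2**31)))
    leaf_markers = _clade_markers(master, spec.n_genomes, spec.marker_divergence, rng)
    taxonomy = taxonomy_for(spec.n_genomes)

    genomes: dict[str, str] = {}
    markers: dict[str, str] = {}
    regions: dict[str, list[tuple[int, int]]] = {}
    for g in range(spec.n_genomes):
        gid = f"g{g}"
        codes = _markov_background(rng, spec.genome_length, spec.background_order)
        regions[gid] = []
        # evenly spaced slots keep multiple marker copies from overlapping
        slot = spec.genome_length // spec.markers_per_genome
        for j in range(spec.markers_per_genome):
            marker_seq = (
                leaf_markers[g]
                if j == 0
                else mutate_marker(leaf_markers[g], spec.marker_divergence / len(RANKS), rng)
            )
            lo, hi = j * slot, (j + 1) * slot - spec.marker_length
            pos = int(rng.integers(lo, hi))
            codes[pos : pos + spec.marker_length] = _str_to_codes(marker_seq)
            regions[gid].append((pos, pos + spec.marker_length))
            mid = f"{gid}_16S_{j}"
            markers[mid] = marker_seq
            taxonomy[mid] = taxonomy[gid]
        genomes[gid] = _codes_to_str(codes)

    reads: list[LabeledRead] = []
    for g in range(spec.n_genomes):
        gid = f"g{g}"
        genome = genomes[gid]
        for L in spec.read_lengths:
            starts = rng.integers(0, spec.genome_length - L, size=spec.reads_per_genome)
            for i, start in enumerate(map(int, starts)):
                seq = genome[start : start + L]
                if spec.error_rate > 0:
                    seq = mutate_marker(seq, spec.error_rate, rng)
                overlap = max(
                    (min(start + L, e) - max(start, s) for s, e in regions[gid]),
                    default=0,
                )
                reads.append(
                    LabeledRead(
                        read_id=f"{gid}|L{L}|r{i}",
                        sequence=seq,
                        source_genome=gid,
                        start=start,
                        end=start + L,
                        is_marker=overlap >= L / 2,
                        length_class=L,
                    )
                )
    return Community(spec, genomes, markers, regions, reads, taxonomy)


def write_community(community: Community, out_dir: str | Path) -> dict[str, Path]:
    """Write genomes/markers/reads FASTA plus labels and taxonomy TSV."""
    from .io import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": out / "genomes.fasta",
        "markers": out / "markers.fasta",
        "reads": out / "reads.fasta",
        "labels": out / "labels.tsv",
        "taxonomy": out / "taxonomy.tsv",
    }
    write_fasta(paths["genomes"], community.genomes.items())
    write_fasta(paths["markers"], community.markers.items())
    write_fasta(paths["reads"], ((r.read_id, r.sequence) for r in community.reads))
    with open(paths["labels"], "w") as fh:
        for r in community.reads:
            fh.write(f"{r.read_id}\t{int(r.is_marker)}\n")
    with open(paths["taxonomy"], "w") as fh:
        fh.write("sequence_id\t" + "\t".join(RANKS) + "\n")
        for sid, clades in community.taxonomy.items():
            fh.write(sid + "\t" + "\t".join(clades[rank] for rank in RANKS) + "\n")
    return paths
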