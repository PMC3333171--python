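"""FASTA streaming, model serialization, labels/taxonomy tables, run config.

The model file is a zip archive (extension ``.irdna`` by convention) holding
a JSON header — format version, feature spec, cluster sizes, tagged ids,
provenance, and a SHA-256 digest of the centroid matrix — next to the dense
centroid matrix itself (``centroids.npy``).  Loading verifies both the
format version string (``irdna-model/1``) and the digest, so truncation or
bit rot surfaces as a CorruptModelError rather than silently wrong screening.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
import logging
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import yaml
from Bio import SeqIO

from .classify import ClassifierParams
from .errors import CorruptModelError, FastaFormatError
from .features import FeatureSpec
from .model import (
    MODEL_FORMAT,
    ClusteringParams,
    ClusterModel,
    FragmentationParams,
    TaggingParams,
)

logger = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from a FASTA file.

    Ids are taken up to the first whitespace; wrapped lines, CRLF and
    trailing whitespace are handled; records with empty sequences are
    skipped with a warning.  A file whose first non-blank character is not
    '>' raises FastaFormatError.
    """
    path = Path(path)
    with open(path) as fh:
        lead = ""
        while True:
            ch = fh.read(1)
            if not ch or not ch.isspace():
                lead = ch
                break
        if lead == "":
            return  # empty file: zero records
        if lead != ">":
            raise FastaFormatError(f"{path} does not look like FASTA (no leading '>')")
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).strip()
            if not seq:
                logger.warning("record %s in %s has an empty sequence: skipped", rec.id, path)
                continue
            yield rec.id, seq


def write_fasta_record(fh, rec_id: str, seq: str, width: int = 70) -> None:
    fh.write(f">{rec_id}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i : i + width] + "\n")


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            write_fasta_record(fh, rec_id, seq, width)


def read_labels(path: str | Path) -> dict[str, bool]:
    """Two-column TSV (read_id, 0/1) -> id -> bool."""
    out: dict[str, bool] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{line_no}: expected 'read_id<TAB>0|1', got {line!r}")
            out[parts[0]] = parts[1] == "1"
    return out


def read_positive_ids(path: str | Path) -> set[str]:
    """One externally confirmed positive id per line -> id set."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """TSV (sequence_id, species..phylum) -> id -> rank -> clade."""
    from .simulate import RANKS

    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sequence_id":
            raise ValueError(f"{path}: first column must be 'sequence_id'")
        ranks = header[1:]
        unknown = set(ranks) - set(RANKS)
        if unknown:
            raise ValueError(f"{path}: unknown ranks {sorted(unknown)}")
        for line_no, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{line_no}: column count mismatch")
            out[parts[0]] = dict(zip(ranks, parts[1:]))
    return out


def save_model(model: ClusterModel, path: str | Path) -> None:
    """Write a versioned model archive (JSON header + centroid matrix)."""
    buf = _stdio.BytesIO()
    np.save(buf, model.centroids, allow_pickle=False)
    centroid_bytes = buf.getvalue()
    header = {
        "format": MODEL_FORMAT,
        "spec": {"k": model.spec.k, "alphabet": model.spec.alphabet},
        "sizes": model.sizes.tolist(),
        "tagged_cluster_ids": sorted(model.tagged_cluster_ids),
        "provenance": model.provenance,
        "centroids_sha256": hashlib.sha256(centroid_bytes).hexdigest(),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=2, sort_keys=True))
        zf.writestr("centroids.npy", centroid_bytes)


def load_model(path: str | Path) -> ClusterModel:
    """Load and verify a model archive; raises CorruptModelError on damage."""
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            centroid_bytes = zf.read("centroids.npy")
    except (zipfile.BadZipFile, KeyError, OSError, json.JSONDecodeError) as exc:
        raise CorruptModelError(f"cannot read model {path}: {exc}") from exc
    if header.get("format") != MODEL_FORMAT:
        raise CorruptModelError(
            f"{path}: format {header.get('format')!r} != {MODEL_FORMAT!r}"
        )
    if hashlib.sha256(centroid_bytes).hexdigest() != header.get("centroids_sha256"):
        raise CorruptModelError(f"{path}: centroid digest mismatch")
    centroids = np.load(_stdio.BytesIO(centroid_bytes), allow_pickle=False)
    return ClusterModel(
        spec=FeatureSpec(**header["spec"]),
        centroids=centroids,
        sizes=np.asarray(header["sizes"], dtype=np.int64),
        tagged_cluster_ids=set(header["tagged_cluster_ids"]),
        provenance=header.get("provenance", {}),
    )


@dataclass
class RunConfig:
    """All knobs of a full run; round-trips losslessly through YAML."""

    feature: FeatureSpec = field(default_factory=FeatureSpec)
    fragmentation: FragmentationParams = field(default_factory=FragmentationParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    tagging: TaggingParams = field(default_factory=TaggingParams)
    classifier: ClassifierParams = field(
        default_factory=lambda: ClassifierParams(budget_fraction=0.04)
    )
    profile: str | None = None
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "feature": asdict(self.feature),
                "fragmentation": asdict(self.fragmentation),
                "clustering": asdict(self.clustering),
                "tagging": asdict(self.tagging),
                "classifier": asdict(self.classifier),
                "profile": self.profile,
                "log_level": self.log_level,
            },
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text)
        return cls(
            feature=FeatureSpec(**raw["feature"]),
            fragmentation=FragmentationParams(**raw["fragmentation"]),
            clustering=ClusteringParams(**raw["clustering"]),
            tagging=TaggingParams(**raw["tagging"]),
            classifier=ClassifierParams(**raw["classifier"]),
            profile=raw.get("profile"),
            log_level=raw.get("log_level", "INFO"),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
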