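"""FASTA reading/writing and run logging.

FASTA handling wraps Biopython's ``SeqIO`` behind the package's
:class:`~mrmkit.digestion.ProteinRecord` type: wrapped or unwrapped input is
accepted, sequences are normalized to uppercase, output wraps at 60 columns.
Strict mode (default) rejects empty files, duplicate ids and residues
outside the amino-acid alphabet; lenient mode downgrades residue problems
to warnings.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digestion import ProteinRecord

__all__ = ["read_fasta", "write_fasta", "read_proteome_dir", "RunLog"]


def read_fasta(path, strict: bool = True) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into protein records.

    Header line = id + optional description; sequences are uppercased.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        pr = ProteinRecord(id=rec.id, sequence=str(rec.seq), description=desc)
        try:
            pr.validate(allow_ambiguous=True)
        except ValueError:
            if strict:
                raise
            warnings.warn(f"skipping record {rec.id!r}: illegal residues", stacklevel=2)
            continue
        records.append(pr)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_proteome_dir(directory) -> dict[str, list[ProteinRecord]]:
    """Read every ``*.fasta``/``*.fa`` in a directory; file stem = species."""
    directory = Path(directory)
    collections: dict[str, list[ProteinRecord]] = {}
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".fasta", ".fa")
    )
    if not paths:
        raise ValueError(f"no FASTA files in {directory}")
    for p in paths:
        collections[p.stem.replace("_", " ")] = read_fasta(p)
    return collections


@dataclass
class RunLog:
    """Timestamped stage records with de-duplicated warnings.

    Collects the soft findings of a pipeline run — background hits, isobaric
    collisions, non-monotone LOD ladders — so each appears exactly once in
    the serialized log.
    """

    config_hash: str = ""
    stages: list[dict] = field(default_factory=list)
    _warnings: set[tuple[str, str]] = field(default_factory=set)

    def stage(self, name: str, **info) -> None:
        self.stages.append(
            {
                "stage": name,
                "time": datetime.datetime.now().isoformat(timespec="seconds"),
                **info,
            }
        )

    def warn(self, stage: str, message: str) -> None:
        self._warnings.add((stage, message))

    @property
    def warnings(self) -> list[dict]:
        return [
            {"stage": s, "message": m} for s, m in sorted(self._warnings)
        ]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "config_hash": self.config_hash,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @staticmethod
    def hash_config(config_dict: dict) -> str:
        blob = json.dumps(config_dict, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
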