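"""In-silico tryptic digestion and peptide→source indexing.

Trypsin cleaves C-terminal of lysine (K) and arginine (R); by the common
Keil convention a following proline blocks the cut.  The digest here tracks
1-based inclusive coordinates of every peptide in its source protein, so a
peptide observed by MS can be traced back to species, protein and position.

A :class:`PeptideIndex` inverts whole proteome collections (species →
proteins) into a map from peptide sequence to all of its sources — the data
structure the species-specificity screen operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ProteinRecord",
    "DigestParams",
    "SourceHit",
    "PeptideIndex",
    "cleavage_sites",
    "tryptic_digest",
    "digest_proteomes",
]

#: Letters accepted in sequences but treated as ambiguous (unknown residue,
#: Asx, Glx, selenocysteine).  Peptides containing them are indexed but
#: flagged so downstream marker selection can exclude them.
AMBIGUOUS_RESIDUES = frozenset("XBZU")

_STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ProteinRecord:
    """One protein sequence with its FASTA identity."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()

    def validate(self, allow_ambiguous: bool = True) -> None:
        allowed = _STANDARD_RESIDUES | (AMBIGUOUS_RESIDUES if allow_ambiguous else set())
        for i, letter in enumerate(self.sequence, start=1):
            if letter not in allowed:
                raise ValueError(
                    f"protein {self.id!r}: illegal residue {letter!r} at position {i}"
                )


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion parameters.

    ``proline_rule`` blocks cleavage of K/R immediately followed by P
    (Keil rule).  ``min_len``/``max_len`` filter the product list last, after
    missed-cleavage variants have been generated.
    """

    missed_cleavages: int = 0
    proline_rule: bool = True
    min_len: int | None = None
    max_len: int | None = None

    def __post_init__(self):
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if (
            self.min_len is not None
            and self.max_len is not None
            and self.min_len > self.max_len
        ):
            raise ValueError("min_len must be <= max_len")


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based cut positions: a cut at ``i`` splits ``seq[:i] | seq[i:]``."""
    sites = []
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and not (proline_rule and sequence[i] == "P"):
            sites.append(i)
    return sites


def tryptic_digest(
    sequence: str, params: DigestParams = DigestParams()
) -> list[tuple[str, int, int]]:
    """Digest one sequence into ``(peptide, start, end)`` with 1-based
    inclusive coordinates, in N→C order.

    Fully cleaved products come first (in order), then the variants with
    1..``missed_cleavages`` retained internal sites, each group in N→C order.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("empty sequence")
    cuts = [0] + cleavage_sites(sequence, params.proline_rule) + [len(sequence)]
    out: list[tuple[str, int, int]] = []
    for missed in range(params.missed_cleavages + 1):
        for i in range(len(cuts) - 1 - missed):
            lo, hi = cuts[i], cuts[i + 1 + missed]
            out.append((sequence[lo:hi], lo + 1, hi))
    if params.min_len is not None or params.max_len is not None:
        lo_n = params.min_len or 0
        hi_n = params.max_len if params.max_len is not None else float("inf")
        out = [p for p in out if lo_n <= len(p[0]) <= hi_n]
    return out


@dataclass(frozen=True, order=True)
class SourceHit:
    """Where a peptide occurs: species, protein, 1-based inclusive span."""

    species: str
    protein_id: str
    start: int
    end: int


class PeptideIndex:
    """Map peptide sequence → every place it occurs in a proteome set."""

    def __init__(self) -> None:
        self._hits: dict[str, list[SourceHit]] = {}
        #: peptides containing ambiguous residues (X/B/Z/U)
        self.ambiguous: set[str] = set()

    def add(self, peptide: str, hit: SourceHit) -> None:
        self._hits.setdefault(peptide, []).append(hit)
        if AMBIGUOUS_RESIDUES & set(peptide):
            self.ambiguous.add(peptide)

    def sources(self, peptide: str) -> list[SourceHit]:
        return list(self._hits.get(peptide, []))

    def species_of(self, peptide: str) -> set[str]:
        return {h.species for h in self._hits.get(peptide, [])}

    def peptides(self) -> Iterator[str]:
        return iter(self._hits)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self._hits

    def __len__(self) -> int:
        return len(self._hits)

    def items(self) -> Iterator[tuple[str, list[SourceHit]]]:
        for pep, hits in self._hits.items():
            yield pep, list(hits)

    def finalize(self) -> "PeptideIndex":
        """Sort source lists for deterministic ordering."""
        for hits in self._hits.values():
            hits.sort()
        return self


def digest_proteomes(
    collections: Mapping[str, Sequence[ProteinRecord]],
    params: DigestParams = DigestParams(),
) -> PeptideIndex:
    """Digest every record of every species and build the peptide index.

    Raises on duplicate protein ids within a species; the same id may occur
    in different species (e.g. the same accession screened in two panels).
    """
    index = PeptideIndex()
    for species, records in collections.items():
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise ValueError(
                    f"duplicate protein id {rec.id!r} within species {species!r}"
                )
            seen.add(rec.id)
            for pep, start, end in tryptic_digest(rec.sequence, params):
                index.add(pep, SourceHit(species, rec.id, start, end))
    return index.finalize()
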