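"""Species-specific marker-peptide selection.

The filter cascade mirrors how multiplex food-authentication assays pick
proteotypic peptides:

1. **Specificity screen** — keep peptides whose every indexed source lies in
   a single panel species (exact full-length identity; I and L are distinct
   letters here, matching sequence-database semantics).
2. **Physicochemical filter** — length 6–20, no cysteine, and fully tryptic
   (no internal missed-cleavage site) by default.
3. **Background screen** — peptides also present in background matrices
   (meat species, spices, common ingredients) are *flagged*, not dropped:
   whether a background hit disqualifies a marker is a quantitative call
   left to the analyst.
4. **Isobaric collision check** — I/L isomers are indistinguishable by mass;
   any indexed peptide equal to a candidate under I↔L substitution is
   reported as a warning (such pairs are resolved chromatographically).
5. **Rank and pick** — the final markers per species are the most intense
   candidates, preferring coverage of at least two distinct source proteins
   so that a single-protein processing artefact cannot silence a species.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .digestion import PeptideIndex, SourceHit, cleavage_sites

__all__ = [
    "SelectionCriteria",
    "CandidateMarker",
    "SpecificityResult",
    "specificity_screen",
    "is_fully_tryptic",
    "physicochemical_filter",
    "background_screen",
    "isobaric_collision_check",
    "rank_and_pick",
    "select_markers",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Marker candidacy rules (all overridable)."""

    min_len: int = 6
    max_len: int = 20
    forbidden_residues: frozenset[str] = frozenset("C")
    require_fully_tryptic: bool = True
    missed_cleavages: int = 0
    unique_to_single_species: bool = True


@dataclass
class CandidateMarker:
    """A marker candidate with provenance and screening annotations."""

    peptide: str
    species: str
    sources: list[SourceHit] = field(default_factory=list)
    homologs: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    #: named flags: shared_species, background_hit:<matrix>,
    #: isobaric_collision:<peptide>, ambiguous_residue
    rank_score: float | None = None

    @property
    def source_proteins(self) -> set[str]:
        return {h.protein_id for h in self.sources}


@dataclass
class SpecificityResult:
    """Outcome of the single-species uniqueness screen."""

    unique: dict[str, list[str]]  # species -> peptides unique to it
    shared: dict[str, frozenset[str]]  # peptide -> panel species sharing it


def specificity_screen(index: PeptideIndex, panel: Sequence[str]) -> SpecificityResult:
    """Partition indexed peptides into species-unique and panel-shared.

    A peptide is unique to species *s* iff **all** of its sources are in *s*.
    Peptides found in two or more panel species are excluded from every
    unique set and recorded with the full species set.
    """
    if not panel:
        raise ValueError("empty species panel")
    panel_set = set(panel)
    unique: dict[str, list[str]] = {sp: [] for sp in panel}
    shared: dict[str, frozenset[str]] = {}
    for pep, hits in index.items():
        species = {h.species for h in hits}
        in_panel = species & panel_set
        if not in_panel:
            continue
        if len(species) == 1:
            unique[next(iter(species))].append(pep)
        elif len(in_panel) >= 2:
            shared[pep] = frozenset(in_panel)
        # else: occurs in one panel species plus non-panel species -> not
        # unique, not a panel-shared conflict either; simply dropped here.
    for sp in unique:
        unique[sp].sort()
    return SpecificityResult(unique=unique, shared=shared)


def is_fully_tryptic(peptide: str, proline_rule: bool = True) -> bool:
    """True iff the peptide contains no internal cleavage site, i.e. it is a
    0-missed-cleavage tryptic product of any protein containing it."""
    return not cleavage_sites(peptide, proline_rule=proline_rule)


def physicochemical_filter(
    peptides: Iterable[str],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply length/composition/trypticity rules.

    Returns ``(kept, rejections)`` where ``rejections`` maps each excluded
    peptide to its list of reasons.
    """
    kept: list[str] = []
    rejections: dict[str, list[str]] = {}
    for pep in peptides:
        reasons = []
        if not criteria.min_len <= len(pep) <= criteria.max_len:
            reasons.append(
                f"length {len(pep)} outside {criteria.min_len}-{criteria.max_len}"
            )
        bad = sorted(set(pep) & criteria.forbidden_residues)
        if bad:
            reasons.append(f"forbidden residue(s): {','.join(bad)}")
        if criteria.require_fully_tryptic and not is_fully_tryptic(pep):
            reasons.append("internal missed-cleavage site")
        if reasons:
            rejections[pep] = reasons
        else:
            kept.append(pep)
    return kept, rejections


def background_screen(
    candidates: Sequence[CandidateMarker], background_index: PeptideIndex
) -> list[CandidateMarker]:
    """Flag candidates whose exact sequence occurs in a background matrix.

    Flags are named ``background_hit:<matrix>``; candidates are never
    silently dropped.
    """
    for cand in candidates:
        for matrix in sorted(background_index.species_of(cand.peptide)):
            cand.flags.add(f"background_hit:{matrix}")
    return list(candidates)


def _il_key(peptide: str) -> str:
    return peptide.replace("I", "L")


def isobaric_collision_check(
    candidate: CandidateMarker | str,
    index: PeptideIndex,
    il_equivalence: bool = True,
) -> list[str]:
    """Report indexed peptides isobaric with the candidate.

    With ``il_equivalence`` on, any indexed peptide equal to the candidate
    under I↔L substitution — but not identical — is returned; a
    ``CandidateMarker`` additionally gets a per-collision flag.  These are
    warnings: isomeric pairs are typically separable by retention time.
    """
    pep = candidate.peptide if isinstance(candidate, CandidateMarker) else candidate
    if not il_equivalence:
        return []
    key = _il_key(pep)
    collisions = sorted(
        other for other in index.peptides() if other != pep and _il_key(other) == key
    )
    if isinstance(candidate, CandidateMarker):
        for other in collisions:
            candidate.flags.add(f"isobaric_collision:{other}")
    return collisions


def rank_and_pick(
    candidates: Sequence[CandidateMarker],
    intensities: Mapping[str, float],
    top_n: int = 3,
    require_distinct_proteins: bool = True,
) -> list[CandidateMarker]:
    """Pick the ``top_n`` most intense candidates for one species.

    Ordering is by descending intensity with a deterministic lexicographic
    tie-break on the sequence.  When ``require_distinct_proteins`` is set
    and the plain top-N all stem from one protein while another protein has
    candidates, the weakest pick is swapped for the best candidate from a
    second protein — markers should come from at least two target proteins
    when possible.
    """

    def score(c: CandidateMarker) -> float:
        if c.peptide in intensities:
            return float(intensities[c.peptide])
        if c.rank_score is not None:
            return float(c.rank_score)
        raise KeyError(f"no intensity or fallback rank for candidate {c.peptide!r}")

    ranked = sorted(candidates, key=lambda c: (-score(c), c.peptide))
    for c in ranked:
        c.rank_score = score(c)
    if len(ranked) < top_n:
        warnings.warn(
            f"only {len(ranked)} candidates available (requested {top_n})",
            stacklevel=2,
        )
        return ranked
    picked = ranked[:top_n]
    if require_distinct_proteins and len(ranked) > top_n:
        proteins = set().union(*(c.source_proteins for c in picked)) or set()
        all_proteins = set().union(*(c.source_proteins for c in ranked)) or set()
        if len(proteins) == 1 and len(all_proteins) > 1:
            other = next(
                c for c in ranked[top_n:] if c.source_proteins - proteins
            )
            picked = picked[:-1] + [other]
    return picked


def select_markers(
    index: PeptideIndex,
    panel: Sequence[str],
    criteria: SelectionCriteria = SelectionCriteria(),
    background_index: PeptideIndex | None = None,
    intensities: Mapping[str, float] | None = None,
    top_n: int = 3,
) -> dict[str, list[CandidateMarker]]:
    """Run the full cascade and return final markers per panel species.

    Without an intensity table, candidates are ranked by a neutral fallback
    (all equal, so the lexicographic tie-break decides) — fine for synthetic
    benchmarks, but real assay design should pass measured intensities.
    """
    spec = specificity_screen(index, panel)
    result: dict[str, list[CandidateMarker]] = {}
    for species in panel:
        peps = spec.unique[species]
        if criteria.unique_to_single_species is False:
            peps = sorted(
                set(peps) | {p for p, s in spec.shared.items() if species in s}
            )
        peps = [p for p in peps if p not in index.ambiguous]
        kept, _ = physicochemical_filter(peps, criteria)
        cands = [
            CandidateMarker(peptide=p, species=species, sources=index.sources(p))
            for p in kept
        ]
        for c in cands:
            if criteria.unique_to_single_species is False and c.peptide in spec.shared:
                c.flags.add("shared_species")
            isobaric_collision_check(c, index)
        if background_index is not None:
            background_screen(cands, background_index)
        table = intensities if intensities is not None else {}
        for c in cands:
            if c.peptide not in table:
                c.rank_score = 0.0
        result[species] = rank_and_pick(cands, table, top_n=top_n)
    return result
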