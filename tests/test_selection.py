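"""Marker-selection cascade: specificity, filters, background and isobaric
screens, and intensity-based final picks."""

import itertools

import pytest

from mrmkit.digestion import DigestParams, PeptideIndex, ProteinRecord, SourceHit, digest_proteomes
from mrmkit.selection import (
    CandidateMarker,
    SelectionCriteria,
    background_screen,
    is_fully_tryptic,
    isobaric_collision_check,
    physicochemical_filter,
    rank_and_pick,
    select_markers,
    specificity_screen,
)


def index_of(mapping):
    """Build a PeptideIndex from {peptide: [species, ...]}."""
    idx = PeptideIndex()
    for pep, species_list in mapping.items():
        for i, sp in enumerate(species_list):
            idx.add(pep, SourceHit(sp, f"{sp}_p{i}", 1, len(pep)))
    return idx.finalize()


class TestSpecificityScreen:
    def test_unique_and_shared_partition(self):
        idx = index_of(
            {
                "AAAAAK": ["sp1"],
                "DDDDDR": ["sp2"],
                "NTLEATFNTR": ["sp1", "sp2"],  # shared within panel
            }
        )
        res = specificity_screen(idx, ["sp1", "sp2"])
        assert res.unique == {"sp1": ["AAAAAK"], "sp2": ["DDDDDR"]}
        assert res.shared == {"NTLEATFNTR": frozenset({"sp1", "sp2"})}

    def test_hit_outside_panel_disqualifies(self):
        idx = index_of({"AAAAAK": ["sp1", "other"]})
        res = specificity_screen(idx, ["sp1"])
        assert res.unique["sp1"] == []
        assert res.shared == {}

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            specificity_screen(index_of({}), [])

    def test_matches_set_operations_oracle(self, synthetic_panel):
        _, _, manifest, index, _ = synthetic_panel
        panel = manifest["species"]
        res = specificity_screen(index, panel)
        # oracle: per species, peptides whose full source-species set == {sp}
        by_pep = {pep: index.species_of(pep) for pep in index.peptides()}
        for sp in panel:
            oracle = sorted(p for p, ss in by_pep.items() if ss == {sp})
            assert res.unique[sp] == oracle
        oracle_shared = {
            p for p, ss in by_pep.items() if len(ss & set(panel)) >= 2
        }
        assert set(res.shared) == oracle_shared

    def test_adding_proteome_only_shrinks_unique_sets(self, synthetic_panel):
        proteomes, _, manifest, index, _ = synthetic_panel
        panel = manifest["species"]
        before = specificity_screen(index, panel).unique
        # extend panel with a proteome that duplicates sp1's sequences
        extended = dict(proteomes)
        extended["copycat"] = [
            ProteinRecord(id=r.id + "_c", sequence=r.sequence)
            for r in proteomes[panel[0]]
        ]
        after = specificity_screen(
            digest_proteomes(extended, DigestParams()), panel + ["copycat"]
        ).unique
        for sp in panel:
            assert set(after[sp]) <= set(before[sp])
        assert after[panel[0]] == []  # fully duplicated -> nothing unique


class TestPhysicochemicalFilter:
    @pytest.mark.parametrize(
        "pep,ok",
        [
            ("SQSDNFEYVSFK", True),
            ("ACDK", False),  # cysteine and too short
            ("A" * 20 + "K", False),  # 21 residues
            ("AAAKDDDR", False),  # internal missed cleavage
            ("AAAKPDDDR", True),  # K-P junction is not a cut site
        ],
    )
    def test_rules(self, pep, ok):
        kept, rejections = physicochemical_filter([pep])
        assert (pep in kept) is ok
        if not ok:
            assert rejections[pep]

    def test_idempotent(self, synthetic_panel):
        _, _, manifest, index, _ = synthetic_panel
        peps = sorted(index.peptides())
        once, _ = physicochemical_filter(peps)
        twice, rej = physicochemical_filter(once)
        assert twice == once and rej == {}

    def test_fully_tryptic_predicate(self):
        assert is_fully_tryptic("VVDFVISLNRPGK")  # internal R-P allowed
        assert not is_fully_tryptic("AAKVLR")


class TestBackgroundScreen:
    def test_planted_collisions_flagged_exactly(self, rng):
        bg = PeptideIndex()
        planted = [f"{'ADE'[i % 3] * 7}K{i}"[:-1] + "K" for i in range(5)]
        planted = [f"AAADE{i}FGHK".replace(str(i), "ILMNQ"[i]) for i in range(5)]
        for pep in planted:
            bg.add(pep, SourceHit("fenugreek", "bg1", 1, len(pep)))
        cands = [CandidateMarker(peptide=p, species="sp") for p in planted] + [
            CandidateMarker(peptide="WWWWWWK", species="sp")
        ]
        background_screen(cands, bg)
        for c in cands[:5]:
            assert c.flags == {"background_hit:fenugreek"}
        assert cands[5].flags == set()


class TestIsobaricCollisions:
    def test_known_isomer_pair(self):
        idx = index_of({"VLLEDQEQEPQHR": ["other"]})
        cand = CandidateMarker(peptide="VILEDQEQEPQHR", species="lentil")
        hits = isobaric_collision_check(cand, idx)
        assert hits == ["VLLEDQEQEPQHR"]
        assert "isobaric_collision:VLLEDQEQEPQHR" in cand.flags

    def test_identical_sequence_not_a_collision(self):
        idx = index_of({"VILEDQEQEPQHR": ["lentil"]})
        assert isobaric_collision_check("VILEDQEQEPQHR", idx) == []

    def test_exhaustive_il_variants_reported(self):
        base = "VIAILEK"
        positions = [i for i, a in enumerate(base) if a in "IL"]
        variants = set()
        for combo in itertools.product("IL", repeat=len(positions)):
            s = list(base)
            for p, a in zip(positions, combo):
                s[p] = a
            variants.add("".join(s))
        idx = index_of({v: ["x"] for v in variants})
        hits = isobaric_collision_check(base, idx)
        assert set(hits) == variants - {base}


class TestRankAndPick:
    def cands(self, spec):
        """spec: list of (peptide, protein)."""
        return [
            CandidateMarker(
                peptide=p, species="sp", sources=[SourceHit("sp", prot, 1, len(p))]
            )
            for p, prot in spec
        ]

    def test_orders_by_intensity(self):
        cands = self.cands([("AAA", "p1"), ("BBB", "p2"), ("DDD", "p1")])
        picked = rank_and_pick(cands, {"AAA": 10, "BBB": 5, "DDD": 1}, top_n=3)
        assert [c.peptide for c in picked] == ["AAA", "BBB", "DDD"]

    def test_second_protein_guaranteed_when_possible(self):
        spec = [(f"PEP{i}A", "p1") for i in range(5)] + [("OTHER", "p2")]
        intens = {p: 100 - i for i, (p, _) in enumerate(spec)}
        picked = rank_and_pick(self.cands(spec), intens, top_n=3)
        assert {"p1", "p2"} == set().union(*(c.source_proteins for c in picked))

    def test_fewer_candidates_than_requested_warns(self):
        with pytest.warns(UserWarning):
            picked = rank_and_pick(self.cands([("AAA", "p1")]), {"AAA": 1}, top_n=3)
        assert len(picked) == 1

    def test_agrees_with_sort_oracle(self, rng):
        for _ in range(20):
            peps = [f"P{i}K" for i in range(10)]
            intens = {p: float(rng.integers(0, 5)) for p in peps}  # many ties
            cands = self.cands([(p, f"pr{i}") for i, p in enumerate(peps)])
            picked = rank_and_pick(cands, intens, top_n=4,
                                   require_distinct_proteins=False)
            oracle = sorted(peps, key=lambda p: (-intens[p], p))[:4]
            assert [c.peptide for c in picked] == oracle


class TestEndToEnd:
    def test_planted_markers_recovered_and_flagged(self, synthetic_panel):
        _, _, manifest, index, bg_index = synthetic_panel
        picked = select_markers(
            index,
            panel=manifest["species"],
            background_index=bg_index,
            intensities=manifest["intensities"],
            top_n=3,
        )
        for sp in manifest["species"]:
            assert sorted(c.peptide for c in picked[sp]) == sorted(
                manifest["unique"][sp]
            )
        # planted shared peptides never appear among the picks
        shared = {d["peptide"] for d in manifest["shared"]}
        all_picked = {c.peptide for cands in picked.values() for c in cands}
        assert not shared & all_picked

    def test_panel_peptides_pass_criteria(self, panel):
        peps = [e.peptide for e in panel.entries]
        kept, rejections = physicochemical_filter(peps)
        assert rejections == {}
        assert sorted(kept) == sorted(peps)
        assert all(8 <= len(p) <= 18 for p in peps)
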