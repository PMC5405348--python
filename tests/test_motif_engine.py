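"""Motif parsing, strict/fuzzy scanning and triad location."""

import pytest

from nitriminer.motif_engine import (MotifParseError, best_match, load_motifs,
                                     locate_triad, match_fuzzy, match_strict,
                                     parse_motif)
from nitriminer.seqio import ProteinSequence

from conftest import random_protein
from oracles import fuzzy_best_bruteforce

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def element_sets(pattern):
    """Pattern elements as residue-sets for the brute-force oracle."""
    return [set() if e.kind == "wildcard" else set(e.residues)
            for e in pattern.elements]


class TestParse:
    def test_aliphatic_motif_1_structure(self):
        p = parse_motif("[FL]-[ILV]-[AV]-F-P-E-[VT]-[FW]-[IL]-P-[GY]-Y-P-[WY]",
                        "ali-1", "aliphatic", {"E": 6})
        assert len(p) == 14
        e6 = p.elements[5]
        assert e6.kind == "fixed" and e6.residues == "E" and e6.catalytic == "E"

    def test_aromatic_motif_2_wildcard(self):
        p = parse_motif("[AGN]-[KR]-H-R-K-L-[MK]-P-T-[AGN]-X-E-R",
                        "aro-2", "aromatic", {"K": 5})
        assert len(p) == 13
        assert p.elements[10].kind == "wildcard"

    def test_emphasis_markers_stripped(self):
        p = parse_motif("**C**-W-E", "x", "aliphatic")
        assert p.elements[0].residues == "C"

    @pytest.mark.parametrize("bad", ["A-[B]-C", "A-[Q]-C", "A-ZZ-C", "A--[]"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(MotifParseError):
            parse_motif(bad, "x", "aliphatic")

    def test_packaged_set_roundtrips(self, patterns):
        assert len(patterns) == 8
        for p in patterns:
            again = parse_motif(p.to_string(), p.id, p.class_label,
                                {r: i + 1 for r, i in p.catalytic_positions.items()})
            assert again == p

    def test_catalytic_tags_on_first_three_of_each_class(self, patterns):
        for cls in ("aliphatic", "aromatic"):
            tags = [list(p.catalytic_positions) for p in patterns
                    if p.class_label == cls]
            assert tags == [["E"], ["K"], ["C"], []]


class TestStrict:
    def test_full_match_reported_at_position(self, patterns_by_id):
        prot = ProteinSequence("p", "FIAFPEVFIPGYPW")
        m = match_strict(patterns_by_id["ali-1"], prot)
        assert len(m) == 1 and m[0].start == 0 and m[0].strict

    def test_observed_span_is_strict_match(self, patterns_by_id):
        prot = ProteinSequence("p", "GGGRRKLKPTHVERGGG")
        m = match_strict(patterns_by_id["ali-2"], prot)
        assert len(m) == 1 and m[0].start == 3

    def test_single_violation_rejected(self, patterns_by_id):
        prot = ProteinSequence("p", "RRKAKPTHVER")  # A not in [LI]
        assert match_strict(patterns_by_id["ali-2"], prot) == []

    def test_shift_equivariance(self, patterns_by_id, rng):
        prot = ProteinSequence("p", "FIAFPEVFIPGYPW")
        shifted = ProteinSequence("p", random_protein(rng, 7) + prot.seq)
        m0 = match_strict(patterns_by_id["ali-1"], prot)
        m1 = match_strict(patterns_by_id["ali-1"], shifted)
        assert [m.start + 7 for m in m0] == [m.start for m in m1][-len(m0):]


class TestFuzzy:
    def test_partial_block_with_zero_mismatches(self, patterns_by_id):
        prot = ProteinSequence("p", "GGGHRKLKPTGLERGGG")
        hits = match_fuzzy(patterns_by_id["aro-2"], prot)
        best = min(hits, key=lambda m: (m.mismatch_fraction, -m.elements_covered))
        # covers elements 3-13 (11 of 13), no mismatches
        assert best.elements_covered == 11
        assert best.mismatches == 0
        assert best.element_start == 2
        assert best.matched_span == "HRKLKPTGLER"

    def test_strict_subset_of_fuzzy(self, patterns, rng):
        for pat in patterns:
            seq = random_protein(rng, 60) + "".join(
                (e.residues or "A")[0] for e in pat.elements) + random_protein(rng, 60)
            prot = ProteinSequence("p", seq)
            strict = match_strict(pat, prot)
            fuzzy = match_fuzzy(pat, prot)
            fuzzy_keys = {(m.start, m.elements_covered) for m in fuzzy}
            assert strict, pat.id
            for m in strict:
                assert (m.start, m.elements_covered) in fuzzy_keys

    def test_matches_exhaustive_oracle_on_random_proteins(self, patterns, rng):
        """The best reported hit equals the brute-force window/block optimum."""
        for _ in range(6):
            prot = ProteinSequence("p", random_protein(rng, 120))
            for pat in patterns:
                oracle = fuzzy_best_bruteforce(element_sets(pat), prot.seq, 8)
                hits = match_fuzzy(pat, prot, min_elements=8,
                                   max_mismatch_fraction=1.0)
                best = min(hits, key=lambda m: (m.mismatch_fraction,
                                                -m.elements_covered, m.start,
                                                m.element_start))
                assert (best.mismatch_fraction, best.elements_covered,
                        best.start, best.element_start) == (
                        oracle[0], oracle[1], oracle[2], oracle[3])

    def test_threshold_respected(self, patterns_by_id, rng):
        prot = ProteinSequence("p", random_protein(rng, 150))
        for m in match_fuzzy(patterns_by_id["ali-1"], prot,
                             max_mismatch_fraction=0.3):
            assert m.mismatch_fraction <= 0.3
            assert m.elements_covered >= 8


class TestTriad:
    def test_complete_triad_on_synthetic_aliphatic(self, patterns):
        from nitriminer.synthetic_data import generate_nitrilase_protein
        prot, placements = generate_nitrilase_protein("aliphatic", 300, seed=5)
        ali = [p for p in patterns if p.class_label == "aliphatic"]
        rep = locate_triad(prot, ali)
        assert rep["complete"]
        # tagged positions sit inside their motif placements
        assert placements["ali-1"][0] <= rep["E"] < placements["ali-1"][1]
        assert placements["ali-2"][0] <= rep["K"] < placements["ali-2"][1]
        assert placements["ali-3"][0] <= rep["C"] < placements["ali-3"][1]
        assert prot.seq[rep["E"]] == "E"

    def test_missing_cysteine_motif_incomplete(self, patterns_by_id, rng):
        # strict E- and K-motifs only; no C-motif anywhere
        seq = ("M" + random_protein(rng, 30) + "FIAFPEVFIPGYPW"
               + random_protein(rng, 20) + "RRKLKPTHVER"
               + "".join(c for c in random_protein(rng, 160) if c != "C"))
        prot = ProteinSequence("p", seq)
        ali = [patterns_by_id[f"ali-{i}"] for i in (1, 2, 3, 4)]
        rep = locate_triad(prot, ali)
        assert rep["E"] is not None and rep["K"] is not None
        assert rep["C"] is None and not rep["complete"]

    def test_wrong_residue_at_tagged_element_rejected(self, patterns_by_id):
        # fuzzy ali-2 hit with Q replacing the catalytic K
        prot = ProteinSequence("p", "GGGGRRQLKPTHVERGGGG")
        rep = locate_triad(prot, [patterns_by_id["ali-2"]])
        assert rep["K"] is None


class TestBestMatch:
    def test_prefers_strict_over_fuzzy(self, patterns_by_id):
        prot = ProteinSequence("p", "RRKLKPTHVAR" + "G" * 5 + "RRKLKPTHVER")
        m = best_match(patterns_by_id["ali-2"], prot)
        assert m.strict and m.start == 16
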