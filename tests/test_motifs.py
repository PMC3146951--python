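import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crestscan.io_formats import ProteinRecord, TMSegment, Topology
from crestscan.motifs import (HXXXH, SXXXH, MotifHit, MotifPattern,
                              PatternElement, ScanConfig, find_pattern,
                              naive_scan, parse_pattern, scan_tm_windows,
                              window_for)

from _oracles import (HXXXH_SPEC, SXXXH_SPEC, brute_matches,
                      brute_windowed_hits, naive_spec, random_protein,
                      random_segments)


class TestParsePattern:
    @pytest.mark.parametrize("text", ["SxxxH", "S-x(3)-H", "S-x-x-x-H"])
    def test_equivalent_notations(self, text):
        pat = parse_pattern(text, name="SxxxH")
        assert pat.min_length == pat.max_length == 5
        assert [e.residue for e in pat.elements if e.residue] == ["S", "H"]

    def test_bounded_wildcard(self):
        pat = parse_pattern("S-x(3)-H-x(100,10000)-H-x(3)-H")
        assert pat.min_length == 110
        assert pat.max_length == 10010

    @pytest.mark.parametrize("text", ["S-x(5,2)-H", "x(3)", "S?H", ""])
    def test_invalid_patterns_rejected(self, text):
        with pytest.raises(ValueError):
            parse_pattern(text)


class TestFindPattern:
    @pytest.mark.parametrize("seq,expected", [
        ("SAAAH", [(1, 5)]),
        ("SAAAHSAAAH", [(1, 5), (6, 10)]),
        ("SASAHAH", [(1, 5), (3, 7)]),  # overlapping matches both reported
        ("AAAAA", []),
    ])
    def test_sxxxh_enumeration(self, seq, expected):
        assert find_pattern(seq, SXXXH) == expected

    def test_wildcards_match_ambiguity_but_literals_do_not(self):
        assert find_pattern("SXXXH", SXXXH) == [(1, 5)]  # X under wildcards
        assert find_pattern("XAAAH", SXXXH) == []        # X is not S
        assert find_pattern("SAAAB", SXXXH) == []        # B is not H

    def test_composite_spacer_enumeration(self):
        seq = "SAAAH" + "A" * 100 + "HAAAH"
        pat = parse_pattern("S-x(3)-H-x(100,10000)-H-x(3)-H")
        expected = brute_matches(seq, naive_spec(100, 10000))
        assert expected == [(1, 110)]
        assert find_pattern(seq, pat) == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="SHAXLG", min_size=0, max_size=60),
           st.sampled_from([
               ("S-x(3)-H", SXXXH_SPEC),
               ("H-x(3)-H", HXXXH_SPEC),
               ("S-x(0,4)-H", (("lit", "S"), ("x", 0, 4), ("lit", "H"))),
               ("S-x(2)-G-x(1,3)-H",
                (("lit", "S"), ("x", 2, 2), ("lit", "G"), ("x", 1, 3),
                 ("lit", "H"))),
           ]))
    def test_agrees_with_bruteforce_matcher(self, seq, pattern_and_spec):
        text, spec = pattern_and_spec
        assert find_pattern(seq, parse_pattern(text)) == brute_matches(seq,
                                                                       spec)


class TestWindows:
    def test_c_half_window_is_second_half_plus_flank(self, scan_config):
        tm = TMSegment(index=2, start=10, end=30)
        assert window_for(tm, "c_half", scan_config, 1000) == (20, 35)

    def test_n_half_window_is_first_half_plus_flank(self, scan_config):
        tm = TMSegment(index=2, start=10, end=30)
        assert window_for(tm, "n_half", scan_config, 1000) == (5, 20)

    def test_windows_clamped_to_sequence(self, scan_config):
        tm = TMSegment(index=1, start=3, end=21)
        assert window_for(tm, "n_half", scan_config, 1000) == (1, 12)
        assert window_for(tm, "c_half", scan_config, 23) == (12, 23)


def _record_with_tm(loop_a=30, tm_len=20, loop_b=30, plant=None):
    """One-TM protein made of A-loops and an L-helix, with optional motif."""
    chars = list("G" * loop_a + "L" * tm_len + "G" * loop_b)
    if plant is not None:
        start, motif = plant
        chars[start - 1:start - 1 + len(motif)] = motif
    seq = "".join(chars)
    tm = TMSegment(index=1, start=loop_a + 1, end=loop_a + tm_len)
    rec = ProteinRecord(id="t", sequence=seq)
    return rec, Topology(protein_id="t", segments=(tm,))


class TestScanTmWindows:
    def test_motif_at_tm_end_hits_c_half(self, scan_config):
        rec, topo = _record_with_tm(plant=(46, "SLLLH"))  # last 5 of the TM
        hits = scan_tm_windows(rec, topo, scan_config)
        assert hits == [MotifHit("SxxxH", 46, 50, 1, "c_half")]

    def test_motif_in_n_half_is_not_a_c_half_hit(self, scan_config):
        rec, topo = _record_with_tm(plant=(31, "SLLLH"))  # first 5 of the TM
        assert scan_tm_windows(rec, topo, scan_config) == []

    def test_empty_topology_yields_no_hits(self, scan_config):
        rec = ProteinRecord(id="t", sequence="SAAAH" * 20)
        assert scan_tm_windows(rec, Topology(protein_id="t"), scan_config) == []

    def test_id_mismatch_rejected(self, scan_config):
        rec = ProteinRecord(id="a", sequence="A" * 50)
        with pytest.raises(ValueError, match="belongs to"):
            scan_tm_windows(rec, Topology(protein_id="b"), scan_config)

    def test_matches_bruteforce_containment_oracle(self, scan_config, rng):
        for _ in range(40):
            seq = random_protein(rng, max_len=600)
            segments = random_segments(rng, len(seq))
            rec = ProteinRecord(id="r", sequence=seq)
            topo = Topology(protein_id="r", segments=segments)
            got = [(h.pattern, h.start, h.end, h.tm_index, h.window_kind)
                   for h in scan_tm_windows(rec, topo, scan_config)]
            assert sorted(got) == brute_windowed_hits(seq, segments)

    def test_shift_equivariance(self, scan_config, rng):
        seq = random_protein(rng, max_len=400)
        segments = random_segments(rng, len(seq))
        # keep windows away from the termini so clamping plays no role
        segments = tuple(s for s in segments
                         if s.start > 10 and s.end + 10 < len(seq))
        segments = tuple(TMSegment(k + 1, s.start, s.end)
                         for k, s in enumerate(segments))
        rec = ProteinRecord(id="r", sequence=seq)
        base = scan_tm_windows(rec, Topology("r", segments), scan_config)

        k = 17
        shifted_seq = "G" * k + seq
        shifted_segments = tuple(
            TMSegment(s.index, s.start + k, s.end + k) for s in segments)
        rec2 = ProteinRecord(id="r", sequence=shifted_seq)
        shifted = scan_tm_windows(rec2, Topology("r", shifted_segments),
                                  scan_config)
        assert [(h.pattern, h.start + k, h.end + k, h.tm_index, h.window_kind)
                for h in base] == \
               [(h.pattern, h.start, h.end, h.tm_index, h.window_kind)
                for h in shifted]


class TestNaiveScan:
    @pytest.mark.parametrize("spacer,matches", [
        (99, False), (100, True), (150, True),
    ])
    def test_minimum_spacer_boundary(self, spacer, matches, scan_config):
        seq = "SAAAH" + "A" * spacer + "HAAAH"
        rec = ProteinRecord(id="n", sequence=seq)
        hits = naive_scan(rec, scan_config)
        assert bool(hits) == matches
        if matches:
            assert (hits[0].start, hits[0].end) == (1, len(seq))

    def test_spacer_never_outside_bounds(self, rng):
        cfg = ScanConfig(naive_spacer_min=5, naive_spacer_max=20)
        for _ in range(20):
            seq = random_protein(rng, max_len=300, alphabet="SHAG")
            hits = naive_scan(ProteinRecord(id="n", sequence=seq), cfg)
            s_matches = brute_matches(seq, SXXXH_SPEC)
            h_matches = brute_matches(seq, HXXXH_SPEC)
            expected = set()
            for a, b in s_matches:
                for c, d in h_matches:
                    if 5 <= c - b - 1 <= 20:
                        expected.add((a, d))
            assert {(h.start, h.end) for h in hits} == expected
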