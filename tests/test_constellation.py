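import numpy as np
import pytest

from crestscan import (GeneratorSpec, ScanConfig, generate_dataset,
                       generate_decoy, generate_positive)
from crestscan.constellation import (ConstellationCall, call_constellations,
                                     classify_protein, evaluate)
from crestscan.io_formats import ProteinRecord, TMSegment, Topology
from crestscan.motifs import MotifHit


def _topology(n_tm=7, tm_len=20, loop=30, pid="p"):
    segments = []
    pos = loop + 1
    for k in range(1, n_tm + 1):
        segments.append(TMSegment(index=k, start=pos, end=pos + tm_len - 1))
        pos += tm_len + loop
    return Topology(protein_id=pid, segments=tuple(segments))


def _s_hit(tm, start=None):
    start = start or tm * 100
    return MotifHit("SxxxH", start, start + 4, tm, "c_half")


def _h_hit(tm, start=None):
    start = start or tm * 100
    return MotifHit("HxxxH", start, start + 4, tm, "n_half")


class TestCallConstellations:
    def test_canonical_tm2_tm7_pair_passes(self, scan_config):
        calls = call_constellations([_s_hit(2), _h_hit(7)], _topology(),
                                    scan_config)
        assert len(calls) == 1
        assert calls[0].tm_separation == 5
        assert calls[0].passed

    def test_two_tm_separation_fails(self, scan_config):
        calls = call_constellations([_s_hit(2), _h_hit(4)], _topology(),
                                    scan_config)
        assert calls[0].tm_separation == 2
        assert not calls[0].passed

    def test_reversed_order_fails(self, scan_config):
        calls = call_constellations([_s_hit(7), _h_hit(2)], _topology(),
                                    scan_config)
        assert calls[0].tm_separation == -5
        assert not calls[0].passed

    def test_hit_beyond_topology_rejected(self, scan_config):
        with pytest.raises(ValueError, match="references TM"):
            call_constellations([_s_hit(9)], _topology(), scan_config)

    def test_all_pairs_enumerated(self, scan_config):
        hits = [_s_hit(2), _s_hit(3), _h_hit(6), _h_hit(7)]
        calls = call_constellations(hits, _topology(), scan_config)
        assert len(calls) == 4
        assert sum(c.passed for c in calls) == 4

    def test_extended_mode_needs_the_aspartate(self):
        cfg = ScanConfig(mode="extended")
        hits = [_s_hit(2), _h_hit(7)]
        calls = call_constellations(hits, _topology(), cfg)
        assert not calls[0].passed  # no D hit in TM3's n-half window
        d = MotifHit("D", 290, 290, 3, "n_half")
        calls = call_constellations(hits + [d], _topology(), cfg)
        assert calls[0].passed and calls[0].d_motif == d

    def test_pair_order_invariant(self, scan_config, rng):
        hits = [_s_hit(2), _s_hit(5), _h_hit(7), _h_hit(3)]
        expected = {(c.sxxxh.tm_index, c.hxxxh.tm_index, c.passed)
                    for c in call_constellations(hits, _topology(),
                                                 scan_config)}
        for _ in range(5):
            shuffled = list(hits)
            rng.shuffle(shuffled)
            got = {(c.sxxxh.tm_index, c.hxxxh.tm_index, c.passed)
                   for c in call_constellations(shuffled, _topology(),
                                                scan_config)}
            assert got == expected

    def test_inconsistent_separation_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ConstellationCall(protein_id="p", sxxxh=_s_hit(2),
                              hxxxh=_h_hit(7), tm_separation=4, passed=True)


class TestClassifyProtein:
    def test_generated_positive_is_positive(self, spec, scan_config):
        rec, truth = generate_positive(spec, np.random.default_rng(3),
                                       protein_id="p")
        label, calls = classify_protein(rec, truth.topology, scan_config)
        assert label == "positive"
        assert any(c.passed for c in calls)

    def test_passed_call_spans_are_ordered_and_disjoint(self, spec,
                                                        scan_config):
        rng = np.random.default_rng(4)
        for k in range(20):
            rec, truth = generate_positive(spec, rng, protein_id=f"p{k}")
            _, calls = classify_protein(rec, truth.topology, scan_config)
            for c in calls:
                if c.passed:
                    assert c.sxxxh.end < c.hxxxh.start

    def test_no_motif_decoy_is_negative(self, spec, scan_config):
        rec, truth = generate_decoy("decoy_no_motif", spec,
                                    np.random.default_rng(5), protein_id="d")
        assert classify_protein(rec, truth.topology, scan_config)[0] == \
            "negative"

    def test_soluble_protein_is_negative(self, spec, scan_config):
        rec, truth = generate_decoy("soluble", spec,
                                    np.random.default_rng(6), protein_id="s")
        label, calls = classify_protein(rec, truth.topology, scan_config)
        assert label == "negative" and calls == []

    def test_relaxing_separation_grows_the_positive_set(self, spec):
        dataset = generate_dataset(8, spec=spec, seed=91)
        previous: set[str] | None = None
        for min_sep in (5, 4, 3, 2, 1, 0):
            cfg = ScanConfig(min_tm_separation=min_sep)
            positives = {
                rec.id for rec in dataset.records
                if classify_protein(rec, dataset.truths[rec.id].topology,
                                    cfg)[0] == "positive"
            }
            if previous is not None:
                assert previous <= positives
            previous = positives


class TestEvaluate:
    def test_perfect_toy_set(self):
        truth = {"a": "positive", "b": "positive", "c": "decoy_order",
                 "d": "soluble"}
        pred = {"a": "positive", "b": "positive", "c": "negative",
                "d": "negative"}
        report = evaluate(truth, pred)
        assert report.sensitivity == 1.0
        assert report.specificity_pooled == 1.0
        assert report.confusion == {"TP": 2, "FN": 0, "TN": 2, "FP": 0}

    def test_half_sensitivity(self):
        truth = {"a": "positive", "b": "positive"}
        pred = {"a": "positive", "b": "negative"}
        assert evaluate(truth, pred).sensitivity == 0.5

    def test_per_class_specificity(self):
        truth = {"a": "decoy_order", "b": "decoy_order", "c": "soluble"}
        pred = {"a": "positive", "b": "negative", "c": "negative"}
        report = evaluate(truth, pred)
        assert report.specificity_by_class == {"decoy_order": 0.5,
                                               "soluble": 1.0}
        assert report.sensitivity is None

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate({}, {})

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate({"a": "positive"}, {"b": "positive"})
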