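"""Combine windowed motif hits into constellation calls and evaluate them.

A protein is a CREST candidate when an SxxxH hit (C-terminal half-window of
one TM) and an HxxxH hit (N-terminal half-window of another TM) co-occur
with SxxxH N-terminal to HxxxH and the two TMs at least
``min_tm_separation`` indices apart. In the canonical architecture the
motifs sit in TM2 and TM7 — five TMs apart — and the separation requirement
is relaxed to 3 to tolerate TMs missed by the topology predictor. The
optional ``extended`` mode additionally demands the conserved aspartate at
the start of the TM directly following the SxxxH-bearing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import ProteinRecord, Topology
from .motifs import MotifHit, ScanConfig, scan_tm_windows

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ConstellationCall:
    """One candidate (SxxxH-TM, HxxxH-TM) pairing and its constraint record.

    ``tm_separation`` is the signed TM-index difference
    ``hxxxh.tm_index - sxxxh.tm_index`` (negative when the motifs are in the
    wrong order). ``passed`` records whether both the ordering and the
    separation constraints hold (plus the aspartate requirement in extended
    mode).
    """

    protein_id: str
    sxxxh: MotifHit
    hxxxh: MotifHit
    tm_separation: int
    passed: bool
    mode: str = "core"
    d_motif: MotifHit | None = None

    def __post_init__(self):
        if self.tm_separation != self.hxxxh.tm_index - self.sxxxh.tm_index:
            raise ValueError("tm_separation inconsistent with hit TM indices")


def call_constellations(hits: Sequence[MotifHit], topology: Topology,
                        config: ScanConfig | None = None
                        ) -> list[ConstellationCall]:
    """Enumerate every (c_half SxxxH, n_half HxxxH) pair as a call.

    All pairs are reported, passing or not, so downstream filtering stays
    auditable. Hits referencing TM indices absent from the topology raise
    ``ValueError``.
    """
    config = config or ScanConfig()
    n_tm = topology.n_segments
    for h in hits:
        if h.tm_index < 1 or h.tm_index > n_tm:
            raise ValueError(
                f"{topology.protein_id}: hit {h.pattern}@{h.start} references "
                f"TM {h.tm_index}, topology has {n_tm}"
            )

    s_hits = [h for h in hits
              if h.pattern == "SxxxH" and h.window_kind == "c_half"]
    h_hits = [h for h in hits
              if h.pattern == "HxxxH" and h.window_kind == "n_half"]
    d_by_tm: dict[int, list[MotifHit]] = {}
    for h in hits:
        if h.pattern == "D" and h.window_kind == "n_half":
            d_by_tm.setdefault(h.tm_index, []).append(h)

    calls: list[ConstellationCall] = []
    for sh in sorted(s_hits, key=lambda h: (h.tm_index, h.start)):
        for hh in sorted(h_hits, key=lambda h: (h.tm_index, h.start)):
            sep = hh.tm_index - sh.tm_index
            passed = (sh.tm_index < hh.tm_index
                      and sep >= config.min_tm_separation)
            d_hit: MotifHit | None = None
            if config.mode == "extended":
                d_candidates = d_by_tm.get(sh.tm_index + 1, [])
                d_hit = d_candidates[0] if d_candidates else None
                passed = passed and d_hit is not None
            calls.append(ConstellationCall(
                protein_id=topology.protein_id,
                sxxxh=sh, hxxxh=hh, tm_separation=sep, passed=passed,
                mode=config.mode, d_motif=d_hit,
            ))
    return calls


def classify_protein(record: ProteinRecord, topology: Topology,
                     config: ScanConfig | None = None
                     ) -> tuple[str, list[ConstellationCall]]:
    """Scan, pair, and label one protein.

    Returns ``("positive", calls)`` iff at least one call passes; a protein
    with an empty topology has no windows and is trivially negative.
    """
    config = config or ScanConfig()
    hits = scan_tm_windows(record, topology, config)
    calls = call_constellations(hits, topology, config)
    label = POSITIVE if any(c.passed for c in calls) else NEGATIVE
    return label, calls


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class counts and headline rates against generator ground truth."""

    n_total: int
    per_class: Mapping[str, Mapping[str, int]]  # label -> {n, called_positive}
    sensitivity: float | None
    specificity_by_class: Mapping[str, float]
    specificity_pooled: float | None
    confusion: Mapping[str, int]  # TP / FN / TN / FP

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "sensitivity": self.sensitivity,
            "specificity_by_class": dict(self.specificity_by_class),
            "specificity_pooled": self.specificity_pooled,
            "confusion": dict(self.confusion),
        }


def evaluate(truth_labels: Mapping[str, str],
             predicted_labels: Mapping[str, str]) -> EvaluationReport:
    """Confusion counts, sensitivity and per-class specificity.

    ``truth_labels`` maps protein id to its generator class (``positive`` or
    a decoy class); ``predicted_labels`` maps id to ``positive``/``negative``.
    The two id sets must coincide and be non-empty.
    """
    if not truth_labels:
        raise ValueError("empty dataset: nothing to evaluate")
    if set(truth_labels) != set(predicted_labels):
        missing = set(truth_labels) ^ set(predicted_labels)
        raise ValueError(f"truth/prediction id mismatch, e.g. "
                         f"{sorted(missing)[:3]}")

    per_class: dict[str, dict[str, int]] = {}
    for pid, cls in truth_labels.items():
        d = per_class.setdefault(cls, {"n": 0, "called_positive": 0})
        d["n"] += 1
        if predicted_labels[pid] == POSITIVE:
            d["called_positive"] += 1

    pos = per_class.get(POSITIVE, {"n": 0, "called_positive": 0})
    tp, fn = pos["called_positive"], pos["n"] - pos["called_positive"]
    fp = sum(d["called_positive"] for c, d in per_class.items()
             if c != POSITIVE)
    neg_n = sum(d["n"] for c, d in per_class.items() if c != POSITIVE)
    tn = neg_n - fp

    sensitivity = tp / pos["n"] if pos["n"] else None
    specificity_by_class = {
        c: 1.0 - d["called_positive"] / d["n"]
        for c, d in sorted(per_class.items()) if c != POSITIVE
    }
    specificity_pooled = tn / neg_n if neg_n else None

    return EvaluationReport(
        n_total=len(truth_labels),
        per_class={c: per_class[c] for c in sorted(per_class)},
        sensitivity=sensitivity,
        specificity_by_class=specificity_by_class,
        specificity_pooled=specificity_pooled,
        confusion={"TP": tp, "FN": fn, "TN": tn, "FP": fp},
    )
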