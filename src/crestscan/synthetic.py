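"""Labelled synthetic membrane proteomes with a planted motif constellation.

Positives emulate the canonical architecture of the CREST superfamily:
seven strongly hydrophobic transmembrane (TM) segments separated by
hydrophilic loops, with ``SxxxH`` at the end of TM2, a lone aspartate at the
beginning of TM3 and ``HxxxH`` at the beginning of TM7. Each decoy class
violates exactly one constellation constraint; chance motif occurrences that
would blur a decoy's semantics are removed by rejection sampling.

Planted motifs are centred on the membrane boundary of their TM (the SxxxH
span straddles the TM2 C-terminus, the HxxxH span the TM7 N-terminus),
matching their described location at the segment ends and keeping the polar
motif residues from eroding the hydrophobic signal of the segment core.
Wildcard positions inside planted motifs are drawn from the hydrophobic
alphabet for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constellation import NEGATIVE, classify_protein
from .io_formats import (COORDINATE_COMMENT, ProteinRecord, TMSegment,
                         Topology, write_fasta, write_topology_table)
from .motifs import ScanConfig, scan_tm_windows

LABEL_POSITIVE = "positive"
LABEL_ORDER = "decoy_order"
LABEL_SEPARATION = "decoy_separation"
LABEL_WINDOW = "decoy_window"
LABEL_NO_MOTIF = "decoy_no_motif"
LABEL_SOLUBLE = "soluble"
LABELS = (LABEL_POSITIVE, LABEL_ORDER, LABEL_SEPARATION, LABEL_WINDOW,
          LABEL_NO_MOTIF, LABEL_SOLUBLE)

#: TM residues: aliphatic-dominated, as in membrane-spanning helices
#: restricted to the strongly hydrophobic letters. Weights are chosen so an
#: 18-residue segment (the shortest the generator emits) still produces a
#: >= 15-residue above-threshold run under the default 19-residue
#: Kyte-Doolittle window at threshold 1.6 (mean hydropathy ~= 4.0).
DEFAULT_HYDROPHOBIC_WEIGHTS: dict[str, float] = {
    "I": 0.38, "L": 0.35, "V": 0.20, "F": 0.04, "M": 0.02, "W": 0.01,
}
#: Loop residues: small polar residues dominate with a modest charged
#: fraction — hydrophilic relative to the TM alphabet (mean hydropathy
#: ~= -0.9, far below the TM threshold) without the strongly negative mean
#: an all-charged linker would have, which would smear the boundaries of
#: short TMs below the detection threshold.
DEFAULT_LOOP_WEIGHTS: dict[str, float] = {
    "G": 0.20, "S": 0.18, "A": 0.18, "T": 0.16, "P": 0.05, "N": 0.04,
    "Q": 0.04, "D": 0.03, "E": 0.03, "K": 0.03, "R": 0.02, "H": 0.02,
    "Y": 0.02,
}

# Planted motif anchoring: SxxxH starts this many residues before the TM2
# end (span [j-2, j+2]); HxxxH starts this many residues before the TM7
# start (span [i-2, i+2]); the aspartate sits 1 residue before the TM3 start.
_EDGE_OFFSET = 2
_D_OFFSET = 1


class GenerationError(RuntimeError):
    """Raised when a spec cannot host the planted architecture."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture and composition of the synthetic proteins.

    ``n_tm`` core TM segments (>= 7 for the canonical constellation), each
    ``tm_length_range`` residues long, separated (and flanked) by loops of
    ``loop_length_range`` residues. ``extra_tm_pairs`` optionally inserts
    additional TM pairs between the motif-bearing segments, emulating
    SID-1-like architectures with extra membrane segments inside the core
    domain; the constellation separation grows accordingly.
    """

    n_tm: int = 7
    tm_length_range: tuple[int, int] = (18, 25)
    loop_length_range: tuple[int, int] = (10, 60)
    hydrophobic_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HYDROPHOBIC_WEIGHTS))
    loop_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_WEIGHTS))
    extra_tm_pairs: int = 0
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self):
        if self.n_tm < 1:
            raise ValueError(f"n_tm must be >= 1, got {self.n_tm}")
        for name, rng_ in (("tm_length_range", self.tm_length_range),
                           ("loop_length_range", self.loop_length_range)):
            lo, hi = rng_
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi, "
                                 f"got {rng_}")
        for name, weights in (("hydrophobic_weights", self.hydrophobic_weights),
                              ("loop_weights", self.loop_weights)):
            if not weights:
                raise ValueError(f"{name} is empty")
            for res, w in weights.items():
                if not (np.isfinite(w) and w > 0):
                    raise ValueError(f"{name}[{res!r}] must be positive and "
                                     f"finite, got {w}")
        if self.extra_tm_pairs < 0:
            raise ValueError("extra_tm_pairs must be >= 0")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")

    @property
    def total_tm(self) -> int:
        return self.n_tm + 2 * self.extra_tm_pairs

    @property
    def hxxxh_tm_ordinal(self) -> int:
        """Index of the HxxxH-bearing TM (core TM7, shifted by extra pairs)."""
        return 7 + 2 * self.extra_tm_pairs


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one synthetic protein."""

    protein_id: str
    label: str
    topology: Topology
    motif_positions: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _normalized(weights: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    letters = sorted(weights)
    p = np.array([weights[c] for c in letters], dtype=float)
    return letters, p / p.sum()


def _draw(weights: Mapping[str, float], n: int, rng: np.random.Generator) -> list[str]:
    letters, p = _normalized(weights)
    return list(rng.choice(letters, size=n, p=p))


def _backbone(spec: GeneratorSpec, rng: np.random.Generator
              ) -> tuple[list[str], tuple[TMSegment, ...]]:
    """Random loops and TM segments; returns mutable chars plus topology."""
    n = spec.total_tm
    tm_lo, tm_hi = spec.tm_length_range
    lp_lo, lp_hi = spec.loop_length_range
    tm_lens = rng.integers(tm_lo, tm_hi + 1, size=n)
    loop_lens = rng.integers(lp_lo, lp_hi + 1, size=n + 1)

    chars: list[str] = []
    segments: list[TMSegment] = []
    for k in range(n):
        chars.extend(_draw(spec.loop_weights, int(loop_lens[k]), rng))
        start = len(chars) + 1
        chars.extend(_draw(spec.hydrophobic_weights, int(tm_lens[k]), rng))
        segments.append(TMSegment(index=k + 1, start=start, end=len(chars)))
    chars.extend(_draw(spec.loop_weights, int(loop_lens[n]), rng))
    return chars, tuple(segments)


def _plant(chars: list[str], start: int, motif: str, spec: GeneratorSpec,
           rng: np.random.Generator) -> None:
    """Overwrite ``chars`` with a motif at 1-based ``start``; 'x' positions
    are drawn from the hydrophobic alphabet."""
    if start < 1 or start + len(motif) - 1 > len(chars):
        raise GenerationError(
            f"motif {motif!r} at {start} does not fit in sequence of "
            f"length {len(chars)}"
        )
    for off, c in enumerate(motif):
        chars[start - 1 + off] = (
            _draw(spec.hydrophobic_weights, 1, rng)[0] if c == "x" else c
        )


def _check_feasible(spec: GeneratorSpec) -> None:
    tm_lo = spec.tm_length_range[0]
    lp_lo = spec.loop_length_range[0]
    # the straddling 5-residue motif needs: containment of its span in the
    # half-window (start >= midpoint for c_half, end <= midpoint for n_half)
    # and enough loop to host the overhanging _EDGE_OFFSET residues.
    if tm_lo < 2 * _EDGE_OFFSET + 5 or lp_lo < _EDGE_OFFSET:
        raise GenerationError(
            f"tm_length_range {spec.tm_length_range} / loop_length_range "
            f"{spec.loop_length_range} too small to fit a 5-residue motif "
            f"inside a TM half-window"
        )
    if spec.n_tm < 7:
        raise GenerationError(
            f"the canonical constellation needs n_tm >= 7, got {spec.n_tm}"
        )


def _motif_tms(spec: GeneratorSpec, segments: Sequence[TMSegment]
               ) -> tuple[TMSegment, TMSegment, TMSegment]:
    return (segments[1], segments[2], segments[spec.hxxxh_tm_ordinal - 1])


def generate_positive(spec: GeneratorSpec | None = None,
                      rng: np.random.Generator | None = None,
                      protein_id: str = "positive_0000",
                      ) -> tuple[ProteinRecord, SyntheticTruth]:
    """One synthetic protein satisfying the full constellation by construction."""
    spec = spec or GeneratorSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    _check_feasible(spec)
    chars, segments = _backbone(spec, rng)
    tm_s, tm_d, tm_h = _motif_tms(spec, segments)

    s_start = tm_s.end - _EDGE_OFFSET
    d_pos = tm_d.start - _D_OFFSET
    h_start = tm_h.start - _EDGE_OFFSET
    _plant(chars, s_start, "SxxxH", spec, rng)
    _plant(chars, d_pos, "D", spec, rng)
    _plant(chars, h_start, "HxxxH", spec, rng)

    record = ProteinRecord(
        id=protein_id, sequence="".join(chars),
        description="synthetic positive (planted constellation)",
    )
    topology = Topology(protein_id=protein_id, segments=segments)
    truth = SyntheticTruth(
        protein_id=protein_id, label=LABEL_POSITIVE, topology=topology,
        motif_positions={"SxxxH": s_start, "D": d_pos, "HxxxH": h_start},
    )
    return record, truth


def _decoy_attempt(kind: str, spec: GeneratorSpec, rng: np.random.Generator,
                   protein_id: str) -> tuple[ProteinRecord, SyntheticTruth]:
    if kind == LABEL_SOLUBLE:
        n = spec.total_tm
        tm_lo, tm_hi = spec.tm_length_range
        lp_lo, lp_hi = spec.loop_length_range
        length = int(rng.integers(tm_lo, tm_hi + 1, size=n).sum()
                     + rng.integers(lp_lo, lp_hi + 1, size=n + 1).sum())
        seq = "".join(_draw(spec.loop_weights, length, rng))
        record = ProteinRecord(id=protein_id, sequence=seq,
                               description="synthetic soluble decoy")
        truth = SyntheticTruth(protein_id=protein_id, label=kind,
                               topology=Topology(protein_id=protein_id))
        return record, truth

    chars, segments = _backbone(spec, rng)
    tm_s, tm_d, tm_h = _motif_tms(spec, segments)
    motifs: dict[str, int] = {}

    if kind == LABEL_ORDER:
        # swapped motif-bearing TMs: HxxxH at the start of TM2, SxxxH at the
        # end of TM7 — same windows, wrong N-to-C order.
        h_start = tm_s.start - _EDGE_OFFSET
        s_start = tm_h.end - _EDGE_OFFSET
        _plant(chars, h_start, "HxxxH", spec, rng)
        _plant(chars, s_start, "SxxxH", spec, rng)
        _plant(chars, tm_d.start - _D_OFFSET, "D", spec, rng)
        motifs = {"HxxxH": h_start, "SxxxH": s_start,
                  "D": tm_d.start - _D_OFFSET}
    elif kind == LABEL_SEPARATION:
        # both motifs correctly windowed and ordered but only 2 TMs apart.
        tm_close = segments[3]  # TM4 — index difference 2 from TM2
        s_start = tm_s.end - _EDGE_OFFSET
        h_start = tm_close.start - _EDGE_OFFSET
        _plant(chars, s_start, "SxxxH", spec, rng)
        _plant(chars, h_start, "HxxxH", spec, rng)
        _plant(chars, tm_d.start - _D_OFFSET, "D", spec, rng)
        motifs = {"SxxxH": s_start, "HxxxH": h_start,
                  "D": tm_d.start - _D_OFFSET}
    elif kind == LABEL_WINDOW:
        # each motif in the wrong half of its own TM.
        s_start = tm_s.start - _EDGE_OFFSET   # SxxxH in the N-half of TM2
        h_start = tm_h.end - _EDGE_OFFSET     # HxxxH in the C-half of TM7
        _plant(chars, s_start, "SxxxH", spec, rng)
        _plant(chars, h_start, "HxxxH", spec, rng)
        _plant(chars, tm_d.start - _D_OFFSET, "D", spec, rng)
        motifs = {"SxxxH": s_start, "HxxxH": h_start,
                  "D": tm_d.start - _D_OFFSET}
    elif kind == LABEL_NO_MOTIF:
        pass  # nothing planted; rejection removes chance pattern hits
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")

    record = ProteinRecord(id=protein_id, sequence="".join(chars),
                           description=f"synthetic {kind}")
    topology = Topology(protein_id=protein_id, segments=segments)
    truth = SyntheticTruth(protein_id=protein_id, label=kind,
                           topology=topology, motif_positions=motifs)
    return record, truth


def generate_decoy(kind: str, spec: GeneratorSpec | None = None,
                   rng: np.random.Generator | None = None,
                   protein_id: str | None = None,
                   ) -> tuple[ProteinRecord, SyntheticTruth]:
    """One decoy of the named class, negative under its planted topology.

    Rejection sampling (capped at ``spec.max_attempts``) discards draws in
    which chance motif occurrences would contradict the class label: a
    passing constellation for any decoy, or — for ``decoy_no_motif`` — any
    windowed SxxxH/HxxxH hit at all.
    """
    if kind not in LABELS[1:]:
        raise ValueError(f"unknown decoy kind {kind!r}; "
                         f"expected one of {LABELS[1:]}")
    spec = spec or GeneratorSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if kind != LABEL_SOLUBLE:
        _check_feasible(spec)
    protein_id = protein_id or f"{kind}_0000"
    scan_cfg = ScanConfig()

    for _ in range(spec.max_attempts):
        record, truth = _decoy_attempt(kind, spec, rng, protein_id)
        if kind == LABEL_NO_MOTIF:
            hits = scan_tm_windows(record, truth.topology, scan_cfg)
            if not hits:
                return record, truth
        else:
            label, _calls = classify_protein(record, truth.topology, scan_cfg)
            if label == NEGATIVE:
                return record, truth
    raise GenerationError(
        f"could not generate a clean {kind} decoy in "
        f"{spec.max_attempts} attempts"
    )


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple[ProteinRecord, ...]
    truths: Mapping[str, SyntheticTruth]

    @property
    def labels(self) -> dict[str, str]:
        return {pid: t.label for pid, t in self.truths.items()}

    @property
    def topologies(self) -> dict[str, Topology]:
        return {pid: t.topology for pid, t in self.truths.items()}


def generate_dataset(n_per_class: int, spec: GeneratorSpec | None = None,
                     seed: int | None = None,
                     outdir: str | Path | None = None,
                     classes: Sequence[str] = LABELS,
                     comments: Sequence[str] = (),
                     ) -> SyntheticDataset:
    """A labelled dataset with ``n_per_class`` proteins per class.

    Ids encode the class for auditing only; downstream code must take labels
    from the truth table, never from ids. With ``outdir`` set, writes
    ``proteins.fasta``, ``topology.tsv`` and ``truth.json``.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    spec = spec or GeneratorSpec()
    for cls in classes:
        if cls not in LABELS:
            raise ValueError(f"unknown class {cls!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    records: list[ProteinRecord] = []
    truths: dict[str, SyntheticTruth] = {}
    for cls in classes:
        for k in range(n_per_class):
            pid = f"{cls}_{k:04d}"
            if cls == LABEL_POSITIVE:
                rec, truth = generate_positive(spec, rng, protein_id=pid)
            else:
                rec, truth = generate_decoy(cls, spec, rng, protein_id=pid)
            records.append(rec)
            truths[pid] = truth
    dataset = SyntheticDataset(records=tuple(records), truths=truths)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "proteins.fasta", dataset.records)
        write_topology_table(outdir / "topology.tsv", dataset.topologies,
                             comments=comments)
        write_truth_json(outdir / "truth.json", dataset.truths,
                         comments=comments)
    return dataset


def write_truth_json(path: str | Path, truths: Mapping[str, SyntheticTruth],
                     comments: Sequence[str] = ()) -> None:
    payload = {
        "comments": [*comments, COORDINATE_COMMENT],
        "proteins": [
            {
                "id": t.protein_id,
                "label": t.label,
                "segments": [[s.index, s.start, s.end]
                             for s in t.topology.segments],
                "motifs": dict(t.motif_positions),
            }
            for _, t in sorted(truths.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="ascii")


def read_truth_json(path: str | Path) -> dict[str, SyntheticTruth]:
    payload = json.loads(Path(path).read_text(encoding="ascii"))
    truths: dict[str, SyntheticTruth] = {}
    for entry in payload["proteins"]:
        topology = Topology(
            protein_id=entry["id"],
            segments=tuple(TMSegment(index=i, start=a, end=b)
                           for i, a, b in entry["segments"]),
        )
        truths[entry["id"]] = SyntheticTruth(
            protein_id=entry["id"], label=entry["label"], topology=topology,
            motif_positions=dict(entry["motifs"]),
        )
    return truths
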