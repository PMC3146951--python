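"""PROSITE-style motif matching and the topology-anchored window scan.

The scan looks for two short histidine-containing motifs relative to
predicted transmembrane (TM) segments: ``SxxxH`` in the C-terminal half of a
TM extended by a small flank (``[floor((i+j)/2), j+5]`` for a TM spanning
``[i, j]``), and ``HxxxH`` in the N-terminal half extended likewise
(``[i-5, floor((i+j)/2)]``). A motif counts only if its full span lies inside
the window. The naive baseline ignores topology entirely and matches the
composite pattern ``S-x(3)-H-x(100,10000)-H-x(3)-H`` over the whole sequence.

Pattern language: literal residues (the 20 standard letters) and the
wildcard ``x`` with optional repeat bounds ``x(n)`` / ``x(n,m)``. Wildcards
match any residue including the ambiguity letters; literals match only the
exact standard residue, so an ``X`` in a sequence never produces a spurious
serine or histidine call.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import ProteinRecord, STANDARD_RESIDUES, TMSegment, Topology

WINDOW_KINDS = ("c_half", "n_half", "whole_sequence")


@dataclass(frozen=True)
class PatternElement:
    """One pattern position: a literal residue, or ``x`` with repeat bounds."""

    residue: str | None  # None for a wildcard
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self):
        if self.residue is not None:
            if self.residue not in STANDARD_RESIDUES:
                raise ValueError(f"literal must be a standard residue, "
                                 f"got {self.residue!r}")
            if (self.min_repeat, self.max_repeat) != (1, 1):
                raise ValueError("literal elements have repeat bounds (1, 1)")
        if not (0 <= self.min_repeat <= self.max_repeat):
            raise ValueError(
                f"invalid repeat bounds ({self.min_repeat}, {self.max_repeat})"
            )

    @property
    def is_wildcard(self) -> bool:
        return self.residue is None


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[PatternElement, ...]

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(self.elements))
        if not any(e.residue is not None for e in self.elements):
            raise ValueError(f"pattern {self.name!r} has no literal element")

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_repeat for e in self.elements)


_TOKEN = re.compile(r"([ACDEFGHIKLMNPQRSTVWY])|x(?:\((\d+)(?:,(\d+))?\))?")


def parse_pattern(text: str, name: str | None = None) -> MotifPattern:
    """Parse PROSITE-like notation, with or without dashes.

    Accepted forms: ``SxxxH``, ``S-x(3)-H``, ``S-x(3)-H-x(100,10000)-H-x(3)-H``.
    ``x(n)`` means exactly n arbitrary residues, ``x(n,m)`` between n and m.
    """
    compact = text.replace("-", "").replace(" ", "")
    elements: list[PatternElement] = []
    pos = 0
    while pos < len(compact):
        m = _TOKEN.match(compact, pos)
        if m is None:
            raise ValueError(f"cannot parse pattern {text!r} at {compact[pos:]!r}")
        literal, lo, hi = m.groups()
        if literal is not None:
            elements.append(PatternElement(residue=literal))
        else:
            lo_n = int(lo) if lo is not None else 1
            hi_n = int(hi) if hi is not None else lo_n
            elements.append(
                PatternElement(residue=None, min_repeat=lo_n, max_repeat=hi_n)
            )
        pos = m.end()
    return MotifPattern(name=name or text, elements=tuple(elements))


SXXXH = parse_pattern("S-x(3)-H", name="SxxxH")
HXXXH = parse_pattern("H-x(3)-H", name="HxxxH")
#: Single conserved aspartate checked by the extended constellation mode.
D_MOTIF = parse_pattern("D", name="D")


def find_pattern(sequence: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """Enumerate all pattern occurrences as 1-based inclusive (start, end).

    Overlapping matches are reported; a bounded wildcard enumerates every
    admissible repeat count, so one start may yield several spans.
    """
    n = len(sequence)
    elems = pattern.elements
    # residual minimum lengths for pruning
    rest_min = [0] * (len(elems) + 1)
    for k in range(len(elems) - 1, -1, -1):
        rest_min[k] = rest_min[k + 1] + elems[k].min_repeat

    spans: set[tuple[int, int]] = set()

    def walk(pos: int, k: int, start: int) -> None:
        if k == len(elems):
            spans.add((start + 1, pos))  # end: 0-based exclusive == 1-based incl.
            return
        if pos + rest_min[k] > n:
            return
        e = elems[k]
        if e.residue is not None:
            if sequence[pos] == e.residue:
                walk(pos + 1, k + 1, start)
        else:
            hi = min(e.max_repeat, n - pos - rest_min[k + 1])
            for r in range(e.min_repeat, hi + 1):
                walk(pos + r, k + 1, start)

    for s in range(n - pattern.min_length + 1):
        walk(s, 0, s)
    return sorted(spans)


@dataclass(frozen=True)
class MotifHit:
    """One pattern occurrence, optionally anchored to a TM half-window."""

    pattern: str
    start: int
    end: int
    tm_index: int = 0  # 0 when not anchored to a TM
    window_kind: str = "whole_sequence"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"hit start {self.start} > end {self.end}")
        if self.window_kind not in WINDOW_KINDS:
            raise ValueError(f"unknown window kind {self.window_kind!r}")


@dataclass(frozen=True)
class ScanConfig:
    """Constants of the topology-anchored scan and the naive baseline.

    ``c_half_flank``/``n_half_flank``: residues added beyond the TM end /
    before the TM start when forming the half-windows (default 5).
    ``min_tm_separation``: minimum TM-index difference between the SxxxH- and
    HxxxH-bearing TMs for a passing call (default 3; the canonical
    constellation sits in TM2 and TM7, 5 apart, relaxed to tolerate missed
    TM predictions). ``naive_spacer_min``/``max``: bounds on the number of
    residues between the two motifs in the whole-sequence baseline pattern.
    ``mode``: ``core`` checks SxxxH + HxxxH only; ``extended`` additionally
    requires the conserved aspartate at the start of the TM following the
    SxxxH-bearing one.
    """

    c_half_flank: int = 5
    n_half_flank: int = 5
    min_tm_separation: int = 3
    naive_spacer_min: int = 100
    naive_spacer_max: int = 10000
    mode: str = "core"

    def __post_init__(self):
        if self.c_half_flank < 0 or self.n_half_flank < 0:
            raise ValueError("window flanks must be >= 0")
        if not (0 <= self.naive_spacer_min <= self.naive_spacer_max):
            raise ValueError("need 0 <= naive_spacer_min <= naive_spacer_max")
        if self.min_tm_separation < 0:
            raise ValueError("min_tm_separation must be >= 0")
        if self.mode not in ("core", "extended"):
            raise ValueError(f"unknown scan mode {self.mode!r}")

    def naive_pattern(self) -> MotifPattern:
        return parse_pattern(
            f"S-x(3)-H-x({self.naive_spacer_min},{self.naive_spacer_max})"
            f"-H-x(3)-H",
            name="SxxxH..HxxxH",
        )


def window_for(tm: TMSegment, kind: str, config: ScanConfig,
               sequence_length: int) -> tuple[int, int]:
    """The half-window interval [a, b] of a TM, clamped to the sequence.

    ``c_half`` is ``[floor((i+j)/2), j + c_half_flank]`` (C-terminal half of
    the TM plus the flank beyond it); ``n_half`` is
    ``[i - n_half_flank, floor((i+j)/2)]``.
    """
    mid = tm.midpoint
    if kind == "c_half":
        a, b = mid, tm.end + config.c_half_flank
    elif kind == "n_half":
        a, b = tm.start - config.n_half_flank, mid
    else:
        raise ValueError(f"unknown window kind {kind!r}")
    return max(1, a), min(sequence_length, b)


def _contained(span: tuple[int, int], window: tuple[int, int]) -> bool:
    return window[0] <= span[0] and span[1] <= window[1]


def scan_tm_windows(record: ProteinRecord, topology: Topology,
                    config: ScanConfig | None = None) -> list[MotifHit]:
    """Windowed motif hits for one protein under its topology.

    For every TM: SxxxH matches whose full span lies inside the c_half
    window, and HxxxH matches whose full span lies inside the n_half window.
    In ``extended`` mode single-aspartate hits inside n_half windows are
    emitted as well (pattern name ``D``), for the constellation caller to
    consume. An empty topology yields an empty hit list.
    """
    config = config or ScanConfig()
    if topology.protein_id != record.id:
        raise ValueError(
            f"topology belongs to {topology.protein_id!r}, "
            f"record is {record.id!r}"
        )
    n = len(record.sequence)
    s_spans = find_pattern(record.sequence, SXXXH)
    h_spans = find_pattern(record.sequence, HXXXH)
    d_spans = (find_pattern(record.sequence, D_MOTIF)
               if config.mode == "extended" else [])

    hits: list[MotifHit] = []
    for tm in topology.segments:
        cw = window_for(tm, "c_half", config, n)
        nw = window_for(tm, "n_half", config, n)
        for span in s_spans:
            if _contained(span, cw):
                hits.append(MotifHit("SxxxH", span[0], span[1], tm.index,
                                     "c_half"))
        for span in h_spans:
            if _contained(span, nw):
                hits.append(MotifHit("HxxxH", span[0], span[1], tm.index,
                                     "n_half"))
        for span in d_spans:
            if _contained(span, nw):
                hits.append(MotifHit("D", span[0], span[1], tm.index,
                                     "n_half"))
    hits.sort(key=lambda h: (h.tm_index, h.window_kind, h.start, h.end,
                             h.pattern))
    return hits


def naive_scan(record: ProteinRecord, config: ScanConfig | None = None
               ) -> list[MotifHit]:
    """Whole-sequence matches of the composite baseline pattern.

    Equivalent to enumerating all (SxxxH at s, HxxxH..H at t) pairs whose
    spacer t - (s + 5) lies within [naive_spacer_min, naive_spacer_max].
    """
    config = config or ScanConfig()
    pattern = config.naive_pattern()
    return [
        MotifHit(pattern.name, a, b, 0, "whole_sequence")
        for a, b in find_pattern(record.sequence, pattern)
    ]
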