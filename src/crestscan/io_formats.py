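"""Domain types and file formats shared by every pipeline stage.

All residue coordinates are 1-based and inclusive on both ends, matching the
(i, j) convention for transmembrane segment bounds used throughout the
package. Tabular writers emit ``#`` comment lines stating this convention
together with caller-supplied provenance.

Downstream modules consume only the types defined here (:class:`ProteinRecord`,
:class:`TMSegment`, :class:`Topology`); no other module touches raw files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity / non-standard letters accepted in sequences. They are matched
#: by pattern wildcards but never by literal pattern positions.
AMBIGUITY_RESIDUES = frozenset("XBZUOJ")
VALID_RESIDUES = STANDARD_RESIDUES | AMBIGUITY_RESIDUES

COORDINATE_COMMENT = "coordinates: 1-based, inclusive on both ends"

#: Column order of the constellation-call table; stable by contract.
CALL_COLUMNS = (
    "protein_id",
    "sxxxh_tm",
    "sxxxh_start",
    "hxxxh_tm",
    "hxxxh_start",
    "tm_separation",
    "passed",
    "mode",
)


class FormatError(ValueError):
    """Raised for malformed input files; carries file and line context."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        where = ""
        if path is not None:
            where += f"{path}"
        if line is not None:
            where += f":{line}"
        super().__init__(f"{where}: {message}" if where else message)
        self.path = str(path) if path is not None else None
        self.line = line


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence.

    The sequence is uppercase over the 20 standard amino-acid letters plus
    the ambiguity letters ``X B Z U O J``; gaps and whitespace are rejected.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid protein id: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.id}: illegal sequence character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class TMSegment:
    """One predicted transmembrane segment.

    ``start``/``end`` are the i and j bounds of the segment, 1-based and
    inclusive; ``index`` is the 1-based ordinal of the segment along the
    protein.
    """

    index: int
    start: int
    end: int

    def __post_init__(self):
        if self.index < 1:
            raise ValueError(f"TM index must be >= 1, got {self.index}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"TM{self.index}: invalid bounds [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        """floor((i + j) / 2) — the split point between the two half-windows."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Topology:
    """Ordered, non-overlapping transmembrane segments of one protein."""

    protein_id: str
    segments: tuple[TMSegment, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        prev: TMSegment | None = None
        for k, seg in enumerate(self.segments, start=1):
            if seg.index != k:
                raise ValueError(
                    f"{self.protein_id}: TM indices must be consecutive 1..n; "
                    f"position {k} has index {seg.index}"
                )
            if prev is not None and seg.start <= prev.end:
                raise ValueError(
                    f"{self.protein_id}: TM{seg.index} [{seg.start},{seg.end}] "
                    f"overlaps TM{prev.index} [{prev.start},{prev.end}]"
                )
            prev = seg

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment(self, index: int) -> TMSegment:
        try:
            seg = self.segments[index - 1]
        except IndexError:
            raise KeyError(
                f"{self.protein_id}: no TM with index {index}"
            ) from None
        return seg


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into validated :class:`ProteinRecord` objects.

    Multi-line records and CRLF endings are accepted; sequences are
    uppercased; ``*`` stop characters are stripped with a warning. Gap
    characters (``-`` or ``.``), other illegal characters, empty sequences,
    text before the first header and duplicate ids raise :class:`FormatError`
    naming the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    stripped_stop = False

    def flush(line_no: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {header!r} has an empty sequence",
                              path, header_line)
        fields = header.split(maxsplit=1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r}", path, header_line)
        seen.add(rid)
        try:
            records.append(ProteinRecord(id=rid, sequence=seq, description=desc))
        except ValueError as exc:
            raise FormatError(str(exc), path, header_line) from exc
        header, chunks = None, []

    line_no = 0
    with path.open("r", encoding="ascii") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise FormatError("empty FASTA header", path, line_no)
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        "sequence data before the first '>' header", path, line_no
                    )
                seq = line.upper()
                if "*" in seq:
                    stripped_stop = True
                    seq = seq.replace("*", "")
                for c in seq:
                    if c in "-.":
                        raise FormatError(
                            f"gap character {c!r} in sequence of {header!r}",
                            path, line_no,
                        )
                    if c not in VALID_RESIDUES:
                        raise FormatError(
                            f"illegal character {c!r} in sequence of {header!r}",
                            path, line_no,
                        )
                chunks.append(seq)
        flush(line_no)
    if stripped_stop:
        warnings.warn(f"{path}: '*' stop characters were stripped", stacklevel=2)
    if not records:
        raise FormatError("no FASTA records found", path)
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord],
                width: int = 60) -> None:
    """Write records as FASTA, wrapping sequences at ``width`` columns."""
    path = Path(path)
    with path.open("w", encoding="ascii") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for k in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[k:k + width] + "\n")


# ---------------------------------------------------------------------------
# Topology table (TSV)
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = ("protein_id", "tm_index", "start", "end")


def read_topology_table(path: str | Path, min_tm_len: int = 15
                        ) -> dict[str, Topology]:
    """Read a per-protein TM-segment table into :class:`Topology` objects.

    Expected columns (tab-separated): ``protein_id  tm_index  start  end``
    with an optional fifth orientation column, which is ignored. ``#``
    comment lines and an optional header row are skipped. Rows are grouped
    per protein and validated (consecutive indices, no overlaps, segment
    length >= ``min_tm_len``); violations raise :class:`FormatError` citing
    the row.
    """
    path = Path(path)
    rows: dict[str, list[tuple[int, TMSegment]]] = {}
    with path.open("r", encoding="ascii") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"expected >= 4 tab-separated columns, got {len(fields)}",
                    path, line_no,
                )
            if fields[0] == "protein_id":  # header row
                continue
            try:
                idx, start, end = (int(fields[1]), int(fields[2]), int(fields[3]))
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", path,
                                  line_no) from exc
            if start > end:
                raise FormatError(
                    f"start {start} > end {end}", path, line_no
                )
            if end - start + 1 < min_tm_len:
                raise FormatError(
                    f"TM segment [{start},{end}] shorter than "
                    f"min_tm_len={min_tm_len}", path, line_no,
                )
            try:
                seg = TMSegment(index=idx, start=start, end=end)
            except ValueError as exc:
                raise FormatError(str(exc), path, line_no) from exc
            rows.setdefault(fields[0], []).append((line_no, seg))

    topologies: dict[str, Topology] = {}
    for pid, entries in rows.items():
        entries.sort(key=lambda e: e[1].start)
        try:
            topologies[pid] = Topology(
                protein_id=pid, segments=tuple(seg for _, seg in entries)
            )
        except ValueError as exc:
            raise FormatError(str(exc), path, entries[0][0]) from exc
    return topologies


def write_topology_table(path: str | Path,
                         topologies: Mapping[str, Topology] | Iterable[Topology],
                         comments: Sequence[str] = ()) -> None:
    """Write topologies in the dialect accepted by :func:`read_topology_table`.

    Proteins with zero segments contribute no rows (a soluble protein).
    Output is deterministic: proteins sorted by id, segments by index.
    """
    if isinstance(topologies, Mapping):
        topo_list = [topologies[k] for k in sorted(topologies)]
    else:
        topo_list = sorted(topologies, key=lambda t: t.protein_id)
    path = Path(path)
    with path.open("w", encoding="ascii") as fh:
        for c in (*comments, COORDINATE_COMMENT):
            fh.write(f"# {c}\n")
        fh.write("\t".join(_TOPOLOGY_COLUMNS) + "\n")
        for topo in topo_list:
            for seg in topo.segments:
                fh.write(f"{topo.protein_id}\t{seg.index}\t{seg.start}"
                         f"\t{seg.end}\n")


# ---------------------------------------------------------------------------
# Constellation-call table (TSV or JSON)
# ---------------------------------------------------------------------------

def _call_row(call) -> dict:
    return {
        "protein_id": call.protein_id,
        "sxxxh_tm": call.sxxxh.tm_index,
        "sxxxh_start": call.sxxxh.start,
        "hxxxh_tm": call.hxxxh.tm_index,
        "hxxxh_start": call.hxxxh.start,
        "tm_separation": call.tm_separation,
        "passed": call.passed,
        "mode": call.mode,
    }


def write_calls(path: str | Path, calls: Sequence, fmt: str = "tsv",
                comments: Sequence[str] = ()) -> None:
    """Write constellation calls with a stable column and row order.

    Rows are ordered by ``(protein_id, sxxxh_start, hxxxh_start)``; identical
    input therefore yields byte-identical output.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError(f"unknown calls format: {fmt!r}")
    rows = sorted(
        (_call_row(c) for c in calls),
        key=lambda r: (r["protein_id"], r["sxxxh_start"], r["hxxxh_start"]),
    )
    path = Path(path)
    if fmt == "json":
        payload = {"comments": [*comments, COORDINATE_COMMENT], "calls": rows}
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="ascii")
        return
    with path.open("w", encoding="ascii") as fh:
        for c in (*comments, COORDINATE_COMMENT):
            fh.write(f"# {c}\n")
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(
                str(r[col]).lower() if col == "passed" else str(r[col])
                for col in CALL_COLUMNS
            ) + "\n")
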