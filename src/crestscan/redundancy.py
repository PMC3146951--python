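"""Sequence-set reduction: fragment removal, de-duplication, grouping.

Mirrors the standard pre-clustering hygiene applied to large homolog sets:
fragments below 100 residues are dropped, near-identical sequences are
removed at a 95% identity level by greedy incremental clustering (CD-HIT
convention: longest sequence founds each cluster), and the remainder can be
grouped by a per-column alignment score plus one-sided length coverage
(BLASTCLUST-style ``-S 1 -L 0.5 -b F`` thresholds).

All pairwise comparisons use one global BLOSUM62 alignment (gap open 11,
extend 1, terminal gaps free). The per-column "bit" score is approximated
as half the raw BLOSUM62 score per alignment column; exact Karlin–Altschul
scaling is intentionally out of scope for a representative-picking
heuristic, and the threshold is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord

# BLOSUM62 lacks U/O/J; map them to the generic X before aligning.
_TO_X = str.maketrans({"U": "X", "O": "X", "J": "X"})


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one global pairwise alignment.

    ``columns`` counts alignment columns between the first and last aligned
    residue pair, internal gap columns included (terminal overhangs are
    excluded, as in local-alignment-based clustering tools). ``coverage_a``
    and ``coverage_b`` are the fractions of each sequence inside that
    aligned region.
    """

    identity: float
    columns: int
    score_per_column: float
    coverage_a: float
    coverage_b: float


@dataclass(frozen=True)
class ClusterAssignment:
    representative_id: str
    member_ids: tuple[str, ...]
    threshold_used: float

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be one of the members")


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def remove_fragments(records: Sequence[ProteinRecord], min_len: int = 100
                     ) -> list[ProteinRecord]:
    """Drop sequences shorter than ``min_len`` residues, preserving order."""
    return [r for r in records if len(r.sequence) >= min_len]


def pairwise_identity(a: str, b: str) -> AlignmentStats:
    """Globally align two sequences and summarise identity and score.

    Identity is the fraction of identical aligned pairs over alignment
    columns (internal gap columns counted in the denominator); the
    normalised score is (raw BLOSUM62 score / 2) per alignment column.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a_x, b_x = a.translate(_TO_X), b.translate(_TO_X)
    alignment = _aligner().align(a_x, b_x)[0]
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:  # nothing aligned at all
        return AlignmentStats(0.0, 0, 0.0, 0.0, 0.0)

    identical = 0
    aligned_pairs = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned_pairs += a1 - a0
        identical += sum(x == y for x, y in zip(a_x[a0:a1], b_x[b0:b1]))

    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = span_a + span_b - aligned_pairs
    # terminal gaps score 0, so the raw score is the aligned-region score
    score_per_column = (float(alignment.score) / 2.0) / columns
    return AlignmentStats(
        identity=identical / columns,
        columns=columns,
        score_per_column=score_per_column,
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
    )


def _greedy_order(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    return sorted(records, key=lambda r: (-len(r.sequence), r.id))


def dedupe(records: Sequence[ProteinRecord], identity_threshold: float = 0.95
           ) -> tuple[list[ProteinRecord], list[ClusterAssignment]]:
    """Greedy incremental de-duplication at an identity threshold.

    Records are visited by decreasing length (ties broken by id); each joins
    the first existing representative with pairwise identity strictly above
    the threshold, otherwise it founds a new cluster. Returns the
    representatives (in visiting order) and the cluster table; by
    construction no two representatives exceed the threshold.
    """
    if not records:
        raise ValueError("dedupe needs a non-empty record list")
    reps: list[ProteinRecord] = []
    members: dict[str, list[str]] = {}
    for rec in _greedy_order(records):
        home = None
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence).identity \
                    > identity_threshold:
                home = rep
                break
        if home is None:
            reps.append(rec)
            members[rec.id] = [rec.id]
        else:
            members[home.id].append(rec.id)
    assignments = [
        ClusterAssignment(representative_id=rep.id,
                          member_ids=tuple(members[rep.id]),
                          threshold_used=identity_threshold)
        for rep in reps
    ]
    return reps, assignments


def group_by_coverage(records: Sequence[ProteinRecord],
                      score_per_column_min: float = 1.0,
                      length_coverage_min: float = 0.5
                      ) -> list[ClusterAssignment]:
    """Single-linkage grouping on score and one-sided length coverage.

    An edge joins two sequences iff the normalised alignment score reaches
    ``score_per_column_min`` and the aligned region covers at least
    ``length_coverage_min`` of *either* sequence (coverage is not required
    on both). Connected components form the groups; each group is
    represented by its longest member (ties by id). Every record lands in
    exactly one group.
    """
    idx = {r.id: k for k, r in enumerate(records)}
    parent = list(range(len(records)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            stats = pairwise_identity(records[i].sequence, records[j].sequence)
            if (stats.score_per_column >= score_per_column_min
                    and max(stats.coverage_a, stats.coverage_b)
                    >= length_coverage_min):
                union(i, j)

    groups: dict[int, list[ProteinRecord]] = {}
    for rec in records:
        groups.setdefault(find(idx[rec.id]), []).append(rec)

    assignments = []
    for group in groups.values():
        rep = min(group, key=lambda r: (-len(r.sequence), r.id))
        assignments.append(ClusterAssignment(
            representative_id=rep.id,
            member_ids=tuple(sorted(r.id for r in group)),
            threshold_used=score_per_column_min,
        ))
    return sorted(assignments, key=lambda a: a.representative_id)
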