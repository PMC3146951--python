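"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's matching code paths: patterns are
checked position-by-position with explicitly enumerated wildcard lengths,
and profile values are computed with plain Python loops.
"""

from __future__ import annotations

import itertools

from crestscan.hydropathy import KYTE_DOOLITTLE

# pattern specs are tuples of ("lit", residue) or ("x", lo, hi)
SXXXH_SPEC = (("lit", "S"), ("x", 3, 3), ("lit", "H"))
HXXXH_SPEC = (("lit", "H"), ("x", 3, 3), ("lit", "H"))


def naive_spec(lo: int, hi: int):
    return (("lit", "S"), ("x", 3, 3), ("lit", "H"), ("x", lo, hi),
            ("lit", "H"), ("x", 3, 3), ("lit", "H"))


def brute_matches(seq: str, spec) -> list[tuple[int, int]]:
    """All (start, end) occurrences, 1-based inclusive, by enumeration."""
    n = len(seq)
    wild_ranges = [range(e[1], e[2] + 1) for e in spec if e[0] == "x"]
    found = set()
    for counts in itertools.product(*wild_ranges):
        layout = []  # residue or None per position of the realised pattern
        it = iter(counts)
        for e in spec:
            if e[0] == "lit":
                layout.append(e[1])
            else:
                layout.extend([None] * next(it))
        m = len(layout)
        for s in range(n - m + 1):
            if all(c is None or seq[s + k] == c for k, c in enumerate(layout)):
                found.add((s + 1, s + m))
    return sorted(found)


def brute_windowed_hits(seq: str, segments, c_flank: int = 5,
                        n_flank: int = 5) -> list[tuple]:
    """Match-everywhere-then-filter oracle for the topology-anchored scan.

    Returns tuples (pattern, start, end, tm_index, kind), sorted.
    """
    n = len(seq)
    s_matches = brute_matches(seq, SXXXH_SPEC)
    h_matches = brute_matches(seq, HXXXH_SPEC)
    hits = []
    for seg in segments:
        mid = (seg.start + seg.end) // 2
        cw = (max(1, mid), min(n, seg.end + c_flank))
        nw = (max(1, seg.start - n_flank), min(n, mid))
        for a, b in s_matches:
            if cw[0] <= a and b <= cw[1]:
                hits.append(("SxxxH", a, b, seg.index, "c_half"))
        for a, b in h_matches:
            if nw[0] <= a and b <= nw[1]:
                hits.append(("HxxxH", a, b, seg.index, "n_half"))
    return sorted(hits)


def brute_profile(seq: str, window: int) -> list[float]:
    """Truncated-window mean Kyte-Doolittle profile, plain loops."""
    mean = sum(KYTE_DOOLITTLE.values()) / len(KYTE_DOOLITTLE)
    vals = [KYTE_DOOLITTLE.get(c, mean) for c in seq]
    half = window // 2
    out = []
    for p in range(len(seq)):
        lo, hi = max(0, p - half), min(len(seq), p + half + 1)
        out.append(sum(vals[lo:hi]) / (hi - lo))
    return out


def random_protein(rng, max_len: int = 2000,
                   alphabet: str = "SHAGLIVDETKRX") -> str:
    """A random sequence enriched in the motif letters S/H/D."""
    n = int(rng.integers(60, max_len + 1))
    return "".join(rng.choice(list(alphabet), size=n))


def random_segments(rng, seq_len: int, min_len: int = 15, max_len: int = 30):
    """A random valid set of non-overlapping TM segments (possibly empty)."""
    from crestscan.io_formats import TMSegment

    segments = []
    pos = int(rng.integers(1, 30))
    idx = 1
    while pos + min_len - 1 <= seq_len:
        length = int(rng.integers(min_len, max_len + 1))
        end = pos + length - 1
        if end > seq_len:
            break
        if rng.random() < 0.8:
            segments.append(TMSegment(index=idx, start=pos, end=end))
            idx += 1
        pos = end + int(rng.integers(1, 40))
    return tuple(segments)
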