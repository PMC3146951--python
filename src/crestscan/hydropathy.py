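"""Sliding-window hydropathy profiles and a simple TM-segment predictor.

This is a deliberately transparent, dependency-free stand-in for dedicated
topology predictors (Phobius, TMHMM): a Kyte–Doolittle window average is
thresholded, near-adjacent runs are merged, and short runs are discarded.
Scan results never depend on this module when a topology table is supplied
externally, which decouples motif calling from predictor quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_formats import ProteinRecord, TMSegment, Topology

#: Kyte–Doolittle hydropathy values for the 20 standard residues.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class SequenceTooShortError(ValueError):
    """Sequence shorter than the smoothing window; supply an external topology."""


@dataclass(frozen=True)
class HydropathyConfig:
    """Parameters of the hydropathy TM predictor.

    ``window`` (odd residue count) and ``threshold`` (scale units) follow the
    classical single-TM heuristic for the Kyte–Doolittle scale; ``min_tm_len``
    discards implausibly short runs and ``merge_gap`` bridges brief dips
    inside a helix. Runs are merged first, then filtered by length, so output
    is deterministic.
    """

    scale: Mapping[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE))
    window: int = 19
    threshold: float = 1.6
    min_tm_len: int = 15
    merge_gap: int = 3

    def __post_init__(self):
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 5, got {self.window}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.min_tm_len < 5:
            raise ValueError(f"min_tm_len must be >= 5, got {self.min_tm_len}")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


def hydropathy_profile(sequence: str, config: HydropathyConfig | None = None
                       ) -> np.ndarray:
    """Smoothed per-residue hydropathy values.

    The value at position p is the mean scale value over the window centred
    at p; within half a window of either terminus the mean is taken over the
    truncated window, so short termini can still host TM segments. Ambiguity
    letters contribute the mean value of the scale.
    """
    config = config or HydropathyConfig()
    n = len(sequence)
    if n < config.window:
        raise SequenceTooShortError(
            f"sequence length {n} < window {config.window}; "
            "provide an external topology table for this protein"
        )
    scale_mean = float(np.mean(list(config.scale.values())))
    vals = np.array([config.scale.get(c, scale_mean) for c in sequence],
                    dtype=float)
    kernel = np.ones(config.window)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return sums / counts


def predict_tm(record: ProteinRecord, config: HydropathyConfig | None = None
               ) -> Topology:
    """Predict TM segments as thresholded runs of the hydropathy profile.

    Maximal runs of positions with profile >= threshold are found; runs
    separated by fewer than ``merge_gap`` below-threshold positions are
    merged (gap residues included in the merged segment); surviving runs
    shorter than ``min_tm_len`` are discarded. Remaining runs become
    TMSegments indexed 1..n from the N-terminus. An empty topology is a
    valid result.
    """
    config = config or HydropathyConfig()
    profile = hydropathy_profile(record.sequence, config)
    above = profile >= config.threshold

    runs: list[list[int]] = []  # [start0, end0] 0-based inclusive
    start = None
    for p, flag in enumerate(above):
        if flag and start is None:
            start = p
        elif not flag and start is not None:
            runs.append([start, p - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < config.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    segments = [
        TMSegment(index=k, start=a + 1, end=b + 1)
        for k, (a, b) in enumerate(
            (r for r in merged if r[1] - r[0] + 1 >= config.min_tm_len),
            start=1,
        )
    ]
    return Topology(protein_id=record.id, segments=tuple(segments))
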