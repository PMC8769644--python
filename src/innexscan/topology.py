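"""Membrane-topology inference from a hydropathy profile.

Innexin-family gap-junction proteins thread the membrane four times, with
both termini and the single connecting loop between TM2 and TM3 inside the
cell, and the two loops between TM1-TM2 and TM3-TM4 outside (the docking
interface of the hemichannel).  This module locates the four transmembrane
helices as high-hydropathy runs of a windowed Kyte-Doolittle profile and
labels the inter-helix regions under that fixed N-inside orientation.

Coordinates are 1-based and inclusive throughout; conversion to 0-based
happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: Kyte-Doolittle hydropathy scale (dimensionless).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

SEGMENT_ORDER = (
    "NTERM_IN", "TM1", "EL1", "TM2", "CL", "TM3", "EL2", "TM4", "CTERM_IN",
)
TM_LABELS = ("TM1", "TM2", "TM3", "TM4")
EXTRACELLULAR_LOOPS = ("EL1", "EL2")


class TopologyError(ValueError):
    """Sequence does not present the required four-TM architecture."""

    def __init__(self, message: str, tm_count: int | None = None) -> None:
        super().__init__(message)
        self.tm_count = tm_count


@dataclass(frozen=True)
class HydropathyProfile:
    """Windowed mean hydropathy, one value per residue."""

    values: np.ndarray
    window: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TopologySegment:
    label: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.label}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class TopologyModel:
    """Ordered segments tiling [1, length] under the N-inside orientation."""

    segments: tuple[TopologySegment, ...]
    length: int

    def __post_init__(self) -> None:
        pos = 1
        order_iter = iter(SEGMENT_ORDER)
        for seg in self.segments:
            if seg.start != pos:
                raise ValueError(
                    f"segments do not tile the sequence: expected start {pos}, "
                    f"got {seg.label} at {seg.start}"
                )
            for expected in order_iter:
                if expected == seg.label:
                    break
            else:
                raise ValueError(f"segment {seg.label} out of order")
            pos = seg.end + 1
        if pos != self.length + 1:
            raise ValueError(
                f"segments end at {pos - 1}, sequence length is {self.length}"
            )
        if len(self.tm_segments) != 4:
            raise ValueError("topology model must contain exactly four TM segments")

    @property
    def tm_segments(self) -> tuple[TopologySegment, ...]:
        return tuple(s for s in self.segments if s.label in TM_LABELS)

    def segment_of(self, pos: int) -> TopologySegment:
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside sequence span 1..{self.length}")
        for seg in self.segments:
            if seg.contains(pos):
                return seg
        raise AssertionError("unreachable: segments tile the sequence")

    def span(self, label: str) -> tuple[int, int] | None:
        for seg in self.segments:
            if seg.label == label:
                return (seg.start, seg.end)
        return None

    def tm_boundaries(self) -> list[int]:
        bounds: list[int] = []
        for seg in self.tm_segments:
            bounds.extend((seg.start, seg.end))
        return bounds

    def to_string(self) -> str:
        return ";".join(f"{s.label}:{s.start}-{s.end}" for s in self.segments)

    @classmethod
    def from_string(cls, text: str, length: int) -> "TopologyModel":
        segs = []
        for token in text.split(";"):
            label, span = token.split(":")
            start, end = span.split("-")
            segs.append(TopologySegment(label, int(start), int(end)))
        return cls(segments=tuple(segs), length=length)


def hydropathy_profile(sequence: str, window: int = 19) -> HydropathyProfile:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    Windows are truncated (not mirrored) at the termini so the profile has
    one value per residue.
    """
    n = len(sequence)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 5 <= window <= 31:
        raise ValueError(f"window must be in [5, 31], got {window}")
    if window > n:
        raise ValueError(f"window {window} longer than sequence ({n} aa)")
    try:
        vals = np.array([KYTE_DOOLITTLE[aa] for aa in sequence], dtype=float)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not on the hydropathy scale") from exc
    half = window // 2
    cum = np.concatenate(([0.0], np.cumsum(vals)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    profile = (cum[hi] - cum[lo]) / (hi - lo)
    return HydropathyProfile(values=profile, window=window)


def _runs_above(values: np.ndarray, threshold: float) -> list[list[int]]:
    """Maximal runs of indices (0-based) with value >= threshold."""
    above = values >= threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(values) - 1])
    return runs


def _split_long(run: tuple[int, int], values: np.ndarray,
                min_len: int, max_len: int) -> list[tuple[int, int]]:
    # fused-helix artifact: a run longer than max_len is split at its lowest
    # internal profile value, provided both halves stay >= min_len
    s, e = run
    if e - s + 1 <= max_len:
        return [(s, e)]
    lo, hi = s + min_len, e - min_len
    if lo > hi:
        return [(s, e)]
    m = lo + int(np.argmin(values[lo : hi + 1]))
    return _split_long((s, m - 1), values, min_len, max_len) + _split_long(
        (m + 1, e), values, min_len, max_len
    )


def call_tm_segments(profile: HydropathyProfile, threshold: float = 1.6,
                     min_len: int = 15, merge_gap: int = 3,
                     max_len: int = 35) -> list[tuple[int, int]]:
    """Call TM helices as above-threshold runs of the profile.

    Runs separated by fewer than ``merge_gap`` sub-threshold positions are
    merged; runs longer than ``max_len`` are split at their weakest interior
    point; runs shorter than ``min_len`` are discarded.  Returned intervals
    are 1-based inclusive, sorted and disjoint.
    """
    runs = _runs_above(profile.values, threshold)
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(list(run))
    out: list[tuple[int, int]] = []
    for s, e in merged:
        out.extend(_split_long((s, e), profile.values, min_len, max_len))
    return [(s + 1, e + 1) for s, e in out if e - s + 1 >= min_len]


def assign_topology(tm_intervals: Sequence[tuple[int, int]], seq_len: int) -> TopologyModel:
    """Label four TM intervals and the regions between them.

    Raises :class:`TopologyError` (carrying the observed TM count) when the
    count differs from four or when adjacent helices leave no loop between
    them; raises ``ValueError`` for malformed interval lists.
    """
    prev_end = 0
    for s, e in tm_intervals:
        if s < 1 or e > seq_len:
            raise ValueError(f"interval ({s}, {e}) outside sequence span 1..{seq_len}")
        if s > e or s <= prev_end:
            raise ValueError(f"intervals not sorted/disjoint at ({s}, {e})")
        prev_end = e
    if len(tm_intervals) != 4:
        raise TopologyError(
            f"expected 4 TM segments, found {len(tm_intervals)}",
            tm_count=len(tm_intervals),
        )
    loop_labels = ("EL1", "CL", "EL2")
    for k in range(3):
        if tm_intervals[k + 1][0] - tm_intervals[k][1] < 2:
            raise TopologyError(
                f"no {loop_labels[k]} loop between TM{k + 1} and TM{k + 2}",
                tm_count=4,
            )
    segments: list[TopologySegment] = []
    first_start = tm_intervals[0][0]
    if first_start > 1:
        segments.append(TopologySegment("NTERM_IN", 1, first_start - 1))
    for k, (s, e) in enumerate(tm_intervals):
        segments.append(TopologySegment(f"TM{k + 1}", s, e))
        if k < 3:
            segments.append(
                TopologySegment(loop_labels[k], e + 1, tm_intervals[k + 1][0] - 1)
            )
    last_end = tm_intervals[3][1]
    if last_end < seq_len:
        segments.append(TopologySegment("CTERM_IN", last_end + 1, seq_len))
    return TopologyModel(segments=tuple(segments), length=seq_len)


def infer_topology(sequence: str, window: int = 19, threshold: float = 1.6,
                   min_len: int = 15, merge_gap: int = 3,
                   max_len: int = 35) -> TopologyModel:
    """Profile, call and label in one step; raises on non-four-TM sequences."""
    profile = hydropathy_profile(sequence, window=window)
    intervals = call_tm_segments(profile, threshold=threshold, min_len=min_len,
                                 merge_gap=merge_gap, max_len=max_len)
    return assign_topology(intervals, len(sequence))
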