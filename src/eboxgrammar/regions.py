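"""Genomic interval and signal plumbing.

Peaks are 0-based half-open intervals carrying an absolute summit position
(the single-base maximum of the underlying signal).  Signal tracks are
per-contig sorted, non-overlapping intervals with numeric values (e.g. %CpG
methylation in [0, 100] or RPKM), the in-memory form of a bedGraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Peak",
    "SignalTrack",
    "consensus_peaks",
    "resize_to_summit",
    "signal_matrix",
    "interval_jaccard",
    "merge_intervals",
]


@dataclass(frozen=True)
class Peak:
    contig: str
    start: int
    end: int
    summit: int
    name: Optional[str] = None
    score: Optional[float] = None
    clipped: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


def consensus_peaks(rep_a: Sequence[Peak], rep_b: Sequence[Peak]) -> list[Peak]:
    """Two-replicate consensus: keep intersecting pairs whose intersection
    contains both summits.

    The consensus interval is the intersection; the consensus summit is the
    floor of the two summits' midpoint.  When one peak qualifies against
    several of the other replicate's peaks, every qualifying pair produces a
    record and overlapping records on the same contig are then merged (union
    interval, leftmost summit).
    """
    by_contig: dict[str, list[Peak]] = {}
    for p in rep_b:
        by_contig.setdefault(p.contig, []).append(p)
    for v in by_contig.values():
        v.sort(key=lambda p: p.start)

    raw: list[Peak] = []
    for a in rep_a:
        for b in by_contig.get(a.contig, ()):
            if b.start >= a.end:
                break
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo >= hi:
                continue
            if lo <= a.summit < hi and lo <= b.summit < hi:
                raw.append(
                    Peak(a.contig, lo, hi, (a.summit + b.summit) // 2)
                )
    raw.sort(key=lambda p: (p.contig, p.start))
    merged: list[Peak] = []
    for p in raw:
        if merged and merged[-1].contig == p.contig and p.start < merged[-1].end:
            last = merged.pop()
            merged.append(
                Peak(p.contig, last.start, max(last.end, p.end), last.summit)
            )
        else:
            merged.append(p)
    return merged


def resize_to_summit(
    peaks: Iterable[Peak],
    width: int,
    contig_lengths: Optional[dict[str, int]] = None,
) -> list[Peak]:
    """Recenter each peak on its summit and set a fixed width.

    The new interval is [summit - width//2, summit - width//2 + width); at
    contig edges it is clipped (not discarded) and flagged.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out = []
    half = width // 2
    for p in peaks:
        lo, hi = p.summit - half, p.summit - half + width
        clipped = False
        if lo < 0:
            lo, clipped = 0, True
        if contig_lengths is not None and p.contig in contig_lengths:
            L = contig_lengths[p.contig]
            if hi > L:
                hi, clipped = L, True
        out.append(
            Peak(p.contig, lo, hi, p.summit, name=p.name, score=p.score,
                 clipped=clipped)
        )
    return out


class SignalTrack:
    """Per-contig sorted, non-overlapping intervals with values (bedGraph)."""

    def __init__(self, data: Optional[dict[str, tuple]] = None):
        # contig -> (starts, ends, values) as numpy arrays
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if data:
            for contig, (s, e, v) in data.items():
                self.add_contig(contig, s, e, v)

    def add_contig(self, contig, starts, ends, values):
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        v = np.asarray(values, dtype=float)
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(e[:-1] > s[1:]):
            raise ValueError(f"overlapping intervals on {contig}")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values on {contig}")
        self._data[contig] = (s, e, v)

    @property
    def contigs(self) -> list[str]:
        return list(self._data)

    def intervals(self, contig):
        return self._data[contig]

    def window_mean(self, contig: str, start: int, end: int) -> float:
        """Coverage-weighted mean value over [start, end); NaN if no data."""
        if contig not in self._data or end <= start:
            return float("nan")
        s, e, v = self._data[contig]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if hi <= lo:
            return float("nan")
        ss = np.maximum(s[lo:hi], start)
        ee = np.minimum(e[lo:hi], end)
        w = (ee - ss).astype(float)
        keep = w > 0
        if not keep.any():
            return float("nan")
        return float(np.average(v[lo:hi][keep], weights=w[keep]))

    def to_frame(self):
        import pandas as pd

        rows = []
        for contig, (s, e, v) in self._data.items():
            rows.append(
                pd.DataFrame(
                    {"contig": contig, "start": s, "end": e, "value": v}
                )
            )
        if not rows:
            return pd.DataFrame(columns=["contig", "start", "end", "value"])
        return pd.concat(rows, ignore_index=True)


def signal_matrix(
    track: SignalTrack,
    anchors: Sequence[tuple[str, int]],
    flank: int,
    bin: int,
) -> np.ndarray:
    """Anchor-centered binned signal matrix.

    Entry (i, j) is the coverage-weighted mean of the track over bin ``j`` of
    the window [anchor_i - flank, anchor_i + flank); bins with no covered base
    pairs are NaN.  Anchors on contigs absent from the track give all-NaN rows
    (with a warning).  ``flank`` must be a multiple of ``bin``.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    n_bins = 2 * flank // bin
    out = np.full((len(anchors), n_bins), np.nan)
    missing = set()
    for i, (contig, pos) in enumerate(anchors):
        if contig not in track.contigs:
            missing.add(contig)
            continue
        lo = pos - flank
        for j in range(n_bins):
            out[i, j] = track.window_mean(contig, lo + j * bin, lo + (j + 1) * bin)
    if missing:
        warnings.warn(f"anchors on contigs without signal: {sorted(missing)}")
    return out


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    """Union of half-open intervals as a sorted (n, 2) array."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(sorted(intervals), dtype=np.int64)
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _grouped(peaks: Iterable[Peak]) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by.setdefault(p.contig, []).append((p.start, p.end))
    return {c: merge_intervals(v) for c, v in by.items()}


def interval_jaccard(set_a: Sequence[Peak], set_b: Sequence[Peak]) -> float:
    """Base-pair Jaccard index between two peak sets (0 for empty union)."""
    a, b = _grouped(set_a), _grouped(set_b)
    inter = 0
    total_a = sum(int((m[:, 1] - m[:, 0]).sum()) for m in a.values())
    total_b = sum(int((m[:, 1] - m[:, 0]).sum()) for m in b.values())
    for contig, ma in a.items():
        mb = b.get(contig)
        if mb is None:
            continue
        i = j = 0
        while i < len(ma) and j < len(mb):
            lo = max(ma[i, 0], mb[j, 0])
            hi = min(ma[i, 1], mb[j, 1])
            if hi > lo:
                inter += int(hi - lo)
            if ma[i, 1] < mb[j, 1]:
                i += 1
            else:
                j += 1
    union = total_a + total_b - inter
    return inter / union if union > 0 else 0.0


def overlaps_any(peak: Peak, merged: dict[str, np.ndarray]) -> bool:
    """Whether a peak overlaps a pre-merged interval set (see ``_grouped``)."""
    m = merged.get(peak.contig)
    if m is None or len(m) == 0:
        return False
    i = np.searchsorted(m[:, 0], peak.end, side="left")
    return bool(i > 0 and m[i - 1, 1] > peak.start)


def merge_peak_sets(peaks: Iterable[Peak]) -> dict[str, np.ndarray]:
    """Public wrapper used by occupancy/Jaccard consumers."""
    return _grouped(peaks)
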