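"""%CpG methylation profiling around peaks and E-boxes.

Tracks carry percent methylation in [0, 100] at CpG-covered positions; base
pairs without data are missing, never zero, and are excluded from every mean.
The stage delta contrasts neural stem cells (NSC) against postmitotic
neurons (PN) in a small window around each E-box.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .eboxes import CLASS_LABELS, EBoxSite
from .regions import SignalTrack, signal_matrix

__all__ = ["methylation_profile", "ebox_methylation_delta"]


def methylation_profile(
    tracks: dict[str, SignalTrack],
    anchors: Sequence[tuple[str, int]],
    flank: int = 1000,
    bin: int = 10,
) -> pd.DataFrame:
    """Per-stage mean methylation curve around anchors, with SEM.

    Anchors are summit or E-box midpoint positions.  Column means and SEMs
    are taken over the anchors with data in each bin.
    """
    rows = []
    for stage, track in tracks.items():
        if len(anchors) == 0:
            continue
        mat = signal_matrix(track, anchors, flank, bin)
        n = np.sum(~np.isnan(mat), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1)
        sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
        centers = np.arange(-flank, flank, bin) + bin / 2
        for c, m, s, k in zip(centers, mean, sem, n):
            rows.append((stage, c, m, s, int(k)))
    return pd.DataFrame(
        rows, columns=["stage", "position", "mean", "sem", "n"]
    )


def ebox_methylation_delta(
    track_nsc: SignalTrack,
    track_pn: SignalTrack,
    sites: Sequence[EBoxSite],
    halfwidth: int = 5,
    include_hexamer: bool = False,
) -> pd.DataFrame:
    """Per-class mean %mCpG near E-boxes per stage and the PN - NSC delta.

    The window is ±``halfwidth`` bp around the hexamer midpoint (default an
    11 bp window); with ``include_hexamer`` it instead spans the hexamer plus
    ``halfwidth`` bp on each side.  Means pool all covered base pairs over
    all sites of the class; classes without covered CpGs report NaN.
    """
    sums = {cls: [0.0, 0.0] for cls in CLASS_LABELS}   # weighted value sums
    wts = {cls: [0.0, 0.0] for cls in CLASS_LABELS}
    for s in sites:
        if include_hexamer:
            lo, hi = s.start - halfwidth, s.start + 6 + halfwidth
        else:
            lo, hi = s.midpoint - halfwidth, s.midpoint + halfwidth + 1
        for k, track in enumerate((track_nsc, track_pn)):
            if s.contig not in track.contigs:
                continue
            st, en, vals = track.intervals(s.contig)
            i0 = np.searchsorted(en, lo, side="right")
            i1 = np.searchsorted(st, hi, side="left")
            if i1 <= i0:
                continue
            w = (np.minimum(en[i0:i1], hi) - np.maximum(st[i0:i1], lo)).astype(float)
            keep = w > 0
            sums[s.ebox_class][k] += float((vals[i0:i1][keep] * w[keep]).sum())
            wts[s.ebox_class][k] += float(w[keep].sum())
    rows = []
    for cls in CLASS_LABELS:
        mean_nsc = sums[cls][0] / wts[cls][0] if wts[cls][0] else np.nan
        mean_pn = sums[cls][1] / wts[cls][1] if wts[cls][1] else np.nan
        rows.append((cls, mean_nsc, mean_pn, mean_pn - mean_nsc))
    return pd.DataFrame(
        rows, columns=["ebox_class", "mean_nsc", "mean_pn", "delta"]
    )
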