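"""Motif grammar statistics around ChIP-seq/ATAC peak summits.

Centrality is the fold change of motif density (occurrences per bp) in a
window around the summit versus a distal window inside the same resized
peaks: > 1 means centrally enriched.  Flank bias compares upstream half-site
dinucleotide usage near vs far from summits; pair spacing tallies the number
of intervening nucleotides between E-box pairs in the same peak.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .eboxes import CLASS_LABELS, EBoxSite
from .regions import Peak

__all__ = [
    "motif_centrality",
    "motifs_per_peak",
    "distance_density",
    "flank_bias",
    "pair_spacing",
    "score_bin_enrichment",
]

_DINUCS = ["".join(p) for p in product("ACGT", repeat=2)]


def _abs_dist(sites: Sequence[EBoxSite]) -> np.ndarray:
    d = np.array([s.summit_distance for s in sites], dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("all sites must carry summit distances")
    return np.abs(d)


def motif_centrality(
    sites: Sequence[EBoxSite],
    n_peaks: int,
    near_halfwidth: int = 50,
    distal_start: int = 250,
    distal_end: int = 750,
) -> pd.DataFrame:
    """Per-class summit centrality: near/distal motif density fold.

    near window: |d| <= near_halfwidth; distal window:
    distal_start <= |d| <= distal_end.  Window footprints are
    2*near_halfwidth*n_peaks and 2*(distal_end - distal_start)*n_peaks bp.
    A class with zero distal occurrences reports a missing fold (NaN).
    """
    if not distal_start > near_halfwidth:
        raise ValueError("distal window must start beyond the near window")
    d = _abs_dist(sites)
    labels = np.array([s.ebox_class for s in sites])
    near_bp = 2 * near_halfwidth * n_peaks
    distal_bp = 2 * (distal_end - distal_start) * n_peaks
    rows = []
    for cls in CLASS_LABELS:
        m = labels == cls
        near = int(((d <= near_halfwidth) & m).sum())
        distal = int(((d >= distal_start) & (d <= distal_end) & m).sum())
        if distal > 0 and near_bp > 0:
            fold = (near / near_bp) / (distal / distal_bp)
        else:
            fold = np.nan
        rows.append((cls, near, distal, near_bp, distal_bp, fold))
    return pd.DataFrame(
        rows,
        columns=["ebox_class", "near_count", "distal_count", "near_bp",
                 "distal_bp", "centrality"],
    )


def motifs_per_peak(
    sites: Sequence[EBoxSite],
    n_peaks: int,
    near_halfwidth: int = 100,
    distal_threshold: int = 200,
    peak_halfwidth: int = 750,
) -> pd.DataFrame:
    """Mean motifs per peak near the summit, and near/distal per-bp fold.

    near: |d| <= near_halfwidth; distal: |d| > distal_threshold (out to the
    resized-peak half-width, which bounds the distal footprint).
    """
    d = _abs_dist(sites)
    labels = np.array([s.ebox_class for s in sites])
    near_bp = 2 * near_halfwidth * n_peaks
    distal_bp = 2 * (peak_halfwidth - distal_threshold) * n_peaks
    rows = []
    for cls in CLASS_LABELS:
        m = labels == cls
        near = int(((d <= near_halfwidth) & m).sum())
        distal = int(((d > distal_threshold) & m).sum())
        mean_near = near / n_peaks if n_peaks else np.nan
        if distal > 0 and distal_bp > 0:
            fold = (near / near_bp) / (distal / distal_bp)
        else:
            fold = np.nan
        rows.append((cls, mean_near, near, distal, fold))
    return pd.DataFrame(
        rows,
        columns=["ebox_class", "mean_per_peak", "near_count", "distal_count",
                 "fold"],
    )


def distance_density(
    sites: Sequence[EBoxSite],
    n_peaks: int,
    bin_width: int = 50,
    max_distance: int = 750,
) -> pd.DataFrame:
    """Overall motifs-per-bp profile by absolute summit distance."""
    d = _abs_dist(sites)
    edges = np.arange(0, max_distance + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    per_bp = counts / (2 * bin_width * n_peaks) if n_peaks else counts * np.nan
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:],
         "count": counts, "per_bp": per_bp}
    )


def _halfsite_flank_counts(sites: Sequence[EBoxSite]) -> pd.DataFrame:
    counts: dict[str, Counter] = defaultdict(Counter)
    for s in sites:
        for half, flank in ((s.half_a, s.flank_a), (s.half_b, s.flank_b)):
            key = flank if flank in _DINUCS else "other"
            counts[half][key] += 1
    rows = []
    for half, ctr in counts.items():
        total = sum(ctr.values())
        for dn in _DINUCS + ["other"]:
            rows.append((half, dn, ctr[dn], ctr[dn] / total if total else np.nan))
    return pd.DataFrame(rows, columns=["half_site", "dinuc", "count", "proportion"])


def flank_bias(
    near_sites: Sequence[EBoxSite],
    distal_sites: Sequence[EBoxSite],
) -> pd.DataFrame:
    """Upstream-dinucleotide composition per half-site, near vs distal.

    Every E-box contributes two half-site observations (both halves).  For
    each of the 4 half-site types the 16 dinucleotide proportions (plus an
    N-containing "other" bucket) are reported with the near/distal fold.
    """
    near = _halfsite_flank_counts(near_sites).rename(
        columns={"count": "near_count", "proportion": "near_prop"})
    distal = _halfsite_flank_counts(distal_sites).rename(
        columns={"count": "distal_count", "proportion": "distal_prop"})
    out = near.merge(distal, on=["half_site", "dinuc"], how="outer")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold"] = out["near_prop"] / out["distal_prop"]
    out.loc[~np.isfinite(out["fold"]), "fold"] = np.nan
    return out


def pair_spacing(
    sites: Sequence[EBoxSite],
    strata: Optional[Sequence[str]] = None,
    group_key: Callable[[EBoxSite], str] = lambda s: s.contig,
    max_gap: int = 30,
) -> pd.DataFrame:
    """Distribution of intervening-nucleotide gaps between E-box pairs.

    For every ordered-by-position pair of sites in the same peak (group),
    gap = downstream.start - (upstream.start + 6).  Gaps in [0, max_gap] are
    tallied; negative gaps (overlapping hexamers) go to an ``overlap`` bucket
    excluded from the proportions.  All pairs are counted, not only adjacent
    ones.  ``strata`` gives one stratum label per site (pairs crossing strata
    are skipped); default a single stratum "all".
    """
    if strata is None:
        strata = ["all"] * len(sites)
    groups: dict[tuple[str, str], list[EBoxSite]] = defaultdict(list)
    for s, st in zip(sites, strata):
        groups[(st, group_key(s))].append(s)
    gap_counts: dict[str, Counter] = defaultdict(Counter)
    overlap: Counter = Counter()
    for (st, _), ss in groups.items():
        ss = sorted(ss, key=lambda s: s.start)
        for i in range(len(ss)):
            for j in range(i + 1, len(ss)):
                gap = ss[j].start - (ss[i].start + 6)
                if gap < 0:
                    overlap[st] += 1
                elif gap <= max_gap:
                    gap_counts[st][gap] += 1
    rows = []
    for st in sorted(gap_counts | overlap):
        total = sum(gap_counts[st].values())
        for gap in range(max_gap + 1):
            c = gap_counts[st][gap]
            rows.append((st, gap, c, c / total if total else np.nan,
                         overlap[st]))
    return pd.DataFrame(
        rows, columns=["stratum", "gap", "count", "proportion", "n_overlap"]
    )


def score_bin_enrichment(
    peaks: Sequence[Peak],
    scores: Sequence[float],
    sites_per_peak: Sequence[Sequence[EBoxSite]],
    n_bins: int = 10,
    window_halfwidth: Optional[int] = None,
    window_fraction: Optional[float] = 0.4,
    scale_rows: bool = False,
) -> pd.DataFrame:
    """Mean motifs per peak per class across score bins.

    Peaks are sorted by score into ``n_bins`` near-equal bins (bin 0 = lowest
    scores, e.g. pre-induction accessibility or pre/post fold change).  A
    site counts when the full hexamer lies inside the summit-centered window:
    either a fixed half-width or a window of ``window_fraction`` of the peak
    length (the default 0.4).  ``scale_rows`` z-scores each class across bins
    (rows with zero spread become zeros).
    """
    if (window_halfwidth is None) == (window_fraction is None):
        raise ValueError("give exactly one of window_halfwidth/window_fraction")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    order = np.argsort(scores, kind="stable")
    bins = np.array_split(order, n_bins)
    mat = np.zeros((len(CLASS_LABELS), n_bins))
    idx = {c: i for i, c in enumerate(CLASS_LABELS)}
    for b, members in enumerate(bins):
        if len(members) == 0:
            mat[:, b] = np.nan
            continue
        for k in members:
            pk = peaks[k]
            if window_halfwidth is not None:
                half = window_halfwidth
            else:
                half = int(round(pk.width * window_fraction / 2))
            lo, hi = pk.summit - half, pk.summit + half
            for s in sites_per_peak[k]:
                if s.start >= lo and s.start + 6 <= hi:
                    mat[idx[s.ebox_class], b] += 1
        mat[:, b] /= len(members)
    if scale_rows:
        mean = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, keepdims=True)
        mat = np.where(sd > 0, (mat - mean) / np.where(sd == 0, 1, sd), 0.0)
    out = pd.DataFrame(mat, index=list(CLASS_LABELS),
                       columns=[f"bin_{b}" for b in range(n_bins)])
    out.index.name = "ebox_class"
    return out
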