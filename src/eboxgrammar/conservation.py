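"""Polymorphism/divergence selection analysis of E-boxes.

Within-species diversity comes from a wild-mouse SNV panel (polymorphic when
minor allele frequency >= 0.05); between-species divergence from pairwise
alignment to an outgroup (rat), counting single-nucleotide substitutions
inside the hexamer and excluding motifs spanning indels.  E-boxes within
50 bp of the peak summit are putatively selected sites (PSS), those 200-400
bp away non-selected sites (NSS); per-class PSS/NSS rate ratios below 1 for
both diversity (pPSS/pNSS) and divergence (dPSS/dNSS) indicate purifying
selection in a McDonald-Kreitman-style contrast.  Phylostratigraphic depth
is the deepest clade across which a motif stays conserved given per-clade
species thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .eboxes import CLASS_LABELS

__all__ = [
    "CladeScheme",
    "DEFAULT_CLADE_SCHEME",
    "CLADE_ORDER",
    "count_polymorphisms",
    "count_substitutions",
    "distance_binned_variation",
    "pss_nss_ratios",
    "mk_resample",
    "species_conservation",
    "assign_phylostratum",
]

# shallow -> deep
CLADE_ORDER = ("placental", "marsupial", "monotreme", "non_mammal")


@dataclass(frozen=True)
class CladeScheme:
    """Per-clade (required conserved species, total species) thresholds."""

    thresholds: Mapping[str, tuple[int, int]]

    def __post_init__(self):
        for clade, (req, total) in self.thresholds.items():
            if req > total:
                raise ValueError(f"{clade}: required {req} > total {total}")


DEFAULT_CLADE_SCHEME = CladeScheme(
    {
        "placental": (20, 39),
        "marsupial": (1, 3),
        "monotreme": (1, 1),
        "non_mammal": (8, 16),
    }
)


def count_polymorphisms(
    sites_df: pd.DataFrame,
    variants: pd.DataFrame,
    maf_min: float = 0.05,
) -> pd.Series:
    """Per-site count of SNVs with MAF >= ``maf_min`` inside the hexamer.

    ``sites_df`` needs columns contig/start; the hexamer interval is
    [start, start+6).  The MAF cutoff is inclusive.
    """
    kept = variants[variants["maf"] >= maf_min]
    counts = np.zeros(len(sites_df), dtype=np.int64)
    by_contig = {c: g["pos"].to_numpy() for c, g in kept.groupby("contig")}
    for i, (contig, start) in enumerate(
        zip(sites_df["contig"].to_numpy(), sites_df["start"].to_numpy())
    ):
        pos = by_contig.get(contig)
        if pos is None:
            continue
        counts[i] = int(((pos >= start) & (pos < start + 6)).sum())
    return pd.Series(counts, index=sites_df.index, name="poly_count")


def count_substitutions(
    sites_df: pd.DataFrame,
    alignments: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Per-site substitution count against the outgroup, or an exclusion.

    ``alignments`` maps site id -> (reference hexamer, aligned outgroup
    string).  Any gap in either string excludes the motif (``indel``); sites
    without an alignment are excluded as ``uncovered``.
    """
    counts, status = [], []
    for sid in sites_df["site_id"]:
        aln = alignments.get(sid)
        if aln is None:
            counts.append(np.nan)
            status.append("uncovered")
            continue
        ref, out = (a.upper() for a in aln)
        if "-" in ref or "-" in out or len(ref) != len(out):
            counts.append(np.nan)
            status.append("indel")
            continue
        counts.append(sum(a != b for a, b in zip(ref, out)))
        status.append("ok")
    return pd.DataFrame(
        {"sub_count": counts, "status": status}, index=sites_df.index
    )


def distance_binned_variation(
    summit_distances: Sequence[float],
    counts: Sequence[float],
    bin_width: int = 50,
    max_distance: int = 500,
) -> pd.DataFrame:
    """Mean and dispersion of per-motif counts in |summit distance| bins."""
    d = np.abs(np.asarray(summit_distances, dtype=float))
    c = np.asarray(counts, dtype=float)
    ok = ~np.isnan(c)
    edges = np.arange(0, max_distance + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = ok & (d >= lo) & (d < hi)
        if m.sum() == 0:
            rows.append((lo, hi, 0, np.nan, np.nan))
        else:
            rows.append((lo, hi, int(m.sum()), float(c[m].mean()),
                         float(c[m].std(ddof=1)) if m.sum() > 1 else 0.0))
    return pd.DataFrame(
        rows, columns=["bin_start", "bin_end", "n", "mean", "sd"]
    )


def _zone(abs_d: np.ndarray, pss_halfwidth: int, nss_range: tuple[int, int]):
    pss = abs_d <= pss_halfwidth
    nss = (abs_d >= nss_range[0]) & (abs_d <= nss_range[1])
    return pss, nss


def pss_nss_ratios(
    sites_df: pd.DataFrame,
    pss_halfwidth: int = 50,
    nss_range: tuple[int, int] = (200, 400),
) -> pd.DataFrame:
    """Per-class PSS and NSS rates (counts per motif) and their ratios.

    ``sites_df`` needs columns ebox_class, summit_distance, poly_count and
    sub_count (NaN sub_count = excluded motif, dropped from divergence rates
    only).  Boundaries are inclusive as printed (|d| <= 50; 200 <= |d| <= 400).
    """
    if nss_range[0] >= nss_range[1]:
        raise ValueError("nss_range must be increasing")
    if nss_range[0] <= pss_halfwidth:
        raise ValueError("NSS window must lie beyond the PSS window")
    d = np.abs(sites_df["summit_distance"].to_numpy(dtype=float))
    pss, nss = _zone(d, pss_halfwidth, nss_range)
    cls = sites_df["ebox_class"].to_numpy()
    poly = sites_df["poly_count"].to_numpy(dtype=float)
    sub = sites_df["sub_count"].to_numpy(dtype=float)
    rows = []
    for label in CLASS_LABELS:
        m = cls == label
        res = {"ebox_class": label}
        for prefix, counts in (("p", poly), ("d", sub)):
            ok = m & ~np.isnan(counts)
            n_pss, n_nss = int((ok & pss).sum()), int((ok & nss).sum())
            r_pss = counts[ok & pss].sum() / n_pss if n_pss else np.nan
            r_nss = counts[ok & nss].sum() / n_nss if n_nss else np.nan
            res[f"{prefix}PSS"] = r_pss
            res[f"{prefix}NSS"] = r_nss
            res[f"{prefix}_ratio"] = (
                r_pss / r_nss if (n_nss and r_nss > 0) else np.nan
            )
            res[f"n_{prefix}PSS"], res[f"n_{prefix}NSS"] = n_pss, n_nss
        rows.append(res)
    return pd.DataFrame(rows)


def mk_resample(
    sites_df: pd.DataFrame,
    n_subsets: int = 100,
    subset_size: Optional[int] = None,
    seed: int = 0,
    pss_halfwidth: int = 50,
    nss_range: tuple[int, int] = (200, 400),
) -> pd.DataFrame:
    """McDonald-Kreitman-style resampling: ratio pairs over random E-box
    subsets of each class.

    Subsets are drawn without replacement (seeded).  ``subset_size`` defaults
    to the smallest per-class motif count across classes present.  Quadrant
    is ``purifying`` when both ratios are < 1.
    """
    rng = np.random.default_rng(seed)
    cls = sites_df["ebox_class"].to_numpy()
    present = [c for c in CLASS_LABELS if (cls == c).sum() > 0]
    if subset_size is None:
        subset_size = min(int((cls == c).sum()) for c in present)
    rows = []
    for label in present:
        idx = np.flatnonzero(cls == label)
        if subset_size > idx.size:
            raise ValueError(f"subset_size {subset_size} > {idx.size} "
                             f"motifs in class {label}")
        for k in range(n_subsets):
            take = rng.choice(idx, size=subset_size, replace=False)
            sub = sites_df.iloc[take]
            rat = pss_nss_ratios(sub, pss_halfwidth, nss_range)
            rat = rat[rat["ebox_class"] == label].iloc[0]
            p_r, d_r = rat["p_ratio"], rat["d_ratio"]
            if np.isnan(p_r) or np.isnan(d_r):
                quad = "undefined"
            elif p_r < 1 and d_r < 1:
                quad = "purifying"
            else:
                quad = "other"
            rows.append((label, k, p_r, d_r, quad))
    return pd.DataFrame(
        rows, columns=["ebox_class", "subset", "p_ratio", "d_ratio", "quadrant"]
    )


def species_conservation(
    reference: str,
    species_alignments: Mapping[str, str],
    species_list: Optional[Sequence[str]] = None,
) -> dict[str, str]:
    """Per-species status of one motif: conserved / diverged / excluded.

    Conserved means 0 substitutions across the 6 core positions; any gap in
    the aligned string (or a missing species) excludes it.
    """
    ref = reference.upper()
    if "-" in ref or len(ref) != 6:
        raise ValueError("reference must be a gap-free hexamer")
    if species_list is None:
        species_list = list(species_alignments)
    out = {}
    for sp in species_list:
        aln = species_alignments.get(sp)
        if aln is None:
            out[sp] = "excluded"
            continue
        aln = aln.upper()
        if "-" in aln or len(aln) != 6:
            out[sp] = "excluded"
        elif aln == ref:
            out[sp] = "conserved"
        else:
            out[sp] = "diverged"
    return out


def assign_phylostratum(
    statuses: Mapping[str, str],
    species_clades: Mapping[str, str],
    scheme: CladeScheme = DEFAULT_CLADE_SCHEME,
) -> str:
    """Deepest clade whose threshold and all shallower thresholds are met.

    Excluded species do not count as conserved but the required count stays
    absolute (the clade total is not reduced).  Returns one of ``none``,
    ``placental``, ``marsupial``, ``monotreme``, ``non_mammal``.
    """
    conserved = {clade: 0 for clade in CLADE_ORDER}
    for sp, status in statuses.items():
        if status == "conserved":
            clade = species_clades.get(sp)
            if clade in conserved:
                conserved[clade] += 1
    depth = "none"
    for clade in CLADE_ORDER:
        req, _total = scheme.thresholds[clade]
        if conserved[clade] >= req:
            depth = clade
        else:
            break  # cumulative gate: a failed shallow threshold stops descent
    return depth
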