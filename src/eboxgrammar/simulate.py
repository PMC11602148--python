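"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: planted-motif
genomes with summit-enriched E-box placement, trajectory-shaped pseudobulk
accessibility, affinity-driven SELEX selection, clade-structured
substitutions with stronger constraint near summits, allele-frequency
distributed polymorphisms, and methylation tracks with demethylation dips at
motifs.  Generation is a pure function of (parameters, seed); each generator
returns its truth table separately so analysis code never sees it.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .conservation import CLADE_ORDER, DEFAULT_CLADE_SCHEME
from .eboxes import CLASS_LABELS, EBoxSite, get_class, scan_eboxes
from .regions import Peak, SignalTrack
from .trajectories import (
    CELL_TYPE_ORDER,
    PseudobulkMatrix,
    TrajectoryTemplate,
    build_templates,
)

__all__ = [
    "gen_genome_with_peaks",
    "gen_pseudobulk",
    "gen_expression_coupled_cells",
    "gen_selex",
    "gen_sites",
    "ebox_sites_from_frame",
    "gen_alignments_and_variants",
    "gen_methylation",
]

_BASES = np.array(list("ACGT"))

DEFAULT_LAYOUT = (8, 5, 7, 8, 2)  # pseudobulk groups per cell type


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _has_unintended_ebox(seq: np.ndarray, planted: set[int], lo: int, hi: int) -> bool:
    window = "".join(seq[max(lo, 0) : min(hi, len(seq))])
    for site in scan_eboxes(window, offset=max(lo, 0)):
        if site.start not in planted:
            return True
    return False


def _plant(
    rng: np.random.Generator,
    seq: np.ndarray,
    planted: dict[int, str],
    start: int,
    label: str,
) -> bool:
    """Write one representative hexamer at ``start``; revert on creating an
    unintended E-box within +/-8 bp or on collision with a planted motif."""
    if start < 0 or start + 6 > len(seq):
        return False
    for other in planted:
        if abs(other - start) < 6:  # planted motifs must not overwrite
            return False            # each other
    reps = get_class(label).representatives
    hexamer = reps[rng.integers(len(reps))]
    backup = seq[start : start + 6].copy()
    seq[start : start + 6] = list(hexamer)
    if _has_unintended_ebox(seq, set(planted) | {start}, start - 8, start + 14):
        seq[start : start + 6] = backup
        return False
    planted[start] = label
    return True


def gen_genome_with_peaks(
    n_peaks: int = 200,
    peak_width: int = 1500,
    class_density_near: Optional[Mapping[str, float]] = None,
    class_density_distal: Optional[Mapping[str, float]] = None,
    gc_background: float = 0.5,
    near_halfwidth: int = 50,
    paired_gap: Optional[int] = None,
    paired_fraction: float = 0.5,
    seed: int = 0,
    max_tries: int = 50,
) -> tuple[dict[str, str], list[Peak], pd.DataFrame]:
    """Synthetic genome of summit-centered peaks with planted E-boxes.

    Each peak is its own contig of ``peak_width`` bp with the summit at the
    center.  Per class, motif counts are Poisson with per-bp rates
    ``class_density_near`` inside |d| <= near_halfwidth of the summit and
    ``class_density_distal`` elsewhere in the peak.  With ``paired_gap``, a
    fraction of peaks additionally carries a pair of CAT-CAT E-boxes at that
    intervening-nucleotide gap near the summit.  Planting rejects positions
    where writing the hexamer creates an unintended E-box within +/-8 bp
    (background E-boxes elsewhere remain, as in a real genome).

    Returns (sequences, peaks, truth table).
    """
    near = dict(class_density_near or {})
    distal = dict(class_density_distal or {})
    if any(v < 0 for v in list(near.values()) + list(distal.values())):
        raise ValueError("densities must be >= 0")
    rng = np.random.default_rng(seed)
    summit_off = peak_width // 2
    near_bp = 2 * near_halfwidth
    distal_bp = peak_width - near_bp
    sequences: dict[str, str] = {}
    peaks: list[Peak] = []
    truth_rows = []
    for ip in range(n_peaks):
        contig = f"peak_{ip:05d}"
        seq = _random_sequence(rng, peak_width, gc_background)
        planted: dict[int, str] = {}

        def place(label: str, zone: str) -> None:
            for attempt in range(max_tries):
                if zone == "near":
                    d = int(rng.integers(-near_halfwidth, near_halfwidth + 1))
                else:
                    d = int(rng.integers(-(summit_off - 3), peak_width - summit_off - 3))
                    if abs(d) <= near_halfwidth:
                        continue
                start = summit_off + d - 3
                if _plant(rng, seq, planted, start, label):
                    truth_rows.append((contig, start, label, zone))
                    return
            raise RuntimeError(
                "could not place motif without creating unintended E-boxes; "
                "densities too high for the rejection rule"
            )

        for label, rate in near.items():
            for _ in range(rng.poisson(rate * near_bp)):
                place(label, "near")
        for label, rate in distal.items():
            for _ in range(rng.poisson(rate * distal_bp)):
                place(label, "distal")
        if paired_gap is not None and rng.random() < paired_fraction:
            for attempt in range(max_tries):
                d = int(rng.integers(-near_halfwidth, near_halfwidth + 1))
                s1 = summit_off + d - 3
                s2 = s1 + 6 + paired_gap
                backup = dict(planted)
                if _plant(rng, seq, planted, s1, "CAT-CAT"):
                    # second member may sit closer than the 14 bp guard allows
                    # for independent motifs; place it directly with its own
                    # rejection scan
                    if s2 + 6 <= len(seq):
                        reps = get_class("CAT-CAT").representatives
                        hexamer = reps[rng.integers(len(reps))]
                        b2 = seq[s2 : s2 + 6].copy()
                        seq[s2 : s2 + 6] = list(hexamer)
                        if not _has_unintended_ebox(
                            seq, set(planted) | {s2}, s2 - 8, s2 + 14
                        ):
                            planted[s2] = "CAT-CAT"
                            truth_rows.append((contig, s1, "CAT-CAT", "pair"))
                            truth_rows.append((contig, s2, "CAT-CAT", "pair"))
                            break
                        seq[s2 : s2 + 6] = b2
                    # undo first member
                    seq[s1 : s1 + 6] = _random_sequence(rng, 6, gc_background)
                    planted.clear()
                    planted.update(backup)
        sequences[contig] = "".join(seq)
        peaks.append(Peak(contig, 0, peak_width, summit_off, name=contig))
    truth = pd.DataFrame(
        truth_rows, columns=["contig", "start", "ebox_class", "zone"]
    )
    return sequences, peaks, truth


def gen_pseudobulk(
    layout: Sequence[int] = DEFAULT_LAYOUT,
    n_regions: Mapping[str, int] | int = 500,
    amplitude: float = 4.0,
    noise_sd: Optional[float] = None,
    baseline: float = 3.0,
    seed: int = 0,
) -> tuple[PseudobulkMatrix, pd.DataFrame]:
    """Trajectory-shaped pseudobulk count matrix.

    Per region, the log2 signal is baseline + amplitude * template + Gaussian
    noise (default sd = 0.25 * amplitude), rounded from its exponential into
    counts.  ``n_regions`` is either a per-group mapping over
    {falling, transient, neuronal, invariant} or one count applied to each.
    Truth records the template (or invariant) per region.
    """
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = 0.25 * amplitude
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(n_regions, int):
        n_regions = {g: n_regions
                     for g in ("falling", "transient", "neuronal", "invariant")}
    block_names = CELL_TYPE_ORDER[: len(layout)]
    templates = build_templates(layout, block_names)
    by_group: dict[str, list[TrajectoryTemplate]] = {}
    for t in templates:
        by_group.setdefault(t.group, []).append(t)
    total = int(np.sum(layout))
    rows, truth_rows, region_ids = [], [], []
    i = 0
    for group, n in n_regions.items():
        for _ in range(n):
            rid = f"region_{i:05d}"
            if group == "invariant":
                vec = np.zeros(total)
                tname = None
            else:
                t = by_group[group][rng.integers(len(by_group[group]))]
                vec = np.asarray(t.vector, dtype=float)
                tname = t.name
            log_sig = baseline + amplitude * vec + rng.normal(0, noise_sd, total)
            rows.append(np.rint(2.0 ** log_sig))
            truth_rows.append((rid, group, tname))
            region_ids.append(rid)
            i += 1
    values = np.vstack(rows)
    labels = tuple(
        name for name, k in zip(block_names, layout) for _ in range(k)
    )
    pb = PseudobulkMatrix(values, labels, tuple(region_ids))
    truth = pd.DataFrame(truth_rows, columns=["region", "group", "template"])
    return pb, truth


def gen_expression_coupled_cells(
    n_cells: int = 2000,
    target_r: Sequence[float] = (0.0, 0.6, 1.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-cell TF expression plus accessibility with set correlations.

    Accessibility of region j is built from a bivariate-Gaussian construction
    with population correlation ``target_r[j]`` to the expression value.
    """
    rng = np.random.default_rng(seed)
    target_r = np.asarray(target_r, dtype=float)
    if np.any(np.abs(target_r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    expr = rng.normal(size=n_cells)
    noise = rng.normal(size=(n_cells, target_r.size))
    access = expr[:, None] * target_r + noise * np.sqrt(1 - target_r**2)
    truth = pd.DataFrame(
        {"region": [f"region_{j}" for j in range(target_r.size)],
         "target_r": target_r}
    )
    return expr, access, truth


def _read_weights(reads: list[str], affinity: Mapping[str, float]) -> np.ndarray:
    w = np.ones(len(reads))
    for label, odds in affinity.items():
        reps = get_class(label).representatives
        for i, read in enumerate(reads):
            k = sum(read.count(rep) for rep in reps)
            if k:
                w[i] *= odds ** k
    return w


def gen_selex(
    n_reads: int = 50_000,
    read_len: int = 20,
    n_rounds: int = 4,
    affinity: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> tuple[list[list[str]], pd.DataFrame]:
    """Affinity-driven SELEX rounds.

    The selected molecular pool is treated as effectively infinite: after
    ``t`` selection steps its read distribution is the random-library
    distribution tilted by ``odds**(k*t)``, with ``k`` the number of
    contained representative hexamers of each high-affinity class.  Each
    round's reads are an independent sample from that tilted pool (drawn by
    importance resampling from a fresh candidate library), the way a
    sequencing run samples a vanishing fraction of the molecules.
    """
    rng = np.random.default_rng(seed)
    affinity = dict(affinity or {})
    rounds = []
    for t in range(n_rounds):
        n_cand = n_reads if t == 0 or not affinity else 4 * n_reads
        cand = [
            "".join(_BASES[rng.integers(0, 4, read_len)])
            for _ in range(n_cand)
        ]
        if t == 0 or not affinity:
            rounds.append(cand[:n_reads])
            continue
        tilted = {label: odds ** t for label, odds in affinity.items()}
        w = _read_weights(cand, tilted)
        idx = rng.choice(n_cand, size=n_reads, replace=True, p=w / w.sum())
        rounds.append([cand[i] for i in idx])
    truth = pd.DataFrame(
        {"ebox_class": list(CLASS_LABELS),
         "retention_odds": [affinity.get(c, 1.0) for c in CLASS_LABELS]}
    )
    return rounds, truth


def gen_sites(
    n_sites: int = 10_000,
    class_probs: Optional[Mapping[str, float]] = None,
    pss_fraction: float = 0.5,
    pss_halfwidth: int = 50,
    nss_range: tuple[int, int] = (200, 400),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic E-box site table for the selection analysis.

    Sites are laid 1 kb apart on one contig; a ``pss_fraction`` of them sit
    within ``pss_halfwidth`` of their summit, the rest inside ``nss_range``.
    Columns: site_id, contig, start, hexamer, ebox_class, summit_distance.
    """
    rng = np.random.default_rng(seed)
    if class_probs is None:
        class_probs = {c: 1 / len(CLASS_LABELS) for c in CLASS_LABELS}
    labels = list(class_probs)
    p = np.array([class_probs[c] for c in labels], dtype=float)
    p = p / p.sum()
    rows = []
    for i in range(n_sites):
        label = labels[rng.choice(len(labels), p=p)]
        reps = get_class(label).representatives
        hexamer = reps[rng.integers(len(reps))]
        if rng.random() < pss_fraction:
            d = int(rng.integers(-pss_halfwidth, pss_halfwidth + 1))
        else:
            mag = int(rng.integers(nss_range[0], nss_range[1] + 1))
            d = mag if rng.random() < 0.5 else -mag
        rows.append((f"site_{i:06d}", "simchr", 1000 * i, hexamer, label, d))
    return pd.DataFrame(
        rows,
        columns=["site_id", "contig", "start", "hexamer", "ebox_class",
                 "summit_distance"],
    )


def ebox_sites_from_frame(df: pd.DataFrame) -> list[EBoxSite]:
    """Materialize :class:`EBoxSite` objects from a site table."""
    out = []
    for row in df.itertuples(index=False):
        d = getattr(row, "summit_distance", None)
        out.append(
            EBoxSite(contig=row.contig, start=int(row.start),
                     hexamer=row.hexamer, ebox_class=row.ebox_class,
                     summit_distance=None if d is None or pd.isna(d) else int(d))
        )
    return out


def _default_species() -> tuple[list[str], dict[str, str]]:
    species, clades = [], {}
    for clade in CLADE_ORDER:
        _req, total = DEFAULT_CLADE_SCHEME.thresholds[clade]
        for i in range(total):
            name = f"{clade}_{i:02d}"
            species.append(name)
            clades[name] = clade
    return species, clades


def gen_alignments_and_variants(
    sites_df: pd.DataFrame,
    poly_rate: float = 0.2,
    outgroup_rate: float = 0.2,
    clade_rates: Optional[Mapping[str, float]] = None,
    pss_constraint_factor: float = 1.0,
    pss_halfwidth: int = 50,
    maf_sampler: Optional[Callable[[np.random.Generator], float]] = None,
    indel_rate: float = 0.0,
    make_species_blocks: bool = False,
    seed: int = 0,
) -> dict:
    """Clade-structured substitutions and MAF-distributed polymorphisms.

    Rates are expected events per motif (spread over the 6 positions).  Sites
    with |summit_distance| <= ``pss_halfwidth`` have all their rates scaled by
    ``pss_constraint_factor`` (< 1 models purifying selection at putatively
    selected sites).  ``indel_rate`` plants occasional gaps to exercise the
    exclusion rules.  MAFs default to Uniform(0, 0.5), so a known share falls
    below the 0.05 polymorphism cutoff.

    Returns a dict with keys ``variants`` (table), ``pairwise`` (site_id ->
    (ref, outgroup string)), ``blocks`` and ``species_clades`` (when
    ``make_species_blocks``), and ``truth``.
    """
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        maf_sampler = lambda r: float(r.uniform(0.0, 0.5))
    clade_rates = dict(clade_rates or {c: outgroup_rate for c in CLADE_ORDER})
    species, species_clades = _default_species()

    var_rows, pairwise, blocks, truth_rows = [], {}, {}, []
    for row in sites_df.itertuples(index=False):
        is_pss = abs(row.summit_distance) <= pss_halfwidth
        c = pss_constraint_factor if is_pss else 1.0
        hexamer = row.hexamer
        # polymorphisms
        for off in range(6):
            if rng.random() < poly_rate * c / 6:
                ref = hexamer[off]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                var_rows.append(
                    (row.contig, row.start + off, ref, alt, maf_sampler(rng))
                )
        # pairwise outgroup
        out = list(hexamer)
        for off in range(6):
            if rng.random() < outgroup_rate * c / 6:
                out[off] = str(rng.choice([b for b in "ACGT" if b != out[off]]))
        if rng.random() < indel_rate:
            out[rng.integers(6)] = "-"
        pairwise[row.site_id] = (hexamer, "".join(out))
        # per-species blocks
        if make_species_blocks:
            block = {}
            for sp in species:
                rate = clade_rates[species_clades[sp]] * c
                aln = list(hexamer)
                for off in range(6):
                    if rng.random() < rate / 6:
                        aln[off] = str(
                            rng.choice([b for b in "ACGT" if b != aln[off]])
                        )
                if rng.random() < indel_rate:
                    aln[rng.integers(6)] = "-"
                block[sp] = "".join(aln)
            blocks[row.site_id] = block
        truth_rows.append((row.site_id, is_pss, c))

    out = {
        "variants": pd.DataFrame(
            var_rows, columns=["contig", "pos", "ref", "alt", "maf"]
        ),
        "pairwise": pairwise,
        "truth": pd.DataFrame(
            truth_rows, columns=["site_id", "is_pss", "constraint"]
        ),
    }
    if make_species_blocks:
        out["blocks"] = blocks
        out["species_clades"] = species_clades
    return out


def gen_methylation(
    sites: Sequence[EBoxSite],
    baseline_pct: float = 80.0,
    dip_pct: float = 60.0,
    dip_halfwidth: int = 100,
    dip_classes: Sequence[str] = ("CAT-CAT",),
    stage_with_dip: str = "PN",
    span: int = 400,
    cpg_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[SignalTrack, SignalTrack, pd.DataFrame]:
    """Two methylation tracks (NSC, PN) with demethylation dips at motifs.

    Both stages sit at ``baseline_pct``; the dip stage drops by ``dip_pct``
    within ``dip_halfwidth`` bp of the midpoint of every site whose class is
    in ``dip_classes``.  ``cpg_fraction`` subsamples covered positions to
    emulate CpG sparsity.  Returns (track_nsc, track_pn, truth).
    """
    rng = np.random.default_rng(seed)
    if not 0 <= dip_pct <= baseline_pct:
        raise ValueError("need 0 <= dip_pct <= baseline_pct")
    per_contig: dict[str, list[EBoxSite]] = {}
    for s in sites:
        per_contig.setdefault(s.contig, []).append(s)
    tracks = {"NSC": SignalTrack(), "PN": SignalTrack()}
    for contig, ss in per_contig.items():
        lo = max(0, min(s.midpoint for s in ss) - span)
        hi = max(s.midpoint for s in ss) + span
        pos = np.arange(lo, hi)
        if cpg_fraction < 1.0:
            pos = pos[rng.random(pos.size) < cpg_fraction]
        base = np.full(pos.size, baseline_pct)
        dipped = base.copy()
        for s in ss:
            if s.ebox_class in dip_classes:
                m = np.abs(pos - s.midpoint) <= dip_halfwidth
                dipped[m] = baseline_pct - dip_pct
        for stage in ("NSC", "PN"):
            vals = dipped if stage == stage_with_dip else base
            tracks[stage].add_contig(contig, pos, pos + 1, vals)
    truth = pd.DataFrame(
        {"dip_class": list(dip_classes), "dip_pct": dip_pct,
         "stage_with_dip": stage_with_dip}
    )
    return tracks["NSC"], tracks["PN"], truth
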