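"""Accessibility trajectory classification along the neurogenic lineage.

Single cells (NSC -> IPC -> PN1 -> PN2 -> PN3) are ordered by pseudotime and
aggregated into fixed-size pseudobulk groups within each cell type.  A region
is called *invariant* when a one-way ANOVA across cell types fails to reach
p < 1e-6 on its log2 CPM profile; dynamic regions are assigned to the
trajectory (falling / transient / neuronal) whose binary template vector
correlates best (Pearson) with the profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import Peak, merge_peak_sets, overlaps_any

__all__ = [
    "CELL_TYPE_ORDER",
    "PseudobulkMatrix",
    "TrajectoryTemplate",
    "pseudobulk_aggregate",
    "log2_cpm",
    "anova_invariant",
    "build_templates",
    "assign_trajectory",
    "classify_trajectories",
    "expr_access_correlation",
    "quantile_occupancy",
    "accessible_in_cluster",
    "scaled_jaccard",
]

CELL_TYPE_ORDER = ("NSC", "IPC", "PN1", "PN2", "PN3")

DEFAULT_INVARIANT_P = 1e-6


@dataclass
class PseudobulkMatrix:
    """Regions x pseudotime-ordered pseudobulk samples."""

    values: np.ndarray                 # regions x samples
    sample_cell_types: tuple[str, ...] # one label per sample, block-ordered
    region_ids: tuple[str, ...]
    is_log: bool = False
    pseudocount: Optional[float] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.sample_cell_types)):
            raise ValueError("shape mismatch between values and labels")

    @property
    def block_sizes(self) -> tuple[int, ...]:
        sizes, last = [], None
        for ct in self.sample_cell_types:
            if ct != last:
                sizes.append(0)
                last = ct
            sizes[-1] += 1
        return tuple(sizes)

    @property
    def block_names(self) -> tuple[str, ...]:
        names, last = [], None
        for ct in self.sample_cell_types:
            if ct != last:
                names.append(ct)
                last = ct
        return tuple(names)


@dataclass(frozen=True)
class TrajectoryTemplate:
    name: str
    vector: tuple[int, ...]
    group: str  # falling | transient | neuronal


def pseudobulk_aggregate(
    cell_counts: np.ndarray,
    cell_types: Sequence[str],
    pseudotime: Sequence[float],
    group_size: int,
    region_ids: Optional[Sequence[str]] = None,
    type_order: Sequence[str] = CELL_TYPE_ORDER,
) -> PseudobulkMatrix:
    """Sum cells into consecutive pseudotime-ordered groups within cell type.

    ``cell_counts`` is cells x regions.  Within each cell type cells are
    sorted by pseudotime and chunked into blocks of ``group_size``; trailing
    cells form their own final group only when at least half a group remains,
    otherwise they merge into the previous group.  A cell type with fewer
    cells than one group contributes a single (smaller) group, with a warning.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    counts = np.asarray(cell_counts)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    cell_types = np.asarray(cell_types)
    pseudotime = np.asarray(pseudotime, dtype=float)

    cols, labels = [], []
    for ct in type_order:
        idx = np.flatnonzero(cell_types == ct)
        if idx.size == 0:
            continue
        idx = idx[np.argsort(pseudotime[idx], kind="stable")]
        if idx.size < group_size:
            warnings.warn(f"cell type {ct}: {idx.size} cells < one group")
            groups = [idx]
        else:
            n_full = idx.size // group_size
            rem = idx.size - n_full * group_size
            groups = [
                idx[i * group_size : (i + 1) * group_size] for i in range(n_full)
            ]
            if rem:
                tail = idx[n_full * group_size :]
                if rem >= group_size / 2:
                    groups.append(tail)
                else:
                    groups[-1] = np.concatenate([groups[-1], tail])
        for g in groups:
            cols.append(counts[g].sum(axis=0))
            labels.append(ct)

    values = np.column_stack(cols) if cols else np.zeros((counts.shape[1], 0))
    if region_ids is None:
        region_ids = tuple(f"region_{i}" for i in range(counts.shape[1]))
    return PseudobulkMatrix(values, tuple(labels), tuple(region_ids))


def log2_cpm(pb: PseudobulkMatrix, pseudocount: float = 1.0) -> PseudobulkMatrix:
    """log2(count / column_sum * 1e6 + pseudocount) per sample."""
    colsum = pb.values.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(f"zero column sum in sample(s) {zero.tolist()}")
    vals = np.log2(pb.values / colsum * 1e6 + pseudocount)
    return PseudobulkMatrix(vals, pb.sample_cell_types, pb.region_ids,
                            is_log=True, pseudocount=pseudocount)


def anova_invariant(
    pb: PseudobulkMatrix, threshold: float = DEFAULT_INVARIANT_P
) -> pd.DataFrame:
    """Per-region one-way ANOVA across cell types on the (normalized) values.

    Returns a frame with F, p and the invariant flag (p >= threshold, or
    degenerate zero-variance input).
    """
    ct = np.asarray(pb.sample_cell_types)
    groups = [np.flatnonzero(ct == name) for name in pb.block_names]
    if len(groups) < 2:
        raise ValueError("need at least two cell types")
    F = np.full(len(pb.region_ids), np.nan)
    p = np.ones(len(pb.region_ids))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings from scipy
        for i, row in enumerate(pb.values):
            if np.allclose(row, row[0]):
                continue  # degenerate -> invariant by convention
            res = stats.f_oneway(*[row[g] for g in groups])
            F[i], p[i] = res.statistic, res.pvalue
            if np.isnan(p[i]):
                # zero within-group variance with differing group means:
                # infinitely strong evidence of difference
                means = [row[g].mean() for g in groups]
                p[i] = 0.0 if np.ptp(means) > 0 else 1.0
    return pd.DataFrame(
        {"region": pb.region_ids, "F": F, "p": p, "invariant": p >= threshold}
    )


def build_templates(
    block_sizes: Sequence[int], block_names: Optional[Sequence[str]] = None
) -> list[TrajectoryTemplate]:
    """All single-run binary vectors with run edges on cell-type block
    boundaries, excluding the all-0 and all-1 vectors.

    Group assignment: *falling* runs start at the first sample and end before
    the last; *neuronal* runs end at the last sample and start after the
    first; *transient* runs are internal.
    """
    n_blocks = len(block_sizes)
    if block_names is None:
        block_names = [f"block{i}" for i in range(n_blocks)]
    offsets = np.concatenate([[0], np.cumsum(block_sizes)])
    total = int(offsets[-1])
    out = []
    for i in range(n_blocks):
        for j in range(i, n_blocks):
            if i == 0 and j == n_blocks - 1:
                continue  # all-1
            vec = np.zeros(total, dtype=int)
            vec[offsets[i] : offsets[j + 1]] = 1
            if i == 0:
                group = "falling"
            elif j == n_blocks - 1:
                group = "neuronal"
            else:
                group = "transient"
            name = (
                block_names[i] if i == j else f"{block_names[i]}-{block_names[j]}"
            )
            out.append(TrajectoryTemplate(name, tuple(vec), group))
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0:
        return np.nan
    return float((xd * yd).sum() / denom)


def assign_trajectory(
    vector: np.ndarray,
    templates: Sequence[TrajectoryTemplate],
    anova_p: float,
    threshold: float = DEFAULT_INVARIANT_P,
) -> tuple[str, Optional[str], float]:
    """Label one region: ``(label, best_template_name, pearson_r)``.

    Invariant when the ANOVA p-value fails the threshold or the region vector
    has zero variance; otherwise the template with the highest Pearson r wins
    (ties broken by enumeration order).
    """
    vector = np.asarray(vector, dtype=float)
    if anova_p >= threshold or np.allclose(vector, vector[0]):
        return "invariant", None, np.nan
    best, best_r = None, -np.inf
    for t in templates:
        r = _pearson(vector, np.asarray(t.vector, dtype=float))
        if np.isfinite(r) and r > best_r:
            best, best_r = t, r
    if best is None:
        return "invariant", None, np.nan
    return best.group, best.name, best_r


def classify_trajectories(
    pb: PseudobulkMatrix,
    threshold: float = DEFAULT_INVARIANT_P,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full trajectory calling: log2 CPM (unless already normalized), ANOVA
    invariance, then template correlation for dynamic regions."""
    norm = log2_cpm(pb) if (normalize and not pb.is_log) else pb
    templates = build_templates(norm.block_sizes, norm.block_names)
    anova = anova_invariant(norm, threshold)
    rows = []
    for i, rid in enumerate(norm.region_ids):
        label, tname, r = assign_trajectory(
            norm.values[i], templates, anova["p"].iat[i], threshold
        )
        rows.append((rid, label, tname, r, anova["p"].iat[i]))
    return pd.DataFrame(
        rows, columns=["region", "label", "best_template", "pearson_r", "anova_p"]
    )


def expr_access_correlation(
    expression: np.ndarray,
    cell_access: np.ndarray,
    group_size: int = 50,
) -> np.ndarray:
    """Per-region Pearson r between mean TF expression and mean accessibility
    over expression-ordered pseudobulk groups of ``group_size`` cells."""
    expression = np.asarray(expression, dtype=float)
    access = np.asarray(cell_access, dtype=float)
    order = np.argsort(expression, kind="stable")
    n_full = order.size // group_size
    if n_full < 2:
        raise ValueError("need at least 2 groups")
    rem = order.size - n_full * group_size
    bounds = [order[i * group_size : (i + 1) * group_size] for i in range(n_full)]
    if rem:
        tail = order[n_full * group_size :]
        if rem >= group_size / 2:
            bounds.append(tail)
        else:
            bounds[-1] = np.concatenate([bounds[-1], tail])
    mean_expr = np.array([expression[g].mean() for g in bounds])
    mean_acc = np.vstack([access[g].mean(axis=0) for g in bounds])
    out = np.array([_pearson(mean_expr, mean_acc[:, j])
                    for j in range(mean_acc.shape[1])])
    return out


def quantile_occupancy(
    regions: Sequence[Peak],
    scores: Sequence[float],
    bound_sets: dict[str, Sequence[Peak]],
    n_bins: int = 50,
) -> pd.DataFrame:
    """Bound fraction per score-quantile bin, plus the top/bottom fold.

    Regions are ranked by score into ``n_bins`` near-equal bins (bin 0 =
    lowest scores).  For each bound set the fraction of regions overlapping
    it is reported per bin; the fold is top-bin / bottom-bin fraction
    (infinite when the bottom bin has none).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(scores, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    for name, bset in bound_sets.items():
        merged = merge_peak_sets(bset)
        flags = np.array([overlaps_any(r, merged) for r in regions])
        fracs = [flags[b].mean() if len(b) else np.nan for b in bins]
        fold = fracs[-1] / fracs[0] if fracs[0] > 0 else np.inf
        for k, f in enumerate(fracs):
            rows.append((name, k, f, fold))
    return pd.DataFrame(rows, columns=["bound_set", "bin", "fraction", "fold"])


def accessible_in_cluster(cluster_counts: np.ndarray, min_frac: float = 0.03) -> bool:
    """A region counts as accessible in a cell cluster when at least
    ``min_frac`` of the cells carry >= 1 count (boundary inclusive)."""
    counts = np.asarray(cluster_counts)
    if counts.size == 0:
        raise ValueError("empty cluster")
    return bool((counts >= 1).mean() >= min_frac)


def scaled_jaccard(
    query_sets: dict[str, Sequence[Peak]],
    reference_sets: dict[str, Sequence[Peak]],
) -> pd.DataFrame:
    """Base-pair Jaccard matrix, each query row scaled by its row maximum."""
    from .regions import interval_jaccard

    mat = pd.DataFrame(
        {
            ref: [interval_jaccard(q, r) for q in query_sets.values()]
            for ref, r in reference_sets.items()
        },
        index=list(query_sets),
    )
    rowmax = mat.max(axis=1)
    scaled = mat.div(rowmax.where(rowmax > 0, 1.0), axis=0)
    return scaled
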