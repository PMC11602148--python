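"""HT-SELEX round-wise E-box class enrichment.

For each selection round, the fraction of reads carrying at least one
representative hexamer of each class is computed (a read may count toward
several classes).  Matching the forward strand against both representatives
of a class makes detection strand-insensitive.  Enrichment across rounds is
summarized by a least-squares slope over the round index and a
strictly-monotone-increase flag.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .eboxes import enumerate_classes

__all__ = ["round_class_fractions", "enrichment_trend"]


def round_class_fractions(rounds: Sequence[Sequence[str]]) -> pd.DataFrame:
    """class x round matrix of the fraction of reads carrying each class.

    The denominator is all reads in the round (reads shorter than 6 nt are
    skipped with a warning); hexamers containing N never match.
    """
    if len(rounds) < 1:
        raise ValueError("need at least one round")
    classes = enumerate_classes()
    mat = np.zeros((len(classes), len(rounds)))
    for r, reads in enumerate(rounds):
        n = 0
        short = 0
        hits = np.zeros(len(classes), dtype=np.int64)
        for read in reads:
            if len(read) < 6:
                short += 1
                continue
            n += 1
            seq = read.upper()
            for k, cls in enumerate(classes):
                if any(rep in seq for rep in cls.representatives):
                    hits[k] += 1
        if short:
            warnings.warn(f"round {r}: skipped {short} reads shorter than 6 nt")
        if n == 0:
            raise ValueError(f"round {r} has no usable reads")
        mat[:, r] = hits / n
    return pd.DataFrame(
        mat, index=[c.label for c in classes],
        columns=[f"round_{r + 1}" for r in range(len(rounds))],
    ).rename_axis("ebox_class")


def enrichment_trend(fractions: pd.DataFrame) -> pd.DataFrame:
    """Per-class slope across rounds and a strict monotone-increase flag."""
    if fractions.shape[1] < 2:
        raise ValueError("need at least two rounds")
    x = np.arange(fractions.shape[1], dtype=float)
    rows = []
    for cls, row in fractions.iterrows():
        y = row.to_numpy(dtype=float)
        slope = float(np.polyfit(x, y, 1)[0])
        monotone = bool(np.all(np.diff(y) > 0))
        rows.append((cls, slope, monotone))
    return pd.DataFrame(rows, columns=["ebox_class", "slope", "monotone"])
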