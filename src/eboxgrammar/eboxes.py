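"""E-box alphabet: canonical classes, genome scanning and half-site flanks.

An E-box is the hexanucleotide CANNTG bound by bHLH transcription-factor
dimers.  Each monomer contacts one CAN trinucleotide half-site, the two
half-sites lying on opposing strands; an E-box is therefore named by its two
5'->3' half-sites (e.g. CAGATG = CATCTG on the other strand = "CAT-CAG").
Collapsing the 16 CANNTG hexamers under reverse complementation yields 10
strand-symmetric classes: 4 homotypic (palindromic hexamers, one
representative each) and 6 heterotypic (two representatives each).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

__all__ = [
    "EBoxClass",
    "EBoxSite",
    "CLASS_LABELS",
    "enumerate_classes",
    "canonical_class",
    "scan_eboxes",
    "half_site_flanks",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

HALF_SITES = ("CAA", "CAC", "CAG", "CAT")

# Fixed label table: half-site ordering within a heterotypic name follows the
# published nomenclature (CAT-CAG, CAG-CAC, but CAA-CAT) and is not derivable
# from a single lexical rule, hence a lookup rather than sorting.
_LABEL_PAIRS: tuple[tuple[str, str], ...] = (
    ("CAT", "CAT"),
    ("CAT", "CAG"),
    ("CAT", "CAC"),
    ("CAG", "CAG"),
    ("CAG", "CAC"),
    ("CAC", "CAC"),
    ("CAA", "CAT"),
    ("CAA", "CAG"),
    ("CAA", "CAC"),
    ("CAA", "CAA"),
)

CLASS_LABELS: tuple[str, ...] = tuple(f"{a}-{b}" for a, b in _LABEL_PAIRS)

_EBOX_RE = re.compile(r"(?=(CA[ACGT]{2}TG))")


def revcomp(seq: str) -> str:
    """Reverse complement over the alphabet ACGTN."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EBoxClass:
    """One of the 10 strand-symmetric CANNTG classes.

    Attributes
    ----------
    label : str
        Canonical name, e.g. ``"CAT-CAG"``.
    half_a, half_b : str
        The two CAN half-sites (order as in the label).
    representatives : tuple[str, ...]
        Forward-strand hexamers belonging to the class: one for homotypic
        classes (self-reverse-complement), two for heterotypic.
    """

    label: str
    half_a: str
    half_b: str
    representatives: tuple[str, ...]

    @property
    def homotypic(self) -> bool:
        return self.half_a == self.half_b


def _build_classes() -> tuple[EBoxClass, ...]:
    classes = []
    for a, b in _LABEL_PAIRS:
        # hexamer with half_a read forward = half_a + revcomp(half_b)
        reps = {a + revcomp(b), b + revcomp(a)}
        classes.append(
            EBoxClass(label=f"{a}-{b}", half_a=a, half_b=b,
                      representatives=tuple(sorted(reps)))
        )
    return tuple(classes)


_CLASSES: tuple[EBoxClass, ...] = _build_classes()
_CLASS_BY_LABEL: dict[str, EBoxClass] = {c.label: c for c in _CLASSES}
_CLASS_BY_HEXAMER: dict[str, EBoxClass] = {
    rep: c for c in _CLASSES for rep in c.representatives
}


def enumerate_classes() -> list[EBoxClass]:
    """Return the 10 E-box classes in fixed canonical order."""
    return list(_CLASSES)


def get_class(label: str) -> EBoxClass:
    """Look up an :class:`EBoxClass` by its label."""
    return _CLASS_BY_LABEL[label]


def canonical_class(hexamer: str) -> Optional[str]:
    """Map a hexamer to its E-box class label, or ``None`` if not CANNTG.

    Strand-invariant: ``canonical_class(x) == canonical_class(revcomp(x))``.

    Raises
    ------
    ValueError
        If the input is not exactly 6 characters long.
    """
    if len(hexamer) != 6:
        raise ValueError(f"expected a hexamer, got {len(hexamer)} characters")
    cls = _CLASS_BY_HEXAMER.get(hexamer.upper())
    return cls.label if cls is not None else None


@dataclass(frozen=True)
class EBoxSite:
    """A located CANNTG occurrence on the forward strand.

    ``flank_a`` is the dinucleotide immediately upstream of the forward
    half-site; ``flank_b`` the dinucleotide upstream of the reverse-strand
    half-site, read 5'->3' on that strand.  ``summit_distance`` is the signed
    offset (bp) from the hexamer midpoint to the associated peak summit, when
    a peak context exists.
    """

    contig: str
    start: int
    hexamer: str
    ebox_class: str
    flank_a: str = "NN"
    flank_b: str = "NN"
    summit_distance: Optional[int] = None

    @property
    def half_a(self) -> str:
        return self.hexamer[:3]

    @property
    def half_b(self) -> str:
        return revcomp(self.hexamer[3:])

    @property
    def midpoint(self) -> int:
        # integer convention: midpoint of [start, start+6) taken as start+3
        return self.start + 3

    def with_summit(self, summit: int) -> "EBoxSite":
        return replace(self, summit_distance=self.midpoint - summit)


def _flanks_at(sequence: str, start: int) -> tuple[str, str]:
    n = len(sequence)
    up = "".join(
        sequence[i] if 0 <= i < n else "N" for i in (start - 2, start - 1)
    )
    down = "".join(
        sequence[i] if 0 <= i < n else "N" for i in (start + 6, start + 7)
    )
    return up.upper(), revcomp(down.upper())


def half_site_flanks(site: EBoxSite, sequence: str) -> tuple[str, str]:
    """Upstream flanking dinucleotides of the two half-sites.

    ``flank_a`` = sequence[start-2:start]; ``flank_b`` = reverse complement of
    sequence[start+6:start+8] (so it reads 5'->3' on the reverse strand, just
    upstream of the reverse half-site).  Positions beyond the sequence ends
    are padded with ``N``.
    """
    return _flanks_at(sequence, site.start)


def scan_eboxes(
    sequence: str,
    contig: str = "",
    offset: int = 0,
    summit: Optional[int] = None,
) -> list[EBoxSite]:
    """Find every CANNTG occurrence on the forward strand of ``sequence``.

    Overlapping occurrences are all reported.  Scanning the forward strand is
    complete: a reverse-strand E-box is itself a forward-strand E-box, and
    canonicalization absorbs strand.  Hexamers containing ``N`` never match;
    flanks may contain ``N``.

    Parameters
    ----------
    offset : int
        Added to every reported start (coordinates of ``sequence[0]``).
    summit : int, optional
        Absolute summit position; when given, each site carries its signed
        midpoint-to-summit distance.
    """
    seq = sequence.upper()
    sites = []
    for m in _EBOX_RE.finditer(seq):
        i = m.start()
        hexamer = m.group(1)
        fa, fb = _flanks_at(seq, i)
        d = (offset + i + 3) - summit if summit is not None else None
        sites.append(
            EBoxSite(
                contig=contig,
                start=offset + i,
                hexamer=hexamer,
                ebox_class=_CLASS_BY_HEXAMER[hexamer].label,
                flank_a=fa,
                flank_b=fb,
                summit_distance=d,
            )
        )
    return sites


def class_table():
    """The class table as a DataFrame (label, half sites, representatives)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [c.label for c in _CLASSES],
            "half_a": [c.half_a for c in _CLASSES],
            "half_b": [c.half_b for c in _CLASSES],
            "representatives": [",".join(c.representatives) for c in _CLASSES],
        }
    )


def sites_from_sequences(
    sequences: dict[str, str],
    peaks: Optional[Iterable] = None,
) -> list[EBoxSite]:
    """Scan a set of contigs; with ``peaks``, restrict to peak intervals and
    attach summit distances (one scan per peak, coordinates absolute)."""
    if peaks is None:
        out: list[EBoxSite] = []
        for name, seq in sequences.items():
            out.extend(scan_eboxes(seq, contig=name))
        return out
    out = []
    for pk in peaks:
        seq = sequences[pk.contig][pk.start : pk.end]
        out.extend(
            scan_eboxes(seq, contig=pk.contig, offset=pk.start, summit=pk.summit)
        )
    return out
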