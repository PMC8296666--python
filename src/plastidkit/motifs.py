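"""Sigma70-type promoter element scanning with spacing constraints.

The plastid-encoded polymerase (PEP) recognizes bacterial-type promoters
with a -10 element a few nucleotides upstream of the transcription start
point. Consensus patterns use IUPAC letters with case semantics:
uppercase positions are strongly conserved (weight 2), lowercase weakly
conserved (weight 1). The default -10 pattern is ``TAttaT`` and the
legal spacing between the element's 3' end and the TSS is 3-9 nt.

This module locates and verifies user-supplied consensus elements; it
performs no de novo motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import BoundsError, StateError

#: IUPAC degeneracy sets for case-insensitive base matching.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_MINUS10 = "TAttaT"
DEFAULT_SPACING = (3, 9)
MINUS35_SPACER = (15, 19)


@dataclass(frozen=True)
class ConsensusMotif:
    """An IUPAC consensus with case-encoded position weights.

    ``min_score`` defaults to the maximum attainable score minus one: all
    strongly conserved positions must match and at most one weakly
    conserved position may miss (for ``TAttaT``, score >= 8 of 9).
    """

    pattern: str
    min_score: int | None = None

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        for ch in self.pattern:
            if ch.upper() not in _IUPAC:
                raise ValueError(f"non-IUPAC pattern character {ch!r}")
        if self.min_score is not None and self.min_score > self.max_score:
            raise ValueError("min_score exceeds the maximum attainable score")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def weights(self) -> tuple[int, ...]:
        return tuple(2 if c.isupper() else 1 for c in self.pattern)

    @property
    def max_score(self) -> int:
        return sum(self.weights)

    @property
    def threshold(self) -> int:
        return self.min_score if self.min_score is not None else self.max_score - 1

    def score(self, subseq: str) -> int:
        """Sum of position weights at matching positions (case-insensitive)."""
        if len(subseq) != len(self.pattern):
            raise ValueError("subsequence length must equal pattern length")
        total = 0
        for base, patt, w in zip(subseq.upper(), self.pattern.upper(), self.weights):
            if base in _IUPAC.get(patt, ""):
                total += w
        return total


@dataclass(frozen=True)
class MotifHit:
    """One placement of a consensus element within an upstream window."""

    spacing: int  # nt between the element's 3' end and the TSS
    score: int
    matched: str  # the window subsequence under the element
    window_offset: int  # 0-based start of the element within the window

    def __post_init__(self) -> None:
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")


def extract_upstream_window(
    position: int,
    strand: str,
    genome: str,
    width: int = 50,
    *,
    circular: bool = True,
) -> str:
    """The ``width`` nt immediately 5' of a TSS, on the TSS strand.

    The TSS base itself is excluded; the returned string reads 5'->3' on
    the transcript strand (reverse-complemented for minus-strand TSSs)
    and wraps through the origin on circular genomes.
    """
    from .io import reverse_complement

    length = len(genome)
    if width > length:
        raise BoundsError(f"window width {width} exceeds genome length {length}")
    if not 0 <= position < length:
        raise BoundsError(f"TSS position {position} outside genome")
    if strand == "+":
        idx = range(position - width, position)
    else:
        idx = range(position + 1, position + 1 + width)
    if circular:
        window = "".join(genome[i % length] for i in idx)
    else:
        if idx[0] < 0 or idx[-1] >= length:
            raise BoundsError("upstream window runs off a non-circular genome")
        window = genome[idx[0] : idx[-1] + 1]
    return window if strand == "+" else reverse_complement(window)


def scan_consensus(
    window: str,
    motif: ConsensusMotif | str = DEFAULT_MINUS10,
    spacing_range: tuple[int, int] = DEFAULT_SPACING,
) -> MotifHit | None:
    """Best-scoring placement of a -10 element at legal spacing, or None.

    ``window`` must read 5'->3' with its last base immediately adjacent
    to the TSS. For each spacing s in the range, the element is laid at
    ``window[-s-m : -s]``; the highest-scoring placement with score >=
    the motif threshold wins, ties going to the smaller spacing.
    """
    if isinstance(motif, str):
        motif = ConsensusMotif(motif)
    m = len(motif)
    lo, hi = spacing_range
    if len(window) < m + hi:
        raise BoundsError(
            f"window of {len(window)} nt too short for a {m} nt motif at spacing {hi}"
        )
    best: MotifHit | None = None
    for s in range(lo, hi + 1):
        start = len(window) - s - m
        sub = window[start : start + m]
        score = motif.score(sub)
        if score >= motif.threshold and (best is None or score > best.score):
            best = MotifHit(spacing=s, score=score, matched=sub, window_offset=start)
    return best


def scan_minus35(
    window: str,
    minus10_hit: MotifHit | None,
    motif35: ConsensusMotif | str,
    spacer_range: tuple[int, int] = MINUS35_SPACER,
) -> MotifHit | None:
    """Optional -35 element 15-19 nt 5' of an existing -10 element.

    Absence is a valid result: only a minority of PEP promoters show a
    recognizable -35 box. The returned hit's ``spacing`` is the spacer
    length between the -35 element's 3' end and the -10 element's 5' end.
    """
    if minus10_hit is None:
        raise StateError("scan_minus35 requires an existing -10 hit")
    if isinstance(motif35, str):
        motif35 = ConsensusMotif(motif35)
    m = len(motif35)
    lo, hi = spacer_range
    best: MotifHit | None = None
    for g in range(lo, hi + 1):
        start = minus10_hit.window_offset - g - m
        if start < 0:
            continue
        sub = window[start : start + m]
        score = motif35.score(sub)
        if score >= motif35.threshold and (best is None or score > best.score):
            best = MotifHit(spacing=g, score=score, matched=sub, window_offset=start)
    return best
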