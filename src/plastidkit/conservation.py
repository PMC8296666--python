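"""Per-column conservation of aligned upstream regions and footprint calls.

Pentatricopeptide-repeat (PPR) proteins bind short stretches of a
transcript's 5' leader and protect it from 5'->3' exonucleolytic decay;
their binding sites show up as blocks of near-perfectly conserved
columns in multiple alignments of upstream regions across species.
This module consumes pre-computed alignments anchored at the start
codon, scores each column's majority-residue fraction, bins it for
display the way alignment-shading figures do, and calls maximal runs of
conserved columns upstream of the ATG as putative footprints.

Coordinates are ATG-relative and counted over the ungapped reference row
(the first sequence): the A of ATG is +1, the base immediately 5' of it
is -1, and there is no position 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, FormatError, ParameterError

_ALPHABET = frozenset("ACGTN-")

#: Similarity display bins, highest first: (name, inclusive lower bound).
SHADING_BINS = (
    ("black", 1.0),
    ("dark_gray", 0.8),
    ("light_gray", 0.6),
    ("white", 0.0),
)


@dataclass
class AlignmentBlock:
    """Equal-length gapped sequences with an ATG anchor column."""

    sequences: list[str]
    labels: list[str]
    anchor: int  # column index of the A of ATG

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("alignment block has no rows")
        if len(self.labels) != len(self.sequences):
            raise FormatError("one label per sequence required")
        width = len(self.sequences[0])
        for label, seq in zip(self.labels, self.sequences):
            if len(seq) != width:
                raise FormatError(f"row {label!r} has length {len(seq)} != {width}")
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise FormatError(f"row {label!r} contains {sorted(bad)}")
        if not 0 <= self.anchor < width:
            raise BoundsError(f"anchor column {self.anchor} outside alignment")

    @property
    def n_rows(self) -> int:
        return len(self.sequences)

    @property
    def n_cols(self) -> int:
        return len(self.sequences[0])

    def column(self, idx: int) -> str:
        return "".join(seq[idx] for seq in self.sequences)


@dataclass
class ColumnSimilarity:
    """Per-column majority fraction and display bin."""

    fractions: np.ndarray
    bins: list[str]


@dataclass(frozen=True)
class FootprintCall:
    """A maximal conserved run upstream of the ATG (putative PPR site)."""

    start_offset: int  # ATG-relative, inclusive (negative = upstream)
    end_offset: int  # ATG-relative, inclusive
    length: int  # number of columns
    mean_similarity: float


def bin_for(fraction: float) -> str:
    """Display bin for a similarity fraction: black == 1.0, dark gray
    [0.8, 1.0), light gray [0.6, 0.8), white below 0.6."""
    for name, lower in SHADING_BINS:
        if fraction >= lower:
            return name
    return "white"


def column_similarity(
    block: AlignmentBlock, *, ignore_gap_rows: bool = False
) -> ColumnSimilarity:
    """Majority-residue fraction per column.

    The most frequent A/C/G/T residue is counted; N never counts toward
    the majority. By default gap rows stay in the denominator (a gapped
    species is evidence against conservation); ``ignore_gap_rows`` drops
    them from it instead. An all-gap column scores 0.
    """
    fractions = np.zeros(block.n_cols)
    for col in range(block.n_cols):
        residues = block.column(col).upper()
        counts = {b: residues.count(b) for b in "ACGT"}
        top = max(counts.values())
        denom = block.n_rows
        if ignore_gap_rows:
            denom -= residues.count("-")
        fractions[col] = top / denom if denom > 0 else 0.0
    return ColumnSimilarity(fractions, [bin_for(f) for f in fractions])


def to_atg_coordinates(block: AlignmentBlock, column: int) -> int:
    """ATG-relative signed offset of an alignment column.

    Offsets count ungapped reference-row positions: the anchor column is
    +1 and the base immediately 5' of the ATG is -1 (no 0). A column
    where the reference is gapped takes the offset of the nearest
    reference base toward the anchor.
    """
    if not 0 <= column < block.n_cols:
        raise BoundsError(f"column {column} outside alignment of width {block.n_cols}")
    ref = block.sequences[0]
    if column < block.anchor:
        n = sum(1 for c in ref[column : block.anchor] if c != "-")
        return -n if n > 0 else -1
    n = sum(1 for c in ref[block.anchor : column + 1] if c != "-")
    return max(n, 1)


def detect_footprints(
    block: AlignmentBlock,
    similarity: ColumnSimilarity | None = None,
    *,
    threshold: float = 0.8,
    min_len: int = 6,
    search_window: tuple[int, int] = (-100, -1),
) -> list[FootprintCall]:
    """Maximal runs of conserved columns upstream of the start codon.

    A run is >= ``min_len`` consecutive columns with similarity >=
    ``threshold`` whose offsets fall inside ``search_window`` (inclusive
    ATG-relative bounds, both negative). Runs never bridge a
    sub-threshold column; calls are non-overlapping and sorted 5'->3'.
    """
    if not -1 >= search_window[1] >= search_window[0]:
        raise ParameterError("search window must be upstream of the anchor")
    if similarity is None:
        similarity = column_similarity(block)
    offsets = [to_atg_coordinates(block, c) for c in range(block.n_cols)]
    eligible = [
        c
        for c in range(block.n_cols)
        if search_window[0] <= offsets[c] <= search_window[1]
    ]
    calls: list[FootprintCall] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= min_len:
            frs = similarity.fractions[run]
            calls.append(
                FootprintCall(
                    start_offset=offsets[run[0]],
                    end_offset=offsets[run[-1]],
                    length=len(run),
                    mean_similarity=float(frs.mean()),
                )
            )

    prev = None
    for c in eligible:
        good = similarity.fractions[c] >= threshold
        if good and (not run or c == prev + 1):
            run.append(c)
        else:
            flush()
            run = [c] if good else []
        prev = c
    flush()
    return calls


def read_alignment_fasta(path, anchor: int | None = None) -> AlignmentBlock:
    """Load an aligned FASTA as a block, locating the ATG anchor.

    When ``anchor`` is omitted the reference (first) row is scanned for
    its 3'-terminal ATG triplet (ignoring gaps), matching the convention
    of upstream alignments that end at the start codon.
    """
    from .io import read_fasta

    seqs = read_fasta(path)
    labels = list(seqs)
    sequences = [seqs[k] for k in labels]
    if anchor is None:
        ref = sequences[0].upper()
        bases = [i for i, c in enumerate(ref) if c != "-"]
        if len(bases) < 3 or ref[bases[-3]] + ref[bases[-2]] + ref[bases[-1]] != "ATG":
            raise FormatError("reference row does not end in ATG; pass anchor explicitly")
        anchor = bases[-3]
    return AlignmentBlock(sequences, labels, anchor)
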