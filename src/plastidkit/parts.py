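"""Expression-part extraction and Type IIS common-syntax rules.

Promoter and 5'UTR fragments located by TSS mapping become reusable DNA
parts for hierarchical (Loop) assembly. The standard plant common syntax
joins a 5'UTR part to a CDS through an AATG overhang, which inserts one
extra adenosine immediately 5' of the start codon; a customized ATGg
overhang avoids the insertion but requires the fourth CDS base to be G.
Parts must be free of internal BsaI (GGTCTC) and SapI (GCTCTTC)
recognition sites on either strand ("domesticated") to be usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import BoundsError, FormatError, OrientationError, ParameterError
from .io import GenomeAnnotation, reverse_complement

PART_KINDS = ("promoter", "five_prime_utr", "promoter_utr", "cds")
SYNTAX_MODES = ("standard_AATG", "custom_ATGg", "none")

#: Type IIS recognition sequences checked during domestication.
RECOGNITION_SITES = {"BsaI": "GGTCTC", "SapI": "GCTCTTC"}


@dataclass(frozen=True)
class ExpressionPart:
    """A sequence fragment reported 5'->3' on its transcript strand."""

    kind: str
    sequence: str
    start: int  # genomic interval, 0-based half-open, forward axis
    end: int
    strand: str
    name: str = ""
    syntax_mode: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in PART_KINDS:
            raise ParameterError(f"unknown part kind {self.kind!r}")
        if self.syntax_mode not in SYNTAX_MODES:
            raise ParameterError(f"unknown syntax mode {self.syntax_mode!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FootprintMutation:
    """A targeted disruption of a putative PPR-binding footprint."""

    start: int  # relative to the part, 0-based half-open
    end: int
    strategy: str = "transversion"  # or "shuffle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("transversion", "shuffle"):
            raise ParameterError(f"unknown mutation strategy {self.strategy!r}")
        if not 0 <= self.start < self.end:
            raise BoundsError(f"invalid mutation interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class Fusion:
    """A 5'UTR-CDS junction assembled under one syntax mode."""

    sequence: str
    junction: int  # index of the first CDS base (the A of ATG)
    mode: str
    inserted_adenosine: bool


def _slice(genome: str, start: int, end: int, strand: str, circular: bool) -> str:
    length = len(genome)
    if start < 0 or end > length:
        if not circular:
            raise BoundsError(f"interval [{start}, {end}) outside linear genome")
        seq = "".join(genome[i % length] for i in range(start, end))
    else:
        seq = genome[start:end]
    return seq if strand == "+" else reverse_complement(seq)


def extract_part(
    genome: str,
    annotation: GenomeAnnotation,
    gene_id: str,
    *,
    kind: str = "five_prime_utr",
    tss: int | None = None,
    upstream: int | None = None,
    interval: tuple[int, int] | None = None,
    name: str = "",
) -> ExpressionPart:
    """Extract a promoter/5'UTR/CDS fragment for a gene, strand-aware.

    For ``five_prime_utr`` supply the TSS: the part runs from the TSS to
    the base immediately before the start codon, so its length equals the
    TSS-to-ATG distance. For ``promoter_utr`` supply ``upstream``, the
    number of nucleotides before the start codon (e.g. the full 185 nt
    rbcL promoter + leader). ``promoter`` takes an explicit genomic
    interval; ``cds`` takes none and returns the annotated gene body.
    """
    gene = annotation.get(gene_id)
    circular = annotation.circular
    length = annotation.genome_length
    g5 = gene.five_prime_start  # genomic coordinate of the A of ATG

    if kind == "cds":
        seq = _slice(genome, gene.start, gene.end, gene.strand, circular)
        return ExpressionPart(kind, seq, gene.start, gene.end, gene.strand, name or gene_id)

    if kind == "promoter":
        if interval is None:
            raise ParameterError("promoter extraction needs an explicit interval")
        start, end = interval
        seq = _slice(genome, start, end, gene.strand, circular)
        return ExpressionPart(kind, seq, start % length, end % length, gene.strand, name or gene_id)

    if kind == "promoter_utr":
        if upstream is None:
            raise ParameterError("promoter_utr extraction needs an upstream length")
        d = upstream
    elif kind == "five_prime_utr":
        if tss is None:
            raise ParameterError("five_prime_utr extraction needs a TSS position")
        if gene.strand == "+":
            d = g5 - tss
            if circular:
                d %= length
        else:
            d = tss - g5
            if circular:
                d %= length
        if circular and d > length // 2:
            raise OrientationError(
                f"TSS {tss} lies downstream of the {gene_id} start codon"
            )
        if d < 0:
            raise OrientationError(
                f"TSS {tss} lies downstream of the {gene_id} start codon"
            )
        if d == 0:
            raise ParameterError(
                f"TSS coincides with the {gene_id} start codon: zero-length UTR"
            )
    else:
        raise ParameterError(f"unknown part kind {kind!r}")

    if gene.strand == "+":
        start, end = g5 - d, g5
    else:
        start, end = g5 + 1, g5 + 1 + d
    seq = _slice(genome, start, end, gene.strand, circular)
    return ExpressionPart(kind, seq, start % length, ((end - 1) % length) + 1, gene.strand, name or gene_id)


def apply_common_syntax(utr, cds: str, mode: str = "standard_AATG") -> Fusion:
    """Fuse a 5'UTR part to a CDS under the chosen overhang syntax.

    ``standard_AATG`` inserts one adenosine between the UTR and the ATG
    (fusion length = UTR + CDS + 1); ``custom_ATGg`` joins them directly
    but requires the fourth CDS base to be G (fusion length = UTR + CDS).
    """
    utr_seq = utr.sequence if isinstance(utr, ExpressionPart) else str(utr)
    if not cds.upper().startswith("ATG"):
        raise FormatError("CDS must begin with ATG")
    if mode == "standard_AATG":
        return Fusion(utr_seq + "A" + cds, junction=len(utr_seq) + 1,
                      mode=mode, inserted_adenosine=True)
    if mode == "custom_ATGg":
        if len(cds) < 4 or cds[3].upper() != "G":
            raise FormatError("custom ATGg overhang requires the fourth CDS base to be G")
        return Fusion(utr_seq + cds, junction=len(utr_seq), mode=mode,
                      inserted_adenosine=False)
    raise ParameterError(f"unknown syntax mode {mode!r}")


def domestication_check(sequence: str) -> list[tuple[str, int, str]]:
    """All BsaI/SapI recognition sites on either strand of a sequence.

    Returns (enzyme, 0-based position of the match in the given
    sequence, strand) tuples; an empty list means the part is
    domesticated and safe for Type IIS assembly.
    """
    seq = sequence.upper()
    hits: list[tuple[str, int, str]] = []
    for enzyme, site in RECOGNITION_SITES.items():
        for probe, strand in ((site, "+"), (reverse_complement(site), "-")):
            start = seq.find(probe)
            while start != -1:
                hits.append((enzyme, start, strand))
                start = seq.find(probe, start + 1)
    return sorted(hits, key=lambda h: (h[1], h[0], h[2]))


_TRANSVERSION = str.maketrans("ACGTacgt", "CATGcatg")


def mutate_footprint(part: ExpressionPart, mutation: FootprintMutation) -> ExpressionPart:
    """Disrupt a footprint interval within a part, length-preserving.

    ``transversion`` maps A<->C and G<->T at every targeted base (a
    fixed-point-free involution, so every base changes and applying it
    twice restores the original); ``shuffle`` applies a seeded random
    permutation of the interval. The mutated part is re-checked for
    accidentally introduced BsaI/SapI sites, which raise a warning.
    """
    if mutation.end > len(part):
        raise BoundsError(
            f"mutation interval [{mutation.start}, {mutation.end}) outside part of "
            f"length {len(part)}"
        )
    seq = part.sequence
    segment = seq[mutation.start : mutation.end]
    if mutation.strategy == "transversion":
        new_segment = segment.translate(_TRANSVERSION)
    else:
        rng = np.random.default_rng(mutation.seed)
        new_segment = "".join(np.array(list(segment))[rng.permutation(len(segment))])
    mutated = seq[: mutation.start] + new_segment + seq[mutation.end :]
    before = set(domestication_check(seq))
    after = set(domestication_check(mutated))
    introduced = after - before
    if introduced:
        warnings.warn(
            f"footprint mutation introduced Type IIS sites: {sorted(introduced)}",
            stacklevel=2,
        )
    return replace(part, sequence=mutated, name=f"{part.name}_{mutation.strategy}" if part.name else mutation.strategy)
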