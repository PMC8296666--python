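"""Three-tier TSS calling from TEX+/TEX- tracks and four-way classification.

Tier rules (evaluated on per-million-normalized 5'-end tracks):

* **Tier 1** — a 5' end with (i) coverage strictly > 2 per million in
  both libraries, (ii) a local maximum at the identical nucleotide in
  both libraries, and (iii) TEX+/TEX- enrichment strictly > 1.
* **Tier 2** — a 5' end meeting (i) and (ii) but not enriched is rescued
  when it "extends into" an annotated gene: it lies inside a same-strand
  gene, or a same-strand gene start lies within the extension limit
  downstream with near-continuous TEX- body coverage in between.
* **Tier 3** — remaining candidates are rescued when gene extension
  holds *and* a -10 promoter element sits at legal spacing *and* the
  TEX+ 5'-end signal clears a minimal floor.

Classification by genomic location: inside a same-strand gene -> iTSS;
inside an opposite-strand gene -> aTSS; within the upstream window of a
same-strand gene start -> gTSS (distance recorded); otherwise oTSS.
Containment beats upstream proximity, so a TSS inside the upstream gene
of an operon is internal even when it is also upstream of the next gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .coverage import CoverageTrackPair, normalize_pair
from .errors import StateError
from .io import GenomeAnnotation
from .motifs import (
    DEFAULT_MINUS10,
    DEFAULT_SPACING,
    ConsensusMotif,
    extract_upstream_window,
    scan_consensus,
)

TSS_CLASSES = ("gTSS", "iTSS", "aTSS", "oTSS")


@dataclass
class ClassifierConfig:
    """Thresholds of the tier rules and the location classifier.

    The printed tier-1 rule fixes only the 2-per-million floor and the
    >1 enrichment; everything else here is an operational choice and
    configurable: the gTSS upstream window (300 nt, conservative against
    the largest printed gTSS distances of ~144 nt), the gene-extension
    limit and continuity requirements for tier 2, the tier-3 TEX+ floor
    that keeps chance motifs at background positions out, and the
    candidate merge distance of the peak detector.
    """

    upstream_window: int = 300  # W, nt: gTSS search range upstream of starts
    extension_limit: int = 500  # D, nt: max gap for "extends into a gene"
    continuity_floor: float = 1.0  # per-million body coverage floor
    continuity_fraction: float = 0.9  # fraction of gap bases above floor
    min_coverage: float = 2.0  # tier-1 per-million floor, both libraries
    tier3_min_tex_plus: float = 0.5  # per-million TEX+ floor for tier 3
    merge_distance: int = 5  # nt: candidates closer than this are merged
    local_max_window: int = 3  # nt: half-width of the local-maximum test

    def __post_init__(self) -> None:
        for name in (
            "upstream_window", "extension_limit", "continuity_floor",
            "continuity_fraction", "min_coverage", "tier3_min_tex_plus",
            "merge_distance", "local_max_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TSSCandidate:
    """A strand-specific local maximum of the TEX+ 5'-end track."""

    position: int
    strand: str
    tex_plus_5p: float
    tex_minus_5p: float
    same_start: bool  # TEX- local maximum at the identical nucleotide


@dataclass
class TSSRecord:
    """An accepted transcription start site."""

    position: int
    strand: str
    tier: int
    tex_plus_5p: float
    tex_minus_5p: float
    enrichment: float | None  # undefined when TEX- is zero
    tss_class: str = "oTSS"
    gene_id: str | None = None
    distance: int | None = None  # nt to the downstream start codon (gTSS)


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


def _local_maxima(arr: np.ndarray, half_width: int, circular: bool) -> np.ndarray:
    mode = "wrap" if circular else "nearest"
    filt = maximum_filter1d(arr, size=2 * half_width + 1, mode=mode)
    return (arr > 0) & (arr >= filt)


def detect_candidates(
    pair: CoverageTrackPair,
    config: ClassifierConfig | None = None,
    *,
    circular: bool = True,
) -> list[TSSCandidate]:
    """Strand-specific TEX+ 5'-end peaks, merged within the merge distance.

    Peaks closer together than ``merge_distance`` collapse to the one
    with the highest TEX+ value (leftmost on ties). ``same_start`` is
    true when the TEX- 5'-end track also has a local maximum at exactly
    that nucleotide.
    """
    if config is None:
        config = ClassifierConfig()
    if not pair.normalized:
        raise StateError("detect_candidates requires a normalized pair")
    out: list[TSSCandidate] = []
    for strand in "+-":
        tp = pair.tex_plus.five_prime.values(strand)
        tm = pair.tex_minus.five_prime.values(strand)
        is_max_p = _local_maxima(tp, config.local_max_window, circular)
        is_max_m = _local_maxima(tm, config.local_max_window, circular)
        positions = np.flatnonzero(is_max_p)
        # merge nearby peaks, keeping the highest (first on ties)
        merged: list[int] = []
        group: list[int] = []
        for pos in positions:
            if group and pos - group[-1] > config.merge_distance:
                merged.append(max(group, key=lambda q: (tp[q], -q)))
                group = []
            group.append(int(pos))
        if group:
            merged.append(max(group, key=lambda q: (tp[q], -q)))
        for pos in merged:
            out.append(
                TSSCandidate(
                    position=pos,
                    strand=strand,
                    tex_plus_5p=float(tp[pos]),
                    tex_minus_5p=float(tm[pos]),
                    same_start=bool(is_max_m[pos] and tm[pos] > 0),
                )
            )
    return sorted(out, key=lambda c: (c.strand, c.position))


# ---------------------------------------------------------------------------
# tier rules
# ---------------------------------------------------------------------------


def _record(candidate: TSSCandidate, tier: int) -> TSSRecord:
    ratio = (
        candidate.tex_plus_5p / candidate.tex_minus_5p
        if candidate.tex_minus_5p > 0
        else None
    )
    return TSSRecord(
        position=candidate.position,
        strand=candidate.strand,
        tier=tier,
        tex_plus_5p=candidate.tex_plus_5p,
        tex_minus_5p=candidate.tex_minus_5p,
        enrichment=ratio,
    )


def call_tier1(
    candidates: list[TSSCandidate], config: ClassifierConfig | None = None
) -> tuple[list[TSSRecord], list[TSSCandidate]]:
    """Apply the strict three-part rule; everything else is deferred."""
    if config is None:
        config = ClassifierConfig()
    accepted, deferred = [], []
    for cand in candidates:
        if (
            cand.tex_plus_5p > config.min_coverage
            and cand.tex_minus_5p > config.min_coverage
            and cand.same_start
            and cand.tex_minus_5p > 0
            and cand.tex_plus_5p / cand.tex_minus_5p > 1.0
        ):
            accepted.append(_record(cand, tier=1))
        else:
            deferred.append(cand)
    return accepted, deferred


def _extends_into_gene(
    position: int,
    strand: str,
    annotation: GenomeAnnotation,
    tex_minus_cov: np.ndarray,
    config: ClassifierConfig,
) -> bool:
    """Containment in a same-strand gene, or continuous coverage to a
    same-strand gene start within the extension limit downstream."""
    length = annotation.genome_length
    circular = annotation.circular
    for gene in annotation.same_strand(strand):
        if gene.start <= position < gene.end:
            return True
    for gene in annotation.same_strand(strand):
        g5 = gene.five_prime_start
        if strand == "+":
            d = (g5 - position) % length if circular else g5 - position
        else:
            d = (position - g5) % length if circular else position - g5
        if not 0 < d <= config.extension_limit:
            continue
        if strand == "+":
            idx = np.arange(position + 1, position + d) % length
        else:
            idx = np.arange(position - d + 1, position) % length
        if idx.size == 0:
            return True
        frac = float(np.mean(tex_minus_cov[idx] >= config.continuity_floor))
        if frac >= config.continuity_fraction:
            return True
    return False


def rescue_gene_extension(
    deferred: list[TSSCandidate],
    pair: CoverageTrackPair,
    annotation: GenomeAnnotation,
    config: ClassifierConfig | None = None,
) -> tuple[list[TSSRecord], list[TSSCandidate]]:
    """Tier 2: unenriched 5' ends that extend into an annotated gene.

    Only candidates that satisfied rules (i) and (ii) — coverage > 2 per
    million in both libraries at the identical nucleotide — but failed
    the enrichment rule are eligible.
    """
    if config is None:
        config = ClassifierConfig()
    accepted, remaining = [], []
    for cand in deferred:
        eligible = (
            cand.tex_plus_5p > config.min_coverage
            and cand.tex_minus_5p > config.min_coverage
            and cand.same_start
        )
        if eligible and _extends_into_gene(
            cand.position,
            cand.strand,
            annotation,
            pair.tex_minus.coverage.values(cand.strand),
            config,
        ):
            accepted.append(_record(cand, tier=2))
        else:
            remaining.append(cand)
    return accepted, remaining


def rescue_with_motif(
    remaining: list[TSSCandidate],
    pair: CoverageTrackPair,
    genome: str,
    annotation: GenomeAnnotation,
    config: ClassifierConfig | None = None,
    *,
    motif: ConsensusMotif | str = DEFAULT_MINUS10,
    spacing_range: tuple[int, int] = DEFAULT_SPACING,
) -> tuple[list[TSSRecord], list[TSSCandidate]]:
    """Tier 3: gene extension plus a predicted PEP -10 element.

    Candidates outside the tier-1/2 criteria are accepted when they
    extend into an annotated gene, a -10 consensus element lies at legal
    spacing upstream, and the TEX+ 5'-end signal clears the tier-3 floor.
    """
    if config is None:
        config = ClassifierConfig()
    accepted, rejected = [], []
    for cand in remaining:
        ok = cand.tex_plus_5p > config.tier3_min_tex_plus and _extends_into_gene(
            cand.position,
            cand.strand,
            annotation,
            pair.tex_minus.coverage.values(cand.strand),
            config,
        )
        if ok:
            window = extract_upstream_window(
                cand.position, cand.strand, genome, circular=annotation.circular
            )
            ok = scan_consensus(window, motif, spacing_range) is not None
        if ok:
            accepted.append(_record(cand, tier=3))
        else:
            rejected.append(cand)
    return accepted, rejected


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_tss(
    position: int,
    strand: str,
    annotation: GenomeAnnotation,
    config: ClassifierConfig | None = None,
) -> tuple[str, str | None, int | None]:
    """Locate a TSS relative to the annotation: (class, gene id, distance).

    Precedence: same-strand containment (iTSS) > opposite-strand
    containment (aTSS) > within the upstream window of a same-strand
    gene start (gTSS, distance to the start codon recorded) > oTSS.
    Ties between containing genes or between upstream genes go to the
    nearer start codon, then the lower gene coordinate.
    """
    if config is None:
        config = ClassifierConfig()
    length = annotation.genome_length
    circular = annotation.circular

    def start_distance(gene) -> int:
        """Strand-aware distance from the TSS to the gene's start codon."""
        g5 = gene.five_prime_start
        if strand == "+":
            d = g5 - position
        else:
            d = position - g5
        if circular:
            d %= length
        return d

    def codon_proximity(gene) -> int:
        """Unsigned (circular) distance between the TSS and a start codon."""
        g5 = gene.five_prime_start
        if circular:
            return min((position - g5) % length, (g5 - position) % length)
        return abs(position - g5)

    containing_same = [
        g for g in annotation.same_strand(strand) if g.start <= position < g.end
    ]
    if containing_same:
        gene = min(containing_same, key=lambda g: (codon_proximity(g), g.start))
        return "iTSS", gene.gene_id, None

    other = "-" if strand == "+" else "+"
    containing_anti = [
        g for g in annotation.same_strand(other) if g.start <= position < g.end
    ]
    if containing_anti:
        gene = min(containing_anti, key=lambda g: g.start)
        return "aTSS", gene.gene_id, None

    upstream = []
    for gene in annotation.same_strand(strand):
        d = start_distance(gene)
        if 0 < d <= config.upstream_window:
            upstream.append((d, gene))
    if upstream:
        d, gene = min(upstream, key=lambda dg: (dg[0], dg[1].start))
        return "gTSS", gene.gene_id, d
    return "oTSS", None, None


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def call_tss(
    pair: CoverageTrackPair,
    genome: str,
    annotation: GenomeAnnotation,
    config: ClassifierConfig | None = None,
    *,
    motif: ConsensusMotif | str = DEFAULT_MINUS10,
) -> list[TSSRecord]:
    """Normalize, detect candidates, run the three tiers, classify.

    Returns accepted TSS records sorted by strand and position; each
    carries its tier, enrichment ratio, class and (for gTSSs) the
    distance to the downstream start codon.
    """
    if config is None:
        config = ClassifierConfig()
    pair = normalize_pair(pair)
    candidates = detect_candidates(pair, config, circular=annotation.circular)
    tier1, deferred = call_tier1(candidates, config)
    tier2, remaining = rescue_gene_extension(deferred, pair, annotation, config)
    tier3, _ = rescue_with_motif(
        remaining, pair, genome, annotation, config, motif=motif
    )
    records = tier1 + tier2 + tier3
    for rec in records:
        cls, gene_id, dist = classify_tss(rec.position, rec.strand, annotation, config)
        rec.tss_class, rec.gene_id, rec.distance = cls, gene_id, dist
    return sorted(records, key=lambda r: (r.strand, r.position))


def class_counts(records: list[TSSRecord]) -> dict[str, int]:
    """Summary counts per TSS class (gTSS/iTSS/aTSS/oTSS)."""
    counts = {c: 0 for c in TSS_CLASSES}
    for rec in records:
        counts[rec.tss_class] += 1
    return counts
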