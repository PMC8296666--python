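"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the observable structure of a chloroplast
dRNA-seq experiment without simulating reads: a circular plastome with
non-overlapping genes on both strands, paired TEX+/TEX- per-base tracks
in which primary 5' ends are enriched by TEX treatment while processed
5' ends are depleted, gapped upstream alignments with planted conserved
footprints anchored at the start codon, and two-channel plastid images
with depth-dependent signal attenuation.

Count model
-----------
A :class:`TruthTSS` ``strength`` is the expected TEX- 5'-end read count
at a reference depth of 1e6 mapped reads; expectations scale linearly
with ``depth / 1e6``. At a primary site the TEX+ expectation is
``alpha * strength`` (TEX spares triphosphate ends and the relative
share of surviving material rises); at a processed site it is
``s * strength`` with survival ``s`` in [0, 1]. A uniform Poisson
background of ``background`` counts/base sits under everything, and
gene-body coverage decays geometrically downstream of every 5' end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conservation import AlignmentBlock
from .coverage import CoverageTrackPair, LibraryTracks
from .errors import BoundsError, ParameterError, SizingError
from .io import GeneRecord, GenomeAnnotation, StrandedTrack

_REFERENCE_DEPTH = 1e6


@dataclass(frozen=True)
class TruthTSS:
    """A planted transcription start site."""

    position: int
    strand: str
    strength: float  # expected TEX- 5'-end count at 1e6 mapped reads
    tier_truth: int = 1
    class_truth: str = "gTSS"
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ParameterError("TSS strength must be >= 0")
        if self.strand not in "+-":
            raise ParameterError("strand must be '+' or '-'")


@dataclass(frozen=True)
class ProcessedSite:
    """A planted processed (5' monophosphate) transcript end."""

    position: int
    strand: str
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ParameterError("processed-site strength must be >= 0")


@dataclass
class SimulationParams:
    """Dials of the dRNA-seq generator.

    alpha (primary_enrichment) defaults to 2.5, the fold enrichment
    observed at the psbA 5' end after TEX treatment; survival and
    background are set for clear tier separation at the default depth.
    """

    genome_length: int = 120_000
    n_genes: int = 60
    depth: float = 1e6  # mapped reads per library
    tex_survival: float = 0.2  # fraction of processed ends surviving TEX
    primary_enrichment: float = 2.5  # TEX+ fold gain at primary ends
    background: float = 0.05  # Poisson counts per base at 1e6 reads
    body_decay: float = 0.999  # per-nt geometric decay of body coverage
    processed_density: float = 1 / 300  # processed ends per gene-body nt
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.tex_survival <= 1:
            raise ParameterError("tex_survival must be in [0, 1]")
        if self.primary_enrichment < 1:
            raise ParameterError("primary_enrichment must be >= 1")
        for name in ("depth", "background", "body_decay", "processed_density"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.genome_length < 1:
            raise ParameterError("genome_length must be >= 1")


# ---------------------------------------------------------------------------
# plastome
# ---------------------------------------------------------------------------

_MIN_GAP = 60
_GENE_LEN_RANGE = (300, 1200)


def simulate_plastome(params: SimulationParams) -> tuple[str, GenomeAnnotation]:
    """Random circular plastome with non-overlapping genes on both strands.

    Gene starts carry a real ATG (strand-aware) so downstream part
    extraction sees plausible start codons. The first two genes form a
    two-gene operon: same strand, minimal intergenic gap. Deterministic
    for a given seed.
    """
    params.validate()
    if params.genome_length < 1000:
        raise SizingError("genome_length must be >= 1000")
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    genome = rng.choice(list("ACGT"), size=params.genome_length)

    if n == 0:
        return "".join(genome), GenomeAnnotation([], params.genome_length)

    lengths = rng.integers(*_GENE_LEN_RANGE, size=n, endpoint=True)
    slack = params.genome_length - int(lengths.sum()) - (n + 1) * _MIN_GAP
    if slack < 0:
        raise SizingError(
            f"cannot place {n} genes totalling {lengths.sum()} nt plus gaps "
            f"on a {params.genome_length} nt genome"
        )
    extra = rng.multinomial(slack, np.full(n + 1, 1 / (n + 1)))
    gaps = extra + _MIN_GAP
    if n >= 2:  # operon: pull genes 0 and 1 together, give the slack back at the end
        gaps[-1] += gaps[1] - _MIN_GAP
        gaps[1] = _MIN_GAP

    strands = rng.choice(["+", "-"], size=n)
    if n >= 2:
        strands[1] = strands[0]
    types = rng.choice(["CDS", "tRNA"], size=n, p=[0.75, 0.25])

    records: list[GeneRecord] = []
    pos = int(gaps[0])
    for i in range(n):
        start, end = pos, pos + int(lengths[i])
        if strands[i] == "+":
            genome[start : start + 3] = list("ATG")
        else:
            genome[end - 3 : end] = list("CAT")  # reverse complement of ATG
        records.append(GeneRecord(f"g{i:03d}", str(types[i]), start, end, str(strands[i])))
        pos = end + int(gaps[i + 1])
    return "".join(genome), GenomeAnnotation(records, params.genome_length)


# ---------------------------------------------------------------------------
# dRNA-seq tracks
# ---------------------------------------------------------------------------

_BODY_WINDOW = 600  # nt of downstream body coverage added per 5' end


def _add_body(lam: np.ndarray, pos: int, strand: str, amount: float, decay: float, circular: bool) -> None:
    length = lam.shape[0]
    idx = np.arange(_BODY_WINDOW)
    contrib = amount * decay ** idx
    if strand == "+":
        targets = pos + idx
    else:
        targets = pos - idx
    if circular:
        targets = targets % length
    else:
        keep = (targets >= 0) & (targets < length)
        targets, contrib = targets[keep], contrib[keep]
    np.add.at(lam, targets, contrib)


def simulate_drnaseq(
    genome_length: int,
    truth: list[TruthTSS],
    processed_sites: list[ProcessedSite],
    params: SimulationParams,
    *,
    circular: bool = True,
) -> CoverageTrackPair:
    """Paired raw TEX+/TEX- tracks (5'-end counts and body coverage).

    TEX- 5'-end counts at a primary TSS are Poisson(strength * scale);
    TEX+ counts are Poisson(alpha * strength * scale). At a processed
    site the TEX+ expectation is multiplied by the survival fraction
    instead. A Poisson background sits under every base; body coverage
    decays geometrically downstream of each end (both libraries for
    primary ends, survival-scaled in TEX+ for processed ends). Total
    mapped reads are recorded as the nominal depth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    scale = params.depth / _REFERENCE_DEPTH
    shape = (genome_length,)

    lam5 = {
        lib: {s: np.full(shape, params.background * scale) for s in "+-"}
        for lib in ("tex+", "tex-")
    }
    lam_cov = {
        lib: {s: np.zeros(shape) for s in "+-"} for lib in ("tex+", "tex-")
    }

    for t in truth:
        if not 0 <= t.position < genome_length:
            raise BoundsError(f"TSS position {t.position} outside genome")
        amt = t.strength * scale
        lam5["tex-"][t.strand][t.position] += amt
        lam5["tex+"][t.strand][t.position] += params.primary_enrichment * amt
        _add_body(lam_cov["tex-"][t.strand], t.position, t.strand, amt, params.body_decay, circular)
        _add_body(lam_cov["tex+"][t.strand], t.position, t.strand,
                  params.primary_enrichment * amt, params.body_decay, circular)

    for p in processed_sites:
        if not 0 <= p.position < genome_length:
            raise BoundsError(f"processed site {p.position} outside genome")
        amt = p.strength * scale
        lam5["tex-"][p.strand][p.position] += amt
        lam5["tex+"][p.strand][p.position] += params.tex_survival * amt
        _add_body(lam_cov["tex-"][p.strand], p.position, p.strand, amt, params.body_decay, circular)
        _add_body(lam_cov["tex+"][p.strand], p.position, p.strand,
                  params.tex_survival * amt, params.body_decay, circular)

    def sample(lam: np.ndarray) -> np.ndarray:
        return rng.poisson(lam).astype(float)

    def track(signal: dict[str, np.ndarray], label: str) -> StrandedTrack:
        return StrandedTrack(
            sample(signal["+"]), sample(signal["-"]),
            label=label, total_mapped_reads=params.depth,
        )

    return CoverageTrackPair(
        tex_plus=LibraryTracks(
            track(lam5["tex+"], "TEX+ 5p"),
            track(lam_cov["tex+"], "TEX+ cov"),
        ),
        tex_minus=LibraryTracks(
            track(lam5["tex-"], "TEX- 5p"),
            track(lam_cov["tex-"], "TEX- cov"),
        ),
    )


def plant_primary_tss(
    annotation: GenomeAnnotation,
    n_tss: int,
    rng: np.random.Generator,
    *,
    upstream_range: tuple[int, int] = (20, 150),
    strength_range: tuple[float, float] = (10.0, 100.0),
    min_separation: int = 10,
) -> list[TruthTSS]:
    """Plant strong primary TSSs upstream of annotated gene starts.

    Strengths are drawn well above the 2-per-million tier-1 floor so the
    planted sites are tier-1 by construction at the default depth.
    """
    genes = list(annotation.records)
    if not genes:
        raise ParameterError("annotation has no genes to anchor TSSs")
    length = annotation.genome_length
    out: list[TruthTSS] = []
    used: dict[str, list[int]] = {"+": [], "-": []}
    gi = 0
    attempts = 0
    while len(out) < n_tss and attempts < 50 * n_tss:
        attempts += 1
        gene = genes[gi % len(genes)]
        gi += 1
        d = int(rng.integers(*upstream_range, endpoint=True))
        if gene.strand == "+":
            pos = (gene.start - d) % length
        else:
            pos = (gene.end - 1 + d) % length
        if any(abs(pos - q) <= min_separation for q in used[gene.strand]):
            continue
        used[gene.strand].append(pos)
        out.append(
            TruthTSS(
                position=pos,
                strand=gene.strand,
                strength=float(rng.uniform(*strength_range)),
                tier_truth=1,
                class_truth="gTSS",
                gene_id=gene.gene_id,
            )
        )
    if len(out) < n_tss:
        raise SizingError(f"could only place {len(out)} of {n_tss} TSSs")
    return out


def plant_processed_sites(
    annotation: GenomeAnnotation,
    params: SimulationParams,
    rng: np.random.Generator,
    *,
    strength_range: tuple[float, float] = (20.0, 80.0),
) -> list[ProcessedSite]:
    """Uniform processed 5' ends inside gene bodies at the configured density.

    The strength floor keeps the survival-scaled TEX+ expectation
    (s * strength >= 4 per million at default survival) well clear of
    both the 2-per-million tier-1 floor and Poisson tails that could
    mimic enrichment, preserving the tier separation the count model is
    calibrated for.
    """
    out: list[ProcessedSite] = []
    for gene in annotation.records:
        body = gene.end - gene.start
        n_sites = round(body * params.processed_density)
        if n_sites == 0:
            continue
        positions = rng.choice(np.arange(gene.start + 30, gene.end), size=n_sites, replace=False)
        for pos in np.sort(positions):
            out.append(
                ProcessedSite(int(pos), gene.strand, float(rng.uniform(*strength_range)))
            )
    return out


def default_scenario(seed: int, *, n_tss: int = 40, params: SimulationParams | None = None):
    """The standard study-condition scenario used throughout the tests.

    One 120 kb plastome with 60 genes, 40 planted tier-1 primary TSSs,
    processed ends at one per 300 nt of gene body, and 1e6 mapped reads
    per library.
    """
    if params is None:
        params = SimulationParams(seed=seed)
    else:
        params.seed = seed
    genome, annotation = simulate_plastome(params)
    rng = np.random.default_rng(params.seed + 1_000_003)
    truth = plant_primary_tss(annotation, n_tss, rng)
    processed = plant_processed_sites(annotation, params, rng)
    pair = simulate_drnaseq(params.genome_length, truth, processed, params)
    return {
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "processed": processed,
        "pair": pair,
        "params": params,
    }


# ---------------------------------------------------------------------------
# upstream alignments
# ---------------------------------------------------------------------------


def simulate_alignment(
    n_species: int,
    window_length: int,
    footprints: list[tuple[int, int]],
    conservation: float = 0.9,
    seed: int = 0,
    *,
    gap_prob: float = 0.02,
) -> tuple[AlignmentBlock, list[dict]]:
    """Gapped upstream alignment anchored at an ATG, with planted footprints.

    ``footprints`` are half-open intervals in ATG-relative offsets, e.g.
    ``(-45, -30)`` covers offsets -45..-31 (the base immediately 5' of the
    A of ATG is -1; there is no offset 0). Inside a footprint exactly
    ``ceil(conservation * n_species)`` rows carry the column's consensus
    base, guaranteeing a majority-residue frequency >= the stated level;
    outside, residues are drawn uniformly and non-reference rows may be
    gapped. The first row is the ungapped reference.
    """
    if not 0 <= conservation <= 1:
        raise ParameterError("conservation level must be in [0, 1]")
    if n_species < 1:
        raise ParameterError("need at least one species")
    for a, b in footprints:
        if not (-window_length <= a < b <= 0):
            raise BoundsError(f"footprint ({a},{b}) outside window (-{window_length}, 0]")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n_cols = window_length + 3  # upstream window + ATG anchor
    anchor = window_length
    in_footprint = np.zeros(n_cols, dtype=bool)
    for a, b in footprints:
        # offset -k lives at column anchor - k
        in_footprint[anchor + a : anchor + b] = True

    aln = np.empty((n_species, n_cols), dtype="<U1")
    n_keep = math.ceil(conservation * n_species)
    for col in range(window_length):
        if in_footprint[col]:
            consensus = rng.choice(bases)
            rows = rng.permutation(n_species)[:n_keep]
            others = bases[bases != consensus]
            aln[:, col] = rng.choice(others, size=n_species)
            aln[rows, col] = consensus
        else:
            aln[:, col] = rng.choice(bases, size=n_species)
            if gap_prob > 0 and n_species > 1:
                gaps = rng.random(n_species - 1) < gap_prob
                aln[1:, col][gaps] = "-"
    aln[:, anchor : anchor + 3] = list("ATG")

    block = AlignmentBlock(
        sequences=["".join(row) for row in aln],
        labels=[f"sp{i:02d}" for i in range(n_species)],
        anchor=anchor,
    )
    truth = [
        {"interval": (a, b), "conservation": conservation} for a, b in footprints
    ]
    return block, truth


# ---------------------------------------------------------------------------
# two-channel plastid images
# ---------------------------------------------------------------------------


@dataclass
class SyntheticImageTruth:
    """Ground truth for a simulated two-channel micrograph."""

    labels: np.ndarray  # per-pixel plastid id, 0 = background
    true_ratio: np.ndarray  # CFP/chlorophyll ratio per plastid (1-based ids)
    attenuation: np.ndarray  # per-pixel multiplicative factor in (0, 1]


_CELL = 32  # px grid cell per plastid
_BASE_INTENSITY = 0.6  # chlorophyll signal as a fraction of dynamic range


def simulate_images(
    n_plastids: int,
    true_ratios,
    attenuation_depth: float = np.inf,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    touching_pairs: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticImageTruth]:
    """Two-channel (CFP, chlorophyll) image of elliptical plastids.

    Plastids sit on a grid (non-overlapping by construction); the first
    ``touching_pairs`` grid cells instead hold two touching ellipses for
    watershed tests. Each plastid gets a depth z ~ U(0, attenuation_depth)
    and both channels are attenuated by exp(-z / attenuation_depth), so
    attenuation reaches e^-1 but the per-plastid CFP/chlorophyll ratio is
    untouched. Gaussian noise of the given SD is added independently per
    channel and the result clipped at zero.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    true_ratios = np.asarray(true_ratios, dtype=float)
    n_blobs = n_plastids + touching_pairs  # each pair adds one extra ellipse
    if true_ratios.shape[0] != n_blobs:
        raise ParameterError(
            f"need {n_blobs} ratios ({n_plastids} plastids incl. {touching_pairs} touching pairs)"
        )
    if (true_ratios <= 0).any():
        raise ParameterError("true ratios must be > 0")

    rng = np.random.default_rng(seed)
    n_cells = n_plastids  # touching pairs share a cell
    ncol = math.ceil(math.sqrt(n_cells))
    nrow = math.ceil(n_cells / ncol)
    h, w = nrow * _CELL, ncol * _CELL
    labels = np.zeros((h, w), dtype=int)
    att_map = np.ones((h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]

    def draw(label: int, cy: float, cx: float, a: float, b: float, theta: float, att: float):
        ct, st = math.cos(theta), math.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        labels[inside] = label
        att_map[inside] = att

    label = 0
    for cell in range(n_cells):
        r, c = divmod(cell, ncol)
        cy = r * _CELL + _CELL / 2 + rng.uniform(-2, 2)
        cx = c * _CELL + _CELL / 2 + rng.uniform(-2, 2)
        if math.isfinite(attenuation_depth):
            att = math.exp(-rng.uniform(0, attenuation_depth) / attenuation_depth)
        else:
            att = 1.0
        if cell < touching_pairs:
            a = rng.uniform(5, 6.5)
            b = rng.uniform(4, 5)
            for k, dx in enumerate((-a, a)):  # centers 2a apart: tangent ellipses
                label += 1
                draw(label, cy, cx + dx, a, b, 0.0, att)
        else:
            label += 1
            a = rng.uniform(6, 9)
            b = rng.uniform(4, 7)
            draw(label, cy, cx, a, b, rng.uniform(0, math.pi), att)

    ratio_map = np.zeros((h, w), dtype=float)
    for i in range(1, n_blobs + 1):
        ratio_map[labels == i] = true_ratios[i - 1]

    signal = _BASE_INTENSITY * att_map * (labels > 0)
    chl = signal + rng.normal(0, noise_sd, size=signal.shape) if noise_sd else signal.copy()
    cfp = ratio_map * signal
    if noise_sd:
        cfp = cfp + rng.normal(0, noise_sd, size=signal.shape)
    chl = np.clip(chl, 0, None)
    cfp = np.clip(cfp, 0, None)
    att_map = np.where(labels > 0, att_map, 1.0)
    return cfp, chl, SyntheticImageTruth(labels, true_ratios, att_map)
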