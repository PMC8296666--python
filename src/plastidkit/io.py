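"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open on the forward genomic
axis. GFF3 (1-based inclusive) is the only 1-based surface and is
converted at the boundary. On the minus strand a transcript's 5' end is
the interval's *larger* coordinate, so all "upstream" arithmetic is
strand-aware. Plastomes are treated as circular by default, which means
windows may wrap through the origin.

bedGraph files are 0-based half-open; zero-valued runs are omitted on
write. The library's total mapped read count is carried in a
``# total_mapped_reads=<float>`` header comment so that per-million
normalization survives a write/read round-trip.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import BoundsError, FormatError

#: IUPAC nucleotide codes plus gap characters (alignments) in both cases.
_ALLOWED_CHARS = frozenset("ACGTURYSWKMBDHVNacgturyswkmbdhvn-.")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string; case is preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

GENE_FEATURE_TYPES = ("CDS", "tRNA", "rRNA")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene-bearing feature, 0-based half-open."""

    gene_id: str
    feature_type: str  # CDS / tRNA / rRNA / other
    start: int
    end: int
    strand: str  # "+" or "-"
    duplicate: bool = False  # shares its id with another record (IR copies)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )

    @property
    def five_prime_start(self) -> int:
        """Genomic coordinate of the transcript's first base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    """Gene-bearing features of one (usually circular) plastome."""

    records: list[GeneRecord]
    genome_length: int
    circular: bool = True

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.end > self.genome_length:
                raise BoundsError(
                    f"{rec.gene_id} ends at {rec.end} beyond genome length "
                    f"{self.genome_length}"
                )

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, gene_id: str) -> GeneRecord:
        for rec in self.records:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(gene_id)

    def same_strand(self, strand: str) -> list[GeneRecord]:
        return [r for r in self.records if r.strand == strand]


def read_gff3(
    path: str | os.PathLike,
    genome_length: int,
    *,
    circular: bool = True,
    feature_types: Sequence[str] = GENE_FEATURE_TYPES + ("gene",),
) -> GenomeAnnotation:
    """Load gene-bearing features from a GFF3 file.

    1-based inclusive GFF3 coordinates become 0-based half-open. Features
    whose type is not in *feature_types* are dropped. Records sharing a
    gene id (the plastome's inverted-repeat duplicates) are all retained
    and flagged ``duplicate=True``.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        # a header-only GFF3 is a valid empty annotation
        return GenomeAnnotation([], genome_length, circular=circular)
    raw: list[tuple[str, str, int, int, str]] = []
    for feat in db.all_features():
        if feat.featuretype not in feature_types:
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.end < feat.start:
            raise FormatError(f"feature {gene_id}: end {feat.end} < start {feat.start}")
        start, end = feat.start - 1, feat.end
        if end > genome_length and not circular:
            raise BoundsError(
                f"feature {gene_id} extends to {end} beyond non-circular "
                f"genome of length {genome_length}"
            )
        ftype = feat.featuretype if feat.featuretype in GENE_FEATURE_TYPES else "other"
        raw.append((gene_id, ftype, start, end, feat.strand))

    counts: dict[str, int] = {}
    for gene_id, *_ in raw:
        counts[gene_id] = counts.get(gene_id, 0) + 1
    records = [
        GeneRecord(gid, ftype, start, end, strand, duplicate=counts[gid] > 1)
        for gid, ftype, start, end, strand in raw
    ]
    return GenomeAnnotation(records, genome_length, circular=circular)


def write_gff3(
    annotation: GenomeAnnotation,
    path: str | os.PathLike,
    *,
    seqid: str = "plastome",
    source: str = "plastidkit",
) -> None:
    """Serialize an annotation back to 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.genome_length}\n")
        for rec in annotation.records:
            ftype = rec.feature_type if rec.feature_type != "other" else "gene"
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\tID={rec.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read named sequences; case is preserved (it carries motif meaning)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq)
        bad = set(seq) - _ALLOWED_CHARS
        if bad:
            raise FormatError(
                f"sequence {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, *, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# per-base tracks / bedGraph
# ---------------------------------------------------------------------------


@dataclass
class StrandedTrack:
    """Per-base values for one signal on both strands of one library."""

    fwd: np.ndarray
    rev: np.ndarray
    label: str = ""
    total_mapped_reads: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=float)
        self.rev = np.asarray(self.rev, dtype=float)
        if self.fwd.shape != self.rev.shape:
            raise FormatError("forward/reverse arrays differ in length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise FormatError("track values must be non-negative")

    @property
    def genome_length(self) -> int:
        return int(self.fwd.shape[0])

    def values(self, strand: str) -> np.ndarray:
        return self.fwd if strand == "+" else self.rev

    def copy(self) -> "StrandedTrack":
        return replace(self, fwd=self.fwd.copy(), rev=self.rev.copy())


def read_bedgraph(path: str | os.PathLike, genome_length: int) -> tuple[np.ndarray, float | None]:
    """Expand a bedGraph file to a dense per-base array.

    Returns the array plus the total mapped read count if the file carries
    a ``# total_mapped_reads=`` header. Overlapping intervals and negative
    values are format errors.
    """
    values = np.zeros(genome_length, dtype=float)
    seen = np.zeros(genome_length, dtype=bool)
    total: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "total_mapped_reads=" in line:
                    total = float(line.split("total_mapped_reads=")[1])
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if not 0 <= start < end <= genome_length:
                raise BoundsError(f"{path}:{lineno}: interval [{start},{end}) out of range")
            if seen[start:end].any():
                raise FormatError(f"{path}:{lineno}: overlapping intervals")
            values[start:end] = value
            seen[start:end] = True
    return values, total


def write_bedgraph(
    values: np.ndarray,
    path: str | os.PathLike,
    *,
    chrom: str = "plastome",
    name: str = "",
    total_mapped_reads: float | None = None,
) -> None:
    """Run-length encode a dense array; zero runs are omitted."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if total_mapped_reads is not None:
            fh.write(f"# total_mapped_reads={total_mapped_reads:g}\n")
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_track(
    fwd_path: str | os.PathLike,
    rev_path: str | os.PathLike,
    genome_length: int,
    *,
    label: str = "",
) -> StrandedTrack:
    fwd, total_f = read_bedgraph(fwd_path, genome_length)
    rev, total_r = read_bedgraph(rev_path, genome_length)
    total = total_f if total_f is not None else total_r
    return StrandedTrack(fwd, rev, label=label, total_mapped_reads=total or 0.0)


def write_track(
    track: StrandedTrack,
    fwd_path: str | os.PathLike,
    rev_path: str | os.PathLike,
    *,
    chrom: str = "plastome",
) -> None:
    write_bedgraph(
        track.fwd, fwd_path, chrom=chrom, name=f"{track.label} fwd",
        total_mapped_reads=track.total_mapped_reads,
    )
    write_bedgraph(
        track.rev, rev_path, chrom=chrom, name=f"{track.label} rev",
        total_mapped_reads=track.total_mapped_reads,
    )


def read_bedgraph_pair(
    tex_plus_fwd: str | os.PathLike,
    tex_plus_rev: str | os.PathLike,
    tex_minus_fwd: str | os.PathLike,
    tex_minus_rev: str | os.PathLike,
    genome_length: int,
):
    """Load the four 5'-end bedGraph files of a TEX+/TEX- experiment.

    Returns a :class:`~plastidkit.coverage.CoverageTrackPair` whose body
    coverage tracks mirror the 5'-end tracks (tier-2 continuity rescue
    then degrades gracefully when only 5'-end files are available).
    """
    from .coverage import CoverageTrackPair, LibraryTracks  # local: avoid cycle

    plus = read_track(tex_plus_fwd, tex_plus_rev, genome_length, label="TEX+")
    minus = read_track(tex_minus_fwd, tex_minus_rev, genome_length, label="TEX-")
    return CoverageTrackPair(
        tex_plus=LibraryTracks(plus, plus.copy()),
        tex_minus=LibraryTracks(minus, minus.copy()),
    )


# ---------------------------------------------------------------------------
# TSS BED output
# ---------------------------------------------------------------------------


def write_tss_bed(records: Iterable, path: str | os.PathLike, *, chrom: str = "plastome") -> None:
    """BED6 of TSS calls; the name field encodes class and tier, e.g. ``gTSS/t1``."""
    with open(path, "w") as fh:
        for rec in records:
            score = int(np.clip(round(rec.tex_plus_5p), 0, 1000))
            fh.write(
                f"{chrom}\t{rec.position}\t{rec.position + 1}\t"
                f"{rec.tss_class}/t{rec.tier}\t{score}\t{rec.strand}\n"
            )
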