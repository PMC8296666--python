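"""Normalization, TEX enrichment state and transcript-abundance math.

A dRNA-seq experiment yields two libraries from the same RNA pool: one
treated with the 5'-phosphate-dependent Terminator exonuclease (TEX+),
which degrades processed 5' monophosphate ends while sparing primary
5' triphosphate ends, and an untreated control (TEX-). Comparing the two
is what makes transcription start sites callable. All comparisons happen
on coverage-per-million-mapped-reads scales so that libraries of
different depth are commensurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import ParameterError, StateError
from .io import StrandedTrack


class EnrichmentState(Enum):
    """Which library dominates at a position (display semantics)."""

    TEX_PLUS_ENRICHED = "TEX_PLUS_ENRICHED"
    TEX_MINUS_ENRICHED = "TEX_MINUS_ENRICHED"
    EQUAL = "EQUAL"


@dataclass
class LibraryTracks:
    """The two signals of one library: 5'-end counts and body coverage."""

    five_prime: StrandedTrack
    coverage: StrandedTrack


@dataclass
class CoverageTrackPair:
    """Matched TEX+ / TEX- libraries over one genome."""

    tex_plus: LibraryTracks
    tex_minus: LibraryTracks

    def __post_init__(self) -> None:
        lengths = {
            t.genome_length
            for lib in (self.tex_plus, self.tex_minus)
            for t in (lib.five_prime, lib.coverage)
        }
        if len(lengths) != 1:
            raise ParameterError("all tracks in a pair must share one genome length")

    @property
    def genome_length(self) -> int:
        return self.tex_plus.five_prime.genome_length

    @property
    def normalized(self) -> bool:
        return all(
            t.normalized
            for lib in (self.tex_plus, self.tex_minus)
            for t in (lib.five_prime, lib.coverage)
        )


def normalize_per_million(track: StrandedTrack) -> StrandedTrack:
    """Rescale raw per-base values to coverage per million mapped reads.

    value' = value * 1e6 / total_mapped_reads. Idempotent: a track whose
    ``normalized`` flag is already set is returned unchanged.
    """
    if track.normalized:
        return track
    if track.total_mapped_reads <= 0:
        raise ParameterError("cannot normalize: total mapped reads must be > 0")
    factor = 1e6 / track.total_mapped_reads
    return replace(
        track, fwd=track.fwd * factor, rev=track.rev * factor, normalized=True
    )


def normalize_pair(pair: CoverageTrackPair) -> CoverageTrackPair:
    """Per-million normalize every track of a TEX+/TEX- pair."""
    return CoverageTrackPair(
        tex_plus=LibraryTracks(
            normalize_per_million(pair.tex_plus.five_prime),
            normalize_per_million(pair.tex_plus.coverage),
        ),
        tex_minus=LibraryTracks(
            normalize_per_million(pair.tex_minus.five_prime),
            normalize_per_million(pair.tex_minus.coverage),
        ),
    )


def enrichment(
    position: int, strand: str, pair: CoverageTrackPair
) -> tuple[float | None, EnrichmentState]:
    """TEX+/TEX- ratio and enrichment state at one position.

    The ratio is computed on the 5'-end tracks and is reported as None
    (undefined, not infinity) when the TEX- value is zero. The state uses
    exact comparison of the normalized values.
    """
    if not pair.normalized:
        raise StateError("enrichment requires a per-million-normalized pair")
    p = float(pair.tex_plus.five_prime.values(strand)[position])
    m = float(pair.tex_minus.five_prime.values(strand)[position])
    if p > m:
        state = EnrichmentState.TEX_PLUS_ENRICHED
    elif m > p:
        state = EnrichmentState.TEX_MINUS_ENRICHED
    else:
        state = EnrichmentState.EQUAL
    ratio = p / m if m > 0 else None
    return ratio, state


def compute_tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: TPM_i = (c_i/l_i) * 1e6 / sum_j (c_j/l_j).

    Length-normalized relative abundance; sums to 1e6 whenever any count
    is positive. An all-zero count vector yields all-zero TPM with a
    warning rather than an error.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ParameterError("counts and lengths must have matching shapes")
    if (lengths <= 0).any():
        raise ParameterError("transcript lengths must be positive")
    if (counts < 0).any():
        raise ParameterError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        warnings.warn("all counts are zero; TPM is all-zero", stacklevel=2)
        return np.zeros_like(rates)
    return rates * 1e6 / total
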