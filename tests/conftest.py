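import numpy as np
import pytest

import plastidkit as pk


@pytest.fixture(scope="session")
def scenario():
    """One default study-condition scenario shared across read-only tests."""
    return pk.default_scenario(1)


@pytest.fixture()
def small_annotation():
    """Hand-built annotation on a 10 kb linear-ish circular genome."""
    records = [
        pk.GeneRecord("gA", "CDS", 1000, 2000, "+"),
        pk.GeneRecord("gB", "CDS", 2100, 2800, "+"),  # operon partner of gA
        pk.GeneRecord("gC", "tRNA", 4000, 4080, "-"),
        pk.GeneRecord("gD", "CDS", 6000, 7500, "-"),
    ]
    return pk.GenomeAnnotation(records, 10_000, circular=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_pair(length, plus_5p=(), minus_5p=(), minus_cov=(), total=1e6):
    """Build a raw CoverageTrackPair from sparse (pos, strand, value) specs."""
    arrays = {
        name: {s: np.zeros(length) for s in "+-"}
        for name in ("p5", "m5", "pcov", "mcov")
    }
    for pos, strand, value in plus_5p:
        arrays["p5"][strand][pos] = value
    for pos, strand, value in minus_5p:
        arrays["m5"][strand][pos] = value
    for start, end, strand, value in minus_cov:
        arrays["mcov"][strand][start:end] = value
        arrays["pcov"][strand][start:end] = value

    def track(key, label):
        return pk.StrandedTrack(
            arrays[key]["+"], arrays[key]["-"], label=label, total_mapped_reads=total
        )

    return pk.CoverageTrackPair(
        tex_plus=pk.LibraryTracks(track("p5", "TEX+ 5p"), track("pcov", "TEX+ cov")),
        tex_minus=pk.LibraryTracks(track("m5", "TEX- 5p"), track("mcov", "TEX- cov")),
    )
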