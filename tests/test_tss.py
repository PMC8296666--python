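"""Tier rules, candidate detection and location classification.

The tier evaluator and the location classifier are each checked against
independent brute-force oracles implemented here with plain loops.
"""

import numpy as np
import pytest

import plastidkit as pk
from plastidkit.tss import TSSCandidate
from tests.conftest import make_pair

CFG = pk.ClassifierConfig()


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_tier(p, m, same_start, extends, has_motif, cfg=CFG):
    """Hand-coded restatement of the three printed tier rules."""
    if p > cfg.min_coverage and m > cfg.min_coverage and same_start and p / m > 1.0:
        return 1
    if p > cfg.min_coverage and m > cfg.min_coverage and same_start and extends:
        return 2
    if extends and has_motif and p > cfg.tier3_min_tex_plus:
        return 3
    return None


def oracle_classify(pos, strand, ann, W=CFG.upstream_window):
    """Exhaustive-scan location classifier, independent of the package's."""
    L = ann.genome_length

    def circ(a):
        return a % L if ann.circular else a

    inside_same, inside_anti, upstream = [], [], []
    for g in ann.records:
        g5 = g.start if g.strand == "+" else g.end - 1
        contained = g.start <= pos < g.end
        if contained and g.strand == strand:
            prox = min((pos - g5) % L, (g5 - pos) % L) if ann.circular else abs(pos - g5)
            inside_same.append((prox, g.start, g))
        elif contained:
            inside_anti.append((g.start, g))
        if g.strand == strand:
            d = circ(g5 - pos) if strand == "+" else circ(pos - g5)
            if 0 < d <= W:
                upstream.append((d, g.start, g))
    if inside_same:
        return "iTSS", sorted(inside_same)[0][2].gene_id, None
    if inside_anti:
        return "aTSS", sorted(inside_anti)[0][1].gene_id, None
    if upstream:
        d, _, g = sorted(upstream)[0]
        return "gTSS", g.gene_id, d
    return "oTSS", None, None


def run_tiers(candidates, pair, genome, annotation, cfg=CFG):
    """Run the package's three-stage tier pipeline; {candidate: tier}."""
    tier1, deferred = pk.call_tier1(candidates, cfg)
    tier2, remaining = pk.rescue_gene_extension(deferred, pair, annotation, cfg)
    tier3, rejected = pk.rescue_with_motif(remaining, pair, genome, annotation, cfg)
    out = {}
    for recs, tier in ((tier1, 1), (tier2, 2), (tier3, 3)):
        for r in recs:
            out[(r.position, r.strand)] = tier
    for c in rejected:
        out[(c.position, c.strand)] = None
    return out


def boundary_candidates(n, seed):
    """Candidates + a controlled world where extension and motif truth are
    known by construction: loci 400 nt apart on an all-C genome, a
    containing same-strand gene iff ``extends``, a planted TATTAT at
    spacing 5 iff ``has_motif``."""
    rng = np.random.default_rng(seed)
    values = np.array([0.0, 0.4, 0.5, 0.51, 1.0, 1.9, 2.0, 2.01, 2.5, 3.0, 8.0])
    length = 400 * n + 400
    genome = ["C"] * length
    genes, cands, truth = [], [], []
    for i in range(n):
        base = 400 * i + 200
        p, m = rng.choice(values), rng.choice(values)
        same_start = bool(rng.integers(2))
        extends = bool(rng.integers(2))
        has_motif = bool(rng.integers(2))
        if extends:
            genes.append(pk.GeneRecord(f"g{i}", "CDS", base - 50, base + 300, "+"))
        if has_motif:
            genome[base - 11 : base - 5] = list("TATTAT")
        cands.append(TSSCandidate(base, "+", float(p), float(m), same_start))
        truth.append((p, m, same_start, extends, has_motif))
    ann = pk.GenomeAnnotation(genes, length, circular=True)
    pair = pk.normalize_pair(make_pair(length))
    return cands, truth, "".join(genome), ann


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


class TestDetectCandidates:
    def test_shared_spike_is_same_start(self):
        pair = pk.normalize_pair(
            make_pair(5000, plus_5p=[(1000, "+", 8.0)], minus_5p=[(1000, "+", 4.0)])
        )
        cands = pk.detect_candidates(pair)
        assert len(cands) == 1
        assert cands[0].position == 1000 and cands[0].same_start

    def test_offset_tex_minus_spike_is_not_same_start(self):
        pair = pk.normalize_pair(
            make_pair(5000, plus_5p=[(1000, "+", 8.0)], minus_5p=[(1003, "+", 4.0)])
        )
        (cand,) = [c for c in pk.detect_candidates(pair) if c.strand == "+"]
        assert cand.position == 1000 and not cand.same_start

    def test_nearby_spikes_merge_to_highest(self):
        pair = pk.normalize_pair(
            make_pair(5000, plus_5p=[(1000, "+", 8.0), (1003, "+", 5.0)])
        )
        cands = pk.detect_candidates(pair)
        assert [c.position for c in cands] == [1000]
        assert cands[0].tex_plus_5p == 8.0

    def test_empty_tracks_give_no_candidates(self):
        pair = pk.normalize_pair(make_pair(1000))
        assert pk.detect_candidates(pair) == []


# ---------------------------------------------------------------------------
# tier rules
# ---------------------------------------------------------------------------


class TestTierRules:
    @pytest.mark.parametrize(
        "p,m,same_start,expect_tier1",
        [
            (5.0, 2.5, True, True),  # all three rules pass, enrichment 2.0
            (5.0, 1.5, True, False),  # TEX- fails the strict > 2 floor
            (3.0, 4.0, True, False),  # enrichment 0.75 <= 1
            (5.0, 2.5, False, False),  # 5' ends not at the same nucleotide
            (2.0, 2.0, True, False),  # exactly 2.0 per million is not > 2
        ],
    )
    def test_tier1_rule(self, p, m, same_start, expect_tier1):
        accepted, deferred = pk.call_tier1([TSSCandidate(10, "+", p, m, same_start)])
        assert bool(accepted) is expect_tier1
        if accepted:
            assert accepted[0].enrichment == pytest.approx(p / m)

    def test_tier2_containment_branch(self, small_annotation):
        pair = pk.normalize_pair(make_pair(10_000))
        cand = TSSCandidate(1500, "+", 3.0, 4.0, True)  # unenriched, inside gA
        accepted, _ = pk.rescue_gene_extension([cand], pair, small_annotation)
        assert accepted and accepted[0].tier == 2

    def test_tier2_continuity_branch(self, small_annotation):
        """Unenriched 5' end 200 nt upstream of gA with continuous TEX-
        coverage 2.0 across the whole gap is rescued."""
        pair = pk.normalize_pair(
            make_pair(10_000, minus_cov=[(800, 1005, "+", 2.0)])
        )
        cand = TSSCandidate(800, "+", 3.0, 4.0, True)
        accepted, _ = pk.rescue_gene_extension([cand], pair, small_annotation)
        assert accepted and accepted[0].tier == 2

    def test_tier2_gap_in_coverage_blocks_rescue(self, small_annotation):
        pair = pk.normalize_pair(
            make_pair(10_000, minus_cov=[(800, 950, "+", 2.0)])  # 25% of gap uncovered
        )
        cand = TSSCandidate(800, "+", 3.0, 4.0, True)
        accepted, remaining = pk.rescue_gene_extension([cand], pair, small_annotation)
        assert not accepted and remaining == [cand]

    def test_tier2_no_gene_in_range_stays_rejected(self, small_annotation):
        pair = pk.normalize_pair(make_pair(10_000))
        cand = TSSCandidate(9000, "+", 3.0, 4.0, True)
        accepted, remaining = pk.rescue_gene_extension([cand], pair, small_annotation)
        assert not accepted and remaining == [cand]

    def test_tier3_needs_motif_extension_and_floor(self, small_annotation):
        genome = ["C"] * 10_000
        genome[1500 - 11 : 1500 - 5] = list("TATTAT")  # spacing 5 before 1500
        genome = "".join(genome)
        pair = pk.normalize_pair(make_pair(10_000))
        inside_with_motif = TSSCandidate(1500, "+", 1.2, 0.0, False)
        inside_no_motif = TSSCandidate(1700, "+", 1.2, 0.0, False)
        outside_with_motif = TSSCandidate(9000, "+", 1.2, 0.0, False)
        below_floor = TSSCandidate(1500, "+", 0.4, 0.0, False)
        accepted, rejected = pk.rescue_with_motif(
            [inside_with_motif, inside_no_motif, outside_with_motif, below_floor],
            pair, genome, small_annotation,
        )
        assert [(r.position, r.tier) for r in accepted] == [(1500, 3)]

    def test_tier3_spacing_12_is_rejected(self, small_annotation):
        genome = ["C"] * 10_000
        genome[1500 - 18 : 1500 - 12] = list("TATTAT")  # spacing 12: illegal
        pair = pk.normalize_pair(make_pair(10_000))
        accepted, _ = pk.rescue_with_motif(
            [TSSCandidate(1500, "+", 1.2, 0.0, False)], pair, "".join(genome),
            small_annotation,
        )
        assert not accepted

    def test_tier_assignment_matches_oracle_on_boundary_sweep(self):
        cands, truth, genome, ann = boundary_candidates(1000, seed=99)
        pair = pk.normalize_pair(make_pair(ann.genome_length))
        got = run_tiers(cands, pair, genome, ann)
        for cand, (p, m, same_start, extends, has_motif) in zip(cands, truth):
            assert got[(cand.position, cand.strand)] == oracle_tier(
                p, m, same_start, extends, has_motif
            ), (p, m, same_start, extends, has_motif)

    def test_tier_partition_is_exhaustive_and_disjoint(self):
        cands, _, genome, ann = boundary_candidates(500, seed=7)
        pair = pk.normalize_pair(make_pair(ann.genome_length))
        tier1, deferred = pk.call_tier1(cands)
        tier2, remaining = pk.rescue_gene_extension(deferred, pair, ann)
        tier3, rejected = pk.rescue_with_motif(remaining, pair, genome, ann)
        groups = [
            {(r.position, r.strand) for r in tier1},
            {(r.position, r.strand) for r in tier2},
            {(r.position, r.strand) for r in tier3},
            {(c.position, c.strand) for c in rejected},
        ]
        union = set().union(*groups)
        assert union == {(c.position, c.strand) for c in cands}
        assert sum(len(g) for g in groups) == len(cands)

    def test_raising_threshold_never_adds_tier1_calls(self):
        cands, *_ = boundary_candidates(300, seed=13)
        counts = []
        for floor in (1.0, 2.0, 3.0, 5.0):
            cfg = pk.ClassifierConfig(min_coverage=floor)
            counts.append(len(pk.call_tier1(cands, cfg)[0]))
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


class TestClassifyTss:
    def test_operon_internal_tss_beats_upstream_proximity(self, small_annotation):
        """A TSS inside the upstream gene of an operon, 141 nt before the
        next gene's start codon, is internal — containment wins."""
        cls, gene, dist = pk.classify_tss(2100 - 141, "+", small_annotation)
        assert cls == "iTSS" and gene == "gA" and dist is None

    def test_antisense_inside_opposite_strand_gene(self, small_annotation):
        cls, gene, _ = pk.classify_tss(1500, "-", small_annotation)
        assert cls == "aTSS" and gene == "gA"

    def test_gene_tss_with_distance(self, small_annotation):
        cls, gene, dist = pk.classify_tss(1000 - 124, "+", small_annotation)
        assert (cls, gene, dist) == ("gTSS", "gA", 124)

    def test_minus_strand_gene_tss(self, small_annotation):
        # gD start codon at 7499 on -, TSS 54 nt upstream = 7553
        cls, gene, dist = pk.classify_tss(7553, "-", small_annotation)
        assert (cls, gene, dist) == ("gTSS", "gD", 54)

    def test_orphan_far_from_everything(self, small_annotation):
        cls, gene, dist = pk.classify_tss(9500, "+", small_annotation)
        assert (cls, gene, dist) == ("oTSS", None, None)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        checked = 0
        for seed in range(10):
            _, ann = pk.simulate_plastome(
                pk.SimulationParams(genome_length=30_000, n_genes=15, seed=seed)
            )
            for _ in range(100):
                pos = int(rng.integers(0, 30_000))
                strand = "+" if rng.integers(2) else "-"
                assert pk.classify_tss(pos, strand, ann) == oracle_classify(pos, strand, ann)
                checked += 1
        assert checked == 1000


class TestFullPipeline:
    def test_planted_tss_recovered_as_tier1_gtss(self, scenario):
        records = pk.call_tss(scenario["pair"], scenario["genome"], scenario["annotation"])
        tier1 = {(r.position, r.strand) for r in records if r.tier == 1}
        truth = {(t.position, t.strand) for t in scenario["truth"]}
        assert truth <= tier1 and tier1 <= truth
        by_pos = {(r.position, r.strand): r for r in records}
        gtss = [by_pos[k].tss_class for k in truth]
        assert gtss.count("gTSS") >= 0.8 * len(gtss)  # a few land inside neighbors

    def test_processed_sites_never_tier1(self, scenario):
        records = pk.call_tss(scenario["pair"], scenario["genome"], scenario["annotation"])
        tier1 = {(r.position, r.strand) for r in records if r.tier == 1}
        proc = {(p.position, p.strand) for p in scenario["processed"]}
        assert not (tier1 & proc)

    def test_strand_symmetry_of_tier1_calls(self):
        """Mirroring the experiment (reverse-complement genome, reversed
        swapped-strand tracks, mirrored annotation) mirrors every tier-1
        call to position L-1-p on the opposite strand."""
        scen = pk.default_scenario(3, n_tss=15)
        L = scen["params"].genome_length
        records = pk.call_tss(scen["pair"], scen["genome"], scen["annotation"])

        def mirror_track(t):
            return pk.StrandedTrack(t.rev[::-1].copy(), t.fwd[::-1].copy(),
                                    label=t.label, total_mapped_reads=t.total_mapped_reads)

        pair = scen["pair"]
        mpair = pk.CoverageTrackPair(
            tex_plus=pk.LibraryTracks(mirror_track(pair.tex_plus.five_prime),
                                      mirror_track(pair.tex_plus.coverage)),
            tex_minus=pk.LibraryTracks(mirror_track(pair.tex_minus.five_prime),
                                       mirror_track(pair.tex_minus.coverage)),
        )
        mann = pk.GenomeAnnotation(
            [pk.GeneRecord(g.gene_id, g.feature_type, L - g.end, L - g.start,
                           "-" if g.strand == "+" else "+")
             for g in scen["annotation"].records],
            L, circular=True,
        )
        mgenome = pk.reverse_complement(scen["genome"])
        mrecords = pk.call_tss(mpair, mgenome, mann)
        t1 = {(r.position, r.strand) for r in records if r.tier == 1}
        mt1 = {(L - 1 - r.position, "-" if r.strand == "+" else "+")
               for r in mrecords if r.tier == 1}
        assert t1 == mt1
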