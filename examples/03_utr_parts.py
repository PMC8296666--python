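"""Extract a 5'UTR expression part and fuse it to a CDS.

Takes a gene from a synthetic plastome, extracts the leader between a
TSS 124 nt upstream and the start codon, checks Type IIS domestication,
fuses it to a reporter CDS under both overhang syntaxes, and disrupts a
putative PPR footprint by transversion.
"""

import plastidkit as pk

genome, ann = pk.simulate_plastome(
    pk.SimulationParams(genome_length=30_000, n_genes=12, seed=21)
)
gene = next(g for g in ann.records if g.strand == "+")
part = pk.extract_part(genome, ann, gene.gene_id, tss=gene.start - 124)
print(f"5'UTR part for {gene.gene_id}: {len(part)} nt, ends ...{part.sequence[-6:]}")

sites = pk.domestication_check(part.sequence)
print(f"internal BsaI/SapI sites: {len(sites)}"
      + (f" {sites}" if sites else " (domesticated)"))

cds = "ATGGTGAGCAAGGGCGAG"  # reporter CDS start; 4th base G allows ATGg syntax
standard = pk.apply_common_syntax(part, cds, "standard_AATG")
custom = pk.apply_common_syntax(part, cds, "custom_ATGg")
print(f"standard AATG fusion: {len(standard.sequence)} nt "
      f"(= {len(part)} + {len(cds)} + 1 inserted adenosine)")
print(f"custom ATGg fusion:   {len(custom.sequence)} nt (no insertion)")
print(f"junction: ...{standard.sequence[len(part)-4:len(part)+7]}... "
      "(the extra A sits before the ATG)")

# disrupt a 10 bp footprint candidate at -30..-20
mut = pk.FootprintMutation(len(part) - 30, len(part) - 20)
mutated = pk.mutate_footprint(part, mut)
changed = sum(a != b for a, b in zip(part.sequence, mutated.sequence))
print(f"transversion mutagenesis changed {changed}/10 targeted bases; "
      "applying it twice restores the original:",
      pk.mutate_footprint(mutated, mut).sequence == part.sequence)
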