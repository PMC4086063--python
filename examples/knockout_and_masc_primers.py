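"""Translational knockout of a gene plus its verification primers.

Converts three consecutive codons in the first half of a CDS into the
three stop codon types with as few substitutions as possible, then designs
the MASC PCR primer set used to genotype colonies: allele-specific forward
primers (wild type vs mutant, both melting at >= 62 C) and a ladder of ten
reverse primers giving staggered amplicon sizes for multiplexing.
"""

from magedesign import ToyFoldingEvaluator, design_knockout, design_masc_set, design_oligo, fixture_genome

genome = fixture_genome(50_000, 20, seed=1)
gene = genome.resolve_target("gene002")

mutation, window = design_knockout(genome, gene, n_stops=3)
print(f"gene            : {gene.name} ({gene.strand} strand, {gene.length // 3} codons)")
print(f"stop window     : codons {window.start_codon_index}.."
      f"{window.start_codon_index + 2} -> {' '.join(window.assignment)}")
print(f"substitutions   : {window.cost}")

oligo = design_oligo(genome, mutation, ToyFoldingEvaluator(), oligo_id="ko_gene002")
print(f"knockout oligo  : {oligo.sequence}")

primers = design_masc_set(genome, mutation, oligo.id)
print(f"fw_wt  ({primers.fw_wt.tm:5.1f} C): {primers.fw_wt.sequence}")
print(f"fw_mut ({primers.fw_mut.tm:5.1f} C): {primers.fw_mut.sequence}")
print("reverse ladder  :")
for p in primers.reverse_primers:
    print(f"  {p.amplicon_length:>4} bp amplicon  {p.sequence}  ({p.tm:.1f} C)")
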