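"""Design a single lagging-strand oligo for a point mutation.

Builds a synthetic 50-kb annotated genome, introduces one A->G style
substitution, and prints the optimized 90-nt oligo: its orientation tells
you which replichore the site is on (minus = the origin->terminus arm in
increasing coordinates), the MFE how stably the final oligo folds (closer
to zero is better for recombineering), and the homology arms how far the
mutation sits from either end (>= 15 bp by design).
"""

from magedesign import ToyFoldingEvaluator, design_oligo, fixture_genome
from magedesign.mutation import Mutation

genome = fixture_genome(50_000, 20, seed=1)

position = 12_345  # 1-based genome coordinate
ref = genome.base_at(position)
alt = "G" if ref != "G" else "A"
mutation = Mutation(position - 1, ref, alt, label=f"{ref}{position}{alt}")

design = design_oligo(genome, mutation, ToyFoldingEvaluator(), oligo_id="snp_1")

print(f"mutation        : {mutation.label}")
print(f"replichore      : {genome.replichore_of(position)}")
print(f"orientation     : {design.orientation}")
print(f"genome window   : {design.genome_window[0]}..{design.genome_window[1]}")
print(f"folding MFE     : {design.mfe:.1f} kcal/mol")
print(f"homology arms   : {design.left_homology} / {design.right_homology} bp")
print(f"oligo ({design.length} nt) : {design.sequence}")
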