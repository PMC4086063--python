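# magedesign

Automated design of single-stranded DNA oligos for **MAGE** (multiplex
automated genome engineering) and ssDNA recombineering, plus the
verification and pooling reagents that go with them.

Recombineering with short ssDNA oligos edits bacterial genomes at high
efficiency without selection markers, but designing good oligos by hand is
slow and error-prone: the oligo must target the lagging strand of
replication, keep the mutation ≥ 15 bp from either end, avoid stable
secondary structure, and — for phenotypic goals like "knock this gene out"
or "triple this gene's translation rate" — the right mutations must first
be found. `magedesign` turns an annotated GenBank genome plus a plain-text
list of desired changes into:

- **optimized 90-nt MAGE oligos** (point mutations, insertions, deletions,
  amino-acid substitutions), reverse complemented where needed to anneal to
  the lagging-strand template, with the design frame chosen to maximize the
  folding minimum free energy (MFE) subject to 15-bp homology arms;
- **translational knockouts**: a window of consecutive codons in the first
  half of a CDS converted into tandem stop codons of all three types
  (TAA/TAG/TGA) with the provably minimal number of substitutions
  (exhaustive window × assignment scoring);
- **translation-rate tuning**: Monte Carlo simulated annealing over 5' UTR
  sequences against a pluggable expression predictor, with a per-pass
  mutation budget (pass *k* allows *k* substitutions), Metropolis
  acceptance `P(accept) = min(1, exp(-Δf/T))` on the fitness
  `f = |log(rate) − log(target)|`, automatic starting-temperature
  estimation, wobble-only constraints where the UTR overlaps an upstream
  CDS, and geometric target spacing for expression libraries;
- **MASC PCR primer sets** per mutation: allele-specific forward primers
  (`fw_wt`, `fw_mut`) 3'-anchored on the mutated bases and grown 5'-ward to
  a 62 °C nearest-neighbor melting temperature, plus ten shared reverse
  primers giving amplicons of 100–850 bp for multiplexed genotyping;
- **20-bp PCR barcodes** at both oligo ends for selective subpool
  amplification of microarray-synthesized libraries (MO-MAGE).

It is aimed at bacterial genome engineers and metabolic engineers running
recombineering/MAGE experiments, and works fully offline: a synthetic
annotated-genome generator ships in the package, and replication-geometry
presets are included for six organisms with published ssDNA-oligo
protocols (E. coli K-12 MG1655, S. typhimurium LT2, P. syringae DC3000,
L. plantarum WCFS1, L. reuteri F275, P. ananatis AJ13355).

## Worked example

```bash
python examples/knockout_and_masc_primers.py
```

prints, for the packaged 50-kb synthetic genome:

```
gene            : gene002 (+ strand, 113 codons)
stop window     : codons 21..23 -> TAA TAG TGA
substitutions   : 3
knockout oligo  : TTCAGAGTCGCAAAGGTGCCTGACCCGCAGATGCAGCTTCACTATTAGTGCGTGGTATCTGGAGAGCTCCTGCGCCTGGAAACCAGATTC
fw_wt  ( 62.6 C): TCTCCAGATACCACGCACTATCAGTGG
fw_mut ( 62.5 C): GCTCTCCAGATACCACGCACTAATAGTGA
reverse ladder  :
   100 bp amplicon  TTGAGCACAGGATCAAATTTGCATCTAGTCG  (62.4 C)
   ...
   850 bp amplicon  TCTTGGTCGCGCAGGTCTAGC  (62.9 C)
```

Reading: gene002 can be translationally knocked out with only **3**
nucleotide substitutions, converting codons 21–23 into the three stop
codon types; the 90-nt oligo carries that change with ≥ 15 bp homology
arms; the forward primers end on the mutated bases (so only the matching
allele amplifies) and melt at ≥ 62 °C; picking one reverse primer sets the
band size seen on a gel, letting several loci share one multiplexed
colony-PCR reaction.

The other examples show single-oligo design
(`examples/point_mutation_oligo.py`) and an RBS expression library
(`examples/rbs_expression_library.py`), e.g. a 57-fold predicted increase
in translation rate from 5 UTR substitutions.

## Command line

```bash
magedesign fixture --length 50000 --genes 20 --seed 1 --out demo/
magedesign run --genome demo/SYN000001.gb --replication demo/SYN000001.cfg \
    --instructions muts.txt --out results/ --seed 7
```

where `muts.txt` lists one change per line, e.g.

```
point_mutation 12345 ref=A,alt=G
knockout gene002 n_stops=3
aa_substitution gene005 residue=41,aa=W
rbs_tune gene003 fold=4,max_mutations=5
rbs_library gene001 n=10,max_mutations=5 barcode=bc_01
```

Outputs: `oligos.tsv` / `oligos.fasta`, `masc_primers.tsv`,
`expression_report.tsv` (plot-ready wild-type / maximum / per-oligo
levels), `job.log` and `config.json`. Identical inputs and `--seed` give
byte-identical outputs.

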