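# Methods

This note documents the models and procedures implemented in `magedesign`,
their assumptions, the tunable parameters with defaults and units, the
numerical choices made where the design was genuinely open, and what the
synthetic test genomes do and do not emulate.

## Replication geometry and lagging-strand targeting

ssDNA oligos recombine most efficiently when they anneal to the
lagging-strand template at the replication fork, so oligo orientation is a
function of position on the chromosome. The model: a circular chromosome
with a single bidirectional origin. The user supplies (or the loader
auto-detects from a `rep_origin` feature) an origin interval and a terminus
interval, each collapsed to the integer floor of its center. If no terminus
is known it defaults to the point diametrically opposite the origin
(`(ori_mid + L/2) mod L`) — an approximation that is adequate because
orientation only flips at the two boundaries. Arm A is the arc travelled
from the origin midpoint toward the terminus midpoint in increasing
coordinates; arm B is the complement; the origin midpoint itself belongs to
arm A and the terminus midpoint to arm B (an arbitrary but fixed
tie-break).

On arm A the fork moves in increasing coordinates; the lagging-strand
template there is the plus strand, so the annealing oligo is the
minus-strand (reverse-complemented) sequence. This mapping is a derivation
from fork direction, not an observational constant, and some bookkeeping
conventions invert it — it is therefore exposed as
`ReplicationConfig.orientation_convention` (`"standard"` / `"inverted"`).

Limitations: one origin per replicon, no multi-replicon genomes, no
origin prediction, no dif-site detection. Linear topology is supported as a
flag (windows crossing the ends become errors).

## Mutations

All edits reduce to one normalized object: a 0-based plus-strand offset,
the removed bases, the inserted bases, with any shared prefix/suffix
trimmed so the mutated region is minimal. Every mutation is verified
against the loaded genome before use; a reference mismatch is always a
hard error that reports expected vs found bases.

Amino-acid substitutions pick, among the codons of the requested residue,
one at minimal Hamming distance from the current codon. Ties break by
codon usage computed from the loaded genome's own CDSs (organism-matched
without external tables), then lexicographically for determinism.
Minus-strand genes are handled by coordinate reflection; the emitted
mutation is always in plus-strand coordinates.

Overlapping *direct* edits in one job are rejected: MAGE delivers each
oligo independently, so two oligos whose edits overlap describe an
ambiguous joint genotype. RBS library members are exempt — they all target
the same UTR window by construction and are alternatives, not
combinations.

## Oligo design

Defaults: oligo length 90 nt, minimum homology 15 bp per arm (both
user-adjustable). For a mutated region of `m` inserted bases the engine
enumerates all `L − m − 2h + 1` windows that contain the region with at
least `h` intact bases on each side (insertions enlarge the replaced
region, never the oligo; a pure deletion is a zero-width junction). Each
candidate is scored by the folding MFE **of the final oriented oligo** —
the physical molecule that folds is the reverse-complemented one on arm A,
and folding is not strand-symmetric under nearest-neighbor energies. The
maximum-MFE (least structured) frame wins; ties go to the most-centered
mutation, then the smallest window start, making output deterministic.
With optimization disabled the centered frame is returned unevaluated.

Two folding backends implement one interface:

- **ViennaRNA** (`fold_compound.mfe()` at 37 °C), the production default.
- **Toy Nussinov evaluator**: maximum nested Watson–Crick pairing, −1
  kcal/mol per pair, hairpin loops ≥ 3 nt, numba-compiled. It is exact for
  its own objective (verified against exhaustive enumeration on ≤ 14-mers)
  and is the evaluator used in tests and large sweeps, where tens of
  thousands of 90-nt folds are needed.

## Translational knockouts

A window of `n_stops` consecutive codons (default 3) is converted into
stop codons covering all three types — multiple tandem stops resist
reversion, and using all three types resists single tRNA-suppressor
escape. Placement is restricted to the first half of the gene (window's
last codon index ≤ ⌈n/2⌉) to minimize residual activity of the truncated
product, and the start codon is excluded. Scoring is exhaustive: a
codon × stop Hamming matrix, every window position, every assignment of
distinct stop types (all 3! orderings at `n_stops = 3`; for longer windows
every combination containing all three types). Minimum total substitutions
wins; equal-cost windows resolve to the one nearest the start codon. The
per-base substitutions merge into a single contiguous mutation (interior
matching bases retained) so one oligo carries the whole window.
Essentiality is not checked.

## Translation-rate tuning

The optimizer searches 5' UTR variants (window: 35 bp immediately upstream
of the start codon, configurable) whose *predicted* initiation rate hits a
target with as few substitutions as possible.

**Search.** Pass `k` (k = 1..`max_mutations`, default cap 10) runs
simulated annealing with a Hamming budget of `k` bases from wild type,
seeded from the previous pass's best sequence. Fitness is
`f = |log(rate) − log(target)|` — log scale because predicted rates span
orders of magnitude, making relative error the natural metric. Proposals
mutate one random admissible position; at the budget, half the proposals
edit or revert an already-differing position and half *relocate* a
substitution (revert one differing base, substitute a fresh position).
Without relocation the chain at budget 1 can only tinker with its single
differing position and measurably stalls (~88% success finding a planted
single-mutation optimum vs 100% with relocation at the same budget of
evaluations). Acceptance is standard Metropolis: improvements always,
worsenings with probability `exp(-Δf/T)`. Each pass cools geometrically,
`T ← 0.95·T` per round, over 1000 rounds (defaults; the pass ends early
once `f ≤ tolerance`, default 0.05 ≈ 5% relative). The starting
temperature is estimated per pass: probe 100 random single mutations,
`T₀ = median(worsening Δf) / −ln(0.8)`, so a typical worsening move starts
~80% acceptable; if nothing worsens, `T₀ = 1`. The best-so-far sequence is
tracked separately from the walking state and is monotone within and
across passes. Budget semantics are Hamming distance from wild type, not
proposal counts, so reversions free budget. If the target is never reached
the best effort is returned flagged `target_not_reached`.

**Wobble constraint.** UTR positions overlapping another annotated CDS
(either strand) admit only base changes that leave that CDS's protein
byte-identical, checked codon-wise; unconstrained positions admit all four
bases. The admissible sets are computed once per gene and enforced at
proposal time, so every visited candidate satisfies them.

**Predictor.** The expression predictor is pluggable (`predict(utr,
cds_prefix) → AU`). The packaged default is a transparent thermodynamic
surrogate, not a published calculator:

    rate = K·exp(−β·ΔG_total),
    ΔG_total = ΔG_SD + ΔG_spacing + ΔG_start − ΔG_mRNA

with the SD term the best match against the perfect anti-SD pairing motif
5'-TAAGGAGGT-3' (−2 kcal/mol per matching G/C, −1 per A/T), a quadratic
spacing penalty `0.25·(s − 5)²` kcal/mol around the optimal 5-nt aligned
spacing (minimized jointly with the alignment), start-codon terms
ATG −1.19 / GTG −0.075 / TTG 0 kcal/mol, and ΔG_mRNA the folding MFE of
the translation-initiation region (UTR + first 35 nt of CDS). `K = 2500`,
`β = 0.45 mol/kcal`. The surrogate's folding backend defaults to the toy
evaluator because an annealing run makes 10⁴–10⁵ predictor calls and a
nearest-neighbor fold of the 70-nt region costs ~50× more; results are
cached per sequence. All rates are arbitrary units; only ratios are
meaningful, and all tests of the annealer itself use mock predictors so
they test the search, not the surrogate.

**Libraries.** `generate_library(n)` spaces `n` targets geometrically
between a floor and a ceiling (the ceiling defaults to the best rate an
unconstrained maximization run can find; the job runner floors libraries
at 1.25× wild type so every member actually requires a mutation). The
geometric spacing aims the collected predicted levels at an exponential
spread across the achievable range.

## MASC PCR primers

For each designed mutation: `fw_wt` and `fw_mut` are anchored with their
3' termini on the last altered base of the wild-type and mutant sequence
respectively (allele discrimination lives at the 3' terminus, where
polymerase extension is most mismatch-sensitive) and grown base-by-base in
the 5' direction until the melting temperature reaches 62 °C — by
construction each primer is minimal. If the two primers come out
identical (possible for indels in repetitive context), the anchor shifts
one base downstream and the design repeats; exhausting the context is an
error. Ten reverse primers are designed on the *mutant* sequence, their
5' ends placed at `fw_wt 5' + L − 1` for L ∈ {100, 150, 200, 250, 300,
400, 500, 600, 700, 850} bp — amplicon length is measured 5'-to-5'
inclusive — and grown toward the amplicon interior to the same 62 °C
threshold. Lengths that run off the available context are reported as a
warning listing the missing sizes, not an error.

Melting temperatures are nearest-neighbor (unified SantaLucia parameter
set via Biopython's `Tm_NN`) at 50 mM monovalent salt and 250 nM primer,
the template in excess; these are documented configuration, and the test
suite checks them against an independently hand-rolled NN implementation.

A real limitation: a deletion of one unit of a perfect tandem repeat
longer than a primer is sequence-indistinguishable at any anchor — both
alleles contain identical primer-length windows everywhere downstream. The
shift loop then correctly exhausts the context and reports failure; such
loci need amplicon-length genotyping instead.

## Barcoding

Barcoded oligo = `left + oligo + revcomp(right)`: appending the right
barcode as its reverse complement makes both barcode strands prime toward
the insert during subpool PCR. Tables are TSV (`id`, `left`, `right`), all
sequences exactly 20 nt. The packaged default
(`data/synthetic_barcodes_default.tsv`) is a **synthetic stand-in** (the
published barcode primer sets are not reproduced here) generated by
`generate_barcode_table`: 20 pairs, GC 40–60%, and no 8-mer shared between
any two barcodes or their reverse complements — which implies the subpool
selectivity property that no left barcode shares an 8-mer with the reverse
complement of any right barcode. Enzymatic barcode removal after
amplification is out of scope.

## Synthetic fixture genomes

`make_fixture_genome(length, n_genes, seed, gc)` emits a deterministic
(byte-identical per seed) GenBank file: a random circular sequence at the
requested GC content, non-overlapping CDSs on both strands (ATG + random
non-stop codons + stop, 50–150 codons), a 201-bp `rep_origin` feature at
80% of the genome, and a matching replication config. It emulates the
*structural* properties the designers consume — annotation, strandedness,
codon structure, replication geometry — and deliberately not the
statistics of real genomes: no operons, no overlapping genes, no real SD
sequences upstream of genes, uniform base composition, no repeats.
Passing tests therefore demonstrate correctness of the design algorithms
and their invariants, not calibration of predicted rates or primer
performance on any real organism. Replication presets for six real
chromosomes ship as config files keyed by accession.

## Determinism and numerics

Every stochastic component takes an explicit seed; job-level seeds derive
per-line seeds (`(seed·1000003 + line·10007 + member·101) mod 2³¹`), which
are echoed in the reports. Reruns with identical inputs and seed are
byte-identical (fixture GenBank files carry a fixed date stamp for this
reason). Ties everywhere (frame choice, codon choice, window choice) break
by explicit deterministic rules stated above. MFE values of 0 mean
"unstructured"; evaluators never return positive values. Degenerate
inputs — empty instruction files, genes too short for a stop window,
contexts too short for the primer ladder — produce warnings or errors as
documented rather than silent fallbacks.
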