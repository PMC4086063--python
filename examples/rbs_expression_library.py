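"""Build an expression library by tuning a gene's ribosome binding site.

Runs the simulated-annealing 5' UTR optimizer against six geometrically
spaced translation-rate targets (the spread aims the collected predicted
levels at an exponential distribution).  Rates come from the packaged
thermodynamic surrogate and are arbitrary units (AU): only ratios between
them are meaningful.  Each design reports how many bases it changes — the
annealer adds substitutions one at a time and stops as soon as a target is
within 5% on the log scale.
"""

from magedesign import default_predictor, fixture_genome, generate_library, utr_context

genome = fixture_genome(50_000, 20, seed=1)
gene = genome.resolve_target("gene001")
predictor = default_predictor()

ctx = utr_context(genome, gene)
wt_rate = predictor.predict(ctx.wildtype, ctx.cds_prefix)
print(f"gene {gene.name}: wild-type predicted rate {wt_rate:.2f} AU")
print(f"wild-type UTR : {ctx.wildtype}")

library = generate_library(
    genome, gene, n=6, predictor=predictor,
    max_mutations=5, rng_seed=7, rate_floor=wt_rate * 1.25,
)

print(f"{'target (AU)':>12} {'achieved (AU)':>14} {'fold vs wt':>11} {'n mut':>6}  UTR")
for r in library:
    flag = "  (target not reached)" if r.target_not_reached else ""
    print(
        f"{r.target_rate:12.2f} {r.achieved_rate:14.2f} "
        f"{r.achieved_rate / wt_rate:11.2f} {r.n_mutations:6d}  {r.utr_best}{flag}"
    )
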