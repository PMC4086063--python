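"""Translation-rate tuning of 5' UTRs by Monte Carlo simulated annealing.

The translation initiation rate of a bacterial gene is largely set by its
5' UTR (Shine-Dalgarno strength, spacing to the start codon, start-codon
identity, and mRNA structure over the initiation region).  This module
searches for UTR variants whose *predicted* rate hits a user target with as
few nucleotide substitutions as possible:

* pass ``k`` (k = 1..max_mutations) runs a simulated-annealing walk allowed
  to differ from wild type at no more than ``k`` bases, seeded from the
  best sequence of pass ``k-1``;
* each pass cools geometrically (T <- 0.95 T per round) from a freshly
  auto-estimated starting temperature;
* proposals are accepted by the standard Metropolis criterion on the
  fitness f = |log(rate) - log(target)| (improvements always, worsenings
  with probability exp(-df/T));
* UTR positions overlapping an upstream CDS are restricted to changes that
  leave that protein untouched (wobble constraint).

Rates are arbitrary units (AU) from a pluggable predictor; the default is a
documented thermodynamic surrogate, not a published calculator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from .folding import FoldingEvaluator
from .genome import Genome, GeneRecord, GenomeError, reverse_complement
from .mutation import Mutation, MutationError, hamming, normalize, translate

BASES = ("A", "C", "G", "T")
DEFAULT_UTR_LEN = 35
DEFAULT_CDS_PREFIX_CODONS = 35


class RBSError(ValueError):
    pass


class ExpressionPredictor(Protocol):
    name: str

    def predict(self, pre_sequence: str, cds_prefix: str) -> float: ...


# ---------------------------------------------------------------------------
# Default predictor: a transparent thermodynamic surrogate


class SurrogateRBSPredictor:
    """Simplified thermodynamic translation-rate surrogate.

    rate = K * exp(-beta * dG_total) with

        dG_total = dG_SD + dG_spacing + dG_start - dG_mRNA

    * dG_SD: best match of the UTR against the perfect anti-SD pairing
      motif (5'-TAAGGAGGT-3'); each matching G/C contributes -2.0 and each
      matching A/T -1.0 kcal/mol.
    * dG_spacing: quadratic penalty ``spacing_weight * (s - s_opt)^2``
      around the optimal SD/start spacing (s_opt = 5 nt), evaluated jointly
      with the alignment so the reported SD site is the best trade-off.
    * dG_start: start-codon term (ATG -1.19, GTG -0.075, TTG 0.0 kcal/mol).
    * dG_mRNA: folding MFE of the translation-initiation region — the UTR
      plus the first ``fold_cds_nt`` bases of the CDS (a folded initiation
      region must be opened, so a more negative MFE lowers the rate).

    All constants are surrogate choices exposed as parameters; rates are AU
    and only meaningful relative to one another under the same predictor.
    The folding backend defaults to the fast Nussinov toy evaluator: an
    annealing run scores tens of thousands of candidate UTRs, so the
    surrogate favors a cheap structure term (swap in
    :class:`~magedesign.folding.ViennaFoldingEvaluator` for a
    nearest-neighbor structure term at ~50x the cost).
    """

    name = "surrogate-thermo"

    SD_MOTIF = "TAAGGAGGT"
    START_CODON_DG = {"ATG": -1.19, "GTG": -0.075, "TTG": 0.0}

    def __init__(
        self,
        evaluator: Optional[FoldingEvaluator] = None,
        scale: float = 2500.0,
        beta: float = 0.45,
        spacing_optimum: int = 5,
        spacing_weight: float = 0.25,
        fold_cds_nt: int = 35,
    ):
        from .folding import ToyFoldingEvaluator

        self.evaluator = evaluator if evaluator is not None else ToyFoldingEvaluator()
        self.scale = scale
        self.beta = beta
        self.spacing_optimum = spacing_optimum
        self.spacing_weight = spacing_weight
        self.fold_cds_nt = fold_cds_nt
        self._cache: dict[tuple[str, str], float] = {}

    def _sd_terms(self, utr: str) -> float:
        motif = self.SD_MOTIF
        best = 0.0  # no SD found: zero hybridization, full spacing penalty
        found = False
        for off in range(0, len(utr) - len(motif) + 1):
            window = utr[off : off + len(motif)]
            dg = 0.0
            for a, b in zip(window, motif):
                if a == b:
                    dg -= 2.0 if a in "GC" else 1.0
            spacing = len(utr) - (off + len(motif))
            dg += self.spacing_weight * (spacing - self.spacing_optimum) ** 2
            if not found or dg < best:
                best, found = dg, True
        return best

    def predict(self, pre_sequence: str, cds_prefix: str) -> float:
        key = (pre_sequence, cds_prefix)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        utr = pre_sequence.upper()
        cds = cds_prefix.upper()
        dg = self._sd_terms(utr)
        dg += self.START_CODON_DG.get(cds[:3], 0.5)
        initiation_region = utr + cds[: self.fold_cds_nt]
        if initiation_region:
            dg -= self.evaluator.evaluate(initiation_region)
        rate = self.scale * math.exp(-self.beta * dg)
        if len(self._cache) > 200_000:
            self._cache.clear()
        self._cache[key] = rate
        return rate


def default_predictor(evaluator: Optional[FoldingEvaluator] = None) -> SurrogateRBSPredictor:
    return SurrogateRBSPredictor(evaluator)


# ---------------------------------------------------------------------------
# UTR context and wobble constraint


@dataclass(frozen=True)
class UTRContext:
    """Everything the annealer needs about one gene's initiation region."""

    gene: GeneRecord
    wildtype: str  # UTR in coding orientation, 5'->3', ending at the start codon
    cds_prefix: str
    mutable: dict[int, tuple[str, ...]]  # local index -> admissible bases (incl. wt)
    utr_len: int

    def genome_offset(self, local: int, genome_length: int) -> int:
        """Plus-strand 0-based genome offset of UTR-local index ``local``."""
        g = self.gene
        if g.strand == "+":
            return (g.start - 1 - self.utr_len + local) % genome_length
        return (g.end + self.utr_len - 1 - local) % genome_length


def _overlapping_cds(genome: Genome, gene: GeneRecord, position0: int) -> list[GeneRecord]:
    pos1 = position0 + 1
    hits = []
    for feat in genome.cds_features():
        if feat is gene or feat.span == gene.span:
            continue
        if feat.start <= pos1 <= feat.end:
            hits.append(feat)
    return hits


def _codon_preserving(genome: Genome, feat: GeneRecord, position0: int, base: str) -> bool:
    """Would setting plus-strand ``position0`` to ``base`` keep feat's protein?"""
    if feat.strand == "+":
        off = position0 - (feat.start - 1)
    else:
        off = feat.end - 1 - position0
    codon_idx = off // 3
    in_codon = off % 3
    cds = genome.gene_sequence(feat)
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        return True
    coding_base = base if feat.strand == "+" else reverse_complement(base)
    new_codon = codon[:in_codon] + coding_base + codon[in_codon + 1 :]
    return translate(new_codon) == translate(codon)


def wobble_constrain(
    genome: Genome, gene: GeneRecord, utr_len: int = DEFAULT_UTR_LEN
) -> dict[int, tuple[str, ...]]:
    """Admissible-base sets for each UTR position (coding orientation).

    Positions free of upstream-CDS overlap admit all four bases; positions
    inside another CDS admit only bases that leave that CDS's protein
    byte-identical (in practice, synonymous wobble changes).
    """
    ctx_seq = _utr_sequence(genome, gene, utr_len)
    mutable: dict[int, tuple[str, ...]] = {}
    for local in range(utr_len):
        if gene.strand == "+":
            pos0 = (gene.start - 1 - utr_len + local) % genome.length
        else:
            pos0 = (gene.end + utr_len - 1 - local) % genome.length
        feats = _overlapping_cds(genome, gene, pos0)
        current = ctx_seq[local]
        admissible = []
        for base in BASES:
            if base == current:
                admissible.append(base)
                continue
            plus_base = base if gene.strand == "+" else reverse_complement(base)
            if all(_codon_preserving(genome, f, pos0, plus_base) for f in feats):
                admissible.append(base)
        mutable[local] = tuple(admissible)
    return mutable


def _utr_sequence(genome: Genome, gene: GeneRecord, utr_len: int) -> str:
    L = genome.length
    if gene.strand == "+":
        start0 = (gene.start - 1 - utr_len) % L
        return genome.extract_window(start0 + 1, utr_len)
    start0 = gene.end % L
    window = genome.extract_window(start0 + 1, utr_len)
    return reverse_complement(window)


def utr_context(
    genome: Genome,
    gene: GeneRecord,
    utr_len: int = DEFAULT_UTR_LEN,
    cds_prefix_codons: int = DEFAULT_CDS_PREFIX_CODONS,
) -> UTRContext:
    if utr_len < 1:
        raise RBSError("UTR window must be >= 1 bp")
    cds = genome.gene_sequence(gene)
    prefix = cds[: 3 * cds_prefix_codons]
    wildtype = _utr_sequence(genome, gene, utr_len)
    mutable = wobble_constrain(genome, gene, utr_len)
    return UTRContext(gene, wildtype, prefix, mutable, utr_len)


# ---------------------------------------------------------------------------
# Annealing


@dataclass
class AnnealState:
    """State of one annealing pass."""

    wildtype: str
    current_seq: str
    best_seq: str
    current_rate: float
    best_rate: float
    target_rate: float
    temperature: float
    pass_index: int
    mutation_budget: int
    mutable: dict[int, tuple[str, ...]]
    rng_seed: int = 0

    def fitness(self, rate: float) -> float:
        return abs(math.log(rate) - math.log(self.target_rate))

    @property
    def current_fitness(self) -> float:
        return self.fitness(self.current_rate)

    @property
    def best_fitness(self) -> float:
        return self.fitness(self.best_rate)


def _mutate_at(state: AnnealState, seq: str, i: int, rng: np.random.Generator) -> str:
    choices = [b for b in state.mutable[i] if b != seq[i]]
    if not choices:  # position differs from wt but admits only one base
        choices = [state.wildtype[i]]
    b = choices[rng.integers(len(choices))]
    return seq[:i] + b + seq[i + 1 :]


def propose(state: AnnealState, rng: np.random.Generator) -> str:
    """One random admissible change respecting the mutation budget.

    Below the budget: a single random mutable position is set to a random
    different admissible base.  At the budget, half the proposals edit or
    revert an already-differing position and half *relocate* a substitution
    (revert one differing base to wild type, substitute a fresh position),
    so the walk keeps exploring instead of stalling at the budget boundary.
    Either way Hamming(proposal, wildtype) <= budget.
    """
    differing = [i for i in state.mutable if state.current_seq[i] != state.wildtype[i]]
    at_budget = len(differing) >= state.mutation_budget
    if not at_budget:
        positions = [i for i, bases in state.mutable.items() if len(bases) > 1]
        if not positions:
            raise RBSError("no mutable UTR positions available")
        return _mutate_at(state, state.current_seq, positions[rng.integers(len(positions))], rng)
    if rng.random() < 0.5:
        return _mutate_at(state, state.current_seq, differing[rng.integers(len(differing))], rng)
    # relocation: revert one substitution, spend it elsewhere
    j = differing[rng.integers(len(differing))]
    reverted = state.current_seq[:j] + state.wildtype[j] + state.current_seq[j + 1 :]
    fresh = [
        i for i, bases in state.mutable.items()
        if i != j and len(bases) > 1 and reverted[i] == state.wildtype[i]
    ]
    if not fresh:
        return reverted
    return _mutate_at(state, reverted, fresh[rng.integers(len(fresh))], rng)


def metropolis_step(
    state: AnnealState,
    predictor: ExpressionPredictor,
    rng: np.random.Generator,
    cds_prefix: str,
) -> AnnealState:
    """One proposal + Metropolis accept/reject, updating state in place."""
    if state.temperature <= 0:
        raise RBSError("metropolis_step needs temperature > 0")
    candidate = propose(state, rng)
    rate = predictor.predict(candidate, cds_prefix)
    df = state.fitness(rate) - state.current_fitness
    if df < 0 or rng.random() < math.exp(-df / state.temperature):
        state.current_seq, state.current_rate = candidate, rate
        if state.fitness(rate) < state.best_fitness:
            state.best_seq, state.best_rate = candidate, rate
    return state


def estimate_start_temperature(
    state: AnnealState,
    predictor: ExpressionPredictor,
    rng: np.random.Generator,
    cds_prefix: str,
    n_probe: int = 100,
    p_accept_target: float = 0.8,
) -> float:
    """Starting temperature giving ~p_accept_target acceptance of a typical
    worsening move: T0 = median(worsening df) / -ln(p); 1.0 if no probe
    worsens the fitness."""
    if n_probe < 2:
        raise RBSError("n_probe must be >= 2")
    worsenings = []
    for _ in range(n_probe):
        candidate = propose(state, rng)
        df = state.fitness(predictor.predict(candidate, cds_prefix)) - state.current_fitness
        if df > 0:
            worsenings.append(df)
    if not worsenings:
        return 1.0
    return float(np.median(worsenings)) / -math.log(p_accept_target)


@dataclass(frozen=True)
class RBSResult:
    """Outcome of one tuning run."""

    gene: str
    utr_wildtype: str
    utr_best: str
    wildtype_rate: float
    achieved_rate: float
    target_rate: float
    n_mutations: int
    target_not_reached: bool
    seed: int
    mutation: Optional[Mutation]  # None when zero substitutions suffice


def optimize_rbs(
    genome: Genome,
    gene: GeneRecord,
    target_rate: float,
    predictor: ExpressionPredictor,
    max_mutations: int = 10,
    rounds_per_pass: int = 1000,
    cooling: float = 0.95,
    tolerance: float = 0.05,
    rng_seed: int = 0,
    utr_len: int = DEFAULT_UTR_LEN,
    context: Optional[UTRContext] = None,
) -> RBSResult:
    """Hit ``target_rate`` with the fewest UTR substitutions.

    Pass k allows at most k bases to differ from wild type and starts from
    the previous pass's best sequence; annealing stops early once
    |log(best/target)| <= tolerance.  When the target is unreachable within
    ``max_mutations`` bases, the best effort is returned flagged
    ``target_not_reached``.
    """
    if target_rate <= 0:
        raise RBSError("target rate must be > 0")
    ctx = context if context is not None else utr_context(genome, gene, utr_len)
    rng = np.random.default_rng(rng_seed)
    wt_rate = predictor.predict(ctx.wildtype, ctx.cds_prefix)
    best_seq, best_rate = ctx.wildtype, wt_rate

    def fit(rate: float) -> float:
        return abs(math.log(rate) - math.log(target_rate))

    reached = fit(best_rate) <= tolerance
    for k in range(1, max_mutations + 1):
        if reached:
            break
        state = AnnealState(
            wildtype=ctx.wildtype,
            current_seq=best_seq,
            best_seq=best_seq,
            current_rate=best_rate,
            best_rate=best_rate,
            target_rate=target_rate,
            temperature=1.0,
            pass_index=k,
            mutation_budget=k,
            mutable=ctx.mutable,
            rng_seed=rng_seed,
        )
        state.temperature = estimate_start_temperature(
            state, predictor, rng, ctx.cds_prefix
        )
        for _ in range(rounds_per_pass):
            metropolis_step(state, predictor, rng, ctx.cds_prefix)
            state.temperature = max(state.temperature * cooling, 1e-12)
            if fit(state.best_rate) <= tolerance:
                break
        best_seq, best_rate = state.best_seq, state.best_rate
        reached = fit(best_rate) <= tolerance

    n_mut = hamming(best_seq, ctx.wildtype)
    mutation = _utr_mutation(genome, ctx, best_seq) if n_mut else None
    return RBSResult(
        gene=gene.name,
        utr_wildtype=ctx.wildtype,
        utr_best=best_seq,
        wildtype_rate=wt_rate,
        achieved_rate=best_rate,
        target_rate=target_rate,
        n_mutations=n_mut,
        target_not_reached=not reached,
        seed=rng_seed,
        mutation=mutation,
    )


def _utr_mutation(genome: Genome, ctx: UTRContext, best_seq: str) -> Mutation:
    """Merge UTR substitutions into one plus-strand genome Mutation."""
    g = ctx.gene
    L = genome.length
    if g.strand == "+":
        g0 = (g.start - 1 - ctx.utr_len) % L
        removed, inserted = ctx.wildtype, best_seq
    else:
        g0 = g.end % L
        removed = reverse_complement(ctx.wildtype)
        inserted = reverse_complement(best_seq)
    if g0 + ctx.utr_len > L:
        raise RBSError("UTR window wraps the genome origin; not supported")
    return normalize(g0, removed, inserted, label=f"rbs_{g.name}")


def generate_library(
    genome: Genome,
    gene: GeneRecord,
    n: int,
    predictor: ExpressionPredictor,
    max_mutations: int = 10,
    rounds_per_pass: int = 1000,
    tolerance: float = 0.05,
    rng_seed: int = 0,
    utr_len: int = DEFAULT_UTR_LEN,
    rate_floor: Optional[float] = None,
    rate_ceiling: Optional[float] = None,
) -> list[RBSResult]:
    """n designs whose targets span the achievable range geometrically.

    The ceiling defaults to the best rate found by an unconstrained
    maximization run; the floor to the wild-type rate.  Geometric target
    spacing aims the collected predicted levels at an exponential spread.
    """
    if n < 2:
        raise RBSError("library size must be >= 2")
    ctx = utr_context(genome, gene, utr_len)
    wt_rate = predictor.predict(ctx.wildtype, ctx.cds_prefix)
    if rate_ceiling is None:
        probe = optimize_rbs(
            genome, gene, wt_rate * 1e9, predictor,
            max_mutations=max_mutations, rounds_per_pass=rounds_per_pass,
            tolerance=tolerance, rng_seed=rng_seed, context=ctx,
        )
        rate_ceiling = probe.achieved_rate
    r_lo = rate_floor if rate_floor is not None else wt_rate
    r_hi = max(rate_ceiling, r_lo * 1.0001)
    targets = [r_lo * (r_hi / r_lo) ** (i / (n - 1)) for i in range(n)]
    results = []
    for i, target in enumerate(targets):
        results.append(
            optimize_rbs(
                genome, gene, target, predictor,
                max_mutations=max_mutations, rounds_per_pass=rounds_per_pass,
                tolerance=tolerance, rng_seed=rng_seed + 1 + i, context=ctx,
            )
        )
    return results
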