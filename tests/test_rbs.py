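"""Simulated-annealing RBS tuning: predictor, Metropolis walk, constraints."""

import math
import zlib

import numpy as np
import pytest

from magedesign.folding import ToyFoldingEvaluator, UniformFoldingEvaluator
from magedesign.genome import Genome, GeneRecord, ReplicationConfig, reverse_complement
from magedesign.mutation import apply_mutation, hamming, translate
from magedesign.rbs import (
    AnnealState,
    RBSError,
    SurrogateRBSPredictor,
    estimate_start_temperature,
    generate_library,
    metropolis_step,
    optimize_rbs,
    utr_context,
    wobble_constrain,
)


class MockPredictor:
    """Rate is an arbitrary deterministic function of the UTR alone."""

    name = "mock"

    def __init__(self, fn):
        self.fn = fn

    def predict(self, pre_sequence, cds_prefix):
        return self.fn(pre_sequence)


def crc_landscape(utr: str) -> float:
    """Deterministic rugged landscape in (1, 1001)."""
    return 1.0 + (zlib.crc32(utr.encode()) % 10_000) / 10.0


def make_state(wildtype, predictor, target, budget, temperature=1.0, current=None):
    current = current if current is not None else wildtype
    rate = predictor.predict(current, "")
    mutable = {i: ("A", "C", "G", "T") for i in range(len(wildtype))}
    return AnnealState(
        wildtype=wildtype,
        current_seq=current,
        best_seq=current,
        current_rate=rate,
        best_rate=rate,
        target_rate=target,
        temperature=temperature,
        pass_index=1,
        mutation_budget=budget,
        mutable=mutable,
    )


WT = "ACTACTACTACTACTACTACTACTACTACTACTAC"  # 35 nt, SD-free


class TestSurrogatePredictor:
    def test_sd_strength_increases_rate(self):
        pred = SurrogateRBSPredictor(UniformFoldingEvaluator())
        utr_sd = "A" * 17 + "AGGAGG" + "ACAAACAACACA"[:12]
        utr_weak = "A" * 17 + "ACTACT" + "ACAAACAACACA"[:12]
        cds = "ATG" + "GCT" * 10
        assert pred.predict(utr_sd, cds) > pred.predict(utr_weak, cds)

    def test_hairpin_over_sd_decreases_rate(self):
        pred = SurrogateRBSPredictor(ToyFoldingEvaluator())
        core = "TAAGGAGGT"
        plain = "A" * 14 + core + "ACAACAACAACA"[:12]
        hairpin = "A" * 5 + reverse_complement(core) + core + "ACAACAACAACA"[:12]
        cds = "ATG" + "GCT" * 10
        assert pred.predict(hairpin, cds) < pred.predict(plain, cds)

    def test_start_codon_ordering(self):
        pred = SurrogateRBSPredictor(UniformFoldingEvaluator())
        utr = "A" * 17 + "AGGAGG" + "A" * 12
        tail = "GCT" * 10
        atg = pred.predict(utr, "ATG" + tail)
        gtg = pred.predict(utr, "GTG" + tail)
        ttg = pred.predict(utr, "TTG" + tail)
        assert atg > gtg > ttg

    def test_deterministic_and_positive(self):
        pred = SurrogateRBSPredictor(ToyFoldingEvaluator())
        cds = "ATG" + "GCT" * 12
        r1 = pred.predict(WT, cds)
        assert r1 == pred.predict(WT, cds)
        assert r1 > 0


class TestStartTemperature:
    def test_closed_form_constant_worsening(self):
        # every single mutation worsens fitness by exactly 2.0
        pred = MockPredictor(lambda u: 1000.0 if u == WT else 1000.0 * math.e**2)
        state = make_state(WT, pred, target=1000.0, budget=5)
        t0 = estimate_start_temperature(state, pred, np.random.default_rng(0), "")
        assert t0 == pytest.approx(2.0 / -math.log(0.8), rel=1e-9)
        assert t0 == pytest.approx(8.963, abs=5e-3)

    def test_fallback_when_nothing_worsens(self):
        pred = MockPredictor(lambda u: 500.0)
        state = make_state(WT, pred, target=500.0, budget=5)
        assert estimate_start_temperature(state, pred, np.random.default_rng(0), "") == 1.0

    def test_seeded_reproducibility(self):
        pred = MockPredictor(crc_landscape)
        t = [
            estimate_start_temperature(
                make_state(WT, pred, 900.0, 5), pred, np.random.default_rng(3), ""
            )
            for _ in range(2)
        ]
        assert t[0] == t[1]


class TestMetropolis:
    def test_acceptance_frequency_matches_boltzmann(self):
        # every proposal worsens by exactly df; acceptance ~ exp(-df/T)
        df, temp, n = 0.5, 1.0, 10_000
        pred = MockPredictor(lambda u: 1000.0 if u == WT else 1000.0 * math.exp(df))
        rng = np.random.default_rng(123)
        accepted = 0
        for _ in range(n):
            state = make_state(WT, pred, target=1000.0, budget=35, temperature=temp)
            metropolis_step(state, pred, rng, "")
            accepted += state.current_seq != WT
        p = math.exp(-df / temp)
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(accepted / n - p) < 3 * sigma

    def test_improving_moves_always_accepted(self):
        # from a uniformly bad sequence every proposal improves; all accepted
        pred = MockPredictor(lambda u: 10.0 if u == WT else 1000.0)
        rng = np.random.default_rng(5)
        for _ in range(50):
            state = make_state(WT, pred, target=1000.0, budget=35, temperature=1e-9)
            metropolis_step(state, pred, rng, "")
            assert state.current_seq != WT

    def test_zero_temperature_limit_is_hill_climbing(self):
        pred = MockPredictor(crc_landscape)
        rng = np.random.default_rng(17)
        state = make_state(WT, pred, target=990.0, budget=35, temperature=1e-12)
        last = state.current_fitness
        for _ in range(2000):
            metropolis_step(state, pred, rng, "")
            assert state.current_fitness <= last + 1e-12
            last = state.current_fitness

    def test_budget_invariant_under_fuzzing(self):
        pred = MockPredictor(crc_landscape)
        rng = np.random.default_rng(29)
        state = make_state(WT, pred, target=990.0, budget=3, temperature=5.0)
        for _ in range(2000):
            metropolis_step(state, pred, rng, "")
            assert hamming(state.current_seq, WT) <= 3
            assert hamming(state.best_seq, WT) <= 3

    def test_best_fitness_monotone_within_pass(self):
        pred = MockPredictor(crc_landscape)
        rng = np.random.default_rng(31)
        state = make_state(WT, pred, target=990.0, budget=5, temperature=2.0)
        best = state.best_fitness
        for _ in range(1000):
            metropolis_step(state, pred, rng, "")
            assert state.best_fitness <= best + 1e-12
            best = state.best_fitness
            state.temperature *= 0.99

    def test_requires_positive_temperature(self):
        pred = MockPredictor(crc_landscape)
        state = make_state(WT, pred, target=990.0, budget=5, temperature=0.0)
        with pytest.raises(RBSError):
            metropolis_step(state, pred, np.random.default_rng(0), "")


class TestOptimizeRBS:
    def test_target_equal_to_wildtype_returns_immediately(self, genome):
        gene = genome.cds_features()[0]
        pred = SurrogateRBSPredictor(ToyFoldingEvaluator())
        ctx = utr_context(genome, gene)
        wt_rate = pred.predict(ctx.wildtype, ctx.cds_prefix)
        res = optimize_rbs(genome, gene, wt_rate, pred, rng_seed=1)
        assert res.n_mutations == 0
        assert res.mutation is None
        assert not res.target_not_reached

    def test_single_mutation_optimum_found_in_pass_one(self, genome):
        gene = genome.cds_features()[0]
        ctx = utr_context(genome, gene)
        idx = 7
        goal = "G" if ctx.wildtype[idx] != "G" else "C"

        def fn(utr):
            return 1000.0 if utr[idx] == goal else 1.0

        hits = 0
        for seed in range(5):
            res = optimize_rbs(
                genome, gene, 1000.0, MockPredictor(fn),
                max_mutations=3, rounds_per_pass=300, rng_seed=seed,
            )
            if res.n_mutations == 1 and not res.target_not_reached:
                hits += 1
        assert hits >= 4

    def test_unreachable_target_flagged_and_budget_respected(self, genome):
        gene = genome.cds_features()[0]
        res = optimize_rbs(
            genome, gene, 1e12, MockPredictor(crc_landscape),
            max_mutations=5, rounds_per_pass=50, rng_seed=2,
        )
        assert res.target_not_reached
        assert res.n_mutations <= 5
        assert hamming(res.utr_best, res.utr_wildtype) == res.n_mutations

    def test_invalid_target(self, genome):
        gene = genome.cds_features()[0]
        with pytest.raises(RBSError):
            optimize_rbs(genome, gene, -5.0, MockPredictor(crc_landscape))

    def test_mutation_maps_back_to_genome(self, genome):
        gene = next(g for g in genome.cds_features() if g.strand == "-")
        ctx = utr_context(genome, gene)
        idx = 3
        goal = "G" if ctx.wildtype[idx] != "G" else "C"
        res = optimize_rbs(
            genome, gene, 1000.0,
            MockPredictor(lambda u: 1000.0 if u[idx] == goal else 1.0),
            max_mutations=3, rounds_per_pass=300, rng_seed=4,
        )
        assert res.mutation is not None
        mutated = apply_mutation(genome.sequence, res.mutation)
        new_utr = reverse_complement(mutated[gene.end : gene.end + 35])
        assert new_utr == res.utr_best


def wobble_oracle(genome, upstream, base_pos0, plus_base):
    """Direct check: mutate the genome base and retranslate the upstream CDS."""
    before = translate(genome.gene_sequence(upstream))
    seq = genome.sequence
    mutated = seq[:base_pos0] + plus_base + seq[base_pos0 + 1 :]
    region = mutated[upstream.start - 1 : upstream.end]
    if upstream.strand == "-":
        region = reverse_complement(region)
    return translate(region) == before


def overlap_genome(upstream_strand="+"):
    """geneU's 3' end overlaps geneT's 35-bp UTR window."""
    from magedesign.fixtures import _random_cds

    rng = np.random.default_rng(99)
    cds_u = _random_cds(rng, 30)  # 90 nt
    cds_t = _random_cds(rng, 40)  # 120 nt
    placed_u = cds_u if upstream_strand == "+" else reverse_complement(cds_u)
    seq = "A" * 200 + placed_u + "AAAAAAAAAA" + cds_t + "A" * 300
    u_start = 201
    t_start = u_start + 90 + 10
    features = [
        GeneRecord("geneU", "U1", upstream_strand, (u_start, u_start + 89)),
        GeneRecord("geneT", "T1", "+", (t_start, t_start + 119)),
    ]
    L = len(seq)
    return Genome(seq, features, ReplicationConfig((1, 1), (L // 2, L // 2)))


class TestWobbleConstraint:
    def test_no_overlap_fully_mutable(self, genome):
        gene = genome.cds_features()[0]
        mutable = wobble_constrain(genome, gene)
        assert all(len(bases) == 4 for bases in mutable.values())

    @pytest.mark.parametrize("upstream_strand", ["+", "-"])
    def test_admissible_sets_match_retranslation_oracle(self, upstream_strand):
        g = overlap_genome(upstream_strand)
        gene_t = g.resolve_target("geneT")
        upstream = g.resolve_target("geneU")
        mutable = wobble_constrain(g, gene_t)
        overlap_seen = False
        for local, admissible in mutable.items():
            pos0 = gene_t.start - 1 - 35 + local  # geneT is plus strand
            current = g.sequence[pos0]
            in_overlap = upstream.start <= pos0 + 1 <= upstream.end
            overlap_seen |= in_overlap
            for base in "ACGT":
                expected = base == current or (
                    wobble_oracle(g, upstream, pos0, base) if in_overlap else True
                )
                assert (base in admissible) == expected, (local, base)
        assert overlap_seen

    def test_accepted_candidates_preserve_upstream_protein(self):
        g = overlap_genome("+")
        gene_t = g.resolve_target("geneT")
        upstream = g.resolve_target("geneU")
        before = translate(g.gene_sequence(upstream))
        res = optimize_rbs(
            g, gene_t, 1e9, MockPredictor(crc_landscape),
            max_mutations=6, rounds_per_pass=100, rng_seed=11,
        )
        assert res.mutation is not None
        mutated = apply_mutation(g.sequence, res.mutation)
        region = mutated[upstream.start - 1 : upstream.end]
        assert translate(region) == before


class TestGenerateLibrary:
    def test_geometric_target_spacing(self, genome):
        gene = genome.cds_features()[1]
        results = generate_library(
            genome, gene, 10, MockPredictor(crc_landscape),
            max_mutations=2, rounds_per_pass=20, rng_seed=0,
            rate_floor=10.0, rate_ceiling=10_000.0,
        )
        targets = [r.target_rate for r in results]
        assert targets[0] == pytest.approx(10.0)
        assert targets[-1] == pytest.approx(10_000.0)
        ratios = [b / a for a, b in zip(targets, targets[1:])]
        assert all(r == pytest.approx(1000 ** (1 / 9), rel=1e-9) for r in ratios)

    def test_budget_respected_and_rates_ordered(self, genome):
        gene = genome.cds_features()[1]

        def smooth(utr):  # rate grows with G content: an easy, monotone landscape
            return 10.0 * 2.0 ** sum(b == "G" for b in utr)

        pred = MockPredictor(smooth)
        ctx = utr_context(genome, gene)
        wt = pred.predict(ctx.wildtype, ctx.cds_prefix)
        results = generate_library(
            genome, gene, 6, pred,
            max_mutations=8, rounds_per_pass=150, rng_seed=1,
            rate_floor=wt * 1.2, rate_ceiling=wt * 50,
        )
        assert all(r.n_mutations <= 8 for r in results)
        by_target = sorted(results, key=lambda r: r.target_rate)
        achieved = [r.achieved_rate for r in by_target]
        assert achieved == sorted(achieved)

    def test_library_size_validated(self, genome):
        gene = genome.cds_features()[0]
        with pytest.raises(RBSError):
            generate_library(genome, gene, 1, MockPredictor(crc_landscape))
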