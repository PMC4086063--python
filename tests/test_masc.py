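"""MASC PCR primer design: Tm model, allele anchoring, amplicon ladder."""

import math

import numpy as np
import pytest

from magedesign.genome import reverse_complement
from magedesign.masc import (
    AMPLICON_LENGTHS,
    TM_THRESHOLD,
    PrimerDesignError,
    design_forward_primers,
    design_masc_set,
    design_reverse_primers,
    melting_temperature,
)
from magedesign.mutation import Mutation, apply_mutation

from conftest import random_point_mutation

# Independent nearest-neighbor Tm oracle: unified NN parameters
# (SantaLucia & Hicks 2004), written out by hand so it shares no code with
# the implementation.  dH kcal/mol, dS cal/(mol*K).
NN = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT = (0.2, -5.7)
TERM_AT = (2.2, 6.9)


def tm_oracle(seq, na_mm=50.0, primer_nm=250.0):
    dh, ds = INIT
    for a, b in zip(seq, seq[1:]):
        h, s = NN[a + b]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            h, s = TERM_AT
            dh += h
            ds += s
    # salt correction (SantaLucia 1998 entropy form); with the template in
    # vast excess the effective strand concentration is the full 250 nM
    ds += 0.368 * (len(seq) - 1) * math.log(na_mm / 1000.0)
    R = 1.987
    k = primer_nm * 1e-9
    return dh * 1000.0 / (ds + R * math.log(k)) - 273.15


class TestMeltingTemperature:
    def test_gc_rich_melts_higher(self):
        gc = "GCGGCCGCATGCGGCCGCAT"
        at = "ATTATAATTAATTAATATTA"
        assert melting_temperature(gc) > melting_temperature(at)

    @pytest.mark.parametrize(
        "seq",
        [
            "ACGTACGTACGTACGTACGT",
            "GGGCCCAAATTTGGGCCCAT",
            "TTGACAATTAATCATCGGCTC",
            "AGCTAGCTAGCTAGCTAGCTAGCT",
        ],
    )
    def test_matches_independent_nn_oracle(self, seq):
        assert melting_temperature(seq) == pytest.approx(tm_oracle(seq), abs=0.5)

    def test_too_short_primer(self):
        with pytest.raises(PrimerDesignError, match="shorter"):
            melting_temperature("ACGTA")

    def test_invalid_characters(self):
        with pytest.raises(PrimerDesignError):
            melting_temperature("ACGTACGTNN")


class TestForwardPrimers:
    def _contexts(self, genome, mutation):
        start0 = mutation.position - 300
        wt = genome.sequence[start0 : start0 + 1300]
        mut = apply_mutation(wt, Mutation(300, mutation.removed, mutation.inserted))
        return wt, mut

    def test_snp_primers_differ_at_3prime_base(self, genome):
        mut = random_point_mutation(genome, np.random.default_rng(20))
        wt_ctx, mut_ctx = self._contexts(genome, mut)
        fw_wt, fw_mut, _ = design_forward_primers(wt_ctx, mut_ctx, 300, 300)
        assert fw_wt[-1] != fw_mut[-1]
        assert fw_wt[-1] == mut.removed and fw_mut[-1] == mut.inserted
        assert melting_temperature(fw_wt) >= TM_THRESHOLD
        assert melting_temperature(fw_mut) >= TM_THRESHOLD

    def test_primers_are_minimal(self, genome):
        mut = random_point_mutation(genome, np.random.default_rng(21))
        wt_ctx, mut_ctx = self._contexts(genome, mut)
        fw_wt, fw_mut, _ = design_forward_primers(wt_ctx, mut_ctx, 300, 300)
        for primer in (fw_wt, fw_mut):
            if len(primer) > 8:
                assert melting_temperature(primer[1:]) < TM_THRESHOLD

    def test_anchor_shifts_until_primers_differ(self, genome):
        # contexts identical around the initial anchor (as after deleting one
        # unit of a local repeat): the anchor must walk downstream until the
        # grown primers become distinguishable
        rng = np.random.default_rng(22)
        common = "".join("ACGT"[i] for i in rng.integers(4, size=400))
        tail_a = "".join("ACGT"[i] for i in rng.integers(4, size=400))
        tail_b = "".join("ACGT"[i] for i in rng.integers(4, size=400))
        wt_ctx, mut_ctx = common + tail_a, common + tail_b
        fw_wt, fw_mut, anchor = design_forward_primers(wt_ctx, mut_ctx, 340, 340)
        assert fw_wt != fw_mut
        assert anchor >= 400  # shifted past the shared region
        assert melting_temperature(fw_wt) >= TM_THRESHOLD
        assert melting_temperature(fw_mut) >= TM_THRESHOLD

    def test_deletion_with_unique_context_needs_no_shift(self, genome):
        pos = 22_000
        removed = genome.extract_window(pos + 1, 3)
        mut = Mutation(pos, removed, "")
        ps = design_masc_set(genome, mut, "del_1")
        assert ps.fw_wt.sequence != ps.fw_mut.sequence
        # wt primer ends on the deleted bases, mut primer on the junction
        assert ps.fw_wt.sequence.endswith(removed[-1])

    def test_identical_contexts_rejected(self):
        ctx = "ACGT" * 200
        with pytest.raises(PrimerDesignError, match="cannot be distinguished"):
            design_forward_primers(ctx, ctx, 300, 300)


class TestReversePrimers:
    def test_full_ladder(self, genome):
        mut = random_point_mutation(genome, np.random.default_rng(23))
        start0 = mut.position - 100
        ctx = apply_mutation(
            genome.sequence[start0 : start0 + 1100],
            Mutation(100, mut.removed, mut.inserted),
        )
        primers, warnings = design_reverse_primers(ctx, 80)
        assert [p.amplicon_length for p in primers] == list(AMPLICON_LENGTHS)
        assert not warnings
        for p in primers:
            assert melting_temperature(p.sequence) >= TM_THRESHOLD
            # exact reverse-complement substring of the mutant sequence
            assert reverse_complement(p.sequence) in ctx

    def test_truncated_context_warns_with_missing_lengths(self, genome):
        ctx = genome.sequence[1000:1450]  # 450 bp total
        primers, warnings = design_reverse_primers(ctx, 0)
        lengths = [p.amplicon_length for p in primers]
        assert lengths == [100, 150, 200, 250, 300, 400]
        assert len(warnings) == 1
        for missing in (500, 600, 700, 850):
            assert str(missing) in warnings[0]

    def test_amplicon_length_is_five_prime_to_five_prime(self, genome):
        mut = random_point_mutation(genome, np.random.default_rng(24))
        start0 = mut.position - 100
        ctx = genome.sequence[start0 : start0 + 1100]
        fw_start = 80
        primers, _ = design_reverse_primers(ctx, fw_start)
        for p in primers:
            # the primer's template (its reverse complement) must end exactly
            # at (fw 5' position + L - 1): lengths are 5'-to-5' inclusive
            end = fw_start + p.amplicon_length - 1
            template = ctx[end - len(p.sequence) + 1 : end + 1]
            assert reverse_complement(p.sequence) == template


class TestMascSet:
    def test_fixture_snp_complete_set(self, genome):
        mut = random_point_mutation(genome, np.random.default_rng(25))
        ps = design_masc_set(genome, mut, "oligo_1")
        assert ps.fw_wt.sequence != ps.fw_mut.sequence
        assert all(p.tm >= TM_THRESHOLD for p in ps.all_primers())
        lengths = [p.amplicon_length for p in ps.reverse_primers]
        assert lengths == sorted(lengths) == list(AMPLICON_LENGTHS)

    def test_allele_specificity_at_3prime_terminus(self, genome):
        mut = random_point_mutation(genome, np.random.default_rng(26))
        start0 = mut.position - 300
        wt_ctx = genome.sequence[start0 : start0 + 1300]
        mut_ctx = apply_mutation(wt_ctx, Mutation(300, mut.removed, mut.inserted))
        ps = design_masc_set(genome, mut, "oligo_2")
        assert ps.fw_mut.sequence in mut_ctx
        assert ps.fw_wt.sequence in wt_ctx
        # fw_mut mismatches the wild type within its 3 terminal 3' bases
        site = mut_ctx.index(ps.fw_mut.sequence)
        wt_counterpart = wt_ctx[site : site + len(ps.fw_mut.sequence)]
        assert ps.fw_mut.sequence[-3:] != wt_counterpart[-3:]

    def test_distinct_sets_keyed_by_oligo_id(self, genome):
        rng = np.random.default_rng(27)
        m1, m2 = random_point_mutation(genome, rng), random_point_mutation(genome, rng)
        s1 = design_masc_set(genome, m1, "a")
        s2 = design_masc_set(genome, m2, "b")
        assert {s1.oligo_id, s2.oligo_id} == {"a", "b"}
        assert s1.fw_mut.sequence != s2.fw_mut.sequence
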