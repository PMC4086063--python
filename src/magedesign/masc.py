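"""Multiplex allele-specific colony PCR (MASC PCR) primer design.

For each designed mutation three primer roles are produced: a forward
primer specific to the wild-type allele (fw_wt), one specific to the
mutant allele (fw_mut) — both 3'-anchored on the mutated bases and grown
5'-ward until they reach a 62 C melting temperature — and a ladder of ten
shared reverse primers giving amplicons of 100, 150, 200, 250, 300, 400,
500, 600, 700 and 850 bp, so many loci can be genotyped in one multiplexed
reaction and read out by band size.

Melting temperatures use nearest-neighbor thermodynamics (unified
SantaLucia table via Biopython) at 50 mM monovalent salt and 250 nM primer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.SeqUtils import MeltingTemp as _mt

from .genome import Genome, reverse_complement
from .mutation import Mutation, apply_mutation, verify_mutation

AMPLICON_LENGTHS = (100, 150, 200, 250, 300, 400, 500, 600, 700, 850)
TM_THRESHOLD = 62.0
MIN_PRIMER_LEN = 8

#: Tm model parameters (documented config): unified NN table, 50 mM Na+,
#: 250 nM primer, no template excess.
TM_PARAMS = dict(Na=50, dnac1=250.0, dnac2=0.0, saltcorr=5)


class PrimerDesignError(ValueError):
    pass


def melting_temperature(primer: str) -> float:
    """Nearest-neighbor Tm in C; primers must be >= 8 nt and ACGT-only."""
    if len(primer) < MIN_PRIMER_LEN:
        raise PrimerDesignError(
            f"primer {primer!r} shorter than {MIN_PRIMER_LEN} nt"
        )
    bad = set(primer) - set("ACGT")
    if bad:
        raise PrimerDesignError(f"non-ACGT characters in primer: {sorted(bad)}")
    return float(_mt.Tm_NN(primer, nn_table=_mt.DNA_NN3, **TM_PARAMS))


@dataclass(frozen=True)
class Primer:
    role: str
    sequence: str
    tm: float
    amplicon_length: Optional[int] = None


@dataclass(frozen=True)
class PrimerSet:
    oligo_id: str
    fw_wt: Primer
    fw_mut: Primer
    reverse_primers: tuple[Primer, ...]
    warnings: tuple[str, ...] = ()

    def all_primers(self) -> list[Primer]:
        return [self.fw_wt, self.fw_mut, *self.reverse_primers]


def _grow_5prime(context: str, anchor: int, threshold: float = TM_THRESHOLD) -> str:
    """Grow a forward primer 5'-ward from 3' anchor ``anchor`` (0-based,
    inclusive) until Tm >= threshold; minimal by construction."""
    for length in range(MIN_PRIMER_LEN, anchor + 2):
        start = anchor + 1 - length
        if start < 0:
            break
        primer = context[start : anchor + 1]
        if melting_temperature(primer) >= threshold:
            return primer
    achieved = melting_temperature(context[: anchor + 1]) if anchor + 1 >= MIN_PRIMER_LEN else 0.0
    raise PrimerDesignError(
        f"cannot reach Tm {threshold} C within available upstream context "
        f"(achieved {achieved:.1f} C)"
    )


def design_forward_primers(
    wt_context: str,
    mut_context: str,
    wt_anchor: int,
    mut_anchor: int,
    threshold: float = TM_THRESHOLD,
) -> tuple[str, str, int]:
    """Allele-discriminating forward primers, 3'-anchored on the mutation.

    Both primers end at the last altered base of their own sequence and are
    extended upstream until they melt at ``threshold``.  If the two come
    out identical (possible for deletions) the anchor is shifted one base
    downstream and the design repeated until they differ.  Returns
    (fw_wt, fw_mut, final wt anchor offset).
    """
    if wt_context == mut_context:
        raise PrimerDesignError("primers cannot be distinguished: contexts are identical")
    shift = 0
    while True:
        wa, ma = wt_anchor + shift, mut_anchor + shift
        if wa >= len(wt_context) or ma >= len(mut_context):
            raise PrimerDesignError(
                "anchor shifted past available context without finding "
                "distinguishable primers"
            )
        fw_wt = _grow_5prime(wt_context, wa, threshold)
        fw_mut = _grow_5prime(mut_context, ma, threshold)
        if fw_wt != fw_mut:
            return fw_wt, fw_mut, wa
        shift += 1


def design_reverse_primers(
    mut_context: str,
    fw_wt_5prime: int,
    threshold: float = TM_THRESHOLD,
    amplicon_lengths: tuple[int, ...] = AMPLICON_LENGTHS,
) -> tuple[list[Primer], list[str]]:
    """Reverse-primer ladder on the mutant sequence.

    For target amplicon length L the reverse primer's 5' end sits at
    (fw_wt 5' position + L - 1); lengths are therefore measured 5'-to-5'
    inclusive.  The primer is the reverse complement of the template, grown
    toward the amplicon interior until it melts at ``threshold``.  Lengths
    that run off the context are reported as warnings, not errors.
    """
    primers: list[Primer] = []
    missing: list[int] = []
    for L in amplicon_lengths:
        end = fw_wt_5prime + L - 1  # 5' end of the reverse primer on the template
        if end >= len(mut_context):
            missing.append(L)
            continue
        primer = None
        for k in range(MIN_PRIMER_LEN, end + 2):
            candidate = reverse_complement(mut_context[end - k + 1 : end + 1])
            if melting_temperature(candidate) >= threshold:
                primer = candidate
                break
        if primer is None:
            missing.append(L)
            continue
        primers.append(Primer("rev", primer, melting_temperature(primer), L))
    warnings = (
        [f"insufficient downstream context for amplicon lengths {missing}"]
        if missing
        else []
    )
    return primers, warnings


def design_masc_set(
    genome: Genome,
    mutation: Mutation,
    oligo_id: str,
    threshold: float = TM_THRESHOLD,
    upstream: int = 300,
    downstream: int = 1000,
) -> PrimerSet:
    """Complete MASC primer set for one designed mutation.

    Context is cut from the genome around the mutation (circularly); the
    mutant context is obtained by applying the mutation to it.
    """
    verify_mutation(genome, mutation)
    upstream = min(upstream, genome.length // 3)
    start0 = (mutation.position - upstream) % genome.length
    total = min(upstream + len(mutation.removed) + downstream, genome.length)
    wt_context = genome.extract_window(start0 + 1, total)
    local = Mutation(upstream, mutation.removed, mutation.inserted, mutation.label)
    mut_context = apply_mutation(wt_context, local)

    wt_anchor = upstream + len(mutation.removed) - 1 if mutation.removed else upstream - 1
    mut_anchor = upstream + len(mutation.inserted) - 1 if mutation.inserted else upstream - 1
    fw_wt_seq, fw_mut_seq, wa = design_forward_primers(
        wt_context, mut_context, wt_anchor, mut_anchor, threshold
    )
    fw_wt_5prime = wa + 1 - len(fw_wt_seq)
    # the reverse ladder lives on the mutant coordinate system; a 5' end
    # upstream of the mutated region has the same offset in both systems
    if fw_wt_5prime <= upstream:
        mut_fw_wt_5prime = fw_wt_5prime
    else:
        mut_fw_wt_5prime = fw_wt_5prime + mutation.length_change
    rev, warnings = design_reverse_primers(
        mut_context, max(mut_fw_wt_5prime, 0), threshold
    )
    return PrimerSet(
        oligo_id=oligo_id,
        fw_wt=Primer("fw_wt", fw_wt_seq, melting_temperature(fw_wt_seq)),
        fw_mut=Primer("fw_mut", fw_mut_seq, melting_temperature(fw_mut_seq)),
        reverse_primers=tuple(rev),
        warnings=tuple(warnings),
    )
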