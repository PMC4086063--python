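"""Translational gene knockouts via tandem stop codons.

Instead of deleting a gene (which recombines poorly without selection), a
window of consecutive codons in the first half of the CDS is converted into
tandem stop codons — by default three, one of each type (TAA/TAG/TGA), so
that neither reversion nor a single tRNA suppressor can restore function.
A brute-force scoring scheme finds the window and stop assignment needing
the fewest nucleotide substitutions; ties go to the window closest to the
start codon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .genome import Genome, GeneRecord, reverse_complement
from .mutation import Mutation, MutationError, hamming, normalize

STOP_CODONS = ("TAA", "TAG", "TGA")


class KnockoutError(ValueError):
    pass


@dataclass(frozen=True)
class StopWindow:
    """Chosen window of codons to convert into stop codons.

    ``start_codon_index`` is the 1-based codon position of the first window
    codon within the CDS; ``assignment`` the ordered stop codons, one per
    window codon.
    """

    start_codon_index: int
    assignment: tuple[str, ...]
    cost: int


def split_codons(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise KnockoutError(f"CDS length {len(cds)} is not codon-aligned")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def stop_codon_matrix(codons: list[str]) -> list[dict[str, int]]:
    """Per-codon Hamming distances to each stop codon type."""
    return [{stop: hamming(c, stop) for stop in STOP_CODONS} for c in codons]


def _assignments(n_stops: int, distinct_types: bool):
    if not distinct_types:
        yield from itertools.product(STOP_CODONS, repeat=n_stops)
        return
    if n_stops <= len(STOP_CODONS):
        yield from itertools.permutations(STOP_CODONS, n_stops)
        return
    # longer windows: every type must appear at least once
    for combo in itertools.product(STOP_CODONS, repeat=n_stops):
        if set(combo) == set(STOP_CODONS):
            yield combo


def best_stop_window(
    codons: list[str], n_stops: int = 3, distinct_types: bool = True
) -> StopWindow:
    """Cheapest window of ``n_stops`` consecutive stop codons in the first half.

    The window slides over codon indices 2..ceil(n/2): the start codon is
    excluded and the window must lie entirely within the first half of the
    CDS.  Per window the cost is minimized over stop-type assignments
    (all orderings of distinct types by default).  Equal-cost windows
    resolve to the one nearest the start codon; equal-cost assignments to
    the lexicographically first.
    """
    n = len(codons)
    if n_stops < 1:
        raise KnockoutError("n_stops must be >= 1")
    half = math.ceil(n / 2)
    last_start = half - n_stops + 1  # window's last codon index <= half
    if last_start < 2:
        raise KnockoutError(
            f"CDS of {n} codons too short for {n_stops} stop codons in its first half"
        )
    matrix = stop_codon_matrix(codons)
    best: StopWindow | None = None
    for start in range(2, last_start + 1):
        for assignment in _assignments(n_stops, distinct_types):
            cost = sum(
                matrix[start - 1 + k][assignment[k]] for k in range(n_stops)
            )
            if best is None or cost < best.cost:
                best = StopWindow(start, tuple(assignment), cost)
    assert best is not None
    return best


def design_knockout(
    genome: Genome,
    gene: GeneRecord,
    n_stops: int = 3,
    distinct_types: bool = True,
) -> tuple[Mutation, StopWindow]:
    """Merge the best stop window's substitutions into one genome Mutation.

    The mutation spans from the first to the last substituted base (bases in
    between that already match are retained and later trimmed only at the
    ends by normalization), expressed in plus-strand coordinates whatever
    the gene's strand.
    """
    if not gene.is_cds:
        raise KnockoutError(f"{gene.name} is not a CDS")
    cds = genome.gene_sequence(gene)
    codons = split_codons(cds)
    window = best_stop_window(codons, n_stops, distinct_types)
    cds_off = (window.start_codon_index - 1) * 3
    removed_cds = cds[cds_off : cds_off + 3 * n_stops]
    inserted_cds = "".join(window.assignment)
    if gene.strand == "+":
        gpos = gene.start - 1 + cds_off
        removed, inserted = removed_cds, inserted_cds
    else:
        gpos = gene.end - cds_off - 3 * n_stops
        removed = reverse_complement(removed_cds)
        inserted = reverse_complement(inserted_cds)
    if removed == inserted:
        raise KnockoutError(f"{gene.name} already carries the stop window")
    mutation = normalize(gpos, removed, inserted, label=f"ko_{gene.name}")
    return mutation, window
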