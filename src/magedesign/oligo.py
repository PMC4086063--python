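"""Design of lagging-strand ssDNA oligos with folding-energy optimization.

Each mutation is embedded in a fixed-length oligo (default 90 nt).  The
design frame is slid along the mutated sequence, keeping at least
``min_homology`` intact bases (default 15) between the mutated region and
each oligo end; of all admissible frames the one whose *final, oriented*
oligo folds least stably (maximum MFE) is chosen.  Oligos on the
origin->terminus arm are reverse complemented so they anneal to the
lagging-strand template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .folding import FoldingEvaluator, fold_mfe
from .genome import Genome, GenomeError, reverse_complement
from .mutation import Mutation, MutationError, apply_mutation, verify_mutation


class OligoDesignError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateFrame:
    """One admissible placement of the oligo window on the mutated sequence.

    ``genome_start`` is the 0-based plus-strand genome offset of the first
    oligo base; ``mut_offset`` the 0-based offset of the mutated region
    within the window.
    """

    genome_start: int
    mut_offset: int
    region_len: int
    length: int

    @property
    def left_homology(self) -> int:
        return self.mut_offset

    @property
    def right_homology(self) -> int:
        return self.length - self.mut_offset - self.region_len


@dataclass(frozen=True)
class OligoDesign:
    """A final, oriented oligo ready for synthesis."""

    id: str
    sequence: str
    genome_window: tuple[int, int]  # 1-based inclusive, plus strand
    orientation: str  # "plus" | "minus"
    mfe: float
    left_homology: int
    right_homology: int
    mutation: Mutation
    predicted_rate: Optional[float] = None
    target_rate: Optional[float] = None
    operation: str = ""
    target: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def required_oligo_length(mutation: Mutation, min_homology: int) -> int:
    return len(mutation.inserted) + 2 * min_homology


def enumerate_frames(
    genome: Genome,
    mutation: Mutation,
    oligo_length: int = 90,
    min_homology: int = 15,
) -> list[CandidateFrame]:
    """All oligo windows containing the mutated region with full homology arms.

    The mutated region is the (normalized) inserted sequence — a zero-width
    junction for pure deletions.  Windows are circular on the plus strand of
    the *mutated* genome and are returned in increasing start order.
    """
    verify_mutation(genome, mutation)
    region = len(mutation.inserted)
    need = required_oligo_length(mutation, min_homology)
    if oligo_length < need:
        raise OligoDesignError(
            f"oligo length {oligo_length} cannot hold a {region}-bp mutated "
            f"region with {min_homology}-bp homology arms; needs >= {need}"
        )
    frames = []
    # offset of the mutated region within the window
    for mut_offset in range(min_homology, oligo_length - region - min_homology + 1):
        genome_start = (mutation.position - mut_offset) % genome.length
        frames.append(CandidateFrame(genome_start, mut_offset, region, oligo_length))
    return frames


def _frame_sequences(
    genome: Genome, mutation: Mutation, frame: CandidateFrame
) -> tuple[str, str]:
    """(wild-type window, mutated window) for a frame, both plus strand."""
    upstream_len = frame.mut_offset
    downstream_len = frame.length - frame.mut_offset - frame.region_len
    upstream = genome.extract_window(
        frame.genome_start + 1, upstream_len
    ) if upstream_len else ""
    down_start = (mutation.position + len(mutation.removed)) % genome.length
    downstream = genome.extract_window(
        down_start + 1, downstream_len
    ) if downstream_len else ""
    wt = upstream + mutation.removed + downstream
    mutated = upstream + mutation.inserted + downstream
    return wt, mutated


def design_oligo(
    genome: Genome,
    mutation: Mutation,
    evaluator: FoldingEvaluator,
    oligo_length: int = 90,
    min_homology: int = 15,
    optimize: bool = True,
    oligo_id: str = "oligo",
    operation: str = "",
    target: str = "",
) -> OligoDesign:
    """Pick the admissible frame whose oriented oligo has the highest MFE.

    The MFE is computed on the final physical oligo — after lagging-strand
    reverse complementation — since that is the molecule that folds.  Ties
    go to the most-centered mutation, then the smallest window start.  With
    ``optimize=False`` the centered frame is returned without evaluation.
    """
    frames = enumerate_frames(genome, mutation, oligo_length, min_homology)
    orientation = genome.oligo_orientation(mutation.position + 1)

    def oriented(seq: str) -> str:
        return reverse_complement(seq) if orientation == "minus" else seq

    def centeredness(frame: CandidateFrame) -> int:
        return abs(frame.left_homology - frame.right_homology)

    if optimize:
        scored = []
        for frame in frames:
            _, mutated = _frame_sequences(genome, mutation, frame)
            scored.append((fold_mfe(evaluator, oriented(mutated)), frame))
        best_mfe = max(s for s, _ in scored)
        tied = [f for s, f in scored if s == best_mfe]
        chosen = min(tied, key=lambda f: (centeredness(f), f.genome_start))
    else:
        chosen = min(frames, key=lambda f: (centeredness(f), f.genome_start))
        _, mutated = _frame_sequences(genome, mutation, chosen)
        best_mfe = fold_mfe(evaluator, oriented(mutated))

    _, mutated = _frame_sequences(genome, mutation, chosen)
    sequence = oriented(mutated)
    left, right = chosen.left_homology, chosen.right_homology
    if orientation == "minus":
        left, right = right, left
    window_len = chosen.length - mutation.length_change
    end = (chosen.genome_start + window_len - 1) % genome.length + 1
    return OligoDesign(
        id=oligo_id,
        sequence=sequence,
        genome_window=(chosen.genome_start + 1, end),
        orientation=orientation,
        mfe=best_mfe,
        left_homology=left,
        right_homology=right,
        mutation=mutation,
        operation=operation,
        target=target,
    )


def revert_oligo(design: OligoDesign, genome: Genome) -> str:
    """Undo the mutation inside the oligo, returning the wild-type window
    in the oligo's orientation (used by round-trip checks)."""
    seq = design.sequence
    if design.orientation == "minus":
        seq = reverse_complement(seq)
    offset = design.left_homology if design.orientation == "plus" else design.right_homology
    wt = seq[:offset] + design.mutation.removed + seq[offset + len(design.mutation.inserted):]
    return reverse_complement(wt) if design.orientation == "minus" else wt
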