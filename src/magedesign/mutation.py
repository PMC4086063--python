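"""Reference-anchored mutations and the instruction-file dialect.

A :class:`Mutation` is the common currency between all design modules: a
0-based genome offset, the plus-strand bases removed there, and the bases
inserted in their place.  Every mutation is verified against the genome
before use — a mismatching reference is always an error, never a silent
edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .genome import Genome, GeneRecord, GenomeError, reverse_complement

OPERATIONS = frozenset(
    {
        "point_mutation",
        "insertion",
        "deletion",
        "aa_substitution",
        "gene_deletion",
        "knockout",
        "rbs_tune",
        "rbs_library",
    }
)


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    """One parsed instruction line (operation + target + options)."""

    operation: str
    target: str
    options: dict[str, str] = field(default_factory=dict)
    barcode_id: Optional[str] = None
    line_no: int = 0

    def opt(self, key: str, default: Optional[str] = None) -> Optional[str]:
        return self.options.get(key, default)


@dataclass(frozen=True)
class Mutation:
    """A normalized, reference-anchored edit on the plus strand.

    ``position`` is the 0-based offset of the first affected base;
    ``removed`` must equal the genome sequence there.  Construction trims
    any common prefix/suffix of removed/inserted so the mutated region is
    minimal.
    """

    position: int
    removed: str
    inserted: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.removed and not self.inserted:
            raise MutationError("mutation removes and inserts nothing")

    @property
    def end(self) -> int:
        """0-based exclusive end of the removed span."""
        return self.position + len(self.removed)

    @property
    def length_change(self) -> int:
        return len(self.inserted) - len(self.removed)

    def inverted(self) -> "Mutation":
        """The mutation that undoes this one on the mutated sequence."""
        return Mutation(self.position, self.inserted, self.removed, self.label)


def normalize(position: int, removed: str, inserted: str, label: str = "") -> Mutation:
    """Trim shared prefix/suffix so the mutated region is minimal."""
    while removed and inserted and removed[0] == inserted[0]:
        removed, inserted, position = removed[1:], inserted[1:], position + 1
    while removed and inserted and removed[-1] == inserted[-1]:
        removed, inserted = removed[:-1], inserted[:-1]
    return Mutation(position, removed, inserted, label)


def verify_mutation(genome: Genome, mutation: Mutation) -> None:
    """Check ``mutation.removed`` against the genome; raise on mismatch."""
    if mutation.removed:
        found = genome.extract_window(mutation.position + 1, len(mutation.removed))
        if found != mutation.removed:
            raise MutationError(
                f"reference mismatch at position {mutation.position + 1}: "
                f"expected {mutation.removed}, genome has {found}"
            )


def apply_mutation(sequence: str, mutation: Mutation) -> str:
    """Apply a mutation to a plain sequence string (0-based coordinates)."""
    p = mutation.position
    if p < 0 or p + len(mutation.removed) > len(sequence):
        raise MutationError(f"mutation at {p} out of bounds for {len(sequence)}-bp sequence")
    if sequence[p : p + len(mutation.removed)] != mutation.removed:
        raise MutationError(
            f"mismatch at application site {p}: expected {mutation.removed!r}, "
            f"found {sequence[p : p + len(mutation.removed)]!r}"
        )
    return sequence[:p] + mutation.inserted + sequence[p + len(mutation.removed) :]


# ---------------------------------------------------------------------------
# Instruction file


def parse_instruction_file(text: str, genome: Optional[Genome] = None) -> list[MutationSpec]:
    """Parse the whitespace-separated instruction dialect.

    One instruction per line: ``<operation> <target> [opt=val[,opt=val...]]
    [barcode=<id>]``.  ``#`` starts a comment; blank lines are skipped.
    Parsing is all-or-nothing: every malformed line is reported (with its
    line number) in a single error.
    """
    specs: list[MutationSpec] = []
    errors: list[str] = []
    for line_no, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        op = fields[0]
        if op not in OPERATIONS:
            errors.append(f"unknown operation {op!r} (line {line_no})")
            continue
        if len(fields) < 2:
            errors.append(f"missing target for {op} (line {line_no})")
            continue
        target = fields[1]
        options: dict[str, str] = {}
        barcode: Optional[str] = None
        ok = True
        for chunk in fields[2:]:
            for item in chunk.split(","):
                if not item:
                    continue
                if "=" not in item:
                    errors.append(f"malformed option {item!r} (line {line_no})")
                    ok = False
                    continue
                key, _, val = item.partition("=")
                if key == "barcode":
                    barcode = val
                    continue
                if key in options and options[key] != val:
                    errors.append(
                        f"duplicate conflicting option {key!r} (line {line_no})"
                    )
                    ok = False
                    continue
                options[key] = val
        if ok:
            specs.append(MutationSpec(op, target, options, barcode, line_no))
    if errors:
        raise MutationError("; ".join(errors))
    return specs


# ---------------------------------------------------------------------------
# Spec -> Mutation


def make_mutation(genome: Genome, spec: MutationSpec) -> Mutation:
    """Build a verified Mutation from a simple (non-phenotypic) spec."""
    op = spec.operation
    if op == "point_mutation":
        pos = _position(genome, spec.target, spec)
        ref, alt = _require(spec, "ref"), _require(spec, "alt")
        _check_bases(ref + alt, spec)
        found = genome.extract_window(pos, len(ref))
        if found != ref:
            raise MutationError(
                f"reference mismatch: expected {ref}, genome has {found} "
                f"(position {pos}, line {spec.line_no})"
            )
        mut = normalize(pos - 1, ref, alt, label=f"{ref}{pos}{alt}")
        if not mut.removed and not mut.inserted:
            raise MutationError(f"point mutation is identity (line {spec.line_no})")
        return mut
    if op == "insertion":
        pos = _position(genome, spec.target, spec)
        seq = _require(spec, "seq").upper()
        _check_bases(seq, spec)
        return Mutation(pos - 1, "", seq, label=f"ins@{pos}:{seq}")
    if op == "deletion":
        pos = _position(genome, spec.target, spec)
        length = int(_require(spec, "len"))
        if length < 1:
            raise MutationError(f"deletion length must be >= 1 (line {spec.line_no})")
        removed = genome.extract_window(pos, length)
        return Mutation(pos - 1, removed, "", label=f"del@{pos}+{length}")
    if op == "gene_deletion":
        gene = _gene(genome, spec.target, spec)
        removed = genome.extract_window(gene.start, gene.length)
        return Mutation(gene.start - 1, removed, "", label=f"del_{gene.name}")
    raise MutationError(
        f"operation {op!r} is not a direct mutation (line {spec.line_no})"
    )


def _position(genome: Genome, target: str, spec: MutationSpec) -> int:
    resolved = genome.resolve_target(target)
    if isinstance(resolved, GeneRecord):
        raise MutationError(
            f"{spec.operation} needs a genome coordinate, got gene {target!r} "
            f"(line {spec.line_no})"
        )
    return resolved


def _gene(genome: Genome, target: str, spec: MutationSpec) -> GeneRecord:
    resolved = genome.resolve_target(target)
    if not isinstance(resolved, GeneRecord):
        raise MutationError(
            f"{spec.operation} needs a gene target, got coordinate {target!r} "
            f"(line {spec.line_no})"
        )
    return resolved


def _require(spec: MutationSpec, key: str) -> str:
    val = spec.opt(key)
    if val is None:
        raise MutationError(
            f"{spec.operation} requires option {key}= (line {spec.line_no})"
        )
    return val


def _check_bases(seq: str, spec: MutationSpec) -> None:
    bad = set(seq.upper()) - set("ACGT")
    if bad:
        raise MutationError(
            f"non-ACGT characters {sorted(bad)} (line {spec.line_no})"
        )


# ---------------------------------------------------------------------------
# Amino acid substitution

_CODON_TABLE = standard_dna_table.forward_table
_STOPS = tuple(sorted(standard_dna_table.stop_codons))  # TAA, TAG, TGA


def codons_for(aa: str) -> list[str]:
    aa = aa.upper()
    if aa == "*":
        return list(_STOPS)
    return sorted(c for c, a in _CODON_TABLE.items() if a == aa)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def best_codon_for(
    current: str, new_aa: str, usage: Optional[dict[str, float]] = None
) -> str:
    """Minimum-Hamming codon encoding ``new_aa``.

    Ties are broken by the higher genome codon usage (if given), then
    lexicographically, so the choice is deterministic.
    """
    candidates = codons_for(new_aa)
    if not candidates:
        raise MutationError(f"unknown amino acid {new_aa!r}")
    usage = usage or {}
    return min(candidates, key=lambda c: (hamming(current, c), -usage.get(c, 0.0), c))


def aa_substitution(
    genome: Genome, gene: GeneRecord, residue_index: int, new_aa: str
) -> Mutation:
    """Codon-level substitution of residue ``residue_index`` (1-based).

    Picks the codon for ``new_aa`` at minimal Hamming distance from the
    current codon, breaking ties by codon usage over the genome's own CDSs.
    The returned Mutation is in plus-strand genome coordinates regardless of
    gene strand.
    """
    if not gene.is_cds:
        raise MutationError(f"{gene.name} is not a CDS")
    cds = genome.gene_sequence(gene)
    n_res = len(cds) // 3
    if not 1 <= residue_index <= n_res:
        raise MutationError(
            f"residue index {residue_index} out of range 1..{n_res} for {gene.name}"
        )
    codon_off = (residue_index - 1) * 3
    current = cds[codon_off : codon_off + 3]
    new_codon = best_codon_for(current, new_aa, genome.codon_usage())
    if new_codon == current:
        raise MutationError(
            f"substitution is identity: {gene.name} residue {residue_index} "
            f"already encodes {new_aa.upper()}"
        )
    if gene.strand == "+":
        gpos = gene.start - 1 + codon_off
        removed, inserted = current, new_codon
    else:
        # codon sits at the far end of the plus-strand span, reverse complemented
        gpos = gene.end - codon_off - 3
        removed = reverse_complement(current)
        inserted = reverse_complement(new_codon)
    label = f"{gene.name}:{_CODON_TABLE.get(current, '*')}{residue_index}{new_aa.upper()}"
    return normalize(gpos, removed, inserted, label=label)


def translate(cds: str) -> str:
    """Translate a codon-aligned DNA string; stops are '*'."""
    return str(Seq(cds[: len(cds) - len(cds) % 3]).translate())


def check_no_overlap(mutations: list[Mutation]) -> None:
    """Reject overlapping mutations: MAGE applies each oligo independently."""
    spans = sorted(
        (m.position, max(m.end, m.position + 1), m.label) for m in mutations
    )
    for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise MutationError(f"overlapping mutations: {l1!r} and {l2!r}")
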