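"""Genome container, replication geometry and lagging-strand orientation.

MAGE oligos recombine most efficiently when they anneal to the lagging-strand
template at the replication fork.  Which strand that is depends on which
replichore (origin->terminus arc) the target falls on, so the genome model
carries the replication origin and terminus alongside the sequence and its
CDS annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGT")

#: Accessions with packaged replication presets (origin/terminus intervals
#: for organisms with published ssDNA-oligo recombineering protocols).
PRESET_ACCESSIONS = (
    "NC_000913",  # Escherichia coli K-12 MG1655
    "NC_003197",  # Salmonella typhimurium LT2
    "NC_004578",  # Pseudomonas syringae DC3000
    "NC_004567",  # Lactobacillus plantarum WCFS1
    "NC_010609",  # Lactobacillus reuteri F275
    "NC_017531",  # Pantoea ananatis AJ13355
)


class GenomeError(ValueError):
    """Raised for unloadable genomes, bad coordinates or bad configuration."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class ReplicationConfig:
    """Replication geometry of a (circular) bacterial chromosome.

    Intervals are 1-based inclusive.  For arm computation each interval is
    collapsed to the integer floor of its center; the two midpoints are the
    single fork boundaries that split the chromosome into its replichores.

    ``orientation_convention`` decides which arm receives reverse-complemented
    (minus) oligos; ``"standard"`` maps the origin->terminus arc in increasing
    coordinates (arm A) to minus.  Flip it if your fork-direction bookkeeping
    disagrees.
    """

    origin_interval: tuple[int, int]
    terminus_interval: tuple[int, int]
    topology: str = "circular"
    orientation_convention: str = "standard"

    def __post_init__(self) -> None:
        for name, (a, b) in (
            ("origin", self.origin_interval),
            ("terminus", self.terminus_interval),
        ):
            if a < 1 or b < a:
                raise GenomeError(f"bad {name} interval {a}..{b}")
        if self.topology not in ("circular", "linear"):
            raise GenomeError(f"topology must be circular|linear, got {self.topology!r}")
        if self.orientation_convention not in ("standard", "inverted"):
            raise GenomeError(
                f"orientation_convention must be standard|inverted, "
                f"got {self.orientation_convention!r}"
            )

    @property
    def origin_mid(self) -> int:
        a, b = self.origin_interval
        return (a + b) // 2

    @property
    def terminus_mid(self) -> int:
        a, b = self.terminus_interval
        return (a + b) // 2

    def validate_against(self, genome_length: int) -> None:
        for name, (a, b) in (
            ("origin", self.origin_interval),
            ("terminus", self.terminus_interval),
        ):
            if b > genome_length:
                raise GenomeError(
                    f"{name} interval {a}..{b} exceeds genome length {genome_length}"
                )
        if self.origin_mid == self.terminus_mid:
            raise GenomeError("origin and terminus midpoints coincide")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene/CDS. ``span`` is 1-based inclusive on the plus strand."""

    name: str
    locus_tag: str
    strand: str  # "+" or "-"
    span: tuple[int, int]
    is_cds: bool = True

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass
class Genome:
    """Circular DNA sequence plus annotations and replication geometry."""

    sequence: str
    features: list[GeneRecord]
    replication: ReplicationConfig
    id: str = "genome"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeError(
                f"sequence contains non-ACGT characters {sorted(bad)}; "
                "ambiguity codes are not supported"
            )
        self.replication.validate_against(len(self.sequence))
        for feat in self.features:
            if not (1 <= feat.start <= len(self.sequence)):
                raise GenomeError(f"feature {feat.name} start out of bounds")
        self._codon_usage: Optional[dict[str, float]] = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.replication.topology == "circular"

    # -- sequence access ---------------------------------------------------

    def extract_window(self, start: int, length: int) -> str:
        """Plus-strand window of ``length`` bp starting at 1-based ``start``.

        Wraps around the origin on circular genomes; on linear genomes a
        window crossing either end is an error.
        """
        L = self.length
        if not 1 <= length <= L:
            raise GenomeError(f"window length {length} out of range 1..{L}")
        if not 1 <= start <= L:
            raise GenomeError(f"window start {start} out of range 1..{L}")
        i = start - 1
        if i + length <= L:
            return self.sequence[i : i + length]
        if not self.is_circular:
            raise GenomeError("window crosses the end of a linear genome")
        return self.sequence[i:] + self.sequence[: (i + length) % L]

    def base_at(self, position: int) -> str:
        """Base at 1-based plus-strand ``position``."""
        return self.extract_window(position, 1)

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Coding-orientation sequence of a gene (reverse complemented for minus)."""
        seq = self.extract_window(gene.start, gene.length)
        return reverse_complement(seq) if gene.strand == "-" else seq

    # -- annotation lookup -------------------------------------------------

    def resolve_target(self, target: Union[str, int]) -> Union[GeneRecord, int]:
        """Resolve a gene name, locus tag, or integer coordinate.

        Names match case-insensitively against gene symbols first, then
        locus tags.  Integer-like targets return the genome position.
        """
        if isinstance(target, int) or (isinstance(target, str) and target.isdigit()):
            pos = int(target)
            if not 1 <= pos <= self.length:
                raise GenomeError(f"position {pos} out of range 1..{self.length}")
            return pos
        key = target.lower()
        for attr in ("name", "locus_tag"):
            hits = [f for f in self.features if getattr(f, attr).lower() == key]
            if len(hits) == 1:
                return hits[0]
            if len(hits) > 1:
                names = ", ".join(f"{f.name}@{f.start}..{f.end}" for f in hits)
                raise GenomeError(f"ambiguous target {target!r}: matches {names}")
        raise GenomeError(
            f"no gene or locus tag matches {target!r} "
            f"(searched {len(self.features)} features)"
        )

    def cds_features(self) -> list[GeneRecord]:
        return [f for f in self.features if f.is_cds]

    def codon_usage(self) -> dict[str, float]:
        """Relative codon frequencies over all annotated CDSs (cached)."""
        if self._codon_usage is None:
            counts: dict[str, int] = {}
            for gene in self.cds_features():
                seq = self.gene_sequence(gene)
                for i in range(0, len(seq) - len(seq) % 3, 3):
                    codon = seq[i : i + 3]
                    counts[codon] = counts.get(codon, 0) + 1
            total = sum(counts.values()) or 1
            self._codon_usage = {c: n / total for c, n in counts.items()}
        return self._codon_usage

    # -- replication geometry ----------------------------------------------

    def replichore_of(self, position: int) -> str:
        """Arm of the chromosome ("armA"/"armB") containing 1-based ``position``.

        Arm A is the arc travelled from the origin midpoint towards the
        terminus midpoint in increasing coordinates (mod length); arm B is
        the complementary arc.  The origin midpoint itself is arm A, the
        terminus midpoint arm B.
        """
        if not 1 <= position <= self.length:
            raise GenomeError(f"position {position} out of range 1..{self.length}")
        ori = self.replication.origin_mid
        ter = self.replication.terminus_mid
        L = self.length
        arm_a_len = (ter - ori) % L
        dist = (position - ori) % L
        return "armA" if dist < arm_a_len else "armB"

    def oligo_orientation(self, position: int) -> str:
        """Strand ("plus"/"minus") of the oligo targeting the lagging strand.

        On arm A the fork runs in increasing coordinates, the lagging-strand
        template is the plus strand, and the annealing oligo is therefore the
        minus-strand (reverse-complemented) sequence — under the "standard"
        convention; "inverted" swaps the mapping.
        """
        arm = self.replichore_of(position)
        standard = "minus" if arm == "armA" else "plus"
        if self.replication.orientation_convention == "inverted":
            return "plus" if standard == "minus" else "minus"
        return standard


# ---------------------------------------------------------------------------
# Loading


def _features_from_record(record) -> tuple[list[GeneRecord], list[str]]:
    features: list[GeneRecord] = []
    warnings: list[str] = []
    for feat in record.features:
        if feat.type not in ("CDS", "gene"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("label") or [""])[0]
        locus = (quals.get("locus_tag") or [""])[0]
        if not name and not locus:
            continue
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        is_cds = feat.type == "CDS"
        if is_cds and (end - start + 1) % 3 != 0:
            warnings.append(
                f"CDS {name or locus} span {start}..{end} is not a multiple of 3; "
                "excluded from codon-level operations"
            )
            is_cds = False
        rec = GeneRecord(name or locus, locus or name, strand, (start, end), is_cds)
        features.append(rec)
    # collapse gene+CDS duplicates on identical spans, preferring the CDS entry
    by_span: dict[tuple, GeneRecord] = {}
    for rec in features:
        key = (rec.span, rec.strand)
        if key not in by_span or (rec.is_cds and not by_span[key].is_cds):
            by_span[key] = rec
    return list(by_span.values()), warnings


def _auto_replication(record, length: int) -> ReplicationConfig:
    ori = None
    for feat in record.features:
        if feat.type == "rep_origin":
            ori = (int(feat.location.start) + 1, int(feat.location.end))
            break
    if ori is None:
        raise GenomeError(
            "replication='auto' requires an annotated rep_origin feature; "
            "supply an explicit ReplicationConfig or config file"
        )
    ori_mid = (ori[0] + ori[1]) // 2
    ter_mid = (ori_mid + length // 2) % length
    if ter_mid == 0:
        ter_mid = length
    return ReplicationConfig(ori, (ter_mid, ter_mid))


def load_genome(
    genbank_path: Union[str, Path],
    replication: Union[ReplicationConfig, str] = "auto",
    warn: Optional[list] = None,
) -> Genome:
    """Load an annotated GenBank flat file into a :class:`Genome`.

    ``replication`` is either an explicit :class:`ReplicationConfig` or
    ``"auto"``, which requires an annotated ``rep_origin`` feature; the
    terminus then defaults to the opposite side of the circular genome.
    Non-ACGT bases are rejected.  CDSs whose length is not a multiple of 3
    load with a warning (appended to ``warn`` if given) and are excluded
    from codon-level operations.
    """
    path = Path(genbank_path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises assorted types
        raise GenomeError(f"cannot parse GenBank file {path}: {exc}") from exc
    sequence = str(record.seq).upper()
    if not sequence:
        raise GenomeError(f"GenBank file {path} has no sequence")
    features, warnings = _features_from_record(record)
    if warn is not None:
        warn.extend(warnings)
    if replication == "auto":
        replication = _auto_replication(record, len(sequence))
    elif not isinstance(replication, ReplicationConfig):
        raise GenomeError("replication must be a ReplicationConfig or 'auto'")
    return Genome(sequence, features, replication, id=record.id or path.stem)


# ---------------------------------------------------------------------------
# Replication config files


def parse_replication_config(text: str) -> ReplicationConfig:
    """Parse a key=value replication config.

    Keys: ``origin=START..END``, ``terminus=START..END`` (or a single
    coordinate), optional ``topology=circular|linear`` and
    ``orientation_convention=standard|inverted``.
    """
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise GenomeError(f"replication config line {lineno}: expected key=value")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    try:
        origin = _parse_interval(values.pop("origin"))
        terminus = _parse_interval(values.pop("terminus"))
    except KeyError as exc:
        raise GenomeError(f"replication config missing key {exc.args[0]!r}") from exc
    topology = values.pop("topology", "circular")
    convention = values.pop("orientation_convention", "standard")
    if values:
        raise GenomeError(f"unknown replication config keys {sorted(values)}")
    return ReplicationConfig(origin, terminus, topology, convention)


def _parse_interval(text: str) -> tuple[int, int]:
    if ".." in text:
        a, _, b = text.partition("..")
        return int(a), int(b)
    v = int(text)
    return v, v


def load_replication_config(path: Union[str, Path]) -> ReplicationConfig:
    return parse_replication_config(Path(path).read_text())


def replication_preset(accession: str) -> ReplicationConfig:
    """Packaged replication preset for a supported accession (e.g. NC_000913)."""
    if accession not in PRESET_ACCESSIONS:
        raise GenomeError(
            f"no replication preset for {accession!r}; "
            f"available: {', '.join(PRESET_ACCESSIONS)}"
        )
    ref = resources.files("magedesign.data.replication").joinpath(f"{accession}.cfg")
    return parse_replication_config(ref.read_text())
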