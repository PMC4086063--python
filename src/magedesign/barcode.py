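"""20-bp PCR barcodes for microarray-derived oligo subpools (MO-MAGE).

Chip-synthesized oligo pools are amplified subpool-by-subpool with barcode
primer pairs: each design gets 20 bp appended at both ends, the right one
reverse complemented so both barcode strands prime toward the insert.  The
packaged default table (data/synthetic_barcodes_default.tsv) is a synthetic
stand-in for published barcode primer sets: 20 pairs of 20-mers with GC
between 40 and 60% and no shared 8-mer between any left barcode and the
reverse complement of any right barcode, generated by
:func:`generate_barcode_table`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .genome import reverse_complement
from .oligo import OligoDesign

BARCODE_LEN = 20


class BarcodeError(ValueError):
    pass


@dataclass(frozen=True)
class BarcodeTable:
    entries: dict[str, tuple[str, str]]  # id -> (left, right)

    def __post_init__(self) -> None:
        for bc_id, (left, right) in self.entries.items():
            for side, seq in (("left", left), ("right", right)):
                if len(seq) != BARCODE_LEN:
                    raise BarcodeError(
                        f"barcode {bc_id!r} {side} sequence has length "
                        f"{len(seq)}, expected {BARCODE_LEN}"
                    )
                bad = set(seq) - set("ACGT")
                if bad:
                    raise BarcodeError(
                        f"barcode {bc_id!r} {side} has invalid characters {sorted(bad)}"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, bc_id: str) -> bool:
        return bc_id in self.entries


def parse_barcode_table(text: str) -> BarcodeTable:
    """Parse a TSV with columns id, left, right (header optional)."""
    entries: dict[str, tuple[str, str]] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lower() == "id":
            continue
        if len(fields) != 3:
            raise BarcodeError(f"barcode table line {lineno}: expected 3 columns")
        bc_id, left, right = fields
        if bc_id in entries:
            raise BarcodeError(f"duplicate barcode id {bc_id!r} (line {lineno})")
        entries[bc_id] = (left.upper(), right.upper())
    return BarcodeTable(entries)


def load_barcode_table(source: Union[str, Path, None] = None) -> BarcodeTable:
    """Load a barcode TSV, or the packaged synthetic default when None."""
    if source is None:
        ref = resources.files("magedesign.data").joinpath(
            "synthetic_barcodes_default.tsv"
        )
        return parse_barcode_table(ref.read_text())
    return parse_barcode_table(Path(source).read_text())


def apply_barcode(
    oligo: Union[OligoDesign, str], barcode_id: str, table: BarcodeTable
) -> str:
    """left + oligo + revcomp(right): both barcodes prime toward the insert."""
    if barcode_id not in table:
        raise BarcodeError(
            f"unknown barcode id {barcode_id!r} "
            f"(table has {len(table)} entries)"
        )
    left, right = table.entries[barcode_id]
    seq = oligo.sequence if isinstance(oligo, OligoDesign) else oligo
    return left + seq + reverse_complement(right)


def strip_barcode(barcoded: str) -> str:
    return barcoded[BARCODE_LEN:-BARCODE_LEN]


def generate_barcode_table(n: int = 20, seed: int = 20140516, k: int = 8) -> BarcodeTable:
    """Generate n synthetic barcode pairs with documented properties.

    Each 20-mer has 40-60% GC; no k-mer (default 8) of any accepted barcode
    or its reverse complement recurs anywhere in the set, which in
    particular guarantees that no left barcode shares an 8-mer with the
    reverse complement of any right barcode (subpool selectivity).
    """
    rng = random.Random(seed)
    used_kmers: set[str] = set()

    def kmers(seq: str):
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    def draw() -> str:
        while True:
            seq = "".join(rng.choice("ACGT") for _ in range(BARCODE_LEN))
            gc = sum(b in "GC" for b in seq) / BARCODE_LEN
            if not 0.4 <= gc <= 0.6:
                continue
            mers = kmers(seq) | kmers(reverse_complement(seq))
            if mers & used_kmers:
                continue
            used_kmers.update(mers)
            return seq

    entries = {f"bc_{i + 1:02d}": (draw(), draw()) for i in range(n)}
    return BarcodeTable(entries)


def write_barcode_table(table: BarcodeTable, path: Union[str, Path]) -> None:
    lines = ["id\tleft\tright"]
    for bc_id, (left, right) in table.entries.items():
        lines.append(f"{bc_id}\t{left}\t{right}")
    Path(path).write_text("\n".join(lines) + "\n")
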