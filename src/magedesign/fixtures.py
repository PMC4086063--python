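"""Synthetic annotated genomes for tests, examples and benchmarks.

Generates a seeded random circular chromosome with non-overlapping CDSs on
both strands (ATG + random non-stop codons + stop), a ``rep_origin``
feature at 80% of the genome, and a matching replication config — a
GenBank file that round-trips through :func:`magedesign.genome.load_genome`
with no network access.  Identical seeds produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genome import Genome, GeneRecord, ReplicationConfig, reverse_complement

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOPS = ("TAA", "TAG", "TGA")
_EDGE_MARGIN = 200  # keep genes away from position 1 so UTR windows never wrap


class FixtureError(ValueError):
    pass


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(
        _NONSTOP_CODONS[i]
        for i in rng.integers(len(_NONSTOP_CODONS), size=n_codons - 2)
    )
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + body + stop


def build_fixture(
    length: int = 50_000,
    n_genes: int = 20,
    seed: int = 1,
    gc: float = 0.5,
    min_codons: int = 50,
    max_codons: int = 150,
) -> tuple[SeqRecord, ReplicationConfig]:
    """Assemble the synthetic chromosome as a Biopython SeqRecord."""
    if n_genes * 300 >= length:
        raise FixtureError(
            f"cannot pack {n_genes} genes of >=300 bp into {length} bp"
        )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list("".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)]))

    ori_start0 = int(length * 0.8) - 1  # 1-based start = 0.8 * length
    ori_end0 = ori_start0 + 201  # 201-bp origin feature
    features = []
    cursor = _EDGE_MARGIN
    for i in range(n_genes):
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        span = 3 * n_codons
        cursor += int(rng.integers(60, 200))
        # keep clear of the origin feature and its flanks
        if cursor < ori_end0 + _EDGE_MARGIN and cursor + span > ori_start0 - _EDGE_MARGIN:
            cursor = ori_end0 + _EDGE_MARGIN
        if cursor + span > length - _EDGE_MARGIN:
            raise FixtureError(
                f"infeasible packing: gene {i + 1} of {n_genes} does not fit"
            )
        strand = 1 if rng.random() < 0.5 else -1
        cds = _random_cds(rng, n_codons)
        placed = cds if strand == 1 else reverse_complement(cds)
        seq[cursor : cursor + span] = list(placed)
        name = f"gene{i + 1:03d}"
        features.append(
            SeqFeature(
                FeatureLocation(cursor, cursor + span, strand=strand),
                type="CDS",
                qualifiers={
                    "gene": [name],
                    "locus_tag": [f"MD_{i + 1:05d}"],
                    "product": ["synthetic fixture protein"],
                },
            )
        )
        cursor += span

    features.append(
        SeqFeature(
            FeatureLocation(ori_start0, ori_end0, strand=1),
            type="rep_origin",
            qualifiers={"note": ["synthetic oriC"]},
        )
    )
    record = SeqRecord(
        Seq("".join(seq)),
        id=f"SYN{seed:06d}",
        name=f"SYN{seed:06d}",
        description=f"synthetic circular fixture genome, seed {seed}",
        features=features,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "data_file_division": "BCT",
            "date": "16-MAY-2014",  # fixed so identical seeds give identical bytes
        },
    )
    ori_mid = (ori_start0 + 1 + ori_end0) // 2
    ter_mid = (ori_mid + length // 2) % length or length
    config = ReplicationConfig((ori_start0 + 1, ori_end0), (ter_mid, ter_mid))
    return record, config


def make_fixture_genome(
    length: int = 50_000,
    n_genes: int = 20,
    seed: int = 1,
    gc: float = 0.5,
    out_dir: Union[str, Path] = ".",
) -> tuple[Path, Path]:
    """Write fixture GenBank + replication config files; returns their paths."""
    record, config = build_fixture(length, n_genes, seed, gc)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gb_path = out / f"{record.id}.gb"
    cfg_path = out / f"{record.id}.cfg"
    SeqIO.write([record], str(gb_path), "genbank")
    a, b = config.origin_interval
    t1, t2 = config.terminus_interval
    cfg_path.write_text(
        f"origin={a}..{b}\nterminus={t1}..{t2}\ntopology=circular\n"
    )
    return gb_path, cfg_path


def fixture_genome(
    length: int = 50_000, n_genes: int = 20, seed: int = 1, gc: float = 0.5
) -> Genome:
    """In-memory fixture Genome (no file round-trip)."""
    record, config = build_fixture(length, n_genes, seed, gc)
    features = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        features.append(
            GeneRecord(
                name=feat.qualifiers["gene"][0],
                locus_tag=feat.qualifiers["locus_tag"][0],
                strand="+" if feat.location.strand == 1 else "-",
                span=(int(feat.location.start) + 1, int(feat.location.end)),
                is_cds=True,
            )
        )
    return Genome(str(record.seq), features, config, id=record.id)
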