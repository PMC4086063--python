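"""End-to-end job runner: genome + instruction file -> oligos, primers, report.

Each instruction line dispatches to its design module, the resulting
mutation is turned into a lagging-strand oligo, and every oligo gets a
MASC PCR primer set (and optionally barcodes).  Per-line design failures
are collected with their line numbers while the job continues; parse
errors fail the whole job up front.  With identical inputs and seed, all
outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .barcode import BarcodeTable, apply_barcode, load_barcode_table
from .folding import FoldingEvaluator, ToyFoldingEvaluator, default_evaluator
from .genome import Genome, GeneRecord, ReplicationConfig, load_genome, load_replication_config
from .knockout import design_knockout
from .masc import PrimerSet, design_masc_set
from .mutation import (
    Mutation,
    MutationError,
    MutationSpec,
    aa_substitution,
    check_no_overlap,
    make_mutation,
    parse_instruction_file,
)
from .oligo import OligoDesign, design_oligo
from .rbs import RBSResult, default_predictor, generate_library, optimize_rbs

DIRECT_OPS = {"point_mutation", "insertion", "deletion", "gene_deletion"}


class JobError(ValueError):
    pass


@dataclass
class JobResult:
    oligos: list[OligoDesign] = field(default_factory=list)
    primer_sets: list[PrimerSet] = field(default_factory=list)
    barcoded: dict[str, str] = field(default_factory=dict)
    rbs_results: dict[str, RBSResult] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)


def _line_seed(seed: int, line_no: int, member: int = 0) -> int:
    return (seed * 1_000_003 + line_no * 10_007 + member * 101) % (2**31)


def run_job(
    genome_path: Union[str, Path, Genome],
    replication_config: Union[str, Path, ReplicationConfig, None],
    instructions_path: Union[str, Path],
    out_dir: Union[str, Path, None] = None,
    oligo_length: int = 90,
    min_homology: int = 15,
    barcode_table: Union[str, Path, BarcodeTable, None] = None,
    seed: int = 0,
    optimize_structure: bool = True,
    evaluator: Optional[FoldingEvaluator] = None,
    design_primers: bool = True,
    rbs_rounds_per_pass: int = 1000,
    job_name: str = "job",
) -> JobResult:
    """Run a full design job and (optionally) write the output files.

    ``replication_config`` may be a config file path, a ReplicationConfig,
    or None for auto-detection from an annotated rep_origin feature.
    """
    result = JobResult()
    if isinstance(genome_path, Genome):
        genome = genome_path
    else:
        if replication_config is None:
            replication = "auto"
        elif isinstance(replication_config, ReplicationConfig):
            replication = replication_config
        else:
            replication = load_replication_config(replication_config)
        genome = load_genome(genome_path, replication, warn=result.warnings)

    instructions = Path(instructions_path).read_text()
    specs = parse_instruction_file(instructions, genome)  # all-or-nothing
    if not specs:
        result.warnings.append("instruction file contains no instructions")

    evaluator = evaluator if evaluator is not None else default_evaluator()
    predictor = default_predictor(evaluator)
    table = (
        barcode_table
        if isinstance(barcode_table, BarcodeTable)
        else load_barcode_table(barcode_table)
    )
    result.config_echo = {
        "genome": genome.id,
        "genome_length": genome.length,
        "origin_mid": genome.replication.origin_mid,
        "terminus_mid": genome.replication.terminus_mid,
        "oligo_length": oligo_length,
        "min_homology": min_homology,
        "optimize_structure": optimize_structure,
        "folding_evaluator": evaluator.name,
        "expression_predictor": predictor.name,
        "rbs_rounds_per_pass": rbs_rounds_per_pass,
        "seed": seed,
        "n_instructions": len(specs),
    }

    direct_mutations: list[Mutation] = []
    designed: list[tuple[MutationSpec, str, Mutation, Optional[RBSResult]]] = []
    for spec in specs:
        oligo_id = f"{job_name}_{spec.line_no}_{spec.operation}"
        try:
            for member_id, mutation, rbs in _dispatch(
                genome, spec, predictor, oligo_id, seed, rbs_rounds_per_pass, result
            ):
                designed.append((spec, member_id, mutation, rbs))
                if spec.operation in DIRECT_OPS or spec.operation in (
                    "aa_substitution",
                    "knockout",
                ):
                    direct_mutations.append(mutation)
        except (MutationError, ValueError) as exc:
            result.errors.append(f"line {spec.line_no}: {exc}")
            result.log.append(f"ERROR line {spec.line_no} ({spec.operation}): {exc}")

    try:
        check_no_overlap(direct_mutations)
    except MutationError as exc:
        result.errors.append(str(exc))

    for spec, member_id, mutation, rbs in designed:
        try:
            design = design_oligo(
                genome,
                mutation,
                evaluator,
                oligo_length=oligo_length,
                min_homology=min_homology,
                optimize=optimize_structure,
                oligo_id=member_id,
                operation=spec.operation,
                target=spec.target,
            )
            if rbs is not None:
                design = _with_rates(design, rbs)
                result.rbs_results[member_id] = rbs
            result.oligos.append(design)
            result.log.append(
                f"INFO {member_id}: {design.orientation} oligo, mfe {design.mfe:.2f}, "
                f"homology {design.left_homology}/{design.right_homology}"
            )
            if design_primers:
                result.primer_sets.append(
                    design_masc_set(genome, mutation, member_id)
                )
            if spec.barcode_id is not None:
                result.barcoded[member_id] = apply_barcode(
                    design, spec.barcode_id, table
                )
        except ValueError as exc:
            result.errors.append(f"line {spec.line_no} ({member_id}): {exc}")
            result.log.append(f"ERROR {member_id}: {exc}")

    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def _with_rates(design: OligoDesign, rbs: RBSResult) -> OligoDesign:
    from dataclasses import replace

    return replace(
        design, predicted_rate=rbs.achieved_rate, target_rate=rbs.target_rate
    )


def _dispatch(
    genome: Genome,
    spec: MutationSpec,
    predictor,
    oligo_id: str,
    seed: int,
    rounds_per_pass: int,
    result: JobResult,
):
    """Yield (oligo_id, Mutation, RBSResult-or-None) per designed oligo."""
    op = spec.operation
    if op in DIRECT_OPS:
        yield oligo_id, make_mutation(genome, spec), None
        return
    if op == "aa_substitution":
        gene = _gene(genome, spec)
        residue = int(_opt(spec, "residue"))
        new_aa = _opt(spec, "aa")
        yield oligo_id, aa_substitution(genome, gene, residue, new_aa), None
        return
    if op == "knockout":
        gene = _gene(genome, spec)
        n_stops = int(spec.opt("n_stops", "3"))
        mutation, window = design_knockout(genome, gene, n_stops)
        result.log.append(
            f"INFO {oligo_id}: stop window at codon {window.start_codon_index}, "
            f"{window.cost} substitutions, {'+'.join(window.assignment)}"
        )
        yield oligo_id, mutation, None
        return
    if op == "rbs_tune":
        gene = _gene(genome, spec)
        rbs = optimize_rbs(
            genome,
            gene,
            _target_rate(genome, gene, spec, predictor),
            predictor,
            max_mutations=int(spec.opt("max_mutations", "10")),
            rounds_per_pass=rounds_per_pass,
            tolerance=float(spec.opt("tolerance", "0.05")),
            rng_seed=_line_seed(seed, spec.line_no),
        )
        if rbs.mutation is None:
            result.warnings.append(
                f"line {spec.line_no}: target rate met by the wild-type UTR; "
                "no oligo designed"
            )
            return
        if rbs.target_not_reached:
            result.warnings.append(
                f"line {spec.line_no}: target {rbs.target_rate:.1f} AU not reached; "
                f"best effort {rbs.achieved_rate:.1f} AU with {rbs.n_mutations} mutations"
            )
        yield oligo_id, rbs.mutation, rbs
        return
    if op == "rbs_library":
        gene = _gene(genome, spec)
        n = int(spec.opt("n", "10"))
        floor_fold = float(spec.opt("floor_fold", "1.25"))
        wt_rate = predictor.predict(
            *_utr_and_prefix(genome, gene)
        )
        members = generate_library(
            genome,
            gene,
            n,
            predictor,
            max_mutations=int(spec.opt("max_mutations", "10")),
            rounds_per_pass=rounds_per_pass,
            rng_seed=_line_seed(seed, spec.line_no),
            rate_floor=wt_rate * floor_fold,
        )
        for i, rbs in enumerate(members, 1):
            if rbs.mutation is None:
                result.warnings.append(
                    f"line {spec.line_no}: library member {i} needs no mutation; skipped"
                )
                continue
            yield f"{oligo_id}_{i}", rbs.mutation, rbs
        return
    raise MutationError(f"unhandled operation {op!r} (line {spec.line_no})")


def _utr_and_prefix(genome: Genome, gene: GeneRecord):
    from .rbs import utr_context

    ctx = utr_context(genome, gene)
    return ctx.wildtype, ctx.cds_prefix


def _target_rate(genome: Genome, gene: GeneRecord, spec: MutationSpec, predictor) -> float:
    target = spec.opt("target")
    if target is not None:
        return float(target)
    fold = spec.opt("fold")
    if fold is None:
        raise MutationError(
            f"rbs_tune needs target= (AU) or fold= (relative to wild type) "
            f"(line {spec.line_no})"
        )
    wt = predictor.predict(*_utr_and_prefix(genome, gene))
    return wt * float(fold)


def _gene(genome: Genome, spec: MutationSpec) -> GeneRecord:
    resolved = genome.resolve_target(spec.target)
    if not isinstance(resolved, GeneRecord):
        raise MutationError(
            f"{spec.operation} needs a gene target (line {spec.line_no})"
        )
    return resolved


def _opt(spec: MutationSpec, key: str) -> str:
    val = spec.opt(key)
    if val is None:
        raise MutationError(
            f"{spec.operation} requires option {key}= (line {spec.line_no})"
        )
    return val


# ---------------------------------------------------------------------------
# Output files


def write_outputs(result: JobResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_oligo_tsv(result, out_dir / "oligos.tsv")
    _write_oligo_fasta(result, out_dir / "oligos.fasta")
    _write_primer_tsv(result, out_dir / "masc_primers.tsv")
    _write_expression_tsv(result, out_dir / "expression_report.tsv")
    log_lines = result.log + [f"WARNING {w}" for w in result.warnings]
    log_lines += [f"ERROR {e}" for e in result.errors]
    (out_dir / "job.log").write_text("\n".join(log_lines) + "\n")
    (out_dir / "config.json").write_text(
        json.dumps(result.config_echo, indent=2, sort_keys=True) + "\n"
    )


def _write_oligo_tsv(result: JobResult, path: Path) -> None:
    header = (
        "id\toperation\ttarget\tgenome_window\torientation\tlength\tmfe"
        "\tleft_homology\tright_homology\tsequence"
    )
    rows = [header]
    for o in result.oligos:
        rows.append(
            f"{o.id}\t{o.operation}\t{o.target}\t{o.genome_window[0]}.."
            f"{o.genome_window[1]}\t{o.orientation}\t{o.length}\t{o.mfe:.2f}"
            f"\t{o.left_homology}\t{o.right_homology}\t{o.sequence}"
        )
    path.write_text("\n".join(rows) + "\n")


def _write_oligo_fasta(result: JobResult, path: Path) -> None:
    chunks = []
    for o in result.oligos:
        seq = result.barcoded.get(o.id, o.sequence)
        chunks.append(f">{o.id}\n{seq}")
    path.write_text("\n".join(chunks) + ("\n" if chunks else ""))


def _write_primer_tsv(result: JobResult, path: Path) -> None:
    rows = ["oligo_id\trole\tsequence\ttm\tamplicon_length"]
    for ps in result.primer_sets:
        for primer in ps.all_primers():
            amp = primer.amplicon_length if primer.amplicon_length else ""
            rows.append(
                f"{ps.oligo_id}\t{primer.role}\t{primer.sequence}"
                f"\t{primer.tm:.2f}\t{amp}"
            )
    path.write_text("\n".join(rows) + "\n")


def _write_expression_tsv(result: JobResult, path: Path) -> None:
    """Plot-ready expression table: wild type, maximum and per-oligo levels."""
    rows = [
        "oligo_id\tgene\ttarget_rate\tachieved_rate\twildtype_rate\tmax_rate"
        "\tn_mutations\tseed\ttarget_not_reached"
    ]
    by_gene_max: dict[str, float] = {}
    for rbs in result.rbs_results.values():
        by_gene_max[rbs.gene] = max(
            by_gene_max.get(rbs.gene, 0.0), rbs.achieved_rate
        )
    for oligo_id, rbs in result.rbs_results.items():
        rows.append(
            f"{oligo_id}\t{rbs.gene}\t{rbs.target_rate:.3f}\t{rbs.achieved_rate:.3f}"
            f"\t{rbs.wildtype_rate:.3f}\t{by_gene_max[rbs.gene]:.3f}"
            f"\t{rbs.n_mutations}\t{rbs.seed}\t{rbs.target_not_reached}"
        )
    path.write_text("\n".join(rows) + "\n")
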