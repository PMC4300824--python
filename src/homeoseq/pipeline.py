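"""One-command orchestration: map, call, classify, tally, report.

Each gene is analysed independently (pileup -> site calls -> read
classification -> optional chimera evidence -> tallies), so the run is a loop
over genes whose per-gene results are written as small checkpoint artifacts.
The final tables are assembled from those artifacts in a fixed gene order,
which makes outputs byte-identical across interruption/resume, gene
permutation, and repeated runs — the contract that also licenses parallel
execution.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shlex
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chimera as chimera_mod
from .io_model import (
    GeneReference,
    ProtocolTable,
    read_alignments,
    write_outputs,
)
from .pileup import build_pileup, pool_columns
from .read_classify import classify_read, read_table, tally
from .snp_model import GeneSiteCalls, SnpModelParams, call_gene_sites

logger = logging.getLogger("homeoseq")

DEFAULT_MAPPER_TEMPLATE = "minimap2 -ax sr --sam-hit-only {ref} {fastq} -o {out}"


class PipelineError(RuntimeError):
    pass


class MapperError(PipelineError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines a run's outputs (hashed for resume safety)."""

    params: SnpModelParams = field(default_factory=SnpModelParams)
    min_mapq: int = 20
    include_gdna: bool = True
    chimera: bool = False
    min_support: int = 3
    checkpoint_every: int = 50
    mapper_template: str = DEFAULT_MAPPER_TEMPLATE

    def fingerprint_dict(self) -> dict:
        return {
            "epsilon": self.params.epsilon,
            "alpha": self.params.alpha,
            "min_mapq": self.min_mapq,
            "include_gdna": self.include_gdna,
            "chimera": self.chimera,
            "min_support": self.min_support,
        }


def _fingerprint(
    protocol: ProtocolTable, reference: Sequence[GeneReference], config: RunConfig
) -> str:
    h = hashlib.sha256()
    for s in protocol.samples:
        h.update(repr((s.name, s.role, s.data_type, s.replicate, s.format, s.path)).encode())
    h.update(repr(sorted(protocol.ploidy.items())).encode())
    for g in reference:
        h.update(g.gene_id.encode())
        h.update(g.sequence.encode())
    h.update(json.dumps(config.fingerprint_dict(), sort_keys=True).encode())
    return h.hexdigest()


def invoke_mapper(
    protocol: ProtocolTable,
    reference_path: str | Path,
    outdir: str | Path,
    template: str = DEFAULT_MAPPER_TEMPLATE,
) -> dict[str, Path]:
    """Map every FASTQ sample to the gene reference, one SAM per sample.

    ``template`` is a shell-free command template with ``{ref}``, ``{fastq}``
    and ``{out}`` placeholders.  The executable is resolved before any gene
    processing; a non-zero mapper exit aborts with the command line and
    stderr.  Returns sample name -> SAM path for the mapped samples.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastq_samples = [s for s in protocol.samples if s.format == "fastq"]
    if not fastq_samples:
        return {}
    exe = shlex.split(template.format(ref="r", fastq="q", out="o"))[0]
    if shutil.which(exe) is None:
        raise MapperError(
            f"mapper executable {exe!r} not found on PATH; "
            "provide a different --mapper-template or pre-mapped SAM files"
        )
    produced: dict[str, Path] = {}
    for s in fastq_samples:
        out = outdir / f"{s.name}.sam"
        argv = shlex.split(
            template.format(ref=str(reference_path), fastq=s.path, out=str(out))
        )
        logger.info("mapping %s: %s", s.name, " ".join(argv))
        proc = subprocess.run(argv, capture_output=True, text=True)
        if proc.returncode != 0:
            raise MapperError(
                f"mapper failed for sample {s.name!r} "
                f"(command: {' '.join(argv)}):\n{proc.stderr}"
            )
        produced[s.name] = out
    return produced


def _allele_str(alleles: frozenset[str]) -> str:
    return ",".join(sorted(alleles)) if alleles else "."


def _snp_rows(
    calls: GeneSiteCalls, reference: GeneReference, protocol: ProtocolTable
) -> list[dict]:
    """Rows of the SNP table: positions that are polymorphic, novel or diagnostic."""
    organisms = protocol.organisms()
    parent_alleles = np.stack(
        [calls.allele[f"parent{k}"] for k in range(1, calls.n_parents + 1)]
    )
    parents_unmasked = calls.informative
    differs = parents_unmasked & (parent_alleles != parent_alleles[0]).any(axis=(0, 2))
    interesting = (
        differs | (calls.diag_parent > 0).any(axis=1) | calls.novel.any(axis=1)
    )
    rows = []
    for pos in np.nonzero(interesting)[0]:
        site = calls.site(int(pos))
        row = {
            "gene_id": calls.gene_id,
            "position": int(pos),
            "ref_base": reference.sequence[pos],
        }
        for org in organisms:
            call = site.organisms[org]
            row[f"{org}_alleles"] = _allele_str(call.allele_set)
            row[f"{org}_masked"] = int(call.masked)
        row["novel_alleles"] = _allele_str(site.novel_alleles)
        row["diagnostic"] = int(bool(site.diagnostic_alleles))
        rows.append(row)
    return rows


def _process_gene(
    gene: GeneReference,
    reads: Sequence,
    protocol: ProtocolTable,
    config: RunConfig,
) -> dict:
    """Analyse one gene; returns a JSON-serialisable result record."""
    pile = build_pileup(reads, gene, protocol)
    calls = call_gene_sites(pile, protocol, config.params, config.include_gdna)
    classes = [
        classify_read(pile.read_index[rid], calls) for rid in sorted(pile.read_index)
    ]
    expr = tally(classes, protocol, gene_ids=[gene.gene_id])
    reads_df = read_table(classes, protocol.n_parents)
    result = {
        "gene_id": gene.gene_id,
        "expression": expr.to_dict(orient="records"),
        "snp": _snp_rows(calls, gene, protocol),
        "reads": reads_df.to_dict(orient="records"),
        "masked_positions": {
            org: int(calls.masked[org].sum()) for org in protocol.organisms()
        },
        "n_diagnostic_sites": int(len(calls.diagnostic_positions())),
    }
    if config.chimera:
        evidence = [
            ev
            for c in classes
            if c.conflict_flag
            if (ev := chimera_mod.extract_evidence(c)) is not None
        ]
        # per-homeolog depth: miscall mimicry acts on reads of one ancestry
        mean_child_depth = float(
            pool_columns(pile, protocol, "child", include_gdna=False).sum()
        ) / max(1, gene.length) / protocol.n_parents
        reports = chimera_mod.detect_chimeric_genes(
            evidence,
            config.min_support,
            gene_lengths={gene.gene_id: gene.length},
            alpha=config.params.alpha,
            diag_site_counts={gene.gene_id: result["n_diagnostic_sites"]},
            child_depths={gene.gene_id: mean_child_depth},
            epsilon=config.params.epsilon,
        )
        result["chimera"] = chimera_mod.chimera_table(reports).to_dict(orient="records")
    return result


class _Checkpoint:
    """Per-gene artifact store plus a small manifest, enabling resume."""

    def __init__(self, outdir: Path, run_name: str, fingerprint: str) -> None:
        self.dir = outdir / f"{run_name}.checkpoint"
        self.genes_dir = self.dir / "genes"
        self.manifest_path = self.dir / "manifest.json"
        self.fingerprint = fingerprint
        self.completed: set[str] = set()

    def load(self) -> None:
        if not self.manifest_path.exists():
            raise PipelineError(
                f"cannot resume: no checkpoint manifest at {self.manifest_path}"
            )
        manifest = json.loads(self.manifest_path.read_text())
        if manifest["fingerprint"] != self.fingerprint:
            raise PipelineError(
                "cannot resume: protocol, reference or parameters changed since "
                "the checkpoint was written; start a fresh run"
            )
        self.completed = {
            g for g in manifest["completed_genes"] if (self.genes_dir / f"{g}.json").exists()
        }

    def init(self) -> None:
        if self.dir.exists():
            shutil.rmtree(self.dir)
        self.genes_dir.mkdir(parents=True)
        self.write_manifest()

    def write_manifest(self) -> None:
        tmp = self.manifest_path.with_suffix(".tmp")
        tmp.write_text(
            json.dumps(
                {
                    "fingerprint": self.fingerprint,
                    "completed_genes": sorted(self.completed),
                },
                indent=0,
                sort_keys=True,
            )
        )
        tmp.replace(self.manifest_path)

    def store(self, result: dict) -> None:
        gene_id = result["gene_id"]
        path = self.genes_dir / f"{gene_id}.json"
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(result, sort_keys=True))
        tmp.replace(path)
        self.completed.add(gene_id)

    def fetch(self, gene_id: str) -> dict:
        return json.loads((self.genes_dir / f"{gene_id}.json").read_text())


def summarize(
    expression: pd.DataFrame,
    protocol: ProtocolTable,
    masked_totals: Mapping[str, int],
    n_diagnostic_sites: int,
    novel_sites: int,
    chimera_candidates: int | None = None,
) -> pd.DataFrame:
    """Key/value run summary; totals always equal expression-table sums."""
    parents = [f"parent{k}" for k in range(1, protocol.n_parents + 1)]
    rows: list[tuple[str, float]] = [("genes", expression["gene_id"].nunique())]
    for sample in sorted(expression["sample"].unique()):
        sub = expression[expression["sample"] == sample]
        total = int(sub["total"].sum())
        assigned = int(sub[parents].sum().sum())
        rows.append((f"{sample}.total_reads", total))
        for p in parents:
            rows.append((f"{sample}.{p}", int(sub[p].sum())))
        rows.append((f"{sample}.multi_parent", int(sub["multi_parent"].sum())))
        rows.append((f"{sample}.unknown", int(sub["unknown"].sum())))
        rows.append((f"{sample}.new_snp_reads", int(sub["new_snp_reads"].sum())))
        rows.append((f"{sample}.conflict_reads", int(sub["conflict_reads"].sum())))
        rows.append(
            (f"{sample}.assigned_fraction", round(assigned / total, 6) if total else 0.0)
        )
    rows.append(("diagnostic_sites", n_diagnostic_sites))
    rows.append(("novel_snp_sites", novel_sites))
    for org, n in masked_totals.items():
        rows.append((f"masked_positions.{org}", n))
    if chimera_candidates is not None:
        rows.append(("chimera_candidates", chimera_candidates))
    return pd.DataFrame(rows, columns=["key", "value"])


def run(
    protocol: ProtocolTable,
    reference: Sequence[GeneReference],
    outdir: str | Path,
    run_name: str = "run",
    config: RunConfig | None = None,
    reference_path: str | Path | None = None,
    resume: bool = False,
    stop_after: int | None = None,
) -> dict[str, Path] | None:
    """Execute the full analysis; returns output paths, or None if stopped.

    ``stop_after`` checkpoints after that many newly processed genes and
    returns without writing final tables (used to exercise the
    interrupt/resume contract; a resumed run completes normally).  FASTQ
    samples require ``reference_path`` so the mapper can be invoked.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_ids = [g.gene_id for g in reference]
    if len(set(gene_ids)) != len(gene_ids):
        raise PipelineError("duplicate gene ids in reference")
    genes_by_id = {g.gene_id: g for g in reference}

    ck = _Checkpoint(outdir, run_name, _fingerprint(protocol, reference, config))
    if resume:
        ck.load()
        logger.info("resuming: %d genes already complete", len(ck.completed))
    else:
        ck.init()

    # map FASTQ samples (if any) before any gene processing
    sam_paths = {s.name: Path(s.path) for s in protocol.samples if s.format == "sam"}
    fastq_samples = [s for s in protocol.samples if s.format == "fastq"]
    if fastq_samples:
        if reference_path is None:
            raise PipelineError("FASTQ samples require reference_path for mapping")
        mapped_dir = ck.dir / "mapped"
        todo = [s for s in fastq_samples if not (mapped_dir / f"{s.name}.sam").exists()]
        if todo:
            sub = ProtocolTable(
                tuple(protocol.samples), protocol.ploidy
            )  # full roster; invoke_mapper selects fastq ones
            invoke_mapper(sub, reference_path, mapped_dir, config.mapper_template)
        for s in fastq_samples:
            sam_paths[s.name] = mapped_dir / f"{s.name}.sam"

    # bucket alignments per gene (one pass per sample file)
    reads_by_gene: dict[str, list] = {g: [] for g in gene_ids}
    for s in protocol.samples:
        for read in read_alignments(sam_paths[s.name], reference, s, config.min_mapq):
            reads_by_gene[read.gene_id].append(read)

    processed = 0
    for gene_id in sorted(gene_ids):
        if gene_id in ck.completed:
            continue
        result = _process_gene(
            genes_by_id[gene_id], reads_by_gene[gene_id], protocol, config
        )
        ck.store(result)
        processed += 1
        if processed % config.checkpoint_every == 0:
            ck.write_manifest()
            logger.info("checkpoint: %d/%d genes", len(ck.completed), len(gene_ids))
        if stop_after is not None and processed >= stop_after:
            ck.write_manifest()
            logger.info("stopping early after %d genes (checkpoint saved)", processed)
            return None
    ck.write_manifest()

    # assemble final tables in fixed gene order
    expr_rows: list[dict] = []
    snp_rows: list[dict] = []
    read_rows: list[dict] = []
    chim_rows: list[dict] = []
    masked_totals = {org: 0 for org in protocol.organisms()}
    n_diag = 0
    novel_sites = 0
    for gene_id in sorted(gene_ids):
        result = ck.fetch(gene_id)
        expr_rows.extend(result["expression"])
        snp_rows.extend(result["snp"])
        read_rows.extend(result["reads"])
        chim_rows.extend(result.get("chimera", []))
        for org, n in result["masked_positions"].items():
            masked_totals[org] += n
        n_diag += result["n_diagnostic_sites"]
        novel_sites += sum(1 for r in result["snp"] if r["novel_alleles"] != ".")

    expr_cols = ["gene_id", "sample"] + [
        f"parent{k}" for k in range(1, protocol.n_parents + 1)
    ] + ["multi_parent", "unknown", "total", "new_snp_reads", "conflict_reads"]
    expression = pd.DataFrame(expr_rows, columns=expr_cols)
    snp_cols = ["gene_id", "position", "ref_base"] + [
        f"{org}_{f}" for org in protocol.organisms() for f in ("alleles", "masked")
    ] + ["novel_alleles", "diagnostic"]
    snp = pd.DataFrame(snp_rows, columns=snp_cols)
    read_cols = ["read_id", "gene_id", "sample", "category"] + [
        f"votes_parent{k}" for k in range(1, protocol.n_parents + 1)
    ] + ["new_snp_flag", "conflict_flag"]
    reads_df = pd.DataFrame(read_rows, columns=read_cols)
    tables: dict[str, pd.DataFrame] = {
        "expression": expression,
        "snp": snp,
        "read": reads_df,
    }
    if config.chimera:
        tables["chimera"] = pd.DataFrame(
            chim_rows,
            columns=[
                "gene_id", "supporting_reads", "breakpoint_lo", "breakpoint_hi", "orientation",
            ],
        )
    tables["summary"] = summarize(
        expression,
        protocol,
        masked_totals,
        n_diag,
        novel_sites,
        len(chim_rows) if config.chimera else None,
    )
    return write_outputs(tables, outdir, run_name)
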