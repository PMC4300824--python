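"""Truth-labeled simulator of hybrid/allopolyploid sequencing experiments.

The generator emulates the canonical study design: two (or more) parent
lineages diverged by a per-site substitution probability ``d``, a hybrid child
carrying one homeolog per parent lineage, uniform sequencing error, and
optional genomic-DNA tracks, biological replicates, post-merger (novel)
substitutions and chimeric genes.  It emits a gene reference FASTA, per-sample
reads (true-placement SAM by default, or FASTQ for end-to-end runs with a real
mapper), a ready-to-run protocol table, and a :class:`TruthTable` carrying
every latent variable — so the whole analysis stack is testable without any
external data or executables.

Every source of randomness flows from the single mandatory ``seed``; equal
parameters produce byte-identical files.

What it deliberately does not emulate: indels, instrument-specific error
profiles, base-quality variation, paired-end insert sizes, mapping ambiguity
(SAM mode emits the true placement).  Results on simulated data therefore
measure the statistical model and classifier, not the mapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from .io_model import BASES, ProtocolTable, SampleSpec, write_protocol

ORIGIN_CHIMERA = "chimera"


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated system.

    Coverage parameters are mean coverage *per sequence copy* (per homeolog
    for the child, per haplotype for a parent); read counts per copy are
    Poisson with mean ``coverage * gene_length / read_length``.
    """

    seed: int
    n_genes: int = 200
    gene_length: tuple[int, int] = (1000, 1000)  # uniform inclusive range
    n_parents: int = 2
    divergence: float = 0.05  # per-site substitution probability between lineages
    ploidy: tuple[int, ...] | None = None  # per parent; default all haploid
    heterozygosity: float = 0.0  # per-site het rate within diploid parents
    coverage: float = 50.0  # child mRNA coverage per homeolog
    parent_coverage: float | None = None  # default: same as coverage
    read_length: int = 100
    error_rate: float = 0.01  # uniform per-base miscall probability
    gdna_coverage: float = 0.0  # per-haplotype parent gDNA coverage (0 = none)
    chimeric_fraction: float = 0.0
    novel_rate: float = 0.0  # per-site post-merger substitution rate in the child
    child_replicates: int = 1
    parent_replicates: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.n_parents < 2:
            raise ValueError("need at least two parents")
        if self.ploidy is not None and len(self.ploidy) != self.n_parents:
            raise ValueError("ploidy must list one value per parent")

    @property
    def ploidies(self) -> tuple[int, ...]:
        return self.ploidy if self.ploidy is not None else (1,) * self.n_parents


@dataclass
class TruthTable:
    """Latent truth of a simulated system.

    diagnostic : gene -> {position -> {base -> parent index}} for sites where
        an allele is unique to one parent lineage.
    read_origin : read_id -> parent index (1..P) or "chimera".
    novel : set of (gene_id, position, base) child-specific substitutions.
    junctions : gene_id -> first position of the downstream-parent segment of
        the chimeric homeolog copy.
    """

    diagnostic: dict[str, dict[int, dict[str, int]]] = field(default_factory=dict)
    read_origin: dict[str, str] = field(default_factory=dict)
    novel: set[tuple[str, int, str]] = field(default_factory=set)
    junctions: dict[str, int] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)

    def diagnostic_positions(self, gene_id: str) -> list[int]:
        return sorted(self.diagnostic.get(gene_id, {}))


@dataclass
class SimulatedSystem:
    params: SimParams
    outdir: Path
    reference_path: Path
    protocol_path: Path
    sample_paths: dict[str, Path]
    truth: TruthTable


def reads_for_coverage(coverage: float, gene_length: int, read_length: int) -> float:
    """Poisson mean read count giving the requested per-copy coverage."""
    return coverage * gene_length / min(read_length, gene_length)


def _mutate(seq: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute masked positions to a uniformly chosen different base."""
    out = seq.copy()
    shift = rng.integers(1, 4, size=int(mask.sum()))
    out[mask] = (out[mask] + shift) % 4
    return out


def _sample_reads(
    seq: np.ndarray,
    n_reads: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform read starts plus uniform miscalls; returns (starts, bases)."""
    L = seq.shape[0]
    rl = min(read_length, L)
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    windows = seq[starts[:, None] + np.arange(rl)]
    if error_rate > 0:
        err = rng.random((n_reads, rl)) < error_rate
        shift = rng.integers(1, 4, size=(n_reads, rl))
        windows = np.where(err, (windows + shift) % 4, windows)
    return starts, windows


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def simulate_system(
    params: SimParams, outdir: str | Path, mode: str = "sam"
) -> SimulatedSystem:
    """Generate a complete simulated system on disk.

    ``mode`` is "sam" (true placements, no mapper needed) or "fastq".
    Returns paths plus the :class:`TruthTable`; with the same parameters the
    emitted files are byte-identical across runs.
    """
    if mode not in ("sam", "fastq"):
        raise ValueError(f"mode must be 'sam' or 'fastq', got {mode!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    P = params.n_parents
    ploidies = params.ploidies
    truth = TruthTable()

    # -- sample roster -----------------------------------------------------
    samples: list[SampleSpec] = []
    ext = "sam" if mode == "sam" else "fastq"
    for k in range(1, P + 1):
        for r in range(1, params.parent_replicates + 1):
            name = f"P{k}_mRNA_{r}"
            samples.append(
                SampleSpec(name, f"parent{k}", "mRNA", r, f"{name}.{ext}", ext)
            )
        if params.gdna_coverage > 0:
            name = f"P{k}_gDNA_1"
            samples.append(
                SampleSpec(name, f"parent{k}", "gDNA", 1, f"{name}.{ext}", ext)
            )
    for r in range(1, params.child_replicates + 1):
        name = f"child_mRNA_{r}"
        samples.append(SampleSpec(name, "child", "mRNA", r, f"{name}.{ext}", ext))
    protocol = ProtocolTable(
        tuple(samples), {k: ploidies[k - 1] for k in range(1, P + 1)}
    )

    # -- per-gene sequences and truth --------------------------------------
    n_digits = max(4, len(str(params.n_genes)))
    gene_ids = [f"g{i:0{n_digits}d}" for i in range(params.n_genes)]
    lo, hi = params.gene_length
    lengths = rng.integers(lo, hi + 1, size=params.n_genes)
    ref_seqs: dict[str, np.ndarray] = {}
    # gene -> organism copies: "parent<k>" -> list of haplotypes;
    # "child" -> list of (origin label, sequence)
    copies: dict[str, dict[str, list]] = {}

    for gi, gene_id in enumerate(gene_ids):
        L = int(lengths[gi])
        truth.gene_lengths[gene_id] = L
        ancestral = rng.integers(0, 4, size=L).astype(np.uint8)
        # lineage base sequences: parent 1 keeps the ancestral sequence
        lineage = [ancestral]
        for _ in range(2, P + 1):
            div_mask = rng.random(L) < params.divergence
            lineage.append(_mutate(ancestral, div_mask, rng))
        # haplotypes per parent (heterozygosity within diploids)
        haplotypes: list[list[np.ndarray]] = []
        for k in range(P):
            haps = [lineage[k]]
            if ploidies[k] == 2:
                het_mask = rng.random(L) < params.heterozygosity
                haps.append(_mutate(lineage[k], het_mask, rng))
            haplotypes.append(haps)
        # child inherits one haplotype per parent lineage
        child: list[tuple[str, np.ndarray]] = []
        for k in range(P):
            hap = haplotypes[k][int(rng.integers(len(haplotypes[k])))]
            child.append((f"p{k + 1}", hap.copy()))
        # novel (post-merger) substitutions: planted at positions where all
        # parental haplotypes agree, on one randomly chosen homeolog copy
        if params.novel_rate > 0:
            all_haps = np.stack([h for haps in haplotypes for h in haps])
            uniform = (all_haps == all_haps[0]).all(axis=0)
            novel_mask = (rng.random(L) < params.novel_rate) & uniform
            for pos in np.nonzero(novel_mask)[0]:
                copy_i = int(rng.integers(P))
                base = int(all_haps[0][pos])
                new = (base + int(rng.integers(1, 4))) % 4
                child[copy_i][1][pos] = new
                truth.novel.add((gene_id, int(pos), BASES[new]))
        # chimeric genes: homeolog 1 replaced by a parent-1/parent-2 fusion
        if params.chimeric_fraction > 0 and rng.random() < params.chimeric_fraction:
            j = int(rng.integers(max(1, L // 10), max(2, L - L // 10)))
            fused = np.concatenate([child[0][1][:j], child[1][1][j:]])
            child[0] = (ORIGIN_CHIMERA, fused)
            truth.junctions[gene_id] = j
        # truth diagnostic sites from parental allele sets
        diag: dict[int, dict[str, int]] = {}
        hap_stack = [np.stack(haps) for haps in haplotypes]  # per parent: (n_hap, L)
        all_stack = np.concatenate(hap_stack)  # every haplotype of every parent
        for pos in np.nonzero((all_stack != all_stack[0]).any(axis=0))[0]:
            sets = [set(int(b) for b in hs[:, pos]) for hs in hap_stack]
            for base in range(4):
                holders = [k for k, s in enumerate(sets) if base in s]
                if len(holders) == 1:
                    diag.setdefault(int(pos), {})[BASES[base]] = holders[0] + 1
        if diag:
            truth.diagnostic[gene_id] = diag
        ref_seqs[gene_id] = ancestral  # reference = parent-1 lineage sequence
        copies[gene_id] = {
            **{f"parent{k + 1}": haplotypes[k] for k in range(P)},
            "child": child,
        }

    # -- reference FASTA ----------------------------------------------------
    reference_path = outdir / "reference.fasta"
    with open(reference_path, "w") as fh:
        for gene_id in gene_ids:
            fh.write(f">{gene_id}\n{_to_str(ref_seqs[gene_id])}\n")

    # -- reads per sample ---------------------------------------------------
    sample_paths: dict[str, Path] = {}
    buffers: dict[str, list[str]] = {s.name: [] for s in samples}
    header = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{g}\tLN:{truth.gene_lengths[g]}" for g in gene_ids
    ]

    for gene_id in gene_ids:
        L = truth.gene_lengths[gene_id]
        for s in samples:
            if s.is_child:
                source = [(origin, seq) for origin, seq in copies[gene_id]["child"]]
                cov = params.coverage
            else:
                k = s.parent_index
                haps = copies[gene_id][f"parent{k}"]
                source = [(f"p{k}", h) for h in haps]
                cov = (
                    params.gdna_coverage
                    if s.data_type == "gDNA"
                    else (params.parent_coverage or params.coverage)
                )
            lam = reads_for_coverage(cov, L, params.read_length)
            for origin, seq in source:
                n_reads = int(rng.poisson(lam))
                if n_reads == 0:
                    continue
                starts, bases = _sample_reads(
                    seq, n_reads, params.read_length, params.error_rate, rng
                )
                rl = bases.shape[1]
                for i in range(n_reads):
                    rid = f"{gene_id}|{s.name}|{origin}|{i:06d}"
                    truth.read_origin[rid] = origin
                    seq_str = _to_str(bases[i])
                    if mode == "sam":
                        buffers[s.name].append(
                            f"{rid}\t0\t{gene_id}\t{int(starts[i]) + 1}\t60\t{rl}M\t*\t0\t0\t{seq_str}\t{'I' * rl}"
                        )
                    else:
                        buffers[s.name].append(
                            f"@{rid}\n{seq_str}\n+\n{'I' * rl}"
                        )

    for s in samples:
        path = outdir / s.path
        with open(path, "w") as fh:
            if mode == "sam":
                fh.write("\n".join(header) + "\n")
            if buffers[s.name]:
                fh.write("\n".join(buffers[s.name]) + "\n")
        sample_paths[s.name] = path

    protocol_path = outdir / "protocol.tsv"
    write_protocol(protocol, protocol_path)
    return SimulatedSystem(
        params=params,
        outdir=outdir,
        reference_path=reference_path,
        protocol_path=protocol_path,
        sample_paths=sample_paths,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

def _origin_of(read_id: str) -> str:
    return read_id.split("|")[2]


def evaluate(
    truth: TruthTable,
    read_df: pd.DataFrame,
    snp_df: pd.DataFrame | None = None,
    chimera_df: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Score run outputs against the simulation truth.

    Returns diagnostic-site recall/precision, read-assignment error among
    parent-assigned reads, assigned fraction, novel-SNP recall/precision and
    chimera recall / false-candidate rate.  Ratios with zero denominator are
    reported as NaN.
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den else math.nan

    metrics: dict[str, float] = {}

    # read assignment ------------------------------------------------------
    categories = read_df["category"].to_numpy()
    assigned = np.char.startswith(categories.astype(str), "parent")
    origins = np.array([_origin_of(r) for r in read_df["read_id"]])
    for rid in read_df["read_id"]:
        if rid not in truth.read_origin:
            raise KeyError(f"read {rid!r} not present in the truth table")
    n_total = len(read_df)
    n_assigned = int(assigned.sum())
    informative = assigned & (origins != ORIGIN_CHIMERA)
    wrong = informative & (
        np.char.replace(categories.astype(str), "parent", "p") != origins
    )
    metrics["assigned_fraction"] = ratio(n_assigned, n_total)
    metrics["assignment_error"] = ratio(int(wrong.sum()), int(informative.sum()))
    metrics["multi_or_unknown_fraction"] = ratio(n_total - n_assigned, n_total)
    metrics["n_reads"] = float(n_total)
    metrics["n_assigned"] = float(n_assigned)

    # diagnostic sites ------------------------------------------------------
    if snp_df is not None:
        called = {
            (g, int(p))
            for g, p, d in zip(snp_df["gene_id"], snp_df["position"], snp_df["diagnostic"])
            if d
        }
        true = {
            (g, p) for g, positions in truth.diagnostic.items() for p in positions
        }
        tp = len(called & true)
        metrics["diagnostic_recall"] = ratio(tp, len(true))
        metrics["diagnostic_precision"] = ratio(tp, len(called))

        called_novel = set()
        for g, p, alleles in zip(
            snp_df["gene_id"], snp_df["position"], snp_df["novel_alleles"]
        ):
            if isinstance(alleles, str) and alleles != ".":
                for b in alleles.split(","):
                    called_novel.add((g, int(p), b))
        tp_n = len(called_novel & truth.novel)
        metrics["novel_recall"] = ratio(tp_n, len(truth.novel))
        metrics["novel_precision"] = ratio(tp_n, len(called_novel))

    # chimera ----------------------------------------------------------------
    if chimera_df is not None:
        candidates = {
            g: (int(lo), int(hi))
            for g, lo, hi in zip(
                chimera_df["gene_id"],
                chimera_df["breakpoint_lo"],
                chimera_df["breakpoint_hi"],
            )
        }
        true_genes = set(truth.junctions)
        detected = {
            g
            for g, (lo, hi) in candidates.items()
            if g in truth.junctions and lo < truth.junctions[g] <= hi
        }
        n_nonchimeric = len(truth.gene_lengths) - len(true_genes)
        metrics["chimera_recall"] = ratio(len(detected), len(true_genes))
        metrics["chimera_false_rate"] = ratio(
            len(set(candidates) - true_genes), n_nonchimeric
        )
    return metrics
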