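"""Input/output layer: protocol files, gene references, SAM alignments, result tables.

The data model is deliberately small.  A :class:`ProtocolTable` declares which
sequencing samples belong to which organism (parent 1..P or the hybrid child),
what kind of data each is (mRNA or gDNA), and where the reads live.  A
:class:`GeneReference` is one transcript/CDS sequence from the (possibly
foreign) gene reference.  An :class:`AlignedRead` is one primary alignment
reduced to its reference-anchored base observations.

All internal coordinates are 0-based, half-open.  SAM positions are converted
when alignments are parsed and never appear 1-based anywhere else.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

BASES = "ACGT"
#: base -> small-integer code; N (and anything unexpected) maps to 4 and is
#: never counted as an allele observation.
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c


def encode_bases(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode_bases(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


class ProtocolError(ValueError):
    """Raised for a malformed or inconsistent protocol table."""


class ReferenceError_(ValueError):
    """Raised for a malformed gene reference."""


class AlignmentError(ValueError):
    """Raised when a SAM stream is inconsistent with the reference."""


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing sample: its organism role, data type and file."""

    name: str
    role: str  # "parent<k>" or "child"
    data_type: str  # "mRNA" or "gDNA"
    replicate: int
    path: str
    format: str  # "fastq" or "sam"

    @property
    def parent_index(self) -> int | None:
        m = re.fullmatch(r"parent(\d+)", self.role)
        return int(m.group(1)) if m else None

    @property
    def is_child(self) -> bool:
        return self.role == "child"


@dataclass(frozen=True)
class ProtocolTable:
    """Validated collection of samples plus per-parent ploidy."""

    samples: tuple[SampleSpec, ...]
    ploidy: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.samples]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ProtocolError(f"duplicate sample name(s): {sorted(dup)}")
        parent_idx = sorted({s.parent_index for s in self.samples if s.parent_index})
        if not parent_idx:
            raise ProtocolError("no parent declared")
        if parent_idx != list(range(1, len(parent_idx) + 1)) or len(parent_idx) < 2:
            raise ProtocolError(
                f"parent indices must form a contiguous range 1..P with P >= 2, got {parent_idx}"
            )
        for k in parent_idx:
            if not any(
                s.parent_index == k and s.data_type == "mRNA" for s in self.samples
            ):
                raise ProtocolError(f"parent{k} has no mRNA sample")
        if not any(s.is_child and s.data_type == "mRNA" for s in self.samples):
            raise ProtocolError("no child mRNA sample declared")
        ploidy = dict(self.ploidy)
        for k in parent_idx:
            ploidy.setdefault(k, 1)
            if ploidy[k] not in (1, 2):
                raise ProtocolError(f"ploidy of parent{k} must be 1 or 2")
        object.__setattr__(self, "ploidy", ploidy)

    @property
    def n_parents(self) -> int:
        return max(s.parent_index for s in self.samples if s.parent_index)

    def organisms(self) -> list[str]:
        """Parent roles in index order, then 'child'."""
        return [f"parent{k}" for k in range(1, self.n_parents + 1)] + ["child"]

    def samples_for(self, organism: str, data_type: str | None = None) -> list[SampleSpec]:
        out = [s for s in self.samples if s.role == organism]
        if data_type is not None:
            out = [s for s in out if s.data_type == data_type]
        return out

    def sample(self, name: str) -> SampleSpec:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(name)


_PROTOCOL_COLUMNS = ["sample_name", "role", "type", "replicate", "format", "path"]
_ROLE_RE = re.compile(r"parent\d+|child")


def parse_protocol(path: str | Path) -> ProtocolTable:
    """Parse a tab-separated protocol file into a validated :class:`ProtocolTable`.

    Columns: sample_name, role (parent1|parent2|...|child), type (mRNA|gDNA),
    replicate (int), format (fastq|sam), path.  An optional header row and an
    optional ploidy directive line ``#ploidy parent1=1 parent2=2`` are
    recognised; other ``#`` lines are comments.
    """
    path = Path(path)
    samples: list[SampleSpec] = []
    ploidy: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.lower().startswith("#ploidy"):
                    for tok in line.split()[1:]:
                        m = re.fullmatch(r"parent(\d+)=([12])", tok)
                        if not m:
                            raise ProtocolError(
                                f"{path} line {lineno}: bad ploidy token {tok!r}"
                            )
                        ploidy[int(m.group(1))] = int(m.group(2))
                continue
            fields = line.split("\t")
            if [f.strip() for f in fields[:1]] == ["sample_name"]:
                continue  # header row
            if len(fields) != len(_PROTOCOL_COLUMNS):
                raise ProtocolError(
                    f"{path} line {lineno}: expected {len(_PROTOCOL_COLUMNS)} "
                    f"tab-separated fields ({', '.join(_PROTOCOL_COLUMNS)}), got {len(fields)}"
                )
            name, role, dtype, replicate, fmt, fpath = (f.strip() for f in fields)
            if not _ROLE_RE.fullmatch(role):
                raise ProtocolError(f"{path} line {lineno}: unknown role {role!r}")
            if dtype not in ("mRNA", "gDNA"):
                raise ProtocolError(f"{path} line {lineno}: unknown data type {dtype!r}")
            if fmt not in ("fastq", "sam"):
                raise ProtocolError(f"{path} line {lineno}: unknown format {fmt!r}")
            try:
                rep = int(replicate)
                if rep < 1:
                    raise ValueError
            except ValueError:
                raise ProtocolError(
                    f"{path} line {lineno}: replicate must be a positive integer, got {replicate!r}"
                ) from None
            if not Path(fpath).is_absolute():
                fpath = str(path.parent / fpath)  # paths relative to the protocol file
            samples.append(SampleSpec(name, role, dtype, rep, fpath, fmt))
    if not samples:
        raise ProtocolError(f"{path}: no samples declared")
    return ProtocolTable(tuple(samples), ploidy)


def write_protocol(protocol: ProtocolTable, path: str | Path) -> None:
    """Write a protocol table in the dialect accepted by :func:`parse_protocol`."""
    with open(path, "w") as fh:
        fh.write(
            "#ploidy "
            + " ".join(f"parent{k}={v}" for k, v in sorted(protocol.ploidy.items()))
            + "\n"
        )
        fh.write("\t".join(_PROTOCOL_COLUMNS) + "\n")
        for s in protocol.samples:
            fh.write(
                "\t".join(
                    [s.name, s.role, s.data_type, str(s.replicate), s.format, s.path]
                )
                + "\n"
            )


@dataclass(frozen=True)
class GeneReference:
    """One reference transcript/CDS; sequence over A,C,G,T,N (uppercase)."""

    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_reference(path: str | Path) -> list[GeneReference]:
    """Read a FASTA gene reference.

    Headers are truncated at the first whitespace; sequences are uppercased.
    Duplicate gene ids, empty records and non-nucleotide characters are errors.
    """
    genes: list[GeneReference] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        seq = str(rec.seq).upper()
        if gene_id in seen:
            raise ReferenceError_(f"duplicate gene id {gene_id!r} in {path}")
        if not seq:
            raise ReferenceError_(f"empty sequence for gene {gene_id!r} in {path}")
        if re.search(r"[^ACGTN]", seq):
            bad = sorted(set(re.findall(r"[^ACGTN]", seq)))
            raise ReferenceError_(
                f"non-nucleotide character(s) {bad} in record {gene_id!r}"
            )
        seen.add(gene_id)
        genes.append(GeneReference(gene_id, seq))
    if not genes:
        raise ReferenceError_(f"no FASTA records found in {path}")
    return genes


@dataclass(frozen=True)
class AlignedRead:
    """One primary alignment reduced to reference-anchored base observations.

    ``positions`` are strictly increasing 0-based gene coordinates; positions
    consumed by deletions, introns or clips are absent.  ``base_codes`` holds
    the matching read bases (A=0..T=3, N=4).
    """

    read_id: str
    gene_id: str
    sample_name: str
    positions: np.ndarray  # int32, strictly increasing
    base_codes: np.ndarray  # uint8
    mapq: int

    @property
    def start(self) -> int:
        return int(self.positions[0]) if self.positions.size else 0

    @property
    def aligned_bases(self) -> list[tuple[int, str]]:
        return [
            (int(p), BASES[c] if c < 4 else "N")
            for p, c in zip(self.positions, self.base_codes)
        ]


def read_alignments(
    sam: str | Path,
    reference: Sequence[GeneReference],
    sample: SampleSpec,
    min_mapq: int = 20,
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file.

    Unmapped, secondary and supplementary records and records below
    ``min_mapq`` are dropped.  CIGARs are resolved to (position, base) pairs;
    insertions contribute no reference-anchored observation.  A record mapped
    to a gene absent from ``reference`` raises :class:`AlignmentError`.
    """
    lengths = {g.gene_id: g.length for g in reference}
    with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            gene_id = rec.reference_name
            if gene_id not in lengths:
                raise AlignmentError(
                    f"read {rec.query_name!r} maps to {gene_id!r}, "
                    "which is not in the gene reference"
                )
            seq = rec.query_sequence
            if seq is None:
                continue
            try:
                pairs = rec.get_aligned_pairs(matches_only=True)
            except Exception as exc:  # malformed CIGAR surfaces here
                raise AlignmentError(
                    f"read {rec.query_name!r}: cannot resolve CIGAR ({exc})"
                ) from exc
            if not pairs:
                continue
            qpos = np.fromiter((q for q, _ in pairs), dtype=np.int32, count=len(pairs))
            rpos = np.fromiter((r for _, r in pairs), dtype=np.int32, count=len(pairs))
            if rpos[-1] >= lengths[gene_id]:
                raise AlignmentError(
                    f"read {rec.query_name!r} extends past the end of {gene_id!r} "
                    f"({rpos[-1]} >= {lengths[gene_id]})"
                )
            codes = encode_bases(seq)[qpos]
            read_id = rec.query_name
            if rec.is_paired:  # mates are counted as independent reads
                read_id += "/2" if rec.is_read2 else "/1"
            yield AlignedRead(
                read_id=read_id,
                gene_id=gene_id,
                sample_name=sample.name,
                positions=rpos,
                base_codes=codes,
                mapq=rec.mapping_quality,
            )


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format="%.6g")
    os.replace(tmp, path)


def write_outputs(
    tables: Mapping[str, pd.DataFrame], outdir: str | Path, run_name: str
) -> dict[str, Path]:
    """Write the result tables as TSV files with deterministic row order.

    ``tables`` maps short names (``expression``, ``snp``, ``read``,
    ``summary``, optionally ``chimera``) to DataFrames.  Files are written
    atomically (temp + rename) as ``<run>.<name>.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise OSError(f"output directory {outdir} is not writable")
    sort_keys = {
        "expression": ["gene_id", "sample"],
        "snp": ["gene_id", "position"],
        "read": ["gene_id", "sample", "read_id"],
        "chimera": ["gene_id"],
    }
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        keys = [k for k in sort_keys.get(name, []) if k in df.columns]
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
        path = outdir / f"{run_name}.{name}.txt"
        _atomic_write(df, path)
        paths[name] = path
    return paths
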