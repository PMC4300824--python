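"""Per-gene base-count matrices (pileups) and pooling across samples.

Each gene is analysed independently, so the pileup is the unit of work: a
``(gene length, 4)`` count matrix per sample, plus an index of the child mRNA
reads that will later be classified.  N bases are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_model import AlignedRead, GeneReference, ProtocolTable


class PileupError(ValueError):
    """Raised when reads are inconsistent with the gene they claim to cover."""


@dataclass
class GenePileup:
    """Base counts per sample per position for one gene.

    ``counts[sample_name]`` is an int64 array of shape ``(length, 4)`` over
    bases A,C,G,T.  ``read_index`` retains child mRNA reads for classification.
    """

    gene_id: str
    length: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    read_index: dict[str, AlignedRead] = field(default_factory=dict)

    def sample_counts(self, sample_name: str) -> np.ndarray:
        arr = self.counts.get(sample_name)
        if arr is None:
            arr = np.zeros((self.length, 4), dtype=np.int64)
        return arr

    def coverage(self, sample_name: str) -> np.ndarray:
        return self.sample_counts(sample_name).sum(axis=1)


def build_pileup(
    reads: Iterable[AlignedRead], gene: GeneReference, protocol: ProtocolTable
) -> GenePileup:
    """Tally every non-N (position, base) observation of ``reads`` on ``gene``.

    Child mRNA reads are additionally retained in ``read_index``.  A position
    outside the gene indicates a reference/alignment mismatch and is an error.
    """
    pile = GenePileup(gene_id=gene.gene_id, length=gene.length)
    child_mrna = {
        s.name for s in protocol.samples if s.is_child and s.data_type == "mRNA"
    }
    for read in reads:
        if read.gene_id != gene.gene_id:
            raise PileupError(
                f"read {read.read_id!r} belongs to {read.gene_id!r}, not {gene.gene_id!r}"
            )
        if read.positions.size:
            if read.positions[0] < 0 or read.positions[-1] >= gene.length:
                raise PileupError(
                    f"read {read.read_id!r} covers position outside {gene.gene_id!r} "
                    f"(length {gene.length})"
                )
        arr = pile.counts.get(read.sample_name)
        if arr is None:
            arr = pile.counts[read.sample_name] = np.zeros(
                (gene.length, 4), dtype=np.int64
            )
        valid = read.base_codes < 4
        np.add.at(arr, (read.positions[valid], read.base_codes[valid]), 1)
        if read.sample_name in child_mrna:
            pile.read_index[read.read_id] = read
    return pile


def pool_columns(
    pileup: GenePileup,
    protocol: ProtocolTable,
    organism: str,
    include_gdna: bool = True,
) -> np.ndarray:
    """Elementwise sum of counts over all samples of one organism.

    mRNA replicates are always pooled; gDNA samples are added only when
    ``include_gdna`` is set.  Returns an ``(length, 4)`` array.
    """
    if organism not in protocol.organisms():
        raise KeyError(f"unknown organism {organism!r}")
    pooled = np.zeros((pileup.length, 4), dtype=np.int64)
    for s in protocol.samples_for(organism):
        if s.data_type == "gDNA" and not include_gdna:
            continue
        pooled += pileup.sample_counts(s.name)
    return pooled
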