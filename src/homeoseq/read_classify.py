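"""Assignment of hybrid mRNA reads to parental homeologs.

Each child read is scored against the gene's site calls: a base matching a
diagnostic allele of parent k is one vote for parent k.  Reads with votes for
exactly one parent are assigned to that homeolog; reads overlapping
confidently called sites but carrying no diagnostic allele are *multi-parent*
(consistent with two or more parents); reads overlapping only masked or
uncalled positions are *unknown* (more data could rescue them).  Reads voting
for two or more parents are demoted to multi-parent with a conflict flag —
they are evidence for chimeric transcripts, not for either homeolog.  A read
is additionally flagged when it carries a confirmed novel (post-merger) SNP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_model import AlignedRead, ProtocolTable
from .snp_model import GeneSiteCalls

CATEGORY_MULTI = "multi-parent"
CATEGORY_UNKNOWN = "unknown"


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ReadClass:
    """One read's classification outcome."""

    read_id: str
    gene_id: str
    sample_name: str
    category: str  # "parent<k>", "multi-parent" or "unknown"
    votes: dict[int, int]  # parent index -> diagnostic alleles matched
    new_snp_flag: bool
    conflict_flag: bool
    #: position-ordered (position, parent) diagnostic matches, for chimera
    #: evidence extraction.
    diagnostic_hits: tuple[tuple[int, int], ...] = ()


def classify_read(read: AlignedRead, sites: GeneSiteCalls) -> ReadClass:
    """Classify one child mRNA read against its gene's site calls."""
    if read.gene_id != sites.gene_id:
        raise ClassifyError(
            f"read {read.read_id!r} is on {read.gene_id!r}, sites are for {sites.gene_id!r}"
        )
    pos = read.positions
    codes = read.base_codes
    ok = codes < 4
    pos, codes = pos[ok], codes[ok]
    if pos.size and (pos[0] < 0 or pos[-1] >= sites.length):
        raise ClassifyError(
            f"read {read.read_id!r} covers position without a site call"
        )

    informative = sites.informative[pos]
    owners = sites.diag_parent[pos, codes]  # 0 where not diagnostic for this base
    hit = owners > 0
    votes_arr = np.bincount(owners[hit], minlength=sites.n_parents + 1)[1:]
    voted = np.nonzero(votes_arr)[0] + 1
    new_snp = bool(sites.novel[pos, codes].any())

    if voted.size == 1:
        category = f"parent{voted[0]}"
        conflict = False
    elif voted.size >= 2:
        category = CATEGORY_MULTI
        conflict = True
    elif informative.any():
        category = CATEGORY_MULTI
        conflict = False
    else:
        category = CATEGORY_UNKNOWN
        conflict = False

    order = np.argsort(pos[hit], kind="stable")
    hits = tuple(
        (int(p), int(o)) for p, o in zip(pos[hit][order], owners[hit][order])
    )
    return ReadClass(
        read_id=read.read_id,
        gene_id=read.gene_id,
        sample_name=read.sample_name,
        category=category,
        votes={int(k): int(votes_arr[k - 1]) for k in voted},
        new_snp_flag=new_snp,
        conflict_flag=conflict,
        diagnostic_hits=hits,
    )


def classify_gene(
    pileup_reads: Iterable[AlignedRead], sites: GeneSiteCalls
) -> list[ReadClass]:
    """Classify every read of a gene (order of input never affects results)."""
    return [classify_read(r, sites) for r in pileup_reads]


def tally(
    classes: Sequence[ReadClass],
    protocol: ProtocolTable,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-child-sample category counts (the expression table).

    One row per (gene, child mRNA sample), including all-zero rows for genes
    without reads when ``gene_ids`` is given.  Category counts always sum to
    the total classified reads of that gene and sample.
    """
    child_samples = [
        s.name for s in protocol.samples if s.is_child and s.data_type == "mRNA"
    ]
    known = set(child_samples)
    for c in classes:
        if c.sample_name not in known:
            raise ClassifyError(
                f"read {c.read_id!r} belongs to undeclared child sample {c.sample_name!r}"
            )
    parents = list(range(1, protocol.n_parents + 1))
    genes = sorted(set(gene_ids) if gene_ids is not None else {c.gene_id for c in classes})
    index = {(g, s): i for i, (g, s) in enumerate(
        (g, s) for g in genes for s in child_samples
    )}
    n = len(index)
    cols = {f"parent{k}": np.zeros(n, dtype=np.int64) for k in parents}
    multi = np.zeros(n, dtype=np.int64)
    unknown = np.zeros(n, dtype=np.int64)
    new_snp = np.zeros(n, dtype=np.int64)
    conflict = np.zeros(n, dtype=np.int64)
    for c in classes:
        i = index[(c.gene_id, c.sample_name)]
        if c.category == CATEGORY_MULTI:
            multi[i] += 1
        elif c.category == CATEGORY_UNKNOWN:
            unknown[i] += 1
        else:
            cols[c.category][i] += 1
        if c.new_snp_flag:
            new_snp[i] += 1
        if c.conflict_flag:
            conflict[i] += 1
    df = pd.DataFrame(
        {
            "gene_id": [g for g in genes for _ in child_samples],
            "sample": [s for _ in genes for s in child_samples],
            **cols,
            "multi_parent": multi,
            "unknown": unknown,
        }
    )
    df["total"] = df[[f"parent{k}" for k in parents]].sum(axis=1) + df["multi_parent"] + df["unknown"]
    df["new_snp_reads"] = new_snp
    df["conflict_reads"] = conflict
    return df


def read_table(classes: Sequence[ReadClass], n_parents: int) -> pd.DataFrame:
    """Per-read output table."""
    rows = {
        "read_id": [c.read_id for c in classes],
        "gene_id": [c.gene_id for c in classes],
        "sample": [c.sample_name for c in classes],
        "category": [c.category for c in classes],
    }
    for k in range(1, n_parents + 1):
        rows[f"votes_parent{k}"] = [c.votes.get(k, 0) for c in classes]
    rows["new_snp_flag"] = [int(c.new_snp_flag) for c in classes]
    rows["conflict_flag"] = [int(c.conflict_flag) for c in classes]
    return pd.DataFrame(rows)
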