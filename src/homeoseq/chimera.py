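"""Experimental detection of chimeric genes (recombined homeologs).

A read voting for two parents is suspicious; a read whose votes form exactly
two position-ordered runs — parent a up to some position, then parent b — is
*single-switch* evidence that the transcript recombines the two homeologs
somewhere in the gap between the runs.  Reads with three or more runs are
discarded as likely artifacts.  A gene becomes a candidate when at least
``min_support`` single-switch reads agree in switch orientation and their
breakpoint intervals share a common point; the consensus breakpoint is the
intersection of those intervals.

This feature is conservative by design and never alters expression counts:
conflicted reads are already demoted to the multi-parent category before
chimera evidence is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .read_classify import ReadClass

STATUS_CANDIDATE = "candidate"
STATUS_NONE = "none"


@dataclass(frozen=True)
class ChimeraEvidence:
    """One single-switch read supporting a homeolog recombination."""

    gene_id: str
    read_id: str
    vote_runs: tuple[tuple[int, int, int], ...]  # (parent, first_pos, last_pos)
    breakpoint_interval: tuple[int, int]  # open interval between the runs
    orientation: tuple[int, int]  # (parent upstream, parent downstream)


@dataclass(frozen=True)
class ChimeraReport:
    gene_id: str
    supporting_reads: int
    consensus_breakpoint: tuple[int, int] | None
    orientation: tuple[int, int] | None
    status: str


def extract_evidence(read_class: ReadClass) -> ChimeraEvidence | None:
    """Turn a conflicted read into chimera evidence, or None.

    Requires ``conflict_flag``; groups the read's diagnostic matches into
    maximal position-ordered runs by parent and emits evidence only for the
    exactly-one-switch pattern (two runs, different parents).
    """
    if not read_class.conflict_flag:
        raise ValueError(
            f"read {read_class.read_id!r} is not conflicted; no evidence to extract"
        )
    runs: list[tuple[int, int, int]] = []
    for parent, group in groupby(read_class.diagnostic_hits, key=lambda h: h[1]):
        positions = [p for p, _ in group]
        runs.append((parent, positions[0], positions[-1]))
    if len(runs) != 2:
        return None  # zero/one run cannot conflict; >= 3 runs are artifacts
    (pa, _, last_a), (pb, first_b, _) = runs
    return ChimeraEvidence(
        gene_id=read_class.gene_id,
        read_id=read_class.read_id,
        vote_runs=tuple(runs),
        breakpoint_interval=(last_a, first_b),
        orientation=(pa, pb),
    )


def _best_clique(intervals: list[tuple[int, int]]) -> tuple[int, tuple[int, int] | None]:
    """Largest set of open intervals sharing a common point.

    In one dimension pairwise intersection is equivalent to a common point,
    so the maximum clique is the maximum stabbing number.  Returns (size,
    (max lo, min hi) of the clique); ties resolved toward the leftmost point.
    """
    best_n, best = 0, None
    for lo, _ in sorted(intervals):
        x = lo + 0.5  # a point just inside any interval opening at lo
        members = [(a, b) for a, b in intervals if a < x < b]
        if len(members) > best_n:
            best_n = len(members)
            best = (max(a for a, _ in members), min(b for _, b in members))
    return best_n, best


def _clique_pvalue(n: int, support: int, mean_width: float, length: int) -> float:
    """Union-bound chance of an equally large accidental clique.

    Null model: the gene is not chimeric, so its ``n`` single-switch reads of
    this orientation are error artifacts whose breakpoint intervals (mean
    width ``mean_width``) sit at effectively random positions along the gene.
    A clique of ``support`` intervals sharing a point then requires
    ``support - 1`` intervals to cover the anchor interval's opening point,
    each with probability about ``mean_width / length``; the bound sums over
    the n possible anchors.  Conservative for a real chimera, whose clique
    holds most of the gene's evidence.
    """
    p = min(1.0, mean_width / length)
    return float(n * stats.binom.sf(support - 2, n - 1, p))


def _recurrence_pvalue(
    support: int, n_diag_sites: int, child_depth: float, epsilon: float
) -> float:
    """Chance that recurrent miscalls at one diagnostic site mimic the clique.

    A single miscalled base at a diagnostic site turns an otherwise cleanly
    assigned read into single-switch evidence, and several reads miscalled at
    the *same* site produce identical breakpoint intervals — an automatic
    clique.  Only reads of one ancestry can be miscalled into a given switch
    orientation at a given site, so ``child_depth`` is the mean per-homeolog
    depth.  Under the error-only null the number of such reads showing one
    specific wrong base at one site is Binomial(depth, epsilon/3); the bound
    multiplies the per-site tail by the number of diagnostic sites and the
    two switch orientations.
    """
    n = max(support, int(round(child_depth)))
    per_site = stats.binom.sf(support - 1, n, epsilon / 3.0)
    return float(2 * n_diag_sites * per_site)


def detect_chimeric_genes(
    evidence: Iterable[ChimeraEvidence],
    min_support: int = 3,
    gene_lengths: Mapping[str, int] | None = None,
    alpha: float = 1e-3,
    diag_site_counts: Mapping[str, int] | None = None,
    child_depths: Mapping[str, float] | None = None,
    epsilon: float = 0.03,
) -> list[ChimeraReport]:
    """Aggregate per-read evidence into per-gene chimera reports.

    A gene is a candidate when >= ``min_support`` single-switch reads of the
    same orientation have mutually intersecting breakpoint intervals; the
    consensus breakpoint is their intersection.  When gene context is
    provided the clique must additionally be larger than sequencing error can
    plausibly produce: with ``gene_lengths``, accidentally overlapping error
    intervals are priced in (:func:`_clique_pvalue`); with
    ``diag_site_counts`` and ``child_depths`` as well, recurrent miscalls at
    a single site are priced in (:func:`_recurrence_pvalue`).  The summed
    error probability must fall below ``alpha``.  Genes with any evidence but
    insufficient agreement are reported with status "none".
    """
    by_gene: dict[str, dict[tuple[int, int], list[tuple[int, int]]]] = {}
    for ev in evidence:
        by_gene.setdefault(ev.gene_id, {}).setdefault(ev.orientation, []).append(
            ev.breakpoint_interval
        )
    reports = []
    for gene_id in sorted(by_gene):
        best = (0, None, None)  # (support, consensus, orientation)
        best_pv = 0.0
        for orientation in sorted(by_gene[gene_id]):
            intervals = by_gene[gene_id][orientation]
            n, consensus = _best_clique(intervals)
            if n > best[0]:
                best = (n, consensus, orientation)
                pv = 0.0
                if gene_lengths is not None:
                    mean_width = sum(b - a for a, b in intervals) / len(intervals)
                    pv += _clique_pvalue(
                        len(intervals), n, mean_width, gene_lengths[gene_id]
                    )
                if diag_site_counts is not None and child_depths is not None:
                    pv += _recurrence_pvalue(
                        n,
                        diag_site_counts.get(gene_id, 0),
                        child_depths.get(gene_id, 0.0),
                        epsilon,
                    )
                best_pv = pv
        support, consensus, orientation = best
        significant = (
            gene_lengths is None and diag_site_counts is None
        ) or best_pv < alpha
        if support >= min_support and consensus is not None and significant:
            reports.append(
                ChimeraReport(gene_id, support, consensus, orientation, STATUS_CANDIDATE)
            )
        else:
            reports.append(ChimeraReport(gene_id, support, None, orientation, STATUS_NONE))
    return reports


def chimera_table(reports: Sequence[ChimeraReport]) -> pd.DataFrame:
    """Candidate genes as an output table (non-candidates omitted)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "supporting_reads": r.supporting_reads,
            "breakpoint_lo": r.consensus_breakpoint[0],
            "breakpoint_hi": r.consensus_breakpoint[1],
            "orientation": f"parent{r.orientation[0]}->parent{r.orientation[1]}",
        }
        for r in reports
        if r.status == STATUS_CANDIDATE
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "supporting_reads", "breakpoint_lo", "breakpoint_hi", "orientation"],
    )
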