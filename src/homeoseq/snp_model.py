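"""Coverage-conditioned binomial SNP model with dynamic masking.

The question at every nucleotide position is whether an observed alternate
base is a genuine allele or an accumulation of sequencing errors.  With a
per-base error rate epsilon, the chance that any one read shows one *specific*
wrong base is epsilon/3 (uniform miscall spectrum).  Under the error-only null
the count k of a specific base among n covering reads is Binomial(n,
epsilon/3), so the evidence that the base is real is the upper tail
P(X >= k).  A base is called an allele when that tail probability falls below
a significance level alpha.

Because the tail can never be small when n is small, there is a minimum
coverage N_min below which even a unanimous alternate base cannot reach
significance; such positions are *masked* (declared uninformative).  Coverage
varies along a gene, so masking is per-position ("dynamic"): typically only
small regions of a gene are lost.

Per organism and position the model yields an allele set (up to the declared
ploidy) or a masked flag.  Across organisms a site becomes *diagnostic* when
an allele is confidently present in exactly one parent — reads carrying it can
be assigned to that parent's homeolog — and a child allele absent from every
parent allele set is a *novel* SNP, i.e. variation that arose after the genome
merger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_model import BASES, ProtocolTable
from .pileup import GenePileup, pool_columns


@dataclass(frozen=True)
class SnpModelParams:
    """Error model parameters.

    epsilon
        Per-base sequencing error probability (any miscall), default 0.03.
    alpha
        Significance level per site-allele tail test, default 1e-3.

    The probability of one *specific* wrong base is ``epsilon / 3``.
    The defaults give a minimum confident coverage of 2 reads, which keeps
    low-coverage positions masked rather than miscalled.
    """

    epsilon: float = 0.03
    alpha: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def per_base_error(self) -> float:
        return self.epsilon / 3.0


def allele_pvalue(k: int, n: int, params: SnpModelParams) -> float:
    """Upper-tail probability P(X >= k), X ~ Binomial(n, epsilon/3).

    The chance that at least ``k`` of ``n`` covering reads show one specific
    base through sequencing error alone.  Returns 1.0 for k = 0.
    """
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, params.per_base_error))


def min_confident_coverage(params: SnpModelParams) -> int:
    """Smallest coverage at which a unanimous alternate base is significant.

    N_min = min { n : (epsilon/3)^n < alpha }; positions with coverage below
    this are masked because no observation pattern can reach significance.
    """
    p = params.per_base_error
    n = max(1, math.floor(math.log(params.alpha) / math.log(p)) + 1)
    # guard against floating-point edge cases of the closed form
    while p**n >= params.alpha:
        n += 1
    while n > 1 and p ** (n - 1) < params.alpha:
        n -= 1
    return n


def _rank_by_count(counts: np.ndarray, significant: np.ndarray) -> np.ndarray:
    """Rank bases (0 = most frequent) among significant ones, ties A<C<G<T."""
    key = np.where(significant, counts, -1)
    order = np.argsort(-key, axis=-1, kind="stable")
    rank = np.empty_like(order)
    np.put_along_axis(
        rank, order, np.broadcast_to(np.arange(4), order.shape).copy(), axis=-1
    )
    return rank


def call_organism_columns(
    counts: np.ndarray, ploidy: int, params: SnpModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised allele calls for one organism over all positions of a gene.

    Parameters
    ----------
    counts : (L, 4) int array of pooled base counts.
    ploidy : maximum number of alleles this organism may carry (1 or 2 for
        parents; the child is capped by the sum of parent ploidies).

    Returns
    -------
    allele : (L, 4) bool — allele membership per base.
    masked : (L,) bool — True where coverage < N_min or no base reaches
        significance.  Masked positions have empty allele sets.
    """
    counts = np.asarray(counts)
    cov = counts.sum(axis=-1)
    pvals = stats.binom.sf(counts - 1, cov[..., None], params.per_base_error)
    significant = (counts > 0) & (pvals < params.alpha)
    rank = _rank_by_count(counts, significant)
    allele = significant & (rank < ploidy)
    masked = (cov < min_confident_coverage(params)) | ~significant.any(axis=-1)
    allele[masked] = False
    return allele, masked


def call_organism_site(
    counts: Mapping[str, int] | np.ndarray, ploidy: int, params: SnpModelParams
) -> tuple[frozenset[str], bool]:
    """Allele call at a single position: (allele_set, masked).

    ``counts`` maps base -> count (missing bases count 0) or is a length-4
    array in A,C,G,T order.  The allele set is the up-to-``ploidy`` most
    frequent bases whose tail probability is below alpha; the position is
    masked when coverage < N_min or no base is significant.
    """
    if isinstance(counts, Mapping):
        arr = np.array([counts.get(b, 0) for b in BASES], dtype=np.int64)
    else:
        arr = np.asarray(counts, dtype=np.int64)
    allele, masked = call_organism_columns(arr[None, :], ploidy, params)
    alleles = frozenset(BASES[i] for i in np.nonzero(allele[0])[0])
    return alleles, bool(masked[0])


@dataclass(frozen=True)
class OrganismCall:
    allele_set: frozenset[str]
    masked: bool
    coverage: int


@dataclass(frozen=True)
class SiteCall:
    """Per-position verdict across all organisms.

    ``diagnostic_alleles`` maps a base to the single parent carrying it; it is
    only populated when every parent is unmasked at the site.
    ``novel_alleles`` are bases confidently present in the child but absent
    from every parent allele set (again requiring all organisms unmasked).
    """

    gene_id: str
    position: int
    organisms: Mapping[str, OrganismCall]
    diagnostic_alleles: Mapping[str, int]
    novel_alleles: frozenset[str]


class GeneSiteCalls:
    """All site calls of one gene in array form (one row per position).

    Attributes
    ----------
    allele, masked, coverage : dict organism -> arrays ((L,4) bool, (L,) bool,
        (L,) int).
    informative : (L,) bool — all parents unmasked; diagnostic status is
        defined only at informative positions.
    diag_parent : (L, 4) int16 — parent index whose allele set uniquely holds
        the base, 0 otherwise; nonzero only at informative positions.
    novel : (L, 4) bool — confident child alleles absent from every parent
        allele set, at positions where all organisms are unmasked.
    """

    def __init__(
        self,
        gene_id: str,
        n_parents: int,
        allele: dict[str, np.ndarray],
        masked: dict[str, np.ndarray],
        coverage: dict[str, np.ndarray],
    ) -> None:
        self.gene_id = gene_id
        self.n_parents = n_parents
        self.allele = allele
        self.masked = masked
        self.coverage = coverage
        self.length = next(iter(masked.values())).shape[0]

        parent_allele = np.stack(
            [allele[f"parent{k}"] for k in range(1, n_parents + 1)]
        )  # (P, L, 4)
        parent_masked = np.stack(
            [masked[f"parent{k}"] for k in range(1, n_parents + 1)]
        )  # (P, L)
        self.informative = ~parent_masked.any(axis=0)

        membership = parent_allele.sum(axis=0)  # (L, 4) number of parents with base
        unique = membership == 1
        owner = parent_allele.argmax(axis=0).astype(np.int16) + 1
        self.diag_parent = np.where(unique & self.informative[:, None], owner, 0).astype(
            np.int16
        )

        any_parent = parent_allele.any(axis=0)
        child_ok = self.informative & ~masked["child"]
        self.novel = allele["child"] & ~any_parent & child_ok[:, None]

    def diagnostic_positions(self) -> np.ndarray:
        """Strictly increasing positions carrying >= 1 diagnostic allele."""
        return np.nonzero((self.diag_parent > 0).any(axis=1))[0]

    def site(self, position: int) -> SiteCall:
        """Scalar :class:`SiteCall` view of one position."""
        organisms = {
            org: OrganismCall(
                allele_set=frozenset(
                    BASES[i] for i in np.nonzero(self.allele[org][position])[0]
                ),
                masked=bool(self.masked[org][position]),
                coverage=int(self.coverage[org][position]),
            )
            for org in self.allele
        }
        diag = {
            BASES[i]: int(self.diag_parent[position, i])
            for i in range(4)
            if self.diag_parent[position, i] > 0
        }
        novel = frozenset(BASES[i] for i in np.nonzero(self.novel[position])[0])
        return SiteCall(self.gene_id, position, organisms, diag, novel)


def call_gene_sites(
    pileup: GenePileup,
    protocol: ProtocolTable,
    params: SnpModelParams,
    include_gdna: bool = True,
) -> GeneSiteCalls:
    """Call every position of a gene for every organism.

    Parent pools combine mRNA replicates (and gDNA when ``include_gdna``);
    the child pool combines child mRNA replicates (plus child gDNA when
    present and enabled).  The child allele cap is the sum of parent ploidies.
    """
    allele: dict[str, np.ndarray] = {}
    masked: dict[str, np.ndarray] = {}
    coverage: dict[str, np.ndarray] = {}
    child_cap = sum(protocol.ploidy.values())
    for org in protocol.organisms():
        pooled = pool_columns(pileup, protocol, org, include_gdna=include_gdna)
        k = child_cap if org == "child" else protocol.ploidy[int(org.removeprefix("parent"))]
        a, m = call_organism_columns(pooled, k, params)
        allele[org], masked[org], coverage[org] = a, m, pooled.sum(axis=1)
    return GeneSiteCalls(pileup.gene_id, protocol.n_parents, allele, masked, coverage)


def call_site(
    counts_by_organism: Mapping[str, Mapping[str, int] | np.ndarray],
    protocol: ProtocolTable,
    params: SnpModelParams,
    gene_id: str = "gene",
    position: int = 0,
) -> SiteCall:
    """Single-position site call from pooled per-organism counts.

    Convenience scalar form of :func:`call_gene_sites` with the same
    diagnostic and novel-allele semantics.
    """
    allele: dict[str, np.ndarray] = {}
    masked: dict[str, np.ndarray] = {}
    coverage: dict[str, np.ndarray] = {}
    child_cap = sum(protocol.ploidy.values())
    for org in protocol.organisms():
        counts = counts_by_organism.get(org, {})
        if isinstance(counts, Mapping):
            arr = np.array([counts.get(b, 0) for b in BASES], dtype=np.int64)
        else:
            arr = np.asarray(counts, dtype=np.int64)
        k = protocol.ploidy[int(org.removeprefix("parent"))] if org != "child" else child_cap
        a, m = call_organism_columns(arr[None, :], k, params)
        allele[org], masked[org], coverage[org] = a, m, arr.sum()[None]
    calls = GeneSiteCalls(gene_id, protocol.n_parents, allele, masked, coverage)
    site = calls.site(0)
    return SiteCall(
        gene_id, position, site.organisms, site.diagnostic_alleles, site.novel_alleles
    )


def diagnostic_sites(sites: GeneSiteCalls | Sequence[SiteCall]) -> list[int]:
    """Ordered positions with a non-empty diagnostic allele map."""
    if isinstance(sites, GeneSiteCalls):
        return [int(p) for p in sites.diagnostic_positions()]
    return sorted(s.position for s in sites if s.diagnostic_alleles)
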