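# Methods

This note documents the models and procedures implemented in `homeoseq`, the
choices made where the design was genuinely open, and what validation on the
bundled simulator does and does not establish.

## Problem setting

A hybrid or allopolyploid carries one homeolog of every gene per parent
lineage. Given mRNA reads from the child and from each parent, all mapped to
one gene reference (typically from a related species), the task is to count,
per gene and child replicate, how many reads derive from each parental
homeolog. The information carriers are *diagnostic SNPs*: positions where
exactly one parent confidently carries a particular allele.

All coordinates are 0-based half-open; SAM input is converted on parsing.
Only primary alignments with mapping quality ≥ `min_mapq` (default 20) are
used. Read bases recorded as N and insertion bases contribute no
observations; paired mates count as independent reads.

## Error model and allele calls

With a uniform per-base miscall rate ε and a uniform miscall spectrum, a
specific wrong base appears in any read with probability ε/3. At a position
with pooled coverage *n*, the count of a specific base under the error-only
null is Binomial(n, ε/3); base *b* observed *k* times is *significant* when
the upper tail P(X ≥ k) < α. Defaults: ε = 0.03, α = 10⁻³ per site-allele
test, both tunable. ε is global — no per-read base-quality weighting — which
keeps every call exactly reproducible and matches the coverage-conditioned
binomial formulation; recalibrated qualities would demand a different model.

An organism's allele set at a position is the up-to-*ploidy* most frequent
significant bases (ties broken in fixed order A<C<G<T). The position is
**masked** for that organism when coverage is below
N_min = min{n : (ε/3)ⁿ < α} (N_min = 2 at the defaults) or when no base is
significant. Masking is per position ("dynamic"): coverage varies along a
gene, and typically only small regions are lost.

Diploid parents may carry two alleles; each must pass the same tail test
independently. No allele-balance test is applied (a markedly unbalanced
heterozygote still passes if both alleles are individually significant).
The child's allele cap is the sum of the parent ploidies.

A subtlety worth recording: masking is *not* monotone in total coverage.
Adding observations of an existing allele can only help it (P(X ≥ k+1 | n+1)
≤ P(X ≥ k | n)), but adding counts of *other* bases can dilute a borderline
allele below significance — e.g. {A:2} is callable at the defaults while
{A:2, C:2, G:2, T:1} masks. The per-allele monotone form is the one tested.

## Diagnostic and novel sites

Diagnostic status is computed only at positions where **every** parent is
unmasked, preventing ancestry calls from one-sided evidence; a base in
exactly one parent's allele set is diagnostic for that parent. Novel
(post-merger) alleles are child alleles absent from every parent's allele
set, likewise computed only when all parents and the child are unmasked —
with a masked parent, "absent from every parent" would be vacuous.

Replicates of an organism are pooled for site calling (boosting coverage),
as are gDNA samples unless disabled; gDNA never enters expression counts,
which are per mRNA replicate. gDNA pooling is equal-weight with mRNA.

## Read classification

For each child mRNA read, every base at a diagnostic site matching a
parent's diagnostic allele is one vote for that parent.

* votes for exactly one parent → assigned to that parent's homeolog;
* no votes but ≥ 1 overlap with a fully-called (all-parents-unmasked) site →
  **multi-parent** (consistent with several parents; more data cannot help);
* only masked/uncalled positions overlapped → **unknown** (more data could
  rescue it);
* votes for ≥ 2 parents → multi-parent with a **conflict flag** — conflicts
  are evidence for chimeric transcripts, not for either homeolog, so they
  never inflate parent counts.

The vote threshold is a single diagnostic allele. A read base matching a
confirmed novel allele (confirmed in the pooled child pileup, never from the
single read alone) sets the read's new-SNP flag. Category counts sum exactly
to the mapped child reads of each gene and sample.

## Chimera detection (experimental)

A conflicted read whose votes form exactly two position-ordered runs —
parent *a* then parent *b* — is single-switch evidence for a recombination
between the homeologs, with breakpoint in the open interval between the
runs; reads with ≥ 3 runs are discarded as artifacts. A gene is a candidate
when at least `min_support` (default 3) single-switch reads agree in
orientation and their intervals share a common point; the consensus
breakpoint is the intersection of that clique.

Support counts alone are not sufficient at depth: sequencing miscalls at
diagnostic sites generate a steady trickle of single-switch reads, and (a) a
few of their intervals can overlap by chance, while (b) several reads
miscalled at the *same* site yield identical intervals — an automatic
clique. When the caller has gene context (always, inside the pipeline) the
clique must therefore also be statistically inconsistent with the error
model: a union-bound p-value for an accidental interval clique plus a
per-site recurrence bound, Binomial(per-homeolog depth, ε/3) over the gene's
diagnostic sites and both orientations, summed and required below α. On the
simulator this holds the false-candidate rate at 0/200 genes across seeds
while detecting ≥ 90% of true chimeras at 50× — the misses being genes with
no diagnostic-site pair flanking the junction within one read length, which
are undetectable from single reads in principle. Chimera output never alters
expression tables.

## Pipeline contracts

Each gene is analysed independently: pileup → site calls → read
classification → optional chimera evidence → tallies. Per-gene results are
written as small JSON artifacts plus a manifest (checkpoint every
`checkpoint_every` genes, default 50); a run resumes from the manifest only
if a fingerprint over protocol, reference and parameters matches, refusing
silent parameter drift. Final tables are assembled from the artifacts in
lexicographic gene order and written atomically, with fixed sort orders and
no timestamps in data rows — so interrupt+resume, gene-order permutation and
plain reruns are byte-identical, which is also the contract that licenses
parallel execution. Alignments are bucketed per gene in one pass per SAM
file; at desk scale this bucket lives in memory, the per-gene artifacts
being the streaming-friendly part.

FASTQ samples are mapped by substituting `{ref}`, `{fastq}`, `{out}` into a
command template (default `minimap2 -ax sr`); any mapper producing SAM can
be substituted, and the executable is resolved before gene processing
begins.

## The simulator

`simdata` emulates the canonical validation design: parent 1's transcript
sequences are uniform random; each further parent lineage substitutes each
site with probability *d* (uniform among the three alternatives, no
indels — the caller is substitution-only); diploid parents add heterozygous
sites at rate *h*, and the child inherits one haplotype per parent lineage.
Reads of length 100 (default) start uniformly along each transcript with
uniform per-base miscalls at rate ε_sim; per-copy read counts are Poisson
with mean coverage·L/read_length. "Coverage" is per sequence copy — per
homeolog for the child, per haplotype for parents. Novel substitutions are
planted at rate `novel_rate` on one random homeolog copy at sites where all
parental haplotypes agree; chimeric genes replace the child's parent-1 copy
by a parent-1/parent-2 fusion with a uniform junction in the central 80% of
the gene. SAM mode emits the true placements, isolating the statistical
machinery from mapper behaviour; FASTQ mode exists for end-to-end runs with
a real mapper. All randomness flows from one mandatory seed; equal
parameters give byte-identical files.

Default parameters are the benchmark study conditions: 200 genes × 1 kb,
two haploid parents, d = 0.05, 50× per-homeolog coverage, ε_sim = 0.01.
The low-coverage scenario uses ~15 reads per gene (d = 0.06); the chimera
scenario 20 genes, all chimeric, at benchmark depth. These sizes keep the
full validation in the minutes range on one CPU.

What the simulator does not emulate — and what passing therefore does not
show about real data: mapping ambiguity and reference bias (true placements
are emitted), indels and structural variation, instrument-specific or
position-dependent error profiles, base-quality information, paired-end
fragment structure, and expression-level heterogeneity beyond Poisson
sampling. Results on simulated data validate the statistical model and the
classifier, not the mapper or library chemistry.

## Known limitations

* No probabilistic/fractional read assignment; categories are hard.
* No multiple-testing correction across sites by default; α is per
  site-allele test, with masking already suppressing the error-prone
  low-coverage regime.
* Chimera breakpoints are intervals between diagnostic sites, never refined
  to base pairs; multi-breakpoint conversions are out of scope.
* The whole-run read store is in memory; very large experiments would need
  the per-gene bucketing moved to disk.
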