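"""The coverage-conditioned binomial error model, by hand.

Shows how the probability that repeated observations of one base are pure
sequencing error depends on coverage, and where the dynamic-masking
threshold comes from.
"""

import homeoseq as hs

params = hs.SnpModelParams(epsilon=0.03, alpha=1e-3)
print(f"epsilon = {params.epsilon} (per-base error), "
      f"specific wrong base = epsilon/3 = {params.per_base_error}")
print(f"alpha = {params.alpha}\n")

for k, n in [(1, 1), (2, 2), (2, 10), (3, 50), (10, 50)]:
    pv = hs.allele_pvalue(k, n, params)
    verdict = "allele" if pv < params.alpha else "could be error"
    print(f"{k:>3} of {n:>3} reads show the base: P(error alone) = {pv:.3e}  -> {verdict}")

nmin = hs.min_confident_coverage(params)
print(f"\nminimum confident coverage N_min = {nmin}: below this, even a")
print("unanimous alternate base cannot reach significance, so the position")
print("is masked (declared uninformative) rather than miscalled.\n")

for counts, ploidy in [({"A": 20}, 1), ({"A": 1}, 1), ({"A": 10, "G": 12}, 2),
                       ({"A": 10, "G": 12}, 1), ({"A": 99, "G": 1}, 2)]:
    alleles, masked = hs.call_organism_site(counts, ploidy, params)
    state = "masked" if masked else f"alleles {sorted(alleles)}"
    print(f"counts {counts} (ploidy {ploidy}): {state}")
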