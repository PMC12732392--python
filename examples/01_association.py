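"""Single-variant case-control association from pre-counted genotypes.

Uses the published genotype counts for the ETS2 enhancer variant
rs2836882 in an SLE case-control cohort (246 cases / 216 controls) and
reproduces the dominant-model analysis: Hardy-Weinberg checks in each
arm, the carrier odds ratio with its Woolf 95% confidence interval, and
a goodness-of-fit against gnomAD non-Finnish European genotype
frequencies.
"""

from lupusgrs import (
    GenotypeCounts,
    dominant_association,
    genotype_percentages,
    hwe_test,
    reference_gof,
)

cases = GenotypeCounts(n_hom_ref=109, n_het=111, n_hom_alt=26)
controls = GenotypeCounts(n_hom_ref=119, n_het=82, n_hom_alt=15)
gnomad_nfe = (0.533, 0.394, 0.073)  # GG, GA, AA proportions

print("genotype percentages (GG / GA / AA):")
print("  SLE     :", "%.1f / %.1f / %.1f" % genotype_percentages(cases))
print("  controls:", "%.1f / %.1f / %.1f" % genotype_percentages(controls))

for arm, counts in (("SLE", cases), ("controls", controls)):
    hwe = hwe_test(counts)
    print(f"HWE {arm}: chi2 = {hwe.chi2:.3f}, p = {hwe.p:.2f} "
          f"(> 0.05, consistent with Hardy-Weinberg proportions)")

assoc = dominant_association(cases, controls)
print(f"dominant model (GG vs GA+AA): OR = {assoc.or_estimate:.2f} "
      f"(95% CI {assoc.ci_low:.2f}-{assoc.ci_high:.2f}), "
      f"chi2 = {assoc.chi2:.2f}, p = {assoc.p:.3f}")
print("  -> risk-allele carriers have ~1.5-fold higher odds of disease")

gof = reference_gof(cases, gnomad_nfe)  # carrier-collapsed, 1 df
print(f"case genotypes vs gnomAD NFE (carrier-collapsed): "
      f"chi2 = {gof.chi2:.2f}, p = {gof.p:.4f}")
print("  -> the case genotype distribution also differs from the reference population")
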