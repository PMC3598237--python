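"""Translate standardized per-allele effects into natural units, variance
explained, and approximate detection power.

Uses the published within-pair effect sizes and the all-participant trait
SDs: beta (s.d. units) x SD (mg/dl) is the per-allele effect in mg/dl, and
Va = 2pq*beta^2 is the share of a unit-variance trait the locus explains.
"""

import sibassoc.reference as ref
from sibassoc import additive_variance, approx_power, to_natural_units

print(f"{'gene':6} {'trait':5} {'maf':>5} {'beta(sd)':>8} "
      f"{'mg/dl':>7} {'Va=2pq*b^2':>10} {'power(n=6356)':>13}")
for snp in ref.SNP_PANEL:
    if not snp["replicated"]:
        continue
    trait = snp["primary_trait"]
    sd = ref.TRAIT_SCALE_MGDL[trait][1]
    natural = to_natural_units(snp["beta_sd"], sd)
    va, pve = additive_variance(snp["maf"], snp["beta_sd"])
    power = approx_power(pve, 2 * ref.N_PAIRS, alpha=0.05)
    print(f"{snp['gene']:6} {trait:5} {snp['maf']:5.2f} {snp['beta_sd']:8.2f} "
          f"{natural:7.2f} {va:10.4f} {power:13.3f}")

print("\nThe largest locus effect (APOA5 on triglycerides) moves the trait "
      "12.4 mg/dl per\nminor allele yet explains only ~1% of its variance — "
      "the usual GWAS picture.")
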