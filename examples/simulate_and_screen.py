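"""Simulate a sib-pair cohort and run the full association screen.

Generates 800 sibling pairs under the default study-like design (seven lipid
SNPs with their published allele frequencies and effect sizes), runs QC and
the between/within mixed-model screen, and prints the primary-trait results.
The `beta (lo, hi)` column is the within-pair per-minor-allele effect on the
standardized trait with its 95% CI; `mg/dl` is the same effect on the raw
scale; `pve` is the share of trait variance the locus explains (2pq*beta^2).
"""

from sibassoc import RunConfig, SimulationConfig, run_screen, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_pairs=800, seed=42))
result = run_screen(cohort, RunConfig())

print(f"pairs analysed: {cohort.n_pairs}  individuals: {cohort.n_individuals}")
print(f"SNPs excluded by QC: {result.excluded_snps or 'none'}")
thr, rendered = result.thresholds["secondary"]
print(f"secondary-screen Bonferroni threshold: {thr:.5f} (rendered {rendered})\n")

print(f"{'gene':6} {'snp':11} {'trait':5} {'beta (95% CI)':24} "
      f"{'p':>9} {'mg/dl':>6} {'pve':>7}")
for row in result.assoc_rows:
    if not row["is_primary"]:
        continue
    ci = f"{row['beta_sd']:.2f} ({row['ci_low']:.2f}, {row['ci_high']:.2f})"
    print(f"{row['gene']:6} {row['snp']:11} {row['trait']:5} {ci:24} "
          f"{row['p']:9.2g} {row['beta_natural_units']:6.1f} {row['pve']:7.4f}")

print("\nA within-pair beta is estimated purely from genotype contrasts "
      "between siblings,\nso it is immune to population-substructure "
      "confounding that inflates naive scans.")
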