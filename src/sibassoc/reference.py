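"""Published summary values from the Indian Migration Study (IMS) lipid-variant screen.

The IMS recruited 3,178 full sib pairs (one urban factory-worker migrant plus
one sibling still resident in the rural place of origin) across four Indian
cities and genotyped candidate SNPs at lipid loci established by European
GWAS.  The raw data are not public; the constants below are the study's
*printed* summary numbers.  They serve two roles in this package:

1. defaults for the synthetic cohort generator, so simulated cohorts match
   the study's design (sample size, allele frequencies, trait scales,
   effect sizes);
2. inputs to the deterministic worked-example arithmetic (natural-unit
   effect conversion, variance explained, permutation-count p-values).

They are inputs to computation, never outputs.
"""

from __future__ import annotations

N_PAIRS = 3178
"""Complete sib pairs entering association analysis (2 * 3178 = 6356 people)."""

CITIES = ("Lucknow", "Nagpur", "Bangalore", "Hyderabad")

RURAL_FRACTION = 2324 / 6356
"""Fraction of analysed individuals resident in a rural location."""

MALE_FRACTION = 0.576

AGE_MEAN, AGE_SD = 40.8, 10.3

# All-participant trait scales in mg/dl: {trait: (mean, sd)}.
TRAIT_SCALE_MGDL = {
    "tg": (134.1, 69.1),
    "tc": (183.2, 45.1),
    "hdl": (43.5, 9.5),
    "ldl": (113.2, 52.4),
}

HYPERTENSION_PREVALENCE = 0.181

# Candidate panel passing QC: seven biallelic SNPs at distinct lipid loci.
# maf = minor allele frequency in the study sample; beta_sd = within sib-pair
# per-minor-allele effect on the standardized *primary* trait; replicated =
# whether the primary-trait association reached significance in the screen.
# secondary_betas holds the additional standardized effects quoted for the
# locus (used by the natural-unit worked examples).
SNP_PANEL = [
    {"gene": "APOA5", "snp": "rs662799", "chrom": 11, "pos": 116792991,
     "minor": "G", "major": "A", "maf": 0.19, "primary_trait": "tg",
     "beta_sd": 0.18, "replicated": True, "secondary_betas": {}},
    {"gene": "APOB", "snp": "rs562338", "chrom": 2, "pos": 21011755,
     "minor": "A", "major": "G", "maf": 0.13, "primary_trait": "ldl",
     "beta_sd": -0.09, "replicated": True, "secondary_betas": {}},
    {"gene": "CETP", "snp": "rs1864163", "chrom": 16, "pos": 56962376,
     "minor": "A", "major": "G", "maf": 0.20, "primary_trait": "hdl",
     "beta_sd": -0.01, "replicated": False, "secondary_betas": {}},
    {"gene": "GCKR", "snp": "rs780094", "chrom": 2, "pos": 27518370,
     "minor": "T", "major": "C", "maf": 0.21, "primary_trait": "tg",
     "beta_sd": 0.11, "replicated": True,
     "secondary_betas": {"tc": 0.11}},
    {"gene": "LDLR", "snp": "rs6511720", "chrom": 19, "pos": 11091630,
     "minor": "T", "major": "G", "maf": 0.07, "primary_trait": "ldl",
     "beta_sd": -0.06, "replicated": False, "secondary_betas": {}},
    {"gene": "LIPC", "snp": "rs4775041", "chrom": 15, "pos": 58380000,
     "minor": "C", "major": "G", "maf": 0.21, "primary_trait": "hdl",
     "beta_sd": 0.08, "replicated": True, "secondary_betas": {}},
    {"gene": "LPL", "snp": "rs10503669", "chrom": 8, "pos": 19962213,
     "minor": "A", "major": "C", "maf": 0.12, "primary_trait": "tg",
     "beta_sd": -0.18, "replicated": True,
     "secondary_betas": {"tc": -0.09}},
]

# LD-difference permutation summary (HapMap CEU vs GIH windows around each
# locus): {gene: (n_snps_in_window, n_perm_greater, n_perm_lower)} out of
# 100,000 label permutations.  greater + lower sums to 100,001 for the
# internally consistent rows because the observed statistic is counted in
# one tail (add-one convention).
LD_PERMUTATION_COUNTS = {
    "APOA5": (25, 4302, 95699),
    "APOB": (14, 26258, 73743),
    "CETP": (30, 23107, 76894),
    "GCKR": (13, 27258, 72743),
    "LDLR": (6, 17146, 82855),
    "LIPC": (40, 41804, 58917),
    "LPL": (36, 36613, 63388),
}

N_LD_PERMUTATIONS = 100_000

BONFERRONI_SECONDARY_TESTS = 21
"""Secondary lipid-trait screen: 7 SNPs x 3 non-primary lipid traits."""
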