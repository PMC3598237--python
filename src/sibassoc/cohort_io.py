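"""On-disk formats and the in-memory sib-pair cohort container.

Genotypes travel as PLINK-style text PED/MAP (whitespace-delimited, missing
allele ``0``, 4-column MAP); phenotypes and covariates as a tab-separated
table that carries the pair id explicitly, because the study design recruits
sibling pairs without parents so sibships cannot be inferred from PED
parental columns.  All analysis code works on :class:`SibPairCohort`, which
holds minor-allele dosages (0/1/2, NaN for missing), per-individual traits
in mg/dl plus standardized z-scores, and the covariate roster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("sibassoc")

#: trait columns carried in mg/dl (lipids) or mmHg (pressures)
TRAIT_COLUMNS = ("tg", "tc", "hdl", "ldl", "sbp", "dbp")

COVARIATE_COLUMNS = ("age", "sex", "location", "city", "fat_intake")


@dataclass(frozen=True)
class SnpMeta:
    """Marker metadata; ``maf`` is the minor-allele frequency q (q <= 0.5)."""

    snp: str
    chrom: int
    pos: int
    minor: str
    major: str
    maf: float
    gene: str = ""

    def __post_init__(self) -> None:
        if self.minor == self.major:
            raise ValueError(f"{self.snp}: alleles must be distinct")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp}: maf {self.maf} outside [0, 0.5]")


@dataclass
class SibPairCohort:
    """Individuals grouped into sibling pairs.

    ``samples`` rows align 1:1 with ``genotypes`` rows; every retained
    individual belongs to exactly one pair of size 2 and pair members occupy
    adjacent rows (sib_order 1 then 2).
    """

    samples: pd.DataFrame
    genotypes: np.ndarray  # (n_individuals, n_snps), values {0,1,2,NaN}
    snps: list[SnpMeta]

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.samples)
        if self.genotypes.shape != (n, len(self.snps)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{n} samples x {len(self.snps)} SNPs"
            )
        counts = self.samples["pair_id"].value_counts()
        bad = counts[counts != 2]
        if len(bad):
            raise ValueError(f"pairs without exactly 2 members: {list(bad.index[:5])}")
        g = self.genotypes
        ok = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_pairs(self) -> int:
        return self.samples["pair_id"].nunique()

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp for s in self.snps]

    def snp_index(self, snp: str) -> int:
        for i, s in enumerate(self.snps):
            if s.snp == snp:
                return i
        raise KeyError(snp)

    def dosages(self, snp: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp)]

    def pair_rows(self) -> np.ndarray:
        """(n_pairs, 2) row indices, members of each pair side by side."""
        order = np.lexsort(
            (self.samples["sib_order"].to_numpy(), self.samples["pair_id"].to_numpy())
        )
        return order.reshape(-1, 2)

    def standardize_traits(self, traits: Iterable[str] = TRAIT_COLUMNS) -> None:
        """z-score each trait on all non-missing individuals (done once,
        before any stratification)."""
        for t in traits:
            if t not in self.samples.columns:
                continue
            x = self.samples[t].astype(float)
            self.samples[f"z_{t}"] = (x - x.mean()) / x.std(ddof=1)

    def subset_pairs(self, keep_pair_ids: Sequence) -> "SibPairCohort":
        mask = self.samples["pair_id"].isin(keep_pair_ids).to_numpy()
        return SibPairCohort(
            samples=self.samples.loc[mask].reset_index(drop=True),
            genotypes=self.genotypes[mask],
            snps=list(self.snps),
        )


# -- PED / MAP / phenotype table ------------------------------------------

_SEX_CODE = {"M": "1", "F": "2"}
_SEX_DECODE = {"1": "M", "2": "F", "0": "0"}


def write_cohort(cohort: SibPairCohort, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.ped``, ``<prefix>.map`` and ``<prefix>.pheno.tsv``."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    pheno_path = prefix.parent / (prefix.name + ".pheno.tsv")

    with open(map_path, "w") as fh:
        for s in cohort.snps:
            fh.write(f"{s.chrom}\t{s.snp}\t0\t{s.pos}\n")

    g = cohort.genotypes
    with open(ped_path, "w") as fh:
        for i, row in enumerate(cohort.samples.itertuples(index=False)):
            fields = [str(row.fid), str(row.iid), "0", "0",
                      _SEX_CODE.get(row.sex, "0"), "-9"]
            for j, s in enumerate(cohort.snps):
                d = g[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    k = int(d)
                    fields += [s.minor] * k + [s.major] * (2 - k)
            fh.write(" ".join(fields) + "\n")

    pheno_cols = ["fid", "iid", "pair_id", "sib_order", *COVARIATE_COLUMNS,
                  *[t for t in TRAIT_COLUMNS if t in cohort.samples.columns],
                  "hypertension"]
    pheno_cols = [c for c in dict.fromkeys(pheno_cols) if c in cohort.samples.columns]
    cohort.samples[pheno_cols].to_csv(pheno_path, sep="\t", index=False,
                                      float_format="%.10g")
    return ped_path, map_path, pheno_path


def _parse_ped(ped_path: Path, n_snps: int) -> tuple[list[tuple[str, str, str]], list[list[str]]]:
    ids, allele_rows = [], []
    want = 6 + 2 * n_snps
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != want:
                raise ValueError(
                    f"{ped_path} line {lineno}: expected {want} fields, got {len(tok)}"
                )
            ids.append((tok[0], tok[1], _SEX_DECODE.get(tok[4], "0")))
            allele_rows.append(tok[6:])
    return ids, allele_rows


def read_cohort(ped_path: str | Path, map_path: str | Path,
                pheno_path: str | Path,
                snp_meta: Sequence[SnpMeta] | None = None) -> SibPairCohort:
    """Read PED/MAP + phenotype TSV into a :class:`SibPairCohort`.

    Allele pairs are converted to minor-allele dosage, the minor allele
    being determined once on the full sample (ties broken alphabetically)
    and fixed for all analyses.  Individuals without a co-listed sibling are
    dropped with a logged count.  ``snp_meta`` may supply gene labels /
    allele designations to use instead of the data-derived ones.
    """
    ped_path, map_path, pheno_path = Path(ped_path), Path(map_path), Path(pheno_path)
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp", "cm", "pos"])
    n_snps = len(mp)
    ids, allele_rows = _parse_ped(ped_path, n_snps)

    pheno = pd.read_csv(pheno_path, sep="\t")
    ped_iids = [iid for _, iid, _ in ids]
    orphans_ped = sorted(set(ped_iids) - set(pheno["iid"].astype(str)))
    orphans_ph = sorted(set(pheno["iid"].astype(str)) - set(ped_iids))
    if orphans_ped or orphans_ph:
        raise ValueError(
            "phenotype/genotype id mismatch; orphan ids: "
            f"ped-only={orphans_ped[:10]} pheno-only={orphans_ph[:10]}"
        )

    # per-SNP allele counts -> minor allele on the full sample
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), n_snps, 2)
    snps: list[SnpMeta] = []
    dosage = np.full((len(ids), n_snps), np.nan)
    meta_by_id = {m.snp: m for m in (snp_meta or [])}
    for j in range(n_snps):
        col = alleles[:, j, :]
        flat = col.ravel()
        seen = pd.Series(flat[flat != "0"]).value_counts()
        if len(seen) == 0:
            minor, major, maf = "0", "N", 0.0
        elif len(seen) == 1:
            minor, major, maf = "0", str(seen.index[0]), 0.0
        else:
            # least frequent allele is minor; alphabetical tie-break
            pair = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
            minor, major = str(pair[0][0]), str(pair[-1][0])
            maf = seen[minor] / seen.sum()
        prior = meta_by_id.get(str(mp.loc[j, "snp"]))
        if prior is not None and len(seen) > 1:
            minor, major = prior.minor, prior.major
            maf = float(seen.get(minor, 0)) / seen.sum()
        missing = (col == "0").any(axis=1)
        dosage[:, j] = (col == minor).sum(axis=1).astype(float)
        dosage[missing, j] = np.nan
        snps.append(SnpMeta(snp=str(mp.loc[j, "snp"]), chrom=int(mp.loc[j, "chrom"]),
                            pos=int(mp.loc[j, "pos"]), minor=minor, major=major,
                            maf=min(maf, 1 - maf) if maf else maf,
                            gene=prior.gene if prior else ""))

    samples = pheno.copy()
    samples["iid"] = samples["iid"].astype(str)
    samples["fid"] = samples["fid"].astype(str)
    order = {iid: i for i, (_, iid, _) in enumerate(ids)}
    samples = samples.sort_values("iid", key=lambda s: s.map(order), kind="stable")
    dosage = dosage[[order[i] for i in samples["iid"]]]

    # drop individuals lacking a co-listed sibling
    counts = samples["pair_id"].value_counts()
    whole = counts[counts == 2].index
    keep = samples["pair_id"].isin(whole).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d individual(s) without a co-listed sibling", dropped)
    samples = samples.loc[keep].reset_index(drop=True)
    dosage = dosage[keep]
    if "sib_order" not in samples.columns:
        samples["sib_order"] = samples.groupby("pair_id").cumcount() + 1

    cohort = SibPairCohort(samples=samples, genotypes=dosage, snps=snps)
    cohort.standardize_traits()
    return cohort


# -- result tables ----------------------------------------------------------

ASSOC_COLUMNS = ["gene", "snp", "maf", "trait", "beta_sd", "ci_low", "ci_high",
                 "p", "n_pairs", "beta_ci", "beta_natural_units", "va", "pve"]


def write_assoc_table(rows: Iterable[dict], path: str | Path) -> Path:
    """One row per SNP-trait fit, numbers at fixed precision.

    ``beta_ci`` renders the headline "beta (lo, hi)" string at two decimals,
    e.g. ``0.18 (0.11, 0.25)``; raw columns keep six significant digits.
    """
    path = Path(path)
    recs = []
    for r in rows:
        rec = {c: r.get(c, "") for c in ASSOC_COLUMNS}
        rec["beta_ci"] = (
            f"{r['beta_sd']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f})"
            if r.get("beta_sd") is not None else ""
        )
        recs.append(rec)
    df = pd.DataFrame(recs, columns=ASSOC_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_config(path: str | Path) -> dict:
    """YAML key: value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
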