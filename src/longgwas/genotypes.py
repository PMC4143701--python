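"""Additive-coded genotype matrix with SNP map, PLINK .raw-style text IO.

Dosages count copies of the minor allele (0/1/2), stored as float with NaN
for missing genotypes. The on-disk format is a tab-delimited table with an
``ID`` column followed by one column per SNP (``NA`` for missing), plus a
4-column map file (chromosome, SNP id, 1-based position, alleles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NA_TOKEN = "NA"


@dataclass
class SnpInfo:
    """Per-SNP annotations produced by QC."""

    snp_id: str
    chromosome: str
    position: int
    alleles: str
    maf: float
    hwe_p: float
    call_rate: float


class GenotypeMatrix:
    """individuals × SNPs additive dosages plus the SNP map."""

    def __init__(
        self,
        dosages: np.ndarray,
        individual_ids,
        snp_ids,
        snp_map: pd.DataFrame | None = None,
    ):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals × SNPs)")
        n, m = dosages.shape
        individual_ids = [str(i) for i in individual_ids]
        snp_ids = [str(s) for s in snp_ids]
        if len(individual_ids) != n or len(snp_ids) != m:
            raise ValueError("dosage dimensions inconsistent with id lists")
        called = dosages[~np.isnan(dosages)]
        if called.size and not np.isin(called, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0/1/2 where present")
        if snp_map is None:
            snp_map = pd.DataFrame(
                {
                    "chrom": "1",
                    "snp": snp_ids,
                    "pos": np.arange(1, m + 1),
                    "alleles": "A/B",
                }
            )
        if list(snp_map["snp"].astype(str)) != snp_ids:
            raise ValueError("map SNP ids do not match matrix columns")
        self.dosages = dosages
        self.individual_ids = individual_ids
        self.snp_ids = snp_ids
        self.snp_map = snp_map.reset_index(drop=True)

    # ------------------------------------------------------------------ basics
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            list(self.individual_ids),
            list(self.snp_ids),
            self.snp_map.copy(),
        )

    def missing_rate_per_individual(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def call_rate_per_snp(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf_per_snp(self) -> np.ndarray:
        """Minor allele frequency on called genotypes (folded to [0, 0.5])."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_individuals(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            self.dosages[idx],
            [self.individual_ids[i] for i in idx],
            list(self.snp_ids),
            self.snp_map.copy(),
        )

    def subset_snps(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.individual_ids),
            [self.snp_ids[i] for i in idx],
            self.snp_map.iloc[idx].reset_index(drop=True),
        )

    # ---------------------------------------------------------------------- IO
    def to_files(self, geno_path, map_path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "ID", self.individual_ids)
        # dosages print as integers, missing as NA
        for c in self.snp_ids:
            df[c] = df[c].map(lambda v: NA_TOKEN if np.isnan(v) else str(int(v)))
        df.to_csv(geno_path, sep="\t", index=False)
        self.snp_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, geno_path, map_path=None) -> "GenotypeMatrix":
        df = pd.read_csv(geno_path, sep="\t", na_values=[NA_TOKEN], dtype={"ID": str})
        ids = df["ID"].tolist()
        snp_ids = [c for c in df.columns if c != "ID"]
        dosages = df[snp_ids].to_numpy(dtype=float)
        snp_map = None
        if map_path is not None:
            snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str, "snp": str})
        return cls(dosages, ids, snp_ids, snp_map)
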