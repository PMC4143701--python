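"""Sample- and SNP-level genotype quality control.

Sample level: a pairwise identity-by-state (IBS) matrix flags cryptic
relatedness — for each pair, over SNPs genotyped in both, the fraction of
alleles identical by state (2 − |dosage difference| shared alleles per SNP,
out of 2 per SNP). Pairs above a threshold (absolute, or mean + k·SD of the
distribution of unrelated pairs) lose the member with the lower genotyping
rate. Individuals whose genotype missing rate exceeds a cap are dropped.

SNP level (computed on the retained samples): call rate, minor allele
frequency on called genotypes, and the Hardy-Weinberg exact test on
genotype counts. Default thresholds: call rate < 99%, HWE p < 1e-6,
MAF < 1% remove the SNP; all boundaries strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log, exp

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SnpInfo

REMOVAL_REASONS = ("relatedness", "sample_missingness", "snp_callrate", "hwe", "maf")


# --------------------------------------------------------------------------
# IBS
# --------------------------------------------------------------------------

def ibs_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """Symmetric pairwise IBS with unit diagonal; NaN for pairs sharing no SNP.

    Vectorized through genotype-class indicator products: the summed
    |dosage_a − dosage_b| over shared SNPs decomposes into counts of
    (0,1)/(1,2)-type mismatches (distance 1) and (0,2)-type (distance 2).
    """
    if geno.n_individuals < 2:
        raise ValueError("need at least 2 individuals for an IBS matrix")
    D = geno.dosages
    present = ~np.isnan(D)
    A = [((D == g) & present).astype(float) for g in (0.0, 1.0, 2.0)]
    n_shared = present.astype(float) @ present.astype(float).T
    m1 = A[0] @ A[1].T + A[1] @ A[0].T + A[1] @ A[2].T + A[2] @ A[1].T
    m2 = A[0] @ A[2].T + A[2] @ A[0].T
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - (m1 + 2.0 * m2) / (2.0 * n_shared)
    ibs[n_shared == 0] = np.nan
    np.fill_diagonal(ibs, 1.0)
    return ibs


def ibs_summary(ibs: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the off-diagonal (upper-triangle) defined IBS values."""
    iu = np.triu_indices_from(ibs, k=1)
    vals = ibs[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined pairwise IBS values")
    return float(vals.mean()), float(vals.std())


def flag_related(
    ibs: np.ndarray,
    geno: GenotypeMatrix,
    threshold_mode: str = "absolute",
    threshold_value: float = 0.84,
) -> tuple[list[tuple[str, str, float]], list[str]]:
    """Flag pairs above the relatedness threshold; pick one member to remove.

    ``threshold_mode='absolute'`` uses ``threshold_value`` directly;
    ``'sd'`` uses mean + threshold_value·SD of the pairwise distribution.
    From each flagged pair the member with the lower sample call rate goes;
    on a tie, the larger ID.
    """
    if threshold_mode == "absolute":
        thr = threshold_value
    elif threshold_mode == "sd":
        mean, sd = ibs_summary(ibs)
        thr = mean + threshold_value * sd
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    call = 1.0 - geno.missing_rate_per_individual()
    ids = geno.individual_ids
    flagged, removed = [], []
    iu = np.triu_indices_from(ibs, k=1)
    for a, b in zip(*iu):
        v = ibs[a, b]
        if np.isnan(v) or v <= thr:
            continue
        flagged.append((ids[a], ids[b], float(v)))
        if call[a] < call[b]:
            loser = ids[a]
        elif call[b] < call[a]:
            loser = ids[b]
        else:
            loser = max(ids[a], ids[b])
        if loser not in removed:
            removed.append(loser)
    return flagged, removed


# --------------------------------------------------------------------------
# sample missingness
# --------------------------------------------------------------------------

def sample_missingness_filter(geno: GenotypeMatrix, max_missing: float = 0.40) -> list[str]:
    """Individuals whose missing-genotype proportion strictly exceeds the cap."""
    rates = geno.missing_rate_per_individual()
    return [gid for gid, r in zip(geno.individual_ids, rates) if r > max_missing]


# --------------------------------------------------------------------------
# HWE exact test
# --------------------------------------------------------------------------

def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed
    configuration's. Log-space via lgamma keeps large n stable. Returns 1.0
    for monomorphic SNPs (no test possible).
    """
    for c in (n_hom_minor, n_het, n_hom_major):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0 or n_minor == 0 or n_minor == 2 * n:
        return 1.0

    def log_prob(het: int) -> float:
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        return (
            lgamma(n + 1)
            - lgamma(hom_min + 1)
            - lgamma(het + 1)
            - lgamma(hom_maj + 1)
            + het * log(2.0)
            + lgamma(n_minor + 1)
            + lgamma(2 * n - n_minor + 1)
            - lgamma(2 * n + 1)
        )

    het_values = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logs = {h: log_prob(h) for h in het_values}
    lp_obs = logs[n_het]
    # tolerance guards the p <= p_obs comparison against rounding
    p = sum(exp(lp) for lp in logs.values() if lp <= lp_obs + 1e-12)
    return min(1.0, p)


def hwe_from_dosages(dosages: np.ndarray) -> float:
    """HWE exact p for one SNP's dosage column (NaN = missing)."""
    called = dosages[~np.isnan(dosages)]
    counts = [(called == g).sum() for g in (2.0, 1.0, 0.0)]
    return hwe_exact_test(*[int(c) for c in counts])


# --------------------------------------------------------------------------
# SNP filters
# --------------------------------------------------------------------------

def snp_filters(
    geno: GenotypeMatrix,
    min_callrate: float = 0.99,
    hwe_alpha: float = 1e-6,
    min_maf: float = 0.01,
) -> tuple[list[SnpInfo], pd.DataFrame]:
    """Per-SNP stats and the removal table (snp, reason).

    Reasons report the first violated criterion in the order
    callrate → HWE → MAF; the retained set is the same whatever the order.
    """
    call = geno.call_rate_per_snp()
    maf = geno.maf_per_snp()
    infos, removals = [], []
    for j, sid in enumerate(geno.snp_ids):
        p_hwe = hwe_from_dosages(geno.dosages[:, j])
        row = geno.snp_map.iloc[j]
        m = 0.0 if np.isnan(maf[j]) else float(maf[j])
        infos.append(
            SnpInfo(
                snp_id=sid,
                chromosome=str(row["chrom"]),
                position=int(row["pos"]),
                alleles=str(row["alleles"]),
                maf=m,
                hwe_p=p_hwe,
                call_rate=float(call[j]),
            )
        )
        if call[j] < min_callrate:
            removals.append({"snp": sid, "reason": "snp_callrate"})
        elif p_hwe < hwe_alpha:
            removals.append({"snp": sid, "reason": "hwe"})
        elif m < min_maf:
            removals.append({"snp": sid, "reason": "maf"})
    return infos, pd.DataFrame(removals, columns=["snp", "reason"])


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class QcReport:
    ibs_mean: float
    ibs_sd: float
    flagged_pairs: list
    samples_removed: pd.DataFrame  # id, reason
    snps_removed: pd.DataFrame  # snp, reason
    snp_info: list
    n_samples_kept: int
    n_snps_kept: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Genotype QC",
                f"  pairwise IBS mean {self.ibs_mean:.4f}, SD {self.ibs_sd:.4g}",
                f"  related pairs flagged: {len(self.flagged_pairs)}",
                f"  samples removed: {len(self.samples_removed)} "
                f"(kept {self.n_samples_kept})",
                f"  SNPs removed: {len(self.snps_removed)} (kept {self.n_snps_kept})",
            ]
        )


class GenotypeQC:
    """QC pipeline over a genotype matrix; ``run()`` -> (clean matrix, QcReport)."""

    def __init__(
        self,
        geno: GenotypeMatrix,
        ibs_threshold: float = 0.84,
        ibs_threshold_mode: str = "absolute",
        max_missing: float = 0.40,
        min_callrate: float = 0.99,
        hwe_alpha: float = 1e-6,
        min_maf: float = 0.01,
    ):
        self.geno = geno
        self.ibs_threshold = ibs_threshold
        self.ibs_threshold_mode = ibs_threshold_mode
        self.max_missing = max_missing
        self.min_callrate = min_callrate
        self.hwe_alpha = hwe_alpha
        self.min_maf = min_maf

    def run(self) -> tuple[GenotypeMatrix, QcReport]:
        geno = self.geno
        ibs = ibs_matrix(geno)
        mean, sd = ibs_summary(ibs)
        flagged, related_removed = flag_related(
            ibs, geno, self.ibs_threshold_mode, self.ibs_threshold
        )
        miss_removed = sample_missingness_filter(geno, self.max_missing)
        sample_rows = [{"id": i, "reason": "relatedness"} for i in related_removed]
        sample_rows += [
            {"id": i, "reason": "sample_missingness"}
            for i in miss_removed
            if i not in related_removed
        ]
        samples_removed = pd.DataFrame(sample_rows, columns=["id", "reason"])
        keep = [i for i in geno.individual_ids if i not in set(samples_removed["id"])]
        kept_idx = [geno.individual_ids.index(i) for i in keep]
        geno2 = geno.subset_individuals(np.asarray(kept_idx, dtype=int))

        infos, snps_removed = snp_filters(
            geno2, self.min_callrate, self.hwe_alpha, self.min_maf
        )
        keep_snps = ~pd.Series(geno2.snp_ids).isin(set(snps_removed["snp"])).to_numpy()
        geno3 = geno2.subset_snps(keep_snps)
        report = QcReport(
            ibs_mean=mean,
            ibs_sd=sd,
            flagged_pairs=flagged,
            samples_removed=samples_removed,
            snps_removed=snps_removed,
            snp_info=infos,
            n_samples_kept=geno3.n_individuals,
            n_snps_kept=geno3.n_snps,
        )
        return geno3, report
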