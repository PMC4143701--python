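"""Quantitative-trait association scans for SBP progression.

Trait: ΔSBP/Δt — the change in systolic blood pressure between the first
and last attended examinations divided by the years elapsed. On imputed
(complete) phenotypes this is (SBP_3 − SBP_0)/(AGE_3 − AGE_0); without
imputation it uses each individual's actually attended first/last exams.

Single-marker test: ordinary least squares of the trait on the additive
minor-allele dosage plus retained covariates; the 1-df test is the t-test
on the dosage coefficient. Genome-wide calibration is summarized by the
median-based genomic-control inflation factor λ.

Two-marker allelic-interaction test: the nested comparison of
M^A = b0 + b1·x1 + b2·x2 against M^{A,I} = M^A + b12·x1·x2 through their
residual sums of squares. Both the SSE-ratio statistic
t = (SSE^A − SSE^{A,I})/SSE^A and the standard nested-model
F = (SSE^A − SSE^{A,I})/(SSE^{A,I}/(n − 4)) are reported; p-values come
from F(1, n − 4), the distribution the nested comparison actually follows.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .phenotypes import EXAM_VARS, N_EXAMS, PhenotypeTable
from .qc import hwe_from_dosages

CANDIDATE_COVARIATES = ("AGE0s", "SBP0s", "MED0s", "SMK0s", "dMED", "dSMK", "SEX")
CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549364...


# --------------------------------------------------------------------------
# OLS core (closed-form; statsmodels is the cross-check in the test suite)
# --------------------------------------------------------------------------

def ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS estimates, standard errors, two-sided t-test p-values and SSE.

    Returns None when the design is rank-deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p or np.linalg.matrix_rank(X) < p:
        return None
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    dof = n - p
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return {"beta": beta, "se": se, "t": tvals, "p": pvals, "sse": sse, "dof": dof}


# --------------------------------------------------------------------------
# trait construction
# --------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-individual ΔSBP/Δt with candidate covariates.

    Columns: ID, dsbp_dt, AGE0s, SBP0s, MED0s, SMK0s, dMED, dSMK, SEX.
    Starred (``*``, here suffix ``s``) covariates are the first non-missing
    values; on imputed data they equal the exam-0 values.
    """

    df: pd.DataFrame
    mode: str  # imputed | no_imputation
    excluded: list = field(default_factory=list)
    retained_covariates: list = field(default_factory=list)

    def __len__(self):
        return len(self.df)


def _first_last_attended(vals: np.ndarray) -> tuple[int, int] | None:
    obs = np.flatnonzero(~np.isnan(vals))
    if obs.size < 2:
        return None
    return int(obs[0]), int(obs[-1])


def build_trait(pheno: PhenotypeTable, mode: str = "imputed") -> TraitTable:
    """ΔSBP/Δt and candidate covariates from a phenotype table.

    ``imputed`` mode expects complete records and uses exams 0 and 3;
    ``no_imputation`` uses each individual's first and last attended exams
    (attendance = SBP and AGE observed at that wave). Individuals with
    Δt ≤ 0 or fewer than two attended exams are excluded with a warning.
    """
    if mode not in ("imputed", "no_imputation"):
        raise ValueError(f"unknown trait mode {mode!r}")
    rows, excluded = [], []
    sbp, age = pheno.values("SBP"), pheno.values("AGE")
    med, smk = pheno.values("MED"), pheno.values("SMK")
    for k, pid in enumerate(pheno.ids):
        if mode == "imputed":
            if np.isnan(sbp[k]).any() or np.isnan(age[k]).any():
                raise ValueError(
                    f"incomplete record {pid} in imputed mode; run the imputer first"
                )
            first, last = 0, N_EXAMS - 1
        else:
            att = _first_last_attended(np.where(np.isnan(age[k]), np.nan, sbp[k]))
            if att is None:
                excluded.append((pid, "fewer than 2 attended exams"))
                continue
            first, last = att
        dt = age[k, last] - age[k, first]
        if dt <= 0:
            excluded.append((pid, "non-positive time span"))
            continue

        def first_nonmissing(v):
            obs = v[~np.isnan(v)]
            return obs[0] if obs.size else np.nan

        def delta(v):
            fl = _first_last_attended(v)
            if fl is None:
                return np.nan
            return v[fl[1]] - v[fl[0]]

        rows.append(
            {
                "ID": pid,
                "dsbp_dt": (sbp[k, last] - sbp[k, first]) / dt,
                "AGE0s": first_nonmissing(age[k]),
                "SBP0s": first_nonmissing(sbp[k]),
                "MED0s": first_nonmissing(med[k]),
                "SMK0s": first_nonmissing(smk[k]),
                "dMED": delta(med[k]) if mode == "no_imputation" else med[k, 3] - med[k, 0],
                "dSMK": delta(smk[k]) if mode == "no_imputation" else smk[k, 3] - smk[k, 0],
                "SEX": float(pheno.df["SEX"].iloc[k]),
            }
        )
    for pid, why in excluded:
        warnings.warn(f"individual {pid} excluded from trait table: {why}")
    df = pd.DataFrame(rows, columns=["ID", "dsbp_dt", *CANDIDATE_COVARIATES])
    return TraitTable(df=df, mode=mode, excluded=excluded)


def select_covariates(
    trait: TraitTable, completer_ids, alpha: float = 0.05
) -> list[str]:
    """Retain candidates univariately associated with the trait over completers."""
    sub = trait.df[trait.df["ID"].isin(set(map(str, completer_ids)))]
    y = sub["dsbp_dt"].to_numpy(float)
    retained = []
    for cand in CANDIDATE_COVARIATES:
        x = sub[cand].to_numpy(float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            warnings.warn(f"covariate {cand} skipped (zero variance or too few obs)")
            continue
        fit = ols_fit(np.column_stack([np.ones(ok.sum()), x[ok]]), y[ok])
        if fit is not None and fit["p"][1] < alpha:
            retained.append(cand)
    if not retained:
        warnings.warn("no covariate retained; scan proceeds unadjusted")
    return retained


# --------------------------------------------------------------------------
# single-marker scan
# --------------------------------------------------------------------------

@dataclass
class ScanResult:
    snp_id: str
    beta: float
    se: float
    statistic: float
    p_parametric: float
    n_used: int
    p_mc: float | None = None


class GWASResults:
    """Results of a single-marker scan; mirrors a per-SNP summary table."""

    def __init__(self, table: pd.DataFrame, covariates: list[str], mode: str):
        self.table = table
        self.covariates = covariates
        self.mode = mode

    def genomic_lambda(self) -> float:
        return genomic_inflation(self.table["p"].dropna().to_numpy())

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "p")

    def summary(self) -> str:
        lam = self.genomic_lambda() if self.table["p"].notna().sum() else np.nan
        lines = [
            f"Single-marker scan ({self.mode} phenotypes)",
            f"  SNPs tested: {len(self.table)}   covariates: {self.covariates or 'none'}",
            f"  genomic inflation factor lambda = {lam:.3f}",
            "  top hits:",
            self.top(5).to_string(index=False),
        ]
        return "\n".join(lines)


class SingleMarkerGWAS:
    """OLS scan of ΔSBP/Δt on additive dosages; ``fit()`` -> GWASResults."""

    def __init__(
        self,
        trait: TraitTable,
        geno: GenotypeMatrix,
        covariates: list[str] | None = None,
    ):
        self.trait = trait
        self.geno = geno
        self.covariates = list(covariates) if covariates is not None else []
        for c in self.covariates:
            if c not in trait.df.columns:
                raise ValueError(f"unknown covariate {c!r}")

    def fit(self) -> GWASResults:
        trait_df = self.trait.df.set_index("ID")
        common = [i for i in self.geno.individual_ids if i in trait_df.index]
        if not common:
            raise ValueError("no individuals shared between trait table and genotypes")
        geno = self.geno.subset_individuals(
            np.asarray([self.geno.individual_ids.index(i) for i in common], dtype=int)
        )
        td = trait_df.loc[common]
        y_all = td["dsbp_dt"].to_numpy(float)
        cov_all = td[self.covariates].to_numpy(float) if self.covariates else None

        rows = []
        for j, sid in enumerate(geno.snp_ids):
            dos = geno.dosages[:, j]
            ok = ~np.isnan(dos) & ~np.isnan(y_all)
            if cov_all is not None:
                ok &= ~np.isnan(cov_all).any(axis=1)
            x = dos[ok]
            n_used = int(ok.sum())
            rec = {
                "snp": sid,
                "chrom": str(geno.snp_map["chrom"].iloc[j]),
                "pos": int(geno.snp_map["pos"].iloc[j]),
                "alleles": str(geno.snp_map["alleles"].iloc[j]),
                "maf": np.nan, "hwe_p": np.nan,
                "beta": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
                "n_used": n_used,
            }
            if n_used >= 3 and np.std(x) > 0:
                p_hat = x.mean() / 2.0
                rec["maf"] = min(p_hat, 1 - p_hat)
                rec["hwe_p"] = hwe_from_dosages(x)
                cols = [np.ones(n_used), x]
                if cov_all is not None:
                    cols.extend(cov_all[ok].T)
                fit = ols_fit(np.column_stack(cols), y_all[ok])
                if fit is not None:
                    rec.update(
                        beta=fit["beta"][1], se=fit["se"][1],
                        stat=fit["t"][1], p=fit["p"][1],
                    )
            rows.append(rec)
        return GWASResults(pd.DataFrame(rows), self.covariates, self.trait.mode)


def single_marker_scan(trait, geno, covariates=None) -> GWASResults:
    return SingleMarkerGWAS(trait, geno, covariates).fit()


def genomic_inflation(p_values) -> float:
    """Median-based genomic-control λ: median observed 1-df χ² / 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.size < 100:
        warnings.warn(f"only {p.size} p-values; lambda estimate is unstable")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


# --------------------------------------------------------------------------
# two-marker allelic interaction
# --------------------------------------------------------------------------

@dataclass
class InteractionModels:
    sse_a: float
    sse_ai: float
    t_ratio: float  # (SSE^A − SSE^{A,I}) / SSE^A
    f_standard: float  # nested-model F with (1, n − p_full) df
    p_f: float
    beta_12: float
    se_12: float
    n_used: int


def interaction_test(
    y: np.ndarray,
    dosage_1: np.ndarray,
    dosage_2: np.ndarray,
    covariates: np.ndarray | None = None,
) -> InteractionModels | None:
    """Nested SSE comparison of the additive vs additive-plus-product models.

    Returns None when the design is degenerate (collinear interaction
    column, constant dosage, or too few individuals).
    """
    y = np.asarray(y, float)
    d1 = np.asarray(dosage_1, float)
    d2 = np.asarray(dosage_2, float)
    ok = ~np.isnan(y) & ~np.isnan(d1) & ~np.isnan(d2)
    if covariates is not None:
        covariates = np.asarray(covariates, float)
        ok &= ~np.isnan(covariates).any(axis=1)
    y, d1, d2 = y[ok], d1[ok], d2[ok]
    cov = covariates[ok] if covariates is not None else None
    n = y.size
    cols_a = [np.ones(n), d1, d2]
    if cov is not None:
        cols_a.extend(cov.T)
    X_a = np.column_stack(cols_a)
    X_ai = np.column_stack(cols_a + [d1 * d2])
    if n <= X_ai.shape[1]:
        return None
    fit_ai = ols_fit(X_ai, y)
    fit_a = ols_fit(X_a, y)
    if fit_ai is None or fit_a is None:
        return None
    sse_a, sse_ai = fit_a["sse"], min(fit_ai["sse"], fit_a["sse"])
    dof = n - X_ai.shape[1]  # n − 4 without covariates
    f = (sse_a - sse_ai) / (sse_ai / dof) if sse_ai > 0 else np.inf
    j12 = X_ai.shape[1] - 1
    return InteractionModels(
        sse_a=sse_a,
        sse_ai=sse_ai,
        t_ratio=(sse_a - sse_ai) / sse_a if sse_a > 0 else 0.0,
        f_standard=f,
        p_f=float(stats.f.sf(f, 1, dof)),
        beta_12=float(fit_ai["beta"][j12]),
        se_12=float(fit_ai["se"][j12]),
        n_used=n,
    )


class InteractionResults:
    def __init__(self, table: pd.DataFrame, n_pairs_tested: int, min_maf: float):
        self.table = table  # top-K plus below-threshold reports, sorted by p
        self.n_pairs_tested = n_pairs_tested
        self.min_maf = min_maf

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "p")

    def summary(self) -> str:
        return "\n".join(
            [
                f"Two-marker interaction scan (MAF >= {self.min_maf})",
                f"  pairs tested: {self.n_pairs_tested}",
                "  top pairs:",
                self.top(5).to_string(index=False),
            ]
        )


class InteractionScan:
    """Exhaustive SNP-pair allelic-interaction scan.

    Enumerates all unordered pairs of SNPs whose MAF (on the analyzed
    individuals) meets ``min_maf``, in (i < j) index order, keeping a
    bounded top-K heap plus every pair with p below ``report_below``.
    Memory scales with ``chunk_size`` and K, not with the pair count.
    """

    def __init__(
        self,
        trait: TraitTable,
        geno: GenotypeMatrix,
        min_maf: float = 0.05,
        covariates: list[str] | None = None,
    ):
        self.trait = trait
        self.geno = geno
        self.min_maf = min_maf
        self.covariates = list(covariates) if covariates else []

    def fit(
        self,
        report_below: float = 0.0,
        top_k: int = 100,
        chunk_size: int = 10000,
    ) -> InteractionResults:
        trait_df = self.trait.df.set_index("ID")
        common = [i for i in self.geno.individual_ids if i in trait_df.index]
        geno = self.geno.subset_individuals(
            np.asarray([self.geno.individual_ids.index(i) for i in common], dtype=int)
        )
        y = trait_df.loc[common, "dsbp_dt"].to_numpy(float)
        cov = (
            trait_df.loc[common, self.covariates].to_numpy(float)
            if self.covariates
            else None
        )
        maf = geno.maf_per_snp()
        elig = np.flatnonzero(~np.isnan(maf) & (maf >= self.min_maf))
        if elig.size < 2:
            raise ValueError("fewer than 2 SNPs pass the interaction MAF criterion")

        def pair_iter():
            for a in range(elig.size):
                for b in range(a + 1, elig.size):
                    yield int(elig[a]), int(elig[b])

        heap: list = []  # max-heap on p via negation
        reported = []
        n_tested = 0
        chunk: list = []

        def flush(chunk):
            nonlocal n_tested
            for i, j in chunk:
                res = interaction_test(y, geno.dosages[:, i], geno.dosages[:, j], cov)
                n_tested += 1
                if res is None:
                    continue
                row = (
                    res.p_f, geno.snp_ids[i], geno.snp_ids[j],
                    res.beta_12, res.se_12, res.t_ratio, res.f_standard,
                    res.sse_a, res.sse_ai, res.n_used,
                )
                if res.p_f <= report_below:
                    reported.append(row)
                item = (-res.p_f, row)
                if len(heap) < top_k:
                    heapq.heappush(heap, item)
                elif item[0] > heap[0][0]:
                    heapq.heapreplace(heap, item)

        for pair in pair_iter():
            chunk.append(pair)
            if len(chunk) >= chunk_size:
                flush(chunk)
                chunk = []
        flush(chunk)

        rows = {r[1:3]: r for _, r in heap}
        for r in reported:
            rows[r[1:3]] = r
        table = pd.DataFrame(
            sorted(rows.values()),
            columns=[
                "p", "snp_1", "snp_2", "beta_12", "se_12",
                "t_ratio", "f_standard", "sse_a", "sse_ai", "n_used",
            ],
        )
        return InteractionResults(table, n_tested, self.min_maf)


def interaction_scan(trait, geno, min_maf: float = 0.05, **fit_kwargs) -> InteractionResults:
    return InteractionScan(trait, geno, min_maf).fit(**fit_kwargs)
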