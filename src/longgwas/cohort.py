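"""Synthetic longitudinal blood-pressure cohort with known ground truth.

Emulates a four-wave longitudinal study of systolic blood pressure (SBP) of
the kind run by family blood-pressure consortia: individuals aged 20-70 at
baseline are examined around fixed calendar years (default 1993/1998/2003/
2009), recording AGE, SBP, antihypertensive-medication use (MED) and smoking
status (SMK) at each wave. SBP follows a linear individual trajectory
(random intercept and slope) with exam-level noise; medication uptake is a
persistent Bernoulli process whose probability rises with current SBP and
which in turn lowers subsequent SBP; smoking is a persistent binary chain.

Dropout can be switched between MCAR (attendance independent of everything),
MAR via age (older individuals miss follow-ups more often) and MNAR via
current SBP. A missed wave masks all four variables of that wave. Genotypes
are independent biallelic loci with dosages ~ Binomial(2, MAF); main-effect
and interaction SNPs can be planted on the latent SBP slope, and cryptic
relative pairs can be injected by near-copying genotype vectors.

Every random component draws from its own named stream derived from one
integer seed, so toggling (say) dropout does not perturb the genotype draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .phenotypes import ALL_COLS, EXAM_VARS, N_EXAMS, PhenotypeTable, exam_cols

_STREAMS = ("phenotypes", "genotypes", "dropout", "relatives")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    Units: SBP in mm Hg, ages and times in years, effects in mm Hg/year of
    latent SBP slope per copy of the minor allele (per dosage product for
    interactions).
    """

    n_individuals: int = 300
    n_snps: int = 100
    exam_years: tuple = (1993, 1998, 2003, 2009)
    maf_range: tuple = (0.05, 0.5)
    dropout_mode: str = "none"  # none | mcar | mar_age | mnar_sbp
    dropout_strength: float = 0.06  # logistic slope per unit predictor
    dropout_intercept: float = 1.5  # attendance logit at the predictor center
    planted_main_effects: tuple = ()  # ((snp_index, effect), ...)
    planted_interactions: tuple = ()  # ((snp_i, snp_j, effect), ...)
    n_relative_pairs: int = 0
    copy_error_rate: float = 0.02
    seed: int = 0

    # phenotype-model constants
    age0_range: tuple = (20, 70)
    sbp_intercept: float = 120.0  # mm Hg at reference age, female, untreated
    sbp_age_coef: float = 0.5  # mm Hg per year of baseline age
    sbp_sex_coef: float = 5.0  # mm Hg added for sex == 1
    sbp_smk_coef: float = 2.0  # mm Hg added while a current smoker
    sbp_indiv_sd: float = 10.0  # SD of the random individual intercept
    age_ref: float = 40.0
    slope_mean: float = 0.5  # mm Hg/year mean latent slope
    slope_sd: float = 0.4
    slope_age_coef: float = 0.01  # slope increase per year of baseline age
    exam_noise_sd: float = 5.0
    med_intercept: float = -2.0  # logit of medication uptake at SBP == sbp_ref
    med_sbp_coef: float = 0.04  # logit slope per mm Hg above sbp_ref
    med_sbp_effect: float = -5.0  # mm Hg while on medication at previous wave
    sbp_ref: float = 140.0
    smk_init: float = 0.3
    smk_persist: float = 0.9  # P(smoker stays a smoker between waves)
    smk_start: float = 0.02  # P(non-smoker starts between waves)

    # dropout-model constants
    age_center: float = 50.0
    sbp_center: float = 140.0
    mask_exam0: bool = False
    item_missing_rate: float = 0.0  # extra per-item MCAR masking on attended waves
    geno_missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        ys = tuple(self.exam_years)
        if len(ys) != N_EXAMS or any(b <= a for a, b in zip(ys, ys[1:])):
            raise ValueError("exam_years must be 4 strictly increasing years")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        for idx, _ in self.planted_main_effects:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"planted main-effect SNP index {idx} out of range")
        for i, j, _ in self.planted_interactions:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps) or i == j:
                raise ValueError("planted interaction indices invalid")
        if not 0 <= self.copy_error_rate <= 1:
            raise ValueError("copy_error_rate must be in [0, 1]")
        if 2 * self.n_relative_pairs > self.n_individuals:
            raise ValueError("n_relative_pairs * 2 exceeds n_individuals")
        if self.dropout_mode not in ("none", "mcar", "mar_age", "mnar_sbp"):
            raise ValueError(f"unknown dropout_mode {self.dropout_mode!r}")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class TrueCohort:
    """A generated cohort plus everything needed to score downstream stages."""

    config: CohortConfig
    phenotypes_complete: PhenotypeTable
    phenotypes_observed: PhenotypeTable
    genotypes: GenotypeMatrix
    slopes: np.ndarray  # realized per-individual SBP slope incl. genetic terms
    latent: dict = field(default_factory=dict)
    true_mafs: np.ndarray | None = None
    relative_pairs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def draw_latents(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Draw every phenotype-level random quantity once.

    Stored uniforms (not outcomes) are kept for MED/SMK so phenotypes can be
    re-materialized consistently after genetic effects shift the SBP slope.
    """
    n = config.n_individuals
    lo, hi = config.age0_range
    age0 = rng.integers(lo, hi + 1, size=n)
    return {
        "sex": rng.integers(0, 2, size=n),
        "birth_year": np.asarray(config.exam_years[0] - age0, dtype=int),
        "intercept_dev": rng.normal(0.0, config.sbp_indiv_sd, size=n),
        "slope_dev": rng.normal(0.0, config.slope_sd, size=n),
        "exam_noise": rng.normal(0.0, config.exam_noise_sd, size=(n, N_EXAMS)),
        "u_med": rng.uniform(size=(n, N_EXAMS)),
        "u_smk": rng.uniform(size=(n, N_EXAMS)),
    }


def materialize_phenotypes(
    config: CohortConfig, latent: dict, genetic_slope: np.ndarray | None = None
) -> tuple[PhenotypeTable, np.ndarray]:
    """Deterministically build the complete phenotype table from latents.

    The SBP trajectory is built wave by wave because medication feeds back:
    being on medication at the previous wave lowers current SBP, while the
    probability of starting medication rises with current SBP.
    """
    n = config.n_individuals
    years = np.asarray(config.exam_years)
    birth_year = latent["birth_year"]
    ages = years[None, :] - birth_year[:, None]
    age0 = ages[:, 0]

    slope = (
        config.slope_mean
        + config.slope_age_coef * (age0 - config.age_ref)
        + latent["slope_dev"]
    )
    if genetic_slope is not None:
        slope = slope + genetic_slope
    base = (
        config.sbp_intercept
        + config.sbp_age_coef * (age0 - config.age_ref)
        + config.sbp_sex_coef * latent["sex"]
        + latent["intercept_dev"]
    )

    # smoking: persistent chain, independent of SBP
    smk = np.zeros((n, N_EXAMS), dtype=int)
    smk[:, 0] = latent["u_smk"][:, 0] < config.smk_init
    for i in range(1, N_EXAMS):
        stay = latent["u_smk"][:, i] < config.smk_persist
        start = latent["u_smk"][:, i] < config.smk_start
        smk[:, i] = np.where(smk[:, i - 1] == 1, stay, start).astype(int)

    sbp = np.zeros((n, N_EXAMS))
    med = np.zeros((n, N_EXAMS), dtype=int)
    on_med_prev = np.zeros(n, dtype=bool)
    for i in range(N_EXAMS):
        sbp[:, i] = (
            base
            + slope * (ages[:, i] - age0)
            + latent["exam_noise"][:, i]
            + config.sbp_smk_coef * smk[:, i]
            + config.med_sbp_effect * on_med_prev
        )
        p_start = _sigmoid(
            config.med_intercept + config.med_sbp_coef * (sbp[:, i] - config.sbp_ref)
        )
        start_now = latent["u_med"][:, i] < p_start
        med[:, i] = (on_med_prev | start_now).astype(int)  # persistent once 1
        on_med_prev = med[:, i] == 1

    df = pd.DataFrame(
        {
            "ID": [f"SIM{k:06d}" for k in range(n)],
            "SEX": latent["sex"],
            "BIRTH_YEAR": birth_year,
        }
    )
    for i in range(N_EXAMS):
        df[f"AGE{i}"] = ages[:, i]
    for i in range(N_EXAMS):
        df[f"SBP{i}"] = sbp[:, i]
    for i in range(N_EXAMS):
        df[f"MED{i}"] = med[:, i]
    for i in range(N_EXAMS):
        df[f"SMK{i}"] = smk[:, i]
    return PhenotypeTable(df[ALL_COLS]), slope


def generate_phenotypes(config: CohortConfig, rng=None) -> tuple[PhenotypeTable, dict, np.ndarray]:
    """Complete (pre-dropout) phenotypes; returns (table, latents, slopes)."""
    config.validate()
    if rng is None:
        rng = config.rngs()["phenotypes"]
    latent = draw_latents(config, rng)
    table, slope = materialize_phenotypes(config, latent)
    return table, latent, slope


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def generate_genotypes(config: CohortConfig, rng=None) -> tuple[GenotypeMatrix, np.ndarray]:
    """Independent biallelic loci: dosage ~ Binomial(2, MAF) per entry."""
    config.validate()
    if rng is None:
        rng = config.rngs()["genotypes"]
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    if config.geno_missing_rate > 0:
        mask = rng.uniform(size=(n, m)) < config.geno_missing_rate
        dosages[mask] = np.nan
    snp_ids = [f"snp{j:05d}" for j in range(m)]
    snp_map = pd.DataFrame(
        {
            "chrom": np.asarray(1 + (np.arange(m) % 22), dtype=str),
            "snp": snp_ids,
            "pos": 1 + 1000 * np.arange(m),
            "alleles": "A/B",
        }
    )
    ids = [f"SIM{k:06d}" for k in range(n)]
    return GenotypeMatrix(dosages, ids, snp_ids, snp_map), mafs


def genetic_slope_contribution(
    config: CohortConfig, geno: GenotypeMatrix
) -> tuple[np.ndarray, list[str]]:
    """Planted effects on the latent SBP slope: Σ β·x plus Σ β·x_i·x_j."""
    contrib = np.zeros(geno.n_individuals)
    warns: list[str] = []
    d = np.nan_to_num(geno.dosages, nan=0.0)
    for idx, eff in config.planted_main_effects:
        col = d[:, idx]
        if np.all(col == col[0]):
            warns.append(f"planted main effect on zero-variance SNP index {idx}")
        contrib += eff * col
    for i, j, eff in config.planted_interactions:
        prod = d[:, i] * d[:, j]
        if np.all(prod == prod[0]):
            warns.append(f"planted interaction on zero-variance pair ({i},{j})")
        contrib += eff * prod
    return contrib, warns


# --------------------------------------------------------------------------
# dropout
# --------------------------------------------------------------------------

def apply_dropout(
    complete: PhenotypeTable, config: CohortConfig, rng=None
) -> tuple[PhenotypeTable, list[str]]:
    """Mask whole exam waves by a logistic attendance model.

    Attendance logit = intercept − strength·(predictor − center) where the
    predictor is the wave's age (mar_age), the wave's SBP (mnar_sbp) or a
    constant (mcar). Exam 0 is exempt unless ``mask_exam0``. An attended
    wave can additionally lose individual items at ``item_missing_rate``
    (MCAR), producing partial-wave non-completers.
    """
    config.validate()
    warns: list[str] = []
    if config.dropout_mode == "none" and config.item_missing_rate == 0:
        return complete.copy(), warns
    if rng is None:
        rng = config.rngs()["dropout"]
    df = complete.df.copy()
    n = len(df)
    first_wave = 0 if config.mask_exam0 else 1
    for i in range(first_wave, N_EXAMS):
        if config.dropout_mode == "mar_age":
            pred = df[f"AGE{i}"].to_numpy(float) - config.age_center
        elif config.dropout_mode == "mnar_sbp":
            pred = df[f"SBP{i}"].to_numpy(float) - config.sbp_center
        else:  # mcar or item-missingness only
            pred = np.zeros(n)
        p = _sigmoid(config.dropout_intercept - config.dropout_strength * pred)
        if np.any((p <= 0) | (p >= 1)):
            warns.append(f"attendance probability clamped at wave {i}")
            p = np.clip(p, 1e-12, 1 - 1e-12)
        if config.dropout_mode == "none":
            attend = np.ones(n, dtype=bool)
        else:
            attend = rng.uniform(size=n) < p
        for var in EXAM_VARS:
            df.loc[~attend, f"{var}{i}"] = np.nan
        if config.item_missing_rate > 0:
            for var in EXAM_VARS:
                drop = attend & (rng.uniform(size=n) < config.item_missing_rate)
                df.loc[drop, f"{var}{i}"] = np.nan
    return PhenotypeTable(df), warns


# --------------------------------------------------------------------------
# relatives
# --------------------------------------------------------------------------

def inject_relatives(
    geno: GenotypeMatrix,
    n_pairs: int,
    copy_error_rate: float,
    seed_or_rng,
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Plant cryptic relative pairs by near-copying genotype vectors.

    For each pair the second member's vector becomes a copy of the first
    with every dosage independently resampled (from Binomial(2, p̂) at the
    SNP's empirical allele frequency) with probability ``copy_error_rate``.
    ``copy_error_rate=0`` yields exact duplicates; 1 yields an unrelated
    redraw.
    """
    if not 0 <= copy_error_rate <= 1:
        raise ValueError("copy_error_rate must be in [0, 1]")
    if 2 * n_pairs > geno.n_individuals:
        raise ValueError("not enough individuals for the requested pairs")
    if n_pairs == 0:
        return geno.copy(), []
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    out = geno.copy()
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(out.dosages, axis=0) / 2.0
    freqs = np.nan_to_num(freqs, nan=0.0)
    chosen = rng.choice(geno.n_individuals, size=2 * n_pairs, replace=False)
    pairs = []
    for k in range(n_pairs):
        a, b = int(chosen[2 * k]), int(chosen[2 * k + 1])
        vec = out.dosages[a].copy()
        flip = rng.uniform(size=geno.n_snps) < copy_error_rate
        vec[flip] = rng.binomial(2, freqs[flip]).astype(float)
        out.dosages[b] = vec
        pairs.append((out.individual_ids[a], out.individual_ids[b]))
    return out, pairs


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> TrueCohort:
    """Full generator: phenotypes, genotypes, planted effects, dropout, relatives."""
    config.validate()
    rngs = config.rngs()
    latent = draw_latents(config, rngs["phenotypes"])
    geno, mafs = generate_genotypes(config, rngs["genotypes"])
    gen_slope, warns = genetic_slope_contribution(config, geno)
    complete, slopes = materialize_phenotypes(config, latent, gen_slope)
    observed, drop_warns = apply_dropout(complete, config, rngs["dropout"])
    geno, pairs = inject_relatives(
        geno, config.n_relative_pairs, config.copy_error_rate, rngs["relatives"]
    )
    all_warns = warns + drop_warns
    for w in all_warns:
        warnings.warn(w, stacklevel=2)
    return TrueCohort(
        config=config,
        phenotypes_complete=complete,
        phenotypes_observed=observed,
        genotypes=geno,
        slopes=slopes,
        latent=latent,
        true_mafs=mafs,
        relative_pairs=pairs,
        warnings=all_warns,
    )


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
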