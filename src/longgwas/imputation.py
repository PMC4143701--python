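"""Correlation-weighted nearest-completer (hot-deck) imputation.

Missing longitudinal phenotype values are filled from the single most
similar *completer* — an individual with every AGE/SBP/MED/SMK value
recorded at all four exams. The algorithm:

1. Determine the average calendar year of each exam wave.
2. Fill missing ages from birth year and those average years (ages are
   always recoverable, so they never come from a donor).
3. On completers, compute Pearson correlations of ΔSBP = SBP_3 − SBP_0
   with AGE_0, MED_0, SMK_0 (α1, α2, α3) and with SBP_0 (β).
4. Define a weighted squared-distance between a non-completer N and a
   completer C over z-score-normalized values:

       d(C,N) = Σ_i [ w_age·(ÂGE_i^N − ÂGE_i^C)²
                      + I_SBP·(ŜBP_i^N − ŜBP_i^C)²
                      + w_med·I_MED·(M̂ED_i^N − M̂ED_i^C)²
                      + w_smk·I_SMK·(ŜMK_i^N − ŜMK_i^C)² ]

   with w_age = |α1/β|, w_med = |α2/β|, w_smk = |α3/β|; the SBP term has
   weight 1, and I_(·) gates each term on the non-completer actually having
   that measurement. The weights let variables that co-move strongly with
   the SBP change (relative to baseline SBP) dominate the match.
5. Each non-completer's donor is the completer minimizing d (ties to the
   lexicographically smallest donor ID).
6. Missing SBP/MED/SMK values are copied from the donor at the same exam.

Normalization constants (mean and population SD per variable per exam) are
computed over all individuals with that value observed at that exam and
applied identically to completers and non-completers, so distances compare
on one common scale. Observed values are never overwritten, and imputing an
already-complete table is the identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phenotypes import EXAM_VARS, N_EXAMS, PhenotypeTable, exam_cols

BETA_TOL = 1e-8
DONOR_VARS = ("SBP", "MED", "SMK")  # AGE is filled from birth year, not donated


@dataclass
class ImputationWeights:
    """Correlation coefficients over completers and the derived distance weights."""

    alpha_1: float  # corr(ΔSBP, AGE_0)
    alpha_2: float  # corr(ΔSBP, MED_0)
    alpha_3: float  # corr(ΔSBP, SMK_0)
    beta: float  # corr(ΔSBP, SBP_0)

    @property
    def w_age(self) -> float:
        return abs(self.alpha_1 / self.beta)

    @property
    def w_med(self) -> float:
        return abs(self.alpha_2 / self.beta)

    @property
    def w_smk(self) -> float:
        return abs(self.alpha_3 / self.beta)

    def as_dict(self) -> dict:
        return {
            "alpha_1": self.alpha_1,
            "alpha_2": self.alpha_2,
            "alpha_3": self.alpha_3,
            "beta": self.beta,
            "w_age": self.w_age,
            "w_med": self.w_med,
            "w_smk": self.w_smk,
        }


@dataclass
class NormalizationConstants:
    """Per-variable per-exam mean and population SD over observed values."""

    mu: dict  # mu[var] -> length-4 array
    sigma: dict  # sigma[var] -> length-4 array

    def normalize(self, var: str, values: np.ndarray) -> np.ndarray:
        """z-scores of an (n, 4) value matrix; NaN propagates."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return (values - self.mu[var]) / self.sigma[var]


@dataclass
class DistanceRecord:
    noncompleter_id: str
    completer_id: str
    d: float


# --------------------------------------------------------------------------
# steps 1-3
# --------------------------------------------------------------------------

def extract_completers(pheno: PhenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (completers, non-completers); errors if no completer."""
    comp = pheno.completer_mask()
    if not comp.any():
        raise ValueError("no completers: imputation impossible")
    return comp, ~comp


def average_exam_years(pheno: PhenotypeTable) -> tuple[int, ...]:
    """Rounded mean calendar year of each exam over individuals attending it."""
    ages = pheno.values("AGE")
    by = pheno.df["BIRTH_YEAR"].to_numpy(float)
    years = []
    for i in range(N_EXAMS):
        obs = ~np.isnan(ages[:, i])
        if not obs.any():
            raise ValueError(f"exam {i} attended by nobody; cannot average its year")
        years.append(int(round(np.mean(by[obs] + ages[obs, i]))))
    return tuple(years)


def impute_ages(pheno: PhenotypeTable, exam_years) -> PhenotypeTable:
    """Fill missing AGE_i as exam_year_i − birth_year; observed ages untouched."""
    df = pheno.df.copy()
    by = df["BIRTH_YEAR"].to_numpy(float)
    for i, yr in enumerate(exam_years):
        col = f"AGE{i}"
        filled = yr - by
        if np.any(filled[df[col].isna()] <= 0):
            raise ValueError(f"imputed age <= 0 at exam {i}")
        df[col] = df[col].fillna(pd.Series(filled, index=df.index))
    return PhenotypeTable(df)


def compute_weights(completers: PhenotypeTable) -> ImputationWeights:
    """Pearson correlations of ΔSBP = SBP_3 − SBP_0 with the baseline variables."""
    if len(completers) < 3:
        raise ValueError("need at least 3 completers to estimate correlations")
    sbp = completers.values("SBP")
    dsbp = sbp[:, 3] - sbp[:, 0]
    base = {
        "alpha_1": completers.values("AGE")[:, 0],
        "alpha_2": completers.values("MED")[:, 0],
        "alpha_3": completers.values("SMK")[:, 0],
        "beta": sbp[:, 0],
    }
    out = {}
    for name, x in base.items():
        if np.std(x) == 0 or np.std(dsbp) == 0:
            if name == "beta":
                raise ValueError("SBP_0 (or ΔSBP) has zero variance over completers")
            warnings.warn(f"zero-variance predictor for {name}; correlation set to 0")
            out[name] = 0.0
        else:
            out[name] = float(np.corrcoef(dsbp, x)[0, 1])
    if abs(out["beta"]) < BETA_TOL:
        raise ValueError("|beta| below tolerance; distance weights undefined")
    return ImputationWeights(**out)


def compute_normalization(pheno: PhenotypeTable) -> NormalizationConstants:
    """Mean/SD per variable per exam over all individuals with that value observed."""
    mu, sigma = {}, {}
    for var in EXAM_VARS:
        vals = pheno.values(var)
        mu[var] = np.nanmean(vals, axis=0)
        sigma[var] = np.nanstd(vals, axis=0)  # population SD, ddof=0
    return NormalizationConstants(mu=mu, sigma=sigma)


# --------------------------------------------------------------------------
# steps 4-5: distance and donor search
# --------------------------------------------------------------------------

def _term_weights(weights: ImputationWeights, constants: NormalizationConstants):
    """Per-(variable, exam) weights; a zero-SD exam term is silenced."""
    base = {"AGE": weights.w_age, "SBP": 1.0, "MED": weights.w_med, "SMK": weights.w_smk}
    w = {}
    for var in EXAM_VARS:
        ok = constants.sigma[var] > 0
        if not ok.all() and base[var] != 0:
            warnings.warn(f"zero SD for {var} at exams {list(np.flatnonzero(~ok))}; "
                          "those terms dropped from the distance")
        w[var] = base[var] * ok
    return w


def distance_matrix(
    noncompleters: PhenotypeTable,
    completers: PhenotypeTable,
    weights: ImputationWeights,
    constants: NormalizationConstants,
    presence: dict | None = None,
) -> np.ndarray:
    """(n_noncompleters × n_completers) matrix of the weighted distances.

    ``presence`` optionally carries the non-completers' original presence
    masks (per variable), for use after ages were imputed; by default the
    tables' own missingness gates the terms.
    """
    w = _term_weights(weights, constants)
    zs_n = {v: constants.normalize(v, noncompleters.values(v)) for v in EXAM_VARS}
    zs_c = {v: constants.normalize(v, completers.values(v)) for v in EXAM_VARS}
    for v in EXAM_VARS:
        if not np.isfinite(zs_c[v][:, w[v] > 0] if np.any(w[v] > 0) else zs_c[v][:, :0]).all():
            raise ValueError(f"non-finite normalized completer value for {v}")
    if presence is None:
        presence = {v: noncompleters.presence(v) for v in EXAM_VARS}
    presence = dict(presence)
    presence["AGE"] = np.ones_like(presence["AGE"], dtype=bool)  # ages imputed upstream

    n, c = len(noncompleters), len(completers)
    d = np.zeros((n, c))
    for v in EXAM_VARS:
        gate = presence[v] * w[v]  # (n, 4) per-term weight incl. indicator
        zn = np.nan_to_num(zs_n[v], nan=0.0)
        diff2_gated = (
            (zn[:, None, :] - zs_c[v][None, :, :]) ** 2 * gate[:, None, :]
        )
        # masked (gate 0) terms may hold NaN*0 artifacts; zero them explicitly
        contrib = np.where(gate[:, None, :] > 0, diff2_gated, 0.0)
        if not np.isfinite(contrib).all():
            raise ValueError(f"non-finite distance term for {v}")
        d += contrib.sum(axis=2)
    return d


def distance(
    noncompleter_row: pd.Series,
    completer_row: pd.Series,
    weights: ImputationWeights,
    constants: NormalizationConstants,
) -> float:
    """Distance between one non-completer and one completer (scalar form)."""
    nt = PhenotypeTable(pd.DataFrame([noncompleter_row]))
    ct = PhenotypeTable(pd.DataFrame([completer_row]))
    return float(distance_matrix(nt, ct, weights, constants)[0, 0])


def select_nearest(records: list[DistanceRecord]) -> DistanceRecord:
    """Argmin over candidate donors; ties go to the smallest donor ID."""
    if not records:
        raise ValueError("no candidate donors")
    dmin = min(r.d for r in records)
    tied = sorted((r for r in records if r.d == dmin), key=lambda r: r.completer_id)
    return tied[0]


def nearest_completer(
    noncompleter_row: pd.Series,
    completers: PhenotypeTable,
    weights: ImputationWeights,
    constants: NormalizationConstants,
) -> tuple[str, float]:
    nt = PhenotypeTable(pd.DataFrame([noncompleter_row]))
    d = distance_matrix(nt, completers, weights, constants)[0]
    recs = [
        DistanceRecord(str(noncompleter_row["ID"]), cid, float(dv))
        for cid, dv in zip(completers.ids, d)
    ]
    best = select_nearest(recs)
    return best.completer_id, best.d


# --------------------------------------------------------------------------
# step 6: transfer
# --------------------------------------------------------------------------

def transfer_values(noncompleter_row: pd.Series, donor_row: pd.Series) -> tuple[pd.Series, list[str]]:
    """Copy the donor's SBP/MED/SMK values into the missing slots.

    Observed slots are never overwritten; returns the completed row and the
    list of filled slots for the audit table.
    """
    out = noncompleter_row.copy()
    filled = []
    for var in DONOR_VARS:
        for col in exam_cols(var):
            if pd.isna(out[col]):
                if pd.isna(donor_row[col]):
                    raise ValueError(f"donor {donor_row['ID']} missing {col}: "
                                     "completer invariant violated")
                out[col] = donor_row[col]
                filled.append(col)
    return out, filled


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class ImputationResult:
    """Completed phenotype table plus a full audit of every donor decision."""

    completed: PhenotypeTable
    audit: pd.DataFrame  # noncompleter_id, donor_id, d, n_ties, imputed_slots
    weights: ImputationWeights
    constants: NormalizationConstants
    exam_years: tuple
    n_completers: int
    n_noncompleters: int

    def summary(self) -> str:
        lines = [
            "Nearest-completer imputation",
            f"  exam calendar years: {self.exam_years}",
            f"  completers: {self.n_completers}   non-completers: {self.n_noncompleters}",
            "  correlations over completers: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.weights.as_dict().items()
                        if k.startswith(("alpha", "beta"))),
            "  distance weights: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.weights.as_dict().items()
                        if k.startswith("w_")),
        ]
        if len(self.audit):
            lines.append(f"  median donor distance: {self.audit['d'].median():.4f}")
        return "\n".join(lines)


class HotDeckImputer:
    """Six-step nearest-completer imputer; ``fit()`` -> ImputationResult.

    ``same_sex_donors=True`` restricts each non-completer's candidate
    donors to completers of the same sex (off by default: the distance
    itself carries no sex term).
    """

    def __init__(self, pheno: PhenotypeTable, same_sex_donors: bool = False,
                 exam_years=None):
        self.pheno = pheno
        self.same_sex_donors = same_sex_donors
        self.exam_years = exam_years

    def fit(self) -> ImputationResult:
        pheno = self.pheno
        comp_mask, nonc_mask = extract_completers(pheno)

        years = tuple(self.exam_years) if self.exam_years else average_exam_years(pheno)
        # original presence (pre age fill) gates the distance terms
        orig_presence = {v: pheno.presence(v) for v in EXAM_VARS}
        aged = impute_ages(pheno, years)

        comp_tbl = PhenotypeTable(aged.df[comp_mask])
        nonc_tbl = PhenotypeTable(aged.df[nonc_mask])
        weights = compute_weights(comp_tbl)
        constants = compute_normalization(aged)

        audit_rows = []
        completed_df = aged.df.copy()
        if nonc_mask.any():
            nonc_presence = {v: orig_presence[v][nonc_mask] for v in EXAM_VARS}
            dmat = distance_matrix(nonc_tbl, comp_tbl, weights, constants,
                                   presence=nonc_presence)
            comp_ids = list(comp_tbl.ids)
            comp_order = sorted(range(len(comp_ids)), key=lambda j: comp_ids[j])
            comp_sex = comp_tbl.df["SEX"].to_numpy()
            nonc_idx = np.flatnonzero(nonc_mask)
            for r, row_idx in enumerate(nonc_idx):
                candidates = comp_order
                if self.same_sex_donors:
                    sex_r = aged.df.iloc[row_idx]["SEX"]
                    candidates = [j for j in comp_order if comp_sex[j] == sex_r]
                    if not candidates:
                        raise ValueError(
                            f"no same-sex donor for {aged.df.iloc[row_idx]['ID']}"
                        )
                dr = dmat[r]
                dmin = min(dr[j] for j in candidates)
                tied = [j for j in candidates if dr[j] == dmin]
                j_best = tied[0]
                donor_row = comp_tbl.df.iloc[j_best]
                filled_row, slots = transfer_values(aged.df.iloc[row_idx], donor_row)
                completed_df.iloc[row_idx] = filled_row
                audit_rows.append(
                    {
                        "noncompleter_id": aged.df.iloc[row_idx]["ID"],
                        "donor_id": comp_ids[j_best],
                        "d": float(dmin),
                        "n_ties": len(tied),
                        "imputed_slots": ";".join(slots),
                    }
                )
        audit = pd.DataFrame(
            audit_rows,
            columns=["noncompleter_id", "donor_id", "d", "n_ties", "imputed_slots"],
        )
        completed = PhenotypeTable(completed_df)
        assert not completed.df[
            [c for v in EXAM_VARS for c in exam_cols(v)]
        ].isna().any().any()
        return ImputationResult(
            completed=completed,
            audit=audit,
            weights=weights,
            constants=constants,
            exam_years=years,
            n_completers=int(comp_mask.sum()),
            n_noncompleters=int(nonc_mask.sum()),
        )

def impute_cohort(pheno: PhenotypeTable, **kwargs) -> ImputationResult:
    """Functional wrapper over :class:`HotDeckImputer`."""
    return HotDeckImputer(pheno, **kwargs).fit()


def mean_impute_sbp(pheno: PhenotypeTable) -> PhenotypeTable:
    """Benchmark baseline: fill missing SBP_i with the per-exam observed mean."""
    df = pheno.df.copy()
    for col in exam_cols("SBP"):
        df[col] = df[col].fillna(df[col].mean())
    return PhenotypeTable(df)
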