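"""Missing-data mechanism diagnostics for longitudinal SBP.

The diagnostic regresses baseline SBP on binary presence indicators of the
follow-up SBP measurements:

    SBP_0 = b0 + b1*x1 + b2*x2 + b3*x3 (+ c*AGE_0)

where x_i = 1 iff SBP at follow-up exam i was recorded. Under MCAR the
follow-up presence pattern carries no information about SBP_0, so the joint
nested-model F test of b1 = b2 = b3 = 0 should be null. A strong rejection
that disappears once baseline age enters the model is the classic signature
of MAR-via-age dropout: older participants both have higher baseline SBP
and miss more follow-ups.

The fit is restricted to individuals with SBP_0 observed (the outcome must
exist); baseline age is recovered from birth year when not directly
recorded, so the age-adjusted model never loses individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotypes import PhenotypeTable

MIN_EXTRA_OBS = 5  # required observations beyond the parameter count


@dataclass
class PresencePattern:
    """Follow-up SBP presence indicators for one individual."""

    individual_id: str
    x: tuple  # (x1, x2, x3)
    sbp_0_observed: bool


@dataclass
class MechanismReport:
    """Both fits of the diagnostic plus the MCAR/MAR verdict."""

    joint_p_unadjusted: float
    joint_p_age_adjusted: float
    params_unadjusted: pd.Series
    params_age_adjusted: pd.Series
    bse_unadjusted: pd.Series
    bse_age_adjusted: pd.Series
    f_unadjusted: float
    f_age_adjusted: float
    n_used: int
    dropped_indicators: list = field(default_factory=list)
    notes: list = field(default_factory=list)
    alpha: float = 0.05

    @property
    def verdict(self) -> str:
        pu, pa = self.joint_p_unadjusted, self.joint_p_age_adjusted
        if np.isnan(pu):
            return "consistent-with-MCAR"
        if pu < self.alpha and (np.isnan(pa) or pa >= self.alpha):
            return "MAR-suspected"
        return "consistent-with-MCAR"

    def summary(self) -> str:
        lines = [
            "Missing-data mechanism diagnostic (SBP_0 ~ follow-up presence)",
            f"  individuals used (SBP_0 observed): {self.n_used}",
            f"  joint F (unadjusted)   = {self.f_unadjusted:.4g}, "
            f"p = {self.joint_p_unadjusted:.4g}",
            f"  joint F (age-adjusted) = {self.f_age_adjusted:.4g}, "
            f"p = {self.joint_p_age_adjusted:.4g}",
            f"  verdict: {self.verdict}",
        ]
        if self.dropped_indicators:
            lines.append(f"  dropped constant indicators: {self.dropped_indicators}")
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "joint_p_unadjusted": self.joint_p_unadjusted,
            "joint_p_age_adjusted": self.joint_p_age_adjusted,
            "f_unadjusted": self.f_unadjusted,
            "f_age_adjusted": self.f_age_adjusted,
            "n_used": self.n_used,
            "verdict": self.verdict,
        }


def code_presence(pheno: PhenotypeTable) -> list[PresencePattern]:
    """Binary presence of follow-up SBP measurements, one pattern per individual."""
    pres = pheno.presence("SBP")
    return [
        PresencePattern(
            individual_id=pid,
            x=tuple(int(v) for v in pres[k, 1:]),
            sbp_0_observed=bool(pres[k, 0]),
        )
        for k, pid in enumerate(pheno.ids)
    ]


def _baseline_age(pheno: PhenotypeTable, exam_year_0: int | None = None) -> np.ndarray:
    """First-exam age; recovered from birth year where not recorded."""
    age0 = pheno.values("AGE")[:, 0].copy()
    missing = np.isnan(age0)
    if missing.any():
        if exam_year_0 is None:
            # average observed first-exam calendar year, rounded
            by = pheno.df["BIRTH_YEAR"].to_numpy(float)
            obs = ~np.isnan(pheno.values("AGE")[:, 0])
            if not obs.any():
                raise ValueError("AGE_0 never observed and no exam year supplied")
            exam_year_0 = int(round(np.mean(by[obs] + age0[obs])))
        age0[missing] = exam_year_0 - pheno.df["BIRTH_YEAR"].to_numpy(float)[missing]
    return age0


def _joint_f(fit_full, indicator_names):
    """Nested-model F for dropping all presence indicators, via the RSS identity."""
    contrast = np.zeros((len(indicator_names), len(fit_full.params)))
    for r, name in enumerate(indicator_names):
        contrast[r, list(fit_full.params.index).index(name)] = 1.0
    ft = fit_full.f_test(contrast)
    return float(np.squeeze(ft.fvalue)), float(ft.pvalue)


class MissingnessModel:
    """Diagnostic model over a phenotype table; ``fit()`` -> MechanismReport."""

    def __init__(self, pheno: PhenotypeTable, exam_year_0: int | None = None):
        self.pheno = pheno
        self.exam_year_0 = exam_year_0

    def fit(self, alpha: float = 0.05) -> MechanismReport:
        patterns = code_presence(self.pheno)
        sbp0 = self.pheno.values("SBP")[:, 0]
        keep = ~np.isnan(sbp0)
        x = np.array([p.x for p in patterns], dtype=float)[keep]
        y = sbp0[keep]
        age0 = _baseline_age(self.pheno, self.exam_year_0)[keep]

        names = ["x1", "x2", "x3"]
        dropped = [nm for j, nm in enumerate(names) if np.all(x[:, j] == x[0, j])]
        kept_names = [nm for nm in names if nm not in dropped]
        notes = []
        if dropped:
            warnings.warn(f"constant presence indicators dropped: {dropped}")
            notes.append(f"constant presence indicators dropped: {dropped}")

        n_params_full = 2 + len(kept_names)  # intercept + age + indicators
        if len(y) < n_params_full + MIN_EXTRA_OBS:
            raise ValueError(
                f"only {len(y)} individuals with SBP_0 observed; "
                f"need at least {n_params_full + MIN_EXTRA_OBS}"
            )

        def run(with_age: bool):
            cols = {"const": np.ones(len(y))}
            if with_age:
                cols["AGE0"] = age0
            for nm in kept_names:
                cols[nm] = x[:, names.index(nm)]
            X = pd.DataFrame(cols)
            fit = sm.OLS(y, X).fit()
            if kept_names:
                f, p = _joint_f(fit, kept_names)
            else:
                f, p = np.nan, np.nan
            return fit, f, p

        fit_u, f_u, p_u = run(with_age=False)
        fit_a, f_a, p_a = run(with_age=True)
        if not kept_names:
            warnings.warn("all presence indicators constant; joint p undefined")
            notes.append("all presence indicators constant; joint p undefined")

        return MechanismReport(
            joint_p_unadjusted=p_u,
            joint_p_age_adjusted=p_a,
            params_unadjusted=fit_u.params,
            params_age_adjusted=fit_a.params,
            bse_unadjusted=fit_u.bse,
            bse_age_adjusted=fit_a.bse,
            f_unadjusted=f_u,
            f_age_adjusted=f_a,
            n_used=len(y),
            dropped_indicators=dropped,
            notes=notes,
            alpha=alpha,
        )


def mcar_joint_test(pheno: PhenotypeTable, alpha: float = 0.05) -> MechanismReport:
    """Functional wrapper over :class:`MissingnessModel`."""
    return MissingnessModel(pheno).fit(alpha=alpha)
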