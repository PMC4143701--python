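"""Shared fixtures: worked-example records and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from longgwas.phenotypes import ALL_COLS, PhenotypeTable


def make_pheno(rows: list[dict]) -> PhenotypeTable:
    """Build a PhenotypeTable from partial row dicts (missing -> NaN)."""
    df = pd.DataFrame(rows)
    for c in ALL_COLS:
        if c not in df.columns:
            df[c] = np.nan
    return PhenotypeTable(df[ALL_COLS])


def _exam_row(id_, sex, birth_year, age, sbp, med, smk):
    row = {"ID": id_, "SEX": sex, "BIRTH_YEAR": birth_year}
    for var, vals in (("AGE", age), ("SBP", sbp), ("MED", med), ("SMK", smk)):
        for i, v in enumerate(vals):
            row[f"{var}{i}"] = np.nan if v is None else float(v)
    return row


# Worked imputation example: one non-completer with SBP/MED/SMK recorded only
# at the middle two exams, plus five fully recorded candidate donors with
# their known distances to the non-completer.
NONCOMPLETER_ID = "T2DG2501049"
DONOR_ID = "T2DG0300150"
DONOR_DISTANCE = 0.072
CANDIDATE_DISTANCES = {
    "T2DG0300150": 0.072,
    "T2DG1700856": 0.108,
    "T2DG0600470": 0.268,
    "T2DG0300165": 18.105,
    "T2DG0600450": 21.673,
}


@pytest.fixture
def worked_noncompleter_row() -> pd.Series:
    row = _exam_row(
        NONCOMPLETER_ID, 0, 1954,
        age=[None, 45, 50, None],
        sbp=[None, 125, 139, None],
        med=[None, 0, 0, None],
        smk=[None, 0, 0, None],
    )
    return make_pheno([row]).df.iloc[0]


@pytest.fixture
def worked_donor_row() -> pd.Series:
    row = _exam_row(
        DONOR_ID, 0, 1958,
        age=[35, 41, 45, 51],
        sbp=[110, 121, 135, 149],
        med=[0, 0, 0, 1],
        smk=[0, 0, 0, 0],
    )
    return make_pheno([row]).df.iloc[0]


@pytest.fixture
def worked_completers() -> PhenotypeTable:
    rows = [
        _exam_row("T2DG0300150", 0, 1958, [35, 41, 45, 51], [110, 121, 135, 149],
                  [0, 0, 0, 1], [0, 0, 0, 0]),
        _exam_row("T2DG1700856", 0, 1960, [33, 38, 43, 50], [110, 123, 130, 132],
                  [0, 0, 0, 1], [0, 0, 0, 0]),
        _exam_row("T2DG0600470", 1, 1950, [43, 46, 51, 58], [133, 127, 131, 185],
                  [0, 0, 0, 0], [1, 1, 0, 1]),
        _exam_row("T2DG0300165", 1, 1943, [50, 57, 61, 66], [151, 175, 176, 139],
                  [0, 0, 0, 1], [0, 0, 0, 0]),
        _exam_row("T2DG0600450", 0, 1945, [48, 53, 61, 65], [136, 190, 128, 130],
                  [0, 1, 1, 1], [1, 0, 0, 0]),
    ]
    return make_pheno(rows)


@pytest.fixture
def small_complete_pheno() -> PhenotypeTable:
    """Deterministic 8-individual complete table for arithmetic tests."""
    rng = np.random.default_rng(42)
    rows = []
    for k in range(8):
        age0 = int(rng.integers(30, 60))
        ages = [age0, age0 + 5, age0 + 10, age0 + 16]
        sbps = list(np.round(rng.normal(125, 12, 4), 1))
        rows.append(
            _exam_row(f"P{k:03d}", int(rng.integers(0, 2)), 1993 - age0,
                      ages, sbps,
                      list(rng.integers(0, 2, 4)), list(rng.integers(0, 2, 4)))
        )
    return make_pheno(rows)
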