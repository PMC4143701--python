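"""Longitudinal phenotype table: per-individual exam records with missingness.

The canonical layout is one row per individual with columns

    ID, SEX, BIRTH_YEAR, AGE0..AGE3, SBP0..SBP3, MED0..MED3, SMK0..SMK3

where exam-level values may be missing (``NaN`` in memory, ``NA`` on disk).
``ID``, ``SEX`` and ``BIRTH_YEAR`` are never missing: sex and birth year are
registry-level facts, not exam measurements.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_EXAMS = 4
EXAM_VARS = ("AGE", "SBP", "MED", "SMK")
NA_TOKEN = "NA"


def exam_cols(var: str) -> list[str]:
    """Column names of one exam-level variable, e.g. ``SBP0..SBP3``."""
    return [f"{var}{i}" for i in range(N_EXAMS)]


ALL_EXAM_COLS = [c for v in EXAM_VARS for c in exam_cols(v)]
META_COLS = ["ID", "SEX", "BIRTH_YEAR"]
ALL_COLS = META_COLS + ALL_EXAM_COLS


@dataclass
class LongitudinalRecord:
    """One individual's per-exam phenotype values plus presence mask.

    Missing exam values are ``None``. ``age``, ``sbp``, ``med``, ``smk``
    each hold one entry per exam wave.
    """

    individual_id: str
    sex: int
    birth_year: int
    age: list = field(default_factory=lambda: [None] * N_EXAMS)
    sbp: list = field(default_factory=lambda: [None] * N_EXAMS)
    med: list = field(default_factory=lambda: [None] * N_EXAMS)
    smk: list = field(default_factory=lambda: [None] * N_EXAMS)

    def values(self, var: str) -> list:
        return getattr(self, var.lower())

    def present(self, var: str, i: int) -> bool:
        v = self.values(var)[i]
        return v is not None and not (isinstance(v, float) and np.isnan(v))

    def is_complete(self) -> bool:
        return all(self.present(v, i) for v in EXAM_VARS for i in range(N_EXAMS))


class PhenotypeTable:
    """Wrapper around the canonical phenotype DataFrame with validation and IO."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in ALL_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")
        df = df.loc[:, ALL_COLS].copy()
        df["ID"] = df["ID"].astype(str)
        if df["ID"].duplicated().any():
            raise ValueError("duplicate individual IDs")
        if df[["SEX", "BIRTH_YEAR"]].isna().any().any():
            raise ValueError("SEX and BIRTH_YEAR must never be missing")
        for c in ALL_EXAM_COLS:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        self.df = df.reset_index(drop=True)

    # ------------------------------------------------------------------ basics
    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["ID"]

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(self.df.copy())

    def presence(self, var: str) -> np.ndarray:
        """Boolean (n, 4) mask: value of `var` observed at each exam."""
        return self.df[exam_cols(var)].notna().to_numpy()

    def values(self, var: str) -> np.ndarray:
        """Float (n, 4) matrix of `var`, NaN where missing."""
        return self.df[exam_cols(var)].to_numpy(dtype=float)

    def completer_mask(self) -> np.ndarray:
        """True for individuals with every AGE/SBP/MED/SMK value at all exams."""
        m = np.ones(len(self.df), dtype=bool)
        for v in EXAM_VARS:
            m &= self.presence(v).all(axis=1)
        return m

    def records(self) -> list[LongitudinalRecord]:
        out = []
        for _, row in self.df.iterrows():
            rec = LongitudinalRecord(
                individual_id=row["ID"],
                sex=int(row["SEX"]),
                birth_year=int(row["BIRTH_YEAR"]),
            )
            for var in EXAM_VARS:
                vals = [
                    None if pd.isna(row[f"{var}{i}"]) else float(row[f"{var}{i}"])
                    for i in range(N_EXAMS)
                ]
                setattr(rec, var.lower(), vals)
            out.append(rec)
        return out

    @classmethod
    def from_records(cls, records: list[LongitudinalRecord]) -> "PhenotypeTable":
        rows = []
        for r in records:
            row = {"ID": r.individual_id, "SEX": r.sex, "BIRTH_YEAR": r.birth_year}
            for var in EXAM_VARS:
                for i, v in enumerate(r.values(var)):
                    row[f"{var}{i}"] = np.nan if v is None else v
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=ALL_COLS))

    # ---------------------------------------------------------------------- IO
    def to_file(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)

    @classmethod
    def from_file(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], dtype={"ID": str})
        return cls(df)

    def to_string(self) -> str:
        buf = io.StringIO()
        self.to_file(buf)
        return buf.getvalue()
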