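"""Clinical table: survival time, event indicator and staging covariates.

Stage, node and grade are carried as the categorical values recorded by
pathology and encoded to binaries the way lung-adenocarcinoma prognosis
studies conventionally dichotomize them: T1-2 vs T3-4, N0 vs N1-2, and
low grade (1) vs intermediate/high grade (2-3).  Unknown entries stay NaN
and are excluded per-model downstream (complete-case).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["patient_id", "time_months", "event", "t_stage", "n_stage", "grade"]

_T_HIGH = {"T3", "T4"}
_T_LOW = {"T1", "T2"}
_N_POS = {"N1", "N2"}
_N_NEG = {"N0"}
_G_HIGH = {"2", "3"}
_G_LOW = {"1"}


class ClinicalTable:
    """Per-patient survival outcome plus binary-encodable covariates."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        df = df.copy()
        df["patient_id"] = df["patient_id"].astype(str)
        if df["patient_id"].duplicated().any():
            raise ValueError("duplicate patient ids in clinical table")
        df["time_months"] = pd.to_numeric(df["time_months"])
        df["event"] = pd.to_numeric(df["event"])
        if (df["time_months"] < 0).any():
            raise ValueError("survival times must be >= 0")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be binary (0=censored, 1=death)")
        self.df = df.reset_index(drop=True)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.df["patient_id"])

    @property
    def time(self) -> np.ndarray:
        return self.df["time_months"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(int)

    def __len__(self) -> int:
        return len(self.df)

    # -- binary encodings ------------------------------------------------
    @staticmethod
    def _encode(values: pd.Series, high: set, low: set) -> pd.Series:
        s = values.astype("string").str.strip().str.upper()
        out = pd.Series(np.nan, index=s.index, dtype=float)
        out[s.isin({v.upper() for v in high})] = 1.0
        out[s.isin({v.upper() for v in low})] = 0.0
        return out

    def t_binary(self) -> pd.Series:
        """1 for T3-T4, 0 for T1-T2, NaN unknown."""
        return self._encode(self.df["t_stage"], _T_HIGH, _T_LOW)

    def n_binary(self) -> pd.Series:
        """1 for node involvement (N1-N2), 0 for N0, NaN unknown."""
        return self._encode(self.df["n_stage"], _N_POS, _N_NEG)

    def grade_binary(self) -> pd.Series:
        """1 for intermediate/high grade (2-3), 0 for low grade (1)."""
        return self._encode(self.df["grade"].astype(str), _G_HIGH, _G_LOW)

    # -- IO ---------------------------------------------------------------
    @classmethod
    def read(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, dtype={"t_stage": str, "n_stage": str, "grade": str})
        return cls(df)

    def write(self, path) -> None:
        self.df.to_csv(path, index=False)
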