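"""Core in-memory containers: the matched-triplet cohort and the clinical table.

A cohort couples a proteins x samples matrix of log2(L/H) SILAC ratios with a
per-sample metadata table.  Samples carry a ``role`` — tumor-adjacent normal,
pre-treatment tumor, post-treatment tumor, or healthy-duct reference — and a
``patient_id`` linking the three matched samples of one patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortStructureError, DataFormatError

ROLE_NORMAL = "normal"
ROLE_PRE = "pre"
ROLE_POST = "post"
ROLE_HEALTHY = "healthy"
TRIPLET_ROLES = (ROLE_NORMAL, ROLE_PRE, ROLE_POST)
ALL_ROLES = TRIPLET_ROLES + (ROLE_HEALTHY,)

#: columns a clinical table must provide
CLINICAL_REQUIRED = (
    "patient_id",
    "mp_score",
    "relapse",
    "death",
    "rfs_years",
    "os_years",
    "grade",
    "ki67",
    "tumor_size",
    "age",
    "subtype",
)


@dataclass
class Cohort:
    """Protein abundance matrix plus per-sample metadata.

    Parameters
    ----------
    matrix
        proteins x samples frame of log2(L/H) values; NaN marks a missing
        quantification.
    sample_meta
        One row per sample with columns ``sample_id``, ``patient_id``,
        ``role`` and ``batch``; row order defines the column order of
        ``matrix``.
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.sample_meta
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        self.sample_meta = meta
        if not self.matrix.index.is_unique:
            dups = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise DataFormatError(f"duplicate protein IDs: {list(dups)[:5]}")
        if list(self.matrix.columns) != list(self.sample_meta.index):
            raise CohortStructureError(
                "matrix columns do not match sample_meta order"
            )
        bad = set(self.sample_meta["role"]) - set(ALL_ROLES)
        if bad:
            raise CohortStructureError(f"unknown sample roles: {sorted(bad)}")
        trip = self.sample_meta[self.sample_meta["role"].isin(TRIPLET_ROLES)]
        dup = trip.duplicated(subset=["patient_id", "role"])
        if dup.any():
            raise CohortStructureError(
                "duplicated (patient_id, role) pairs: "
                f"{trip.index[dup].tolist()}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def n_proteins(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def patients(self) -> list[str]:
        """Patient IDs that own at least one triplet-role sample, in order."""
        trip = self.sample_meta[self.sample_meta["role"].isin(TRIPLET_ROLES)]
        return list(dict.fromkeys(trip["patient_id"]))

    def triplet_patients(self) -> list[str]:
        """Patients with a complete (normal, pre, post) sample triplet."""
        out = []
        for pid in self.patients():
            roles = set(
                self.sample_meta.loc[
                    self.sample_meta["patient_id"] == pid, "role"
                ]
            )
            if set(TRIPLET_ROLES) <= roles:
                out.append(pid)
        return out

    def sample_for(self, patient_id: str, role: str) -> str:
        meta = self.sample_meta
        hit = meta.index[
            (meta["patient_id"] == patient_id) & (meta["role"] == role)
        ]
        if len(hit) != 1:
            raise CohortStructureError(
                f"patient {patient_id!r} lacks a unique {role!r} sample"
            )
        return hit[0]

    def role_matrix(self, role: str, patients: list[str] | None = None) -> pd.DataFrame:
        """proteins x patients slice holding one role, columns renamed to patients."""
        if patients is None:
            patients = self.triplet_patients()
        cols = [self.sample_for(p, role) for p in patients]
        out = self.matrix[cols].copy()
        out.columns = patients
        return out

    def subset_roles(self, roles: tuple[str, ...]) -> "Cohort":
        keep = self.sample_meta["role"].isin(roles)
        meta = self.sample_meta[keep]
        return Cohort(self.matrix[meta.index.tolist()].copy(), meta.copy())

    def copy(self) -> "Cohort":
        return Cohort(self.matrix.copy(), self.sample_meta.copy())


@dataclass
class ClinicalTable:
    """Validated one-row-per-patient clinical record.

    Miller & Payne (M&P) pathological response scores run 1-4 here; the full
    responders (score 5) are excluded from the cohort by design, so a 5 is
    rejected as out of range.
    """

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        df = self.data
        if "patient_id" in df.columns:
            df = df.set_index("patient_id")
        missing = [
            c for c in CLINICAL_REQUIRED if c != "patient_id" and c not in df.columns
        ]
        if missing:
            raise DataFormatError(f"clinical table missing columns: {missing}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicated patient_id: {dups}")
        mp = df["mp_score"].astype(int)
        if ((mp < 1) | (mp > 4)).any():
            bad = df.index[(mp < 1) | (mp > 4)].tolist()
            raise DataFormatError(
                f"mp_score outside 1-4 for patients {bad} "
                "(full responders, score 5, are outside this cohort)"
            )
        for col, lo, hi in (("grade", 1, 3), ("ki67", 1, 3), ("tumor_size", 1, 4)):
            v = df[col].astype(int)
            if ((v < lo) | (v > hi)).any():
                raise DataFormatError(f"{col} outside [{lo}, {hi}]")
        if (df["rfs_years"] < 0).any() or (df["os_years"] < 0).any():
            raise DataFormatError("negative survival time")
        if (df["rfs_years"] > df["os_years"] + 1e-9).any():
            bad = df.index[df["rfs_years"] > df["os_years"] + 1e-9].tolist()
            raise DataFormatError(f"rfs_years > os_years for patients {bad}")
        for col in ("relapse", "death"):
            v = df[col].astype(int)
            if (~v.isin([0, 1])).any():
                raise DataFormatError(f"{col} must be binary 0/1")
        self.data = df

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def aligned(self, patients: list[str]) -> pd.DataFrame:
        missing = [p for p in patients if p not in self.data.index]
        if missing:
            raise CohortStructureError(f"patients absent from clinical table: {missing}")
        return self.data.loc[patients]


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """z-score each row (protein) across samples; constant rows become NaN."""
    vals = matrix.to_numpy(dtype=float)
    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mu) / sd
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
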