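"""Reading/writing cohort tables and the preprocessing rules.

File dialects
-------------
* ratio matrix: TSV, first column protein ID, header row of sample IDs,
  values positive H/L ratios, blank = missing, ``#`` lines are comments.
  In memory the values are stored as log2(L/H) = -log2(H/L).
* sample metadata: TSV with sample_id, patient_id, role, batch.
* clinical table: CSV (or TSV) with the columns of
  :data:`triprot.cohort.CLINICAL_REQUIRED`.

Preprocessing follows the matched-triplet conventions: patient-wise 2-of-3
filtering with left-shifted single-value imputation (downshift 1.2 SD,
width 0.3 SD of the sample column), a 70% valid-values filter across
samples, and batch correction by removing one principal component of the
sample-space PCA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, Cohort, TRIPLET_ROLES
from .errors import (
    CohortStructureError,
    ConfigurationError,
    DataFormatError,
)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_ratio_table(path, orientation: str = "proteins_in_rows",
                     sample_meta: pd.DataFrame | None = None) -> Cohort | pd.DataFrame:
    """Read an H/L ratio matrix; values become log2(L/H) = -log2(H/L).

    With ``sample_meta`` given, returns a :class:`Cohort`; otherwise the bare
    log2 matrix (proteins x samples).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "proteins_in_rows":
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate protein IDs: {dups[:5]}")
    vals = df.to_numpy(dtype=float)
    bad = np.where(np.isfinite(vals) & (vals <= 0))
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise DataFormatError(
            f"non-positive H/L ratio at protein {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    log2lh = pd.DataFrame(-np.log2(vals), index=df.index, columns=df.columns)
    if sample_meta is not None:
        return Cohort(log2lh, sample_meta)
    return log2lh


def write_ratio_table(matrix_or_cohort, path) -> None:
    """Write log2(L/H) values back out as H/L ratios (blank = missing)."""
    matrix = getattr(matrix_or_cohort, "matrix", matrix_or_cohort)
    hl = 2.0 ** (-matrix)
    hl.to_csv(path, sep="\t", float_format="%.8g", na_rep="")


def read_sample_meta(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    meta = pd.read_csv(path, sep=sep, comment="#")
    required = {"sample_id", "patient_id", "role", "batch"}
    missing = required - set(meta.columns)
    if missing:
        raise DataFormatError(f"sample metadata missing columns: {sorted(missing)}")
    return meta


def read_clinical(path) -> ClinicalTable:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return ClinicalTable(pd.read_csv(path, sep=sep, comment="#"))


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, float_format="%.8g")


def read_edge_list(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t", comment="#", header=None,
                        names=["node_a", "node_b"], dtype=str)
    return edges


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def triplet_filter_impute(
    cohort: Cohort,
    min_valid: int = 2,
    width: float = 0.3,
    downshift: float = 1.2,
    seed: int = 0,
) -> Cohort:
    """Patient-wise 2-of-3 filtering with downshifted single-value imputation.

    For each protein within each patient's (normal, pre, post) triplet: if
    fewer than ``min_valid`` of the three values are quantified, all three
    are dropped for that patient; if exactly one is missing it is drawn from
    ``N(mu - downshift * sigma, (width * sigma)^2)`` where mu, sigma are the
    observed mean and SD of the sample column holding the gap — the
    left-shifted normal convention for values missing because the protein
    fell below detection.

    Observed values are never altered.  Healthy-duct samples are left
    untouched (they have no triplet).
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    mat = out.matrix
    patients = out.patients()
    for pid in patients:
        roles = set(out.sample_meta.loc[out.sample_meta["patient_id"] == pid, "role"])
        lacking = set(TRIPLET_ROLES) - roles
        if lacking:
            raise CohortStructureError(
                f"patient {pid!r} lacks roles {sorted(lacking)}"
            )
    # column stats over observed values, fixed before any imputation
    col_mu = mat.mean(axis=0, skipna=True)
    col_sd = mat.std(axis=0, ddof=1, skipna=True)

    for pid in patients:
        cols = [out.sample_for(pid, role) for role in TRIPLET_ROLES]
        block = mat[cols].to_numpy(dtype=float)
        n_valid = np.isfinite(block).sum(axis=1)
        block[n_valid < min_valid] = np.nan
        one_missing = n_valid == 2
        for j, col in enumerate(cols):
            rows = one_missing & ~np.isfinite(block[:, j])
            k = int(rows.sum())
            if k:
                mu, sd = col_mu[col], col_sd[col]
                block[rows, j] = rng.normal(mu - downshift * sd, width * sd, size=k)
        mat[cols] = block
    return out


def valid_fraction_filter(cohort_or_matrix, min_frac: float = 0.7):
    """Keep proteins quantified in at least ``min_frac`` of samples (inclusive)."""
    if not 0.0 < min_frac <= 1.0:
        raise ConfigurationError("min_frac must lie in (0, 1]")
    matrix = getattr(cohort_or_matrix, "matrix", cohort_or_matrix)
    frac = matrix.notna().mean(axis=1)
    # guard against float representation of e.g. 70/100 vs 0.7
    keep = frac.to_numpy() >= min_frac - 1e-12
    if isinstance(cohort_or_matrix, Cohort):
        out = cohort_or_matrix.copy()
        out.matrix = out.matrix.loc[keep]
        return out
    return matrix.loc[keep]


def pca_batch_correct(cohort_or_matrix, component: int = 3):
    """Remove one sample-space principal component (batch-effect correction).

    Samples are observations and proteins variables: the matrix is
    transposed, each protein is mean-centered, the rank-1 contribution of
    the requested component (1-indexed) is subtracted via SVD, and the means
    are restored.  The projection of the corrected data on the removed
    direction is zero.
    """
    matrix = getattr(cohort_or_matrix, "matrix", cohort_or_matrix)
    if matrix.isna().any().any():
        raise CohortStructureError("PCA correction requires a complete matrix")
    X = matrix.to_numpy(dtype=float).T  # samples x proteins
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if component < 1 or component > len(s):
        raise ConfigurationError(
            f"component {component} outside rank {len(s)}"
        )
    k = component - 1
    Xc_corr = Xc - s[k] * np.outer(U[:, k], Vt[k])
    corrected = pd.DataFrame(
        (Xc_corr + mu).T, index=matrix.index, columns=matrix.columns
    )
    if isinstance(cohort_or_matrix, Cohort):
        out = cohort_or_matrix.copy()
        out.matrix = corrected
        return out
    return corrected


def normal_vs_healthy_contrast(cohort: Cohort) -> pd.DataFrame:
    """Welch t-test per protein between adjacent-normal and healthy-duct samples.

    Utility for checking that healthy reference tissue is exchangeable with
    tumor-adjacent normal tissue; returns per-protein t, p and BH q.
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    meta = cohort.sample_meta
    normal_cols = meta.index[meta["role"] == "normal"].tolist()
    healthy_cols = meta.index[meta["role"] == "healthy"].tolist()
    if len(normal_cols) < 2 or len(healthy_cols) < 2:
        raise CohortStructureError("need >= 2 samples per group")
    a = cohort.matrix[normal_cols].to_numpy(dtype=float)
    b = cohort.matrix[healthy_cols].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    out = pd.DataFrame({"t": t, "p": p}, index=cohort.protein_ids)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
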