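"""Signed weighted co-expression modules, eigengenes, and trait statistics.

The signed adjacency between two proteins is ((1 + r) / 2) ** beta with r
the Pearson correlation of their profiles and beta the soft-thresholding
power (default 10).  Modules are average-linkage clusters of the
topological-overlap (or raw adjacency) dissimilarity, cut at a fixed
height; each module is summarised by its eigengene — the first principal
component of the standardized member profiles in sample space — which is
then correlated with clinical traits.  Gene significance (GS) is the
correlation of a protein with a trait; module membership (MM) its
correlation with the own module's eigengene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy import stats

from .cohort import standardize_rows
from .errors import ConfigurationError, DegenerateDataError

UNASSIGNED = "unassigned"
DEFAULT_BETA = 10.0


def signed_adjacency(matrix: pd.DataFrame, beta: float = DEFAULT_BETA) -> pd.DataFrame:
    """Signed network adjacency a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta."""
    if beta <= 0:
        raise ConfigurationError("beta must be positive")
    if matrix.shape[1] < 3:
        raise DegenerateDataError("need at least 3 samples")
    if matrix.isna().any().any():
        raise DegenerateDataError("adjacency requires a complete matrix")
    vals = matrix.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = matrix.index[sd == 0].tolist()
        raise DegenerateDataError(f"constant proteins have undefined correlation: {bad[:5]}")
    r = np.corrcoef(vals)
    adj = ((1.0 + np.clip(r, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    k the connectivity (row sum excluding the diagonal); TOM_ii = 1.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


@dataclass
class ModuleSet:
    """Protein -> module assignment with the parameters that produced it."""

    labels: pd.Series  # protein_id -> module name ("unassigned" allowed)
    beta: float
    min_module_size: int
    cut_height: float

    def members(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()

    @property
    def module_names(self) -> list[str]:
        return sorted(
            set(self.labels) - {UNASSIGNED},
            key=lambda m: (-(self.labels == m).sum(), m),
        )


def detect_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 20,
    cut_height: float = 0.95,
    beta: float = DEFAULT_BETA,
) -> ModuleSet:
    """Average-linkage clustering of a dissimilarity, static cut.

    Clusters smaller than ``min_module_size`` are relabelled "unassigned".
    Module names M1, M2, ... are ordered by decreasing size with a
    lexicographic tie-break on members, so labels do not depend on protein
    input order.
    """
    D = dissimilarity.to_numpy(dtype=float)
    D = np.clip((D + D.T) / 2.0, 0.0, None)  # enforce symmetry
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    index = dissimilarity.index
    clusters: dict[int, list[str]] = {}
    for pid, c in zip(index, raw):
        clusters.setdefault(int(c), []).append(pid)
    kept = [
        sorted(members)
        for members in clusters.values()
        if len(members) >= min_module_size
    ]
    kept.sort(key=lambda m: (-len(m), m))
    labels = pd.Series(UNASSIGNED, index=index, name="module", dtype=object)
    for rank, members in enumerate(kept, start=1):
        labels[members] = f"M{rank}"
    return ModuleSet(labels=labels, beta=beta,
                     min_module_size=min_module_size, cut_height=cut_height)


@dataclass
class Eigengenes:
    """Per-module sample-space summary vectors."""

    vectors: pd.DataFrame  # samples x modules, each column unit-norm
    variance_explained: pd.Series  # module -> fraction in (0, 1]


def module_eigengene(matrix: pd.DataFrame, member_ids: list[str]) -> tuple[pd.Series, float]:
    """First principal component of the standardized member profiles.

    Returns the unit-norm sample-space vector, sign-aligned so it correlates
    non-negatively with the mean member profile, and the fraction of
    variance it explains.
    """
    if len(member_ids) < 2:
        raise DegenerateDataError("a module needs at least 2 members")
    if matrix.shape[1] < 2:
        raise DegenerateDataError("need at least 2 samples")
    X = standardize_rows(matrix.loc[member_ids]).to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DegenerateDataError("constant or missing member profiles")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    vec = Vt[0]
    mean_profile = X.mean(axis=0)
    if float(vec @ mean_profile) < 0:
        vec = -vec
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return pd.Series(vec, index=matrix.columns, name="eigengene"), var_explained


def compute_eigengenes(matrix: pd.DataFrame, modules: ModuleSet) -> Eigengenes:
    vectors = {}
    var = {}
    for name in modules.module_names:
        vec, ve = module_eigengene(matrix, modules.members(name))
        vectors[name] = vec
        var[name] = ve
    return Eigengenes(
        vectors=pd.DataFrame(vectors),
        variance_explained=pd.Series(var, name="variance_explained"),
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def module_trait_correlation(
    eigengenes: Eigengenes, clinical, traits: list[str]
) -> pd.DataFrame:
    """Pearson r (and t-approximation p) of each eigengene with each trait.

    Traits must be numeric or 0/1-coded; ordinal scores enter as integers.
    Rows are (module, trait) pairs.
    """
    vec = eigengenes.vectors
    if vec.shape[0] < 4:
        raise DegenerateDataError("need at least 4 samples/patients")
    data = clinical.data if hasattr(clinical, "data") else clinical
    data = data.loc[vec.index]
    rows = []
    for trait in traits:
        y = data[trait].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            warnings.warn(f"trait {trait!r} is constant; correlation undefined")
            for module in vec.columns:
                rows.append((module, trait, np.nan, np.nan))
            continue
        for module in vec.columns:
            r, p = _pearson_with_p(vec[module].to_numpy(), y)
            rows.append((module, trait, r, p))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p"])


def gene_significance_and_membership(
    matrix: pd.DataFrame,
    modules: ModuleSet,
    eigengenes: Eigengenes,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-protein GS (correlation with trait) and MM (with own eigengene)."""
    y = trait.loc[matrix.columns].to_numpy(dtype=float)
    rows = []
    for pid in matrix.index:
        x = matrix.loc[pid].to_numpy(dtype=float)
        module = modules.labels[pid]
        if np.std(x) == 0:
            rows.append((pid, module, np.nan, np.nan))
            continue
        gs = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else np.nan
        if module != UNASSIGNED and module in eigengenes.vectors.columns:
            mm = float(np.corrcoef(x, eigengenes.vectors[module].to_numpy())[0, 1])
        else:
            mm = np.nan
        rows.append((pid, module, gs, mm))
    return pd.DataFrame(
        rows, columns=["protein_id", "module", "GS", "MM"]
    ).set_index("protein_id")
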