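"""Sample clustering with multiscale-bootstrap support and co-clustering calls.

Samples are clustered with 1 - Spearman correlation as the distance and
average linkage.  Cluster support is assessed by multiscale bootstrap:
proteins (rows) are resampled at several scale factors r, the tree is
rebuilt, and the per-node bootstrap probability BP_r (fraction of bootstrap
trees containing the identical leaf set) is recorded.  Fitting
z_r = Phi^-1(1 - BP_r) against (sqrt(r), 1/sqrt(r)) by weighted least
squares gives the signed-distance and curvature coefficients (v, c) and the
approximately unbiased support AU = 1 - Phi(v - c).

A patient's matched pre- and post-treatment samples "co-cluster" when the
smallest internal node containing both has AU at or above the threshold
(default 0.95, i.e. P < 0.05 that the cluster is a resampling artifact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, DegenerateDataError

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


def _spearman_distance(values: np.ndarray, strict: bool = True) -> np.ndarray:
    """1 - Spearman rho between columns; square matrix."""
    sd = values.std(axis=0)
    if strict and (sd == 0).any():
        raise DegenerateDataError(
            f"constant sample column(s) at positions {np.where(sd == 0)[0].tolist()}"
        )
    ranks = stats.rankdata(values, axis=0)
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.nan_to_num(rho, nan=0.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _node_sets(Z: np.ndarray, n_leaves: int) -> list[frozenset[int]]:
    """Leaf-index set of every internal node, in merge order."""
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for i, (a, b, _, _) in enumerate(Z):
        merged = sets[int(a)] | sets[int(b)]
        sets[n_leaves + i] = merged
        out.append(merged)
    return out


def correlation_dendrogram(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over sample columns, Spearman-correlation distance.

    Returns the scipy linkage matrix and the leaf labels (sample IDs).
    """
    if matrix.shape[1] < 3:
        raise DegenerateDataError("need at least 3 samples")
    D = _spearman_distance(matrix.to_numpy(dtype=float))
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, list(matrix.columns)


@dataclass
class DendrogramSupport:
    """Observed tree plus per-node multiscale bootstrap support."""

    linkage: np.ndarray
    labels: list[str]
    node_sets: list[frozenset[int]] = field(repr=False)
    bp: np.ndarray  # nodes x scales
    au: np.ndarray  # per node
    v: np.ndarray
    c: np.ndarray
    degenerate: np.ndarray  # bool per node: BP pinned at 0 or 1 everywhere
    scales: tuple[float, ...]
    n_boot: int
    seed: int

    def bp_at_unit_scale(self) -> np.ndarray:
        k = int(np.argmin(np.abs(np.asarray(self.scales) - 1.0)))
        return self.bp[:, k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "members": [
                ";".join(sorted(self.labels[i] for i in s)) for s in self.node_sets
            ],
            "size": [len(s) for s in self.node_sets],
            "au": self.au,
            "bp": self.bp_at_unit_scale(),
            "v": self.v,
            "c": self.c,
            "degenerate_fit": self.degenerate,
        })


def _fit_au(bp_row: np.ndarray, scales: np.ndarray, n_boot: int
            ) -> tuple[float, float, float, bool]:
    """(au, v, c, degenerate) from per-scale bootstrap probabilities."""
    eps = 1.0 / (2.0 * n_boot)
    if (bp_row >= 1.0).all():
        return 1.0, np.nan, np.nan, True
    if (bp_row <= 0.0).all():
        return 0.0, np.nan, np.nan, True
    bp = np.clip(bp_row, eps, 1.0 - eps)
    z = stats.norm.ppf(1.0 - bp)
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    w = n_boot * stats.norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    Xw = X * w[:, None]
    try:
        coef = np.linalg.solve(Xw.T @ X, Xw.T @ z)
    except np.linalg.LinAlgError:
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - stats.norm.cdf(v - c))
    return au, v, c, False


def multiscale_bootstrap(
    matrix: pd.DataFrame,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot: int = 1000,
    seed: int = 0,
) -> DendrogramSupport:
    """Multiscale bootstrap support for the sample dendrogram.

    At each scale r, ``n_boot`` resamples of ceil(r * n_proteins) rows (with
    replacement) are drawn, the tree is rebuilt, and each observed node's BP
    is the fraction of bootstrap trees containing its exact leaf set.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be at least 100 per scale")
    Z, labels = correlation_dendrogram(matrix)
    n = len(labels)
    node_sets = _node_sets(Z, n)
    vals = matrix.to_numpy(dtype=float)
    n_prot = vals.shape[0]
    rng = np.random.default_rng(seed)
    scales_arr = np.asarray(scales, dtype=float)
    bp = np.zeros((len(node_sets), len(scales_arr)))
    for si, r in enumerate(scales_arr):
        m = max(3, int(np.ceil(r * n_prot)))
        counts = np.zeros(len(node_sets))
        for _ in range(n_boot):
            idx = rng.integers(0, n_prot, size=m)
            D = _spearman_distance(vals[idx], strict=False)
            Zb = linkage(squareform(D, checks=False), method="average")
            boot_sets = set(_node_sets(Zb, n))
            for ni, s in enumerate(node_sets):
                if s in boot_sets:
                    counts[ni] += 1
        bp[:, si] = counts / n_boot

    au = np.zeros(len(node_sets))
    v = np.zeros(len(node_sets))
    c = np.zeros(len(node_sets))
    degenerate = np.zeros(len(node_sets), dtype=bool)
    for ni in range(len(node_sets)):
        au[ni], v[ni], c[ni], degenerate[ni] = _fit_au(bp[ni], scales_arr, n_boot)
    return DendrogramSupport(
        linkage=Z, labels=labels, node_sets=node_sets, bp=bp, au=au,
        v=v, c=c, degenerate=degenerate, scales=tuple(scales_arr),
        n_boot=n_boot, seed=seed,
    )


def cocluster_pairs(
    support: DendrogramSupport,
    sample_meta: pd.DataFrame,
    au_threshold: float = 0.95,
) -> pd.DataFrame:
    """Per-patient co-clustering call for matched pre/post tumor samples.

    The supporting node is the smallest internal node containing both
    samples; the call is positive when its AU meets the threshold.  A pair
    whose smallest joint node is the root never co-clusters: the root holds
    every leaf in every bootstrap tree, so its support is vacuous.  Patients
    lacking a pre or post leaf get an NA call.
    """
    meta = sample_meta
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    pos = {s: i for i, s in enumerate(support.labels)}
    rows = []
    patients = list(dict.fromkeys(
        meta.loc[meta["role"].isin(["pre", "post"]), "patient_id"]
    ))
    for pid in patients:
        sub = meta[meta["patient_id"] == pid]
        pre = sub.index[sub["role"] == "pre"]
        post = sub.index[sub["role"] == "post"]
        if len(pre) != 1 or len(post) != 1 or pre[0] not in pos or post[0] not in pos:
            rows.append((pid, pd.NA, np.nan, np.nan))
            continue
        a, b = pos[pre[0]], pos[post[0]]
        node_idx = next(
            i for i, s in enumerate(support.node_sets) if a in s and b in s
        )
        au = float(support.au[node_idx])
        is_root = node_idx == len(support.node_sets) - 1
        rows.append((
            pid,
            bool(au >= au_threshold and not is_root),
            au,
            len(support.node_sets[node_idx]),
        ))
    return pd.DataFrame(
        rows, columns=["patient_id", "co_clustered", "au", "node_size"]
    ).set_index("patient_id")


def categorical_association(
    binary_a, binary_b, correction: bool = False
) -> tuple[float, float, str]:
    """Chi-square (Fisher fallback) association between two binary vectors.

    Returns (statistic, p, method); Fisher's exact test replaces the
    chi-square whenever an expected cell count falls below 5, in which case
    the statistic is the odds ratio.
    """
    a = np.asarray(binary_a).astype(int)
    b = np.asarray(binary_b).astype(int)
    if a.shape != b.shape:
        raise ConfigurationError("vectors differ in length")
    table = pd.crosstab(a, b).reindex(index=[0, 1], columns=[0, 1], fill_value=0)
    t = table.to_numpy()
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateDataError(f"degenerate 2x2 margin: {t.tolist()}")
    chi2, p, _, expected = stats.chi2_contingency(t, correction=correction)
    if (expected < 5).any():
        odds, p = stats.fisher_exact(t)
        return float(odds), float(p), "fisher"
    return float(chi2), float(p), "chi2"
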