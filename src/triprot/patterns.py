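"""Eight-pattern classification of matched-triplet protein trajectories.

Each protein, in each patient, moves through three states: tumor-adjacent
normal -> pre-treatment tumor -> post-treatment tumor.  Each of the two
transitions is called UP, DOWN or NONE against a fold-change threshold
(default 1.5 on the linear scale, i.e. log2(1.5) on log2 ratios), and the
3 x 3 transition combinations map onto eight trajectory patterns plus FLAT:

====  ===========  ===========
code  normal->pre  pre->post
====  ===========  ===========
1     UP           DOWN        (tumor-elevated, reverting on treatment)
2     DOWN         UP
3     UP           NONE        (tumor-elevated, persisting — resistance-linked)
4     DOWN         NONE
5     NONE         UP
6     NONE         DOWN
7     UP           UP
8     DOWN         DOWN
FLAT  NONE         NONE
====  ===========  ===========

Two variants are provided: the patient-wise classifier (pure thresholding,
one call per protein per patient) and the global variant, where the two
transition calls come from cohort-level moderated paired tests with
sign-flip permutation FDR control (S0-damped statistic, q <= 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError

UP, NONE, DOWN = 1, 0, -1
FLAT = 0  #: pattern code for a triplet with no called transition
NA = -1  #: pattern code for an incomplete triplet

LOG2_FC_THRESHOLD = math.log2(1.5)
DEFAULT_S0 = 0.3

#: pattern code -> (normal->pre call, pre->post call)
PATTERN_TRANSITIONS: dict[int, tuple[int, int]] = {
    1: (UP, DOWN),
    2: (DOWN, UP),
    3: (UP, NONE),
    4: (DOWN, NONE),
    5: (NONE, UP),
    6: (NONE, DOWN),
    7: (UP, UP),
    8: (DOWN, DOWN),
}
TRANSITIONS_TO_PATTERN = {v: k for k, v in PATTERN_TRANSITIONS.items()}
TRANSITIONS_TO_PATTERN[(NONE, NONE)] = FLAT

#: negating the data swaps UP/DOWN, hence these pattern pairs
NEGATION_SWAP = {1: 2, 2: 1, 3: 4, 4: 3, 5: 6, 6: 5, 7: 8, 8: 7, FLAT: FLAT, NA: NA}

# lookup indexed by (c1 + 1, c2 + 1)
_CODE_TABLE = np.empty((3, 3), dtype=int)
for (_c1, _c2), _code in TRANSITIONS_TO_PATTERN.items():
    _CODE_TABLE[_c1 + 1, _c2 + 1] = _code


def _ternary(delta: np.ndarray, tau: float) -> np.ndarray:
    """UP (+1) / NONE (0) / DOWN (-1) call on a log2 difference."""
    return np.where(delta >= tau, UP, np.where(delta <= -tau, DOWN, NONE))


def classify_triplet(
    normal: float, pre: float, post: float, tau: float = LOG2_FC_THRESHOLD
) -> int:
    """Pattern code (1-8, FLAT=0) for one triplet; NA (-1) if any value missing."""
    if tau <= 0:
        raise ConfigurationError("fold-change threshold tau must be positive")
    vals = np.array([normal, pre, post], dtype=float)
    if not np.isfinite(vals).all():
        return NA
    c1 = int(_ternary(np.array(pre - normal), tau))
    c2 = int(_ternary(np.array(post - pre), tau))
    return int(_CODE_TABLE[c1 + 1, c2 + 1])


def classify_matrix(
    normal: np.ndarray, pre: np.ndarray, post: np.ndarray,
    tau: float = LOG2_FC_THRESHOLD,
) -> np.ndarray:
    """Vectorized :func:`classify_triplet` over aligned arrays."""
    if tau <= 0:
        raise ConfigurationError("fold-change threshold tau must be positive")
    normal, pre, post = (np.asarray(a, dtype=float) for a in (normal, pre, post))
    ok = np.isfinite(normal) & np.isfinite(pre) & np.isfinite(post)
    c1 = _ternary(np.where(ok, pre - normal, 0.0), tau)
    c2 = _ternary(np.where(ok, post - pre, 0.0), tau)
    codes = _CODE_TABLE[c1 + 1, c2 + 1]
    return np.where(ok, codes, NA)


def classify_cohort(cohort, tau: float = LOG2_FC_THRESHOLD) -> pd.DataFrame:
    """Pattern calls for every protein x patient with a complete triplet.

    Returns a proteins x patients frame of codes (1-8, 0=FLAT, -1=NA).
    """
    patients = cohort.triplet_patients()
    normal = cohort.role_matrix("normal", patients).to_numpy()
    pre = cohort.role_matrix("pre", patients).to_numpy()
    post = cohort.role_matrix("post", patients).to_numpy()
    codes = classify_matrix(normal, pre, post, tau)
    return pd.DataFrame(codes, index=cohort.protein_ids, columns=patients)


def negate_symmetry_check(triplets: np.ndarray, tau: float = LOG2_FC_THRESHOLD) -> bool:
    """Check that classifying -X swaps 1<->2, 3<->4, 5<->6, 7<->8 and fixes FLAT.

    ``triplets`` is an (n, 3) array of (normal, pre, post) values.
    """
    t = np.asarray(triplets, dtype=float).reshape(-1, 3)
    fwd = classify_matrix(t[:, 0], t[:, 1], t[:, 2], tau)
    rev = classify_matrix(-t[:, 0], -t[:, 1], -t[:, 2], tau)
    swap = np.vectorize(NEGATION_SWAP.get)
    return bool(np.array_equal(swap(fwd), rev))


def patient_pattern_fractions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-patient percentage of classifiable proteins in each pattern 1-8.

    ``calls`` is the proteins x patients code frame from
    :func:`classify_cohort`.  The denominator counts all non-NA calls, FLAT
    included, so the eight percentages sum to at most 100.
    """
    out = {}
    for patient in calls.columns:
        col = calls[patient].to_numpy()
        classifiable = col != NA
        n = int(classifiable.sum())
        row = {"n_classified": n}
        if n == 0:
            warnings.warn(f"patient {patient} has no classifiable proteins")
            for k in range(1, 9):
                row[f"pattern_{k}"] = np.nan
        else:
            for k in range(1, 9):
                row[f"pattern_{k}"] = 100.0 * float((col == k).sum()) / n
        out[patient] = row
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "patient_id"
    return df[[f"pattern_{k}" for k in range(1, 9)] + ["n_classified"]]


# ---------------------------------------------------------------------------
# moderated paired statistic with sign-flip permutation FDR
# ---------------------------------------------------------------------------

def moderated_paired_stat(diffs: np.ndarray, s0: float = DEFAULT_S0) -> float:
    """S0-damped paired statistic d = mean / (SE + s0) on one difference vector.

    With ``s0 = 0`` this is the classical paired t statistic.  The additive
    constant damps the significance of low-variance proteins, the usual
    trick against artificially tiny standard errors in proteomics.
    """
    x = np.asarray(diffs, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("need at least 3 paired differences")
    se = x.std(ddof=1) / math.sqrt(x.size)
    denom = se + s0
    if denom == 0.0:
        raise DegenerateDataError("zero variance and s0 = 0: statistic undefined")
    return float(x.mean() / denom)


def _moderated_stats(X: np.ndarray, s0: float) -> np.ndarray:
    """Row-wise moderated statistic for a proteins x patients matrix."""
    n = X.shape[1]
    m = X.mean(axis=1)
    se = X.std(axis=1, ddof=1) / math.sqrt(n)
    return m / (se + s0)


@dataclass
class FdrResult:
    """Per-protein moderated statistics with permutation-based q-values."""

    stat: pd.Series
    qvalue: pd.Series
    significant: pd.Series
    threshold: float  # |d| cutoff actually applied; NaN if nothing passes
    s0: float
    n_perm: int


def signflip_permutation_fdr(
    diffs: pd.DataFrame,
    s0: float = DEFAULT_S0,
    q: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
) -> FdrResult:
    """Permutation FDR for paired differences via patient sign-flips.

    The null distribution comes from recomputing the moderated statistic
    after flipping the sign of each patient's difference vector at random.
    For a symmetric cutoff t the FDR estimate is the mean permuted count of
    |d| >= t divided by the observed count; proteins are flagged at the
    smallest cutoff whose estimate stays at or below ``q``.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be at least 100")
    X = diffs.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DegenerateDataError("difference matrix contains missing values")
    n_prot, n = X.shape
    d_obs = _moderated_stats(X, s0)

    rng = np.random.default_rng(seed)
    S = rng.choice(np.array([-1.0, 1.0]), size=(n, n_perm))
    M = (X @ S) / n  # permuted means; squares are sign-invariant
    sumsq = (X ** 2).sum(axis=1)
    var = np.clip((sumsq[:, None] - n * M ** 2) / (n - 1), 0.0, None)
    D = M / (np.sqrt(var / n) + s0)

    obs_abs = np.abs(d_obs)
    perm_sorted = np.sort(np.abs(D).ravel())
    obs_sorted = np.sort(obs_abs)
    thresholds = np.unique(obs_abs)
    n_obs_ge = obs_abs.size - np.searchsorted(obs_sorted, thresholds, side="left")
    n_perm_ge = (perm_sorted.size - np.searchsorted(perm_sorted, thresholds, side="left")) / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_at = np.minimum(n_perm_ge / n_obs_ge, 1.0)
    # q-value of a protein = best FDR achievable at any cutoff it passes,
    # i.e. over thresholds at or below its |d| (thresholds sorted ascending)
    qvals_at = np.minimum.accumulate(fdr_at)
    idx = np.searchsorted(thresholds, obs_abs)
    qvalue = qvals_at[idx]
    significant = qvalue <= q
    threshold = float(obs_abs[significant].min()) if significant.any() else np.nan

    return FdrResult(
        stat=pd.Series(d_obs, index=diffs.index, name="stat"),
        qvalue=pd.Series(qvalue, index=diffs.index, name="qvalue"),
        significant=pd.Series(significant, index=diffs.index, name="significant"),
        threshold=threshold,
        s0=s0,
        n_perm=n_perm,
    )


def assign_global_patterns(
    cohort,
    s0: float = DEFAULT_S0,
    q: float = 0.05,
    n_perm: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort-level pattern assignment from three moderated paired contrasts.

    The normal<->pre and pre<->post contrasts provide the two ternary calls
    (UP/DOWN if the contrast passes the permutation FDR, by sign of the mean
    difference; NONE otherwise); the normal<->post contrast is computed and
    reported but does not enter the assignment.  Proteins with both calls
    NONE get pattern 0 ("none").
    """
    patients = cohort.triplet_patients()
    normal = cohort.role_matrix("normal", patients)
    pre = cohort.role_matrix("pre", patients)
    post = cohort.role_matrix("post", patients)
    contrasts = {
        "pre_vs_normal": pre - normal,
        "post_vs_pre": post - pre,
        "post_vs_normal": post - normal,
    }
    ss = np.random.SeedSequence(seed).spawn(3)
    out = pd.DataFrame(index=cohort.protein_ids)
    results = {}
    for (name, diffs), sub in zip(contrasts.items(), ss):
        res = signflip_permutation_fdr(
            diffs, s0=s0, q=q, n_perm=n_perm, seed=int(sub.generate_state(1)[0] % (2 ** 31))
        )
        results[name] = res
        out[f"d_{name}"] = res.stat
        out[f"q_{name}"] = res.qvalue
        out[f"sig_{name}"] = res.significant

    def call(name: str) -> np.ndarray:
        res = results[name]
        sign = np.sign(res.stat.to_numpy()).astype(int)
        return np.where(res.significant.to_numpy(), sign, NONE)

    c1, c2 = call("pre_vs_normal"), call("post_vs_pre")
    out["pattern"] = _CODE_TABLE[c1 + 1, c2 + 1]
    return out


def pattern_survival_correlation(
    profiles: pd.DataFrame,
    clinical,
    time_field: str = "rfs_years",
) -> pd.DataFrame:
    """Spearman correlation of each pattern's percentage with survival time.

    One test per pattern 1-8 across patients; p from the t approximation,
    Benjamini-Hochberg correction over the eight tests.
    """
    patients = [p for p in profiles.index if p in clinical.data.index]
    if len(patients) < 5:
        raise DegenerateDataError("need at least 5 patients with profile and outcome")
    y = clinical.aligned(patients)[time_field].to_numpy(dtype=float)
    rows = []
    for k in range(1, 9):
        x = profiles.loc[patients, f"pattern_{k}"].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"pattern {k} fraction is constant; correlation undefined")
            rows.append((k, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((k, rho, p))
    df = pd.DataFrame(rows, columns=["pattern", "rho", "p"]).set_index("pattern")
    from statsmodels.stats.multitest import multipletests

    ok = df["p"].notna()
    qv = pd.Series(np.nan, index=df.index)
    if ok.any():
        qv[ok] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["q"] = qv
    df["n"] = len(patients)
    return df
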