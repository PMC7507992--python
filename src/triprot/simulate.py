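"""Synthetic matched-triplet cohorts with known ground truth.

The generator emulates the statistical structure of a neoadjuvant-treatment
proteomic cohort: per patient, three matched samples (tumor-adjacent normal,
pre-treatment tumor, post-treatment tumor) of log2(L/H) SILAC ratios; each
protein follows, in each patient, one of eight trajectory patterns (or stays
flat) defined by two ternary transitions (normal->pre, pre->post); proteins
are organised into block-correlated co-expression modules; missingness is
left-censored (low-abundance values drop out preferentially); relapse-free
survival has a hazard that increases with the patient's burden of pattern-3
proteins (up in tumor, unaffected by treatment).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, Cohort, ROLE_HEALTHY, TRIPLET_ROLES
from .errors import ConfigurationError
from .patterns import FLAT, PATTERN_TRANSITIONS

#: default fold-change effect: two threshold-widths, so planted transitions
#: clear the log2(1.5) patient-wise cutoff with margin
DEFAULT_EFFECT_MEAN = 2.0 * math.log2(1.5)

SUBTYPES = ("HP", "TP", "TN", "HER2")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``pattern_mixture`` gives the expected prevalence of pattern classes
    1-8 plus FLAT (in that order).  Two mechanisms shape the per-patient
    class assignment around that average:

    * protein archetypes — each protein draws one archetype class from the
      mixture and follows it in any given patient with probability
      ``pattern_fidelity``; this cross-patient consistency is what makes
      cohort-level (global) pattern tests able to find anything.
    * a patient resistance axis — the remaining probability mass is drawn
      from the mixture tilted by ``exp(+eta)`` on the persistent patterns 3
      and 4 and ``exp(-eta)`` on the reverting patterns 1 and 2, with a
      per-patient ``eta ~ N(0, resistance_sd)``; resistant patients are
      dominated by patterns 3/4, good responders by 1/2.

    Patient-level pattern-3 dominance links the proteome to outcome: the
    relapse hazard is ``hazard_baseline * exp(log_hr_per_unit * f3)`` where
    ``f3`` is the patient's true pattern-3 fraction.
    """

    n_patients: int = 35
    n_proteins: int = 3000
    # prevalence of classes 1..8 then FLAT; patterns 1-4 dominate, as in
    # patient-wise pattern profiles of treated breast tumors
    pattern_mixture: tuple[float, ...] = (
        0.06, 0.06, 0.08, 0.06, 0.02, 0.03, 0.01, 0.01, 0.67,
    )
    pattern_fidelity: float = 0.5
    resistance_sd: float = 1.5
    effect_mean: float = DEFAULT_EFFECT_MEAN
    effect_sd: float = 0.25
    noise_sd: float = 0.25
    missing_target_rate: float = 0.10
    censor_steepness: float = 1.0
    n_modules: int = 5
    module_size: int = 60
    module_cor: float = 0.8
    module_strength: float = 1.0
    hazard_baseline: float = 0.12
    log_hr_per_unit: float = 12.0
    censor_rate: float = 0.30
    batch_shift: float = 0.3
    n_healthy: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.pattern_mixture, dtype=float)
        if mix.shape != (9,):
            raise ConfigurationError("pattern_mixture needs 9 weights (classes 1-8 + FLAT)")
        if (mix < 0).any():
            raise ConfigurationError("pattern_mixture weights must be non-negative")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"pattern_mixture sums to {mix.sum()}, not 1")
        for name in ("n_patients", "n_proteins", "n_modules", "module_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.missing_target_rate < 1.0:
            raise ConfigurationError("missing_target_rate must lie in [0, 1)")
        if not 0.0 <= self.pattern_fidelity <= 1.0:
            raise ConfigurationError("pattern_fidelity must lie in [0, 1]")
        if self.resistance_sd < 0:
            raise ConfigurationError("resistance_sd must be non-negative")
        if not 0.0 <= self.module_cor < 1.0:
            raise ConfigurationError("module_cor must lie in [0, 1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1)")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted simulation parameters for recovery tests."""

    true_pattern: pd.DataFrame  # proteins x patients, codes 1..8 or 0 (FLAT)
    module_label: pd.Series  # protein -> module name or "none"
    true_log_hr: float
    true_pattern3_fraction: pd.Series  # patient -> fraction in [0, 1]
    true_event_time: pd.Series  # latent (uncensored) relapse time, years
    event_indicator: pd.Series  # 1 if relapse observed, 0 if censored


_MIN_SHIFT_MARGIN = 0.05  # log2 units above the calling threshold


def _draw_shift(rng: np.random.Generator, direction: int, n: int,
                mean: float, sd: float) -> np.ndarray:
    """Signed log2 shift for UP (+1) / DOWN (-1) / NONE (0) transitions.

    Magnitudes are truncated below at the patient-wise fold-change threshold
    (plus a small margin) so planted transitions are recoverable in the
    noise-free limit.
    """
    if direction == 0:
        return np.zeros(n)
    mag = np.abs(rng.normal(mean, sd, size=n))
    floor = math.log2(1.5) + _MIN_SHIFT_MARGIN
    return direction * np.maximum(mag, floor)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, ClinicalTable, GroundTruth]:
    """Generate a complete (no missing values) cohort with ground truth.

    Apply :func:`apply_missingness` afterwards for the left-censored
    missing-data mechanism.
    """
    rng = np.random.default_rng(config.seed)
    P, G = config.n_patients, config.n_proteins
    patients = [f"PT{i + 1:03d}" for i in range(P)]
    proteins = pd.Index([f"PROT{i + 1:05d}" for i in range(G)], name="protein_id")

    mix = np.asarray(config.pattern_mixture, dtype=float)
    # class codes: 1..8, FLAT encoded 0; column order in `mix` is 1..8, FLAT
    codes = np.array([1, 2, 3, 4, 5, 6, 7, 8, FLAT])
    archetype = rng.choice(codes, size=G, p=mix)
    # per-patient mixture tilted along the resistance axis: persistent
    # patterns 3/4 up-weighted, reverting patterns 1/2 down-weighted
    eta = (rng.normal(0.0, config.resistance_sd, size=P)
           if config.resistance_sd > 0 else np.zeros(P))
    axis = np.array([-1.0, -1.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    tilted = mix[None, :] * np.exp(np.outer(eta, axis))
    tilted /= tilted.sum(axis=1, keepdims=True)
    true_pattern = np.empty((G, P), dtype=int)
    for j in range(P):
        drawn = rng.choice(codes, size=G, p=tilted[j])
        follow = rng.random(G) < config.pattern_fidelity
        true_pattern[:, j] = np.where(follow, archetype, drawn)

    # module membership: first n_modules * module_size proteins, in blocks
    labels = np.array(["none"] * G, dtype=object)
    n_block = min(config.n_modules * config.module_size, G)
    for i in range(n_block):
        labels[i] = f"M{i // config.module_size + 1}"
    module_label = pd.Series(labels, index=proteins, name="module_label")

    baseline = rng.normal(0.0, 1.0, size=G)

    # co-expression blocks: members share an additive per-(block, patient)
    # latent factor of amplitude module_strength (log2 units).  The factor is
    # a property of the patient's tumor biology, identical across that
    # patient's three samples, so it cancels out of within-patient
    # transitions (pattern calls) while driving protein-protein correlation
    # across patients.
    n_mod = (n_block + config.module_size - 1) // config.module_size
    block_idx = np.arange(n_block) // config.module_size

    def module_term(n_cols: int) -> np.ndarray:
        out = np.zeros((G, n_cols))
        if config.module_strength > 0 and n_block > 0:
            factors = rng.normal(0.0, 1.0, size=(n_mod, n_cols))
            out[:n_block] = config.module_strength * factors[block_idx]
        return out

    def noise_block(n_samples: int) -> np.ndarray:
        return config.noise_sd * rng.normal(0.0, 1.0, size=(G, n_samples))

    # planted transition shifts per (protein, patient)
    d1 = np.zeros((G, P))
    d2 = np.zeros((G, P))
    for code, (c1, c2) in PATTERN_TRANSITIONS.items():
        mask = true_pattern == code
        k = int(mask.sum())
        if k == 0:
            continue
        d1[mask] = _draw_shift(rng, c1, k, config.effect_mean, config.effect_sd)
        d2[mask] = _draw_shift(rng, c2, k, config.effect_mean, config.effect_sd)

    base = baseline[:, None]
    patient_modules = module_term(P)
    values = {
        "normal": base + patient_modules + noise_block(P),
        "pre": base + patient_modules + d1 + noise_block(P),
        "post": base + patient_modules + d1 + d2 + noise_block(P),
    }

    # assemble samples: triplets per patient, then healthy references
    columns, meta_rows = [], []
    mats = []
    batches = {p: i % 2 for i, p in enumerate(patients)}
    for j, pid in enumerate(patients):
        for role in TRIPLET_ROLES:
            sid = f"{pid}_{role}"
            columns.append(sid)
            meta_rows.append((sid, pid, role, batches[pid]))
            mats.append(values[role][:, j])
    for h in range(config.n_healthy):
        hid = f"H{h + 1:02d}"
        sid = f"{hid}_healthy"
        columns.append(sid)
        meta_rows.append((sid, hid, ROLE_HEALTHY, h % 2))
        # healthy ducts behave like adjacent-normal tissue
        mats.append((base + module_term(1) + noise_block(1))[:, 0])

    matrix = pd.DataFrame(np.column_stack(mats), index=proteins, columns=columns)
    # additive per-batch log2 offset on batch-1 samples
    if config.batch_shift:
        batch1 = [c for c, (_, _, _, b) in zip(columns, meta_rows) if b == 1]
        matrix[batch1] += config.batch_shift
    sample_meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "patient_id", "role", "batch"]
    )
    cohort = Cohort(matrix, sample_meta)

    # survival: hazard scales with the patient's true pattern-3 burden
    f3 = pd.Series((true_pattern == 3).mean(axis=0), index=patients, name="f3")
    lam = config.hazard_baseline * np.exp(config.log_hr_per_unit * f3.to_numpy())
    t_event = rng.exponential(1.0 / lam)
    censored = rng.random(P) < config.censor_rate
    rfs = np.where(censored, rng.random(P) * t_event, t_event)
    relapse = (~censored).astype(int)
    os_years = rfs + rng.exponential(2.0, size=P)
    death = (relapse & (rng.random(P) < 0.7)).astype(int)

    # response score: better responders carry less pattern-3 burden
    mp_latent = -f3.to_numpy() + rng.normal(0.0, f3.std() + 1e-12, size=P)
    mp_score = pd.qcut(mp_latent, 4, labels=False, duplicates="drop") + 1
    clinical = ClinicalTable(pd.DataFrame({
        "patient_id": patients,
        "mp_score": np.asarray(mp_score, dtype=int),
        "relapse": relapse,
        "death": death,
        "rfs_years": rfs,
        "os_years": os_years,
        "grade": rng.integers(1, 4, size=P),
        "ki67": rng.integers(1, 4, size=P),
        "tumor_size": rng.integers(1, 5, size=P),
        "age": rng.integers(32, 75, size=P),
        "subtype": rng.choice(SUBTYPES, size=P),
    }))

    truth = GroundTruth(
        true_pattern=pd.DataFrame(true_pattern, index=proteins, columns=patients),
        module_label=module_label,
        true_log_hr=config.log_hr_per_unit,
        true_pattern3_fraction=f3,
        true_event_time=pd.Series(t_event, index=patients, name="true_event_time"),
        event_indicator=pd.Series(relapse, index=patients, name="event_indicator"),
    )
    return cohort, clinical, truth


def apply_missingness(cohort: Cohort, config: SimulationConfig) -> Cohort:
    """Mask cells with an abundance-dependent (left-censored) mechanism.

    Each cell goes missing with probability ``sigmoid(a - steepness * z)``
    where ``z`` is the cell's global z-score; the intercept ``a`` is found by
    bisection so the overall missing fraction matches
    ``config.missing_target_rate``.  Low values are preferentially lost, the
    MNAR mechanism that motivates downshifted imputation.
    """
    if config.missing_target_rate == 0.0:
        return cohort.copy()
    rng = np.random.default_rng([config.seed, 104729])
    vals = cohort.matrix.to_numpy(dtype=float)
    z = (vals - vals.mean()) / vals.std()
    s = config.censor_steepness

    def mean_rate(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a - s * z)))))

    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < config.missing_target_rate:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    p_miss = 1.0 / (1.0 + np.exp(-(a - s * z)))
    mask = rng.random(vals.shape) < p_miss
    out = cohort.copy()
    out.matrix = out.matrix.mask(pd.DataFrame(mask, index=out.matrix.index,
                                              columns=out.matrix.columns))
    return out


def simulate_network(n_nodes: int, edge_prob: float, seed: int) -> pd.DataFrame:
    """Erdos-Renyi edge list over protein-style node IDs (two-column frame)."""
    if not 0.0 <= edge_prob <= 1.0:
        raise ConfigurationError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"PROT{i + 1:05d}" for i in range(n_nodes)]
    i, j = np.triu_indices(n_nodes, k=1)
    keep = rng.random(i.shape[0]) < edge_prob
    return pd.DataFrame({
        "node_a": [nodes[a] for a in i[keep]],
        "node_b": [nodes[b] for b in j[keep]],
    })


def simulate_block_matrix(
    n_modules: int,
    module_size: int,
    n_samples: int,
    within_cor: float,
    n_background: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pure block-correlated proteins x samples matrix for module-detection tests.

    Proteins within a block share a latent per-sample factor with loading
    ``sqrt(within_cor)``; blocks are mutually independent, as are the
    optional background proteins.  Returns the matrix and the true labels
    ("M1".."Mk", background "none").
    """
    rng = np.random.default_rng(seed)
    G = n_modules * module_size + n_background
    proteins = pd.Index([f"PROT{i + 1:05d}" for i in range(G)], name="protein_id")
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    X = rng.normal(0.0, 1.0, size=(G, n_samples))
    labels = np.array(["none"] * G, dtype=object)
    for m in range(n_modules):
        rows = slice(m * module_size, (m + 1) * module_size)
        factor = rng.normal(0.0, 1.0, size=n_samples)
        X[rows] = math.sqrt(within_cor) * factor + math.sqrt(1 - within_cor) * X[rows]
        labels[rows] = f"M{m + 1}"
    return (
        pd.DataFrame(X, index=proteins, columns=samples),
        pd.Series(labels, index=proteins, name="module_label"),
    )
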