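"""Group-stratified paired contrasts and exclusive-significance selection.

Patients are split into two response groups — by pathological response
score (Miller & Payne 1-2 = worse responders, 3-4 = better; the rare score-4
patient is grouped with score 3) or by relapse status — and the pre- vs
post-treatment paired moderated test is run within each group.  Proteins
significant in one group but unaltered (not passing FDR) in the other are
the group-exclusive treatment responses.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import ClinicalTable, Cohort
from .errors import CohortStructureError, ConfigurationError
from .patterns import DEFAULT_S0, FdrResult, signflip_permutation_fdr


def split_patients(clinical: ClinicalTable, group_by: str = "mp") -> dict[str, list[str]]:
    """Two-way patient split: ``mp`` (score 3-4 vs 1-2) or ``relapse``."""
    df = clinical.data
    if group_by == "mp":
        hi = df.index[df["mp_score"] >= 3].tolist()
        lo = df.index[df["mp_score"] <= 2].tolist()
        return {"better_responders": hi, "worse_responders": lo}
    if group_by == "relapse":
        yes = df.index[df["relapse"] == 1].tolist()
        no = df.index[df["relapse"] == 0].tolist()
        return {"no_relapse": no, "relapse": yes}
    raise ConfigurationError(f"unknown grouping {group_by!r}")


@dataclass
class ContrastResult:
    """Per-group paired pre-vs-post contrast."""

    group_label: str
    table: pd.DataFrame  # protein x (mean_log2_diff, stat, q, significant)

    @property
    def significant_set(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def grouped_paired_contrast(
    cohort: Cohort,
    clinical: ClinicalTable,
    group_by: str = "mp",
    q: float = 0.05,
    s0: float = DEFAULT_S0,
    n_perm: int = 250,
    seed: int = 0,
) -> dict[str, ContrastResult]:
    """Pre- vs post-treatment moderated paired test within each patient group."""
    groups = split_patients(clinical, group_by)
    available = set(cohort.triplet_patients())
    results: dict[str, ContrastResult] = {}
    sizes = {k: len([p for p in v if p in available]) for k, v in groups.items()}
    too_small = {k: n for k, n in sizes.items() if n < 3}
    if too_small:
        raise CohortStructureError(
            f"groups too small for a paired contrast: {sizes}"
        )
    for label, members in groups.items():
        members = [p for p in members if p in available]
        pre = cohort.role_matrix("pre", members)
        post = cohort.role_matrix("post", members)
        diffs = post - pre
        # seed derived from the member set, so the result for a given group
        # of patients does not depend on which label it carries
        member_key = zlib.crc32(",".join(sorted(members)).encode())
        sub = np.random.SeedSequence([seed, member_key])
        res: FdrResult = signflip_permutation_fdr(
            diffs, s0=s0, q=q, n_perm=n_perm,
            seed=int(sub.generate_state(1)[0] % (2 ** 31)),
        )
        table = pd.DataFrame({
            "mean_log2_diff": diffs.mean(axis=1),
            "stat": res.stat,
            "q": res.qvalue,
            "significant": res.significant,
        })
        results[label] = ContrastResult(group_label=label, table=table)
    return results


def exclusive_significant(
    res_a: ContrastResult, res_b: ContrastResult
) -> tuple[set[str], float]:
    """Proteins significant in A but not in B, and the exclusivity fraction.

    The fraction is |exclusive| / |significant in A| (0 when A has no hits).
    """
    if set(res_a.table.index) != set(res_b.table.index):
        raise CohortStructureError("contrasts cover different protein universes")
    sig_a = res_a.significant_set
    sig_b = res_b.significant_set
    exclusive = sig_a - sig_b
    fraction = len(exclusive) / len(sig_a) if sig_a else 0.0
    return exclusive, fraction


def overlap_sets(set_x: set, set_y: set) -> tuple[int, int, int]:
    """(|X|, |Y|, |X intersect Y|)."""
    return len(set_x), len(set_y), len(set_x & set_y)
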