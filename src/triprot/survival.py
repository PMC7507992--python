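"""Survival estimation/regression, enrichment, and network centrality.

Kaplan-Meier curves and (pairwise) log-rank tests, Cox proportional-hazards
regression with Efron (default) or Breslow tie handling, median
dichotomization of a protein's abundance into high/low strata,
Benjamini-Hochberg correction, one-sided Fisher/hypergeometric set
enrichment against a fixed background universe, and exact betweenness
centrality on a protein-interaction network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError


def bh_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dichotomize_at_median(values) -> pd.Series:
    """'high' for strictly above the median, 'low' at or below it."""
    v = pd.Series(values).astype(float)
    if v.notna().sum() < 2:
        raise DegenerateDataError("need at least 2 finite values")
    if v.nunique(dropna=True) == 1:
        raise DegenerateDataError("all values identical: no median split exists")
    med = v.median()
    out = pd.Series(np.where(v > med, "high", "low"), index=v.index, name="stratum")
    out[v.isna()] = pd.NA
    return out


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves with log-rank tests, or a fitted Cox model."""

    model_type: str  # "km" | "cox_univariate" | "cox_multivariate"
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    pairwise: pd.DataFrame | None = None  # group_a, group_b, stat, p, q
    summary: pd.DataFrame | None = None  # per covariate: coef, HR, CI, p
    global_p: float | None = None
    ties: str | None = None


def kaplan_meier_logrank(times, events, groups) -> SurvivalResult:
    """Product-limit curves per group, global and BH-corrected pairwise log-rank."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if (t < 0).any():
        raise ConfigurationError("negative survival times")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ConfigurationError("need at least 2 groups")
    curves = {}
    for lab in labels:
        mask = g == lab
        if mask.sum() == 0:
            raise DegenerateDataError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(lab))
        tab = kmf.event_table
        curves[str(lab)] = pd.DataFrame({
            "time": tab.index.to_numpy(),
            "at_risk": tab["at_risk"].to_numpy(),
            "events": tab["observed"].to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    glob = multivariate_logrank_test(t, g, e)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ma, mb = g == la, g == lb
            res = logrank_test(t[ma], t[mb], e[ma], e[mb])
            rows.append((str(la), str(lb), res.test_statistic, res.p_value))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "stat", "p"])
    pw["q"] = bh_correct(pw["p"]) if len(pw) else []
    return SurvivalResult(
        model_type="km",
        curves=curves,
        logrank_stat=float(glob.test_statistic),
        logrank_p=float(glob.p_value),
        pairwise=pw,
    )


def cox_regression(
    times, events, covariates: pd.DataFrame, ties: str = "efron"
) -> SurvivalResult:
    """Cox proportional-hazards fit; HR with 95% CI per covariate.

    Efron tie handling uses lifelines; Breslow is routed through the
    statsmodels proportional-hazards fitter.  Multivariate models also carry
    the global likelihood-ratio p.
    """
    cov = pd.DataFrame(covariates).astype(float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if cov.isna().any().any():
        raise ConfigurationError("missing covariate values")
    if e.sum() < cov.shape[1] + 1:
        raise DegenerateDataError(
            f"{e.sum()} events cannot support {cov.shape[1]} covariates"
        )
    if ties not in ("efron", "breslow"):
        raise ConfigurationError(f"unknown tie method {ties!r}")
    model_type = "cox_univariate" if cov.shape[1] == 1 else "cox_multivariate"
    if ties == "efron":
        from lifelines import CoxPHFitter
        from lifelines.exceptions import ConvergenceError

        df = cov.copy()
        df["_time"] = t
        df["_event"] = e
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise DegenerateDataError(
                f"Cox fit failed to converge (possible separation): {err}"
            ) from None
        summ = cph.summary
        summary = pd.DataFrame({
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "hr_ci_low": summ["exp(coef) lower 95%"],
            "hr_ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        })
        global_p = float(cph.log_likelihood_ratio_test().p_value)
    else:
        import statsmodels.api as sm

        mod = sm.PHReg(t, cov.to_numpy(), status=e, ties="breslow")
        try:
            res = mod.fit(disp=False)
        except Exception as err:  # statsmodels raises generic errors
            raise DegenerateDataError(f"Cox fit failed: {err}") from None
        coef = res.params
        se = res.bse
        summary = pd.DataFrame({
            "coef": coef,
            "hr": np.exp(coef),
            "hr_ci_low": np.exp(coef - 1.959963984540054 * se),
            "hr_ci_high": np.exp(coef + 1.959963984540054 * se),
            "p": res.pvalues,
        }, index=cov.columns)
        lr = 2.0 * (res.llf - mod.loglike(np.zeros(cov.shape[1])))
        global_p = float(stats.chi2.sf(lr, df=cov.shape[1]))
    if not np.isfinite(summary["coef"]).all():
        raise DegenerateDataError("non-finite Cox coefficients (monotone likelihood?)")
    return SurvivalResult(
        model_type=model_type, summary=summary, global_p=global_p, ties=ties
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSets:
    """Term -> member sets over a fixed background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ConfigurationError(
                    f"term {term!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def read_gmt(path, universe: set[str] | None = None) -> AnnotationSets:
    """GMT-format annotation file: term <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {m for m in parts[2:] if m}
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    sets = {t: m & universe for t, m in sets.items()}
    return AnnotationSets(sets=sets, universe=universe)


def fisher_enrichment(
    foreground: set[str], annotations: AnnotationSets, q_cutoff: float = 0.05
) -> pd.DataFrame:
    """One-sided over-representation test per term, BH-corrected.

    The p-value is the hypergeometric upper tail P(X >= overlap) over the
    background universe; the returned frame contains all terms, with
    ``enriched`` marking those at q <= cutoff.
    """
    if not foreground:
        raise DegenerateDataError("empty foreground set")
    extra = foreground - annotations.universe
    if extra:
        raise ConfigurationError(
            f"foreground outside universe: {sorted(extra)[:5]}"
        )
    N = len(annotations.universe)
    n = len(foreground)
    rows = []
    for term, members in annotations.sets.items():
        K = len(members)
        k = len(foreground & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else 0.0)
        rows.append((term, K, k, odds, p))
    df = pd.DataFrame(
        rows, columns=["term", "term_size", "overlap", "odds_ratio", "p"]
    ).set_index("term")
    df["q"] = bh_correct(df["p"])
    df["enriched"] = df["q"] <= q_cutoff
    return df.sort_values("p")


# ---------------------------------------------------------------------------
# network centrality
# ---------------------------------------------------------------------------

def betweenness_centrality(edges: pd.DataFrame, top_fraction: float = 0.10
                           ) -> pd.DataFrame:
    """Exact shortest-path betweenness per node with top-decile flags.

    Uses unnormalized Brandes accumulation over an undirected simple graph;
    node pairs without a connecting path contribute nothing.  ``top`` marks
    nodes at or above the (1 - top_fraction) quantile of the scores.
    """
    g = nx.Graph()
    g.add_edges_from(edges.itertuples(index=False, name=None))
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["betweenness", "top"])
    scores = nx.betweenness_centrality(g, normalized=False)
    ser = pd.Series(scores, name="betweenness").sort_values(ascending=False)
    cutoff = float(np.quantile(ser.to_numpy(), 1.0 - top_fraction))
    out = ser.to_frame()
    out["top"] = out["betweenness"] >= cutoff
    out.index.name = "node"
    return out
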