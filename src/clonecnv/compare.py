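"""Cross-sample and cross-histology statistics.

Venn-style exact set decompositions of CNV-altered genes/regions, Wilcoxon
rank-sum burden comparisons (exact for small samples), expression-vs-score
correlation, Kaplan-Meier / log-rank machinery, the maximally selected
survival cutpoint (with a permutation-adjusted p alongside the naive,
selection-biased minimum), and univariate Cox regression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import SurvivalTable

__all__ = [
    "OverlapResult",
    "overlap_sets",
    "wilcoxon_compare",
    "correlate_expr_score",
    "km_logrank",
    "best_cutpoint",
    "cox_univariate",
    "logrank_scan",
]


# ---------------------------------------------------------------------------
# Set overlaps


@dataclass
class OverlapResult:
    samples: list
    exclusive: dict  # frozenset of sample names -> set of items in exactly those
    intersection: set
    union: set

    def counts(self) -> dict:
        return {tuple(sorted(k)): len(v) for k, v in self.exclusive.items()}


def overlap_sets(sets: dict) -> OverlapResult:
    """Exact subset decomposition of >= 2 item sets (genes, or regions keyed
    by cytoband string). Every union element lands in exactly one cell."""
    if len(sets) < 2:
        raise ValueError("need at least two sets to overlap")
    names = sorted(sets)
    union = set().union(*sets.values())
    exclusive: dict = {}
    for item in union:
        members = frozenset(n for n in names if item in sets[n])
        exclusive.setdefault(members, set()).add(item)
    intersection = set.intersection(*[set(sets[n]) for n in names])
    return OverlapResult(samples=names, exclusive=exclusive,
                         intersection=intersection, union=union)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@dataclass
class WilcoxonResult:
    statistic: float  # Mann-Whitney U of group a
    pvalue: float
    method: str


def wilcoxon_compare(group_a, group_b, exact: bool | None = None) -> WilcoxonResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration over all C(n1+n2, n1) group assignments when the total
    sample is <= 20 (ties handled through mid-ranks), normal approximation
    with tie correction and continuity correction otherwise. The two-sided
    exact p is P(|U - n1 n2 / 2| >= |u_obs - n1 n2 / 2|), symmetric in the
    groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    u = w - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    if exact is None:
        exact = (n1 + n2) <= 20
    if exact:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), n1)),
            dtype=np.intp,
        ).reshape(-1, n1)
        all_w = ranks[idx].sum(axis=1)
        all_u = all_w - n1 * (n1 + 1) / 2.0
        dev = np.abs(u - mu)
        p = float(np.mean(np.abs(all_u - mu) >= dev - 1e-9))
        return WilcoxonResult(statistic=float(u), pvalue=p, method="exact")
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return WilcoxonResult(statistic=float(u), pvalue=1.0, method="asymptotic")
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(statistic=float(u), pvalue=float(p), method="asymptotic")


# ---------------------------------------------------------------------------
# Correlation


def correlate_expr_score(expr, score, method: str = "spearman"):
    """Correlation (r, two-sided p) between per-cell expression and CNV score."""
    expr = np.asarray(expr, dtype=float)
    score = np.asarray(score, dtype=float)
    if len(expr) != len(score):
        raise ValueError("paired vectors must have equal length")
    if len(expr) < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(expr) == 0 or np.ptp(score) == 0:
        raise ValueError("constant input vector; correlation undefined")
    if method == "spearman":
        res = stats.spearmanr(expr, score)
    elif method == "pearson":
        res = stats.pearsonr(expr, score)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Survival machinery


@dataclass
class KmResult:
    curves: dict  # group label -> DataFrame(time, at_risk, survival)
    statistic: float
    pvalue: float


def km_logrank(t: SurvivalTable, groups) -> KmResult:
    """Kaplan-Meier product-limit curves per group plus the two-group
    log-rank chi-square (1 df)."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    if t.n_events == 0:
        raise ValueError("no events in the table")
    curves = {}
    for g in labels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(t.time[mask], t.event[mask])
        df = kmf.event_table.copy()
        df["survival"] = kmf.survival_function_["KM_estimate"].reindex(df.index).to_numpy()
        curves[str(g)] = pd.DataFrame(
            {"time": df.index.to_numpy(), "at_risk": df["at_risk"].to_numpy(),
             "survival": df["survival"].to_numpy()}
        )
    res = multivariate_logrank_test(t.time, groups, t.event)
    return KmResult(curves=curves, statistic=float(res.test_statistic),
                    pvalue=float(res.p_value))


def logrank_scan(time, event, expr, cuts) -> np.ndarray:
    """Vectorized two-group log-rank chi-square for every dichotomization
    ``expr > cut``; returns an array of chi-square statistics (nan where a
    group is empty of information)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    expr = np.asarray(expr, dtype=float)
    cuts = np.atleast_1d(np.asarray(cuts, dtype=float))
    ut, inv = np.unique(time, return_inverse=True)
    m = len(ut)
    d_tot = np.bincount(inv, weights=event, minlength=m)
    n_tot = np.bincount(inv, minlength=m)[::-1].cumsum()[::-1].astype(float)
    member = (expr[:, None] > cuts[None, :]).astype(float)  # n x C
    d1 = np.zeros((m, len(cuts)))
    np.add.at(d1, inv, member * event[:, None])
    cnt1 = np.zeros((m, len(cuts)))
    np.add.at(cnt1, inv, member)
    n1 = cnt1[::-1].cumsum(axis=0)[::-1]
    frac = n1 / n_tot[:, None]
    has_events = d_tot > 0
    u = (d1 - d_tot[:, None] * frac)[has_events].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = (d_tot * (n_tot - d_tot) / np.maximum(n_tot - 1, 1))[:, None] \
            * frac * (1 - frac)
    v = vterm[has_events & (n_tot > 1)].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(v > 0, u ** 2 / v, np.nan)
    return chi2


@dataclass
class CutpointResult:
    cutpoint: float
    pvalue: float  # minimum over the scan; selection-biased by construction
    p_adjusted: float | None  # permutation-adjusted, honest p
    n_high: int
    n_low: int
    scan: pd.DataFrame
    selection_biased: bool = True


def best_cutpoint(t: SurvivalTable, band=(0.10, 0.90), min_per_arm: int = 10,
                  n_permutations: int = 1000, seed: int = 0) -> CutpointResult:
    """Maximally selected survival cutpoint.

    Scans every distinct expression value inside the percentile ``band``
    (each arm keeping >= ``min_per_arm`` subjects), computes the log-rank p
    for the split ``expression > cut``, and returns the minimizer. The naive
    minimum p is selection-biased; a permutation-adjusted p (expression
    permuted against outcome, default 1000 permutations, seeded) is reported
    alongside it.
    """
    expr = t.expression
    if np.ptp(expr) == 0:
        raise ValueError("expression is constant; no cutpoint exists")
    lo, hi = np.quantile(expr, band)
    values = np.unique(expr)
    cuts = []
    for c in values:
        if c < lo or c > hi:
            continue
        n_high = int((expr > c).sum())
        if n_high >= min_per_arm and t.n - n_high >= min_per_arm:
            cuts.append(c)
    if not cuts:
        raise ValueError("no admissible cutpoint in the requested band")
    cuts = np.asarray(cuts)
    chi2 = logrank_scan(t.time, t.event, expr, cuts)
    pvals = stats.chi2.sf(chi2, df=1)
    if np.all(np.isnan(pvals)):
        raise ValueError("log-rank undefined at every candidate cutpoint")
    best = int(np.nanargmin(pvals))
    p_obs = float(pvals[best])
    p_adj = None
    if n_permutations and n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(expr)
            perm_chi2 = logrank_scan(t.time, t.event, perm, cuts)
            perm_p = np.nanmin(stats.chi2.sf(perm_chi2, df=1))
            if perm_p <= p_obs:
                hits += 1
        p_adj = (1 + hits) / (1 + n_permutations)
    cut = float(cuts[best])
    return CutpointResult(
        cutpoint=cut,
        pvalue=p_obs,
        p_adjusted=p_adj,
        n_high=int((expr > cut).sum()),
        n_low=int((expr <= cut).sum()),
        scan=pd.DataFrame({"cutpoint": cuts, "chi2": chi2, "pvalue": pvals}),
    )


@dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    coef: float
    n_events: int


def cox_univariate(t: SurvivalTable, covariate=None, min_events: int = 10) -> CoxResult:
    """Univariate Cox proportional hazards: partial-likelihood estimate with a
    Wald CI; exp(beta) reported as the hazard ratio. Separation / monotone
    likelihood is flagged as an error rather than silently estimated."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    x = t.expression if covariate is None else np.asarray(covariate, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if t.n_events == 0:
        raise ValueError("no events in the table")
    if t.n_events < min_events:
        raise ValueError(f"only {t.n_events} events; >= {min_events} required")
    df = pd.DataFrame({"time": t.time, "event": t.event, "x": x})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ConvergenceWarning) as exc:
            raise ValueError(
                f"Cox fit did not converge (separation/monotone likelihood?): {exc}"
            ) from exc
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    z = stats.norm.ppf(0.975)
    return CoxResult(
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        pvalue=float(cph.summary.loc["x", "p"]),
        coef=coef,
        n_events=t.n_events,
    )
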