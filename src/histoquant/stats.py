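"""Assumption-routed group comparison: ANOVA/Tukey or Kruskal-Wallis/Dunn.

The routing mirrors common practice for small-n treatment-group designs:
normality is assessed per group with the Shapiro-Wilk test and variance
homogeneity with Levene's test (median-centered).  If every group passes
both at the routing alpha, groups are compared by one-way ANOVA with
Tukey's HSD post hoc; otherwise by the tie-corrected Kruskal-Wallis test
with Dunn's rank-sum post hoc (Holm-adjusted by default).  Post hoc tables
are produced only when the omnibus test is significant.

Dunn's test is implemented here in closed form: with pooled mid-ranks
R and tie correction T = sum(t^3 - t) over tie groups,

    z_ij = (Rbar_i - Rbar_j) / sqrt[ (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) ]

with two-sided normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "dunn_test",
    "route_and_compare",
    "type1_error_sim",
]


@dataclass
class GroupSample:
    """One treatment group's per-animal values."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")


@dataclass
class ComparisonResult:
    """Outcome of the two-stage (assumption check -> test) comparison."""

    route: str  # "anova_tukey" | "kruskal_dunn"
    shapiro_p: dict
    levene_p: float
    omnibus_statistic: float
    omnibus_p: float
    alpha: float
    significant: bool
    posthoc: pd.DataFrame | None = None
    assumptions: dict = field(default_factory=dict)


def _as_samples(samples) -> list[GroupSample]:
    out = []
    for s in samples:
        if isinstance(s, GroupSample):
            out.append(s)
        else:  # (label, values) pair
            out.append(GroupSample(label=s[0], values=np.asarray(s[1], dtype=float)))
    return out


def dunn_test(samples: list[GroupSample], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's post hoc pairwise rank comparisons with tie correction.

    ``adjust`` is one of ``none``, ``bonferroni``, ``holm``.  Returns a table
    with one row per group pair: z statistic, raw and adjusted two-sided p.
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError("adjust must be 'none', 'bonferroni' or 'holm'")
    pooled = np.concatenate([s.values for s in samples])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction over pooled tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_term -= tie_sum / (12.0 * (n_total - 1))

    mean_ranks, sizes = {}, {}
    pos = 0
    for s in samples:
        n = len(s.values)
        mean_ranks[s.label] = float(np.mean(ranks[pos : pos + n]))
        sizes[s.label] = n
        pos += n

    rows = []
    for a, b in combinations([s.label for s in samples], 2):
        se = np.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adjusted"] = table["p_raw"]
    else:
        table["p_adjusted"] = multipletests(table["p_raw"], method=adjust)[1]
    return table


def _tukey_table(samples: list[GroupSample]) -> pd.DataFrame:
    res = sps.tukey_hsd(*[s.values for s in samples])
    labels = [s.label for s in samples]
    rows = [
        {
            "group_a": labels[i],
            "group_b": labels[j],
            "statistic": float(res.statistic[i, j]),
            "p_adjusted": float(res.pvalue[i, j]),
        }
        for i, j in combinations(range(len(labels)), 2)
    ]
    return pd.DataFrame(rows)


def route_and_compare(
    samples,
    alpha: float = 0.05,
    posthoc_adjust: str = "holm",
) -> ComparisonResult:
    """Check assumptions, route to the appropriate omnibus test, run post hoc.

    Parametric route (one-way ANOVA + Tukey HSD) requires every group's
    Shapiro-Wilk p > alpha AND Levene's (median-centered) p > alpha;
    otherwise the rank route (tie-corrected Kruskal-Wallis + Dunn) is taken.
    ``significant`` flags omnibus p <= alpha; the post hoc table is attached
    only in that case.
    """
    samples = _as_samples(samples)
    if len(samples) < 2:
        raise ValueError("at least two groups are required")
    for s in samples:
        if len(s.values) < 3:
            raise ValueError(
                f"group {s.label!r} has {len(s.values)} values; "
                "Shapiro-Wilk needs at least 3"
            )

    shapiro_p = {}
    for s in samples:
        if np.ptp(s.values) == 0:  # constant: normality test undefined, treat as non-normal
            shapiro_p[s.label] = 0.0
        else:
            shapiro_p[s.label] = float(sps.shapiro(s.values).pvalue)
    arrays = [s.values for s in samples]
    if np.ptp(np.concatenate(arrays)) == 0:  # all identical: no variances to compare
        levene_p = 1.0
    else:
        levene_p = float(sps.levene(*arrays, center="median").pvalue)

    parametric = all(p > alpha for p in shapiro_p.values()) and levene_p > alpha
    if parametric:
        route = "anova_tukey"
        stat, p = sps.f_oneway(*arrays)
        stat, p = float(stat), float(p)
    else:
        route = "kruskal_dunn"
        if np.ptp(np.concatenate(arrays)) == 0:  # all values identical: H degenerate
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*arrays)
            stat, p = float(stat), float(p)
    if np.isnan(p):  # degenerate (e.g. zero within-group variance ANOVA)
        stat, p = 0.0, 1.0

    significant = p <= alpha
    posthoc = None
    if significant:
        posthoc = (
            _tukey_table(samples) if route == "anova_tukey" else dunn_test(samples, posthoc_adjust)
        )

    return ComparisonResult(
        route=route,
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        omnibus_statistic=stat,
        omnibus_p=p,
        alpha=alpha,
        significant=significant,
        posthoc=posthoc,
        assumptions={"normality_ok": all(p_ > alpha for p_ in shapiro_p.values()),
                     "equal_variance_ok": levene_p > alpha},
    )


def type1_error_sim(
    n_per_group: int = 8,
    n_groups: int = 3,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    dist: str = "normal",
) -> float:
    """Monte-Carlo type-I error of the full two-stage procedure under the null.

    All groups are drawn from the same distribution (``normal`` or
    ``lognormal``); returns the fraction of simulations whose omnibus p is
    at or below alpha.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful rate")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        if dist == "normal":
            data = rng.normal(0.0, 1.0, size=(n_groups, n_per_group))
        elif dist == "lognormal":
            data = rng.lognormal(0.0, 1.0, size=(n_groups, n_per_group))
        else:
            raise ValueError(f"unknown dist {dist!r}")
        res = route_and_compare(
            [GroupSample(str(i), row) for i, row in enumerate(data)], alpha=alpha
        )
        if res.significant:
            rejections += 1
    return rejections / reps
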