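"""Group comparison of vascular parameters across MNV types 1/2/3.

For each parameter the analysis first checks the one-way-ANOVA
preconditions — variance homogeneity (Levene) and normality of the
groupwise-centered residuals (Shapiro–Wilk).  If either fails at the chosen
level, the omnibus test is Kruskal–Wallis (with mid-rank tie correction)
followed by Dunn's pairwise post hoc z tests; otherwise one-way ANOVA
followed by pairwise pooled-variance t tests.  Pairwise p-values are
Bonferroni-adjusted by the number of pairs (3), per parameter; no
cross-parameter adjustment is applied.

Kruskal–Wallis and Dunn are implemented here (they carry the tie-correction
conventions the results depend on); Levene, Shapiro–Wilk, ANOVA and the t
test are delegated to scipy.stats with degenerate inputs handled explicitly.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "levene_test",
    "shapiro_wilk",
    "kruskal_wallis",
    "dunn_posthoc",
    "one_way_anova",
    "compare_types",
    "GroupComparisonResult",
    "PairwiseResult",
    "PARAMETERS",
]

logger = logging.getLogger(__name__)

#: canonical parameter order (matches the metrics CSV columns)
PARAMETERS = ["area_mm2", "fd", "numN_per_mm2", "flow_pct", "sumL_mm", "avgW_um"]


@dataclass
class PairwiseResult:
    pair: tuple[int, int]
    statistic: float  # Dunn z or t, signed
    p_raw: float
    p_adj: float


@dataclass
class GroupComparisonResult:
    parameter: str
    levene_p: float
    shapiro_p: float
    omnibus_method: str  # "anova" | "kruskal_wallis"
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    degenerate: bool = False
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "levene_p": self.levene_p,
            "shapiro_p": self.shapiro_p,
            "omnibus_method": self.omnibus_method,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "degenerate": self.degenerate,
            "n_dropped": self.n_dropped,
            "pairwise": [
                {
                    "pair": list(p.pair),
                    "statistic": p.statistic,
                    "p_raw": p.p_raw,
                    "p_adj": p.p_adj,
                }
                for p in self.pairwise
            ],
        }


def _as_groups(groups) -> list[np.ndarray]:
    return [np.asarray(g, dtype=np.float64) for g in groups]


def levene_test(*groups) -> tuple[float, float]:
    """Classic (mean-centered) Levene test for variance homogeneity.

    Equivalent to a one-way ANOVA on absolute deviations from the group
    means.  If every deviation is zero (all groups constant) the statistic is
    defined as 0 with p = 1, with a warning.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("levene_test needs >= 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs n >= 2 for the Levene test")
    devs = [np.abs(g - g.mean()) for g in gs]
    if all(np.all(d == 0) for d in devs):
        warnings.warn("all groups constant; Levene statistic defined as 0, p = 1")
        return 0.0, 1.0
    if np.var(np.concatenate(devs)) == 0:
        # identical deviation profiles (e.g. identical groups): W = 0 exactly
        return 0.0, 1.0
    w, p = sps.levene(*gs, center="mean")
    return float(w), float(p)


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro–Wilk normality test, valid for 3 <= n <= 5000."""
    x = np.asarray(residuals, dtype=np.float64)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n = {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("constant sample; Shapiro-Wilk undefined, returning p = 1")
        return 1.0, 1.0
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _pooled_ranks(gs: list[np.ndarray]) -> tuple[list[np.ndarray], float]:
    """Mid-ranks of the pooled sample split back per group, plus tie term Σ(t³−t)."""
    pooled = np.concatenate(gs)
    ranks = sps.rankdata(pooled, method="average")
    out, i = [], 0
    for g in gs:
        out.append(ranks[i : i + g.size])
        i += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(np.float64) ** 3 - counts))
    return out, tie_term


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis H with mid-rank tie correction; p from χ²(k−1).

    H = [12 / (N(N+1))] Σ nᵢ R̄ᵢ² − 3(N+1), divided by 1 − Σ(t³−t)/(N³−N).
    If all pooled values are identical the correction vanishes; the result is
    defined as H = 0, p = 1 with a warning.
    """
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("kruskal_wallis needs >= 2 nonempty groups")
    n_total = sum(g.size for g in gs)
    if n_total < 3:
        raise ValueError("kruskal_wallis needs total N >= 3")
    group_ranks, tie_term = _pooled_ranks(gs)
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:
        warnings.warn("all values identical; Kruskal-Wallis defined as H = 0, p = 1")
        return 0.0, 1.0
    h = (12.0 / (n_total * (n_total + 1))) * sum(
        r.size * r.mean() ** 2 for r in group_ranks
    ) - 3.0 * (n_total + 1)
    h /= correction
    df = len(gs) - 1
    return float(h), float(sps.chi2.sf(h, df))


def dunn_posthoc(*groups, bonferroni_factor: int | None = None) -> list[PairwiseResult]:
    """Dunn's post hoc z tests on pooled mean ranks, Bonferroni-adjusted.

    z_ij = (R̄ᵢ − R̄ⱼ) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/nᵢ + 1/nⱼ)]

    p_raw is two-sided normal; p_adj = min(1, m·p_raw) with m the number of
    pairs (3 for three groups) unless overridden.
    """
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("dunn_posthoc needs >= 2 nonempty groups")
    n_total = sum(g.size for g in gs)
    group_ranks, tie_term = _pooled_ranks(gs)
    mean_ranks = [r.mean() for r in group_ranks]
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(range(len(gs)), 2))
    m = bonferroni_factor if bonferroni_factor is not None else len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / gs[i].size + 1.0 / gs[j].size))
        if se == 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out.append(
            PairwiseResult(
                pair=(i + 1, j + 1),
                statistic=float(z),
                p_raw=p_raw,
                p_adj=min(1.0, m * p_raw),
            )
        )
    return out


def one_way_anova(*groups) -> tuple[float, float]:
    """Standard one-way ANOVA F and p; degenerate within-variance handled."""
    gs = _as_groups(groups)
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("one_way_anova needs >= 2 groups with n >= 2 each")
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ssw == 0:
        if ssb == 0:
            warnings.warn("all values identical; ANOVA defined as F = 0, p = 1")
            return 0.0, 1.0
        warnings.warn("zero within-group variance; F diverges, p -> 0")
        return float("inf"), 0.0
    f, p = sps.f_oneway(*gs)
    return float(f), float(p)


def _pairwise_t(gs: list[np.ndarray], m: int) -> list[PairwiseResult]:
    out = []
    for i, j in itertools.combinations(range(len(gs)), 2):
        t, p = sps.ttest_ind(gs[i], gs[j], equal_var=True)
        p = float(p)
        out.append(
            PairwiseResult(pair=(i + 1, j + 1), statistic=float(t), p_raw=p,
                           p_adj=min(1.0, m * p))
        )
    return out


def compare_types(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    parameters: list[str] | None = None,
) -> list[GroupComparisonResult]:
    """Per-parameter three-group comparison of a cohort table.

    ``cohort`` must have ``mnv_type`` in {1, 2, 3} plus the metric columns.
    Rows with a missing value for a parameter are dropped for that parameter
    (with a logged count).  Precondition checks (Levene on the three groups,
    Shapiro–Wilk on pooled groupwise-centered residuals) decide the branch:
    Kruskal–Wallis + Dunn if either p < alpha, else ANOVA + pairwise t.
    """
    parameters = parameters or [p for p in PARAMETERS if p in cohort.columns]
    types = sorted(cohort["mnv_type"].unique().tolist())
    if types != [1, 2, 3]:
        raise ValueError(f"cohort must contain MNV types 1, 2, 3; found {types}")
    results = []
    for param in parameters:
        sub = cohort[["mnv_type", param]]
        n_dropped = int(sub[param].isna().sum())
        if n_dropped:
            logger.info("%s: dropping %d rows with missing values", param, n_dropped)
            sub = sub.dropna(subset=[param])
        gs = [sub.loc[sub["mnv_type"] == t, param].to_numpy(np.float64) for t in (1, 2, 3)]
        if any(g.size < 2 for g in gs):
            raise ValueError(f"{param}: every MNV type needs >= 2 values")
        residuals = np.concatenate([g - g.mean() for g in gs])
        degenerate = bool(np.ptp(np.concatenate(gs)) == 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, levene_p = levene_test(*gs)
            _, shapiro_p = shapiro_wilk(residuals)
            if degenerate:
                results.append(
                    GroupComparisonResult(
                        parameter=param, levene_p=levene_p, shapiro_p=shapiro_p,
                        omnibus_method="kruskal_wallis", omnibus_stat=0.0, omnibus_p=1.0,
                        pairwise=dunn_posthoc(*gs), degenerate=True, n_dropped=n_dropped,
                    )
                )
                continue
            if levene_p < alpha or shapiro_p < alpha:
                stat, p = kruskal_wallis(*gs)
                pairwise = dunn_posthoc(*gs)
                method = "kruskal_wallis"
            else:
                stat, p = one_way_anova(*gs)
                pairwise = _pairwise_t(gs, m=3)
                method = "anova"
        results.append(
            GroupComparisonResult(
                parameter=param, levene_p=levene_p, shapiro_p=shapiro_p,
                omnibus_method=method, omnibus_stat=stat, omnibus_p=p,
                pairwise=pairwise, degenerate=degenerate, n_dropped=n_dropped,
            )
        )
    return results
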