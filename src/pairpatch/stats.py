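"""Group-level statistics behind the reporting layer.

All standard tests are delegated to scipy/statsmodels; only Dunn's
rank-based post-hoc (not available in the installed stack) is computed
here from its textbook definition (pairwise z tests on mean ranks with a
tie correction and Bonferroni adjustment).  Significance convention:
p < 0.05, recorded alongside the exact inputs for audit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

TESTS = ("mann_whitney", "paired_t", "kruskal_wallis_dunn", "chi_square",
         "two_way_anova")


@dataclass(frozen=True)
class GroupComparison:
    """Result of one group comparison, with inputs retained for audit."""

    test: str
    statistic: float
    p_value: float
    groups: dict[str, np.ndarray]
    posthoc: Optional[pd.DataFrame] = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}


def _check_groups(groups: dict[str, np.ndarray], min_groups: int = 2
                  ) -> dict[str, np.ndarray]:
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    clean = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        if not np.isfinite(arr).all():
            raise ValueError(f"group {name!r} contains non-finite values")
        clean[name] = arr
    return clean


def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's multiple-comparison test on pooled ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with
    the tie correction T = sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts ** 3 - counts).sum() / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie
    mean_rank = {}
    start = 0
    for n in names:
        k = len(groups[n])
        mean_rank[n] = ranks[start:start + k].mean()
        start += k
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": z,
                     "p_value": p, "p_adjusted": p_adj})
    return pd.DataFrame(rows)


def _two_way_anova(df: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Type-II two-way ANOVA via statsmodels, plus pairwise Mann-Whitney.

    The pairwise Mann-Whitney table is exposed alongside the ANOVA (the
    combination used in some experimental reports) without asserting one
    as the canonical post-hoc.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(factor_a) * C(factor_b)", data=df).fit()
    an = sm.stats.anova_lm(model, typ=2)
    rows = []
    cells = {name: g["value"].to_numpy()
             for name, g in df.groupby(["factor_a", "factor_b"])}
    for (na, va), (nb, vb) in itertools.combinations(cells.items(), 2):
        if len(va) and len(vb):
            u, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append({"cell_a": str(na), "cell_b": str(nb),
                         "U": float(u), "p_value": float(p)})
    posthoc = pd.DataFrame(rows)
    main = an.iloc[0]
    return float(main["F"]), float(main["PR(>F)"]), posthoc


def group_compare(test: str,
                  groups: Optional[dict[str, Sequence[float]]] = None,
                  table: Optional[np.ndarray] = None,
                  data: Optional[pd.DataFrame] = None) -> GroupComparison:
    """Run one named group comparison.

    * ``mann_whitney`` — two independent groups, two-sided.
    * ``paired_t`` — two equal-length paired samples; a zero-variance
      difference yields p = NaN with a note instead of a crash.
    * ``kruskal_wallis_dunn`` — >=2 groups with Dunn's post-hoc table.
    * ``chi_square`` — Pearson's on a 2 x k ``table`` (no continuity
      correction).
    * ``two_way_anova`` — ``data`` with columns value/factor_a/factor_b;
      the post-hoc table holds pairwise Mann-Whitney results.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}")
    if test == "chi_square":
        if table is None:
            raise ValueError("chi_square needs a contingency table")
        arr = np.asarray(table, float)
        chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
        return GroupComparison(test=test, statistic=float(chi2),
                               p_value=float(p),
                               groups={"table": arr.ravel()})
    if test == "two_way_anova":
        if data is None:
            raise ValueError("two_way_anova needs a data frame")
        f, p, posthoc = _two_way_anova(data)
        return GroupComparison(test=test, statistic=f, p_value=p,
                               groups={"value": data["value"].to_numpy()},
                               posthoc=posthoc)
    if groups is None:
        raise ValueError(f"{test} needs groups")
    g = _check_groups(dict(groups))
    names = list(g)
    if test == "mann_whitney":
        if len(names) != 2:
            raise ValueError("mann_whitney compares exactly two groups")
        u, p = sps.mannwhitneyu(g[names[0]], g[names[1]],
                                alternative="two-sided")
        return GroupComparison(test=test, statistic=float(u),
                               p_value=float(p), groups=g)
    if test == "paired_t":
        if len(names) != 2:
            raise ValueError("paired_t compares exactly two groups")
        a, b = g[names[0]], g[names[1]]
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        diff = a - b
        if np.allclose(diff.std(), 0.0):
            p = 1.0 if np.allclose(diff, 0.0) else math.nan
            return GroupComparison(test=test, statistic=math.nan, p_value=p,
                                   groups=g, note="zero-variance differences")
        t, p = sps.ttest_rel(a, b)
        return GroupComparison(test=test, statistic=float(t),
                               p_value=float(p), groups=g)
    # kruskal_wallis_dunn
    h, p = sps.kruskal(*[g[n] for n in names])
    posthoc = dunn_posthoc(g)
    return GroupComparison(test=test, statistic=float(h), p_value=float(p),
                           groups=g, posthoc=posthoc)
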