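"""Per-species altitudinal bias tests and between-group exact contrasts.

Each species' occurrence pattern is tested for altitudinal bias by
comparing altitude between occupied and unoccupied lakes with a two-tailed
Welch t-test (equal variances not assumed).  Groups are then contrasted on
the proportion of significant species with two-sided Fisher exact tests.

No multiple-testing correction is applied across the per-species tests;
each p-value is reported as-is, which is a deliberate, documented caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityMatrix, SiteTable


@dataclass
class BiasTestResult:
    species: str
    t_stat: float
    df: float
    p_two_sided: float
    direction: str  # {"low", "high", "none"}
    testable: bool = True


@dataclass
class GroupContrast:
    group_a: str
    group_b: str
    a_hits: int
    a_total: int
    b_hits: int
    b_total: int
    p_two_sided: float


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Two-sample t-test without the equal-variance assumption.

    Returns ``(t, df, p_two_sided)`` with Welch–Satterthwaite fractional
    degrees of freedom.  Two constant samples with equal means give
    (0, df, 1) by convention; constant samples with unequal means are a
    degenerate input and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires at least two values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both samples constant with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def altitude_bias_test(
    presence, sites: SiteTable, species: str = "", alpha: float = 0.05
) -> BiasTestResult:
    """Test whether a species' occupied lakes sit at biased altitudes.

    ``presence`` is a boolean/0-1 vector over the site table's lakes.
    Species leaving fewer than two lakes on either side are flagged
    untestable rather than tested.
    """
    pres = np.asarray(presence).astype(bool)
    alt = sites.altitude.to_numpy(dtype=float)
    if pres.size != alt.size:
        raise ValueError("presence vector length does not match site table")
    occ, unocc = alt[pres], alt[~pres]
    if occ.size < 2 or unocc.size < 2:
        return BiasTestResult(species, np.nan, np.nan, np.nan, "none", testable=False)
    t, df, p = welch_t_test(occ, unocc)
    if p < alpha and occ.mean() != unocc.mean():
        direction = "low" if occ.mean() < unocc.mean() else "high"
    else:
        direction = "none"
    return BiasTestResult(species, t, df, p, direction)


def bias_test_table(cm: CommunityMatrix, sites: SiteTable, alpha: float = 0.05) -> pd.DataFrame:
    """Altitudinal bias test for every species of a community matrix."""
    cm = cm.align_to(sites)
    pres = cm.counts.to_numpy() > 0
    rows = []
    for j, sp in enumerate(cm.species):
        r = altitude_bias_test(pres[:, j], sites, species=sp, alpha=alpha)
        rows.append(
            (r.species, r.t_stat, r.df, r.p_two_sided,
             bool(r.testable and r.p_two_sided < alpha), r.direction, r.testable)
        )
    return pd.DataFrame(rows, columns=["species", "t", "df", "p", "biased", "direction", "testable"])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Uses the minimum-likelihood rule: the sum of hypergeometric
    probabilities of all tables with the observed margins that are no more
    probable than the observed table.  A zero margin gives p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_group_proportions(groups: list[tuple[str, int, int]]) -> list[GroupContrast]:
    """All pairwise Fisher contrasts of (hits, total) proportions."""
    if len(groups) < 2:
        raise ValueError("need at least two groups to contrast")
    out: list[GroupContrast] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            na, ha, ta = groups[i][0], groups[i][1], groups[i][2]
            nb, hb, tb = groups[j][0], groups[j][1], groups[j][2]
            if ha > ta or hb > tb:
                raise ValueError("hits exceed totals")
            p = fisher_exact_2x2(ha, ta - ha, hb, tb - hb)
            out.append(GroupContrast(na, nb, ha, ta, hb, tb, p))
    return out


def contrasts_to_frame(contrasts: list[GroupContrast], metric: str) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.group_a, c.group_b, metric, c.a_hits, c.a_total, c.b_hits, c.b_total, c.p_two_sided)
         for c in contrasts],
        columns=["group_a", "group_b", "metric", "a_hits", "a_total", "b_hits", "b_total", "p"],
    )
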