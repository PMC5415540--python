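"""Randomization null for altitudinal range conditioned on occupancy.

A species found in k of the N surveyed lakes has an observed altitudinal
range (highest minus lowest occupied altitude).  Under the null hypothesis
that occupied lakes are a uniformly random k-subset of the survey, the
range has a distribution that depends only on k and the survey altitudes.
Species whose observed range falls below the lower envelope of that null
distribution are *narrow-ranging*: more altitudinally cohesive than random
placement predicts.

Two routes to the null are provided:

* :func:`exhaustive_null_range` — the exact distribution, obtained by
  enumerating subsets.  Because the range depends only on the minimum and
  maximum of the subset, the enumeration reduces to counting, for each
  ordered altitude pair (i, j), the C(j-i-1, k-2) subsets pinned at those
  extremes; this is O(N^2) rather than O(C(N, k)).
* :func:`null_range_distribution` — Monte Carlo resampling (k altitudes
  drawn without replacement, repeated ``n_rep`` times), the workhorse for
  survey-sized N where full enumeration is unnecessary.

Envelope quantiles use the inverse-ECDF (order statistic) rule throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .community import CommunityMatrix, SiteTable

DEFAULT_N_REP = 9999


@dataclass
class SpeciesAltitudeSummary:
    species: str
    k: int
    mean_alt: float
    range_alt: float


@dataclass
class RangeNullEnvelope:
    """Two-sided empirical envelope of the null range distribution at occupancy k."""

    k: int
    n_rep: int
    lower: float
    upper: float
    alpha: float
    seed: int | None


@dataclass
class NarrowRangingCall:
    species: str
    narrow: bool
    observed_range: float
    null_lower: float


def species_altitude_summary(cm: CommunityMatrix, sites: SiteTable) -> list[SpeciesAltitudeSummary]:
    """Per-species occupancy, mean and range of occupied-lake altitudes.

    Species occupying zero lakes are excluded with a warning.
    """
    cm = cm.align_to(sites)
    alt = sites.altitude.loc[cm.sites].to_numpy(dtype=float)
    pres = cm.counts.to_numpy() > 0
    out: list[SpeciesAltitudeSummary] = []
    for j, sp in enumerate(cm.species):
        occ = alt[pres[:, j]]
        if occ.size == 0:
            warnings.warn(f"species {sp!r} occupies no site; excluded from summaries")
            continue
        out.append(
            SpeciesAltitudeSummary(
                species=sp,
                k=int(occ.size),
                mean_alt=float(occ.mean()),
                range_alt=float(occ.max() - occ.min()),
            )
        )
    return out


def summaries_to_frame(summaries: list[SpeciesAltitudeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.species, s.k, s.mean_alt, s.range_alt) for s in summaries],
        columns=["species", "k", "mean_alt", "range_alt"],
    )


def group_mean_span(summaries: list[SpeciesAltitudeSummary]) -> float:
    """Difference between the highest and the lowest species mean altitude."""
    if not summaries:
        raise ValueError("group_mean_span requires at least one species summary")
    means = [s.mean_alt for s in summaries]
    return float(max(means) - min(means))


def _ecdf_quantile(sorted_values: np.ndarray, p: float) -> float:
    """Inverse-ECDF (type-1) quantile: the ceil(p*n)-th order statistic."""
    n = sorted_values.size
    idx = max(int(np.ceil(p * n)) - 1, 0)
    return float(sorted_values[min(idx, n - 1)])


def simulate_null_ranges(
    altitudes: np.ndarray, k: int, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """``n_rep`` ranges of k altitudes drawn without replacement."""
    alt = np.asarray(altitudes, dtype=float)
    n = alt.size
    # vectorised sampling without replacement: k smallest of n uniform keys
    keys = rng.random((n_rep, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    draws = alt[idx]
    return draws.max(axis=1) - draws.min(axis=1)


def null_range_distribution(
    altitudes,
    k: int,
    n_rep: int = DEFAULT_N_REP,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> RangeNullEnvelope:
    """Monte-Carlo null envelope for the altitudinal range at occupancy ``k``.

    The envelope is the two-sided empirical [alpha/2, 1 - alpha/2] interval
    of the resampled range distribution.
    """
    alt = np.asarray(altitudes, dtype=float)
    n = alt.size
    if k < 2 or k > n:
        raise ValueError(f"occupancy k={k} outside [2, {n}]")
    if isinstance(seed, np.random.Generator):
        rng, seed_val = seed, None
    else:
        rng, seed_val = np.random.default_rng(seed), seed
    ranges = np.sort(simulate_null_ranges(alt, k, n_rep, rng))
    return RangeNullEnvelope(
        k=k,
        n_rep=n_rep,
        lower=_ecdf_quantile(ranges, alpha / 2),
        upper=_ecdf_quantile(ranges, 1 - alpha / 2),
        alpha=alpha,
        seed=seed_val,
    )


def exhaustive_null_range(
    altitudes, k: int, enumeration_cap: int | None = 10**6
) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the range over all k-subsets.

    Returns ``(values, probabilities)`` with values sorted ascending.  The
    count of subsets whose extremes are the i-th and j-th sorted altitudes
    is C(j - i - 1, k - 2), so the full pmf costs O(N^2) regardless of
    C(N, k); the cap (disabled with ``None``) keeps the default behaviour
    conservative for survey-sized problems where Monte Carlo is intended.
    """
    alt = np.sort(np.asarray(altitudes, dtype=float))
    n = alt.size
    if k < 2 or k > n:
        raise ValueError(f"occupancy k={k} outside [2, {n}]")
    total = comb(n, k)
    if enumeration_cap is not None and total > enumeration_cap:
        raise ValueError(
            f"C({n},{k})={total} exceeds enumeration cap {enumeration_cap}; "
            "use null_range_distribution (Monte Carlo) instead"
        )
    masses: dict[float, int] = {}
    for i in range(n):
        for j in range(i + k - 1, n):
            c = comb(j - i - 1, k - 2)
            if c:
                r = float(alt[j] - alt[i])
                masses[r] = masses.get(r, 0) + c
    values = np.array(sorted(masses), dtype=float)
    probs = np.array([masses[v] for v in values], dtype=float) / total
    return values, probs


def exact_quantile(values: np.ndarray, probs: np.ndarray, p: float) -> float:
    """Smallest support value whose cumulative probability reaches ``p``."""
    cdf = np.cumsum(probs)
    idx = int(np.searchsorted(cdf, p, side="left"))
    return float(values[min(idx, values.size - 1)])


def classify_narrow_ranging(
    summaries: list[SpeciesAltitudeSummary],
    altitudes,
    n_rep: int = DEFAULT_N_REP,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> list[NarrowRangingCall]:
    """Flag species whose observed range falls below the null lower envelope.

    One envelope is computed per distinct occupancy k and shared by all
    species at that k (the null depends on k only).
    """
    alt = np.asarray(altitudes, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    envelopes: dict[int, RangeNullEnvelope] = {}
    calls: list[NarrowRangingCall] = []
    for s in sorted(summaries, key=lambda s: s.k):
        if s.k not in envelopes:
            envelopes[s.k] = null_range_distribution(alt, s.k, n_rep=n_rep, alpha=alpha, seed=rng)
        env = envelopes[s.k]
        calls.append(
            NarrowRangingCall(
                species=s.species,
                narrow=bool(s.range_alt < env.lower),
                observed_range=s.range_alt,
                null_lower=env.lower,
            )
        )
    order = {s.species: i for i, s in enumerate(summaries)}
    calls.sort(key=lambda c: order[c.species])
    return calls
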