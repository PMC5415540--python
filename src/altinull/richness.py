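"""Species richness along altitude: linear vs quadratic models under AICc.

Per-site richness (number of species present) is regressed on altitude
with ordinary least squares, once linearly and once with a quadratic term.
The preferred model is the one with the lower AICc — the Akaike criterion
with the second-order small-sample correction 2p(p + 1)/(n - p - 1), where
the parameter count p includes the residual variance.  The nested models
are additionally compared with a chi-squared test on the Gaussian deviance
table.  A selected quadratic with negative curvature whose vertex lies
inside the observed altitude span yields a peak-altitude estimate — the
signature of a unimodal (mid-elevation) richness pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .community import CommunityMatrix
from .ordination import adjusted_r2


@dataclass
class RichnessModelFit:
    degree: int
    coefficients: np.ndarray  # intercept, linear[, quadratic]
    r2: float
    adj_r2: float
    p_model: float
    aicc: float
    rss: float
    n: int


@dataclass
class RichnessModelPair:
    linear: RichnessModelFit
    quadratic: RichnessModelFit
    selected: str  # {"linear", "quadratic"}
    delta_aicc: float
    deviance_p: float
    peak_altitude: float | None
    peak_reason: str | None = None


def species_richness(cm: CommunityMatrix) -> pd.Series:
    """Number of species with count > 0 at each site."""
    return (cm.counts > 0).sum(axis=1).rename("richness")


def aicc(rss: float, n: int, p_model: int) -> float:
    """Small-sample AIC for a Gaussian model with RSS and p parameters.

    Uses the full log-likelihood convention (the n·ln(2π) + n constant is
    retained), with ``p_model`` counting the residual variance.
    """
    if rss <= 0:
        raise ValueError("aicc requires rss > 0")
    if n <= p_model + 1:
        raise ValueError(f"aicc undefined for n={n}, p={p_model}")
    p = p_model
    return float(n * np.log(rss / n) + n * np.log(2 * np.pi) + n
                 + 2 * p + 2 * p * (p + 1) / (n - p - 1))


def fit_polynomial_richness(richness, altitude, degree: int) -> RichnessModelFit:
    """OLS of richness on altitude powers 1..degree (degree 1 or 2)."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = np.asarray(richness, dtype=float)
    x = np.asarray(altitude, dtype=float)
    n = y.size
    if n <= degree + 2:
        raise ValueError("too few sites for this polynomial degree")
    if np.ptp(x) == 0:
        raise ValueError("constant altitude: design is degenerate")
    X = sm.add_constant(np.column_stack([x**d for d in range(1, degree + 1)]))
    fit = sm.OLS(y, X).fit()
    rss = float(fit.ssr)
    return RichnessModelFit(
        degree=degree,
        coefficients=np.asarray(fit.params, dtype=float),
        r2=float(fit.rsquared),
        adj_r2=adjusted_r2(float(fit.rsquared), n, degree),
        p_model=float(fit.f_pvalue),
        aicc=aicc(rss, n, degree + 2),  # intercept + slopes + residual variance
        rss=rss,
        n=n,
    )


def quadratic_peak(fit: RichnessModelFit, altitude_range: tuple[float, float]) -> tuple[float | None, str | None]:
    """Vertex of a degree-2 fit, if it is an interior maximum.

    Returns ``(peak, None)`` or ``(None, reason)`` where the reason is one
    of ``flat``, ``u_shaped`` or ``extrapolated``.
    """
    if fit.degree != 2:
        raise ValueError("quadratic_peak requires a degree-2 fit")
    b1, b2 = fit.coefficients[1], fit.coefficients[2]
    if b2 == 0:
        return None, "flat"
    if b2 > 0:
        return None, "u_shaped"
    peak = -b1 / (2 * b2)
    lo, hi = altitude_range
    if not (lo <= peak <= hi):
        return None, "extrapolated"
    return float(peak), None


def compare_models(linear: RichnessModelFit, quadratic: RichnessModelFit,
                   altitude_range: tuple[float, float] | None = None) -> RichnessModelPair:
    """AICc selection and deviance chi-squared comparison of nested fits.

    The deviance statistic (RSS_lin - RSS_quad)/sigma2, with the dispersion
    estimated from the richer model, is referred to chi-squared with 1 df.
    """
    if linear.degree != 1 or quadratic.degree != 2 or linear.n != quadratic.n:
        raise ValueError("compare_models expects nested degree-1/degree-2 fits on the same data")
    n = linear.n
    sigma2 = quadratic.rss / (n - 3)
    dev = max(linear.rss - quadratic.rss, 0.0) / sigma2
    deviance_p = float(stats.chi2.sf(dev, df=1))
    selected = "linear" if linear.aicc <= quadratic.aicc else "quadratic"
    peak, reason = None, None
    if selected == "quadratic" and altitude_range is not None:
        peak, reason = quadratic_peak(quadratic, altitude_range)
    return RichnessModelPair(
        linear=linear,
        quadratic=quadratic,
        selected=selected,
        delta_aicc=float(quadratic.aicc - linear.aicc),
        deviance_p=deviance_p,
        peak_altitude=peak,
        peak_reason=reason,
    )


def richness_model_table(pair: RichnessModelPair, group: str) -> pd.DataFrame:
    """Two-row summary mirroring a per-group model-comparison table."""
    rows = []
    for name, fit in (("linear", pair.linear), ("quadratic", pair.quadratic)):
        rows.append((group, name, fit.r2, fit.adj_r2, fit.p_model, fit.aicc,
                     name == pair.selected,
                     pair.peak_altitude if name == "quadratic" else None))
    return pd.DataFrame(rows, columns=["group", "model", "r2", "adj_r2", "p", "aicc",
                                       "selected", "peak_altitude"])
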