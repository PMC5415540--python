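"""Constrained ordination: Hellinger RDA, forward selection, vector fitting.

Redundancy analysis (RDA) is the principal-component decomposition of the
fitted values from a multivariate least-squares regression of a (here
Hellinger-transformed) community matrix Y on environmental predictors X.
The fraction of community variance captured by the constrained axes is R²;
the Ezekiel adjustment 1 - (1 - R²)(n - 1)/(n - m - 1) corrects its
optimism for m predictors at n sites.

Significance is assessed by Monte-Carlo permutation of the response rows
(pseudo-F, add-one rule).  Variables enter the model by forward selection
under a double-stopping criterion: a candidate is admitted only while its
partial permutation p-value stays below alpha AND the cumulative adjusted
R² stays at or below that of the global (all-candidate) model, after the
global model itself has passed the permutation test.  This combination
controls the inflated type-I error and over-fitting of naive forward
selection.

Environmental preprocessing mirrors standard practice for limnological
variables: variables departing from normality are log(x + 1)-transformed
(zeros and negative values first replaced by a small positive constant one
order of magnitude below the lowest positive measurement), while
percentage-scale habitat variables, pH (already logarithmic) and 0/1
nominal variables are left untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .community import CommunityMatrix, SiteTable


# ---------------------------------------------------------------------------
# environmental preprocessing
# ---------------------------------------------------------------------------

@dataclass
class TransformRule:
    """Per-variable preprocessing action.

    ``action`` is one of ``keep``, ``log1p`` or ``substitute_then_log1p``;
    the latter replaces non-positive values with ``zero_substitute`` before
    the log(x + 1) transform.
    """

    variable: str
    action: str
    zero_substitute: float | None = None

    def __post_init__(self) -> None:
        if self.action not in {"keep", "log1p", "substitute_then_log1p"}:
            raise ValueError(f"unknown transform action {self.action!r}")
        if self.action == "substitute_then_log1p":
            if self.zero_substitute is None or self.zero_substitute <= 0:
                raise ValueError("substitute_then_log1p requires a positive zero_substitute")


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    reject: bool


def ks_normality(values, alpha: float = 0.05, variant: str = "lilliefors") -> NormalityResult:
    """One-sample KS test of normality with estimated mean and SD.

    ``variant='lilliefors'`` (default) uses critical values corrected for
    parameter estimation; ``variant='plain'`` compares the KS statistic to
    the uncorrected reference distribution, which is conservative.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError("ks_normality requires at least 5 finite values")
    if np.ptp(x) == 0:
        raise ValueError("ks_normality undefined for a constant sample")
    if variant == "lilliefors":
        stat, p = _lilliefors(x, dist="norm", pvalmethod="table")
    elif variant == "plain":
        stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown KS variant {variant!r}")
    return NormalityResult(float(stat), float(p), bool(p < alpha))


def infer_transform_rules(
    sites: SiteTable,
    alpha: float = 0.05,
    variant: str = "lilliefors",
    zero_substitutes: dict[str, float] | None = None,
) -> list[TransformRule]:
    """Decide per-variable transforms from kind and a normality test.

    Percentage, pH and nominal variables are kept as-is.  Concentration
    variables failing the normality test get log(x + 1); those containing
    zeros or negatives additionally need a ``zero_substitutes`` entry.
    """
    zero_substitutes = zero_substitutes or {}
    rules: list[TransformRule] = []
    for name in sites.env.columns:
        kind = sites.var_kind[name]
        vals = sites.env[name].to_numpy(dtype=float)
        if kind in {"percentage", "ph", "nominal"}:
            rules.append(TransformRule(name, "keep"))
            continue
        if not ks_normality(vals, alpha=alpha, variant=variant).reject:
            rules.append(TransformRule(name, "keep"))
        elif (vals <= 0).any():
            if name not in zero_substitutes:
                raise ValueError(
                    f"variable {name!r} has non-positive values; provide a zero substitute"
                )
            rules.append(TransformRule(name, "substitute_then_log1p", zero_substitutes[name]))
        else:
            rules.append(TransformRule(name, "log1p"))
    return rules


def transform_env(sites: SiteTable, rules: list[TransformRule]) -> SiteTable:
    """Apply transform rules; every environmental variable must be covered."""
    by_name = {r.variable: r for r in rules}
    missing = set(sites.env.columns) - set(by_name)
    if missing:
        raise ValueError(f"no transform rule for variables: {sorted(missing)}")
    df = sites.data.copy()
    for name in sites.env.columns:
        rule = by_name[name]
        vals = df[name].to_numpy(dtype=float)
        if rule.action == "keep":
            if (vals < 0).any() and sites.var_kind[name] == "concentration":
                # negatives are only meaningful with an explicit substitution
                raise ValueError(f"negative values in {name!r} without a substitution rule")
            continue
        if rule.action == "substitute_then_log1p":
            vals = np.where(vals <= 0, rule.zero_substitute, vals)
        elif (vals < 0).any():
            raise ValueError(f"negative values in {name!r} without a substitution rule")
        df[name] = np.log1p(vals)
    return SiteTable(df, var_kind=dict(sites.var_kind))


# ---------------------------------------------------------------------------
# Hellinger transform and RDA
# ---------------------------------------------------------------------------

def hellinger(cm: CommunityMatrix | np.ndarray) -> np.ndarray:
    """Hellinger transform: sqrt of row-relative abundances.

    All-zero rows map to zero rows; nonzero rows end up with unit
    Euclidean norm, so Euclidean distance between transformed rows equals
    the Hellinger distance between the original rows.
    """
    y = cm.counts.to_numpy(dtype=float) if isinstance(cm, CommunityMatrix) else np.asarray(cm, dtype=float)
    totals = y.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(totals > 0, y / np.where(totals > 0, totals, 1.0), 0.0))
    return out


@dataclass
class RDAResult:
    r2: float
    adj_r2: float
    eigenvalues: np.ndarray
    site_scores: np.ndarray
    species_scores: np.ndarray
    variable_scores: np.ndarray
    n: int
    m: int


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R²)(n - 1)/(n - m - 1)."""
    if n <= m + 1:
        raise ValueError(f"adjusted R2 undefined for n={n}, m={m}")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - m - 1))


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _standardize(a: np.ndarray) -> np.ndarray:
    c = _center(a)
    sd = c.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant predictor column cannot be standardized")
    return c / sd


def rda(Y, X, standardize: bool = True) -> RDAResult:
    """Redundancy analysis of response Y on predictors X.

    Y is column-centered; X is standardized by default (heterogeneous
    units).  Constrained axes are the principal axes of the fitted values.
    Site scores are the unit-scaled left singular vectors (linear-
    combination scores); species scores carry the singular values
    (correlation biplot scaling).  Perfectly collinear predictors are
    handled by least squares on the column space, with a warning, and the
    effective m is the design rank.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, q = Y.shape
    if X.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    Xc = _standardize(X) if standardize else _center(X)
    rank = int(np.linalg.matrix_rank(Xc))
    if rank < Xc.shape[1]:
        warnings.warn("collinear predictors: using least squares on the column space")
    if n <= rank + 1:
        raise ValueError(f"too few sites (n={n}) for m={rank} predictors")
    Yc = _center(Y)
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Yhat = Xc @ B
    ss_tot = float((Yc**2).sum())
    ss_fit = float((Yhat**2).sum())
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(rank, q, int((s > s.max() * 1e-9).sum()) if s.size else 0)
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    eig = s**2 / (n - 1)
    # variable scores: correlations of predictors with the site scores
    var_scores = np.array(
        [[np.corrcoef(Xc[:, j], U[:, a])[0, 1] if U[:, a].std() > 0 else 0.0
          for a in range(n_axes)] for j in range(Xc.shape[1])]
    ) if n_axes else np.zeros((Xc.shape[1], 0))
    return RDAResult(
        r2=r2,
        adj_r2=adjusted_r2(r2, n, rank),
        eigenvalues=eig,
        site_scores=U,
        species_scores=(Vt.T * s),
        variable_scores=var_scores,
        n=n,
        m=rank,
    )


def _fit_projector(Xc: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of the column space of the centered design."""
    Q, R = np.linalg.qr(Xc)
    keep = np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(np.diag(R)).max())
    return Q[:, keep]


def permutation_test_rda(
    Y, X, n_perm: int = 9999, seed: int | np.random.Generator | None = None,
    standardize: bool = True,
) -> tuple[float, float]:
    """Permutation test of the RDA pseudo-F; returns ``(F_observed, p)``.

    Rows of the (centered) response are permuted freely; the p-value uses
    the add-one rule (1 + #{F* >= F}) / (n_perm + 1).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xc = _standardize(X) if standardize else _center(X)
    Q = _fit_projector(Xc)
    m = Q.shape[1]
    n = Y.shape[0]
    if n <= m + 1:
        raise ValueError("too few rows for the permutation pseudo-F")
    Yc = _center(Y)
    ss_tot = float((Yc**2).sum())

    def pseudo_f(Ym: np.ndarray) -> float:
        ss_fit = float(((Q.T @ Ym) ** 2).sum())
        ss_res = max(ss_tot - ss_fit, 1e-300)  # exact fits leave zero residual
        return (ss_fit / m) / (ss_res / (n - m - 1))

    f_obs = pseudo_f(Yc)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(Yc[perm]) >= f_obs:
            count += 1
    return f_obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# forward selection with the double-stopping criterion
# ---------------------------------------------------------------------------

@dataclass
class SelectionStep:
    variable: str
    perm_p: float
    cumulative_adj_r2: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    global_adj_r2: float = np.nan
    global_p: float = np.nan
    stop_reason: str = "exhausted"

    @property
    def selected(self) -> list[str]:
        return [s.variable for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i + 1, s.variable, s.perm_p, s.cumulative_adj_r2) for i, s in enumerate(self.steps)],
            columns=["step", "variable", "perm_p", "cumulative_adj_r2"],
        )


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    adj_r2_tol: float = 1e-10,
) -> SelectionTrace:
    """Forward selection of RDA predictors under the double-stopping rule.

    The global model with all candidates must pass the permutation test at
    ``alpha`` or selection aborts with an empty trace.  At each step the
    candidate adding the most fitted variance (on the response residualized
    for already-selected variables) enters if its partial permutation
    p-value is below alpha and the cumulative adjusted R² does not exceed
    the global model's adjusted R².
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(candidates.columns)
    Xall = _standardize(candidates.to_numpy(dtype=float))

    trace = SelectionTrace()
    global_fit = rda(Y, Xall, standardize=False)
    trace.global_adj_r2 = global_fit.adj_r2
    _, trace.global_p = permutation_test_rda(Y, Xall, n_perm=n_perm, seed=rng, standardize=False)
    if trace.global_p >= alpha:
        trace.stop_reason = "alpha"
        return trace

    remaining = list(range(len(names)))
    selected: list[int] = []
    Yc = _center(Y)
    while remaining:
        if selected:
            Qs = _fit_projector(Xall[:, selected])
            Yres = Yc - Qs @ (Qs.T @ Yc)
            Xres = Xall[:, remaining] - Qs @ (Qs.T @ Xall[:, remaining])
        else:
            Yres = Yc
            Xres = _center(Xall[:, remaining])
        ss_res = float((Yres**2).sum())
        if ss_res <= 0:
            trace.stop_reason = "exhausted"
            break
        # additional fitted SS per candidate on the residualized response
        gains = []
        for c in range(Xres.shape[1]):
            x = Xres[:, c]
            nrm = float(x @ x)
            gains.append(float(((x @ Yres) ** 2).sum()) / nrm if nrm > 1e-12 else -np.inf)
        best_local = int(np.argmax(gains))
        best = remaining[best_local]
        xb = Xres[:, best_local]
        nrm = float(xb @ xb)
        if nrm <= 1e-12:
            trace.stop_reason = "exhausted"
            break
        ub = xb / np.sqrt(nrm)
        m_sel = len(selected)

        def partial_f(Ym: np.ndarray) -> float:
            ss_add = float(((ub @ Ym) ** 2).sum())
            ss_left = max(float((Ym**2).sum()) - ss_add, 1e-300)
            return ss_add / (ss_left / (n - m_sel - 2))

        f_obs = partial_f(Yres)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if partial_f(Yres[perm]) >= f_obs:
                count += 1
        p = (1 + count) / (n_perm + 1)
        if p >= alpha:
            trace.stop_reason = "alpha"
            break
        cum = rda(Y, Xall[:, selected + [best]], standardize=False)
        if cum.adj_r2 > trace.global_adj_r2 + adj_r2_tol:
            trace.stop_reason = "adj_r2_ceiling"
            break
        selected.append(best)
        remaining.remove(best)
        trace.steps.append(SelectionStep(names[best], p, cum.adj_r2))
    else:
        trace.stop_reason = "exhausted"
    return trace


# ---------------------------------------------------------------------------
# vector fitting (envfit)
# ---------------------------------------------------------------------------

@dataclass
class VectorFit:
    variable: str
    squared_correlation: float
    perm_p: float
    direction_cosines: np.ndarray


def fit_vector(
    scores,
    variable,
    name: str = "altitude",
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> VectorFit:
    """Fit an external variable onto ordination site scores.

    The squared correlation is the R² of the least-squares regression of
    the centered variable on the (centered) axis scores; significance is
    by permuting the variable across sites with the add-one rule.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    v = np.asarray(variable, dtype=float)
    if S.shape[0] != v.size or v.size < 3:
        raise ValueError("need matching scores and variable over at least 3 sites")
    if np.ptp(v) == 0:
        raise ValueError("cannot fit a constant variable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Sc = _center(S)
    Q = _fit_projector(Sc)
    vc = v - v.mean()
    ss = float(vc @ vc)

    def r2_of(vv: np.ndarray) -> float:
        proj = Q.T @ vv
        return float(proj @ proj) / ss

    r2 = r2_of(vc)
    coef, *_ = np.linalg.lstsq(Sc, vc, rcond=None)
    norm = np.linalg.norm(coef)
    cosines = coef / norm if norm > 0 else coef
    count = 0
    for _ in range(n_perm):
        if r2_of(vc[rng.permutation(vc.size)]) >= r2:
            count += 1
    return VectorFit(name, r2, (1 + count) / (n_perm + 1), cosines)
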