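"""Closed-population loglinear models with AIC selection (LLM-AIC).

The observable capture-history counts are modeled as independent Poisson
cells, ``log mu_omega = x(omega)' beta``.  Model families (Cormack-style
loglinear parameterizations):

- ``M0``: intercept + number of captures c(omega);
- ``Mt``: intercept + one indicator per list;
- ``Mh``: M0 + a heterogeneity-correction column h(c(omega));
- ``Mb``: M0 + the behavioral exposure column K - f(omega), where
  f(omega) is the list of first capture;
- ``Mbh``, ``Mth``: the corresponding combinations.

Heterogeneity corrections h(c): ``Poisson2`` -> 2**c - 1, ``Darroch`` ->
c**2 / 2, ``Gamma3.5`` -> -log(c + 3.5) + log(3.5); all satisfy h(0) = 0.

Abundance. For M0/Mt/Mh/Mth every covariate vanishes at the all-zero
history and the generative model is loglinear there too, so the intercept
extrapolates exactly: ``N_hat = n + exp(beta_0)``.  For the behavioral
families that extrapolation is inconsistent (the exposure covariate has
no natural value at the unobserved cell); instead the fitted coefficients
are back-transformed to the behavioral model's own parameters — recapture
probability ``c`` from the captures coefficient, first-capture
probability ``p`` from the behavior coefficient — and the zero cell is
estimated by the model-implied ``exp(beta_0) (1-p) c / (p (1-c))``, which
recovers N exactly on an exact Mb table.

Model selection follows the conventional workflow for these estimators:
the heterogeneous families enter the AIC comparison under each available
correction, the winning family is reported for model matching, and the
Poisson2-variant estimate of that family is the one recorded.
Uncertainty intervals are profile-likelihood intervals on the multinomial
likelihood over integer N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import chi2

from msesim.synthetic import FrequencyTable, all_histories

__all__ = [
    "CORRECTIONS",
    "ModelSpec",
    "LoglinearFit",
    "candidate_specs",
    "selection_menu",
    "design_matrix",
    "fit_poisson",
    "fit_candidates",
    "fit_menu",
    "select_best",
    "profile_ci",
    "aic_estimate",
]

# Heterogeneity-correction columns as functions of the number of captures.
CORRECTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "Poisson2": lambda c: 2.0**c - 1.0,
    "Darroch": lambda c: c**2 / 2.0,
    "Gamma3.5": lambda c: -np.log(c + 3.5) + np.log(3.5),
}

_LABELS = ("M0", "Mt", "Mb", "Mh", "Mbh", "Mth")


@dataclass(frozen=True)
class ModelSpec:
    """One loglinear model: family label, heterogeneity correction, K lists."""

    label: str
    K: int
    correction: str = "none"

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown model label {self.label!r}")
        if self.correction != "none" and self.correction not in CORRECTIONS:
            raise ValueError(f"unknown correction {self.correction!r}")
        if "h" in self.label and self.correction == "none":
            raise ValueError(f"model {self.label} requires a heterogeneity correction")
        if "h" not in self.label and self.correction != "none":
            raise ValueError("correction only applies to models containing 'h'")
        if self.n_params > 2**self.K - 1:
            raise ValueError(
                f"model {self.label} with K={self.K} is over-saturated "
                f"({self.n_params} parameters for {2**self.K - 1} cells)"
            )

    @property
    def n_params(self) -> int:
        p = 1  # intercept
        p += self.K if "t" in self.label else 1  # list indicators or c(omega)
        if "b" in self.label:
            p += 1
        if "h" in self.label:
            p += 1
        return p

    @property
    def behavioral(self) -> bool:
        return "b" in self.label


def candidate_specs(K: int, correction: str = "Poisson2") -> list[ModelSpec]:
    """The five-family candidate set with a single heterogeneity correction.

    For K >= 3: {Mb, Mt, Mh, Mbh, Mth}.  For K = 2 only {M0, Mt} are
    estimable (3 observable cells), so those are used.
    """
    if K == 2:
        return [ModelSpec("M0", 2), ModelSpec("Mt", 2)]
    return [
        ModelSpec("Mb", K),
        ModelSpec("Mt", K),
        ModelSpec("Mh", K, correction),
        ModelSpec("Mbh", K, correction),
        ModelSpec("Mth", K, correction),
    ]


def selection_menu(
    K: int, corrections: Sequence[str] = ("Poisson2", "Darroch", "Gamma3.5")
) -> list[ModelSpec]:
    """The AIC-comparison menu: Mh/Mth under each correction, Mb, Mt, Mbh.

    Mirrors the standard closed-population fitting workflow in which the
    heterogeneous families are tabulated under every correction while the
    behavioral-heterogeneous family appears once (Poisson2).
    """
    if K == 2:
        return candidate_specs(2)
    menu = [ModelSpec("Mb", K), ModelSpec("Mt", K), ModelSpec("Mbh", K, "Poisson2")]
    for corr in corrections:
        menu.append(ModelSpec("Mh", K, corr))
        menu.append(ModelSpec("Mth", K, corr))
    return menu


def design_matrix(spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix over the 2**K - 1 observable histories (canonical order)."""
    H = all_histories(spec.K)
    c = H.sum(axis=1).astype(float)
    cols: list[np.ndarray] = [np.ones(len(H))]
    names = ["intercept"]
    if "t" in spec.label:
        for k in range(spec.K):
            cols.append(H[:, k].astype(float))
            names.append(f"list_{k + 1}")
    else:
        cols.append(c)
        names.append("captures")
    if "b" in spec.label:
        # exposure to post-first-capture behavior: K - (first-capture list)
        first = np.argmax(H, axis=1) + 1
        cols.append((spec.K - first).astype(float))
        names.append("behavior")
    if "h" in spec.label:
        cols.append(CORRECTIONS[spec.correction](c))
        names.append(f"h_{spec.correction}")
    return np.column_stack(cols), names


@dataclass
class LoglinearFit:
    """A fitted loglinear model and its abundance estimate."""

    spec: ModelSpec
    coefficients: np.ndarray
    loglik: float
    aic: float
    n_observed: int
    N_hat: float
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)
    ci: tuple[float, float] | None = None


def _behavioral_zero_cell(coefficients: np.ndarray) -> float:
    """Model-implied mean of the unobserved cell for Mb/Mbh fits.

    The captures coefficient equals logit(c) and the behavior coefficient
    equals log((1-c)/(1-p)) under the behavioral model, giving the
    zero-cell mean exp(b0) (1-p) c / (p (1-c)).  Returns inf when the
    implied first-capture probability leaves (0, 1) (unbounded estimate).
    """
    b0, b_capt, b_behav = coefficients[0], coefficients[1], coefficients[2]
    c = expit(b_capt)
    log_1mp = np.log1p(-c) - b_behav  # log(1 - p)
    p = -np.expm1(log_1mp)
    if not 0 < p < 1 or not 0 < c < 1:
        return np.inf
    with np.errstate(over="ignore"):
        return float(np.exp(b0) * (1 - p) * c / (p * (1 - c)))


def _abundance(spec: ModelSpec, coefficients: np.ndarray, n: int) -> float:
    if not np.isfinite(coefficients[0]):
        return np.inf
    if spec.behavioral:
        return n + _behavioral_zero_cell(coefficients)
    with np.errstate(over="ignore"):
        return n + float(np.exp(coefficients[0]))


def fit_poisson(table: FrequencyTable, spec: ModelSpec) -> LoglinearFit:
    """Maximize the Poisson likelihood by IRLS and estimate abundance.

    Non-convergence and singular designs are reported through the
    ``converged`` flag rather than raised: zero-heavy tables legitimately
    produce unbounded (astronomically large) estimates.
    """
    if table.K != spec.K:
        raise ValueError("table and model disagree on the number of lists")
    X, _ = design_matrix(spec)
    y = table.array.astype(float)
    n = table.n_observed
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
        coefs = np.asarray(res.params)
        converged = bool(res.converged) and np.isfinite(coefs).all()
        loglik = float(res.llf)
        aic = float(res.aic)
        fitted = np.asarray(res.fittedvalues)
    except Exception:
        coefs = np.full(X.shape[1], np.nan)
        converged, loglik, aic, fitted = False, -np.inf, np.inf, None
    return LoglinearFit(
        spec=spec,
        coefficients=coefs,
        loglik=loglik,
        aic=aic,
        n_observed=n,
        N_hat=_abundance(spec, coefs, n),
        converged=converged,
        fitted=fitted,
    )


def fit_candidates(table: FrequencyTable, correction: str = "Poisson2") -> list[LoglinearFit]:
    """Fit the five-family candidate set under a single correction."""
    return [fit_poisson(table, spec) for spec in candidate_specs(table.K, correction)]


def fit_menu(
    table: FrequencyTable, corrections: Sequence[str] = ("Poisson2", "Darroch", "Gamma3.5")
) -> list[LoglinearFit]:
    """Fit the full AIC-comparison menu (see :func:`selection_menu`)."""
    return [fit_poisson(table, spec) for spec in selection_menu(table.K, corrections)]


def select_best(fits: Sequence[LoglinearFit]) -> LoglinearFit:
    """Minimal-AIC converged fit; ties broken by parsimony then label order.

    Raises ``RuntimeError`` when no candidate converged (estimation
    failure for that sample).
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise RuntimeError("no converged loglinear fit to select from")
    return min(ok, key=lambda f: (f.aic, f.spec.n_params, _LABELS.index(f.spec.label)))


def aic_estimate(
    table: FrequencyTable,
    ci: bool = False,
    level: float = 0.95,
    ceiling_factor: float = 20.0,
    estimate_correction: str = "Poisson2",
) -> LoglinearFit:
    """The LLM-AIC estimator: menu selection, recorded-correction estimate.

    The AIC winner over the full menu determines the model family; the
    recorded abundance estimate is the ``estimate_correction`` variant of
    that family (heterogeneous families only — Mb/Mt are their own
    recorded fits).  Optionally attaches a profile-likelihood CI computed
    under the recorded model.
    """
    fits = fit_menu(table)
    best = select_best(fits)
    fam = best.spec.label
    if "h" in fam and best.spec.correction != estimate_correction:
        by_spec = {f.spec: f for f in fits if f.converged}
        recorded = by_spec.get(ModelSpec(fam, table.K, estimate_correction), best)
    else:
        recorded = best
    if ci:
        lo, hi, _ = profile_ci(table, recorded.spec, level=level, ceiling_factor=ceiling_factor)
        recorded.ci = (lo, hi)
    return recorded


# ---------------------------------------------------------------------------
# profile-likelihood intervals
# ---------------------------------------------------------------------------


def _completed_loglik_glm(table: FrequencyTable, spec: ModelSpec, N: int) -> float:
    """Multinomial profile log-likelihood at total N for intercept-extrapolating
    models: Poisson GLM on the table completed with N - n in the zero cell."""
    n = table.n_observed
    n0 = N - n
    X, _ = design_matrix(spec)
    X_full = np.vstack([np.r_[1.0, np.zeros(X.shape[1] - 1)], X])
    y_full = np.r_[float(n0), table.array.astype(float)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y_full, X_full, family=sm.families.Poisson()).fit(maxiter=200)
    mu = np.asarray(res.fittedvalues)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y_full > 0, y_full * np.log(mu / N), 0.0)
    return float(gammaln(N + 1) - gammaln(n0 + 1) + terms.sum())


def _completed_loglik_behavioral(table: FrequencyTable, spec: ModelSpec, N: int) -> float:
    """Profile log-likelihood for Mb/Mbh: the zero cell follows the
    behavioral back-transform, so the completed-cell likelihood is
    maximized numerically over the loglinear coefficients."""
    n = table.n_observed
    n0 = N - n
    X, _ = design_matrix(spec)
    y = table.array.astype(float)

    def nll(beta: np.ndarray) -> float:
        eta = X @ beta
        mu0 = _behavioral_zero_cell(beta)
        if not np.isfinite(mu0) or mu0 <= 0:
            return 1e12
        log_mu = np.r_[np.log(mu0), eta]
        log_total = float(np.logaddexp.reduce(log_mu))
        x_all = np.r_[float(n0), y]
        return -float(np.sum(x_all * (log_mu - log_total)))

    start = fit_poisson(table, spec).coefficients
    if not np.isfinite(start).all():
        start = np.zeros(X.shape[1])
    best = minimize(nll, start, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    return float(gammaln(N + 1) - gammaln(n0 + 1) - best.fun)


def _completed_loglik(table: FrequencyTable, spec: ModelSpec, N: int) -> float:
    if spec.behavioral:
        return _completed_loglik_behavioral(table, spec, N)
    return _completed_loglik_glm(table, spec, N)


def profile_ci(
    table: FrequencyTable,
    spec: ModelSpec,
    level: float = 0.95,
    ceiling_factor: float = 20.0,
) -> tuple[float, float, dict]:
    """Profile-likelihood interval for N on an integer grid.

    The interval is {N : 2 * (max_N l(N) - l(N)) <= chi2_1(level)} with
    the upper bound capped at ``n * (1 + ceiling_factor)``; hitting the
    cap or a monotone profile is recorded in the returned info dict.
    """
    n = table.n_observed
    crit = float(chi2.ppf(level, df=1))
    ceiling = int(np.ceil(n * (1 + ceiling_factor)))
    info: dict = {"capped": False, "one_sided": False, "ceiling": ceiling}

    fit = fit_poisson(table, spec)
    if np.isfinite(fit.N_hat):
        N_start = int(np.clip(round(fit.N_hat), n, ceiling))
    else:
        N_start = ceiling

    cache: dict[int, float] = {}

    def ll(N: int) -> float:
        if N not in cache:
            cache[N] = _completed_loglik(table, spec, N)
        return cache[N]

    # climb to the integer profile maximum from N_start (unimodal profile)
    N_max = N_start
    step = max(1, n // 100)
    while N_max + step <= ceiling and ll(N_max + step) > ll(N_max):
        N_max += step
    while N_max - step >= n and ll(N_max - step) > ll(N_max):
        N_max -= step
    while N_max + 1 <= ceiling and ll(N_max + 1) > ll(N_max):
        N_max += 1
    while N_max - 1 >= n and ll(N_max - 1) > ll(N_max):
        N_max -= 1
    l_max = ll(N_max)

    def dev(N: int) -> float:
        return 2.0 * (l_max - ll(N))

    # lower bound
    if dev(n) <= crit:
        lower = float(n)
        if N_max > n:
            info["one_sided"] = True
    else:
        lo_out, hi_in = n, N_max
        while hi_in - lo_out > 1:
            mid = (lo_out + hi_in) // 2
            if dev(mid) <= crit:
                hi_in = mid
            else:
                lo_out = mid
        lower = float(hi_in)

    # upper bound: expand geometrically until outside or capped
    hi = N_max
    step = max(1, int(0.1 * max(n, 10)))
    while dev(hi) <= crit:
        if hi >= ceiling:
            info["capped"] = True
            break
        hi = min(ceiling, hi + step)
        step *= 2
    if info["capped"]:
        upper = float(ceiling)
    else:
        lo_in, hi_out = N_max, hi
        while hi_out - lo_in > 1:
            mid = (lo_in + hi_out) // 2
            if dev(mid) <= crit:
                lo_in = mid
            else:
                hi_out = mid
        upper = float(lo_in)
    return lower, upper, info
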