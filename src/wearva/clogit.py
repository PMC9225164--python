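"""Conditional logistic regression for patient-stratified case/control data.

For a stratum with rows :math:`x_1..x_n` of which the case set :math:`C`
has size :math:`m`, the conditional likelihood contribution is

.. math::

   L_s(\\beta) = \\frac{\\exp(\\sum_{i \\in C} x_i'\\beta)}
                      {\\sum_{|S| = m} \\exp(\\sum_{i \\in S} x_i'\\beta)}

where the denominator runs over all size-``m`` subsets of the stratum.
Conditioning on the per-stratum case count cancels any stratum-constant
term, which is what lets the case-crossover design absorb stable
between-patient differences.

The denominator is enumerated exactly when :math:`\\binom{n}{m}` is small
(default bound 100,000); larger strata — a patient can contribute hundreds
of monitoring days — use the Breslow (default) or Efron approximation for
the tied "failures".  Both approximations coincide with the exact
likelihood for single-case strata.  Fitting is Newton-Raphson with
step-halving; standard errors come from the inverse observed information,
and per-coefficient significance is the two-sided Wald normal test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

DEFAULT_EXACT_LIMIT = 100_000

#: covariate sets of the three model formulae (behavior exposure is always first)
FORMULAE = {1: ("season", "weekday_status"),
            2: ("season", "day_of_week"),
            3: ("season",)}

# reference levels, fixed for reproducibility
SEASON_LEVELS = ("spring", "summer", "fall", "winter")
WEEKDAY_LEVELS = ("weekday", "weekend")
DOW_LEVELS = (1, 2, 3, 4, 5, 6, 7)


class NoInformativeStrataError(ValueError):
    """Every stratum is all-case or all-control, or the exposure never varies."""


@dataclass
class FitResult:
    """Estimates for the behavior exposure of one conditional-logit fit."""

    beta: float
    se: float
    or_: float
    p: float
    n_strata: int
    n_case: int
    n_control: int
    converged: bool
    method: str            # exact | breslow | efron | mixed
    n_iter: int
    loglik: float
    params: np.ndarray = field(repr=False, default=None)
    se_all: np.ndarray = field(repr=False, default=None)
    param_names: tuple = field(repr=False, default=())
    message: str = ""


# -- per-stratum likelihood kernels ---------------------------------------


def _exact_parts(X: np.ndarray, case_mask: np.ndarray, beta: np.ndarray,
                 want_derivs: bool):
    n, m = X.shape[0], int(case_mask.sum())
    eta = X @ beta
    subsets = np.fromiter(
        (i for s in combinations(range(n), m) for i in s), dtype=np.intp,
        count=comb(n, m) * m).reshape(-1, m)
    s_eta = eta[subsets].sum(axis=1)
    log_denom = logsumexp(s_eta)
    ll = float(eta[case_mask].sum() - log_denom)
    if not want_derivs:
        return ll, None, None
    pi = np.exp(s_eta - log_denom)
    XS = X[subsets].sum(axis=1)                      # (C, p)
    mu = pi @ XS
    grad = X[case_mask].sum(axis=0) - mu
    hess = -(XS.T @ (pi[:, None] * XS) - np.outer(mu, mu))
    return ll, grad, hess


def _breslow_parts(X: np.ndarray, case_mask: np.ndarray, beta: np.ndarray,
                   want_derivs: bool):
    m = int(case_mask.sum())
    eta = X @ beta
    log_a = logsumexp(eta)
    ll = float(eta[case_mask].sum() - m * log_a)
    if not want_derivs:
        return ll, None, None
    w = np.exp(eta - log_a)                          # normalised weights
    mu = w @ X
    grad = X[case_mask].sum(axis=0) - m * mu
    hess = -m * (X.T @ (w[:, None] * X) - np.outer(mu, mu))
    return ll, grad, hess


def _efron_parts(X: np.ndarray, case_mask: np.ndarray, beta: np.ndarray,
                 want_derivs: bool):
    m = int(case_mask.sum())
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    a, b = w.sum(), w[case_mask].sum()
    A, B = w @ X, w[case_mask] @ X[case_mask]
    A2 = X.T @ (w[:, None] * X)
    B2 = X[case_mask].T @ (w[case_mask][:, None] * X[case_mask])
    ll = float(eta[case_mask].sum())
    grad = X[case_mask].sum(axis=0).astype(float) if want_derivs else None
    hess = np.zeros((X.shape[1], X.shape[1])) if want_derivs else None
    for k in range(m):
        f = k / m
        d = a - f * b
        ll -= np.log(d) + shift
        if want_derivs:
            mu = (A - f * B) / d
            grad -= mu
            hess -= (A2 - f * B2) / d - np.outer(mu, mu)
    return ll, grad, hess


def conditional_loglik_exact(X, y, beta, limit: int = DEFAULT_EXACT_LIMIT) -> float:
    """Exact conditional log-likelihood contribution of one stratum.

    Raises if the subset count C(n, m) exceeds ``limit`` — callers should
    fall back to :func:`conditional_loglik_approx` for such strata.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.ndim(y) and len(y) > 1:
        X = X.T
    y = np.asarray(y).astype(bool)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n, m = X.shape[0], int(y.sum())
    if comb(n, m) > limit:
        raise ValueError(
            f"C({n},{m}) = {comb(n, m)} exceeds the enumeration bound {limit}; "
            "use conditional_loglik_approx")
    ll, _, _ = _exact_parts(X, y, beta, want_derivs=False)
    return ll


def conditional_loglik_approx(X, y, beta, ties: str = "breslow") -> float:
    """Breslow (default) or Efron tied-failure approximation for one stratum.

    Exact for single-case strata; at the null it reduces to ``-m log n``
    (Breslow).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and np.ndim(y) and len(y) > 1:
        X = X.T
    y = np.asarray(y).astype(bool)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    kernel = {"breslow": _breslow_parts, "efron": _efron_parts}[ties]
    ll, _, _ = kernel(X, y, beta, want_derivs=False)
    return ll


# -- design construction ---------------------------------------------------


def build_design(observations: pd.DataFrame, formula: int):
    """Design matrix for one formula: exposure + dummy-coded time covariates.

    Reference levels: season = spring, weekday_status = weekday,
    day_of_week = 1.  Returns ``(X, y, strata, names)``.
    """
    if formula not in FORMULAE:
        raise ValueError(f"formula must be one of {sorted(FORMULAE)}, got {formula}")
    cols = [observations["exposure"].to_numpy(dtype=float)]
    names = ["exposure"]
    cov = FORMULAE[formula]
    if "season" in cov:
        for level in SEASON_LEVELS[1:]:
            cols.append((observations["season"] == level).to_numpy(dtype=float))
            names.append(f"season[{level}]")
    if "weekday_status" in cov:
        cols.append((observations["weekday_status"] == "weekend").to_numpy(dtype=float))
        names.append("weekday_status[weekend]")
    if "day_of_week" in cov:
        for level in DOW_LEVELS[1:]:
            cols.append((observations["day_of_week"] == level).to_numpy(dtype=float))
            names.append(f"day_of_week[{level}]")
    X = np.column_stack(cols)
    y = observations["outcome"].to_numpy(dtype=int)
    strata = observations["patient_id"].to_numpy()
    return X, y, strata, tuple(names)


# -- fitting ---------------------------------------------------------------


def _prepare_strata(X, y, strata, exact_limit, ties):
    """Prune non-informative strata and choose the per-stratum kernel."""
    groups = []
    methods = set()
    order = pd.unique(strata)
    for s in order:
        mask = strata == s
        ys = y[mask].astype(bool)
        m, n = int(ys.sum()), int(mask.sum())
        if m == 0 or m == n:
            continue  # non-informative: contributes a constant
        Xs = X[mask]
        if comb(n, m) <= exact_limit:
            kernel, name = _exact_parts, "exact"
        else:
            kernel, name = (_breslow_parts, "breslow") if ties == "breslow" else (_efron_parts, "efron")
        methods.add(name)
        groups.append((Xs, ys, kernel))
    return groups, methods


def fit_design(X, y, strata, *, exact_limit: int = DEFAULT_EXACT_LIMIT,
               ties: str = "breslow", param_names: tuple = (),
               max_iter: int = 50, rtol: float = 1e-10) -> FitResult:
    """Maximise the summed stratum log-likelihoods by Newton-Raphson.

    Columns (other than the first, the exposure) that are constant within
    every informative stratum are unidentifiable — conditioning cancels
    them — and are dropped before fitting.  Separation or a singular
    information matrix yields ``converged=False`` with diagnostics, never a
    silent estimate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    strata = np.asarray(strata)
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    groups, methods = _prepare_strata(X, y, strata, exact_limit, ties)
    if not groups:
        raise NoInformativeStrataError("no informative strata (each is all-case or all-control)")

    p = X.shape[1]
    varies = np.zeros(p, dtype=bool)
    for Xs, _, _ in groups:
        varies |= np.ptp(Xs, axis=0) > 0
    if not varies[0]:
        raise NoInformativeStrataError("exposure is constant within every informative stratum")
    keep = np.flatnonzero(varies)
    names = tuple(param_names[i] if param_names else f"x{i}" for i in keep)
    groups = [(Xs[:, keep], ys, kern) for Xs, ys, kern in groups]

    n_strata = len(groups)
    n_case = sum(int(ys.sum()) for _, ys, _ in groups)
    n_control = sum(len(ys) - int(ys.sum()) for _, ys, _ in groups)
    k = keep.size

    def objective(beta, want_derivs=True):
        ll, grad, hess = 0.0, np.zeros(k), np.zeros((k, k))
        for Xs, ys, kern in groups:
            l, g, h = kern(Xs, ys, beta, want_derivs)
            ll += l
            if want_derivs:
                grad += g
                hess += h
        return ll, grad, hess

    beta = np.zeros(k)
    ll, grad, hess = objective(beta)
    converged, message, it = False, "", 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix (possible separation or collinearity)"
            break
        step = 1.0
        new_ll = -np.inf
        for _ in range(30):
            trial = beta + step * delta
            new_ll, _, _ = objective(trial, want_derivs=False)
            if np.isfinite(new_ll) and new_ll >= ll:
                break
            step /= 2
        else:
            message = "step-halving failed to increase the likelihood"
            break
        beta = beta + step * delta
        prev_ll, ll = ll, new_ll
        _, grad, hess = objective(beta)
        if abs(ll - prev_ll) <= rtol * (abs(prev_ll) + 1e-300):
            converged = True
            break
    if not converged and not message:
        message = f"no convergence in {max_iter} iterations (possible separation)"
    if ll > -1e-8:
        # the conditional likelihood has supremum 1; reaching it means the
        # exposure perfectly discriminates cases within every stratum
        converged = False
        message = "likelihood at its supremum: perfect within-stratum separation"

    try:
        cov = np.linalg.inv(-hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(k, np.nan)
        converged = False
        message = message or "observed information not invertible at the optimum"

    b0, s0 = float(beta[0]), float(se_all[0])
    z = b0 / s0 if s0 > 0 else np.nan
    pval = float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
    method = methods.pop() if len(methods) == 1 else "mixed"
    return FitResult(beta=b0, se=s0, or_=float(np.exp(b0)), p=pval,
                     n_strata=n_strata, n_case=n_case, n_control=n_control,
                     converged=converged, method=method, n_iter=it, loglik=float(ll),
                     params=beta, se_all=se_all, param_names=names, message=message)


def fit(observations: pd.DataFrame, formula: int = 3, *,
        exact_limit: int = DEFAULT_EXACT_LIMIT, ties: str = "breslow") -> FitResult:
    """Fit one conditional-logit model on case-crossover observations.

    ``formula`` selects the time-covariate set (1: season + weekday status;
    2: season + day of week; 3: season).  The reported ``beta``/``or_`` are
    per one raw unit of the exposure (1 step, 1 minute, 1 bpm).
    """
    X, y, strata, names = build_design(observations, formula)
    return fit_design(X, y, strata, exact_limit=exact_limit, ties=ties, param_names=names)


def wald_test(result: FitResult) -> tuple[float, float]:
    """Two-sided Wald normal test of the exposure coefficient: (z, p)."""
    if result.se == 0 or not np.isfinite(result.se):
        raise ValueError("Wald test undefined: standard error is zero or not finite")
    z = result.beta / result.se
    return float(z), float(2 * norm.sf(abs(z)))
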