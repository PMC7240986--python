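"""Bivariate Brownian-Motion model of trait coevolution on a phylogeny.

Two expression traits evolving jointly under multivariate Brownian Motion on
a tree with species covariance C have tip values distributed as a 2n-variate
normal with mean (theta_1 1, theta_2 1) and covariance

    Sigma[(a, i), (b, j)] = R[a, b] * C[i, j] + 1{a=b, i=j} * se[a, i]^2

where R is the 2x2 evolutionary rate matrix (per-unit-time trait variances on
the diagonal, trait covariance off-diagonal) and ``se`` the per-observation
measurement error. The evolutionary correlation

    rho_C = r12 / sqrt(r11 * r22)

measures coevolution of the two traits while accounting for shared ancestry.
The likelihood-ratio test compares the full model against a null with r12
fixed at 0 (independent evolution); under the null the statistic is
asymptotically chi-square with 1 degree of freedom.

Root states theta are profiled out exactly by generalized least squares —
they enter the mean only — so the optimization runs over (log r11, log r22,
atanh rho), a parameterization that keeps R positive definite by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from coevo.phylo import SpeciesCovariance

__all__ = [
    "RateMatrix",
    "BMFitResult",
    "PairTest",
    "PhyloPairBM",
    "bm_loglik",
    "fit_pair",
    "lrt",
    "rho_u",
]

_LOG2PI = np.log(2.0 * np.pi)
#: |atanh(rho)| bound; corresponds to |rho| <= 1 - 1e-6
_Z_MAX = np.arctanh(1.0 - 1e-6)
_A_BOUNDS = (-35.0, 35.0)


@dataclass
class RateMatrix:
    """Evolutionary rate matrix of a trait pair (positive definite)."""

    r11: float
    r22: float
    r12: float

    def __post_init__(self):
        if self.r11 <= 0 or self.r22 <= 0:
            raise ValueError("diagonal rates must be positive")
        if self.r12 ** 2 >= self.r11 * self.r22:
            raise ValueError("rate matrix must be positive definite (r12^2 < r11*r22)")

    @property
    def rho(self) -> float:
        return self.r12 / np.sqrt(self.r11 * self.r22)

    def as_array(self) -> np.ndarray:
        return np.array([[self.r11, self.r12], [self.r12, self.r22]])


@dataclass
class BMFitResult:
    """Maximum-likelihood fit of the bivariate BM model for one pair."""

    theta: np.ndarray
    R: RateMatrix
    rho_c: float
    loglik: float
    converged: bool
    n_species: int
    boundary: bool = False
    constrained: bool = False


@dataclass
class PairTest:
    """Likelihood-ratio test of coevolution (r12 = 0 null)."""

    lrt_stat: float
    p_value: float
    q_value: float = np.nan


def _as_matrix(cov) -> np.ndarray:
    if isinstance(cov, SpeciesCovariance):
        return cov.matrix
    return np.asarray(cov, dtype=float)


def _check_xse(C, x, se):
    n = C.shape[0]
    x = np.asarray(x, dtype=float)
    if x.shape != (2, n):
        raise ValueError("x must be 2 traits x %d species" % n)
    if se is None:
        se = np.zeros_like(x)
    else:
        se = np.asarray(se, dtype=float)
        if se.shape != x.shape:
            raise ValueError("se must match x in shape")
        if np.isnan(se).any():
            warnings.warn(
                "missing standard errors treated as 0; consider a proxy-SE fill",
                UserWarning,
            )
            se = np.nan_to_num(se)
        if (se < 0).any():
            raise ValueError("se must be nonnegative")
    if np.isnan(x).any():
        raise ValueError("x contains missing values; filter to complete data first")
    return x, se


def _sigma(C, R2, se):
    S = np.kron(R2, C)
    S[np.diag_indices_from(S)] += se.ravel() ** 2
    return S


def bm_loglik(cov, x, se, theta, R) -> float:
    """Log-likelihood of tip data under bivariate BM with measurement error.

    ``x`` and ``se`` are (2, n) arrays ordered like the covariance's species
    list; ``theta`` is the 2-vector of root states.
    """
    C = _as_matrix(cov)
    x, se = _check_xse(C, x, se)
    R2 = R.as_array() if isinstance(R, RateMatrix) else np.asarray(R, dtype=float)
    S = _sigma(C, R2, se)
    theta = np.asarray(theta, dtype=float)
    resid = x.ravel() - np.repeat(theta, C.shape[0])
    try:
        cf = cho_factor(S, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(S)
        raise np.linalg.LinAlgError(
            "singular model covariance (condition number %.3g): %s" % (cond, exc)
        )
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    quad = resid @ cho_solve(cf, resid, check_finite=False)
    return float(-0.5 * (resid.size * _LOG2PI + logdet + quad))


def _profiled_negloglik(C, x, se, R2):
    """Negative loglik maximized over theta (exact GLS profile), with theta."""
    n = C.shape[0]
    S = _sigma(C, R2, se)
    try:
        cf = cho_factor(S, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, np.full(2, np.nan)
    D = np.kron(np.eye(2), np.ones((n, 1)))
    xv = x.ravel()
    rhs = np.column_stack([xv, D])
    sol = cho_solve(cf, rhs, check_finite=False)
    Si_x, Si_D = sol[:, 0], sol[:, 1:]
    A = D.T @ Si_D
    b = D.T @ Si_x
    theta = np.linalg.solve(A, b)
    resid_quad = xv @ Si_x - b @ theta
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    nll = 0.5 * (2 * n * _LOG2PI + logdet + resid_quad)
    return float(nll), theta


def _univariate_fit(C, xrow, serow, a0):
    """ML fit of a single-trait BM rate (log-parameterized), theta profiled."""

    def nll(a):
        v, _ = _profiled_negloglik_1d(C, xrow, serow, np.exp(a))
        return v

    # bounded golden-section/parabolic search on the log-rate: robust on the
    # flat tails where quasi-Newton line searches stall
    lo = max(_A_BOUNDS[0], a0 - 15.0)
    hi = min(_A_BOUNDS[1], a0 + 15.0)
    res = optimize.minimize_scalar(
        nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
    )
    a_hat = float(res.x)
    nll_val, theta = _profiled_negloglik_1d(C, xrow, serow, np.exp(a_hat))
    converged = bool(res.success and np.isfinite(nll_val)
                     and lo + 1e-6 < a_hat < hi - 1e-6)
    return a_hat, -nll_val, theta, converged


def _profiled_negloglik_1d(C, xrow, serow, sigma2):
    n = C.shape[0]
    S = sigma2 * C + np.diag(serow ** 2)
    try:
        cf = cho_factor(S, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, np.nan
    one = np.ones(n)
    rhs = np.column_stack([xrow, one])
    sol = cho_solve(cf, rhs, check_finite=False)
    theta = float(one @ sol[:, 0] / (one @ sol[:, 1]))
    resid_quad = xrow @ sol[:, 0] - theta * (one @ sol[:, 0])
    logdet = 2.0 * np.log(np.diag(cf[0])).sum()
    return 0.5 * (n * _LOG2PI + logdet + resid_quad), theta


def _pack_R(a, b, z):
    r11, r22 = np.exp(a), np.exp(b)
    rho = np.tanh(z)
    return np.array([[r11, rho * np.sqrt(r11 * r22)],
                     [rho * np.sqrt(r11 * r22), r22]])


def fit_pair(cov, x, se=None, constrain_zero_cov: bool = False,
             z_starts=(-0.5, 0.0, 0.5), _extra_starts=()) -> BMFitResult:
    """Maximum-likelihood bivariate BM fit for one trait pair.

    The null (``constrain_zero_cov=True``) fixes r12 = 0, under which the
    two traits decouple into independent univariate BM fits. The full model
    is optimized over (log r11, log r22, atanh rho) by L-BFGS-B from a fixed
    set of deterministic starts seeded at the null optimum, which guarantees
    the fitted log-likelihood is never below the null's.
    """
    C = _as_matrix(cov)
    x, se = _check_xse(C, x, se)
    n = C.shape[0]
    if n < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(x[0]) == 0 or np.ptp(x[1]) == 0:
        raise ValueError("traits must be non-constant across species")

    mean_depth = float(np.mean(np.diag(C)))
    a_inits = [
        float(np.log(max(np.var(x[t], ddof=1) / mean_depth, 1e-12)))
        for t in (0, 1)
    ]
    uni = [
        _univariate_fit(C, x[t], se[t], a_inits[t]) for t in (0, 1)
    ]
    (a1, ll1, th1, ok1), (a2, ll2, th2, ok2) = uni

    if constrain_zero_cov:
        R = RateMatrix(float(np.exp(a1)), float(np.exp(a2)), 0.0)
        return BMFitResult(
            theta=np.array([th1, th2]), R=R, rho_c=0.0,
            loglik=float(ll1 + ll2), converged=bool(ok1 and ok2),
            n_species=n, constrained=True,
        )

    def nll(p):
        v, _ = _profiled_negloglik(C, x, se, _pack_R(*p))
        return v

    bounds = [_A_BOUNDS, _A_BOUNDS, (-_Z_MAX, _Z_MAX)]
    starts = [np.array([a1, a2, z]) for z in z_starts]
    starts += [np.asarray(s, dtype=float) for s in _extra_starts]
    best = None
    for s0 in starts:
        res = optimize.minimize(
            nll, s0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not best.success:
        # polish stalled line searches with a derivative-free simplex
        polish = optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 2000},
        )
        if polish.fun <= best.fun:
            best = polish
    a, b, z = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    R2 = _pack_R(a, b, z)
    nll_val, theta = _profiled_negloglik(C, x, se, R2)
    rho = float(np.tanh(z))
    boundary = bool(abs(z) >= _Z_MAX - 1e-8)
    # the null optimum is a feasible point (z=0), so loglik >= ll1+ll2 up to tol
    return BMFitResult(
        theta=theta, R=RateMatrix(float(R2[0, 0]), float(R2[1, 1]), float(R2[0, 1])),
        rho_c=rho, loglik=float(-nll_val),
        converged=bool(best.success and np.isfinite(nll_val)),
        n_species=n, boundary=boundary,
    )


def lrt(full: BMFitResult, constrained: BMFitResult) -> PairTest:
    """Likelihood-ratio test of the full model against independent evolution.

    The statistic 2*(loglik_full - loglik_null) is floored at 0; the p-value
    is the upper chi-square(1) tail.
    """
    if not (full.converged and constrained.converged):
        raise ValueError("both fits must have converged")
    stat = 2.0 * (full.loglik - constrained.loglik)
    if stat < -1e-6:
        raise ValueError(
            "constrained log-likelihood exceeds full model by %.3g; refit with "
            "more starts" % (-stat / 2.0)
        )
    stat = max(stat, 0.0)
    return PairTest(lrt_stat=float(stat), p_value=float(stats.chi2.sf(stat, df=1)))


def rho_u(x, y):
    """Phylogenetically-uncorrected Pearson correlation with its t-test.

    Ordinary Pearson r over tip values with a two-sided t-test on n-2 degrees
    of freedom; ignores the tree entirely (the procedure this package's model
    is benchmarked against).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


class PhyloPairBM:
    """Estimator interface to the bivariate BM fit.

    Parameters
    ----------
    cov : SpeciesCovariance or (n, n) array
        Phylogenetic covariance of the species sample.
    constrain_zero_cov : bool
        Fit the independent-evolution null (r12 = 0) instead of the full
        model.

    After ``fit(X, se=se)`` with X of shape (n_species, 2):

    Attributes
    ----------
    theta_ : (2,) root state estimates
    rate_matrix_ : fitted RateMatrix
    rho_c_ : evolutionary correlation
    loglik_ : maximized log-likelihood
    converged_, boundary_ : fit status flags
    lrt_stat_, p_value_ : filled by :meth:`test` against the nested null
    """

    def __init__(self, cov=None, constrain_zero_cov=False, z_starts=(-0.5, 0.0, 0.5)):
        self.cov = cov
        self.constrain_zero_cov = constrain_zero_cov
        self.z_starts = z_starts

    def get_params(self, deep=True):
        return {
            "cov": self.cov,
            "constrain_zero_cov": self.constrain_zero_cov,
            "z_starts": self.z_starts,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError("invalid parameter %r" % k)
            setattr(self, k, v)
        return self

    def fit(self, X, se=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_species, 2)")
        se_t = None if se is None else np.asarray(se, dtype=float).T
        res = fit_pair(
            self.cov, X.T, se_t,
            constrain_zero_cov=self.constrain_zero_cov, z_starts=self.z_starts,
        )
        self.result_ = res
        self.theta_ = res.theta
        self.rate_matrix_ = res.R
        self.rho_c_ = res.rho_c
        self.loglik_ = res.loglik
        self.converged_ = res.converged
        self.boundary_ = res.boundary
        self._X, self._se = X, se
        return self

    def test(self) -> PairTest:
        """LRT of the fitted full model against the r12 = 0 null."""
        if self.constrain_zero_cov:
            raise ValueError("fit the full model to test against the null")
        null = PhyloPairBM(self.cov, constrain_zero_cov=True).fit(self._X, self._se)
        out = lrt(self.result_, null.result_)
        self.lrt_stat_ = out.lrt_stat
        self.p_value_ = out.p_value
        return out
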