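"""Bounded power-law (PLB) model of the individual size distribution.

The individual size distribution (ISD, "size spectrum") of a fish assemblage
treats every measured individual as a draw from a single bounded power law on
body mass ``x`` in ``[x_min, x_max]``::

    f(x) = (b + 1) * x**b / (x_max**(b+1) - x_min**(b+1))      (b != -1)
    f(x) = x**-1 / ln(x_max / x_min)                            (b == -1)

The exponent ``b`` summarises the relative abundance of large versus small
individuals: higher (less negative) ``b`` means proportionally more large
fish.  ``b`` is estimated here by direct maximum likelihood on the individual
body masses, which avoids the biases of binning-and-regression approaches,
with a 95% profile-likelihood interval.

A community-level null expectation for ``b`` follows from trophic-transfer
arguments: ``b = lambda + log(TTE)/log(PPMR)``, where TTE is the trophic
transfer efficiency, PPMR the predator-prey mass ratio and ``lambda`` a
scaling constant (canonical values TTE=0.10, PPMR=10,000, lambda=-0.75 give
b = -1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from sklearn.base import BaseEstimator

__all__ = [
    "PLBParams",
    "ISDFit",
    "CanonicalSpectrumParams",
    "plb_negloglik",
    "plb_pdf",
    "plb_cdf",
    "plb_sample",
    "fit_isd",
    "canonical_b",
    "BoundedPowerLaw",
]

# |b + 1| below this switches to the log-uniform limit branch
_B_NEAR_MINUS_ONE = 1e-8
# chi-square(1) 95% quantile / 2 — profile-likelihood cut-off
_PROFILE_CUT = 1.92
_B_LOWER, _B_UPPER = -10.0, 5.0


@dataclass(frozen=True)
class PLBParams:
    """Parameters of a bounded power law on body mass (grams)."""

    b: float
    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not (self.x_min > 0):
            raise ValueError(f"x_min must be > 0, got {self.x_min}")
        if not (self.x_max > self.x_min):
            raise ValueError(
                f"x_max must exceed x_min, got x_min={self.x_min}, x_max={self.x_max}"
            )
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")


@dataclass(frozen=True)
class ISDFit:
    """Maximum-likelihood ISD fit for one assemblage."""

    b_hat: float
    ci_lo: float
    ci_hi: float
    n: int
    x_min: float
    x_max: float
    neg_loglik_at_mle: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CanonicalSpectrumParams:
    """Trophic-transfer parameters of the canonical size-spectrum relation."""

    tte: float
    ppmr: float
    lam: float

    def __post_init__(self) -> None:
        if not (0.0 < self.tte <= 1.0):
            raise ValueError(f"tte must be in (0, 1], got {self.tte}")
        if not (self.ppmr > 1.0):
            raise ValueError(f"ppmr must be > 1, got {self.ppmr}")


def _as_mass_array(masses) -> np.ndarray:
    x = np.asarray(masses, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("at least one mass is required")
    if not np.all(np.isfinite(x)):
        raise ValueError("masses must be finite")
    return x


def plb_negloglik(masses, params: PLBParams) -> float:
    """Negative log-likelihood of bounded power-law body masses.

    Parameters
    ----------
    masses : array-like of float
        Individual body masses (g), all within ``[x_min, x_max]``.
    params : PLBParams

    Returns
    -------
    float
        ``-[n ln((b+1)/(x_max^(b+1) - x_min^(b+1))) + b * sum(ln x_i)]`` for
        ``b != -1``; the continuous limit
        ``n ln(ln(x_max/x_min)) + sum(ln x_i)`` at ``b == -1``.
    """
    x = _as_mass_array(masses)
    if np.any(x < params.x_min) or np.any(x > params.x_max):
        raise ValueError("masses outside [x_min, x_max]")
    return _negloglik(x.size, float(np.log(x).sum()), params.b, params.x_min, params.x_max)


def _negloglik(n: int, sum_log_x: float, b: float, x_min: float, x_max: float) -> float:
    if abs(b + 1.0) < _B_NEAR_MINUS_ONE:
        return n * np.log(np.log(x_max / x_min)) + sum_log_x
    b1 = b + 1.0
    # (b+1) and (x_max^(b+1) - x_min^(b+1)) always share sign, so the
    # normalising constant is positive for any valid bounds.
    norm = b1 / (x_max**b1 - x_min**b1)
    return -(n * np.log(norm) + b * sum_log_x)


def plb_pdf(x, params: PLBParams) -> np.ndarray:
    """PLB probability density, zero outside the bounds."""
    x = np.asarray(x, dtype=float)
    b, lo, hi = params.b, params.x_min, params.x_max
    if abs(b + 1.0) < _B_NEAR_MINUS_ONE:
        dens = 1.0 / (x * np.log(hi / lo))
    else:
        b1 = b + 1.0
        dens = b1 * x**b / (hi**b1 - lo**b1)
    return np.where((x >= lo) & (x <= hi), dens, 0.0)


def plb_cdf(x, params: PLBParams) -> np.ndarray:
    """PLB cumulative distribution function."""
    x = np.asarray(x, dtype=float)
    b, lo, hi = params.b, params.x_min, params.x_max
    xc = np.clip(x, lo, hi)
    if abs(b + 1.0) < _B_NEAR_MINUS_ONE:
        c = np.log(xc / lo) / np.log(hi / lo)
    else:
        b1 = b + 1.0
        c = (xc**b1 - lo**b1) / (hi**b1 - lo**b1)
    return np.where(x < lo, 0.0, np.where(x > hi, 1.0, c))


def plb_sample(n: int, params: PLBParams, seed=None, *, u=None) -> np.ndarray:
    """Draw ``n`` body masses by inverse-CDF sampling.

    ``u`` (uniform variates in [0, 1]) may be supplied directly for
    deterministic checks; otherwise draws come from
    ``numpy.random.default_rng(seed)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b, lo, hi = params.b, params.x_min, params.x_max
    if u is None:
        u = np.random.default_rng(seed).uniform(size=n)
    else:
        u = np.asarray(u, dtype=float)
    if abs(b + 1.0) < _B_NEAR_MINUS_ONE:
        return lo * (hi / lo) ** u
    b1 = b + 1.0
    return (u * (hi**b1 - lo**b1) + lo**b1) ** (1.0 / b1)


def fit_isd(masses) -> ISDFit:
    """Fit the bounded power law to individual masses by maximum likelihood.

    Bounds are set to the observed minimum and maximum mass.  ``b`` is found
    by bounded 1-D minimisation of the negative log-likelihood on
    ``[-10, 5]``; the 95% confidence interval is the profile-likelihood set
    ``{b : nll(b) <= nll(b_hat) + 1.92}``, located by root bracketing on each
    side.

    Raises
    ------
    ValueError
        Fewer than two masses, or all masses identical (degenerate ISD).
    RuntimeError
        Optimizer failure.
    """
    x = _as_mass_array(masses)
    if x.size < 2:
        raise ValueError("at least two individuals are required to fit an ISD")
    lo, hi = float(x.min()), float(x.max())
    if not (lo > 0):
        raise ValueError("masses must be positive")
    if lo == hi:
        raise ValueError("all masses identical: ISD exponent is not identifiable")

    n, sum_log_x = x.size, float(np.log(x).sum())

    def nll(b: float) -> float:
        return _negloglik(n, sum_log_x, b, lo, hi)

    res = minimize_scalar(
        nll, bounds=(_B_LOWER, _B_UPPER), method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(f"ISD likelihood optimization failed: {res.message}")
    b_hat, nll_min = float(res.x), float(res.fun)

    target = nll_min + _PROFILE_CUT

    def excess(b: float) -> float:
        return nll(b) - target

    ci_lo = _profile_root(excess, b_hat, _B_LOWER)
    ci_hi = _profile_root(excess, b_hat, _B_UPPER)
    return ISDFit(b_hat, ci_lo, ci_hi, n, lo, hi, nll_min)


def _profile_root(excess, b_hat: float, bound: float) -> float:
    """Root of the profile excess between ``b_hat`` and ``bound``.

    Falls back to the box bound if the likelihood never rises 1.92 units
    before reaching it (extremely flat profile).
    """
    if excess(bound) <= 0:
        return bound
    return float(brentq(excess, min(b_hat, bound), max(b_hat, bound), xtol=1e-6))


def canonical_b(tte: float, ppmr: float, lam: float) -> float:
    """Canonical size-spectrum exponent ``lam + log(TTE)/log(PPMR)``.

    The log-ratio is base invariant.  TTE=1 returns ``lam`` exactly.
    """
    params = CanonicalSpectrumParams(tte=tte, ppmr=ppmr, lam=lam)
    return float(params.lam + np.log(params.tte) / np.log(params.ppmr))


class BoundedPowerLaw(BaseEstimator):
    """Maximum-likelihood bounded power-law ISD estimator.

    scikit-learn style: ``fit`` consumes a 1-D array (or single-column 2-D
    array) of individual body masses and exposes the exponent and its profile
    CI as fitted attributes.

    Attributes
    ----------
    b_ : float
        ML estimate of the ISD exponent.
    ci_ : tuple of float
        95% profile-likelihood interval for ``b_``.
    x_min_, x_max_ : float
        Observed mass bounds used by the likelihood.
    n_ : int
        Number of individuals.
    neg_loglik_ : float
        Negative log-likelihood at the MLE.

    Examples
    --------
    >>> rng_masses = plb_sample(5000, PLBParams(-2.0, 1.0, 100.0), seed=0)
    >>> est = BoundedPowerLaw().fit(rng_masses)
    >>> -2.2 < est.b_ < -1.8
    True
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        if X.ndim != 1:
            raise ValueError("expected a 1-D array of body masses")
        fit = fit_isd(X)
        self.b_ = fit.b_hat
        self.ci_ = (fit.ci_lo, fit.ci_hi)
        self.x_min_ = fit.x_min
        self.x_max_ = fit.x_max
        self.n_ = fit.n
        self.neg_loglik_ = fit.neg_loglik_at_mle
        self.result_ = fit
        return self

    def score(self, X, y=None) -> float:
        """Mean log-likelihood of ``X`` under the fitted PLB."""
        params = PLBParams(self.b_, self.x_min_, self.x_max_)
        x = _as_mass_array(X)
        x = x[(x >= self.x_min_) & (x <= self.x_max_)]
        return float(-plb_negloglik(x, params) / x.size)

    def sample(self, n: int, random_state=None) -> np.ndarray:
        """Draw ``n`` masses from the fitted PLB."""
        return plb_sample(n, PLBParams(self.b_, self.x_min_, self.x_max_), seed=random_state)
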