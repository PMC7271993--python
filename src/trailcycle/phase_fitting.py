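"""Fitting duration distributions to right-censored phase lengths.

Phase durations measured in a time-lapse movie are right-censored when a
cell's phase did not end before the movie did: only a lower bound on the
duration is known.  Candidate families (lognormal, gamma, weibull,
normal) are fitted by maximum likelihood with the censored contribution
``log(1 - CDF)`` and compared by BIC.  The module also provides the
descriptive statistics used alongside: Pearson correlation with a Fisher
95% CI, the Wilcoxon rank-sum test, and a two-proportion comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.proportion import proportions_ztest

FAMILIES = ("lognormal", "gamma", "weibull", "normal")


@dataclass
class CensoredSample:
    """Positive durations with per-value right-censoring flags."""

    values: np.ndarray
    censored: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.values.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.values.shape != self.censored.shape:
            raise ValueError("values and censored must have equal length")
        if np.any(self.values <= 0):
            raise ValueError("all values must be > 0")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_uncensored(self) -> int:
        return int((~self.censored).sum())


@dataclass
class FitResult:
    family: str
    params: dict
    loglik: float
    n_params: int
    bic: float
    converged: bool = True
    message: str = ""
    delta_bic: Optional[float] = None


def _frozen(family: str, theta):
    """Map unconstrained optimizer parameters to a frozen scipy dist."""
    if family == "lognormal":
        return stats.lognorm(s=math.exp(theta[1]), scale=math.exp(theta[0]))
    if family == "gamma":
        return stats.gamma(math.exp(theta[0]), scale=math.exp(theta[1]))
    if family == "weibull":
        return stats.weibull_min(math.exp(theta[0]), scale=math.exp(theta[1]))
    if family == "normal":
        return stats.norm(loc=theta[0], scale=math.exp(theta[1]))
    raise ValueError(f"unknown family {family!r}")


def _named_params(family: str, theta) -> dict:
    if family == "lognormal":
        return {"mu": theta[0], "sigma": math.exp(theta[1])}
    if family in ("gamma", "weibull"):
        return {"shape": math.exp(theta[0]), "scale": math.exp(theta[1])}
    return {"mu": theta[0], "sigma": math.exp(theta[1])}


def _initial_theta(family: str, sample: CensoredSample):
    x = sample.values[~sample.censored]
    lx = np.log(x)
    if family == "lognormal":
        return np.array([lx.mean(), math.log(max(lx.std(), 1e-3))])
    if family == "normal":
        return np.array([x.mean(), math.log(max(x.std(), 1e-3))])
    mean, var = x.mean(), max(x.var(), 1e-6)
    if family == "gamma":
        shape = mean ** 2 / var
        return np.log([max(shape, 1e-3), max(mean / shape, 1e-6)])
    # weibull: crude moment-based start
    cv = math.sqrt(var) / mean
    shape = max(cv ** -1.086, 0.2)
    return np.log([shape, mean / math.gamma(1.0 + 1.0 / shape)])


def censored_loglik(theta, sample: CensoredSample, family: str) -> float:
    """log L = sum_uncensored log pdf + sum_censored log(1 - CDF)."""
    dist = _frozen(family, theta)
    ll = dist.logpdf(sample.values[~sample.censored]).sum()
    if sample.censored.any():
        ll += dist.logsf(sample.values[sample.censored]).sum()
    return float(ll)


def fit_censored(sample: CensoredSample, family: str,
                 n_params_override: Optional[int] = None) -> FitResult:
    """Maximum-likelihood fit of one family under right-censoring.

    ``n_params_override`` only changes the parameter count entering the
    BIC penalty (it does not change the fitted family), so alternative
    counting conventions can be reproduced.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if sample.n_uncensored < 2:
        raise ValueError("need at least 2 uncensored values")
    if np.ptp(sample.values[~sample.censored]) == 0:
        raise ValueError("degenerate sample: all uncensored values identical")
    theta0 = _initial_theta(family, sample)

    def nll(theta):
        v = -censored_loglik(theta, sample, family)
        return v if np.isfinite(v) else 1e12

    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 4000})
    loglik = -res.fun
    k = n_params_override if n_params_override is not None else 2
    bic = k * math.log(sample.n) - 2.0 * loglik
    return FitResult(family=family, params=_named_params(family, res.x),
                     loglik=loglik, n_params=k, bic=bic,
                     converged=bool(res.success), message=res.message)


def bic_rank(sample: CensoredSample,
             families: Sequence[str] = FAMILIES,
             n_params: Optional[dict] = None) -> list[FitResult]:
    """Fit several families and rank them by ascending BIC."""
    if len(families) < 2:
        raise ValueError("need at least 2 families to rank")
    n_params = n_params or {}
    fits = [fit_censored(sample, fam, n_params.get(fam)) for fam in families]
    fits.sort(key=lambda f: f.bic)
    best = fits[0].bic
    for f in fits:
        f.delta_bic = f.bic - best
    return fits


class CensoredDurationFitter(BaseEstimator):
    """Censored-MLE distribution fitting with BIC model selection.

    Parameters
    ----------
    families : sequence of str
        Candidate families to fit and rank.
    n_params : dict or None
        Optional per-family parameter-count override for the BIC penalty.

    Attributes
    ----------
    results_ : list of FitResult, ascending BIC
    best_ : FitResult
    """

    def __init__(self, families: Sequence[str] = FAMILIES, n_params=None):
        self.families = families
        self.n_params = n_params

    def fit(self, X, y=None, censored=None):
        sample = CensoredSample(np.ravel(np.asarray(X, float)), censored)
        self.results_ = bic_rank(sample, self.families, self.n_params)
        self.best_ = self.results_[0]
        self.n_features_in_ = 1
        return self


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def pearson_with_ci(x, y, confidence: float = 0.95):
    """Pearson correlation with Fisher z-transform confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return float(res.statistic), float(ci.low), float(ci.high)


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def proportion_difference(k1: int, n1: int, k2: int, n2: int,
                          alpha: float = 0.05) -> dict:
    """Compare two proportions by two labeled criteria.

    Returns both the standard pooled two-proportion z-test p-value and a
    margin-of-error criterion that declares a difference significant
    when |p1 - p2| exceeds ``z_(1-alpha/2) * sqrt(pbar*(1-pbar)/(n1+n2))``
    under the pooled null.  The two criteria use different null standard
    errors and can disagree; both are reported.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("n must be > 0")
        if not 0 <= k <= n:
            raise ValueError("require 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pbar = (k1 + k2) / (n1 + n2)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    margin = zcrit * math.sqrt(max(pbar * (1.0 - pbar), 0.0) / (n1 + n2))
    if 0 < pbar < 1:
        zstat, pval = proportions_ztest([k1, k2], [n1, n2])
    else:
        zstat, pval = 0.0, 1.0
    return {
        "p1": p1, "p2": p2, "diff": p1 - p2,
        "z_test_stat": float(zstat), "z_test_p": float(pval),
        "z_test_significant": bool(pval < alpha),
        "margin_of_error": margin,
        "margin_criterion_significant": bool(abs(p1 - p2) > margin),
    }
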