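"""Maximum-likelihood quantal dose-response analysis.

Implements the classical probit/logit-analysis toolchain for larvicide
bioassays: Abbott's control-mortality correction, Newton-Raphson binomial
ML fitting of mortality on log10 concentration, LCp inversion, Fieller
(fiducial) and delta-method confidence limits with Finney's heterogeneity
inflation, Pearson goodness of fit, and the high-dose activity screen that
reports censored LC50s ("> top dose") for non-active preparations.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm, t as t_dist

from .errors import (
    ConvergenceError,
    DegenerateDataError,
    InvalidControlError,
    MissingDataError,
    NonMonotoneFitError,
    UnboundedLimitsError,
)
from .types import LINKS, BioassayObservation, LethalConcentration, QuantalFit, ScreenResult

logger = logging.getLogger(__name__)

_PCLIP = 1e-12


def abbott_correct(p_treated: float, p_control: float) -> float:
    """Abbott's correction: mortality attributable to treatment,
    (p_treated - p_control) / (1 - p_control), clamped to [0, 1].

    Identity when control mortality is zero.
    """
    if not 0 <= p_control < 1:
        if p_control == 1:
            raise InvalidControlError("control mortality is 100%: no surviving baseline")
        raise ValueError(f"p_control must be in [0, 1), got {p_control}")
    if not 0 <= p_treated <= 1:
        raise ValueError(f"p_treated must be in [0, 1], got {p_treated}")
    return min(1.0, max(0.0, (p_treated - p_control) / (1.0 - p_control)))


def pool_observations(
    observations: Iterable[BioassayObservation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool replicate wells within each nonzero concentration.

    Returns (doses ascending, n exposed, deaths); control wells are excluded.
    """
    totals: dict[float, list[float]] = {}
    for obs in observations:
        if obs.is_control:
            continue
        acc = totals.setdefault(obs.concentration, [0.0, 0.0])
        acc[0] += obs.n_exposed
        acc[1] += obs.n_dead
    if not totals:
        raise MissingDataError("no nonzero-concentration observations to pool")
    doses = np.array(sorted(totals))
    n = np.array([totals[d][0] for d in doses])
    y = np.array([totals[d][1] for d in doses])
    return doses, n, y


def _fprime(link: str, eta: np.ndarray, p: np.ndarray, f: np.ndarray) -> np.ndarray:
    # derivative of the link density: logistic f' = f(1-2F); normal f' = -eta f
    if link == "logit":
        return f * (1.0 - 2.0 * p)
    return -eta * f


def _loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def _saturated_loglik(y: np.ndarray, n: np.ndarray) -> float:
    phat = np.clip(y / n, _PCLIP, 1.0 - _PCLIP)
    return float(np.sum(y * np.log(phat) + (n - y) * np.log1p(-phat)))


def _start_values(x: np.ndarray, n: np.ndarray, y: np.ndarray, link: str) -> np.ndarray:
    # regression of shrunk empirical quantiles on log10 dose
    pstar = (y + 0.5) / (n + 1.0)
    z = LINKS[link].ppf(pstar)
    b, a = np.polyfit(x, z, 1)
    if not np.isfinite(a) or not np.isfinite(b) or b <= 0:
        a, b = float(np.mean(z)), 1.0
    return np.array([a, b])


def fit_quantal(
    observations: Sequence[BioassayObservation],
    link: str = "logit",
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    start: Sequence[float] | None = None,
) -> QuantalFit:
    """Fit mortality ~ F(intercept + slope * log10 dose) by binomial ML.

    Replicates are pooled within concentration; control wells never enter
    the regression.  Newton-Raphson with step-halving; the covariance is
    the inverse observed information at the optimum.

    Raises
    ------
    DegenerateDataError
        All-dead / all-alive / flat response or complete separation; the
        caller should report a censored LC50 via :func:`activity_screen`.
    ConvergenceError
        Newton did not converge within ``max_iter`` iterations.
    """
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}; choose from {sorted(LINKS)}")
    doses, n, y = pool_observations(observations)
    k = len(doses)
    if k < 2:
        raise DegenerateDataError(f"need >= 2 distinct nonzero concentrations, got {k}")
    if k < 3:
        warnings.warn(
            "fewer than 3 distinct concentrations: fit is saturated, no goodness of fit",
            stacklevel=2,
        )
    phat = y / n
    if np.all(y == 0):
        raise DegenerateDataError("no deaths at any dose")
    if np.all(y == n):
        raise DegenerateDataError("complete mortality at every dose")
    if np.allclose(phat, phat[0]):
        raise DegenerateDataError("flat response: slope indistinguishable from 0")
    if np.all((y == 0) | (y == n)):
        raise DegenerateDataError("complete separation: slope diverges")

    x = np.log10(doses)
    dist = LINKS[link]
    beta = np.asarray(start, dtype=float) if start is not None else _start_values(x, n, y, link)
    ll = _loglik(y, n, dist.cdf(beta[0] + beta[1] * x))
    ll_sat = _saturated_loglik(y, n)
    X = np.column_stack([np.ones_like(x), x])

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = np.clip(dist.cdf(eta), _PCLIP, 1.0 - _PCLIP)
        f = dist.pdf(eta)
        pq = p * (1.0 - p)
        resid = y - n * p
        u = f * resid / pq  # dl/deta per dose
        grad = X.T @ u
        # observed information: -d2l/deta2
        d2 = (
            _fprime(link, eta, p, f) * resid / pq
            - n * f**2 / pq
            - f**2 * resid * (1.0 - 2.0 * p) / pq**2
        )
        H = X.T @ (-d2[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix", beta, it)
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = _loglik(y, n, dist.cdf(X @ cand))
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, ll_old, ll = cand, ll, ll_new
        dev_old = 2.0 * (ll_sat - ll_old)
        dev_new = 2.0 * (ll_sat - ll)
        rel = abs(dev_new - dev_old) / (abs(dev_old) + 1e-12)
        if rel < tol or np.max(np.abs(grad)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", beta, it)

    eta = X @ beta
    p = np.clip(dist.cdf(eta), _PCLIP, 1.0 - _PCLIP)
    f = dist.pdf(eta)
    pq = p * (1.0 - p)
    resid = y - n * p
    d2 = (
        _fprime(link, eta, p, f) * resid / pq
        - n * f**2 / pq
        - f**2 * resid * (1.0 - 2.0 * p) / pq**2
    )
    H = X.T @ (-d2[:, None] * X)
    cov = np.linalg.inv(H)

    chi2, df, het = _pearson(doses, n, y, p)
    fit = QuantalFit(
        link=link,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        covariance=cov,
        k_doses=k,
        chi2=chi2,
        df=df,
        heterogeneity=het,
        converged=True,
        iterations=it,
        loglik=ll,
    )
    logger.info(
        "fit link=%s slope=%.4g intercept=%.4g chi2=%.3g df=%d iters=%d",
        link, fit.slope, fit.intercept, chi2, df, it,
    )
    return fit


def _pearson(
    doses: np.ndarray, n: np.ndarray, y: np.ndarray, p: np.ndarray
) -> tuple[float, int, float]:
    keep = n * p * (1.0 - p) > 1e-10
    if not np.all(keep):
        warnings.warn(
            f"excluding {int(np.sum(~keep))} dose(s) with expected count ~0 "
            "from the Pearson statistic",
            stacklevel=3,
        )
    chi2 = float(np.sum((y[keep] - n[keep] * p[keep]) ** 2 / (n[keep] * p[keep] * (1 - p[keep]))))
    df = int(np.sum(keep)) - 2
    het = max(1.0, chi2 / df) if df >= 1 else 1.0
    return chi2, max(df, 0), het


def goodness_of_fit(
    fit: QuantalFit, observations: Sequence[BioassayObservation]
) -> tuple[float, int, float]:
    """Pearson chi-square over pooled doses, df = k - 2, and Finney's
    heterogeneity factor h = max(1, chi2/df)."""
    doses, n, y = pool_observations(observations)
    p = np.clip(np.asarray(fit.predict(doses)), _PCLIP, 1 - _PCLIP)
    return _pearson(doses, n, y, p)


def lc_p(fit: QuantalFit, p_level: float = 0.5) -> LethalConcentration:
    """Invert the fit: the concentration producing mortality ``p_level``.

    LCp = 10^((F^-1(p) - intercept) / slope); for p = 0.5 both links give
    LC50 = 10^(-intercept/slope).
    """
    if not 0 < p_level < 1:
        raise ValueError(f"p_level must be in (0, 1), got {p_level}")
    if fit.slope <= 0:
        raise NonMonotoneFitError(f"slope {fit.slope:.4g} <= 0: LCp undefined")
    z = float(LINKS[fit.link].ppf(p_level))
    est = 10.0 ** ((z - fit.intercept) / fit.slope)
    return LethalConcentration(p_level=p_level, estimate=est)


def confidence_limits(
    fit: QuantalFit,
    p_level: float = 0.5,
    method: str = "fieller",
    confidence: float = 0.95,
) -> LethalConcentration:
    """Confidence limits for LCp on the ng/mL scale.

    ``fieller`` solves the fiducial quadratic for the ratio
    (F^-1(p) - intercept)/slope; ``delta`` propagates first-order error.
    When heterogeneity h > 1 the covariance is inflated by h and t(df)
    quantiles replace normal quantiles (Finney's convention).
    """
    if method not in ("fieller", "delta"):
        raise ValueError(f"method must be 'fieller' or 'delta', got {method!r}")
    point = lc_p(fit, p_level)
    z = float(LINKS[fit.link].ppf(p_level))
    a, b = fit.intercept, fit.slope
    cov = fit.covariance.copy()
    if fit.heterogeneity > 1.0 and fit.df >= 1:
        cov = cov * fit.heterogeneity
        q = float(t_dist.ppf(0.5 + confidence / 2.0, fit.df))
    else:
        q = float(norm.ppf(0.5 + confidence / 2.0))
    v11, v12, v22 = cov[0, 0], cov[0, 1], cov[1, 1]
    rho = (z - a) / b  # log10 LCp

    if not np.any(cov):
        lower = upper = point.estimate
    elif method == "fieller":
        # roots of (a + b*rho - z)^2 = q^2 Var(a + b*rho)
        A = b**2 - q**2 * v22
        if A <= 0:
            raise UnboundedLimitsError(
                f"Fieller g = {q**2 * v22 / b**2:.3g} >= 1: slope not significantly > 0"
            )
        B = 2.0 * (b * (a - z) - q**2 * v12)
        C = (a - z) ** 2 - q**2 * v11
        disc = B**2 - 4.0 * A * C
        if disc < 0:
            raise UnboundedLimitsError("no real fiducial limits")
        r1 = (-B - math.sqrt(disc)) / (2.0 * A)
        r2 = (-B + math.sqrt(disc)) / (2.0 * A)
        lower, upper = 10.0 ** min(r1, r2), 10.0 ** max(r1, r2)
    else:
        se = math.sqrt(max(0.0, v11 + 2.0 * rho * v12 + rho**2 * v22)) / abs(b)
        lower, upper = 10.0 ** (rho - q * se), 10.0 ** (rho + q * se)

    return LethalConcentration(
        p_level=p_level,
        estimate=point.estimate,
        lower=min(lower, point.estimate),
        upper=max(upper, point.estimate),
        confidence=confidence,
        method=method,
    )


def activity_screen(
    treatment_mortality: Mapping[float, float],
    high_dose: float,
    activity_threshold: float = 0.10,
) -> ScreenResult:
    """High-dose screen: a preparation is non-active when its corrected
    mortality at the highest tested dose falls below the threshold; the LC50
    is then censored as '> high_dose'."""
    if not treatment_mortality:
        raise MissingDataError("empty dose -> mortality map")
    if high_dose not in treatment_mortality:
        raise MissingDataError(f"high dose {high_dose} absent from the mortality map")
    if treatment_mortality[high_dose] < activity_threshold:
        return ScreenResult(
            verdict="non_active",
            lc50=LethalConcentration.censored_above(high_dose),
        )
    return ScreenResult(verdict="active")
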