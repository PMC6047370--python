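"""Closed-form instrument-strength and confounding-level measures.

For the treatment-choice model

    P(T=1 | Z, X1, X2, Xu) = expit(a0 + Z*az + X1*a1 + X2*a2 + Xu)

with a Bernoulli(p) instrument Z, three population quantities summarize a
scenario. Writing T* = a0 + Z*az + X1*a1 + X2*a2 + Xu for the latent
treatment index and A_j = exp(-(a0 + j*az + mu1*a1 + mu2*a2 + mu_u)):

* ``corr_TZ`` — Corr(T, Z) with the covariates and confounder frozen at
  their means, so only the instrument drives treatment variation:

      Corr(T,Z) = (1/(1+A1) - 1/(1+A0)) sqrt(p(1-p)) / sqrt(E(1-E)),
      E = p/(1+A1) + (1-p)/(1+A0).

* ``corr_Tstar_Z`` — Corr(Z, T*), the scenario's instrument strength:

      az sqrt(p(1-p)) / sqrt(az^2 p(1-p) + a1^2 s1^2 + a2^2 s2^2 + su^2).

* ``confounding_level`` — Corr(Xu, T*), the confounding level:

      su / sqrt(az^2 p(1-p) + a1^2 s1^2 + a2^2 s2^2 + su^2).

``first_stage_F`` is the sample analogue of the linear first-stage
F-statistic: with a single instrument it is defined here as the squared
Wald z-statistic of the instrument coefficient in the logistic
treatment-choice regression (a likelihood-ratio variant is available).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .estimators import FitResult, SingularDesignError, _logit_ml, _logit_nls
from .simulate import Cohort

__all__ = [
    "corr_TZ",
    "corr_Tstar_Z",
    "confounding_level",
    "first_stage_F",
    "scenario_diagnostics",
]


def _check_p(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")


def _tstar_sd(alpha, p: float, sigma1: float, sigma2: float, sigma_u: float) -> float:
    _, az, a1, a2 = alpha
    v = az**2 * p * (1 - p) + a1**2 * sigma1**2 + a2**2 * sigma2**2 + sigma_u**2
    if v <= 0:
        raise ValueError("latent index has zero variance")
    return float(np.sqrt(v))


def corr_TZ(alpha, p: float, mu1: float, mu2: float, mu_u: float = 0.0) -> float:
    """Corr(T, Z) with covariates/confounder frozen at their means."""
    _check_p(p)
    a0, az, a1, a2 = alpha
    base = a0 + mu1 * a1 + mu2 * a2 + mu_u
    A0 = np.exp(-base)
    A1 = np.exp(-(base + az))
    e1 = 1.0 / (1.0 + A1)
    e0 = 1.0 / (1.0 + A0)
    mean_t = p * e1 + (1 - p) * e0
    var_t = mean_t * (1 - mean_t)
    if var_t <= 0:
        return 0.0
    return float((e1 - e0) * np.sqrt(p * (1 - p)) / np.sqrt(var_t))


def corr_Tstar_Z(alpha, p: float, sigma1: float, sigma2: float, sigma_u: float) -> float:
    """Corr(Z, T*): correlation of the instrument with the latent index."""
    _check_p(p)
    az = alpha[1]
    return float(az * np.sqrt(p * (1 - p)) / _tstar_sd(alpha, p, sigma1, sigma2, sigma_u))


def confounding_level(alpha, p: float, sigma1: float, sigma2: float, sigma_u: float) -> float:
    """Corr(Xu, T*): correlation of the confounder with the latent index."""
    _check_p(p)
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    return float(sigma_u / _tstar_sd(alpha, p, sigma1, sigma2, sigma_u))


def first_stage_F(
    cohort: Cohort,
    instrument_name: str = "pr",
    method: str = "wald",
    loss: str = "nls",
) -> float:
    """Instrument-exclusion statistic in the treatment-choice model.

    Fits the regression of T on (1, instrument, X1, X2) on the given cohort
    (restrict to the estimation sample beforehand) and returns a squared
    instrument t-statistic, the single-instrument analogue of the linear
    first-stage F.

    ``loss`` selects the fit and covariance behind the Wald statistic:

    * ``"nls"`` (default) — logistic-mean nonlinear least squares with the
      conventional least-squares covariance ``s^2 (J'J)^-1``. This is the
      exact analogue of the OLS first-stage F, which also uses a pooled
      residual variance; with a binary treatment it over-states the
      statistic (the true residual variance varies with the linear
      predictor) and is therefore *not* chi-square calibrated under a null
      instrument, exactly as the linear F is anti-conservative under
      heteroscedasticity.
    * ``"ml"`` — logistic ML with the Fisher-information covariance; the
      calibrated Wald test (null mean approximately 1).

    ``method="lr"`` instead returns the ML likelihood-ratio statistic.
    """
    z = cohort.instrument(instrument_name)
    if np.any(~np.isfinite(z)):
        raise ValueError("instrument undefined for some patients; use estimation_sample()")
    full = np.column_stack([np.ones(len(cohort)), z, cohort.X1, cohort.X2])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise SingularDesignError("first-stage design is rank deficient")
    names = ["const", instrument_name, "X1", "X2"]
    if method == "wald" and loss == "nls":
        fit = _logit_nls(cohort.T, full, "first_stage", names)
        if not fit.converged:
            raise RuntimeError("first-stage fit did not converge; F undefined")
        p = expit(full @ fit.coef)
        J = (p * (1 - p))[:, None] * full
        s2 = float(np.sum((cohort.T - p) ** 2)) / (len(cohort) - full.shape[1])
        vcov = s2 * np.linalg.inv(J.T @ J)
        return float((fit.coef[1] / np.sqrt(vcov[1, 1])) ** 2)
    fit = _logit_ml(cohort.T, full, "first_stage", names)
    if not fit.converged:
        raise RuntimeError("first-stage fit did not converge; F undefined")
    if method == "wald":
        se = np.sqrt(fit.vcov[1, 1])
        return float((fit.coef[1] / se) ** 2)
    if method == "lr":
        reduced_X = np.column_stack([np.ones(len(cohort)), cohort.X1, cohort.X2])
        reduced = _logit_ml(cohort.T, reduced_X, "first_stage_reduced", ["const", "X1", "X2"])
        ll_full = _loglik(cohort.T, full, fit.coef)
        ll_red = _loglik(cohort.T, reduced_X, reduced.coef)
        return float(2.0 * (ll_full - ll_red))
    raise ValueError("method must be 'wald' or 'lr'")


def _loglik(y: np.ndarray, X: np.ndarray, coef: np.ndarray) -> float:
    eta = X @ coef
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def scenario_diagnostics(config, cohort: Cohort | None = None,
                         instrument_name: str = "pr") -> dict[str, float]:
    """All closed-form measures for a config, plus the sample F if a cohort
    is supplied."""
    out = {
        "corr_TZ": corr_TZ(config.alpha, config.p_pp, config.mu1, config.mu2, 0.0),
        "corr_Tstar_Z": corr_Tstar_Z(
            config.alpha, config.p_pp, config.sigma1, config.sigma2, config.sigma_u
        ),
        "confounding_level": confounding_level(
            config.alpha, config.p_pp, config.sigma1, config.sigma2, config.sigma_u
        ),
    }
    if cohort is not None:
        out["first_stage_F"] = first_stage_F(
            cohort.estimation_sample(), instrument_name
        )
    return out
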