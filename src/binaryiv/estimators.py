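"""Estimators for the logistic outcome model with an endogenous binary exposure.

Four fitters are compared throughout the package:

``fit_true``
    Logistic ML of Y on (1, T, X1, X2, Xu) — an oracle that observes the
    confounder; only available on simulated data.
``fit_conventional``
    Logistic ML of Y on (1, T, X1, X2), ignoring the confounder. Biased
    under confounding; serves as the naive benchmark.
``fit_2sri``
    Two-stage residual inclusion. Stage 1 regresses T on (1, instrument,
    X1, X2); stage 2 regresses Y on (1, T, X1, X2, U) where U is the stage-1
    residual, acting as a proxy for the confounder. Both stages use
    nonlinear least squares with a logistic mean by default (``stage_loss=
    "nls"``), which is the loss the two-step sandwich covariance assumes; a
    logistic-ML variant is available (``stage_loss="ml"``). The reported
    covariance is the three-term sandwich accounting for stage-1 estimation
    noise (see :func:`sandwich_covariance_2sri`).
``fit_gmm``
    Nonlinear IV-GMM: minimizes the quadratic form in the sample moments
    E[e w] = 0 with e = Y - expit(x'beta), w = (1, instrument, X1, X2).
    Exactly identified, so the point estimate solves the moment equations
    and is invariant to the weighting matrix; the two-step optimal weight
    is used for the covariance.

All fitters return :class:`FitResult`; ``fit_2sri`` returns
:class:`TwoStageFit` bundling both stages. Wald confidence intervals at a
95% nominal level are attached throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .simulate import Cohort

__all__ = [
    "FitResult",
    "TwoStageFit",
    "GmmSpec",
    "SingularDesignError",
    "fit_true",
    "fit_conventional",
    "fit_first_stage",
    "fit_2sri",
    "sandwich_covariance_2sri",
    "sandwich_blocks_2sri",
    "fit_gmm",
    "bootstrap_variance",
]

NOMINAL_LEVEL = 0.95

# beta_t is the second coefficient in every outcome design (1, T, X1, X2, ...)
TREATMENT_INDEX = 1


class SingularDesignError(np.linalg.LinAlgError):
    """Design or weight matrix is (numerically) singular."""


@dataclass
class FitResult:
    """Point estimates, covariance and Wald intervals from one fit."""

    method: str
    names: list[str]
    coef: np.ndarray
    vcov: np.ndarray
    converged: bool
    n_used: int
    ci: np.ndarray = field(default=None)  # type: ignore[assignment]
    notes: list[str] = field(default_factory=list)
    resid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ci is None:
            self.ci = wald_ci(self.coef, self.vcov)

    @property
    def beta_t(self) -> float:
        return float(self.coef[TREATMENT_INDEX])

    @property
    def var_beta_t(self) -> float:
        return float(self.vcov[TREATMENT_INDEX, TREATMENT_INDEX])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "coef": dict(zip(self.names, map(float, self.coef))),
                "vcov": np.asarray(self.vcov).tolist(),
                "ci": np.asarray(self.ci).tolist(),
                "converged": bool(self.converged),
                "n_used": int(self.n_used),
                "notes": list(self.notes),
            },
            indent=2,
        )


@dataclass
class TwoStageFit:
    """Both stages of a 2SRI fit plus the two-step sandwich covariance."""

    first: FitResult
    second: FitResult
    residual: np.ndarray
    sandwich: np.ndarray
    design_first: np.ndarray
    design_second: np.ndarray
    T: np.ndarray
    Y: np.ndarray

    @property
    def converged(self) -> bool:
        return self.first.converged and self.second.converged

    @property
    def beta_t(self) -> float:
        return self.second.beta_t

    @property
    def var_beta_t(self) -> float:
        return self.second.var_beta_t


@dataclass(frozen=True)
class GmmSpec:
    """Options for the IV-GMM fit (exactly identified moment system)."""

    instrument_name: str = "pr"
    weight_scheme: str = "two-step-optimal"  # or "identity"

    def __post_init__(self) -> None:
        if self.weight_scheme not in ("identity", "two-step-optimal"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")


def wald_ci(coef: np.ndarray, vcov: np.ndarray, level: float = NOMINAL_LEVEL) -> np.ndarray:
    z = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.clip(np.diag(np.asarray(vcov)), 0.0, None))
    coef = np.asarray(coef, dtype=float)
    return np.column_stack([coef - z * se, coef + z * se])


def _check_design(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise SingularDesignError("design contains non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")


def _logit_ml(
    y: np.ndarray, X: np.ndarray, method: str, names: list[str]
) -> FitResult:
    """Logistic maximum likelihood via IRLS; non-convergence and separation
    are reported through ``converged`` rather than raised."""
    _check_design(X)
    converged = True
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=100, tol=1e-10)
            coef = np.asarray(res.params)
            vcov = np.asarray(res.cov_params())
        except Exception as exc:  # separation, singularity, no convergence
            converged = False
            notes.append(f"ML fit failed: {type(exc).__name__}: {exc}")
            k = X.shape[1]
            coef = np.full(k, np.nan)
            vcov = np.full((k, k), np.nan)
            res = None
    if res is not None:
        if not res.converged:
            converged = False
            notes.append("IRLS did not converge")
        if np.any(np.abs(coef) > 50):
            converged = False
            notes.append("diverging coefficients (quasi-separation)")
    fit = FitResult(
        method=method,
        names=names,
        coef=coef,
        vcov=vcov,
        converged=converged,
        n_used=len(y),
        notes=notes,
    )
    if converged:
        fit.resid = y - expit(X @ coef)
    return fit


def _logit_nls(
    y: np.ndarray, X: np.ndarray, method: str, names: list[str]
) -> FitResult:
    """Nonlinear least squares with a logistic mean: minimizes
    (1/2n) sum (y_i - expit(x_i'b))^2, warm-started at the ML solution."""
    _check_design(X)
    start = _logit_ml(y, X, method, names)
    x0 = start.coef if start.converged else np.zeros(X.shape[1])

    def resid(b: np.ndarray) -> np.ndarray:
        return y - expit(X @ b)

    def jac(b: np.ndarray) -> np.ndarray:
        p = expit(X @ b)
        return -(p * (1 - p))[:, None] * X

    sol = optimize.least_squares(
        resid, x0, jac=jac, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    converged = bool(sol.success) and np.all(np.isfinite(sol.x))
    coef = sol.x
    if np.any(np.abs(coef) > 50):  # saturated link: quasi-separation
        converged = False
    p = expit(X @ coef)
    W = (p * (1 - p))[:, None] * X
    # Gauss-Newton covariance with heteroscedastic residuals (one-step
    # sandwich); for 2SRI's second stage this is replaced by the two-step
    # sandwich downstream.
    A = W.T @ W
    try:
        Ainv = np.linalg.inv(A)
        u = y - p
        S = (W * u[:, None] ** 2).T @ W
        vcov = Ainv @ S @ Ainv.T
    except np.linalg.LinAlgError:
        converged = False
        vcov = np.full((len(coef), len(coef)), np.nan)
    fit = FitResult(
        method=method,
        names=names,
        coef=coef,
        vcov=vcov,
        converged=converged,
        n_used=len(y),
        notes=[] if converged else ["NLS did not converge"],
    )
    fit.resid = y - p
    return fit


def _outcome_design(cohort: Cohort, with_confounder: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(cohort)), cohort.T, cohort.X1, cohort.X2]
    names = ["const", "T", "X1", "X2"]
    if with_confounder:
        cols.append(cohort.Xu)
        names.append("Xu")
    return np.column_stack(cols), names


def fit_true(cohort: Cohort) -> FitResult:
    """Oracle logistic fit of Y on (1, T, X1, X2, Xu); needs simulated Xu."""
    if np.any(~np.isfinite(cohort.Xu)):
        raise ValueError("true-model fit requires the confounder Xu (simulated data)")
    X, names = _outcome_design(cohort, with_confounder=True)
    return _logit_ml(cohort.Y, X, "true", names)


def fit_conventional(cohort: Cohort) -> FitResult:
    """Naive logistic fit of Y on (1, T, X1, X2), confounder omitted."""
    X, names = _outcome_design(cohort, with_confounder=False)
    return _logit_ml(cohort.Y, X, "conventional", names)


def _first_stage_design(cohort: Cohort, instrument_name: str) -> tuple[np.ndarray, list[str]]:
    z = cohort.instrument(instrument_name)
    if np.any(~np.isfinite(z)):
        raise ValueError(
            "instrument contains undefined values; restrict to the estimation "
            "sample (valid_proxy) first"
        )
    if np.ptp(z) == 0:
        raise SingularDesignError("instrument column is constant")
    w = np.column_stack([np.ones(len(cohort)), z, cohort.X1, cohort.X2])
    return w, ["const", instrument_name, "X1", "X2"]


def fit_first_stage(
    cohort: Cohort, instrument_name: str = "pr", loss: str = "nls"
) -> FitResult:
    """Treatment-choice model: T on (1, instrument, X1, X2).

    Residuals ``T - expit(w'alpha_hat)`` are stored on ``resid``. The
    cohort should already be restricted to patients with defined proxies.
    """
    w, names = _first_stage_design(cohort, instrument_name)
    fitter = {"nls": _logit_nls, "ml": _logit_ml}[loss]
    return fitter(cohort.T, w, f"first_stage[{instrument_name}]", names)


def fit_2sri(
    cohort: Cohort,
    instrument_name: str = "pr",
    stage_loss: str = "nls",
    residual_override: np.ndarray | None = None,
) -> TwoStageFit:
    """Two-stage residual inclusion with the two-step sandwich covariance.

    ``residual_override`` substitutes an arbitrary column for the stage-1
    residual in the stage-2 design (e.g. the true confounder, as an oracle
    check); the sandwich is still assembled from the actual stage-1 fit.
    """
    if stage_loss not in ("nls", "ml"):
        raise ValueError("stage_loss must be 'nls' or 'ml'")
    first = fit_first_stage(cohort, instrument_name, loss=stage_loss)
    w, _ = _first_stage_design(cohort, instrument_name)
    if not first.converged:
        k = 5
        nanfit = FitResult(
            "2sri", ["const", "T", "X1", "X2", "U"],
            np.full(k, np.nan), np.full((k, k), np.nan), False, len(cohort),
            notes=["first stage failed"],
        )
        return TwoStageFit(first, nanfit, np.full(len(cohort), np.nan),
                           np.full((k, k), np.nan), w,
                           np.full((len(cohort), k), np.nan), cohort.T, cohort.Y)

    u_alpha = cohort.T - expit(w @ first.coef)
    u_col = u_alpha if residual_override is None else np.asarray(residual_override, float)
    X = np.column_stack([np.ones(len(cohort)), cohort.T, cohort.X1, cohort.X2, u_col])
    names = ["const", "T", "X1", "X2", "U"]
    fitter = {"nls": _logit_nls, "ml": _logit_ml}[stage_loss]
    second = fitter(cohort.Y, X, "2sri", names)

    two = TwoStageFit(
        first=first,
        second=second,
        residual=u_alpha,
        sandwich=np.full((X.shape[1], X.shape[1]), np.nan),
        design_first=w,
        design_second=X,
        T=np.asarray(cohort.T, float),
        Y=np.asarray(cohort.Y, float),
    )
    if second.converged:
        try:
            V = sandwich_covariance_2sri(two)
            two.sandwich = V
            second.vcov = V
            second.ci = wald_ci(second.coef, V)
            second.notes.append("vcov: two-step sandwich")
        except SingularDesignError as exc:
            second.converged = False
            second.notes.append(f"sandwich failed: {exc}")
    return two


def sandwich_blocks_2sri(
    w: np.ndarray,
    X: np.ndarray,
    P_alpha: np.ndarray,
    P_beta: np.ndarray,
    U_alpha: np.ndarray,
    U_beta: np.ndarray,
    beta_u: float,
) -> dict[str, np.ndarray]:
    """Plug-in A/S blocks of the two-step covariance.

    With g = P_alpha(1-P_alpha) (stage-1 logistic density weight) and
    h = P_beta(1-P_beta) (stage-2 weight)::

        A11 = (1/n) [g w]' [g w]          S1  = (1/n) [g U_a w]' [g U_a w]
        A21 = (b_u/n) [h^2 X]' [g w]      S2  = (1/n) [h U_b X]' [h U_b X]
        A22 = (1/n) [h X]' [h X]          S21 = (1/n) [h U_b X]' [g U_a w]
    """
    n = len(P_alpha)
    g = P_alpha * (1 - P_alpha)
    h = P_beta * (1 - P_beta)
    gw = g[:, None] * w
    hX = h[:, None] * X
    return {
        "A11": gw.T @ gw / n,
        "A21": beta_u / n * ((h**2)[:, None] * X).T @ gw,
        "A22": hX.T @ hX / n,
        "S1": (gw * U_alpha[:, None]).T @ (gw * U_alpha[:, None]) / n,
        "S2": (hX * U_beta[:, None]).T @ (hX * U_beta[:, None]) / n,
        "S21": (hX * U_beta[:, None]).T @ (gw * U_alpha[:, None]) / n,
    }


def sandwich_covariance_2sri(
    two_stage: TwoStageFit, zero_cross_terms: bool = False
) -> np.ndarray:
    """Three-term covariance of the stage-2 coefficients.

    Var(beta_hat) = (1/n) [ A22^-1 S2 A22^-1'
                          + A22^-1 A21 A11^-1 S1 A11^-1' A21' A22^-1'
                          - A22^-1 S21 A11^-1' A21' A22^-1' ]

    The first term is the one-step heteroscedasticity-robust sandwich of the
    stage-2 regression; the remaining terms propagate stage-1 estimation
    noise through the residual column. ``zero_cross_terms`` forces
    A21 = S21 = 0, collapsing the expression to the first term. The result
    is symmetrized as (V + V')/2 before use.
    """
    w = two_stage.design_first
    X = two_stage.design_second
    n = X.shape[0]
    P_a = expit(w @ two_stage.first.coef)
    P_b = expit(X @ two_stage.second.coef)
    U_a = two_stage.T - P_a
    U_b = two_stage.Y - P_b
    beta_u = float(two_stage.second.coef[-1])
    B = sandwich_blocks_2sri(w, X, P_a, P_b, U_a, U_b, beta_u)
    if zero_cross_terms:
        B["A21"] = np.zeros_like(B["A21"])
        B["S21"] = np.zeros_like(B["S21"])
    for key in ("A11", "A22"):
        cond = np.linalg.cond(B[key])
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularDesignError(f"{key} is near-singular (cond={cond:.3g})")
    A11i = np.linalg.inv(B["A11"])
    A22i = np.linalg.inv(B["A22"])
    V = (
        A22i @ B["S2"] @ A22i.T
        + A22i @ B["A21"] @ A11i @ B["S1"] @ A11i.T @ B["A21"].T @ A22i.T
        - A22i @ B["S21"] @ A11i.T @ B["A21"].T @ A22i.T
    ) / n
    return (V + V.T) / 2.0


# ---------------------------------------------------------------------------
# GMM


def _gmm_arrays(cohort: Cohort, instrument_name: str):
    x = np.column_stack([np.ones(len(cohort)), cohort.T, cohort.X1, cohort.X2])
    w, _ = _first_stage_design(cohort, instrument_name)
    return x, w, np.asarray(cohort.Y, float)


def gmm_moments(beta: np.ndarray, x: np.ndarray, w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample moments (1/n) sum e_i w_i with e = y - expit(x'beta)."""
    e = y - expit(x @ beta)
    return w.T @ e / len(y)


def gmm_moment_jacobian(beta, x, w, y) -> np.ndarray:
    p = expit(x @ beta)
    return -(w * (p * (1 - p))[:, None]).T @ x / len(y)


def fit_gmm(
    cohort: Cohort, instrument_name: str = "pr", spec: GmmSpec | None = None
) -> FitResult:
    """IV-GMM for the outcome equation, exactly identified.

    Minimizes q(beta) = m(beta)' Omega m(beta) by multistart BFGS
    (starts: conventional-fit coefficients and the zero vector; gradient
    tolerance 1e-8, at most 500 iterations), then polishes with a Newton
    solve of the moment equations, which the exactly identified minimizer
    satisfies. Singular weight or Jacobian matrices flag the fit as
    non-converged instead of silently dropping it.
    """
    if spec is None:
        spec = GmmSpec(instrument_name=instrument_name)
    x, w, y = _gmm_arrays(cohort, instrument_name)
    n = len(y)
    names = ["const", "T", "X1", "X2"]
    k = x.shape[1]

    def make_q(Omega):
        def q(b):
            m = gmm_moments(b, x, w, y)
            return float(m @ Omega @ m)

        def grad(b):
            m = gmm_moments(b, x, w, y)
            G = gmm_moment_jacobian(b, x, w, y)
            return 2.0 * G.T @ Omega @ m

        return q, grad

    conv = fit_conventional(cohort)
    starts = [np.zeros(k)]
    if conv.converged:
        starts.insert(0, conv.coef)

    def minimize_q(Omega):
        q, grad = make_q(Omega)
        candidates = []
        for x0 in starts:
            sol = optimize.minimize(
                q, x0, jac=grad, method="BFGS",
                options={"gtol": 1e-8, "maxiter": 500},
            )
            candidates.extend([sol.x, x0])
        # Newton polish on the exactly identified moment equations; the
        # objective is numerically flat, so candidates are ranked by the
        # sup-norm of the polished moments, not by the optimizer's q.
        best, best_norm = None, np.inf
        for b0 in candidates:
            root = optimize.root(
                lambda b: gmm_moments(b, x, w, y),
                b0,
                jac=lambda b: gmm_moment_jacobian(b, x, w, y),
                method="hybr",
                tol=1e-12,
            )
            for cand in (root.x, b0):
                norm = np.max(np.abs(gmm_moments(cand, x, w, y)))
                if np.all(np.isfinite(cand)) and norm < best_norm:
                    best, best_norm = cand, norm
        return best

    notes: list[str] = []
    converged = True
    try:
        # Exactly identified: the minimizer solves the moment equations and
        # is invariant to Omega, so one identity-weight pass suffices; the
        # two-step optimal weight only enters the covariance below.
        beta_hat = minimize_q(np.eye(k))
        m_final = gmm_moments(beta_hat, x, w, y)
        if np.max(np.abs(m_final)) > 1e-6 or not np.all(np.isfinite(beta_hat)):
            converged = False
            notes.append(f"moment equations not solved (max |m|={np.max(np.abs(m_final)):.2e})")
        e = y - expit(x @ beta_hat)
        S = (w * e[:, None] ** 2).T @ w / n
        G = gmm_moment_jacobian(beta_hat, x, w, y)
        cond = max(np.linalg.cond(S), np.linalg.cond(G))
        if not np.isfinite(cond) or cond > 1e12:
            raise SingularDesignError(f"singular covariance pieces (cond={cond:.3g})")
        vcov = np.linalg.inv(G.T @ np.linalg.inv(S) @ G) / n
    except (SingularDesignError, np.linalg.LinAlgError) as exc:
        converged = False
        notes.append(f"singular: {exc}")
        beta_hat = np.full(k, np.nan)
        vcov = np.full((k, k), np.nan)

    return FitResult(
        method="gmm",
        names=names,
        coef=beta_hat,
        vcov=vcov,
        converged=converged,
        n_used=n,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_variance(
    cohort: Cohort,
    fitter,
    B: int,
    seed: int = 0,
    unit: str = "patient",
    resample: bool = True,
) -> np.ndarray:
    """Nonparametric bootstrap covariance of refitted coefficients.

    ``fitter`` maps a cohort to an object exposing ``coef`` (FitResult) or
    ``second.coef`` (TwoStageFit). ``unit='patient'`` resamples rows of the
    estimation sample; ``unit='physician'`` resamples whole physician
    blocks. ``resample=False`` refits the original cohort B times (useful
    only as a degenerate check; yields the zero matrix).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if unit not in ("patient", "physician"):
        raise ValueError("unit must be 'patient' or 'physician'")
    rng = np.random.default_rng(seed)
    coefs = []
    failures = 0
    pid = np.asarray(cohort.physician_id)
    phys = np.unique(pid)
    for _ in range(B):
        if not resample:
            boot = cohort
        elif unit == "patient":
            idx = rng.integers(0, len(cohort), len(cohort))
            boot = cohort.subset(np.sort(idx))
        else:
            chosen = rng.choice(phys, size=len(phys), replace=True)
            idx = np.concatenate([np.where(pid == p)[0] for p in chosen])
            boot = cohort.subset(idx)
        try:
            fit = fitter(boot)
            coef = fit.second.coef if hasattr(fit, "second") else fit.coef
            ok = fit.converged and np.all(np.isfinite(coef))
        except (ValueError, np.linalg.LinAlgError):
            ok = False
        if ok:
            coefs.append(np.asarray(coef, float))
        else:
            failures += 1
    if failures > 0.2 * B:
        raise RuntimeError(f"bootstrap: {failures}/{B} resample fits failed")
    arr = np.asarray(coefs)
    return np.atleast_2d(np.cov(arr, rowvar=False, ddof=1))
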