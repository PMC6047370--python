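"""Estimator correctness: oracles, sandwich blocks, GMM moment conditions."""

import copy

import numpy as np
import pytest
from scipy.special import expit

import binaryiv as biv
from binaryiv.estimators import (
    SingularDesignError,
    gmm_moments,
    sandwich_blocks_2sri,
    sandwich_covariance_2sri,
)
from binaryiv.simulate import ScenarioConfig


def test_true_model_parameter_recovery(mc_high_weak):
    """Averaged over 200 replications at n=30000, the oracle logistic fit
    recovers every generating coefficient within 3 MC standard errors."""
    df = mc_high_weak.estimates
    tr = df[(df["method"] == "true") & (df["status"] == "ok")]
    target = (-0.6, 3.0, 1.0, 1.0, 1.0)
    for j, truth in enumerate(target):
        vals = tr[f"c{j}"].to_numpy()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - truth) < 3 * se


def test_perfect_separation_flagged():
    rng = np.random.default_rng(0)
    n = 200
    T = rng.integers(0, 2, n).astype(float)
    c = biv.Cohort(
        physician_id=np.zeros(n, int), order=np.arange(1, n + 1),
        X1=rng.normal(size=n), X2=rng.normal(size=n), Xu=np.zeros(n),
        PP=np.zeros(n), T=T, Y=T.copy(),
    )
    fit = biv.fit_conventional(c)
    assert not fit.converged


def test_constant_instrument_rejected(small_cohort):
    s = copy.copy(small_cohort.estimation_sample())
    s.pr = np.full(len(s), 0.3)
    with pytest.raises(SingularDesignError):
        biv.fit_first_stage(s, "pr")


def test_first_stage_signal_and_score_equation(balanced_cohort):
    s = balanced_cohort.estimation_sample()
    fit = biv.fit_first_stage(s, "pr", loss="ml")
    assert fit.converged
    z = fit.coef[1] / np.sqrt(fit.vcov[1, 1])
    assert z > 4.0  # strong instrument scenario
    assert abs(fit.resid.sum()) < 1e-6  # ML score equation with intercept
    # permuted instrument destroys the association
    rng = np.random.default_rng(1)
    sp = copy.copy(s)
    sp.pr = rng.permutation(s.pr)
    pfit = biv.fit_first_stage(sp, "pr", loss="ml")
    assert abs(pfit.coef[1] / np.sqrt(pfit.vcov[1, 1])) < 4.0


def test_2sri_with_oracle_residual_matches_true_fit(small_cohort):
    """Substituting the confounder itself for the stage-1 residual makes the
    second stage the oracle regression."""
    s = small_cohort.estimation_sample()
    truth = biv.fit_true(s)
    two = biv.fit_2sri(s, "pr", stage_loss="ml", residual_override=s.Xu)
    np.testing.assert_allclose(two.second.coef, truth.coef, rtol=1e-5, atol=1e-6)


def test_sandwich_blocks_match_finite_difference(dense_cohort):
    """Each plug-in A/S block agrees with an assembly in which the logistic
    density weights are obtained by central finite differences."""
    s = dense_cohort.estimation_sample()
    two = biv.fit_2sri(s, "pr")
    assert two.converged
    w, X = two.design_first, two.design_second
    alpha, beta = two.first.coef, two.second.coef
    eps = 1e-6

    def dexpit(eta):
        return (expit(eta + eps) - expit(eta - eps)) / (2 * eps)

    P_a, P_b = expit(w @ alpha), expit(X @ beta)
    g, h = dexpit(w @ alpha), dexpit(X @ beta)
    U_a, U_b = two.T - P_a, two.Y - P_b
    n = len(s)
    gw, hX = g[:, None] * w, h[:, None] * X
    fd = {
        "A11": gw.T @ gw / n,
        "A21": beta[-1] / n * ((h**2)[:, None] * X).T @ gw,
        "A22": hX.T @ hX / n,
        "S1": (gw * U_a[:, None]).T @ (gw * U_a[:, None]) / n,
        "S2": (hX * U_b[:, None]).T @ (hX * U_b[:, None]) / n,
        "S21": (hX * U_b[:, None]).T @ (gw * U_a[:, None]) / n,
    }
    analytic = sandwich_blocks_2sri(w, X, P_a, P_b, U_a, U_b, float(beta[-1]))
    for key, block in analytic.items():
        denom = np.max(np.abs(block))
        assert np.max(np.abs(block - fd[key])) / denom < 1e-6, key


def test_sandwich_cross_terms_zeroed_equals_one_step(balanced_cohort):
    s = balanced_cohort.estimation_sample()
    two = biv.fit_2sri(s, "pr")
    V0 = sandwich_covariance_2sri(two, zero_cross_terms=True)
    X = two.design_second
    p = expit(X @ two.second.coef)
    h = p * (1 - p)
    A22 = (h[:, None] * X).T @ (h[:, None] * X) / len(s)
    u = two.Y - p
    S2 = ((h * u)[:, None] * X).T @ ((h * u)[:, None] * X) / len(s)
    A22i = np.linalg.inv(A22)
    expected = A22i @ S2 @ A22i.T / len(s)
    assert np.max(np.abs(V0 - (expected + expected.T) / 2)) / np.max(np.abs(expected)) < 1e-8


def test_sandwich_invariant_to_covariate_reordering(balanced_cohort):
    s = balanced_cohort.estimation_sample()
    swapped = copy.copy(s)
    swapped.X1, swapped.X2 = s.X2, s.X1
    V = biv.fit_2sri(s, "pr").sandwich
    Vs = biv.fit_2sri(swapped, "pr").sandwich
    perm = [0, 1, 3, 2, 4]  # (const, T, X1, X2, U) with X1/X2 exchanged
    np.testing.assert_allclose(Vs[np.ix_(perm, perm)], V, rtol=1e-4, atol=1e-10)


def test_gmm_moments_vanish_and_dominate_truth(dense_cohort, small_cohort):
    for cohort, b0 in ((dense_cohort, 5.3), (small_cohort, -0.6)):
        s = cohort.estimation_sample()
        fit = biv.fit_gmm(s, "pr")
        assert fit.converged
        x = np.column_stack([np.ones(len(s)), s.T, s.X1, s.X2])
        w = np.column_stack([np.ones(len(s)), s.pr, s.X1, s.X2])
        m_hat = gmm_moments(fit.coef, x, w, s.Y)
        assert np.max(np.abs(m_hat)) < 1e-6
        beta_true = np.array([b0, 3.0, 1.0, 1.0])
        m_true = gmm_moments(beta_true, x, w, s.Y)
        assert m_hat @ m_hat <= m_true @ m_true  # minimizer property


def test_gmm_flags_rootless_moment_system(balanced_cohort):
    """On cohorts whose sample moment system has no finite root the fit is
    flagged instead of returning a spurious solution."""
    fit = biv.fit_gmm(balanced_cohort.estimation_sample(), "pr")
    assert not fit.converged
    assert any("moment equations not solved" in s or "singular" in s for s in fit.notes)


def test_gmm_matches_root_finding_oracle():
    """On a tiny cohort the GMM solution equals an independent damped-Newton
    root solve (finite-difference Jacobian) of the four moment equations."""
    cfg = ScenarioConfig(
        n=50, m=10, alpha=(5.0, 3.0, 2.0, 1.2), beta=(-2.3, 3.0, 1.0, 1.0, 1.0),
        sigma_u=1.0, seed=34,
    )
    s = biv.attach_proxies(biv.simulate_cohort(cfg, seed=34)).estimation_sample()
    fit = biv.fit_gmm(s, "pr")
    assert fit.converged
    x = np.column_stack([np.ones(len(s)), s.T, s.X1, s.X2])
    w = np.column_stack([np.ones(len(s)), s.pr, s.X1, s.X2])

    def moments(b):
        return w.T @ (s.Y - expit(x @ b)) / len(s)

    b = np.zeros(4)
    for _ in range(200):  # damped Newton, numerical Jacobian
        m = moments(b)
        J = np.empty((4, 4))
        for j in range(4):
            db = np.zeros(4)
            db[j] = 1e-6
            J[:, j] = (moments(b + db) - moments(b - db)) / 2e-6
        step = np.linalg.solve(J, -m)
        lam = 1.0
        while lam > 1e-6 and np.linalg.norm(moments(b + lam * step)) > np.linalg.norm(m):
            lam /= 2
        b = b + lam * step
        if np.linalg.norm(moments(b)) < 1e-12:
            break
    assert np.linalg.norm(moments(b)) < 1e-10
    np.testing.assert_allclose(fit.coef, b, atol=1e-5)


def test_conventional_fit_overestimates_under_positive_confounding(mc_high_weak):
    """With beta_u > 0 and a confounder that raises treatment uptake, the
    naive fit overstates the treatment coefficient."""
    ms = mc_high_weak.methods["conventional"]
    assert ms.rb > 3 * 100 * ms.sd_mc / 3.0 / np.sqrt(ms.n_retained)


def test_bootstrap_degenerate_and_doubling(balanced_cohort):
    sub = balanced_cohort.estimation_sample().subset(np.arange(2000))
    V0 = biv.bootstrap_variance(sub, biv.fit_conventional, B=3, seed=0, resample=False)
    assert np.allclose(V0, 0.0)
    V200 = biv.bootstrap_variance(sub, biv.fit_conventional, B=200, seed=1)
    V400 = biv.bootstrap_variance(sub, biv.fit_conventional, B=400, seed=2)
    ratio = V200[1, 1] / V400[1, 1]
    assert 0.6 < ratio < 1.6  # agreement within bootstrap noise
    with pytest.raises(ValueError):
        biv.bootstrap_variance(sub, biv.fit_conventional, B=1, seed=0)


def test_bootstrap_close_to_sandwich_at_scale():
    """Patient-level bootstrap sd of the 2SRI treatment coefficient agrees
    with the two-step sandwich sd within 15% at n=30000."""
    cfg = biv.rare_event_config("strong", "high", 30000, seed=55)
    s = biv.attach_proxies(biv.simulate_cohort(cfg, seed=55)).estimation_sample()
    two = biv.fit_2sri(s, "pr")
    sand_sd = np.sqrt(two.var_beta_t)
    Vb = biv.bootstrap_variance(s, lambda c: biv.fit_2sri(c, "pr"), B=100, seed=56)
    boot_sd = np.sqrt(Vb[1, 1])
    assert abs(boot_sd - sand_sd) / sand_sd < 0.15
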