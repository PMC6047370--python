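"""Shared fixtures.

The three Monte-Carlo fixtures are the expensive study runs reused by the
acceptance layer and by the monotonicity/recovery properties; they are
session-scoped so each grid cell is simulated exactly once per test run.
Replication counts are reduced relative to a full study (200 instead of
1000; 100 for the balanced regime) and the assertions that consume them
scale their tolerances by the Monte-Carlo standard error accordingly.
"""

from __future__ import annotations

import numpy as np
import pytest

import binaryiv as biv
from binaryiv.study import run_scenario


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate rare-regime cohort for estimator unit tests."""
    cfg = biv.rare_event_config("strong", "med", 5000, seed=101)
    return biv.attach_proxies(biv.simulate_cohort(cfg, seed=101))


@pytest.fixture(scope="session")
def balanced_cohort():
    """Balanced-exposure cohort (~30% treated), better conditioned for
    small-sample estimator checks."""
    cfg = biv.balanced_config("strong", "med", 5000, seed=102)
    return biv.attach_proxies(biv.simulate_cohort(cfg, seed=102))


@pytest.fixture(scope="session")
def dense_cohort():
    """Tiny cohort (200 patients, 10 per physician) with common exposure
    and outcome, so small-sample fits are well conditioned; used by the
    finite-difference and root-finding oracle checks."""
    cfg = biv.ScenarioConfig(
        n=200, m=20, alpha=(5.0, 3.0, 2.0, 1.2), beta=(5.3, 1.0, 1.0, 1.0, 1.0),
        sigma_u=1.0, seed=41,
    )
    return biv.attach_proxies(biv.simulate_cohort(cfg, seed=41))


@pytest.fixture(scope="session")
def mc_high_weak():
    """High confounding, weak instrument, n=30000, ns=200, all methods."""
    cfg = biv.rare_event_config("weak", "high", 30000, ns=200, seed=2024)
    return run_scenario(
        cfg, "pr", ("true", "conventional", "2sri", "gmm"), seed=2024,
        record_first_stage_f=False, keep_estimates=True,
    )


@pytest.fixture(scope="session")
def mc_high_strong():
    """High confounding, strong instrument, n=30000, ns=200, all methods,
    with the first-stage F recorded per replication."""
    cfg = biv.rare_event_config("strong", "high", 30000, ns=200, seed=2025)
    return run_scenario(
        cfg, "pr", ("true", "conventional", "2sri", "gmm"), seed=2025,
        record_first_stage_f=True, keep_estimates=True,
    )


@pytest.fixture(scope="session")
def mc_balanced():
    """Balanced regime, high confounding, weak instrument, n=30000, ns=100."""
    cfg = biv.balanced_config("weak", "high", 30000, ns=100, seed=2026)
    return run_scenario(
        cfg, "pr", ("true", "conventional", "2sri"), seed=2026,
        keep_estimates=True,
    )


def mc_se_of_rb(summary, method: str) -> float:
    """Monte-Carlo standard error (in rB percentage points) of a method's
    mean relative bias, from its own retained replications."""
    ms = summary.methods[method]
    return 100.0 * ms.sd_mc / abs(summary.beta_t) / np.sqrt(ms.n_retained)
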