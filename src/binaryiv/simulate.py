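"""Synthetic physician-clustered cohorts with a prescribing-preference instrument.

The generator draws patients nested within physicians. Each physician has a
latent binary prescribing preference ``PP`` (Bernoulli). Patient-level
covariates ``X1``, ``X2`` and an unobserved confounder ``Xu`` are normal.
Treatment and outcome are Bernoulli draws from logistic index models::

    P(T=1) = expit(alpha0 + PP*alpha_z + X1*alpha1 + X2*alpha2 + Xu)
    P(Y=1) = expit(beta0 + T*beta_t + X1*beta1 + X2*beta2 + Xu*beta_u)

``Xu`` confounds treatment and outcome but is never available to the
estimators; ``PP`` is a valid instrument (independent of ``Xu``, ``X1``,
``X2``; associated with ``T`` only). Because ``PP`` itself is latent in
practice, two observable proxies are constructed from the prescribing
history: ``Zstar`` (treatment of the physician's previous patient) and
``pr`` (running proportion of the physician's earlier patients treated).

Randomness discipline: each call consumes a root seed that is split into
named substreams, one per variable, in the fixed order
``("X1", "X2", "Xu", "PP", "T", "Y", "eps")``.  Adding a new variable at the
end of the list therefore does not perturb earlier draws, and identical
seeds reproduce cohorts bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "ScenarioConfig",
    "Cohort",
    "rare_event_config",
    "balanced_config",
    "config_from_levels",
    "simulate_cohort",
    "attach_proxies",
    "index_function_equivalence_check",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_scenario_grid",
    "STRENGTH_ALPHA_Z",
    "CONFOUNDING_SIGMA_U",
]

#: instrument-strength labels -> coefficient of the preference in the
#: treatment index
STRENGTH_ALPHA_Z = {"weak": 1.0, "mod": 2.0, "strong": 3.0}

#: confounding labels -> standard deviation of the unobserved confounder
CONFOUNDING_SIGMA_U = {"low": 0.5, "med": 1.0, "high": 1.5}

_SUBSTREAMS = ("X1", "X2", "Xu", "PP", "T", "Y", "eps")


class ConfigurationError(ValueError):
    """Invalid generative configuration."""


class CohortDataError(ValueError):
    """Cohort table violates the (physician, order) layout contract."""


@dataclass(frozen=True)
class ScenarioConfig:
    """All generative parameters of one simulation scenario.

    Parameters
    ----------
    n : total number of patients; must be a multiple of ``m``.
    m : patients per physician (default 100).
    alpha : ``(alpha0, alpha_z, alpha1, alpha2)`` treatment-index
        coefficients; the confounder enters the treatment index with a
        fixed unit coefficient.
    beta : ``(beta0, beta_t, beta1, beta2, beta_u)`` outcome-index
        coefficients.
    sigma_u : standard deviation of the unobserved confounder (>= 0).
    p_pp : probability that a physician prefers the treatment of interest.
    mu1, mu2, sigma1, sigma2 : moments of the two observed covariates.
    ns : Monte-Carlo replications when the config drives a study run.
    seed : default RNG seed.
    """

    n: int
    m: int = 100
    alpha: tuple[float, float, float, float] = (0.2, 2.0, 2.0, 1.2)
    beta: tuple[float, float, float, float, float] = (-0.6, 3.0, 1.0, 1.0, 1.0)
    sigma_u: float = 1.0
    p_pp: float = 0.7
    mu1: float = -2.0
    mu2: float = -3.0
    sigma1: float = 1.0
    sigma2: float = 1.0
    ns: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.m <= 0:
            raise ConfigurationError("n and m must be positive")
        if self.n % self.m != 0:
            raise ConfigurationError(
                f"n={self.n} must be divisible by patients-per-physician m={self.m}"
            )
        if self.sigma_u < 0:
            raise ConfigurationError("sigma_u must be >= 0")
        if not 0.0 < self.p_pp < 1.0:
            raise ConfigurationError("p_pp must lie in (0, 1)")
        if len(self.alpha) != 4 or len(self.beta) != 5:
            raise ConfigurationError("alpha must have 4 entries, beta 5")
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.beta))):
            raise ConfigurationError("alpha and beta must be finite")

    @property
    def n_physicians(self) -> int:
        return self.n // self.m


def rare_event_config(
    strength: str = "mod",
    confounding: str = "med",
    n: int = 30000,
    *,
    ns: int = 200,
    seed: int = 0,
) -> ScenarioConfig:
    """Rare-exposure / rare-event preset.

    Exposure prevalence falls between 2 and 6% and event prevalence stays
    below 5%, emulating a newly marketed drug with an infrequent adverse
    event.
    """
    return ScenarioConfig(
        n=n,
        alpha=(0.2, STRENGTH_ALPHA_Z[strength], 2.0, 1.2),
        beta=(-0.6, 3.0, 1.0, 1.0, 1.0),
        sigma_u=CONFOUNDING_SIGMA_U[confounding],
        ns=ns,
        seed=seed,
    )


def balanced_config(
    strength: str = "mod",
    confounding: str = "med",
    n: int = 30000,
    *,
    ns: int = 200,
    seed: int = 0,
) -> ScenarioConfig:
    """Balanced-exposure preset: only the two intercepts change
    (``alpha0=5``, ``beta0=-2.3``), raising exposure prevalence to roughly
    26-45% while keeping events rare."""
    return ScenarioConfig(
        n=n,
        alpha=(5.0, STRENGTH_ALPHA_Z[strength], 2.0, 1.2),
        beta=(-2.3, 3.0, 1.0, 1.0, 1.0),
        sigma_u=CONFOUNDING_SIGMA_U[confounding],
        ns=ns,
        seed=seed,
    )


def config_from_levels(
    strength: str,
    confounding: str,
    n: int,
    regime: str = "rare",
    *,
    ns: int = 200,
    seed: int = 0,
) -> ScenarioConfig:
    """Build a config from the scenario-grid vocabulary."""
    strength = strength.lower()
    confounding = confounding.lower()
    if strength not in STRENGTH_ALPHA_Z:
        raise ConfigurationError(f"unknown strength {strength!r}")
    if confounding not in CONFOUNDING_SIGMA_U:
        raise ConfigurationError(f"unknown confounding {confounding!r}")
    maker = {"rare": rare_event_config, "balanced": balanced_config}.get(regime)
    if maker is None:
        raise ConfigurationError(f"unknown regime {regime!r}")
    return maker(strength, confounding, n, ns=ns, seed=seed)


@dataclass
class Cohort:
    """Per-patient arrays of one simulated (or user-supplied) cohort.

    ``Zstar`` and ``pr`` are NaN and ``valid_proxy`` is False until
    :func:`attach_proxies` fills them; the first patient of each physician
    keeps ``valid_proxy=False`` because no prescribing history exists for
    them. ``Xu`` and ``PP`` may be NaN on user data read from CSV.
    """

    physician_id: np.ndarray
    order: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    Xu: np.ndarray
    PP: np.ndarray
    T: np.ndarray
    Y: np.ndarray
    Zstar: np.ndarray = field(default=None)  # type: ignore[assignment]
    pr: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid_proxy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.physician_id)
        if self.Zstar is None:
            self.Zstar = np.full(n, np.nan)
        if self.pr is None:
            self.pr = np.full(n, np.nan)
        if self.valid_proxy is None:
            self.valid_proxy = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.physician_id)

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row subset (boolean mask or integer index array)."""
        return Cohort(**{k: np.asarray(v)[mask] for k, v in self.__dict__.items()})

    def estimation_sample(self) -> "Cohort":
        """Patients with defined proxies (drops each physician's first)."""
        return self.subset(self.valid_proxy)

    def instrument(self, name: str) -> np.ndarray:
        """Return an instrument column: ``pr``, ``zstar`` or ``pp``."""
        cols = {"pr": self.pr, "zstar": self.Zstar, "pp": self.PP}
        key = name.lower()
        if key not in cols:
            raise KeyError(f"unknown instrument {name!r}; use pr, zstar or pp")
        return np.asarray(cols[key], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "physician_id": self.physician_id.astype(int),
                "order": self.order.astype(int),
                "X1": self.X1,
                "X2": self.X2,
                "Xu": self.Xu,
                "PP": self.PP,
                "T": self.T.astype(int),
                "Y": self.Y.astype(int),
                "Zstar": self.Zstar,
                "pr": self.pr,
                "valid_proxy": self.valid_proxy.astype(bool),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        required = ["physician_id", "order", "X1", "X2", "T", "Y"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CohortDataError(f"missing columns: {missing}")
        n = len(df)
        nan = np.full(n, np.nan)

        def col(name: str, default: np.ndarray) -> np.ndarray:
            return df[name].to_numpy(dtype=float) if name in df.columns else default.copy()

        c = cls(
            physician_id=df["physician_id"].to_numpy(dtype=int),
            order=df["order"].to_numpy(dtype=int),
            X1=df["X1"].to_numpy(dtype=float),
            X2=df["X2"].to_numpy(dtype=float),
            Xu=col("Xu", nan),
            PP=col("PP", nan),
            T=df["T"].to_numpy(dtype=float),
            Y=df["Y"].to_numpy(dtype=float),
            Zstar=col("Zstar", nan),
            pr=col("pr", nan),
        )
        if "valid_proxy" in df.columns:
            c.valid_proxy = df["valid_proxy"].to_numpy(dtype=bool)
        return c


def _rngs(seed) -> dict[str, np.random.Generator]:
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


def simulate_cohort(config: ScenarioConfig, seed=None) -> Cohort:
    """Draw one cohort under ``config``.

    Draw order (one substream each, so the sequence is reproducible and
    extension-stable): X1, X2, Xu, PP (per physician), T, Y. Proxies are
    *not* attached; see :func:`attach_proxies`.
    """
    if seed is None:
        seed = config.seed
    rngs = _rngs(seed)
    n, m = config.n, config.m
    n_phys = config.n_physicians

    physician_id = np.repeat(np.arange(n_phys), m)
    order = np.tile(np.arange(1, m + 1), n_phys)

    X1 = rngs["X1"].normal(config.mu1, config.sigma1, n)
    X2 = rngs["X2"].normal(config.mu2, config.sigma2, n)
    Xu = (
        rngs["Xu"].normal(0.0, config.sigma_u, n)
        if config.sigma_u > 0
        else np.zeros(n)
    )
    PP = np.repeat(
        (rngs["PP"].random(n_phys) < config.p_pp).astype(float), m
    )

    a0, az, a1, a2 = config.alpha
    p_treat = expit(a0 + PP * az + X1 * a1 + X2 * a2 + Xu)
    T = (rngs["T"].random(n) < p_treat).astype(float)

    b0, bt, b1, b2, bu = config.beta
    p_event = expit(b0 + T * bt + X1 * b1 + X2 * b2 + Xu * bu)
    Y = (rngs["Y"].random(n) < p_event).astype(float)

    return Cohort(
        physician_id=physician_id,
        order=order,
        X1=X1,
        X2=X2,
        Xu=Xu,
        PP=PP,
        T=T,
        Y=Y,
    )


def attach_proxies(cohort: Cohort) -> Cohort:
    """Construct the two preference proxies from the prescribing history.

    For patient *k* (order >= 2) of a physician, ``Zstar`` is the treatment
    of patient *k-1* and ``pr`` is the fraction of patients ``1..k-1``
    treated.  The first patient of each physician has no history:
    ``valid_proxy`` stays False and both proxies stay NaN, and those
    patients are excluded from estimation samples rather than imputed.
    """
    pid = np.asarray(cohort.physician_id)
    order = np.asarray(cohort.order)
    n = len(pid)
    if n == 0:
        raise CohortDataError("empty cohort")

    sort_ok = np.all(
        (pid[1:] > pid[:-1]) | ((pid[1:] == pid[:-1]) & (order[1:] > order[:-1]))
    )
    if not sort_ok:
        raise CohortDataError("cohort must be sorted by (physician_id, order) with no duplicates")

    T = np.asarray(cohort.T, dtype=float)
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = pid[1:] != pid[:-1]

    Zstar = np.full(n, np.nan)
    Zstar[1:] = T[:-1]
    Zstar[new_group] = np.nan

    # running count of prior treated patients within physician
    cum = np.cumsum(T)
    grp_start = np.where(new_group)[0]
    start_of = grp_start[np.cumsum(new_group) - 1]  # index of group start per row
    prior_count = np.arange(n) - start_of
    cum_before = cum - T
    cum_at_start = cum_before[start_of]
    treated_before = cum_before - cum_at_start
    pr = np.full(n, np.nan)
    valid = prior_count > 0
    pr[valid] = treated_before[valid] / prior_count[valid]

    out = replace(cohort)
    out.Zstar = Zstar
    out.pr = pr
    out.valid_proxy = valid
    return out


def index_function_equivalence_check(
    config: ScenarioConfig, seed: int = 0, n_mc: int = 100_000
) -> bool:
    """Check the two outcome constructions agree in distribution.

    The outcome can equivalently be drawn as ``Bernoulli(expit(eta))`` or as
    the latent-index event ``1(eta - eps > 0)`` with standard-logistic
    ``eps``. Both are implemented; this returns True when their simulated
    outcome prevalences differ by less than three Monte-Carlo standard
    errors of the difference.
    """
    reps = int(np.ceil(n_mc / config.n))
    rngs = _rngs(seed)
    prev_bern = []
    prev_latent = []
    for r in range(reps):
        cohort = simulate_cohort(config, seed=np.random.SeedSequence([int(seed), 7919, r]))
        b0, bt, b1, b2, bu = config.beta
        eta = b0 + cohort.T * bt + cohort.X1 * b1 + cohort.X2 * b2 + cohort.Xu * bu
        prev_bern.append(cohort.Y)  # Bernoulli(expit) route, drawn in simulate_cohort
        eps = rngs["eps"].logistic(0.0, 1.0, len(eta))
        prev_latent.append((eta - eps > 0).astype(float))
    yb = np.concatenate(prev_bern)
    yl = np.concatenate(prev_latent)
    p1, p2 = yb.mean(), yl.mean()
    se = np.sqrt(p1 * (1 - p1) / len(yb) + p2 * (1 - p2) / len(yl))
    return bool(abs(p1 - p2) <= 3 * max(se, 1e-12))


# ---------------------------------------------------------------------------
# I/O


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    c = Cohort.from_frame(pd.read_csv(path))
    if np.all(np.isnan(c.pr)) and np.all(np.isnan(c.Zstar)):
        c = attach_proxies(c)
    return c


def load_scenario_grid(path) -> list[dict]:
    """Read a YAML/JSON scenario grid.

    The file holds a top-level ``scenarios`` list; each entry carries
    ``strength`` (weak/mod/strong), ``confounding`` (low/med/high), ``n``,
    and optionally ``regime`` (rare/balanced), ``ns`` and ``seed``. Returns
    a list of dicts each holding the original keys plus a built ``config``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    entries = raw["scenarios"] if isinstance(raw, dict) else raw
    out = []
    for e in entries:
        e = dict(e)
        e.setdefault("regime", "rare")
        cfg = config_from_levels(
            e["strength"],
            e["confounding"],
            int(e["n"]),
            e["regime"],
            ns=int(e.get("ns", 200)),
            seed=int(e.get("seed", 0)),
        )
        e["config"] = cfg
        out.append(e)
    return out
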