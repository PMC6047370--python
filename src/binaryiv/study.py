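"""Monte-Carlo engine comparing the estimators across scenario grids.

A *scenario* is one generative configuration (instrument strength x
confounding level x sample size x exposure regime). For each scenario the
engine simulates ``ns`` independent cohorts, fits the requested methods on
the proxy-valid estimation sample of each cohort, applies the filtering
rules below, and summarizes the treatment-coefficient estimates by:

rB      100 * mean(beta_t_hat / beta_t - 1)                (relative bias, %)
sd_mc   sqrt( (1/(ns-1)) sum (beta_t_hat - mean)^2 )       (Monte-Carlo sd)
sd_asym sqrt( mean of asymptotic variance estimates )
rMSE    sqrt( mean (beta_t_hat - beta_t)^2 )
Er_inf  100 * fraction of intervals lying entirely above beta_t
Er_sup  100 * fraction of intervals lying entirely below beta_t

Filtering: replications where the GMM fit fails (non-convergence or
singularity) are removed for *all* methods, so every method is summarized
over the same samples; afterwards a method's replication is an *outlier*
(dropped for that method only) when |beta_t_hat/beta_t - 1| exceeds 100% or
its variance estimate is non-finite. All drops are counted and reported,
never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import estimators as est
from .diagnostics import first_stage_F
from .simulate import Cohort, ScenarioConfig, attach_proxies, simulate_cohort

__all__ = [
    "MethodSummary",
    "ScenarioSummary",
    "relative_bias",
    "mc_variance",
    "mean_asymptotic_variance",
    "rmse",
    "noncoverage",
    "outlier_filter",
    "run_scenario",
    "report_tables",
    "plot_relative_bias",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("true", "conventional", "2sri", "gmm")


# ---------------------------------------------------------------------------
# Evaluation criteria


def relative_bias(estimates, beta_t: float) -> float:
    """100 * mean(beta_hat/beta_t - 1); undefined at beta_t = 0."""
    if beta_t == 0:
        raise ValueError("relative bias is undefined for beta_t = 0")
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(100.0 * np.mean(estimates / beta_t - 1.0))


def mc_variance(estimates) -> float:
    """Monte-Carlo variance of the estimates (ns-1 denominator)."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size < 2:
        raise ValueError("mc_variance needs at least two estimates")
    return float(np.var(estimates, ddof=1))


def mean_asymptotic_variance(variances) -> float:
    variances = np.asarray(variances, dtype=float)
    if variances.size == 0:
        raise ValueError("no variances")
    return float(np.mean(variances))


def rmse(estimates, beta_t: float) -> float:
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates")
    return float(np.sqrt(np.mean((estimates - beta_t) ** 2)))


def noncoverage(cis, beta_t: float) -> tuple[float, float]:
    """(Er_inf, Er_sup) in percent, with strict inequalities.

    Er_inf counts intervals whose lower bound exceeds beta_t; Er_sup those
    whose upper bound falls below it.
    """
    cis = np.asarray(cis, dtype=float)
    if cis.ndim != 2 or cis.shape[1] != 2 or cis.size == 0:
        raise ValueError("cis must be a non-empty (ns, 2) array")
    if np.any(cis[:, 0] > cis[:, 1]):
        raise ValueError("malformed interval: lower bound exceeds upper bound")
    er_inf = 100.0 * np.mean(beta_t < cis[:, 0])
    er_sup = 100.0 * np.mean(beta_t > cis[:, 1])
    return float(er_inf), float(er_sup)


# ---------------------------------------------------------------------------
# Per-replication bookkeeping


def outlier_filter(
    records: pd.DataFrame, beta_t: float, propagate_gmm: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the replication-filtering rules.

    ``records`` has one row per (rep, method) with columns ``rep``,
    ``method``, ``beta_t_hat``, ``var_t``, ``status``. Returns the retained
    rows and a per-method count table (n_failed, n_gmm_dropped,
    n_outliers, n_retained).
    """
    df = records.copy()
    reps = df["rep"].unique()
    if propagate_gmm and (df["method"] == "gmm").any():
        bad = set(df.loc[(df["method"] == "gmm") & (df["status"] != "ok"), "rep"])
    else:
        bad = set()
    df["gmm_dropped"] = df["rep"].isin(bad)
    own_failed = df["status"] != "ok"
    rb = np.abs(df["beta_t_hat"] / beta_t - 1.0) * 100.0
    is_outlier = (
        ~df["gmm_dropped"]
        & ~own_failed
        & ((rb > 100.0) | ~np.isfinite(df["var_t"]) | ~np.isfinite(df["beta_t_hat"]))
    )
    df["outlier"] = is_outlier
    retained = df[~df["gmm_dropped"] & ~own_failed & ~is_outlier].copy()

    counts = []
    for method, g in df.groupby("method", sort=False):
        counts.append(
            {
                "method": method,
                "n_gmm_dropped": int((g["gmm_dropped"] & (g["status"] == "ok")).sum()),
                "n_failed": int((g["status"] != "ok").sum()),
                "n_outliers": int(g["outlier"].sum()),
                "n_retained": int(
                    (~g["gmm_dropped"] & (g["status"] == "ok") & ~g["outlier"]).sum()
                ),
            }
        )
    return retained, pd.DataFrame(counts).set_index("method")


@dataclass
class MethodSummary:
    method: str
    rb: float
    sd_mc: float
    sd_asym: float
    rmse: float
    er_inf: float
    er_sup: float
    n_outliers: int
    n_failed: int
    n_gmm_dropped: int
    n_retained: int

    @property
    def pval(self) -> float:
        """Total non-coverage as a proportion (Er_inf + Er_sup)/100."""
        return (self.er_inf + self.er_sup) / 100.0


@dataclass
class ScenarioSummary:
    strength: str
    confounding: str
    n: int
    instrument: str
    regime: str
    ns: int
    seed: int
    beta_t: float
    methods: dict[str, MethodSummary]
    usable: bool = True
    notes: list[str] = field(default_factory=list)
    f_mean: float = float("nan")
    estimates: pd.DataFrame | None = field(default=None, repr=False)
    counts: pd.DataFrame | None = field(default=None, repr=False)


def _classify_levels(config: ScenarioConfig) -> tuple[str, str, str]:
    from .simulate import CONFOUNDING_SIGMA_U, STRENGTH_ALPHA_Z

    strength = next(
        (k for k, v in STRENGTH_ALPHA_Z.items() if np.isclose(v, config.alpha[1])), "custom"
    )
    confounding = next(
        (k for k, v in CONFOUNDING_SIGMA_U.items() if np.isclose(v, config.sigma_u)), "custom"
    )
    regime = "balanced" if config.alpha[0] > 2 else "rare"
    return strength, confounding, regime


def _fit_one(method: str, sample: Cohort, instrument_name: str):
    if method == "true":
        return est.fit_true(sample)
    if method == "conventional":
        return est.fit_conventional(sample)
    if method == "2sri":
        return est.fit_2sri(sample, instrument_name).second
    if method == "gmm":
        return est.fit_gmm(sample, instrument_name)
    raise ValueError(f"unknown method {method!r}")


def _one_replication(
    config: ScenarioConfig,
    instrument_name: str,
    methods,
    root_seed: int,
    rep: int,
    record_f: bool,
):
    seed = np.random.SeedSequence([int(root_seed), int(rep)])
    cohort = attach_proxies(simulate_cohort(config, seed=seed))
    sample = cohort.estimation_sample()
    rows = []
    for method in methods:
        try:
            fit = _fit_one(method, sample, instrument_name)
            status = "ok" if fit.converged else (
                "singular" if any("singular" in s for s in fit.notes) else "nonconverged"
            )
            row = {
                "rep": rep,
                "method": method,
                "beta_t_hat": fit.beta_t,
                "var_t": fit.var_beta_t,
                "ci_lo": float(fit.ci[est.TREATMENT_INDEX, 0]),
                "ci_hi": float(fit.ci[est.TREATMENT_INDEX, 1]),
                "status": status,
            }
            for j, c in enumerate(fit.coef):
                row[f"c{j}"] = float(c)
        except (ValueError, np.linalg.LinAlgError) as exc:
            row = {
                "rep": rep, "method": method, "beta_t_hat": np.nan,
                "var_t": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                "status": "nonconverged",
            }
        rows.append(row)
    f_val = np.nan
    if record_f:
        try:
            f_val = first_stage_F(sample, instrument_name)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            pass
    return rows, f_val


def run_scenario(
    config: ScenarioConfig,
    instrument_name: str = "pr",
    methods=DEFAULT_METHODS,
    seed: int | None = None,
    n_jobs: int = 1,
    record_first_stage_f: bool = False,
    keep_estimates: bool = False,
) -> ScenarioSummary:
    """Run one Monte-Carlo scenario end to end.

    Deterministic given ``seed``: replication *r* uses the seed sequence
    ``(seed, r)``, so results do not depend on the worker count.
    """
    if not methods:
        raise ValueError("methods must be non-empty")
    if seed is None:
        seed = config.seed
    ns = config.ns
    beta_t = config.beta[1]

    jobs = (
        delayed(_one_replication)(config, instrument_name, methods, seed, r, record_first_stage_f)
        for r in range(ns)
    )
    results = Parallel(n_jobs=n_jobs)(jobs)
    records = pd.DataFrame([row for rows, _ in results for row in rows])
    f_stats = np.asarray([f for _, f in results], dtype=float)

    retained, counts = outlier_filter(records, beta_t, propagate_gmm="gmm" in methods)

    notes: list[str] = []
    summaries: dict[str, MethodSummary] = {}
    usable = True
    for method in methods:
        g = retained[retained["method"] == method]
        cnt = counts.loc[method]
        nr = len(g)
        if nr < max(1, ns - cnt["n_gmm_dropped"]) * 0.5 and nr < ns * 0.5:
            usable = False
            notes.append(f"{method}: more than half of replications unusable")
        if nr == 0:
            summaries[method] = MethodSummary(
                method, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                int(cnt["n_outliers"]), int(cnt["n_failed"]),
                int(cnt["n_gmm_dropped"]), 0,
            )
            continue
        ests = g["beta_t_hat"].to_numpy()
        sd_mc = float(np.sqrt(mc_variance(ests))) if nr >= 2 else np.nan
        if nr < 2:
            notes.append(f"{method}: single retained replication, sd_mc undefined")
        er_inf, er_sup = noncoverage(g[["ci_lo", "ci_hi"]].to_numpy(), beta_t)
        summaries[method] = MethodSummary(
            method=method,
            rb=relative_bias(ests, beta_t),
            sd_mc=sd_mc,
            sd_asym=float(np.sqrt(mean_asymptotic_variance(g["var_t"].to_numpy()))),
            rmse=rmse(ests, beta_t),
            er_inf=er_inf,
            er_sup=er_sup,
            n_outliers=int(cnt["n_outliers"]),
            n_failed=int(cnt["n_failed"]),
            n_gmm_dropped=int(cnt["n_gmm_dropped"]),
            n_retained=nr,
        )

    strength, confounding, regime = _classify_levels(config)
    return ScenarioSummary(
        strength=strength,
        confounding=confounding,
        n=config.n,
        instrument=instrument_name,
        regime=regime,
        ns=ns,
        seed=int(seed),
        beta_t=beta_t,
        methods=summaries,
        usable=usable,
        notes=notes,
        f_mean=float(np.nanmean(f_stats)) if record_first_stage_f else float("nan"),
        estimates=records if keep_estimates else None,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Reports

_STRENGTH_ORDER = ["weak", "mod", "strong"]
_CONF_ORDER = ["high", "med", "low"]


def report_tables(summaries, out_dir=None) -> dict[str, pd.DataFrame]:
    """Assemble performance, outlier-count and F-statistic tables.

    ``performance`` has one row per (n, confounding, method) and a column
    block (rB, sd, rMSE, pval) per instrument strength; ``outliers`` and
    ``fstat`` have one row per (n, confounding) and one column per
    strength. Missing cells are rendered as "-". Total non-coverage is
    printed as a proportion.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to report")

    perf_rows: dict[tuple, dict] = {}
    out_rows: dict[tuple, dict] = {}
    f_rows: dict[tuple, dict] = {}
    for s in summaries:
        for method, ms in s.methods.items():
            key = (s.n, s.confounding, method)
            row = perf_rows.setdefault(key, {})
            for crit, val in (
                ("rB", ms.rb), ("sd", ms.sd_mc), ("rMSE", ms.rmse), ("pval", ms.pval),
            ):
                row[f"{s.strength}_{crit}"] = val
            if method == "gmm":
                okey = (s.n, s.confounding)
                out_rows.setdefault(okey, {})[s.strength] = (
                    ms.n_outliers + ms.n_failed
                )
        if np.isfinite(s.f_mean):
            f_rows.setdefault((s.n, s.confounding), {})[s.strength] = s.f_mean

    def frame(rows: dict, index_names) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index = pd.MultiIndex.from_tuples(df.index, names=index_names)
        return df.sort_index().fillna("-")

    tables = {"performance": frame(perf_rows, ["n", "confounding", "method"])}
    if out_rows:
        tables["outliers"] = frame(out_rows, ["n", "confounding"])
    if f_rows:
        tables["fstat"] = frame(f_rows, ["n", "confounding"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        name_map = {"performance": "table1.csv", "outliers": "table2.csv", "fstat": "table3.csv"}
        for key, df in tables.items():
            df.to_csv(out_dir / name_map[key])
    return tables


def plot_relative_bias(records: pd.DataFrame, beta_t: float, path=None):
    """Boxplots of per-replication relative bias (%) by method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = records[records["status"] == "ok"]
    methods = list(ok["method"].unique())
    data = [
        100.0 * (ok.loc[ok["method"] == m, "beta_t_hat"] / beta_t - 1.0).to_numpy()
        for m in methods
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=methods, showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("relative bias of $\\hat\\beta_t$ (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
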