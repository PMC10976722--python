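"""Monte Carlo driver: sweep the correlation grid, aggregate, write summaries.

The experiment generates many cohorts at each value of the
observed/unobserved-confounder correlation weight ``rho``, runs every
estimation strategy on each cohort, and aggregates the per-replicate
coefficients, risk ratios, E-values, balance statistics and
common-support proportions into per-(rho, method) medians, standard
deviations, and 5th/95th percentiles.

Seeding: every (rho, replicate) cell gets its own integer seed derived
from the master seed via ``numpy.random.SeedSequence`` keyed on the
master seed, the rho value (in thousandths) and the replicate index, so
enlarging the grid or adding replicates never perturbs existing streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dgp import DGPParams, SDist, simulate_cohort
from .diagnostics import smd
from .estimators import REGRESSION_COVARIATES, estimate_all_methods
from .sensitivity import evalue, standardized_rr

__all__ = ["MCConfig", "run_monte_carlo", "write_summary", "replicate_seed"]

DEFAULT_RHO_GRID = tuple(round(0.1 * i, 1) for i in range(10))

BALANCE_COVARIATES = ("X_m", "X_u1", "X_u2")


@dataclass(frozen=True)
class MCConfig:
    """Full experiment configuration; defaults reproduce the headline study."""

    beta_T: float = 0.2
    alpha: float = 1.0
    beta_m: float = 0.4
    beta_u1: float = 0.4
    beta_u2: float = 0.4
    V: float = 1.0
    s_family: str = "uniform"
    s_low: float = 1.7
    s_high: float = 2.7
    intercept_C: float = 0.0
    n_obs: int = 10_000
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID
    n_replicates: int = 200
    master_seed: int = 0
    calipers: Sequence[float] = (0.001, 0.01, 0.1)
    #: restrict to a subset of {"no_confounders", "observed_confounder",
    #: "all_confounders", "iptw", "psm"}; None = all
    methods: Optional[Sequence[str]] = None

    def dgp_params(self, rho: float, seed: int) -> DGPParams:
        return DGPParams(
            beta_T=self.beta_T,
            alpha=self.alpha,
            beta_m=self.beta_m,
            beta_u1=self.beta_u1,
            beta_u2=self.beta_u2,
            V=self.V,
            s_dist=SDist(self.s_family, self.s_low, self.s_high),
            rho=rho,
            intercept_C=self.intercept_C,
            n_obs=self.n_obs,
            seed=seed,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "MCConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config fields: {sorted(unknown)}; valid fields: {sorted(known)}"
            )
        d = dict(d)
        for key in ("rho_grid", "calipers", "methods"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "MCConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("rho_grid", "calipers", "methods"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def replicate_seed(master_seed: int, rho: float, replicate: int) -> int:
    """Deterministic per-(rho, replicate) child seed, stable under grid growth."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(round(rho * 1000)), int(replicate))
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _replicate_rows(config: MCConfig, rho: float, rep: int) -> list[dict]:
    """Simulate one cohort, run estimators + diagnostics, return tidy rows."""
    seed = replicate_seed(config.master_seed, rho, rep)
    cohort = simulate_cohort(config.dgp_params(rho, seed), warn=False)
    rows: list[dict] = []
    base = {"replicate": rep, "rho": rho, "seed": seed}
    if cohort.degenerate:
        rows.append({**base, "method": "degenerate", "converged": False})
        return rows

    fits, artifacts = estimate_all_methods(
        cohort, calipers=config.calipers, methods=config.methods
    )
    unadj_smd = {
        cov: smd(cohort.column(cov), cohort.T) for cov in BALANCE_COVARIATES
    }
    for fit in fits:
        row = {
            **base,
            "method": fit.method,
            "caliper": fit.caliper,
            "beta_T_hat": fit.beta_T_hat,
            "se": fit.se_beta_T,
            "odds_ratio": fit.odds_ratio,
            "n_analytic": fit.n_analytic,
            "converged": fit.converged,
        }
        weights = pairs = None
        support = np.nan
        if fit.method == "iptw" and "iptw" in artifacts:
            art = artifacts["iptw"]
            weights = art.weights
            support = art.common_support_prop
            for cov in BALANCE_COVARIATES:
                row[f"smd_{cov}"] = smd(cohort.column(cov), cohort.T, weights=weights)
        elif fit.method == "psm":
            art = artifacts.get(f"psm_{fit.caliper:g}")
            if art is not None and art.matched_pairs is not None and len(art.matched_pairs):
                pairs = art.matched_pairs
                # matched-sample retention: the share of the cohort kept
                support = 2.0 * len(pairs) / cohort.n
                for cov in BALANCE_COVARIATES:
                    row[f"smd_{cov}"] = smd(cohort.column(cov), cohort.T, pairs=pairs)
            else:
                support = 0.0
        else:
            for cov in BALANCE_COVARIATES:
                row[f"smd_{cov}"] = unadj_smd[cov]
        row["common_support"] = support
        if fit.converged:
            rr = standardized_rr(fit, cohort, weights=weights, pairs=pairs)
            row["risk_ratio"] = rr
            row["evalue"] = evalue(rr).evalue
        rows.append(row)
    return rows


def run_monte_carlo(
    config: MCConfig, progress: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full sweep; returns (summary, replicate-level long table).

    Per-replicate failures (degenerate cohorts, non-converged fits) are
    counted in the summary's ``n_failed`` column, never raised.
    """
    rows: list[dict] = []
    iterator = list(enumerate(config.rho_grid))
    for _, rho in iterator:
        reps = range(config.n_replicates)
        if progress:
            from tqdm import tqdm

            reps = tqdm(reps, desc=f"rho={rho:g}", leave=False)
        for rep in reps:
            rows.extend(_replicate_rows(config, rho, rep))
    replicates = pd.DataFrame(rows)
    summary = summarize(replicates, config)
    return summary, replicates


def summarize(replicates: pd.DataFrame, config: MCConfig) -> pd.DataFrame:
    """Aggregate the replicate table to per-(rho, method, caliper) summaries."""
    df = replicates[replicates["method"] != "degenerate"].copy()
    if df.empty:
        return pd.DataFrame()
    df["caliper"] = df.get("caliper", np.nan)
    out = []
    group_cols = ["rho", "method", "caliper"]
    for (rho, method, caliper), g in df.groupby(group_cols, dropna=False, sort=True):
        ok = g[g["converged"].astype(bool)]
        n_used, n_failed = len(ok), len(g) - len(ok)
        rec = {
            "rho": rho,
            "method": method,
            "caliper": caliper,
            "n_replicates_used": n_used,
            "n_failed": n_failed,
        }
        if n_used:
            b = ok["beta_T_hat"].to_numpy(dtype=float)
            rec.update(
                beta_T_hat_median=np.median(b),
                beta_T_hat_sd=np.std(b, ddof=1) if n_used > 1 else np.nan,
                beta_T_hat_p5=np.percentile(b, 5),
                beta_T_hat_p95=np.percentile(b, 95),
            )
            rr = ok["risk_ratio"].to_numpy(dtype=float)
            rec.update(
                rr_median=np.median(rr),
                rr_sd=np.std(rr, ddof=1) if n_used > 1 else np.nan,
            )
            ev = ok["evalue"].to_numpy(dtype=float)
            rec.update(
                evalue_median=np.median(ev),
                evalue_p5=np.percentile(ev, 5),
                evalue_p95=np.percentile(ev, 95),
            )
            for cov in BALANCE_COVARIATES:
                col = f"smd_{cov}"
                if col in ok and ok[col].notna().any():
                    rec[f"smd_{cov}_median"] = ok[col].median()
            cs = ok["common_support"]
            rec["common_support_median"] = cs.median() if cs.notna().any() else np.nan
            rec["bias_median"] = config.beta_T - rec["beta_T_hat_median"]
        out.append(rec)
    summary = pd.DataFrame(out)
    return summary.sort_values(group_cols, na_position="first").reset_index(drop=True)


def _method_label(method: str, caliper) -> str:
    if method == "psm" and caliper is not None and not pd.isna(caliper):
        return f"psm_{caliper:g}"
    return method


def table1(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide per-rho table: median (SD) of the treatment coefficient and RR per method."""
    rows = {}
    for _, rec in summary.iterrows():
        label = _method_label(rec["method"], rec["caliper"])
        rows.setdefault(rec["rho"], {})[label] = rec
    order = ["all_confounders", "no_confounders", "observed_confounder", "iptw"]
    order += sorted(
        {
            _method_label(r["method"], r["caliper"])
            for _, r in summary.iterrows()
            if r["method"] == "psm"
        }
    )
    out = []
    for rho in sorted(rows):
        row = {"rho": rho}
        for label in order:
            rec = rows[rho].get(label)
            if rec is None:
                continue
            row[f"{label}_beta_median"] = rec.get("beta_T_hat_median")
            row[f"{label}_beta_sd"] = rec.get("beta_T_hat_sd")
            row[f"{label}_rr_median"] = rec.get("rr_median")
            row[f"{label}_rr_sd"] = rec.get("rr_sd")
        out.append(row)
    return pd.DataFrame(out)


def write_summary(
    summary: pd.DataFrame,
    replicates: pd.DataFrame,
    out_dir,
    config: Optional[MCConfig] = None,
    figures: bool = False,
) -> dict[str, Path]:
    """Write the summary CSVs (and optional figures) to ``out_dir``.

    Emits ``summary_long.csv`` (tidy per-(rho, method) metrics),
    ``table1.csv`` (wide per-rho medians/SDs), ``replicates.csv``
    (per-replicate fits) and, when a config is given, ``config.yaml``
    echoing the exact settings for provenance.
    """
    if summary.empty:
        raise ValueError("nothing to write: empty summary")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    float_fmt = "%.10g"
    p = out / "summary_long.csv"
    summary.to_csv(p, index=False, float_format=float_fmt)
    paths["summary_long"] = p
    p = out / "table1.csv"
    table1(summary).to_csv(p, index=False, float_format=float_fmt)
    paths["table1"] = p
    p = out / "replicates.csv"
    replicates.to_csv(p, index=False, float_format=float_fmt)
    paths["replicates"] = p
    if config is not None:
        import yaml

        p = out / "config.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        paths["config"] = p
    if figures:
        try:
            fig_paths = _write_figures(summary, out)
        except ImportError:
            fig_paths = {}
        paths.update(fig_paths)
    return paths


def _write_figures(summary: pd.DataFrame, out: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    labels = summary.apply(lambda r: _method_label(r["method"], r["caliper"]), axis=1)
    summary = summary.assign(label=labels)

    def lineplot(ycol, fname, ylabel, methods=None):
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for label, g in summary.groupby("label"):
            if methods is not None and label not in methods:
                continue
            if ycol not in g or g[ycol].isna().all():
                continue
            g = g.sort_values("rho")
            ax.plot(g["rho"], g[ycol], marker="o", label=label)
        ax.set_xlabel(r"correlation weight $\rho$")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out / fname
        fig.savefig(p, dpi=120)
        plt.close(fig)
        return p

    for cov in BALANCE_COVARIATES:
        paths[f"fig_smd_{cov}"] = lineplot(
            f"smd_{cov}_median", f"fig_smd_{cov}.png", f"median SMD of {cov}"
        )
    paths["fig_support"] = lineplot(
        "common_support_median",
        "fig_common_support.png",
        "median common support / retention",
        methods={"iptw"} | {l for l in summary["label"] if l.startswith("psm")},
    )
    paths["fig_beta"] = lineplot(
        "beta_T_hat_median", "fig_beta.png", r"median $\hat\beta_T$"
    )

    # bias vs E-value scatter across (rho, method) cells
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, g in summary.groupby("label"):
        if g["evalue_median"].isna().all():
            continue
        ax.scatter(g["bias_median"].abs(), g["evalue_median"], label=label, s=18)
    ax.set_xlabel(r"|median bias| in $\hat\beta_T$")
    ax.set_ylabel("median E-value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out / "fig_bias_evalue.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["fig_bias_evalue"] = p
    return paths
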