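"""Replication-study orchestration and evaluation.

Runs the condition grid (scenario x study count x missingness), fitting
every requested estimator on the SAME generated dataset per replication
(paired comparison), and summarizes convergence, mean estimates, RMSE,
relative standard-error bias, and exact/close fit rejection rates.

Conditions are deterministic under a master seed and independent of
execution order thanks to per-(condition, replication) child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generate import ConditionSpec, center_within, generate_replication
from .meta import fit_per_study, fit_osmasem, mvma_fixed, study_correlations
from .scenarios import ScenarioID, get_scenario
from .single_level import FitResult, cluster_robust_fit, naive_pooling_fit, tpb_spec
from .twolevel import fit_partially_saturated, fit_saturated, fit_twolevel

__all__ = [
    "METHODS",
    "ReplicationRecord",
    "run_condition",
    "run_grid",
    "rmse",
    "se_bias_pct",
    "rejection_rates",
    "mc_interval",
    "summarize",
    "report",
]

METHODS = ("NP", "CR", "PS", "2L", "MVMA", "OSMASEM", "CR-centered")

#: Path population values compared in evaluation (within-study level).
EVAL_PATHS = tpb_spec().path_names

#: Conditions/methods under this convergence rate are flagged and excluded
#: from comparison.
MIN_CONVERGENCE = 50.0


@dataclass(frozen=True)
class ReplicationRecord:
    condition: ConditionSpec
    replication: int
    method: str
    fit: FitResult


def _mvma_as_fitresult(ds) -> FitResult:
    effects = fit_per_study(ds)
    if len(effects) < 2:
        return FitResult.failure("MVMA", df=0, n=ds.n_total)
    pooled = mvma_fixed(effects)
    nan = float("nan")
    return FitResult(
        method="MVMA",
        estimates=dict(zip(pooled.names, pooled.beta.tolist())),
        se=dict(zip(pooled.names, pooled.se.tolist())),
        chi2=nan,
        df=0,
        chi2_p=nan,
        rmsea=nan,
        rmsea_close_p=nan,
        loglik=nan,
        converged=True,
        n_effective=ds.n_total,
        extra={"q_stat": pooled.q_stat, "k": pooled.k},
    )


def _fit_one(method: str, ds, baseline, compute_se=True):
    if method == "NP":
        return naive_pooling_fit(ds)
    if method == "CR":
        return cluster_robust_fit(ds)
    if method == "CR-centered":
        fit = cluster_robust_fit(center_within(ds))
        fit.method = "CR-centered"
        return fit
    if method == "PS":
        return fit_partially_saturated(ds, baseline=baseline, compute_se=compute_se)
    if method == "2L":
        return fit_twolevel(ds, baseline=baseline, compute_se=compute_se)
    if method == "MVMA":
        return _mvma_as_fitresult(ds)
    if method == "OSMASEM":
        return fit_osmasem(study_correlations(ds))
    raise ValueError(f"unknown method {method!r}")


def run_condition(
    cond: ConditionSpec,
    methods: tuple[str, ...] = METHODS,
    reps: int | None = None,
    compute_se: bool = True,
) -> list[ReplicationRecord]:
    """Generate ``reps`` datasets for one condition and fit every method.

    ``compute_se=False`` skips the observed-information Hessian of the
    two-level fits when only estimates and fit statistics are needed.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    reps = cond.reps if reps is None else reps
    records = []
    needs_baseline = bool({"PS", "2L"} & set(methods))
    for rep in range(reps):
        ds = generate_replication(cond, rep)
        baseline = fit_saturated(ds) if needs_baseline else None
        for method in methods:
            try:
                fit = _fit_one(method, ds, baseline, compute_se)
            except (np.linalg.LinAlgError, ValueError, FloatingPointError):
                fit = FitResult.failure(method, n=ds.n_total)
            records.append(ReplicationRecord(cond, rep, method, fit))
    return records


def full_grid(master_seed: int = 0, reps: int = 200) -> list[ConditionSpec]:
    """The 4 x 3 x 2 condition grid (reduced-scale default of 200 reps)."""
    return [
        ConditionSpec(s, k, missing, reps=reps, master_seed=master_seed)
        for missing in (False, True)
        for s in ScenarioID
        for k in (10, 30, 50)
    ]


def run_grid(
    conditions, methods=METHODS, reps=None, compute_se=True
) -> list[ReplicationRecord]:
    records = []
    for cond in conditions:
        records.extend(run_condition(cond, methods, reps, compute_se))
    return records


# ---------------------------------------------------------------------------
# evaluation criteria


def rmse(estimates: np.ndarray, beta_true: float) -> float:
    """Root mean square error of replication estimates around the truth."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("RMSE undefined for an empty estimate set")
    return float(np.sqrt(np.mean((estimates - beta_true) ** 2)))


def se_bias_pct(mean_se: float, empirical_sd: float) -> float:
    """Relative bias of estimated SEs: 100 (mSE - sd) / sd; |bias| > 10 is
    conventionally unacceptable."""
    if not empirical_sd > 0:
        raise ValueError("empirical SD must be positive")
    return 100.0 * (mean_se - empirical_sd) / empirical_sd


def rejection_rates(fits: list[FitResult], alpha: float = 0.05) -> tuple[float, float]:
    """(exact-fit %, close-fit %) among fits with a defined test."""
    exact = [f.chi2_p for f in fits if f.converged and np.isfinite(f.chi2_p)]
    close = [f.rmsea_close_p for f in fits if f.converged and np.isfinite(f.rmsea_close_p)]
    pct = lambda ps: 100.0 * float(np.mean(np.asarray(ps) < alpha)) if ps else float("nan")
    return pct(exact), pct(close)


def mc_interval(alpha: float, reps: int) -> tuple[float, float]:
    """Monte Carlo interval (in %) around a nominal rate, to 1 decimal."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    half = 1.96 * float(np.sqrt(alpha * (1 - alpha) / reps))
    return (round(100 * (alpha - half), 1), round(100 * (alpha + half), 1))


def summarize(records: list[ReplicationRecord], alpha: float = 0.05) -> pd.DataFrame:
    """Per (condition, method) evaluation summary.

    Estimate-based criteria are computed over converged replications only;
    cells with convergence below 50% are flagged ``excluded``.
    """
    rows = []
    by_cell: dict[tuple, list[ReplicationRecord]] = {}
    for r in records:
        by_cell.setdefault((r.condition, r.method), []).append(r)
    for (cond, method), cell in by_cell.items():
        reps = len(cell)
        fits = [r.fit for r in cell]
        ok = [f for f in fits if f.converged]
        conv = 100.0 * len(ok) / reps
        truth = get_scenario(cond.scenario).within
        idx = {v: i for i, v in enumerate(truth.variables)}
        exact, close = rejection_rates(fits, alpha)
        row = {
            "scenario": cond.scenario.value,
            "k": cond.k,
            "missing": cond.missing,
            "method": method,
            "reps": reps,
            "convergence_rate": conv,
            "excluded": conv < MIN_CONVERGENCE,
            "exact_fit_rejection": exact,
            "close_fit_rejection": close,
        }
        for name in EVAL_PATHS:
            out, pred = name.split("~")
            beta_true = float(truth.B[idx[out], idx[pred]])
            ests = np.array(
                [f.estimates[name] for f in ok if name in f.estimates], dtype=float
            )
            ses = np.array(
                [f.se[name] for f in ok if name in f.se and np.isfinite(f.se[name])],
                dtype=float,
            )
            if ests.size:
                row[f"mean[{name}]"] = float(np.mean(ests))
                row[f"rmse[{name}]"] = rmse(ests, beta_true)
                sd = float(np.std(ests, ddof=1)) if ests.size > 1 else float("nan")
                row[f"sd[{name}]"] = sd
                row[f"mean_se[{name}]"] = (
                    float(np.mean(ses)) if ses.size else float("nan")
                )
                row[f"se_bias_pct[{name}]"] = (
                    se_bias_pct(float(np.mean(ses)), sd)
                    if ses.size and np.isfinite(sd) and sd > 0
                    else float("nan")
                )
            else:
                for stat in ("mean", "rmse", "sd", "mean_se", "se_bias_pct"):
                    row[f"{stat}[{name}]"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["missing", "scenario", "k", "method"], ignore_index=True
    )


def _pivot(summary: pd.DataFrame, column: str) -> pd.DataFrame:
    masked = summary.copy()
    masked.loc[masked["excluded"], column] = np.nan  # below-convergence cells empty
    return masked.pivot_table(
        index=["missing", "scenario", "k"],
        columns="method",
        values=column,
        dropna=False,
    )


def report(summary: pd.DataFrame, outdir) -> list[str]:
    """Emit evaluation tables (CSV) and mean-estimate / RMSE figures."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    tables = {
        "convergence_rates.csv": "convergence_rate",
        "se_bias_int_att.csv": "se_bias_pct[INT~ATT]",
        "exact_fit_rejection.csv": "exact_fit_rejection",
        "close_fit_rejection.csv": "close_fit_rejection",
    }
    for fname, col in tables.items():
        path = outdir / fname
        if len(summary):
            _pivot(summary, col).to_csv(path)
        else:
            pd.DataFrame(columns=["missing", "scenario", "k"]).to_csv(path, index=False)
        written.append(str(path))
    path = outdir / "summary.csv"
    summary.to_csv(path, index=False)
    written.append(str(path))

    # reference values: within (red dashed) and between (blue dotted)
    refs = {"BEH~INT": (0.07, 0.91), "BEH~PBC": (0.53, 0.03)}
    for metric, fname in (("mean", "mean_estimates.png"), ("rmse", "rmse.png")):
        fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharex=True)
        for ax, (path_name, (w_ref, b_ref)) in zip(axes, refs.items()):
            col = f"{metric}[{path_name}]"
            if len(summary) and col in summary:
                sub = summary[~summary["excluded"]]
                for method, grp in sub.groupby("method"):
                    grp = grp.sort_values(["scenario", "k"])
                    labels = grp["scenario"].str[:2] + "/k" + grp["k"].astype(str)
                    ax.plot(labels, grp[col], marker="o", label=method)
            if metric == "mean":
                ax.axhline(w_ref, color="red", ls="--", lw=1)
                ax.axhline(b_ref, color="blue", ls=":", lw=1)
            ax.set_title(f"{metric} {path_name}")
            ax.tick_params(axis="x", rotation=60)
        if axes[0].get_legend_handles_labels()[0]:
            axes[0].legend(fontsize=7)
        fig.tight_layout()
        path = outdir / fname
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(str(path))
    return written
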