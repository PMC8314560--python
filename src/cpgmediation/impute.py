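"""Multiple imputation of outcome missingness by chained equations.

Only the three behavioral outcome columns may be missing (covariates and
beta-values are complete by construction in the methylation sub-cohort), so
the chained system cycles over the incomplete outcomes: each is regressed on
all covariates, the randomized arm, all CpG beta-values and the other
outcomes' current values, parameters are drawn from their approximate
posterior (proper imputation), and values are imputed by predictive mean
matching (PMM) so imputations stay inside the observed outcome range.

Outcome columns with more than 30% missingness are excluded from imputation
and flagged for exclusion from downstream modelling — the inclusion rule
that bounds imputation-model instability.

Model R² values are pooled across completed datasets Rubin-style on the
Fisher-z scale of the multiple correlation: R² → r=√R² → z=atanh(r),
average z (the point-estimate rule), back-transform, square.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import OUTCOMES, encode_design, read_cohort, write_cohort

logger = logging.getLogger(__name__)

MAX_MISSING_FRAC = 0.30
DEFAULT_M = 31
DEFAULT_ITERATIONS = 10
PMM_DONORS = 5


class MissingnessError(ValueError):
    """A column cannot be imputed (e.g. no observed values at all)."""


@dataclass
class ImputedStack:
    """m completed copies of a cohort plus imputation metadata.

    ``datasets`` agree exactly on every originally observed cell;
    ``excluded`` lists outcome columns dropped by the 30% rule (they keep
    their NaNs and must be skipped downstream). ``convergence_trace`` has one
    row per (imputation, iteration, outcome) with the mean of the currently
    imputed values.
    """

    m: int
    datasets: list[pd.DataFrame]
    convergence_trace: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    seed: int = 0
    iterations: int = DEFAULT_ITERATIONS

    def __post_init__(self) -> None:
        if self.m != len(self.datasets):
            raise ValueError("m does not match number of datasets")

    @property
    def imputed_outcomes(self) -> list[str]:
        return [o for o in OUTCOMES if o not in self.excluded]

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, ds in enumerate(self.datasets):
            write_cohort(ds, outdir / f"imputed_{i + 1:03d}.csv")
        manifest = {
            "m": self.m,
            "seed": self.seed,
            "iterations": self.iterations,
            "excluded": self.excluded,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.convergence_trace.to_csv(outdir / "convergence_trace.csv", index=False)

    @classmethod
    def load(cls, outdir) -> "ImputedStack":
        outdir = Path(outdir)
        with open(outdir / "manifest.json") as fh:
            manifest = json.load(fh)
        datasets = [
            read_cohort(outdir / f"imputed_{i + 1:03d}.csv")
            for i in range(manifest["m"])
        ]
        trace_path = outdir / "convergence_trace.csv"
        trace = (
            pd.read_csv(trace_path)
            if trace_path.exists()
            else pd.DataFrame(columns=["imputation", "iteration", "outcome", "imputed_mean"])
        )
        return cls(
            m=manifest["m"],
            datasets=datasets,
            convergence_trace=trace,
            excluded=manifest["excluded"],
            seed=manifest["seed"],
            iterations=manifest["iterations"],
        )


def _bayes_draw_coefs(
    Xo: np.ndarray, yo: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior draw (β*, and β̂) for a normal linear model, ridge-stabilized."""
    n, p = Xo.shape
    xtx = Xo.T @ Xo + 1e-8 * np.eye(p)
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    try:
        chol = np.linalg.cholesky(xtx_inv)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(xtx_inv + 1e-10 * np.eye(p))
    beta_star = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(p))
    return beta_hat, beta_star


def _pmm_impute(
    yhat_obs: np.ndarray,
    y_obs: np.ndarray,
    yhat_mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Type-1 PMM: for each missing case, sample one of the k observed donors
    with predicted value closest to the missing case's (drawn-β) prediction."""
    k = min(k, len(y_obs))
    d = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    donors = np.argpartition(d, kth=k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, size=len(yhat_mis))
    return y_obs[donors[np.arange(len(yhat_mis)), pick]]


def chained_equations_impute(
    cohort: pd.DataFrame,
    m: int = DEFAULT_M,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    pmm_k: int = PMM_DONORS,
) -> ImputedStack:
    """Impute missing outcomes by chained equations with PMM draws.

    Each of the ``m`` datasets runs its own chain for ``iterations`` cycles,
    seeded from ``seed`` by a fixed per-imputation offset (so growing ``m``
    never reshuffles earlier datasets). Observed cells are never altered.

    Outcome columns with more than 30% missingness are excluded (warning,
    not failure); an all-missing outcome raises :class:`MissingnessError`.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")

    excluded: list[str] = []
    incomplete: list[str] = []
    for col in OUTCOMES:
        n_mis = int(cohort[col].isna().sum())
        if n_mis == 0:
            continue
        if n_mis == n:
            raise MissingnessError(f"outcome {col!r} has no observed values")
        frac = n_mis / n
        if frac > MAX_MISSING_FRAC:
            msg = (
                f"outcome {col!r} has {100 * frac:.1f}% missing values, above "
                f"the {100 * MAX_MISSING_FRAC:.0f}% bound for inclusion in "
                "imputation models; excluded from imputation and downstream "
                "modelling"
            )
            warnings.warn(msg)
            logger.warning(msg)
            excluded.append(col)
        else:
            incomplete.append(col)

    base = encode_design(cohort, include_cpg=True, include_intervention=True)
    Xbase = np.column_stack([np.ones(n), base.to_numpy(float)])
    complete_outcomes = [
        o for o in OUTCOMES if o not in incomplete and o not in excluded
    ]

    datasets: list[pd.DataFrame] = []
    trace_rows: list[dict] = []
    for i in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7001, i]))
        work = {c: cohort[c].to_numpy(float).copy() for c in OUTCOMES}
        mis = {c: np.isnan(work[c]) for c in incomplete}
        # initial fill: random draws from the observed values of the column
        for c in incomplete:
            obs_vals = work[c][~mis[c]]
            work[c][mis[c]] = rng.choice(obs_vals, size=int(mis[c].sum()))
        for it in range(iterations if incomplete else 0):
            for c in incomplete:
                others = [o for o in (*incomplete, *complete_outcomes) if o != c]
                X = (
                    np.column_stack([Xbase] + [work[o] for o in others])
                    if others
                    else Xbase
                )
                obs = ~mis[c]
                beta_hat, beta_star = _bayes_draw_coefs(X[obs], work[c][obs], rng)
                imputed = _pmm_impute(
                    X[obs] @ beta_hat, work[c][obs], X[~obs] @ beta_star, pmm_k, rng
                )
                work[c][~obs] = imputed
                trace_rows.append(
                    {
                        "imputation": i + 1,
                        "iteration": it + 1,
                        "outcome": c,
                        "imputed_mean": float(imputed.mean()),
                    }
                )
        ds = cohort.copy()
        for c in incomplete:
            ds[c] = work[c]
        datasets.append(ds)

    trace = pd.DataFrame(
        trace_rows, columns=["imputation", "iteration", "outcome", "imputed_mean"]
    )
    return ImputedStack(
        m=m,
        datasets=datasets,
        convergence_trace=trace,
        excluded=excluded,
        seed=seed,
        iterations=iterations,
    )


def rubin_pool_r2(r2_values) -> float:
    """Pool model R² across imputations via Fisher-z of the multiple
    correlation: pooled = tanh(mean(atanh(√R²)))².

    Inputs must lie in [0, 1]; the result lies in [min, max] of the inputs
    and is invariant to their order.
    """
    arr = np.asarray(list(r2_values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty R² input")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("R² values must lie in [0, 1]")
    z = np.arctanh(np.clip(np.sqrt(arr), 0.0, 1.0 - 1e-15))
    return float(np.tanh(z.mean()) ** 2)


def rubin_pool_mean(estimates, variances) -> tuple[float, float]:
    """Rubin's rules for a scalar estimate: pooled estimate and pooled SE
    from per-imputation estimates and their squared standard errors."""
    q = np.asarray(list(estimates), dtype=float)
    u = np.asarray(list(variances), dtype=float)
    if q.size != u.size or q.size == 0:
        raise ValueError("estimates and variances must be equal-length, non-empty")
    m = q.size
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    t = ubar + (1.0 + 1.0 / m) * b
    return float(qbar), float(np.sqrt(t))
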