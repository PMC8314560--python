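"""Random-forest mediation engine.

The question asked of the data: does a panel of candidate mediator CpG
sites statistically explain the effect of a randomized intervention on a
continuous outcome? The evidence assembled here, per outcome:

* random-forest regressions under four covariate sets — baseline risk
  factors with/without the intervention, each with/without the CpG panel;
* per-covariate significance by permutation-importance p-values: the
  observed impurity importance is ranked against importances obtained by
  refitting the forest on permuted outcome vectors;
* explanatory power as bootstrap optimism-corrected R² (Harrell's
  procedure), pooled across multiply-imputed datasets by Rubin-style
  Fisher-z pooling, and the fold-increase in corrected R² when the CpG
  panel is added;
* robustness as significance *frequencies*: over bootstrap replicates
  (stratified by arm), how often each covariate has permutation p ≤ α.

Mediation is flagged when the intervention is frequently significant in the
baseline-only model, but loses frequency once the CpG panel is added while
at least one CpG becomes frequently significant in its place.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .cohort import INTERVENTION, OUTCOMES, cpg_columns, encode_design
from .impute import ImputedStack, rubin_pool_r2
from .panel import CpGPanel

logger = logging.getLogger(__name__)

MIN_PERMUTATIONS = 19

#: The four model variants, keyed by (include_cpg, include_intervention).
VARIANTS: dict[str, tuple[bool, bool]] = {
    "baseline": (False, False),
    "baseline+interv": (False, True),
    "cpg": (True, False),
    "cpg+interv": (True, True),
}


class FoldIncreaseError(ValueError):
    """Fold-increase undefined: reference R² is not positive."""


@dataclass(frozen=True)
class RFParams:
    """Random-forest hyperparameters.

    ``features_per_split=None`` means the regression convention ⌈p/3⌉.
    Library defaults follow the "hundreds of trees" description (500 trees,
    min_leaf 5); analysis presets use fewer, more regularized trees — see
    docs/methods.md on optimism-correction honesty.
    """

    n_trees: int = 500
    features_per_split: int | None = None
    min_leaf: int = 5

    def resolve_features(self, p: int) -> int:
        if self.features_per_split is not None:
            return min(self.features_per_split, p)
        return max(1, math.ceil(p / 3))


#: Regularized forest used by analysis presets and the pipeline. Leaves are
#: kept large so the bootstrap optimism correction stays honest (near-zero
#: corrected R² on noise); see docs/methods.md.
ANALYSIS_RF = RFParams(n_trees=15, features_per_split=None, min_leaf=18)


@dataclass(frozen=True)
class ModelSpec:
    """One outcome's modelling configuration."""

    outcome: str
    covariate_set: str = "baseline+cpg"  # "baseline_only" or "baseline+cpg"
    include_intervention: bool = True
    rf_params: RFParams = field(default_factory=RFParams)
    n_bootstrap: int = 100
    n_permutations: int = 200
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.covariate_set not in ("baseline_only", "baseline+cpg"):
            raise ValueError(f"unknown covariate_set {self.covariate_set!r}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.n_permutations < MIN_PERMUTATIONS:
            raise ValueError(f"n_permutations must be >= {MIN_PERMUTATIONS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ModelFit:
    """A fitted forest with training-data R² and per-covariate importance."""

    model: RandomForestRegressor
    apparent_r2: float
    importance: pd.Series
    importance_p: pd.Series | None = None
    oob_r2: float | None = None


@dataclass
class OptimismResult:
    apparent_r2: float
    optimism: float

    @property
    def corrected_r2(self) -> float:
        return self.apparent_r2 - self.optimism


def _sub_seed(seed: int, *tags: int) -> int:
    """Deterministic child seed below 2^31 from a master seed and tags."""
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


def _check_xy(X: pd.DataFrame, y: np.ndarray, rf_params: RFParams) -> None:
    if np.isnan(X.to_numpy(float)).any():
        raise ValueError("design matrix contains missing cells")
    if np.isnan(y).any():
        raise ValueError("outcome vector contains missing values")
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if len(y) < max(20, rf_params.min_leaf):
        raise ValueError(f"too few rows ({len(y)}) for min_leaf={rf_params.min_leaf}")
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: R² undefined (SST = 0)")


def _r2(model: RandomForestRegressor, X: np.ndarray, y: np.ndarray) -> float:
    pred = model.predict(X)
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    return 1.0 - sse / sst


def _fit(X: np.ndarray, y: np.ndarray, rf_params: RFParams, seed: int, oob: bool = False):
    rf = RandomForestRegressor(
        n_estimators=rf_params.n_trees,
        max_features=rf_params.resolve_features(X.shape[1]),
        min_samples_leaf=rf_params.min_leaf,
        random_state=seed,
        oob_score=oob,
        n_jobs=1,
    )
    return rf.fit(X, y)


def fit_rf(
    X: pd.DataFrame,
    y,
    rf_params: RFParams = RFParams(),
    seed: int = 0,
    compute_oob: bool = False,
) -> ModelFit:
    """Fit a random-forest regression; apparent R² is 1 − SSE/SST on the
    training data. Deterministic under ``seed``. With ``compute_oob`` the
    out-of-bag R² is reported as an overfit-free reference."""
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, rf_params)
    Xa = X.to_numpy(float)
    model = _fit(Xa, y, rf_params, seed, oob=compute_oob)
    return ModelFit(
        model=model,
        apparent_r2=_r2(model, Xa, y),
        importance=pd.Series(model.feature_importances_, index=X.columns),
        oob_r2=float(model.oob_score_) if compute_oob else None,
    )


def permutation_importance_pvalues(
    X: pd.DataFrame,
    y,
    rf_params: RFParams = RFParams(),
    n_permutations: int = 200,
    seed: int = 0,
    scheme: str = "outcome",
) -> pd.Series:
    """Per-covariate permutation-importance p-values.

    ``scheme="outcome"`` (default): the outcome vector is permuted and the
    forest refit ``n_permutations`` times; each covariate's observed impurity
    importance is ranked against its own null importances,
    p = (1 + #{null ≥ observed}) / (1 + n_permutations). Under independence
    the observed importance is exchangeable with the null draws, so p is
    (sub)uniform by construction and never below 1/(n_permutations+1).

    ``scheme="feature"``: per-feature value permutation against the fitted
    forest (OOB-free variant), same p-value formula.
    """
    if n_permutations < MIN_PERMUTATIONS:
        raise ValueError(f"n_permutations must be >= {MIN_PERMUTATIONS}")
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, rf_params)
    Xa = X.to_numpy(float)
    fit = _fit(Xa, y, rf_params, seed)
    if scheme == "outcome":
        observed = fit.feature_importances_
        null = np.empty((n_permutations, Xa.shape[1]))
        for b in range(n_permutations):
            rng = np.random.default_rng(_sub_seed(seed, 31, b))
            yp = rng.permutation(y)
            null[b] = _fit(Xa, yp, rf_params, _sub_seed(seed, 32, b)).feature_importances_
    elif scheme == "feature":
        # Per-feature permutation nulls: feature j's column is permuted and
        # the forest refit; j's observed impurity importance is ranked
        # against its importances under these refits (which break only j's
        # association while keeping the rest of the model intact).
        # Costs one refit per feature per permutation.
        observed = fit.feature_importances_
        p = np.empty(Xa.shape[1])
        for j in range(Xa.shape[1]):
            null_j = np.empty(n_permutations)
            for b in range(n_permutations):
                rng = np.random.default_rng(_sub_seed(seed, 33, j, b))
                Xp = Xa.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                null_j[b] = _fit(
                    Xp, y, rf_params, _sub_seed(seed, 34, j, b)
                ).feature_importances_[j]
            p[j] = (1.0 + (null_j >= observed[j]).sum()) / (1.0 + n_permutations)
        return pd.Series(p, index=X.columns)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    p = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (1.0 + n_permutations)
    return pd.Series(p, index=X.columns)


def optimism_corrected_r2(
    X: pd.DataFrame,
    y,
    rf_params: RFParams = RFParams(),
    n_bootstrap: int = 100,
    seed: int = 0,
    strata=None,
) -> OptimismResult:
    """Harrell bootstrap optimism correction of the apparent R².

    For each bootstrap resample b: refit on b, optimism_b = R²(fit_b on b)
    − R²(fit_b on original); corrected = apparent − mean(optimism_b). May be
    negative; callers are warned rather than values truncated.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, rf_params)
    Xa = X.to_numpy(float)
    full = _fit(Xa, y, rf_params, _sub_seed(seed, 40))
    apparent = _r2(full, Xa, y)
    opt = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = _bootstrap_indices(len(y), strata, _sub_seed(seed, 41, b))
        yb = y[idx]
        if np.ptp(yb) == 0:  # degenerate resample; contributes no optimism
            opt[b] = 0.0
            continue
        mb = _fit(Xa[idx], yb, rf_params, _sub_seed(seed, 42, b))
        opt[b] = _r2(mb, Xa[idx], yb) - _r2(mb, Xa, y)
    result = OptimismResult(apparent_r2=apparent, optimism=float(opt.mean()))
    if result.corrected_r2 < 0:
        logger.warning(
            "optimism-corrected R² is negative (%.4f); reported unclipped",
            result.corrected_r2,
        )
    return result


def _bootstrap_indices(n: int, strata, seed: int) -> np.ndarray:
    """Resample row indices with replacement, within strata if given."""
    rng = np.random.default_rng(seed)
    if strata is None:
        return rng.integers(0, n, n)
    strata = np.asarray(strata)
    idx = []
    for s in pd.unique(strata):
        rows = np.flatnonzero(strata == s)
        idx.append(rng.choice(rows, size=len(rows), replace=True))
    return np.concatenate(idx)


def fold_increase(r2_with_cpg: float, r2_without_cpg: float) -> float:
    """Ratio of explanatory power with vs without the CpG panel."""
    if not r2_without_cpg > 0:
        raise FoldIncreaseError(
            f"reference R² must be positive (got {r2_without_cpg}); "
            "fold-increase undefined"
        )
    return r2_with_cpg / r2_without_cpg


def bootstrap_significance_frequencies(
    X: pd.DataFrame,
    y,
    rf_params: RFParams = RFParams(),
    n_bootstrap: int = 100,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    strata=None,
) -> pd.Series:
    """Count, per covariate, in how many of ``n_bootstrap`` arm-stratified
    bootstrap refits its permutation-importance p-value is ≤ ``alpha``."""
    y = np.asarray(y, dtype=float)
    _check_xy(X, y, rf_params)
    counts = pd.Series(0, index=X.columns, dtype=int)
    for b in range(n_bootstrap):
        idx = _bootstrap_indices(len(y), strata, _sub_seed(seed, 51, b))
        Xb = X.iloc[idx].reset_index(drop=True)
        yb = y[idx]
        if np.ptp(yb) == 0:
            continue
        p = permutation_importance_pvalues(
            Xb, yb, rf_params, n_permutations, seed=_sub_seed(seed, 52, b)
        )
        counts[p.index[p <= alpha]] += 1
    return counts


@dataclass
class MediationResult:
    """Per-outcome mediation evidence (pooled across imputations)."""

    outcome: str
    n_bootstrap: int
    r2_corrected: dict[str, float]
    r2_apparent: dict[str, float]
    r2_corrected_per_imputation: dict[str, list[float]]
    fold_increase_without_intervention: float | None
    fold_increase_with_intervention: float | None
    significance_frequency: dict[str, dict[str, int]]
    intervention_frequency_baseline: int
    intervention_frequency_with_cpg: int
    mediation_flag: bool
    mediation_threshold: int
    notes: list[str] = field(default_factory=list)

    def frequency_series(self, model: str = "cpg+interv") -> pd.Series:
        return pd.Series(self.significance_frequency[model])

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n_bootstrap": self.n_bootstrap,
            "r2_corrected": self.r2_corrected,
            "r2_apparent": self.r2_apparent,
            "r2_corrected_per_imputation": self.r2_corrected_per_imputation,
            "fold_increase_without_intervention": self.fold_increase_without_intervention,
            "fold_increase_with_intervention": self.fold_increase_with_intervention,
            "significance_frequency": self.significance_frequency,
            "intervention_frequency_baseline": self.intervention_frequency_baseline,
            "intervention_frequency_with_cpg": self.intervention_frequency_with_cpg,
            "mediation_flag": self.mediation_flag,
            "mediation_threshold": self.mediation_threshold,
            "notes": self.notes,
        }


def _pool_r2(values: list[float], notes: list[str], label: str) -> float:
    vals = np.asarray(values, dtype=float)
    if (vals < 0).any():
        notes.append(
            f"{label}: negative corrected R² in {int((vals < 0).sum())} "
            "imputation(s); floored at 0 for pooling (raw values retained)"
        )
    return rubin_pool_r2(np.clip(vals, 0.0, 1.0))


def mediation_analysis(
    stack: ImputedStack,
    panel: CpGPanel | None = None,
    outcomes: list[str] | None = None,
    rf_params: RFParams = ANALYSIS_RF,
    n_bootstrap: int = 100,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    threshold: int | None = None,
    frequency_models: tuple[str, ...] = ("baseline+interv", "cpg+interv"),
    n_bootstrap_optimism: int | None = None,
) -> dict[str, MediationResult]:
    """Full mediation analysis over an imputed stack.

    For every outcome: optimism-corrected R² under the four model variants
    (±CpG panel × ±intervention), Rubin-pooled across imputations;
    fold-increases with-CpG vs baseline-only at both intervention settings;
    bootstrap significance frequencies (averaged over imputations, rounded
    half-to-even) for the models in ``frequency_models``; and the mediation
    flag. Outcomes excluded by the 30% missingness rule are skipped.

    One bootstrap stream serves both the optimism correction and the
    significance frequencies by default; ``n_bootstrap_optimism`` lets the
    optimism estimate use a larger replicate count than the frequency
    counting.
    """
    if threshold is None:
        threshold = n_bootstrap // 2
    if n_bootstrap_optimism is None:
        n_bootstrap_optimism = n_bootstrap
    if outcomes is None:
        outcomes = list(OUTCOMES)
    requested = list(outcomes)
    outcomes = [o for o in requested if o not in stack.excluded]
    for o in requested:
        if o in stack.excluded:
            logger.warning("outcome %r excluded by the 30%% missingness rule; skipped", o)

    ds0 = stack.datasets[0]
    cpg_ids = panel.cpg_ids if panel is not None else cpg_columns(ds0)
    results: dict[str, MediationResult] = {}

    # Datasets identical to the first (e.g. a zero-missingness stack) are
    # analysed once: pooling identical per-imputation results is the
    # identity, so the single-dataset analysis is reproduced exactly.
    unique_map: list[int] = []
    unique_datasets: list[pd.DataFrame] = []
    for ds in stack.datasets:
        for ui, uds in enumerate(unique_datasets):
            if uds.equals(ds):
                unique_map.append(ui)
                break
        else:
            unique_map.append(len(unique_datasets))
            unique_datasets.append(ds)

    for oi, outcome in enumerate(outcomes):
        notes: list[str] = []
        r2_per_imp: dict[str, list[float]] = {v: [] for v in VARIANTS}
        app_per_imp: dict[str, list[float]] = {v: [] for v in VARIANTS}
        freq_per_imp: dict[str, list[pd.Series]] = {v: [] for v in frequency_models}

        u_r2: dict[str, list[float]] = {v: [] for v in VARIANTS}
        u_app: dict[str, list[float]] = {v: [] for v in VARIANTS}
        u_freq: dict[str, list[pd.Series]] = {v: [] for v in frequency_models}
        for ui, ds in enumerate(unique_datasets):
            y = ds[outcome].to_numpy(float)
            strata = ds["arm"].to_numpy()
            for vi, (variant, (with_cpg, with_int)) in enumerate(VARIANTS.items()):
                X = encode_design(
                    ds,
                    include_cpg=with_cpg,
                    include_intervention=with_int,
                    cpg_ids=cpg_ids,
                )
                vseed = _sub_seed(seed, oi, ui, vi)
                opt = optimism_corrected_r2(
                    X, y, rf_params, n_bootstrap_optimism, seed=vseed, strata=strata
                )
                u_r2[variant].append(opt.corrected_r2)
                u_app[variant].append(opt.apparent_r2)
                if variant in frequency_models:
                    u_freq[variant].append(
                        bootstrap_significance_frequencies(
                            X,
                            y,
                            rf_params,
                            n_bootstrap,
                            n_permutations,
                            alpha,
                            seed=vseed,
                            strata=strata,
                        )
                    )
        for ui in unique_map:
            for v in VARIANTS:
                r2_per_imp[v].append(u_r2[v][ui])
                app_per_imp[v].append(u_app[v][ui])
            for v in frequency_models:
                freq_per_imp[v].append(u_freq[v][ui])

        r2_pooled = {v: _pool_r2(r2_per_imp[v], notes, f"{outcome}/{v}") for v in VARIANTS}
        app_pooled = {v: float(np.mean(app_per_imp[v])) for v in VARIANTS}
        freqs: dict[str, dict[str, int]] = {}
        for v in frequency_models:
            mean_counts = pd.concat(freq_per_imp[v], axis=1).mean(axis=1)
            freqs[v] = {
                k: int(c) for k, c in np.round(mean_counts).astype(int).items()
            }

        def _fold(num: str, den: str) -> float | None:
            try:
                return fold_increase(r2_pooled[num], r2_pooled[den])
            except FoldIncreaseError as err:
                notes.append(f"{outcome}: {err}")
                return None

        int_base = freqs.get("baseline+interv", {}).get(INTERVENTION, 0)
        int_cpg = freqs.get("cpg+interv", {}).get(INTERVENTION, 0)
        cpg_freqs = [
            c for k, c in freqs.get("cpg+interv", {}).items() if k in cpg_ids
        ]
        flag = (
            int_base >= threshold
            and int_cpg < int_base
            and bool(cpg_freqs)
            and max(cpg_freqs) >= threshold
        )
        results[outcome] = MediationResult(
            outcome=outcome,
            n_bootstrap=n_bootstrap,
            r2_corrected=r2_pooled,
            r2_apparent=app_pooled,
            r2_corrected_per_imputation={v: list(map(float, r2_per_imp[v])) for v in VARIANTS},
            fold_increase_without_intervention=_fold("cpg", "baseline"),
            fold_increase_with_intervention=_fold("cpg+interv", "baseline+interv"),
            significance_frequency=freqs,
            intervention_frequency_baseline=int(int_base),
            intervention_frequency_with_cpg=int(int_cpg),
            mediation_flag=flag,
            mediation_threshold=threshold,
            notes=notes,
        )
    return results
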