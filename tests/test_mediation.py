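"""Mediation engine: forest fits, permutation p-values, optimism
correction, fold-increase arithmetic, bootstrap frequencies, pooling."""

import numpy as np
import pandas as pd
import pytest

from cpgmediation import (
    FoldIncreaseError,
    RFParams,
    ScenarioConfig,
    bootstrap_significance_frequencies,
    chained_equations_impute,
    fit_rf,
    fold_increase,
    generate_cohort,
    mediation_analysis,
    optimism_corrected_r2,
    permutation_importance_pvalues,
)
from cpgmediation.cohort import encode_design

from conftest import FAST_RF


def _noise_design(n, p, seed):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    return X, rng.normal(size=n)


class TestFitRF:
    def test_recovers_noiseless_linear_signal(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        y = 2.0 * X["a"].to_numpy()
        fit = fit_rf(X, y, RFParams(50, None, 5), seed=0)
        assert fit.apparent_r2 > 0.9
        assert fit.importance["a"] > fit.importance["b"]

    def test_oob_r2_near_zero_for_pure_noise(self):
        X, y = _noise_design(1000, 5, 2)
        fit = fit_rf(X, y, RFParams(100, None, 5), seed=0, compute_oob=True)
        assert abs(fit.oob_r2) < 0.05

    def test_deterministic_under_seed(self):
        X, y = _noise_design(100, 4, 3)
        f1 = fit_rf(X, y, FAST_RF, seed=7)
        f2 = fit_rf(X, y, FAST_RF, seed=7)
        np.testing.assert_array_equal(
            f1.model.predict(X.to_numpy()), f2.model.predict(X.to_numpy())
        )

    def test_constant_outcome_rejected(self):
        X, _ = _noise_design(50, 3, 4)
        with pytest.raises(ValueError, match="constant outcome"):
            fit_rf(X, np.ones(50), FAST_RF)

    def test_missing_cells_rejected(self):
        X, y = _noise_design(50, 3, 5)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_rf(X, y, FAST_RF)


class TestPermutationImportance:
    def test_dominant_predictor_reaches_floor(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy() + 0.3 * rng.normal(size=300)  # R2 ~ 0.9
        p = permutation_importance_pvalues(X, y, FAST_RF, n_permutations=99, seed=0)
        assert p["a"] == pytest.approx(1 / 100)

    def test_floor_bound_never_undershot(self):
        X, y = _noise_design(100, 5, 7)
        p = permutation_importance_pvalues(X, y, FAST_RF, n_permutations=19, seed=1)
        assert (p >= 1 / 20).all() and (p <= 1.0).all()

    def test_too_few_permutations_rejected(self):
        X, y = _noise_design(60, 3, 8)
        with pytest.raises(ValueError, match="19"):
            permutation_importance_pvalues(X, y, FAST_RF, n_permutations=5)

    def test_feature_scheme_flags_dominant_predictor(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy() + 0.3 * rng.normal(size=300)
        p = permutation_importance_pvalues(
            X, y, FAST_RF, n_permutations=19, seed=2, scheme="feature"
        )
        assert p["a"] == pytest.approx(1 / 20)
        assert p["b"] > p["a"]


class TestOptimismCorrection:
    def test_noise_outcome_corrected_below_apparent(self):
        X, y = _noise_design(300, 10, 10)
        res = optimism_corrected_r2(X, y, RFParams(20, None, 25), n_bootstrap=30, seed=0)
        assert res.corrected_r2 < res.apparent_r2
        assert abs(res.corrected_r2) < 0.1

    def test_constant_feature_has_no_optimism(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"const": np.ones(500)})
        y = rng.normal(size=500)
        res = optimism_corrected_r2(X, y, FAST_RF, n_bootstrap=20, seed=0)
        assert res.corrected_r2 == pytest.approx(res.apparent_r2, abs=0.02)

    def test_optimism_nonnegative_in_expectation(self):
        """Corrected never exceeds apparent beyond RF noise tolerance."""
        for seed in range(3):
            X, y = _noise_design(200, 8, 20 + seed)
            res = optimism_corrected_r2(X, y, RFParams(15, None, 15), 20, seed=seed)
            assert res.corrected_r2 <= res.apparent_r2 + 0.01


class TestFoldIncrease:
    def test_arithmetic(self):
        assert fold_increase(0.5, 0.25) == 2.0
        assert fold_increase(0.37, 0.37) == 1.0

    def test_printed_pair_consistency(self):
        # a published with-intervention pair: R2 0.619 at fold 1.851 implies
        # a baseline-model R2 of 0.619/1.851
        baseline = 0.619 / 1.851
        assert baseline == pytest.approx(0.334, abs=5e-4)
        assert fold_increase(0.619, baseline) == pytest.approx(1.851, abs=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -0.2])
    def test_nonpositive_reference_rejected(self, bad):
        with pytest.raises(FoldIncreaseError, match="positive"):
            fold_increase(0.5, bad)


class TestBootstrapFrequencies:
    def test_counts_bounded_and_deterministic(self, small_cohort):
        X = encode_design(small_cohort, include_cpg=False, include_intervention=True)
        y = small_cohort["internalizing"].to_numpy()
        strata = small_cohort["arm"].to_numpy()
        c1 = bootstrap_significance_frequencies(
            X, y, FAST_RF, n_bootstrap=8, n_permutations=19, seed=5, strata=strata
        )
        c2 = bootstrap_significance_frequencies(
            X, y, FAST_RF, n_bootstrap=8, n_permutations=19, seed=5, strata=strata
        )
        assert c1.between(0, 8).all()
        pd.testing.assert_series_equal(c1, c2)

    def test_stratified_resampling_keeps_both_arms(self):
        from cpgmediation.mediation import _bootstrap_indices

        strata = np.array(["a"] * 10 + ["b"] * 90)
        for seed in range(20):
            idx = _bootstrap_indices(100, strata, seed)
            assert (idx < 10).sum() == 10  # all 10 'a' slots resampled from 'a'
            assert len(idx) == 100


def test_monotone_information_with_cpg_panel(small_cohort):
    """Adding the CpG columns never reduces apparent R² beyond RF noise."""
    y = small_cohort["internalizing"].to_numpy()
    rf = RFParams(30, None, 10)
    r_without = fit_rf(
        encode_design(small_cohort, include_cpg=False, include_intervention=True),
        y, rf, seed=3,
    ).apparent_r2
    r_with = fit_rf(
        encode_design(small_cohort, include_cpg=True, include_intervention=True),
        y, rf, seed=3,
    ).apparent_r2
    assert r_with >= r_without - 0.02


def test_mediation_analysis_structure_and_pooling_identity(small_cohort, panel):
    """Zero-missingness stack of identical datasets reproduces the
    single-dataset analysis exactly; result structure is complete."""
    stack3 = chained_equations_impute(small_cohort, m=3, iterations=2, seed=30)
    stack1 = chained_equations_impute(small_cohort, m=1, iterations=2, seed=30)
    kwargs = dict(
        panel=panel, outcomes=["internalizing"], rf_params=FAST_RF,
        n_bootstrap=5, n_permutations=19, seed=31,
    )
    r3 = mediation_analysis(stack3, **kwargs)["internalizing"]
    r1 = mediation_analysis(stack1, **kwargs)["internalizing"]
    for v in r1.r2_corrected:
        assert r3.r2_corrected[v] == pytest.approx(r1.r2_corrected[v], rel=1e-12)
    assert r3.significance_frequency == r1.significance_frequency
    # structure
    assert set(r3.r2_corrected) == {"baseline", "baseline+interv", "cpg", "cpg+interv"}
    for freq in r3.significance_frequency.values():
        assert all(0 <= v <= 5 for v in freq.values())
    assert 0 <= r3.intervention_frequency_baseline <= 5


def test_excluded_outcome_skipped(small_cohort, panel):
    bad = small_cohort.copy()
    k = int(np.ceil(0.35 * len(bad)))
    bad.loc[bad.index[:k], "total"] = np.nan
    with pytest.warns(UserWarning, match="30%"):
        stack = chained_equations_impute(bad, m=2, iterations=2, seed=33)
    results = mediation_analysis(
        stack, panel=panel, outcomes=["internalizing", "total"],
        rf_params=FAST_RF, n_bootstrap=4, n_permutations=19, seed=34,
    )
    assert "total" not in results and "internalizing" in results


def test_intervention_exclusion_leaves_cpg_frequencies_stable(panel):
    """Dropping the randomized arm from the model changes CpG significance
    frequencies only within bootstrap noise under full mediation."""
    cfg = ScenarioConfig(n_per_arm=(125, 125), missing_frac=0.0, seed=55)
    cohort = generate_cohort(cfg, panel=panel)
    y = cohort["internalizing"].to_numpy()
    strata = cohort["arm"].to_numpy()
    rf = RFParams(15, None, 15)
    kwargs = dict(n_bootstrap=20, n_permutations=19, alpha=0.05, seed=56, strata=strata)
    with_arm = bootstrap_significance_frequencies(
        encode_design(cohort, include_cpg=True, include_intervention=True), y, rf, **kwargs
    )
    without_arm = bootstrap_significance_frequencies(
        encode_design(cohort, include_cpg=True, include_intervention=False), y, rf, **kwargs
    )
    cpgs = [c for c in with_arm.index if c.startswith("cg")]
    assert (with_arm[cpgs] - without_arm[cpgs]).abs().max() < 10
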