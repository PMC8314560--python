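import pytest

from cpgmediation import (
    RFParams,
    chained_equations_impute,
    generate_cohort,
    inject_missingness,
    builtin_panel,
    mediation_analysis,
    scenario_config,
)

#: Small regularized forest for unit tests (speed over stability).
FAST_RF = RFParams(n_trees=10, features_per_split=None, min_leaf=10)


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """Complete-data full-mediation cohort, 60 per arm."""
    cfg = scenario_config("full_mediation", n_per_arm=(60, 60), missing_frac=0.0, seed=11)
    return generate_cohort(cfg, panel=panel)


@pytest.fixture(scope="session")
def missing_cohort(panel):
    """Full-mediation cohort with 20% MAR outcome missingness, 75 per arm."""
    cfg = scenario_config("full_mediation", n_per_arm=(75, 75), missing_frac=0.20, seed=12)
    return inject_missingness(generate_cohort(cfg, panel=panel), cfg)


@pytest.fixture(scope="session")
def tiny_results(small_cohort, panel):
    """One cheap end-to-end mediation result set shared by report/cluster tests."""
    stack = chained_equations_impute(small_cohort, m=2, iterations=2, seed=21)
    return mediation_analysis(
        stack,
        panel=panel,
        outcomes=["internalizing", "externalizing"],
        rf_params=FAST_RF,
        n_bootstrap=5,
        n_permutations=19,
        seed=22,
    )
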