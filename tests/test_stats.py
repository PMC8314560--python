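"""Oracles and invariance properties for the baseline-comparison tests."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cpgmediation import (
    ScenarioConfig,
    baseline_frame,
    baseline_table,
    chi_square_test,
    generate_cohort,
    wilcoxon_rank_sum,
)
from cpgmediation.cohort import CohortSchemaError, read_cohort, write_cohort


def closed_form_2x2(a, b, c, d):
    """Pearson chi-square on a 2x2: N(ad-bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def exact_rank_sum_p(x, y):
    """Two-sided exact p by full enumeration of rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    n = len(pooled)
    mean_w = len(x) * (n + 1) / 2
    ws = [sum(c) for c in combinations(ranks, len(x))]
    tail = sum(1 for w in ws if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return tail / len(ws)


class TestChiSquare:
    def test_infection_table_matches_closed_form(self):
        stat, p = chi_square_test([[23, 169], [9, 202]])
        assert stat == pytest.approx(closed_form_2x2(23, 169, 9, 202), abs=1e-9)
        assert stat == pytest.approx(8.18, abs=0.01)
        assert p == pytest.approx(0.004, abs=5e-4)

    def test_homogeneous_table_is_null(self):
        stat, p = chi_square_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_diagonal_table(self):
        stat, p = chi_square_test([[5, 0], [0, 5]])
        assert stat == pytest.approx(10.0, abs=1e-12)
        assert p == pytest.approx(sps.chi2.sf(10.0, df=1), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_test([[0, 5], [0, 7]])

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_closed_form_on_random_2x2(self, cells):
        a, b, c, d = cells
        stat, _ = chi_square_test([[a, b], [c, d]])
        assert stat == pytest.approx(closed_form_2x2(a, b, c, d), rel=1e-12)

    def test_continuity_correction_flag(self):
        plain, _ = chi_square_test([[23, 169], [9, 202]])
        yates, _ = chi_square_test([[23, 169], [9, 202]], continuity=True)
        assert yates < plain


class TestWilcoxonRankSum:
    def test_separated_samples_exact(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(exact_rank_sum_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_normal_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p_norm = wilcoxon_rank_sum(x, y, method="normal")
            # continuity-corrected normal approximation; ~0.015 error is the
            # attainable accuracy at n=m=6
            assert p_norm == pytest.approx(exact_rank_sum_p(x, y), abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=25) + 0.4
        assert wilcoxon_rank_sum(x, y) == wilcoxon_rank_sum(np.exp(x), np.exp(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


def test_null_pvalues_uniform():
    """Both tests produce ~uniform p under the null (KS check, alpha=0.01)."""
    rng = np.random.default_rng(2024)
    p_w = [
        wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))[1]
        for _ in range(2000)
    ]
    assert sps.kstest(p_w, "uniform").pvalue > 0.01
    p_c = []
    for _ in range(2000):
        # chi-square p is intrinsically discrete; uniformity holds in the
        # continuous limit, so per-arm counts must be large for a KS check
        t = np.array([rng.multinomial(20_000, [0.5, 0.5]) for _ in range(2)])
        p_c.append(chi_square_test(t)[1])
    assert sps.kstest(p_c, "uniform").pvalue > 0.01


class TestBaselineTable:
    def test_summaries_match_hand_computation(self, small_cohort):
        rows = {r.variable: r for r in baseline_table(small_cohort, ["age"])}
        early = small_cohort[small_cohort["arm"] == "early-PN"]["age"]
        expect = f"{early.mean():.2f} ({early.std(ddof=1):.2f})"
        assert rows["age"].summary_early == expect
        assert rows["age"].test == "wilcoxon"

    def test_balanced_binary_p_one(self, small_cohort):
        cohort = small_cohort.copy()
        # perfectly balanced binary covariate
        cohort["malignancy"] = np.tile([0, 1], len(cohort) // 2)
        row = baseline_table(cohort, ["malignancy"])[0]
        assert row.test == "chi_square"
        assert row.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self):
        cfg = ScenarioConfig(n_per_arm=(200, 200), seed=31)
        cohort = generate_cohort(cfg)
        cohort.loc[cohort["arm"] == "early-PN", "internalizing"] += 10
        row = baseline_table(cohort, ["internalizing"])[0]
        assert row.p_value < 0.001

    def test_unknown_variable_rejected(self, small_cohort):
        with pytest.raises(KeyError, match="unknown variable"):
            baseline_table(small_cohort, ["nonexistent"])

    def test_frame_export(self, small_cohort):
        df = baseline_frame(baseline_table(small_cohort, ["age", "sex"]))
        assert list(df["variable"]) == ["age", "sex"]
        assert df["p_value"].between(0, 1).all()


class TestCohortIO:
    def test_beta_out_of_range_names_row_and_column(self, tmp_path, small_cohort):
        bad = small_cohort.copy()
        bad.loc[3, "cg14172797"] = 1.2
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match=r"cg14172797.*row 3"):
            read_cohort(path)

    def test_duplicate_patient_id_rejected(self, tmp_path, small_cohort):
        bad = small_cohort.copy()
        bad.loc[1, "patient_id"] = bad.loc[0, "patient_id"]
        path = tmp_path / "dup.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="duplicate patient_id"):
            read_cohort(path)

    def test_missing_arm_rejected(self, tmp_path, small_cohort):
        bad = small_cohort.copy()
        bad.loc[0, "arm"] = np.nan
        path = tmp_path / "noarm.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="missing arm"):
            read_cohort(path)

    def test_missing_column_rejected(self, tmp_path, small_cohort):
        path = tmp_path / "nocol.csv"
        small_cohort.drop(columns=["pim3"]).to_csv(path, index=False)
        with pytest.raises(CohortSchemaError, match="pim3"):
            read_cohort(path)
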