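import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctquant import trial


class TestSampleSize:
    def test_rounded_quantiles_worked_example(self):
        # sigma 5, delta 3, Z=1.96/0.84: 50*7.84/9 = 43.56 -> 44 per group
        res = trial.sample_size_per_group(
            trial.SampleSizeSpec(sigma=5, delta=3, z_alpha=1.96, z_beta=0.84))
        assert res.n == 44
        assert res.n_raw == pytest.approx(43.56, abs=0.005)

    def test_exact_quantiles_give_same_answer(self):
        res = trial.sample_size_per_group(
            trial.SampleSizeSpec(sigma=5, delta=3, alpha=0.05, power=0.8))
        assert res.n == 44

    def test_unit_standardized_difference(self):
        res = trial.sample_size_per_group(trial.SampleSizeSpec(sigma=1, delta=1))
        assert res.n == 16  # ceil(2 * (1.96 + 0.8416)^2)

    def test_huge_effect_needs_one_subject(self):
        res = trial.sample_size_per_group(trial.SampleSizeSpec(sigma=1, delta=100))
        assert res.n == 1

    def test_zero_difference_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            trial.SampleSizeSpec(sigma=5, delta=0)

    @given(st.floats(1, 20), st.floats(0.5, 10), st.floats(0.5, 10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_sigma_and_delta(self, sigma, d1, d2):
        lo_d, hi_d = sorted((d1, d2))
        n_hi = trial.sample_size_per_group(trial.SampleSizeSpec(sigma=sigma, delta=lo_d)).n
        n_lo = trial.sample_size_per_group(trial.SampleSizeSpec(sigma=sigma, delta=hi_d)).n
        assert n_hi >= n_lo  # smaller difference needs more subjects
        n_big_sigma = trial.sample_size_per_group(
            trial.SampleSizeSpec(sigma=sigma + 1, delta=lo_d)).n
        assert n_big_sigma >= n_hi


class TestEnrollment:
    def test_fixed_target_total(self):
        plan = trial.inflate_for_design(44, dropout_rate=0.15, strata=4,
                                        per_stratum_target=50, arms=2)
        assert plan.total == 400

    def test_dropout_inflation_formula(self):
        plan = trial.inflate_for_design(44, dropout_rate=0.15)
        assert plan.inflated_n_per_group == 52  # ceil(44 / 0.85)

    def test_zero_dropout_is_identity(self):
        assert trial.inflate_for_design(44, dropout_rate=0.0).inflated_n_per_group == 44

    def test_full_dropout_rejected(self):
        with pytest.raises(ValueError):
            trial.inflate_for_design(44, dropout_rate=1.0)


class TestGoldGrade:
    @pytest.mark.parametrize("fev1,grade", [
        (48.3, "III"), (80.0, "I"), (25.0, "IV"),
        (50.0, "II"), (30.0, "III"), (79.9, "II"), (150.0, "I"),
    ])
    def test_threshold_partition(self, fev1, grade):
        assert trial.gold_grade(fev1) == grade

    def test_respiratory_failure_forces_grade_four(self):
        assert trial.gold_grade(85.0, respiratory_failure=True) == "IV"

    def test_every_input_maps_to_exactly_one_grade(self):
        for fev1 in np.linspace(0.1, 199.9, 500):
            assert trial.gold_grade(float(fev1)) in trial.GOLD_GRADES

    def test_out_of_range_rejected(self):
        for bad in (0.0, -5.0, 200.0, 250.0):
            with pytest.raises(ValueError):
                trial.gold_grade(bad)


class TestRandomization:
    def test_even_stratum_splits_exactly_one_to_one(self):
        subjects = [f"p{i}" for i in range(48)]
        assignment, imbalanced = trial.stratified_randomize(subjects, ["I"] * 48, seed=5)
        arms = list(assignment.values())
        assert arms.count("EG") == 24 and arms.count("CG") == 24
        assert imbalanced == []

    def test_deterministic_under_seed(self):
        subjects = list(range(30))
        strata = ["a"] * 10 + ["b"] * 20
        a, _ = trial.stratified_randomize(subjects, strata, seed=9)
        b, _ = trial.stratified_randomize(subjects, strata, seed=9)
        assert a == b

    def test_one_to_one_within_each_stratum(self):
        subjects = list(range(40))
        strata = ["I"] * 10 + ["II"] * 10 + ["III"] * 10 + ["IV"] * 10
        assignment, _ = trial.stratified_randomize(subjects, strata, seed=2)
        for g in ("I", "II", "III", "IV"):
            arms = [assignment[s] for s, st_ in zip(subjects, strata) if st_ == g]
            assert arms.count("EG") == 5 and arms.count("CG") == 5

    def test_odd_stratum_flagged_with_one_imbalance(self):
        assignment, imbalanced = trial.stratified_randomize(list(range(5)), ["x"] * 5, seed=3)
        arms = list(assignment.values())
        assert sorted((arms.count("EG"), arms.count("CG"))) == [2, 3]
        assert imbalanced == ["x"]

    def test_no_subjects_rejected(self):
        with pytest.raises(ValueError):
            trial.stratified_randomize([], [], seed=0)


def bh_bruteforce(p):
    """Min-over-suffix step-up oracle: q_(i) = min_{j>=i} m*p_(j)/j, clipped."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        q_sorted[rank - 1] = min(
            min(m * p[order[j - 1]] / j for j in range(rank, m + 1)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert trial.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_triple(self):
        assert trial.bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_all_ones_clip(self):
        assert trial.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            trial.bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_oracle_on_1000_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            assert trial.bh_adjust(p) == pytest.approx(bh_bruteforce(p), abs=1e-12)

    def test_monotone_in_input_ranks(self, rng):
        p = rng.random(15)
        q = trial.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        out = trial.correlation_matrix(x, x.rename(columns={"a": "b"}))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_recovers_generator_specified_correlation(self):
        rng = np.random.default_rng(2024)
        n, r_true = 500, -0.6
        x = rng.standard_normal(n)
        y = r_true * x + np.sqrt(1 - r_true ** 2) * rng.standard_normal(n)
        out = trial.correlation_matrix(pd.DataFrame({"lav_percent": x}),
                                       pd.DataFrame({"fev1": y}))
        assert out.loc[0, "r"] == pytest.approx(-0.6, abs=0.08)

    def test_independent_columns_stay_near_zero(self):
        rng = np.random.default_rng(99)
        out = trial.correlation_matrix(
            pd.DataFrame({"a": rng.standard_normal(500)}),
            pd.DataFrame({"b": rng.standard_normal(500)}))
        assert abs(out.loc[0, "r"]) < 0.15

    def test_constant_column_flagged_undefined(self):
        out = trial.correlation_matrix(
            pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0]}),
            pd.DataFrame({"b": [1.0, 2.0, 3.0, 4.0]}))
        assert not out.loc[0, "defined"]
        assert np.isnan(out.loc[0, "r"])

    def test_pairwise_complete_handling(self):
        im = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0, 5.0]})
        fn = pd.DataFrame({"b": [2.0, 4.0, 6.0, 8.0, 10.0]})
        out = trial.correlation_matrix(im, fn)
        assert out.loc[0, "n"] == 4
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_q_values_are_bh_adjusted_across_cells(self):
        rng = np.random.default_rng(5)
        im = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        fn = pd.DataFrame(rng.standard_normal((50, 2)), columns=list("xy"))
        out = trial.correlation_matrix(im, fn)
        assert out["q"].notna().all()
        assert np.allclose(np.sort(out["q"]), np.sort(trial.bh_adjust(out["p"])))
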