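import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from algaecast import (
    Strategy,
    anova_partition,
    coefficient_of_variation,
    compare_production,
    confusion_and_accuracy,
    crps,
    mean_monthly_crps,
    occurrence_probability,
)
from algaecast.errors import DataError, DomainError


def crps_numerical(members, obs, n_grid=400_001):
    """Independent oracle: trapezoid integration of (F - H)^2 on a fine grid."""
    members = np.sort(np.asarray(members, dtype=float))
    lo = min(members.min(), obs) - 5.0
    hi = max(members.max(), obs) + 5.0
    x = np.linspace(lo, hi, n_grid)
    F = np.searchsorted(members, x, side="right") / members.size
    H = (x >= obs).astype(float)
    return float(np.trapezoid((F - H) ** 2, x))


def crps_piecewise(members, obs):
    """Exact integral of (F - H)^2: the integrand is constant between the
    sorted breakpoints (member values and the observation)."""
    members = np.sort(np.asarray(members, dtype=float))
    points = np.sort(np.unique(np.concatenate([members, [obs]])))
    total = 0.0
    for left, right in zip(points[:-1], points[1:]):
        mid = 0.5 * (left + right)
        F = np.searchsorted(members, mid, side="right") / members.size
        H = 1.0 if mid >= obs else 0.0
        total += (F - H) ** 2 * (right - left)
    return total


class TestCrps:
    def test_perfect_forecast_is_zero(self):
        assert crps([3.0, 3.0, 3.0], 3.0) == 0.0

    def test_single_member_reduces_to_absolute_error(self):
        assert crps([5.0], 2.0) == pytest.approx(3.0)
        assert crps([5.0], 2.0) == pytest.approx(crps_numerical([5.0], 2.0), abs=1e-4)

    def test_two_member_bracketing_case(self):
        assert crps([0.0, 2.0], 1.0) == pytest.approx(0.5)
        assert crps([0.0, 2.0], 1.0) == pytest.approx(
            crps_numerical([0.0, 2.0], 1.0), abs=1e-4
        )

    @settings(max_examples=40, deadline=None)
    @given(
        members=st.lists(st.floats(-20, 20), min_size=1, max_size=6),
        obs=st.floats(-20, 20),
    )
    def test_closed_form_matches_numerical_integration(self, members, obs):
        assert crps(members, obs) == pytest.approx(
            crps_numerical(members, obs), abs=1e-3
        )

    def test_closed_form_tight_agreement_on_random_ensembles(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            members = rng.uniform(-10, 10, rng.integers(1, 7))
            obs = rng.uniform(-10, 10)
            exact = crps_piecewise(members, obs)
            assert crps(members, obs) == pytest.approx(exact, abs=1e-6)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(DataError):
            crps([], 1.0)


class TestMeanMonthlyCrps:
    def test_perfect_ensembles_give_zero(self):
        obs = {(2020, 1): np.arange(31.0), (2021, 1): np.arange(31.0) + 2}
        fc = {k: np.tile(v, (4, 1)) for k, v in obs.items()}
        out = mean_monthly_crps(fc, obs)
        assert out[1] == 0.0

    def test_single_member_equals_mae(self):
        rng = np.random.default_rng(2)
        obs = {(2020, 6): rng.normal(25, 3, 30)}
        fc = {(2020, 6): rng.normal(25, 3, (1, 30))}
        out = mean_monthly_crps(fc, obs)
        mae = np.mean(np.abs(fc[(2020, 6)][0] - obs[(2020, 6)]))
        assert out[6] == pytest.approx(mae)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        obs = {(2020, 2): rng.normal(0, 1, 28)}
        fc = {(2020, 2): rng.normal(0, 1, (5, 28))}
        base = mean_monthly_crps(fc, obs)
        scaled = mean_monthly_crps(
            {k: 3.0 * v for k, v in fc.items()},
            {k: 3.0 * v for k, v in obs.items()},
        )
        assert scaled[2] == pytest.approx(3.0 * base[2])


class TestConfusionAndAccuracy:
    def test_identical_lists_are_perfect(self):
        months = [Strategy("A", 15.0), Strategy("B", 20.0)] * 3
        matrix, total, strain_only = confusion_and_accuracy(months, months)
        assert total == 1.0 and strain_only == 1.0
        assert np.trace(matrix.counts) == 6

    def test_42_of_54_matches_paper_rounding_convention(self):
        optimal = [Strategy("A", 15.0)] * 54
        selected = [Strategy("A", 15.0)] * 42 + [Strategy("B", 20.0)] * 12
        _, total, _ = confusion_and_accuracy(selected, optimal)
        assert round(100 * total, 1) == 77.8

    def test_strain_only_at_least_total(self):
        rng = np.random.default_rng(4)
        strains = ["A", "B"]
        depths = [15.0, 20.0, 25.0, 30.0]
        for _ in range(20):
            sel = [Strategy(rng.choice(strains), rng.choice(depths))
                   for _ in range(30)]
            opt = [Strategy(rng.choice(strains), rng.choice(depths))
                   for _ in range(30)]
            _, total, strain_only = confusion_and_accuracy(sel, opt)
            assert strain_only >= total

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            confusion_and_accuracy([Strategy("A", 15.0)], [])


class TestOccurrence:
    def test_constant_winner(self):
        probs = occurrence_probability([Strategy("A", 15.0)] * 5)
        assert probs == {"A-15": 1.0}

    def test_direct_counting(self):
        winners = [Strategy("A", 15.0), Strategy("A", 15.0),
                   Strategy("B", 20.0), Strategy("A", 15.0)]
        probs = occurrence_probability(winners)
        assert probs["A-15"] == 0.75 and probs["B-20"] == 0.25

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        winners = [Strategy(rng.choice(["A", "B", "C"]), 15.0) for _ in range(37)]
        assert sum(occurrence_probability(winners).values()) == pytest.approx(1.0)


def brute_force_anova(Y):
    """Four-loop sums-of-squares oracle for the balanced two-way design."""
    a, b, n = Y.shape
    grand = Y.mean()
    ss = dict(A=0.0, B=0.0, AB=0.0, E=0.0, T=0.0)
    mean_i = [Y[i].mean() for i in range(a)]
    mean_j = [Y[:, j].mean() for j in range(b)]
    for i in range(a):
        for j in range(b):
            cell = Y[i, j].mean()
            for k in range(n):
                ss["E"] += (Y[i, j, k] - cell) ** 2
                ss["T"] += (Y[i, j, k] - grand) ** 2
            ss["AB"] += n * (cell - mean_i[i] - mean_j[j] + grand) ** 2
    for i in range(a):
        ss["A"] += b * n * (mean_i[i] - grand) ** 2
    for j in range(b):
        ss["B"] += a * n * (mean_j[j] - grand) ** 2
    return ss


class TestAnovaPartition:
    def test_pure_strain_effect(self):
        Y = np.empty((2, 4, 5))
        Y[0] = 10.0
        Y[1] = 20.0
        part = anova_partition(Y)
        assert part.ratio_strain == pytest.approx(1.0)
        assert part.ratio_depth == part.ratio_interaction == part.ratio_residual == 0.0

    def test_additive_effects_have_no_interaction_or_residual(self):
        a_eff = np.array([1.0, 4.0])
        b_eff = np.array([0.0, 2.0, 5.0])
        Y = np.empty((2, 3, 4))
        for i in range(2):
            for j in range(3):
                Y[i, j, :] = a_eff[i] + b_eff[j]
        part = anova_partition(Y)
        assert part.ratio_interaction == pytest.approx(0.0, abs=1e-12)
        assert part.ratio_residual == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_and_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(10, 3, (2, 4, 6))
        part = anova_partition(Y)
        ss = brute_force_anova(Y)
        assert part.ratio_strain == pytest.approx(ss["A"] / ss["T"], abs=1e-10)
        assert part.ratio_depth == pytest.approx(ss["B"] / ss["T"], abs=1e-10)
        assert part.ratio_interaction == pytest.approx(ss["AB"] / ss["T"], abs=1e-10)
        assert part.ratio_residual == pytest.approx(ss["E"] / ss["T"], abs=1e-10)
        total = (part.ratio_strain + part.ratio_depth
                 + part.ratio_interaction + part.ratio_residual)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_constant_data_rejected(self):
        with pytest.raises(DomainError):
            anova_partition(np.full((2, 2, 3), 7.0))

    def test_single_replicate_rejected(self):
        with pytest.raises(DataError):
            anova_partition(np.zeros((2, 2, 1)))


class TestCoefficientOfVariation:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_hand_computed_pair(self):
        assert coefficient_of_variation([8.0, 12.0]) == pytest.approx(
            np.std([8.0, 12.0], ddof=1) / 10.0
        )

    def test_scale_invariance(self):
        x = [3.0, 5.0, 9.0, 4.0]
        assert coefficient_of_variation(x) == pytest.approx(
            coefficient_of_variation([10 * v for v in x])
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(DomainError):
            coefficient_of_variation([-1.0, 1.0])


class TestCompareProduction:
    def test_identical_series_is_zero_everywhere(self):
        cmp = compare_production([10.0, 12.0], [10.0, 12.0])
        assert np.allclose(cmp.monthly_pct_diff, 0.0)
        assert cmp.avg_pct_diff == 0.0

    def test_stored_fields_mutually_consistent(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(5, 30, 10)
        alt = base * rng.uniform(0.8, 1.6, 10)
        cmp = compare_production(base, alt)
        recomputed = (
            (cmp.pairs["alternative"] - cmp.pairs["baseline"])
            / cmp.pairs["baseline"] * 100.0
        )
        pd.testing.assert_series_equal(cmp.monthly_pct_diff, recomputed)
        assert cmp.avg_pct_diff == pytest.approx(
            (alt.mean() - base.mean()) / base.mean() * 100.0
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            compare_production([10.0, 0.0], [9.0, 1.0])
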