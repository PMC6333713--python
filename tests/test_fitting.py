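"""Proportion construction, the G² objective, BIC, and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mdmc
from mdmc import fitting
from mdmc.fitting import (
    CommonRandomNumbers,
    ConditionBins,
    FitConfig,
    ProportionVector,
    bic,
    condition_tables,
    g_squared,
    observed_proportions,
    permutation_pvalue,
    predicted_proportions,
    score_proportions,
)


def brute_force_g2(observed, predicted, floor=1e-5):
    """Independent straight-from-the-formula evaluation of the objective."""
    total = 0.0
    for obs, pred in zip(observed, predicted):
        for i in range(10):
            p = obs.values[i]
            pi = max(pred.values[i], floor)
            if p > 0:
                total += obs.n_trials * abs(p * math.log(p / pi))
    return 2.0 * total


def make_table(rts, acc):
    return pd.DataFrame(
        {
            "rt_ms": np.asarray(rts, dtype=float),
            "accuracy": np.asarray(acc, dtype=int),
        }
    )


class TestObservedProportions:
    def test_all_correct_symmetric(self, rng):
        rts = rng.normal(400, 50, size=1000)
        vec, bins = observed_proportions(make_table(rts, np.ones(1000)))
        np.testing.assert_allclose(vec.values[:5], [0.1, 0.2, 0.2, 0.2, 0.2], atol=1e-9)
        np.testing.assert_array_equal(vec.values[5:], 0.0)
        assert len(bins.quantile_edges) == 5 and len(bins.caf_edges) == 4

    def test_uniform_accuracy_scaling(self, rng):
        # 90% accuracy spread evenly over bins: CDF slots scale by accuracy,
        # CAF slots carry 2% errors each.
        n = 1000
        rts = np.sort(rng.normal(400, 50, size=n))
        acc = np.ones(n, dtype=int)
        for b in range(5):  # 20 errors per quintile bin of 200
            acc[b * 200 + 10 : b * 200 + 190 : 9] = 0
        vec, _ = observed_proportions(make_table(rts, acc))
        np.testing.assert_allclose(vec.values[5:], 0.02, atol=1e-12)
        assert vec.values[:5].sum() == pytest.approx(0.9 * 0.9, abs=0.01)

    def test_slots_plus_top_tail_partition_unity(self, rng):
        n = 837
        rts = rng.normal(420, 60, size=n)
        acc = (rng.random(n) < 0.93).astype(int)
        vec, bins = observed_proportions(make_table(rts, acc))
        top_tail = np.sum(
            (rts > bins.quantile_edges[-1]) & (acc == 1)
        ) / n
        assert vec.values.sum() + top_tail == pytest.approx(1.0, abs=1e-12)

    def test_no_correct_responses_rejected(self):
        with pytest.raises(ValueError, match="IVIT"):
            observed_proportions(
                make_table(np.arange(20.0) + 300, np.zeros(20)), label="IVIT"
            )


class TestPredictedProportions:
    def test_scoring_observed_data_is_self_consistent(self, vt_table):
        kept, _ = mdmc.filter_rts(vt_table)
        _, groups = condition_tables(kept)
        for cond, sub in groups.items():
            vec, bins = observed_proportions(sub, cond.name)
            rescored = score_proportions(
                sub["rt_ms"].to_numpy(),
                sub["accuracy"].to_numpy() > 0.5,
                bins,
            )
            np.testing.assert_array_equal(vec.values, rescored)

    def test_seeded_determinism(self, vt_mdmc, vt_table):
        kept, _ = mdmc.filter_rts(vt_table)
        _, groups = condition_tables(kept)
        cond = next(iter(groups))
        _, bins = observed_proportions(groups[cond], cond.name)
        a = predicted_proportions(vt_mdmc, cond, bins, "mdmc", n_sim=5000, rng=9)
        b = predicted_proportions(vt_mdmc, cond, bins, "mdmc", n_sim=5000, rng=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_fn_variant_with_equal_residual_means_reduces_to_base(
        self, vt_mdmc, vt_table
    ):
        # Constraining mu_rn = mu_r makes the faster-neutral variant
        # prediction-equivalent to the base model under shared noise.
        kept, _ = mdmc.filter_rts(vt_table)
        _, groups = condition_tables(kept)
        crn = CommonRandomNumbers(5000, np.random.SeedSequence(12))
        constrained = vt_mdmc.with_(mu_rn=vt_mdmc.mu_r)
        for cond, sub in groups.items():
            _, bins = observed_proportions(sub, cond.name)
            base = predicted_proportions(vt_mdmc, cond, bins, "mdmc", crn=crn)
            fn = predicted_proportions(constrained, cond, bins, "fn-mdmc", crn=crn)
            np.testing.assert_array_equal(base.values, fn.values)

    def test_fast_errors_concentrate_in_incongruent_visual(self, vt_mdmc, vt_table):
        # The automatic pulse drives early activation toward the wrong
        # boundary when the visual location is incongruent, so the first CAF
        # bin of IV conditions should hold the most predicted error mass.
        kept, _ = mdmc.filter_rts(vt_table)
        _, groups = condition_tables(kept)
        crn = CommonRandomNumbers(20_000, np.random.SeedSequence(4))
        first_bin_error = {}
        for cond, sub in groups.items():
            _, bins = observed_proportions(sub, cond.name)
            pred = predicted_proportions(vt_mdmc, cond, bins, "mdmc", crn=crn)
            first_bin_error[cond.labels["visual"]] = max(
                first_bin_error.get(cond.labels["visual"], 0.0), pred.values[5]
            )
        assert first_bin_error["incongruent"] > first_bin_error["congruent"]
        assert first_bin_error["incongruent"] > first_bin_error["neutral"]


class TestGSquared:
    def test_zero_when_observed_equals_predicted(self, rng):
        v = rng.dirichlet(np.ones(10)) * 0.9
        obs = [ProportionVector(v, 500)]
        assert g_squared(obs, obs) == 0.0

    def test_two_slot_worked_example(self):
        # Toy 2-slot variant: 2 * 100 * (0.5 ln 2 + |0.5 ln(2/3)|) ~ 109.86
        p = np.zeros(10)
        p[:2] = [0.5, 0.5]
        pi = np.zeros(10)
        pi[:2] = [0.25, 0.75]
        g = g_squared([ProportionVector(p, 100)], [ProportionVector(pi, 100)])
        assert g == pytest.approx(
            2 * 100 * (0.5 * math.log(2) + abs(0.5 * math.log(2 / 3))), rel=1e-12
        )
        assert g == pytest.approx(109.86, abs=0.01)

    def test_linear_in_trial_count(self, rng):
        p = rng.dirichlet(np.ones(10)) * 0.8
        q = rng.dirichlet(np.ones(10)) * 0.8
        g1 = g_squared([ProportionVector(p, 100)], [ProportionVector(q, 100)])
        g2 = g_squared([ProportionVector(p, 200)], [ProportionVector(q, 100)])
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_matches_brute_force_on_random_vectors(self, rng):
        # Oracle equivalence over 100 random observed/predicted pairs.
        for _ in range(100):
            obs = [
                ProportionVector(rng.dirichlet(np.ones(11))[:10], int(rng.integers(50, 3000)))
                for _ in range(3)
            ]
            pred = [
                ProportionVector(rng.dirichlet(np.ones(11))[:10], o.n_trials)
                for o in obs
            ]
            assert g_squared(obs, pred) == pytest.approx(
                brute_force_g2(obs, pred), rel=1e-12, abs=1e-12
            )

    def test_absolute_value_form_dominates_signed_form(self, rng):
        obs = [ProportionVector(rng.dirichlet(np.ones(11))[:10], 100)]
        pred = [ProportionVector(rng.dirichlet(np.ones(11))[:10], 100)]
        assert g_squared(obs, pred) >= g_squared(obs, pred, absolute=False)

    def test_zero_observed_slots_contribute_nothing(self):
        p = np.zeros(10)
        p[0] = 1.0
        pi = np.full(10, 0.1)
        g = g_squared([ProportionVector(p, 10)], [ProportionVector(pi, 10)])
        assert g == pytest.approx(2 * 10 * abs(math.log(1 / 0.1)), rel=1e-12)


class TestBIC:
    def test_no_free_parameters(self):
        assert bic(100.0, 0, 270) == 100.0

    def test_arithmetic(self):
        assert bic(100.0, 9, 270) == pytest.approx(100 + 9 * math.log(270), rel=1e-12)

    def test_ordering_invariant_to_common_shift(self):
        d1 = bic(100.0, 9, 270) - bic(90.0, 10, 270)
        d2 = bic(150.0, 9, 270) - bic(140.0, 10, 270)
        assert d1 == pytest.approx(d2)

    @given(st.floats(0, 1e4), st.integers(0, 20), st.integers(1, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_penalty_is_nonnegative(self, g2, f, n):
        assert bic(g2, f, n) >= g2


class TestPermutationTest:
    def test_identical_samples_give_p_one(self, rng):
        assert permutation_pvalue(np.zeros(100), 2000, rng) >= 0.99

    def test_constant_shift_gives_minimal_p(self, rng):
        d = np.full(200, 10.0) + rng.normal(0, 1e-6, 200)
        p = permutation_pvalue(d, 5000, rng)
        assert p <= 1 / 5000 * 2

    def test_null_distribution_is_calibrated(self, rng):
        # Under exchangeable signs the p-value should be roughly uniform.
        ps = [
            permutation_pvalue(rng.normal(0, 1, 50), 500, rng) for _ in range(200)
        ]
        assert 0.35 < np.mean(np.asarray(ps) < 0.5) < 0.65


@pytest.fixture(scope="module")
def small_data(vt_fnmdmc):
    table = mdmc.simulate_experiment(
        vt_fnmdmc, mdmc.nine_conditions("tactile"), 800, "fn-mdmc", 31
    )
    kept, _ = mdmc.filter_rts(table)
    return kept


class TestFitModel:
    def test_fit_initialized_at_truth_does_not_worsen(self, vt_fnmdmc, small_data):
        x0 = fitting.params_to_vector(vt_fnmdmc, "fn-mdmc")
        config = FitConfig(
            n_sim=4000, seed=5, maxfev=60, polish_maxfev=0, initial_vectors=[x0]
        )
        result = mdmc.fit_model(small_data, "fn-mdmc", config)
        crn = CommonRandomNumbers(4000, np.random.SeedSequence(5).spawn(2)[0])
        _, groups = condition_tables(small_data)
        obs, pred = [], []
        for cond, sub in groups.items():
            vec, bins = observed_proportions(sub, cond.name)
            obs.append(vec)
            pred.append(
                predicted_proportions(vt_fnmdmc, cond, bins, "fn-mdmc", crn=crn)
            )
        initial_g2 = g_squared(obs, pred)
        assert result.g2 <= initial_g2
        assert result.n_free == 10
        assert result.bic == pytest.approx(
            result.g2 + 10 * math.log(result.n_total)
        )

    def test_missing_condition_rejected(self, small_data):
        partial = small_data[small_data["visual_congruency"] != "neutral"]
        with pytest.raises(ValueError, match="NV"):
            mdmc.fit_model(partial, "mdmc", FitConfig(n_sim=1000, maxfev=5))

    def test_result_roundtrips_through_dict(self, small_data):
        config = FitConfig(n_starts=1, n_sim=2000, seed=3, maxfev=25, polish_maxfev=0)
        result = mdmc.fit_model(small_data, "mdmc", config)
        doc = result.as_dict()
        assert set(doc["parameters"]) == set(result.parameter_names)
        assert doc["g2"] == result.g2
        assert len(doc["starts"]) == 1

    def test_compare_fit_with_itself_is_null(self, small_data):
        config = FitConfig(n_starts=1, n_sim=2000, seed=3, maxfev=25, polish_maxfev=0)
        result = mdmc.fit_model(small_data, "mdmc", config)
        report = fitting.compare_models(
            result, result, small_data, n_sims=12, n_perms=400,
            rng=1, n_sim_per_condition=2000,
        )
        # Identical models and identical simulation streams: all differences 0.
        assert report["p_g2"] >= 0.99
        assert report["mean_g2"][0] == pytest.approx(report["mean_g2"][1])

    def test_compare_detects_a_clearly_worse_model(self, vt_fnmdmc, small_data):
        good = mdmc.fit_model(
            small_data, "fn-mdmc",
            FitConfig(
                n_sim=2000, seed=3, maxfev=5, polish_maxfev=0,
                initial_vectors=[fitting.params_to_vector(vt_fnmdmc, "fn-mdmc")],
            ),
        )
        bad_params = vt_fnmdmc.with_(mu_r=380.0, mu_rn=380.0)
        bad = mdmc.fit_model(
            small_data, "fn-mdmc",
            FitConfig(
                n_sim=2000, seed=3, maxfev=5, polish_maxfev=0,
                initial_vectors=[fitting.params_to_vector(bad_params, "fn-mdmc")],
            ),
        )
        report = fitting.compare_models(
            good, bad, small_data, n_sims=12, n_perms=2000,
            rng=1, n_sim_per_condition=2000,
        )
        assert report["mean_g2"][0] < report["mean_g2"][1]
        assert report["p_g2"] < 0.05
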