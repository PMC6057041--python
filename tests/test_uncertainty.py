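import numpy as np
import pandas as pd
import pytest

import caremcda as cm
from caremcda.uncertainty import (
    PSAConfig,
    budget_impact,
    renormalize_without,
)

INT, COMP = "integrated_care", "usual_care"


@pytest.fixture(scope="module")
def fitted_beta(truth):
    design = cm.optimize_design(truth.part_worths, n_subdesigns=3, n_sets=6, seed=0)
    data = cm.simulate_dce_responses(design, truth, 300, seed=0)
    return cm.fit_conditional_logit(design, data)


def psa_config(**kw):
    base = dict(n_draws=500, seed=42, population_size=1000,
                budget_grid=(5e6, 7e6, 9e6, 1.2e7))
    base.update(kw)
    return PSAConfig(**base)


class TestExclusionSA:
    def test_recomputation_matches_weighted_sum_oracle(self, example_perf, core_set, example_w):
        res = cm.exclude_criterion_sa(example_perf, core_set, example_w[0], "enjoyment_of_life")
        reduced = core_set.subset([c for c in core_set.ids if c != "enjoyment_of_life"])
        w_r = renormalize_without(example_w[0], "enjoyment_of_life")
        std = cm.standardize_table(example_perf.drop_criterion("enjoyment_of_life"), reduced)
        for alt in (INT, COMP):
            expected = sum(w_r[cid] * std.score(alt, cid) for cid in reduced.ids)
            assert res.without_criterion.value(alt) == pytest.approx(expected, abs=1e-12)

    def test_excluding_dominant_criterion_can_flip_preference(self, example_perf, core_set, example_w):
        # enjoyment of life carries 0.30 of P1's weight and favours the
        # intervention; dropping it narrows the gap
        res = cm.exclude_criterion_sa(example_perf, core_set, example_w[0], "enjoyment_of_life")
        gap_with = res.with_criterion.value(INT) - res.with_criterion.value(COMP)
        gap_without = res.without_criterion.value(INT) - res.without_criterion.value(COMP)
        assert gap_without < gap_with

    def test_zero_weight_criterion_exclusion_is_inert(self, example_perf, core_set):
        w = {cid: 1 / 7 for cid in core_set.ids if cid != "resilience"}
        w["resilience"] = 0.0
        wv = cm.WeightVector(w)
        res = cm.exclude_criterion_sa(example_perf, core_set, wv, "resilience")
        for alt in (INT, COMP):
            assert res.without_criterion.value(alt) == pytest.approx(
                res.with_criterion.value(alt), abs=1e-12
            )

    def test_excluded_criterion_absent_from_breakdown(self, example_perf, core_set, example_w):
        res = cm.exclude_criterion_sa(example_perf, core_set, example_w[0], "resilience")
        assert (INT, "resilience") not in res.without_criterion.contributions

    def test_cannot_reduce_below_two_criteria(self, example_perf, core_set):
        two = core_set.subset(["physical_functioning", "total_costs"])
        w = cm.WeightVector({"physical_functioning": 0.5, "total_costs": 0.5})
        with pytest.raises(ValueError, match="fewer than two"):
            cm.exclude_criterion_sa(example_perf, two, w, "total_costs")


class TestWeightMethodSwap:
    def test_identical_vectors_agree(self, example_perf, core_set, example_w):
        rep = cm.weight_method_swap_sa(example_perf, core_set, example_w[0], example_w[0])
        assert rep.agreement
        assert rep.result_dce.value(INT) == rep.result_swing.value(INT)

    def test_example_weight_sources_disagree(self, example_perf, core_set, example_w):
        rep = cm.weight_method_swap_sa(example_perf, core_set, example_w[0], example_w[1])
        assert rep.preferred_dce == INT
        assert rep.preferred_swing == COMP
        assert not rep.agreement

    def test_report_contains_both_value_pairs(self, example_perf, core_set, example_w):
        rep = cm.weight_method_swap_sa(example_perf, core_set, example_w[0], example_w[1])
        for res in (rep.result_dce, rep.result_swing):
            assert set(res.values) == {INT, COMP}


class TestRunPSA:
    def test_degenerate_distributions_reproduce_deterministic_pipeline(
        self, example_perf, core_set, truth
    ):
        beta = cm.PartWorths(
            core_set.ids, truth.part_worths.coefficients,
            covariance=np.zeros((16, 16)),
        )
        cfg = psa_config(n_draws=50)
        draws = cm.run_psa(example_perf, core_set, cfg, beta=beta)
        w = cm.partworths_to_weights(beta)
        det = cm.score_pipeline(example_perf, core_set, w)
        assert (draws["value_intervention"] == det.value(INT)).all()
        assert (draws["value_comparator"] == det.value(COMP)).all()
        assert (draws["cost_intervention"] == example_perf.mean(INT, "total_costs")).all()

    def test_same_seed_identical_matrix(self, truth, fitted_beta):
        perf = cm.simulate_trial(truth, seed=5)
        cfg = psa_config()
        d1 = cm.run_psa(perf, truth.criteria, cfg, beta=fitted_beta)
        d2 = cm.run_psa(perf, truth.criteria, cfg, beta=fitted_beta)
        pd.testing.assert_frame_equal(d1, d2)

    def test_preference_probability_stable_across_seeds(self, truth, fitted_beta):
        perf = cm.simulate_trial(truth, seed=5)
        n = 10_000
        p = []
        for seed in (101, 202):
            draws = cm.run_psa(perf, truth.criteria, psa_config(n_draws=n, seed=seed),
                               beta=fitted_beta)
            p.append((draws["value_intervention"] > draws["value_comparator"]).mean())
        mc_se = np.sqrt(0.25 / n)
        assert abs(p[0] - p[1]) < 3 * np.sqrt(2) * mc_se

    def test_swing_bootstrap_weight_source(self, truth):
        rankings = cm.simulate_swing_rankings(truth, 40, noise_sd=0.03, seed=8)
        perf = cm.simulate_trial(truth, seed=5)
        draws = cm.run_psa(perf, truth.criteria, psa_config(n_draws=100),
                           swing_rankings=rankings)
        assert len(draws) == 100
        assert draws["value_intervention"].between(0, 1).all()

    def test_requires_exactly_one_weight_source(self, example_perf, core_set, fitted_beta):
        with pytest.raises(ValueError, match="exactly one"):
            cm.run_psa(example_perf, core_set, psa_config())

    def test_non_psd_covariance_rejected(self, example_perf, core_set, truth):
        bad_cov = -np.eye(16)
        beta = cm.PartWorths(core_set.ids, truth.part_worths.coefficients,
                             covariance=bad_cov)
        with pytest.raises(ValueError, match="positive semi-definite"):
            cm.run_psa(example_perf, core_set, psa_config(), beta=beta)


@pytest.fixture(scope="module")
def draws(truth, fitted_beta):
    perf = cm.simulate_trial(truth, seed=5)
    return cm.run_psa(perf, truth.criteria, psa_config(n_draws=2000, seed=9),
                      beta=fitted_beta)


class TestCMAC:
    def test_matches_brute_force_double_loop(self, draws):
        cfg = psa_config(n_draws=2000, seed=9)
        curve = cm.cmac(draws, cfg)
        vi = draws["value_intervention"].to_numpy()
        vc = draws["value_comparator"].to_numpy()
        impact = cfg.population_size * draws["cost_intervention"].to_numpy()
        for b, p in zip(curve.thresholds, curve.probability):
            count = 0
            for i in range(len(vi)):
                if vi[i] > vc[i] and impact[i] <= b:
                    count += 1
            assert p == pytest.approx(count / len(vi), abs=1e-15)

    def test_monotone_and_bounded_by_unconditional(self, draws):
        curve = cm.cmac(draws, psa_config(n_draws=2000, seed=9))
        probs = np.array(curve.probability)
        assert (np.diff(probs) >= 0).all()
        assert (probs <= curve.unconditional_probability + 1e-15).all()

    def test_extreme_thresholds(self, draws):
        cfg = psa_config(n_draws=2000, seed=9)
        impact = budget_impact(draws, cfg)
        below = float(impact.min()) - 1.0
        above = float(impact.max()) + 1.0
        curve = cm.cmac(draws, psa_config(n_draws=2000, seed=9,
                                          budget_grid=(below, above)))
        assert curve.probability[0] == 0.0
        assert curve.probability[1] == curve.unconditional_probability

    def test_incremental_budget_impact_mode(self, draws):
        cfg = psa_config(n_draws=2000, seed=9, budget_impact="incremental")
        incr = budget_impact(draws, cfg)
        expected = cfg.population_size * (
            draws["cost_intervention"] - draws["cost_comparator"]
        )
        assert incr == pytest.approx(expected.to_numpy())

    def test_empty_grid_rejected(self, draws):
        cfg = psa_config(budget_grid=())
        with pytest.raises(ValueError, match="budget grid"):
            cm.cmac(draws, cfg)


class TestPSAConfigValidation:
    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            psa_config(budget_grid=(2.0, 1.0))

    def test_nonpositive_draws_rejected(self):
        with pytest.raises(ValueError, match="n_draws"):
            psa_config(n_draws=0)
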