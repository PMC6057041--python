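import numpy as np
import pytest

import caremcda as cm
from caremcda.dce import (
    ChoiceRecord,
    DCEDesign,
    PartWorths,
    SeparationError,
    _default_blocks,
    code_difference,
    random_design,
    uniform_prior,
    update_priors,
)

ATTRS = cm.build_core_set().ids


class TestCostLevels:
    @pytest.mark.parametrize("mean, exp", [(10000, (12000, 10000, 8000)),
                                           (7000, (8400, 7000, 5600))])
    def test_plus_minus_twenty_percent(self, mean, exp):
        cl = cm.make_cost_levels(mean)
        assert cl.levels == pytest.approx(exp)

    def test_levels_ordered_worst_to_best_by_decreasing_cost(self):
        cl = cm.make_cost_levels(5000)
        assert cl.levels[0] > cl.levels[1] > cl.levels[2]

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cm.make_cost_levels(0)


class TestChoiceProbability:
    def test_zero_coefficients_give_half(self):
        beta = PartWorths(ATTRS, np.zeros(16))
        pair = np.stack([np.zeros(8, int), np.full(8, 2)])
        assert cm.choice_probability(pair, beta) == pytest.approx(0.5)

    def test_overlapped_attributes_cancel(self):
        rng = np.random.default_rng(1)
        beta = PartWorths(ATTRS, rng.normal(size=16))
        pair = np.stack([np.array([2, 1, 0, 0, 0, 0, 0, 0]),
                         np.array([0, 1, 0, 0, 0, 0, 0, 0])])
        # only attribute 0 differs: V difference is its good coefficient
        v = beta.coefficients[1]
        assert cm.choice_probability(pair, beta) == pytest.approx(
            1 / (1 + np.exp(-v))
        )

    def test_unit_utility_difference(self):
        beta = PartWorths(ATTRS, np.r_[[0.0, 1.0], np.zeros(14)])
        pair = np.stack([np.array([2, 0, 0, 0, 0, 0, 0, 0]), np.zeros(8, int)])
        assert cm.choice_probability(pair, beta) == pytest.approx(0.7311, abs=5e-5)

    def test_swap_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        beta = PartWorths(ATTRS, rng.normal(scale=0.8, size=16))
        for _ in range(25):
            pair = rng.integers(0, 3, size=(2, 8))
            p = cm.choice_probability(pair, beta)
            q = cm.choice_probability(pair[::-1], beta)
            assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        beta = PartWorths(ATTRS[:4], np.zeros(8))
        pair = np.zeros((2, 8), int)
        with pytest.raises(ValueError, match="part-worths"):
            cm.choice_probability(pair, beta)


class TestDError:
    def test_fully_overlapped_design_is_singular(self):
        sets = np.stack([np.stack([np.ones(8, int), np.ones(8, int)])] * 6)
        design = DCEDesign(ATTRS, (sets,), _default_blocks(6), overlap_range=(8, 8))
        prior = uniform_prior(ATTRS)
        assert cm.d_error(design, prior) == float("inf")

    def test_duplicating_every_set_halves_d_error(self, small_design, truth):
        doubled = DCEDesign(
            small_design.attribute_ids,
            small_design.sub_designs + small_design.sub_designs,
            small_design.blocks,
            small_design.overlap_range,
        )
        d1 = cm.d_error(small_design, truth.part_worths)
        d2 = cm.d_error(doubled, truth.part_worths)
        assert d2 == pytest.approx(d1 / 2, rel=1e-10)

    def test_invariant_to_alternative_relabelling(self, small_design, truth):
        flipped = DCEDesign(
            small_design.attribute_ids,
            tuple(sd[:, ::-1, :].copy() for sd in small_design.sub_designs),
            small_design.blocks,
            small_design.overlap_range,
        )
        assert cm.d_error(flipped, truth.part_worths) == pytest.approx(
            cm.d_error(small_design, truth.part_worths), rel=1e-12
        )


class TestOptimizeDesign:
    def test_overlap_constraint_satisfied_everywhere(self, small_design):
        for sd in small_design.sub_designs:
            for t in range(sd.shape[0]):
                ov = int((sd[t, 0] == sd[t, 1]).sum())
                assert ov in (4, 5)
                assert ov < 8  # alternatives never identical

    def test_greedy_never_worse_than_random_start(self, truth):
        prior = truth.part_worths
        init = random_design(prior.attribute_ids, 3, 6, seed=11)
        final = cm.optimize_design(prior, n_subdesigns=3, n_sets=6, seed=11)
        assert cm.d_error(final, prior) <= cm.d_error(init, prior)

    def test_deterministic_given_seed(self, truth):
        d1 = cm.optimize_design(truth.part_worths, n_subdesigns=2, n_sets=6, seed=5)
        d2 = cm.optimize_design(truth.part_worths, n_subdesigns=2, n_sets=6, seed=5)
        for a, b in zip(d1.sub_designs, d2.sub_designs):
            assert (a == b).all()


class TestFitConditionalLogit:
    def test_matches_brute_force_grid_mle_on_tiny_instance(self):
        # single attribute -> 2 coefficients; exhaustive grid search oracle
        rng = np.random.default_rng(7)
        # four choice-set types over ONE attribute (2 coefficients)
        pairs = np.array([
            [[1], [0]],
            [[2], [0]],
            [[2], [1]],
            [[0], [2]],
        ])
        design = DCEDesign(("a",), (pairs,), ((0, 1), (2,), (3,)), overlap_range=(0, 0))
        true = PartWorths(("a",), np.array([0.4, 0.9]))
        data = []
        for r in range(10):
            for t in range(4):
                p = cm.choice_probability(pairs[t], true)
                data.append(ChoiceRecord(f"r{r}", "patients", 0, t,
                                         "A" if rng.random() < p else "B"))
        fit = cm.fit_conditional_logit(design, data)

        x = np.array([code_difference(pairs[rec.choice_set_id]) for rec in data])
        y = np.array([1.0 if rec.chosen == "A" else 0.0 for rec in data])

        def ll(b):
            v = x @ b
            return np.sum(y * v - np.logaddexp(0, v))

        grid = np.arange(-2.0, 2.0001, 0.025)
        best, best_ll = None, -np.inf
        for b1 in grid:
            for b2 in grid:
                cand = ll(np.array([b1, b2]))
                if cand > best_ll:
                    best, best_ll = (b1, b2), cand
        fine1 = np.arange(best[0] - 0.05, best[0] + 0.0501, 0.001)
        fine2 = np.arange(best[1] - 0.05, best[1] + 0.0501, 0.001)
        for b1 in fine1:
            for b2 in fine2:
                cand = ll(np.array([b1, b2]))
                if cand > best_ll:
                    best, best_ll = (b1, b2), cand
        assert fit.coefficients == pytest.approx(best, abs=2e-3)

    def test_matches_independent_logistic_mle(self, small_design, truth):
        pytest.importorskip("statsmodels")
        import statsmodels.api as sm
        from caremcda.dce import _stack_choices

        data = cm.simulate_dce_responses(small_design, truth, 150, seed=9)
        fit = cm.fit_conditional_logit(small_design, data)
        x, y = _stack_choices(small_design, data)
        ref = sm.Logit(y, x).fit(disp=0)
        assert fit.coefficients == pytest.approx(ref.params, abs=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_null_truth_yields_small_nonsignificant_coefficients(self, small_design, truth):
        from dataclasses import replace

        null = replace(truth, part_worths=PartWorths(ATTRS, np.zeros(16)))
        data = cm.simulate_dce_responses(small_design, null, 500, seed=3)
        fit = cm.fit_conditional_logit(small_design, data)
        ses = np.sqrt(np.diag(fit.covariance))
        z = np.abs(fit.coefficients) / ses
        assert np.abs(fit.coefficients).max() < 0.15
        # no coefficient significant after Bonferroni over the 16 tests
        assert (z < 3.2).all()

    def test_inestimable_attribute_named(self, truth):
        rng = np.random.default_rng(0)
        # attribute 0 overlapped in every set
        sets = []
        for _ in range(8):
            a = rng.integers(0, 3, 8)
            b = rng.integers(0, 3, 8)
            b[0] = a[0]
            if (a == b).all():
                b[1] = (b[1] + 1) % 3
            sets.append(np.stack([a, b]))
        design = DCEDesign(ATTRS, (np.stack(sets),), ((0, 1, 2, 3), (4, 5), (6, 7)),
                           overlap_range=(0, 8))
        data = [ChoiceRecord(f"r{i}", "patients", 0, t, "A")
                for i in range(5) for t in range(8)]
        with pytest.raises(SeparationError, match="physical_functioning"):
            cm.fit_conditional_logit(design, data)

    def test_rank_deficient_design_rejected(self, truth):
        # 2 x 6 = 12 distinct sets cannot identify 16 coefficients
        tiny = cm.optimize_design(truth.part_worths, n_subdesigns=2, n_sets=6, seed=0)
        data = cm.simulate_dce_responses(tiny, truth, 50, seed=0)
        with pytest.raises(SeparationError, match="rank"):
            cm.fit_conditional_logit(tiny, data)

    def test_covariance_positive_semidefinite(self, small_design, truth):
        data = cm.simulate_dce_responses(small_design, truth, 120, seed=12)
        fit = cm.fit_conditional_logit(small_design, data)
        eigs = np.linalg.eigvalsh(fit.covariance)
        assert (eigs > 0).all()


class TestUpdatePriors:
    def test_below_threshold_is_flagged_noop(self, small_design, truth):
        data = cm.simulate_dce_responses(small_design, truth, 49, seed=1)
        upd = update_priors(small_design, data, threshold=50)
        assert not upd.updated
        assert upd.design is small_design
        assert upd.n_respondents == 49

    def test_at_threshold_refits_and_reoptimizes(self, small_design, truth):
        data = cm.simulate_dce_responses(small_design, truth, 50, seed=1)
        upd = update_priors(small_design, data, threshold=50, seed=2)
        assert upd.updated
        assert upd.n_respondents == 50
        # refit prior is usable and the new design is valid and not worse
        # than the incoming design when judged at the refit prior
        upd.design.validate()
        assert cm.d_error(upd.design, upd.part_worths) <= cm.d_error(
            small_design, upd.part_worths
        ) * (1 + 1e-9)


class TestPartworthsToWeights:
    def test_equal_best_levels_give_uniform_weights(self):
        beta = PartWorths(ATTRS, np.tile([0.3, 0.7], 8))
        w = cm.partworths_to_weights(beta)
        assert all(w[c] == pytest.approx(0.125) for c in ATTRS)
        assert w.method == "dce"

    def test_doubling_one_coefficient_increases_its_weight(self):
        coef = np.tile([0.3, 0.7], 8)
        w0 = cm.partworths_to_weights(PartWorths(ATTRS, coef.copy()))
        coef[1] *= 2
        w1 = cm.partworths_to_weights(PartWorths(ATTRS, coef))
        assert w1[ATTRS[0]] > w0[ATTRS[0]]

    def test_negative_best_level_rejected_with_sign_advice(self):
        coef = np.tile([0.3, 0.7], 8)
        coef[5] = -0.1
        with pytest.raises(ValueError, match="monotone"):
            cm.partworths_to_weights(PartWorths(ATTRS, coef))
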