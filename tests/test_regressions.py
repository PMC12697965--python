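"""Selection and learning-style regressions, pooling, and simple statistics."""

import numpy as np
import pandas as pd
import pytest

from obslearn.regressions import (
    EffectEstimate,
    build_learning_style_design,
    build_selection_design,
    cohens_d,
    fit_mixed_logistic,
    marginal_effects,
    optionwise_glmm,
    pool_effects,
    power_bootstrap,
    simulate_selection,
    ttest_vs_chance,
)


class TestSelectionDesign:
    def test_codings(self, small_study):
        dataset, _ = small_study
        frame = build_selection_design(dataset, "model2")
        for p in dataset.participants:
            for b in p.blocks:
                row = frame.query("participant_id == @p.participant_id and block_id == @b.block_id").iloc[0]
                high = next(ph for ph in b.passive if ph.noise == "high")
                left = next(ph for ph in b.passive if ph.side == "left")
                assert row["Y"] == int(b.selected_side == "left")
                assert row["X1"] == (1 if high.side == "left" else -1)
                assert row["X2"] == (1 if left.order == 1 else -1)

    def test_one_row_per_block(self, small_study, small_design):
        dataset, _ = small_study
        frame = build_selection_design(dataset, "model1")
        assert len(frame) == len(dataset) * small_design.n_blocks

    def test_selection_consistency(self, small_study):
        # Y=1 with high-noise on the left implies the high-noise partner was chosen
        dataset, _ = small_study
        frame = build_selection_design(dataset, "model1")
        chose_high = {
            (p.participant_id, b.block_id): b.selected_partner == "high"
            for p in dataset.participants for b in p.blocks
        }
        for _, row in frame.iterrows():
            expected = (row["Y"] == 1) == (row["X1"] == 1)
            assert chose_high[(row["participant_id"], row["block_id"])] == expected


class TestLearningStyleDesign:
    def test_reward_code_zero_iff_unrewarded(self, small_study):
        dataset, _ = small_study
        designs = build_learning_style_design(dataset, "P")
        for option, f in designs.items():
            trials = [
                t for p in dataset.participants for b in p.blocks for t in b.observational_trials
            ]
            rewards = np.array([t.partner_reward for t in trials])
            assert ((f["R"].to_numpy() == 0) == (rewards == 0)).all()

    def test_each_trial_appears_in_all_three_designs(self, small_study, small_design):
        dataset, _ = small_study
        designs = build_learning_style_design(dataset, "P")
        n_trials = len(dataset) * small_design.n_blocks * 60
        assert all(len(f) == n_trials for f in designs.values())
        # exactly one of the three outcomes is 1 on each trial
        total = sum(f["Y"].to_numpy() for f in designs.values())
        assert (total == 1).all()

    def test_within_moderator_restricts_to_mixed_selectors(self, small_study):
        dataset, _ = small_study
        designs = build_learning_style_design(dataset, "D")
        eligible = {
            p.participant_id
            for p in dataset.participants
            if {b.selected_partner for b in p.blocks} == {"high", "low"}
        }
        assert set(designs[0]["participant_id"]) == eligible


class TestMixedLogistic:
    def test_recovers_negative_noise_effect(self, rng):
        """Simulations with a true negative noise coefficient recover a
        negative estimate in >= 95% of 20 replicates."""
        hits = 0
        for _ in range(20):
            sim = simulate_selection(40, 4, intercept=0.0, noise_effect=-1.0,
                                     sd_intercept=0.5, sd_slope=0.5, rng=rng)
            fit = fit_mixed_logistic(sim, "Y", ["X1"], engine="glm")
            hits += fit.effect("X1").estimate < 0
        assert hits >= 19

    def test_permuted_regressor_has_null_effect(self, rng):
        sim = simulate_selection(60, 4, intercept=0.0, noise_effect=-1.0,
                                 sd_intercept=0.5, sd_slope=0.5, rng=rng)
        sim["X1"] = rng.permutation(sim["X1"].to_numpy())
        fit = fit_mixed_logistic(sim, "Y", ["X1"], engine="glm")
        e = fit.effect("X1")
        assert abs(e.estimate) < 3 * e.se

    def test_symmetric_data_has_null_intercept(self, rng):
        sim = simulate_selection(60, 4, intercept=0.0, noise_effect=0.0,
                                 sd_intercept=0.0, sd_slope=0.0, rng=rng)
        fit = fit_mixed_logistic(sim, "Y", [], random_slopes=[], engine="glm")
        e = fit.effect("intercept")
        assert abs(e.estimate) < 3 * e.se

    def test_single_participant_rejected(self):
        frame = pd.DataFrame({"participant_id": ["a"] * 4, "Y": [0, 1, 0, 1], "X1": [1, -1, 1, -1]})
        with pytest.raises(ValueError):
            fit_mixed_logistic(frame, "Y", ["X1"])


class TestOptionwise:
    def test_imitators_show_action_over_reward_effect(self, rng):
        """Data generated with w_A = 0.9 yields pooled C > pooled R; with
        w_A = 0 the reward effect dominates and C is near zero."""
        from obslearn.obs_models import LearnerParams
        from obslearn.synthetic_data import StudyDesign, generate_study

        def study(w_a, seed):
            design = StudyDesign(n_participants=12, n_blocks=2, seed=seed)
            fn = lambda i, r: LearnerParams(0.4, 0.4, w_a, 8.0)
            return generate_study(design, "full", params_fn=fn)[0]

        ow_imit = optionwise_glmm(study(0.9, 31), "P", engine="glm")
        assert ow_imit.pooled_effect("C").estimate > ow_imit.pooled_effect("R").estimate
        ow_reward = optionwise_glmm(study(0.0, 32), "P", engine="glm")
        c, r = ow_reward.pooled_effect("C"), ow_reward.pooled_effect("R")
        assert r.estimate > 0
        assert abs(c.estimate) < r.estimate


class TestPooling:
    def test_hand_computed_inverse_variance_weights(self):
        effects = [
            EffectEstimate("b", 1.0, 0.1, 10.0, 10, 0.0, "glm"),
            EffectEstimate("b", 2.0, 0.2, 10.0, 10, 0.0, "glm"),
        ]
        pooled = pool_effects(effects)
        assert pooled.estimate == pytest.approx(1.2)
        assert pooled.se == pytest.approx(np.sqrt(1 / 125), abs=1e-10)

    def test_identical_effects_and_order_invariance(self):
        e = [EffectEstimate("b", 0.5, 0.3, 1.7, 10, 0.1, "glm") for _ in range(3)]
        pooled = pool_effects(e)
        assert pooled.estimate == pytest.approx(0.5)
        assert pooled.se == pytest.approx(0.3 / np.sqrt(3))
        shuffled = pool_effects([e[2], e[0], e[1]])
        assert shuffled.estimate == pooled.estimate and shuffled.se == pooled.se

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            pool_effects([EffectEstimate("b", 1.0, 0.0, 0.0, 10, 1.0, "glm")])


class TestMarginalEffects:
    @pytest.fixture()
    def style_fit(self, small_study):
        dataset, _ = small_study
        return optionwise_glmm(dataset, "P", engine="glm").per_option[0]

    def test_zero_moderator_recovers_main_effect(self, style_fit):
        me = marginal_effects(style_fit, "C", "C:M", [0.0])
        assert me["slope"][0] == pytest.approx(style_fit.effect("C").estimate)
        assert me["se"][0] == pytest.approx(style_fit.effect("C").se)

    def test_slopes_average_to_main_effect(self, style_fit):
        me = marginal_effects(style_fit, "C", "C:M", [-0.5, 0.5])
        assert me["slope"].mean() == pytest.approx(style_fit.effect("C").estimate)


class TestSimpleStats:
    def test_cohens_d_identical_groups_error_free_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_cohens_d_hand_value_and_antisymmetry(self):
        d = cohens_d([0.0, 1.0], [1.0, 2.0])
        assert d == pytest.approx(-np.sqrt(2))
        assert cohens_d([1.0, 2.0], [0.0, 1.0]) == pytest.approx(np.sqrt(2))

    def test_cohens_d_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_ttest_at_chance_is_zero(self):
        t, df, p = ttest_vs_chance([1 / 3, 1 / 3, 1 / 3, 1 / 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_ttest_hand_value(self):
        t, df, p = ttest_vs_chance([0.5, 0.6, 0.7])
        assert t == pytest.approx((0.6 - 1 / 3) / (0.1 / np.sqrt(3)), abs=1e-6)
        assert df == 2

    def test_ttest_sign_symmetry(self):
        props = np.array([0.4, 0.5, 0.45])
        mirrored = 2 / 3 - props  # reflect deviations around chance
        t1, _, p1 = ttest_vs_chance(props)
        t2, _, p2 = ttest_vs_chance(mirrored)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)


class TestPower:
    def _fit(self, rng, effect):
        sim = simulate_selection(40, 4, 0.0, effect, 0.4, 0.3, rng)
        return fit_mixed_logistic(sim, "Y", ["X1"], engine="glm")

    def test_single_bootstrap_is_binary(self, rng):
        fit = self._fit(rng, -1.0)
        power = power_bootstrap(fit, [20], n_boot=1, seed=2)
        assert power["power"][0] in (0.0, 1.0)

    def test_null_effect_power_near_alpha(self, rng):
        fit = self._fit(rng, -1.0)
        null_fit = fit
        # rebuild a null generator: same fit object but zeroed X1 effect
        null = pd.DataFrame()
        effects = [
            EffectEstimate("intercept", 0.0, 0.1, 0, 40, 1.0, "glm"),
            EffectEstimate("X1", 0.0, 0.1, 0, 40, 1.0, "glm"),
        ]
        from obslearn.regressions import LogisticFit

        null_fit = LogisticFit(["intercept", "X1"], np.zeros(2), np.eye(2), 40, "glm", effects)
        power = power_bootstrap(null_fit, [40], n_boot=150, seed=3)
        assert abs(power["power"][0] - 0.05) < 0.06

    def test_power_nondecreasing_in_n(self, rng):
        fit = self._fit(rng, -1.2)
        power = power_bootstrap(fit, [8, 30, 80], n_boot=80, seed=4)
        p = power["power"].to_numpy()
        assert p[2] >= p[0] - 0.1  # monotone up to Monte-Carlo tolerance
        assert p[2] > 0.5
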