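"""Sequential Bayes updating: likelihoods, Bayes factors, and both update modes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bnpower as bp
from bnpower.updater import LikelihoodTable, _prior_vector

PRIOR = {"none": 0.50, "medium": 0.25, "strong": 0.25}


def flat_table(rows):
    """Hand-built likelihood table over two outcomes for unit checks."""
    return LikelihoodTable(
        r_states=("none", "medium", "strong"),
        outcomes=("o1", "o2"),
        acem="high",
        acrm="high",
        probs=np.array(rows),
    )


class TestOutcomeLikelihoods:
    def test_perfect_accuracy_values(self, net):
        lik = bp.outcome_likelihoods(net, "perfect", "perfect")
        # P(ll | strong) = P(TE=low) P(TR=low | low, strong) = (1/3) 0.90
        assert lik.prob("ll", "strong") == pytest.approx(0.30, abs=1e-9)
        assert lik.prob("ll", "none") == pytest.approx(1 / 9, abs=1e-9)
        assert lik.prob("ll", "medium") == pytest.approx(0.20, abs=1e-9)

    @pytest.mark.parametrize("acc", ["low", "high", "perfect"])
    def test_rows_are_distributions(self, net, acc):
        lik = bp.outcome_likelihoods(net, acc, acc)
        assert np.allclose(lik.probs.sum(axis=1), 1.0, atol=1e-9)
        assert (lik.probs >= 0).all()

    def test_matches_direct_evidence_inference(self, net, oracle_marginal):
        # P(outcome | R, accuracies) from the enumeration oracle, per outcome
        lik = bp.outcome_likelihoods(net, "high", "low")
        for r in lik.r_states:
            expected = oracle_marginal(
                "ERMatch", {"R": r, "AcEM": "high", "AcRM": "low"}
            )
            for j, o in enumerate(lik.outcomes):
                assert lik.probs[lik.r_states.index(r), j] == pytest.approx(
                    expected[o], abs=1e-9
                )


class TestBayesFactor:
    def test_hand_computed_value(self, net):
        lik = bp.outcome_likelihoods(net, "perfect", "perfect")
        bf = bp.bayes_factor(lik, "ll", "strong", PRIOR)
        # 0.30 / [(0.50/0.75) (1/9) + (0.25/0.75) 0.20]
        assert bf == pytest.approx(2.1316, abs=5e-5)

    def test_equal_likelihoods_give_unit_factor(self):
        lik = flat_table([[0.4, 0.6]] * 3)
        for r in lik.r_states:
            assert bp.bayes_factor(lik, "o1", r, PRIOR) == pytest.approx(1.0)

    def test_exceeds_one_iff_likelihood_beats_complement(self):
        lik = flat_table([[0.7, 0.3], [0.2, 0.8], [0.2, 0.8]])
        assert bp.bayes_factor(lik, "o1", "none", PRIOR) > 1.0
        assert bp.bayes_factor(lik, "o1", "medium", PRIOR) < 1.0

    def test_point_mass_prior_rejected(self):
        lik = flat_table([[0.5, 0.5]] * 3)
        with pytest.raises(ValueError, match="complement"):
            bp.bayes_factor(lik, "o1", "none", {"none": 1.0, "medium": 0.0, "strong": 0.0})

    def test_impossible_under_complement_raises(self):
        lik = flat_table([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        with pytest.raises(bp.InconsistentOutcomeError):
            bp.bayes_factor(lik, "o1", "none", PRIOR)


class TestUpdatePosterior:
    def test_single_ll_case_hand_values(self, net):
        lik = bp.outcome_likelihoods(net, "perfect", "perfect")
        post = bp.update_posterior(PRIOR, lik, "ll")
        assert post["none"] == pytest.approx(0.3077, abs=5e-5)
        assert post["medium"] == pytest.approx(0.2769, abs=5e-5)
        assert post["strong"] == pytest.approx(0.4154, abs=5e-5)

    def test_single_case_matches_evidence_inference(self, net, oracle_marginal):
        # the one-case posterior is P(R | ERMatch=ll, accuracies) in the joint
        lik = bp.outcome_likelihoods(net, "perfect", "perfect")
        post = bp.update_posterior(PRIOR, lik, "ll")
        expected = oracle_marginal(
            "R", {"ERMatch": "ll", "AcEM": "perfect", "AcRM": "perfect"}
        )
        for r in post:
            assert post[r] == pytest.approx(expected[r], abs=1e-9)

    def test_uniform_likelihood_outcome_preserves_prior(self):
        lik = flat_table([[0.4, 0.6]] * 3)
        for mode in bp.updater.MODES:
            post = bp.update_posterior(PRIOR, lik, "o1", mode=mode)
            for r in PRIOR:
                assert post[r] == pytest.approx(PRIOR[r], abs=1e-12)

    def test_point_mass_prior_is_fixed_point(self, net):
        lik = bp.outcome_likelihoods(net, "high", "high")
        point = {"none": 0.0, "medium": 0.0, "strong": 1.0}
        post = bp.update_posterior(point, lik, "mm")
        assert post == point

    def test_zero_likelihood_everywhere_raises(self):
        lik = flat_table([[1.0, 0.0]] * 3)
        with pytest.raises(bp.InconsistentOutcomeError):
            bp.update_posterior(PRIOR, lik, "o2")

    def test_unknown_mode_rejected(self, net):
        lik = bp.outcome_likelihoods(net, "low", "low")
        with pytest.raises(ValueError, match="mode"):
            bp.update_posterior(PRIOR, lik, "ll", mode="genie")

    @settings(derandomize=True, max_examples=40)
    @given(
        weights=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        outcome=st.sampled_from(["ll", "lm", "mm", "hh"]),
        acc=st.sampled_from(["low", "high"]),
    )
    def test_exact_mode_is_bayes_rule(self, weights, outcome, acc):
        net = bp.default_network()
        lik = bp.outcome_likelihoods(net, acc, acc)
        total = sum(weights)
        prior = dict(zip(lik.r_states, (w / total for w in weights)))
        post = bp.update_posterior(prior, lik, outcome)
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)
        o = lik.outcomes.index(outcome)
        unnorm = [prior[r] * lik.probs[i, o] for i, r in enumerate(lik.r_states)]
        for i, r in enumerate(lik.r_states):
            assert post[r] == pytest.approx(unnorm[i] / sum(unnorm), abs=1e-9)


class TestTrajectories:
    def test_empty_prefix_is_prior(self, net):
        dataset = bp.generate_dataset(net, bp.scenario_by_id(5), 10, seed=1)
        traj = bp.run_trajectory(net, dataset)
        assert traj.posterior_after(0) == bp.infer_marginal(net, "R")
        assert len(traj) == 10

    def test_sequential_equals_fold_of_single_updates(self, net):
        sc = bp.scenario_by_id(8)
        dataset = bp.generate_dataset(net, sc, 30, seed=9)
        lik = bp.outcome_likelihoods(net, sc.acem, sc.acrm)
        traj = bp.run_trajectory(net, dataset)
        post = bp.infer_marginal(net, "R")
        for i, case in enumerate(dataset.cases, start=1):
            post = bp.update_posterior(post, lik, case.match)
            for r in post:
                assert traj.posterior_after(i)[r] == pytest.approx(post[r], abs=1e-9)

    def test_sequential_matches_batch_over_scenarios(self, net):
        # conditional independence given R and the clamped accuracies
        rng = np.random.default_rng(2024)
        for k in range(50):
            sc = bp.scenario_by_id(k % 9 + 1)
            n = int(rng.integers(1, 150))
            dataset = bp.generate_dataset(net, sc, n, seed=int(rng.integers(2**31)))
            final = bp.run_trajectory(net, dataset).final
            batch = bp.batch_posterior(
                net, bp.outcome_frequencies(dataset), acem=sc.acem, acrm=sc.acrm
            )
            for r in final:
                assert final[r] == pytest.approx(batch[r], abs=1e-9)

    def test_final_posterior_order_invariant(self, net):
        dataset = bp.generate_dataset(net, bp.scenario_by_id(4), 120, seed=3)
        permuted = dataset.permuted(np.random.default_rng(0).permutation(120))
        a = bp.run_trajectory(net, dataset).final
        b = bp.run_trajectory(net, permuted).final
        for r in a:
            assert a[r] == pytest.approx(b[r], abs=1e-9)

    def test_long_trajectory_stays_normalized(self, net):
        dataset = bp.generate_dataset(net, bp.scenario_by_id(4), 10_000, seed=13)
        traj = bp.run_trajectory(net, dataset)
        assert np.allclose(traj.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.isfinite(traj.probs).all()

    def test_empty_dataset_rejected(self, net):
        from bnpower.simulate import Dataset

        with pytest.raises(ValueError, match="empty"):
            bp.run_trajectory(net, Dataset(bp.scenario_by_id(1), 0, ()))

    def test_fixed_bf_mode_divergence_pinned(self, net):
        # frozen-BF odds updating drifts once the complement weights shift;
        # magnitude pinned on a fixed seeded study (medium truth, high-high)
        dataset = bp.generate_dataset(
            net, bp.scenario_by_id(5), 200, seed=bp.DEFAULT_BASE_SEED + 1
        )
        exact = bp.run_trajectory(net, dataset, mode="exact")
        frozen = bp.run_trajectory(net, dataset, mode="fixed-bf")
        gap = np.abs(exact.probs - frozen.probs)
        assert gap[0].max() < 1e-12  # first update: BFs are exact at the prior
        assert gap.max() == pytest.approx(0.2791700101, abs=1e-6)
        assert np.abs(exact.probs[-1] - frozen.probs[-1]).max() == pytest.approx(
            0.0624281468, abs=1e-6
        )


class TestBatchPosterior:
    def test_zero_counts_return_prior(self, net):
        post = bp.batch_posterior(net, {}, acem="low", acrm="low")
        prior = bp.infer_marginal(net, "R")
        for r in post:
            assert post[r] == pytest.approx(prior[r], abs=1e-12)

    def test_single_count_reproduces_single_update(self, net):
        lik = bp.outcome_likelihoods(net, "high", "high")
        single = bp.update_posterior(PRIOR, lik, "hm")
        batch = bp.batch_posterior(net, {"hm": 1}, PRIOR, acem="high", acrm="high")
        for r in single:
            assert batch[r] == pytest.approx(single[r], abs=1e-12)
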