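"""Path likelihoods, propagators, and exact Monte-Carlo information."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trajinfo import (
    ContinuousTrajectory,
    InputEnsemble,
    PathLikelihoodModel,
    RateSchedule,
    Reaction,
    ReactionNetwork,
    StateSpace,
    discrete_propagator,
    exact_info,
    make_example,
)
from trajinfo.exact import LOG2E, _prior_logsumexp

LABELS = ("u1", "u2")


def birth_death(alphas, betas):
    return ReactionNetwork(
        ["X"],
        [
            Reaction((0,), (1,), {l: RateSchedule.constant(a) for l, a in zip(LABELS, alphas)}),
            Reaction((1,), (0,), {l: RateSchedule.constant(b) for l, b in zip(LABELS, betas)}),
        ],
    )


@pytest.fixture(scope="module")
def example1_model():
    net, ens, x0 = make_example(1)
    return PathLikelihoodModel(net, ens, x0, 10.0)


class TestContinuousLikelihood:
    def test_pure_survival_term(self, example1_model):
        tr = ContinuousTrajectory("u1", [[0]], [10.0], 10.0)
        assert example1_model.loglik_continuous(tr, "u1") == pytest.approx(
            -0.1 * 10.0 * LOG2E
        )

    def test_one_jump_path_hand_evaluation(self, example1_model):
        # survive at 0 for 5 (rate 0.1 out), jump up (rate 0.1), survive at 1
        # for 5 (rate 0.1 + 0.01 out)
        tr = ContinuousTrajectory("u1", [[0], [1]], [5.0, 5.0], 10.0)
        expected = (-0.1 * 5 - 0.11 * 5) * LOG2E + np.log2(0.1)
        assert example1_model.loglik_continuous(tr, "u1") == pytest.approx(expected)

    def test_impossible_transition_is_minus_inf(self):
        net = birth_death((0.1, 0.0), (0.01, 0.01))  # u2 cannot produce
        model = PathLikelihoodModel(net, InputEnsemble(list(LABELS)), 0, 10.0)
        tr = ContinuousTrajectory("u1", [[0], [1]], [5.0, 5.0], 10.0)
        assert model.loglik_continuous(tr, "u2") == -np.inf
        assert np.isfinite(model.loglik_continuous(tr, "u1"))

    def test_dwell_spanning_breakpoint_splits_survival(self):
        net, ens, x0 = make_example(2)
        model = PathLikelihoodModel(net, ens, x0, 1500.0)
        tr = ContinuousTrajectory("u1", [[0]], [1500.0], 1500.0)
        # survival out of 0: rate 0.1 before t=1000, 5e-4 after
        expected = (-0.1 * 1000.0 - 5e-4 * 500.0) * LOG2E
        assert model.loglik_continuous(tr, "u1") == pytest.approx(expected)


class TestPropagator:
    def test_zero_dt_is_identity(self):
        M = np.array([[-0.3, 0.2], [0.3, -0.2]])
        assert np.allclose(discrete_propagator(M, 0.0), np.eye(2))

    def test_pure_death_closed_form(self):
        net = ReactionNetwork(
            ["X"],
            [Reaction((1,), (0,), {l: RateSchedule.constant(0.3) for l in LABELS})],
        )
        model = PathLikelihoodModel(
            net, InputEnsemble(list(LABELS)), 1, 2.0, space=StateSpace.single_species(1)
        )
        W = 2.0 ** model.step_log_propagators("u1", 1)[0]
        assert W[1, 1] == pytest.approx(np.exp(-0.3 * 2.0))
        assert W[0, 1] == pytest.approx(1 - np.exp(-0.3 * 2.0))

    def test_columns_stochastic_up_to_leak(self, examples):
        for ex, (net, ens, x0, model) in examples.items():
            W = 2.0 ** model.step_log_propagators("u1", 100)[0]
            # states with non-negligible occupancy sit well inside the cap
            interior = np.arange(0, 30)
            assert np.all(W[:, interior].sum(axis=0) <= 1.0 + 1e-12)
            assert np.all(W[:, interior].sum(axis=0) >= 1.0 - 1e-8)


class TestDiscreteLikelihood:
    def test_single_step_normalizes(self, example1_model):
        total = sum(
            2.0 ** example1_model.loglik_discrete([s], "u1")
            for s in range(example1_model.space.n_states)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_d_factors_from_known_x0(self, example1_model):
        # a d=1 sample contributes exactly one propagator factor from x0
        logW = example1_model.step_log_propagators("u1", 1)[0]
        x0_idx = example1_model.space.index_of([0])
        assert example1_model.loglik_discrete([4], "u1") == pytest.approx(
            logW[4, x0_idx]
        )

    def test_fine_grid_map_decisions_match_continuous(self, small_datasets, examples):
        # at dt = 1 the discrete likelihood ranking converges to continuous
        from trajinfo.decoding import map_decode
        from trajinfo.simulate import discrete_matrix

        net, ens, x0, model = examples[1]
        paths = small_datasets[1]
        cont = [map_decode(tr, model, "continuous").decoded_label for tr in paths]
        X, _, labels = discrete_matrix(paths, 2000)
        cond = np.column_stack(
            [model.loglik_discrete_matrix(X, lab) for lab in ens.labels]
        )
        disc = [ens.labels[j] for j in np.argmax(cond, axis=1)]
        agree = np.mean([c == d for c, d in zip(cont, disc)])
        assert agree >= 0.99


class TestMarginal:
    def test_degenerate_prior_reduces_to_conditional(self, example1_model):
        tr = ContinuousTrajectory("u1", [[0]], [10.0], 10.0)
        net, ens, x0 = make_example(1)
        model = PathLikelihoodModel(net, InputEnsemble(["u1", "u2"], [1.0, 0.0]), 0, 10.0)
        assert model.marginal_loglik(tr) == pytest.approx(
            model.loglik_continuous(tr, "u1")
        )

    def test_equal_conditionals_pass_through(self):
        assert _prior_logsumexp(np.array([-7.0, -7.0]), np.array([0.5, 0.5])) == pytest.approx(-7.0)

    def test_log_sum_exp_hand_value(self):
        out = _prior_logsumexp(np.array([-10.0, -20.0]), np.array([0.5, 0.5]))
        assert out == pytest.approx(np.log2(0.5 * (2.0**-10 + 2.0**-20)))

    def test_all_minus_inf_stays_minus_inf(self):
        assert _prior_logsumexp(np.array([-np.inf, -np.inf]), np.array([0.5, 0.5])) == -np.inf

    @given(
        st.lists(st.floats(-50, 0), min_size=2, max_size=5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_direct_mixture(self, lls):
        lls = np.array(lls)
        prior = np.full(len(lls), 1.0 / len(lls))
        direct = np.log2(np.sum(prior * 2.0**lls))
        assert _prior_logsumexp(lls, prior) == pytest.approx(direct, abs=1e-9)


class TestExactInfo:
    def test_identical_channels_carry_zero_bits(self):
        net = birth_death((0.1, 0.1), (0.01, 0.01))
        ens = InputEnsemble(list(LABELS))
        model = PathLikelihoodModel(net, ens, 0, 500.0)
        from trajinfo.simulate import simulate_dataset

        data = simulate_dataset(net, ens.labels, 0, 500.0, 100, seed=21)
        info = exact_info(model, data, mode="continuous")
        assert abs(info) < 0.05

    def test_discrete_below_continuous_and_monotone_in_d(self, small_datasets, examples):
        for ex in (1, 2, 3):
            _, _, _, model = examples[ex]
            cont = exact_info(model, small_datasets[ex], mode="continuous")
            vals = [
                exact_info(model, small_datasets[ex], mode="discrete", d=d)
                for d in (10, 50, 100, 500)
            ]
            slack = 0.05  # Monte-Carlo error at N=150 per input
            assert all(v <= cont + slack for v in vals)
            assert all(b >= a - slack for a, b in zip(vals, vals[1:]))

    def test_information_within_entropy_budget(self, small_datasets, examples):
        for ex in (1, 2, 3):
            _, _, _, model = examples[ex]
            info = exact_info(model, small_datasets[ex], mode="continuous")
            assert -0.05 <= info <= 1.0 + 0.05

    def test_label_missing_from_ensemble_rejected(self, examples):
        net, ens, x0, model = examples[1]
        bad = ContinuousTrajectory("nope", [[0]], [2000.0], 2000.0)
        with pytest.raises(ValueError):
            exact_info(model, [bad], mode="continuous")
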