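import numpy as np
import pytest

from atrcn import (
    NetworkSpec,
    TrainingConfig,
    concordance_index,
    cox_loss,
    cox_loss_gradient,
    cross_validate_hyperparams,
    forward_risk,
    init_network,
    train_network,
)

from conftest import make_survival, random_survival


def brute_force_cox_loss(scores, times, events):
    """Oracle: explicit double loop over events and their risk sets."""
    total = 0.0
    for i in range(len(times)):
        if events[i]:
            risk_set = [j for j in range(len(times)) if times[j] >= times[i]]
            total -= scores[i] - np.log(np.sum(np.exp(np.asarray(scores)[risk_set])))
    return total


# ---------------------------------------------------------------------------
# network construction and forward pass
# ---------------------------------------------------------------------------

def test_default_architecture_shapes():
    net = init_network(NetworkSpec(input_dim=100), seed=0)
    assert [w.shape for w in net.weights] == [(100, 50), (50, 20), (20, 10), (10, 1)]
    assert [b.shape for b in net.biases] == [(50,), (20,), (10,), (1,)]


def test_init_reproducible():
    a = init_network(NetworkSpec(7), seed=3)
    b = init_network(NetworkSpec(7), seed=3)
    for wa, wb in zip(a.weights, b.weights):
        np.testing.assert_array_equal(wa, wb)


def test_empty_hidden_stack_is_linear_model(rng):
    net = init_network(NetworkSpec(4, hidden_dims=()), seed=0)
    x = rng.normal(size=(6, 4))
    expected = x @ net.weights[0][:, 0] + net.biases[0][0]
    np.testing.assert_allclose(forward_risk(net, x).score, expected)


def test_forward_matches_hand_computed_relu_composition():
    net = init_network(NetworkSpec(2, hidden_dims=(2,)), seed=0)
    net.weights[0] = np.array([[1.0, -1.0], [0.5, 2.0]])
    net.biases[0] = np.array([0.0, 1.0])
    net.weights[1] = np.array([[2.0], [-1.0]])
    net.biases[1] = np.array([0.5])
    x = np.array([[1.0, 2.0], [-1.0, 0.0]])
    # hand: h1 = relu(x @ W0 + b0); out = h1 @ W1 + b1
    h1 = np.maximum(x @ net.weights[0] + net.biases[0], 0)
    expected = (h1 @ net.weights[1] + net.biases[1])[:, 0]
    np.testing.assert_allclose(forward_risk(net, x).score, expected)
    np.testing.assert_allclose(expected, [4.5 - 4.0, 0.5 - 2.0])


def test_zero_weights_score_zero():
    net = init_network(NetworkSpec(3, hidden_dims=(2,)), seed=0)
    for w in net.weights:
        w[:] = 0.0
    assert (forward_risk(net, np.ones((4, 3))).score == 0).all()


def test_sample_permutation_equivariance(rng):
    net = init_network(NetworkSpec(5), seed=1)
    x = rng.normal(size=(8, 5))
    perm = rng.permutation(8)
    np.testing.assert_allclose(
        forward_risk(net, x[perm]).score, forward_risk(net, x).score[perm]
    )


def test_dimension_mismatch_rejected(rng):
    net = init_network(NetworkSpec(5), seed=0)
    with pytest.raises(ValueError):
        forward_risk(net, rng.normal(size=(3, 4)))


# ---------------------------------------------------------------------------
# partial likelihood loss
# ---------------------------------------------------------------------------

def test_single_event_loss_is_zero():
    s = make_survival([5.0], [1])
    assert cox_loss(np.array([1.7]), s) == pytest.approx(0.0)


def test_two_equal_scores_loss_is_ln2():
    s = make_survival([1.0, 2.0], [1, 1])
    assert cox_loss(np.array([0.3, 0.3]), s) == pytest.approx(np.log(2.0))


def test_loss_matches_brute_force_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(2, 21))
        t = np.round(rng.exponential(5.0, n), 1) + 0.1  # rounding makes ties
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        sc = rng.normal(0, 2, n)
        s = make_survival(t, e)
        assert cox_loss(sc, s) == pytest.approx(
            brute_force_cox_loss(sc, t, e), abs=1e-10
        )


def test_loss_shift_invariance(rng):
    s = random_survival(rng, 15)
    sc = rng.normal(size=15)
    assert cox_loss(sc + 123.456, s) == pytest.approx(cox_loss(sc, s), abs=1e-9)


def test_no_events_error_and_flag():
    s = make_survival([1.0, 2.0], [0, 0])
    with pytest.raises(ValueError):
        cox_loss(np.zeros(2), s)
    assert cox_loss(np.zeros(2), s, allow_no_events=True) == 0.0


def test_gradient_matches_central_differences(rng):
    for _ in range(20):
        n = int(rng.integers(3, 12))
        s = random_survival(rng, n)
        sc = rng.normal(0, 1.5, n)
        grad = cox_loss_gradient(sc, s)
        h = 1e-6
        for k in range(n):
            d = np.zeros(n)
            d[k] = h
            num = (cox_loss(sc + d, s) - cox_loss(sc - d, s)) / (2 * h)
            assert grad[k] == pytest.approx(num, abs=1e-5)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _separable_problem(rng, n=200):
    x = rng.normal(size=(n, 3))
    h = 8.0 * x[:, 0]  # risk driven by one feature
    t = rng.exponential(1.0 / np.exp(h)) + 1e-9
    return x, make_survival(t, np.ones(n, int))


def test_training_learns_separable_risk(rng):
    x, s = _separable_problem(rng)
    assert concordance_index(x[:, 0], s) > 0.9  # generating feature is concordant
    net = init_network(NetworkSpec(3, hidden_dims=(8,)), seed=0)
    fitted = train_network(net, x, s, TrainingConfig(0.01, 200, seed=0))
    assert concordance_index(forward_risk(fitted, x), s) > 0.9
    trace = fitted.loss_trace
    assert trace[-1] < trace[0]


def test_zero_epochs_is_identity(rng):
    x, s = _separable_problem(rng, n=20)
    net = init_network(NetworkSpec(3), seed=0)
    out = train_network(net, x, s, TrainingConfig(0.01, 0, seed=0))
    for w0, w1 in zip(net.weights, out.weights):
        np.testing.assert_array_equal(w0, w1)


def test_training_deterministic(rng):
    x, s = _separable_problem(rng, n=50)
    cfg = TrainingConfig(0.005, 30, seed=9)
    a = train_network(init_network(NetworkSpec(3), seed=9), x, s, cfg)
    b = train_network(init_network(NetworkSpec(3), seed=9), x, s, cfg)
    for wa, wb in zip(a.weights, b.weights):
        np.testing.assert_array_equal(wa, wb)


def test_linear_model_recovers_coefficient_direction():
    """Linear Cox (no hidden layers) on proportional-hazards data aligns
    with the generating coefficients (small-n version of the recovery
    property checked at full scale in the acceptance suite)."""
    rng = np.random.default_rng(5)
    n, p = 800, 5
    beta = rng.normal(size=p)
    beta /= np.linalg.norm(beta)
    x = rng.normal(size=(n, p))
    t = rng.exponential(1.0 / np.exp(x @ beta)) + 1e-9
    s = make_survival(t, np.ones(n, int))
    net = init_network(NetworkSpec(p, hidden_dims=()), seed=0)
    fitted = train_network(net, x, s, TrainingConfig(0.01, 300, seed=0))
    w = fitted.weights[0][:, 0]
    cosine = float(w @ beta / np.linalg.norm(w))
    assert cosine >= 0.9


# ---------------------------------------------------------------------------
# hyperparameter cross-validation
# ---------------------------------------------------------------------------

def test_single_config_grid_returned_unchanged(rng):
    x, s = _separable_problem(rng, n=30)
    cfg = TrainingConfig(0.001, 5, seed=0)
    best, _ = cross_validate_hyperparams(x, s, NetworkSpec(3), [cfg], n_folds=3)
    assert best is cfg


def test_divergent_learning_rate_not_selected(rng):
    x, s = _separable_problem(rng, n=120)
    x = x * 50  # large inputs make the huge-lr candidate blow up
    grid = [
        TrainingConfig(1e3, 60, seed=0),
        TrainingConfig(1e-2, 60, seed=0),
    ]
    best, mean_c = cross_validate_hyperparams(
        x, s, NetworkSpec(3, hidden_dims=(4,)), grid, n_folds=3
    )
    assert best.learning_rate == 1e-2
    assert mean_c[1e-2] > mean_c[1e3]
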