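"""Grid-recurrence forward/backward correctness, training, baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gridrisk as g
from gridrisk import model as mdl
from gridrisk import synthetic as syn

from conftest import random_window


def zero_neighbors(d_h=5):
    z = np.zeros(d_h)
    return z, z, z, z


# ---------------------------------------------------------------------------
# cell update
# ---------------------------------------------------------------------------

def test_cell_forward_zero_parameters():
    p = g.MDLSTMParams.zeros()
    x = np.random.default_rng(0).random(6)
    h, C, S, i, f1, f2, o = g.cell_forward(x, *zero_neighbors(), p)
    np.testing.assert_allclose(S, 0.0)
    np.testing.assert_allclose([i, f1, f2, o], 0.5)
    np.testing.assert_allclose(C, 0.0)
    np.testing.assert_allclose(h, 0.0)


def test_cell_forward_scalar_hand_computation():
    """d_x = d_h = 1, a single unit land-use weight into the candidate
    state: S = tanh(1), C = 0.5 S, h = 0.5 tanh(C) — frozen to 7 decimals."""
    p = g.MDLSTMParams.zeros(d_x=1, d_h=1)
    p.W_C[0, 0] = 1.0
    h, C, S, *_ = g.cell_forward(
        np.array([1.0]), np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1), p
    )
    assert S[0] == pytest.approx(0.7615942, abs=1e-7)
    assert C[0] == pytest.approx(0.3807971, abs=1e-7)
    assert h[0] == pytest.approx(0.1816997, abs=1e-7)


def test_closed_forget_gates_decouple_neighbors():
    p = g.MDLSTMParams.random(seed=4)
    p.b_f1[:] = -40.0
    p.b_f2[:] = -40.0
    p.W_f1[:] = 0.0
    p.W_f2[:] = 0.0
    x = np.random.default_rng(1).random(6)
    rng = np.random.default_rng(2)
    h_ref, *_ = g.cell_forward(x, *zero_neighbors(), p)
    h_perturbed, *_ = g.cell_forward(
        x, rng.random(5) * 0.0, rng.random(5) * 0.0, rng.random(5), rng.random(5), p
    )
    # neighbour states C are fully forgotten
    assert np.abs(h_ref - h_perturbed).max() < 1e-9


def test_gate_and_state_ranges_on_random_inputs():
    rng = np.random.default_rng(9)
    p = g.MDLSTMParams.random(seed=9, scale=2.0)
    f = g.grid_forward(rng.random((7, 7, 6)) * 4 - 2, p)
    for gate in (f.i, f.f1, f.f2, f.o):
        assert np.all((gate > 0) & (gate < 1))
    assert np.all((f.S > -1) & (f.S < 1))
    assert np.all((f.h > -1) & (f.h < 1))


# ---------------------------------------------------------------------------
# grid forward
# ---------------------------------------------------------------------------

def test_1x1_grid_equals_cell_forward():
    p = g.MDLSTMParams.random(seed=3)
    x = np.random.default_rng(3).random((1, 1, 6))
    f = g.grid_forward(x, p)
    h, C, S, i, f1, f2, o = g.cell_forward(x[0, 0], *zero_neighbors(), p)
    np.testing.assert_allclose(f.h[0, 0], h, atol=1e-15)
    np.testing.assert_allclose(f.C[0, 0], C, atol=1e-15)


@pytest.mark.parametrize("seed", range(20))
def test_vectorized_forward_matches_percell_oracle(seed):
    p = g.MDLSTMParams.random(seed=seed + 1000, forget_bias=0.5)
    X, _ = random_window(seed)
    fv = g.grid_forward(X, p)
    fn = g.grid_forward_naive(X, p)
    for var in mdl.StateField.VARIABLES:
        assert np.abs(getattr(fv, var) - getattr(fn, var)).max() <= 1e-12


def test_hidden_channel_permutation_equivariance():
    p = g.MDLSTMParams.random(seed=5)
    X, _ = random_window(11, rows=6, cols=6)
    perm = np.array([2, 0, 4, 1, 3])
    d_x = p.d_x
    q = p.copy()
    for name in p.MATRIX_NAMES:
        m = getattr(p, name)
        # permute output columns, and the h_north/h_west row blocks coherently
        pm = m[:, perm].copy()
        pm[d_x : d_x + 5] = pm[d_x : d_x + 5][perm]
        pm[d_x + 5 :] = pm[d_x + 5 :][perm]
        getattr(q, name)[:] = pm
    for name in p.BIAS_NAMES:
        getattr(q, name)[:] = getattr(p, name)[perm]
    f_p = g.grid_forward(X, p)
    f_q = g.grid_forward(X, q)
    for var in mdl.StateField.VARIABLES:
        np.testing.assert_allclose(
            getattr(f_q, var), getattr(f_p, var)[..., perm], atol=1e-12
        )


def test_non_finite_inputs_rejected():
    p = g.MDLSTMParams.random(seed=0)
    X = np.full((3, 3, 6), np.nan)
    with pytest.raises(ValueError):
        g.grid_forward(X, p)


def test_bounded_state_under_contractive_gates():
    """With f1 + f2 < 1 everywhere the state recursion is contractive:
    ||C||_inf <= max||i*S||_inf / (1 - max(f1 + f2))."""
    p = g.MDLSTMParams.random(seed=21, forget_bias=-1.5)
    rng = np.random.default_rng(21)
    f = g.grid_forward(rng.random((4, 60, 6)), p)
    fsum_max = (f.f1 + f.f2).max()
    assert fsum_max < 1
    bound = np.abs(f.i * f.S).max() / (1 - fsum_max)
    assert np.abs(f.C).max() <= bound + 1e-12


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_loss_central_basic_values():
    X, Y = random_window(0)
    p = g.MDLSTMParams.random(seed=0)
    f = g.grid_forward(X, p)
    assert g.loss_central(f.h, f.h) == 0.0
    assert g.loss_central(f.h, f.h - 1.0) == pytest.approx(1.0)


def test_loss_central_matches_hand_summation():
    X, Y = random_window(13)
    p = g.MDLSTMParams.random(seed=13)
    h = g.grid_forward(X, p).h
    manual = 0.0
    for t in range(3, 6):
        for s in range(3, 6):
            manual += ((h[t, s] - Y[t, s]) ** 2).sum()
    assert g.loss_central(h, Y) == pytest.approx(manual / (9 * 5))


def test_loss_central_respects_mask():
    X, Y = random_window(14)
    p = g.MDLSTMParams.random(seed=14)
    h = g.grid_forward(X, p).h
    mask = np.ones((9, 9), bool)
    mask[3, 3] = False
    manual = sum(
        ((h[t, s] - Y[t, s]) ** 2).sum()
        for t in range(3, 6)
        for s in range(3, 6)
        if (t, s) != (3, 3)
    )
    assert g.loss_central(h, Y, mask) == pytest.approx(manual / (8 * 5))
    with pytest.raises(ValueError):
        g.loss_central(h, Y, np.zeros((9, 9), bool))


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(20))
def test_backprop_matches_finite_differences(seed):
    p = g.MDLSTMParams.random(seed=seed, scale=0.6, forget_bias=0.3)
    X, Y = random_window(seed + 500, rows=5, cols=5)
    assert g.grad_check(p, X, Y) < 1e-6


def test_unreachable_parameters_have_zero_gradient():
    # on a 1x1 grid (region 1) the forget weights touch nothing: C_north
    # and C_west are identically zero
    p = g.MDLSTMParams.random(seed=2)
    X, Y = random_window(2, rows=1, cols=1)
    _, grads = mdl.loss_and_grads(p, X, Y, region=1)
    assert np.abs(grads["W_f1"]).max() == 0.0
    assert np.abs(grads["W_f2"]).max() == 0.0
    assert g.grad_check(p, X, Y, region=1) < 1e-6


def test_gradient_scales_linearly_with_loss():
    p = g.MDLSTMParams.random(seed=8)
    X, Y = random_window(8, rows=5, cols=5)
    h = g.grid_forward(X, p).h
    # doubling the residual everywhere doubles each gradient component
    _, g1 = mdl.loss_and_grads(p, X, Y)
    _, g2 = mdl.loss_and_grads(p, X, 2 * Y - h)
    for k in g1:
        np.testing.assert_allclose(g2[k], 2 * g1[k], rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_teacher_windows():
    cfg = g.SyntheticConfig(rows=17, cols=17, seed=3)
    lu = syn.gen_landuse(cfg)
    teacher = syn.random_teacher(seed=3)
    return syn.teacher_windows(lu, teacher, noise_sd=0.0, seed=3, n_test=20)


def test_training_loss_decreases_monotonically_early(tiny_teacher_windows):
    cfg = mdl.TrainConfig(learning_rate=1e-3, epochs=10, batch_size=None, seed=1)
    res = g.train(tiny_teacher_windows, cfg)
    losses = res.history["train_mse"].to_numpy()
    assert np.all(np.diff(losses) < 0)


def test_training_is_deterministic(tiny_teacher_windows):
    cfg = mdl.TrainConfig(epochs=3, seed=11)
    r1 = g.train(tiny_teacher_windows, cfg)
    r2 = g.train(tiny_teacher_windows, cfg)
    assert r1.history.equals(r2.history)
    for name in g.MDLSTMParams.MATRIX_NAMES:
        np.testing.assert_array_equal(getattr(r1.params, name), getattr(r2.params, name))


def test_training_requires_a_train_split():
    cfg = g.SyntheticConfig(rows=9, cols=9, seed=0)
    lu = syn.gen_landuse(cfg)
    ws = g.sample_windows(lu, syn.gen_accidents_from_teacher(lu, syn.random_teacher()))
    with pytest.raises(ValueError):
        g.train(ws, mdl.TrainConfig(epochs=1))


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def test_bpnn_is_local():
    params = mdl.baseline_init("bpnn", seed=0)
    X, _ = random_window(3)
    H1 = g.baseline_forward("bpnn", X, params)
    X2 = X.copy()
    X2[0, 0] += 10.0
    H2 = g.baseline_forward("bpnn", X2, params)
    changed = np.abs(H2 - H1).max(axis=-1) > 0
    assert changed[0, 0] and changed.sum() == 1


def test_rnn_rows_are_independent():
    params = mdl.baseline_init("rnn", seed=0)
    X, _ = random_window(4)
    H1 = g.baseline_forward("rnn", X, params)
    X2 = X.copy()
    X2[2, 0] += 5.0  # perturb row 2 only
    H2 = g.baseline_forward("rnn", X2, params)
    diff_rows = np.abs(H2 - H1).max(axis=(1, 2)) > 0
    assert diff_rows[2] and diff_rows.sum() == 1


def test_lstm_carries_state_along_rows_only():
    params = mdl.baseline_init("lstm", seed=0)
    X, _ = random_window(5)
    H1 = g.baseline_forward("lstm", X, params)
    X2 = X.copy()
    X2[4, 2] += 5.0
    H2 = g.baseline_forward("lstm", X2, params)
    d = np.abs(H2 - H1).max(axis=-1)
    assert d[4, 2] > 0          # itself
    assert d[4, 3:].max() > 0   # downstream in the row
    assert d[:4].max() == 0 and d[5:].max() == 0  # other rows untouched
    assert d[4, :2].max() == 0  # upstream untouched


@pytest.mark.parametrize("kind", ["bpnn", "rnn", "lstm"])
def test_baseline_gradients_match_finite_differences(kind):
    rng = np.random.default_rng(17)
    X = rng.random((2, 5, 5, 6))
    Y = rng.random((2, 5, 5, 5))
    M = np.ones((2, 5, 5), bool)
    params = mdl.baseline_init(kind, seed=17)
    fwd, bwd = mdl._BASELINES[kind]
    H, cache = fwd(X, params)
    _, dH = mdl._loss_grad_h(H, Y, M, 3)
    grads = bwd(cache, params, dH)
    worst = 0.0
    for key, arr in params.items():
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + 1e-5
            up = mdl.loss_central(fwd(X, params)[0], Y, M)
            arr[idx] = orig - 1e-5
            dn = mdl.loss_central(fwd(X, params)[0], Y, M)
            arr[idx] = orig
            num = (up - dn) / 2e-5
            ana = grads[key][idx]
            worst = max(worst, abs(ana - num) / (max(abs(ana), abs(num)) + 1e-8))
    assert worst < 1e-5


def test_unknown_baseline_kind_rejected():
    with pytest.raises(ValueError):
        mdl.baseline_init("cnn")
    with pytest.raises(ValueError):
        g.baseline_forward("cnn", np.zeros((2, 2, 6)), {})
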