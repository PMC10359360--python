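import itertools

import numpy as np
import pandas as pd
import pytest

from adscore.adnet import (
    NetworkSpec,
    TrainConfig,
    build_network,
    count_parameters,
    load_model,
    mc_predict,
    mc_sample_scores,
    predict_single_pass,
    save_model,
    train,
)
from adscore.deconfound import apply_deconfounder, fit_deconfounder
from adscore.morphometry_io import stratified_split
from adscore.synthetic_cohort import CohortSpec, generate_cohort


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def exhaustive_mask_moments(net, x):
    """Oracle: exact mean/var/4th central moment of the stochastic output of a
    single-hidden-layer net by enumerating every Bernoulli dropout mask."""
    keep = 1.0 - net.spec.dropout_rate
    h = np.tanh(x @ net.weights[0] + net.biases[0])
    outs, probs = [], []
    n_hidden = h.shape[-1]
    for mask in itertools.product([0, 1], repeat=n_hidden):
        m = np.array(mask, dtype=float) / keep
        o = float(_sigmoid((h * m) @ net.weights[1] + net.biases[1])[0, 0])
        outs.append(o)
        probs.append(np.prod([keep if b else 1 - keep for b in mask]))
    outs, probs = np.array(outs), np.array(probs)
    assert abs(probs.sum() - 1) < 1e-12
    mu = float(probs @ outs)
    var = float(probs @ (outs - mu) ** 2)
    m4 = float(probs @ (outs - mu) ** 4)
    return mu, var, m4


@pytest.mark.parametrize(
    "spec,expected",
    [
        (NetworkSpec(), 36_609),
        (NetworkSpec(input_dim=1, hidden_dims=(1,), dropout_rate=0.0), 1 * 1 + 1 + 1 * 1 + 1),
        (NetworkSpec(input_dim=10, hidden_dims=(4,)), 10 * 4 + 4 + 4 * 1 + 1),
    ],
)
def test_parameter_count(spec, expected):
    assert count_parameters(build_network(spec, seed=0)) == expected


def test_default_layer_shapes():
    net = build_network(NetworkSpec(), seed=0)
    assert [w.shape for w in net.weights] == [(155, 128), (128, 128), (128, 1)]


def test_empty_hidden_dims_rejected():
    with pytest.raises(ValueError, match="hidden_dims"):
        NetworkSpec(hidden_dims=())


def test_seeded_initialization_deterministic():
    a = build_network(NetworkSpec(), seed=7)
    b = build_network(NetworkSpec(), seed=7)
    for wa, wb in zip(a.weights, b.weights):
        assert np.array_equal(wa, wb)
    c = build_network(NetworkSpec(), seed=8)
    assert not np.array_equal(a.weights[0], c.weights[0])


def test_manual_forward_pass_matches_hand_arithmetic():
    net = build_network(NetworkSpec(input_dim=2, hidden_dims=(2,), dropout_rate=0.0), seed=0)
    net.weights = [np.array([[0.5, -1.0], [0.25, 0.75]]), np.array([[2.0], [-1.5]])]
    net.biases = [np.array([0.1, -0.2]), np.array([0.3])]
    x = np.array([[1.0, 2.0]])
    h = np.tanh(np.array([0.5 + 0.5 + 0.1, -1.0 + 1.5 - 0.2]))
    expected = _sigmoid(h @ np.array([2.0, -1.5]) + 0.3)
    got = net.forward(x)
    assert abs(got[0] - expected) < 1e-8


def test_zero_dropout_mc_equals_single_pass(small_cohort):
    net = build_network(NetworkSpec(dropout_rate=0.0), seed=1)
    table = small_cohort.features
    mc = mc_predict(net, table, n_passes=10, seed=3)
    sp = predict_single_pass(net, table)
    assert np.allclose(mc["ad_score"], sp["ad_score"], atol=1e-12)
    assert np.allclose(mc["uncertainty"], 0.0)


def test_mc_predict_requires_two_passes(small_cohort):
    net = build_network(NetworkSpec(), seed=1)
    with pytest.raises(ValueError, match="n_passes"):
        mc_predict(net, small_cohort.features, n_passes=1)


def test_mc_predict_bit_identical_under_seed(small_cohort):
    net = build_network(NetworkSpec(), seed=1)
    a = mc_predict(net, small_cohort.features, n_passes=50, seed=5)
    b = mc_predict(net, small_cohort.features, n_passes=50, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = mc_predict(net, small_cohort.features, n_passes=50, seed=6)
    assert not np.array_equal(a["ad_score"], c["ad_score"])


def test_uncertainty_bounded_by_half(small_cohort):
    """SD of [0,1]-valued samples can never exceed 0.5."""
    net = build_network(NetworkSpec(), seed=2)
    mc = mc_predict(net, small_cohort.features, n_passes=50, seed=4)
    assert (mc["uncertainty"] <= 0.5 + 1e-12).all()
    assert mc["ad_score"].between(0, 1).all()


def test_mc_moments_match_exhaustive_mask_oracle():
    """20k stochastic passes on a 2-hidden-unit net agree with the exact
    4-mask enumeration within 3 Monte-Carlo standard errors."""
    net = build_network(NetworkSpec(input_dim=3, hidden_dims=(2,), dropout_rate=0.8), seed=3)
    net.weights = [np.array([[1.2, -0.7], [0.4, 0.9], [-0.5, 0.3]]), np.array([[1.8], [-2.2]])]
    net.biases = [np.array([0.2, -0.1]), np.array([0.4])]
    x = np.array([[0.6, -1.1, 0.8]])
    mu, var, m4 = exhaustive_mask_moments(net, x)
    n = 20_000
    draws = mc_sample_scores(net, x, n_passes=n, seed=11)[:, 0]
    se_mean = np.sqrt(var / n)
    assert abs(draws.mean() - mu) < 3 * se_mean
    sd = np.sqrt(var)
    se_sd = np.sqrt(max(m4 - var**2, 0.0) / (4 * var * n))
    assert abs(draws.std(ddof=1) - sd) < 3 * se_sd


def _separable_setup(n=400, seed=17):
    spec = CohortSpec(
        n_subjects=n,
        atrophy_effect_sizes={f: -3.0 for f in ["lh_hippocampus_volume", "rh_hippocampus_volume"]},
        severity_range=(1.0, 1.0),
        seed=seed,
    )
    t = generate_cohort(spec).features
    sp = stratified_split(t, 0.8, seed=1)
    tr = t[t["subject_id"].isin(sp.train_ids)].reset_index(drop=True)
    va = t[t["subject_id"].isin(sp.validation_ids)].reset_index(drop=True)
    dc = fit_deconfounder(tr)
    return apply_deconfounder(dc, tr), apply_deconfounder(dc, va)


def test_training_separates_strong_effect_cohort():
    trz, vaz = _separable_setup()
    net = build_network(NetworkSpec(), seed=0)
    model = train(net, trz, vaz, TrainConfig(epochs=60, seed=1))
    scores = predict_single_pass(model, trz)
    y = (trz["diagnosis"] == "AD").to_numpy(int)
    acc = ((scores["ad_score"] > 0.5).to_numpy(int) == y).mean()
    assert acc >= 0.95


def test_training_reproducible_under_seed():
    trz, vaz = _separable_setup(n=200)
    cfg = TrainConfig(epochs=15, seed=5)
    m1 = train(build_network(NetworkSpec(), seed=0), trz, vaz, cfg)
    m2 = train(build_network(NetworkSpec(), seed=0), trz, vaz, cfg)
    assert m1.best_epoch == m2.best_epoch
    assert m1.best_val_loss == m2.best_val_loss
    for w1, w2 in zip(m1.network.weights, m2.network.weights):
        assert np.array_equal(w1, w2)


def test_constant_labels_drive_scores_to_constant():
    trz, vaz = _separable_setup(n=200)
    trz = trz.copy()
    vaz = vaz.copy()
    trz["diagnosis"] = "AD"
    vaz["diagnosis"] = "AD"
    model = train(build_network(NetworkSpec(), seed=0), trz, vaz, TrainConfig(epochs=100, seed=2))
    scores = predict_single_pass(model, trz)["ad_score"]
    assert abs(scores.mean() - 1.0) < 0.1


def test_balanced_training_flag_runs():
    trz, vaz = _separable_setup(n=300)
    model = train(
        build_network(NetworkSpec(), seed=0), trz, vaz, TrainConfig(epochs=10, seed=3, balanced=True)
    )
    assert model.log.shape[0] == 10


def test_model_save_load_round_trip(tmp_path):
    trz, vaz = _separable_setup(n=200)
    model = train(build_network(NetworkSpec(), seed=0), trz, vaz, TrainConfig(epochs=5, seed=1))
    path = tmp_path / "model.zip"
    save_model(model, path)
    back = load_model(path)
    a = predict_single_pass(model, vaz)["ad_score"]
    b = predict_single_pass(back, vaz)["ad_score"]
    assert np.allclose(a, b, atol=0)
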