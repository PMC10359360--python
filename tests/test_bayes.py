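import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adscore.bayes_inference import (
    PiecewiseFit,
    RopeSpec,
    SamplerConfig,
    choose_family,
    compare_elpd,
    fit_group_model,
    fit_piecewise,
    rope_decision,
    rope_verdict,
    standardize_to_controls,
)

FAST = SamplerConfig(seed=0)


def rope_oracle(mean, ci, rope):
    """Geometric brute force: probe a dense grid of the CI against the ROPE."""
    lo, hi = ci
    rlo, rhi = rope
    pts = np.linspace(lo, hi, 513)
    # also probe the ROPE edges where they fall inside the CI, so overlaps
    # narrower than the grid spacing are not missed
    edges = [e for e in (rlo, rhi) if lo <= e <= hi]
    pts = np.concatenate([pts, edges]) if edges else pts
    inside = (pts >= rlo) & (pts <= rhi)
    if not inside.any():
        return "strong_evidence"
    if inside.all():
        return "accept_null"
    if mean < rlo or mean > rhi:
        return "some_evidence"
    return "indeterminate"


@pytest.mark.parametrize(
    "mean,ci,rope,expected",
    [
        (0.3, (0.2, 0.4), (-0.1, 0.1), "strong_evidence"),
        (0.15, (-0.05, 0.35), (-0.1, 0.1), "some_evidence"),
        (0.01, (-0.04, 0.06), (-0.1, 0.1), "accept_null"),
        (0.05, (-0.2, 0.3), (-0.1, 0.1), "indeterminate"),
        (-0.3, (-0.4, -0.2), (-0.1, 0.1), "strong_evidence"),
    ],
)
def test_rope_verdict_examples(mean, ci, rope, expected):
    assert rope_verdict(mean, ci, rope) == expected


@settings(max_examples=300, deadline=None)
@given(data=st.data())
def test_rope_verdict_matches_geometric_oracle(data):
    rng_vals = data.draw(
        st.lists(st.floats(-2, 2, allow_nan=False), min_size=4, max_size=4)
    )
    lo, hi = sorted(rng_vals[:2])
    rlo, rhi = sorted(rng_vals[2:])
    if hi - lo < 1e-9 or rhi - rlo < 1e-9:
        return
    mean = data.draw(st.floats(min_value=lo, max_value=hi))
    assert rope_verdict(mean, (lo, hi), (rlo, rhi)) == rope_oracle(mean, (lo, hi), (rlo, rhi))


def test_rope_spec_validation():
    with pytest.raises(ValueError):
        RopeSpec(half_width=0.0)
    rs = RopeSpec.from_control_sd(np.r_[np.zeros(50), np.random.default_rng(0).normal(0, 2, 50)],
                                  np.r_[np.zeros(50, bool), np.ones(50, bool)])
    assert abs(rs.half_width - 0.2) < 0.05


def test_choose_family_heuristics(rng):
    assert choose_family(rng.integers(0, 2, 200).astype(float)) == "bernoulli-logit"
    assert choose_family(rng.integers(0, 4, 200).astype(float)) == "ordinal-probit"
    assert choose_family(rng.normal(0, 1, 2000)) == "gaussian"
    assert choose_family(np.exp(rng.normal(0, 1, 2000))) == "skew-gaussian"


def test_group_effect_recovery_mmse_scale():
    """A -5.2-point planted group deficit in an MMSE-like outcome is
    recovered by the gaussian group model within +/-0.4."""
    rng = np.random.default_rng(3)
    n = 700
    g = (rng.uniform(size=n) < 0.4).astype(float)
    age = rng.uniform(55, 90, n)
    y = 29.0 - 5.2 * g + 0.02 * (age - 70) + rng.normal(0, 2.0, n)
    post = fit_group_model(y, g, covariates={"age": age}, family="gaussian", sampler_cfg=FAST)
    s = post.summary("group")
    assert abs(s["mean"] - (-5.2)) < 0.4
    dec = rope_decision(post, "group", RopeSpec.from_control_sd(y, g == 0))
    assert dec.verdict == "strong_evidence"


def test_gaussian_null_coverage_across_replicates():
    """True effect 0: the 95% CI covers 0 in >= 18/20 seeded replicates."""
    covered = 0
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        n = 1000
        g = (rng.uniform(size=n) < 0.5).astype(float)
        y = rng.normal(0, 1, n)
        post = fit_group_model(y, g, family="gaussian", sampler_cfg=SamplerConfig(seed=seed))
        lo, hi = post.summary("group")["ci95"]
        covered += lo <= 0 <= hi
    assert covered >= 18


def test_bernoulli_null_ci_covers_zero():
    rng = np.random.default_rng(7)
    n = 1500
    g = (rng.uniform(size=n) < 0.5).astype(float)
    y = (rng.uniform(size=n) < 0.4).astype(float)
    post = fit_group_model(y, g, family="bernoulli-logit", sampler_cfg=FAST)
    lo, hi = post.summary("group")["ci95"]
    assert lo <= 0 <= hi


def test_posterior_mean_agrees_with_least_squares():
    """Under weak priors the gaussian posterior mean matches OLS closely."""
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    n = 1500
    g = (rng.uniform(size=n) < 0.3).astype(float)
    y = 1.0 + 0.8 * g + rng.normal(0, 1, n)
    post = fit_group_model(y, g, family="gaussian", sampler_cfg=FAST)
    ols = sm.OLS(y, sm.add_constant(g)).fit()
    d = post.draws("group")
    ess = float(post.diagnostics.loc[post.diagnostics.parameter == "group", "ess"].iloc[0])
    mc_se = d.std(ddof=1) / np.sqrt(ess)
    assert abs(d.mean() - ols.params[1]) < 3 * mc_se + 0.02 * abs(ols.params[1])


def test_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        fit_group_model(np.zeros(10), np.zeros(10), family="gaussian")


def test_rhat_reported_for_every_parameter():
    rng = np.random.default_rng(9)
    n = 400
    g = (rng.uniform(size=n) < 0.5).astype(float)
    y = rng.normal(0, 1, n)
    post = fit_group_model(y, g, family="gaussian", sampler_cfg=FAST)
    assert set(post.diagnostics["parameter"]) == {"intercept", "group", "log_sigma"}
    assert (post.diagnostics["rhat"] <= 1.01).all()


# --- piecewise -------------------------------------------------------------

def _hinge_data(n=2000, seed=0, b1=0.0, b2=-1.0, bp=0.5, noise=0.5):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    y = b1 * np.minimum(x, bp) + b2 * np.maximum(x - bp, 0) + rng.normal(0, noise, n)
    return x, y


def test_piecewise_recovers_hinge_slopes():
    x, y = _hinge_data(seed=2)
    fit = fit_piecewise(x, y, "fixed", SamplerConfig(seed=2))
    lo, hi = fit.slope_above["ci95"]
    assert lo <= -1.0 <= hi and hi < 0
    blo, bhi = fit.slope_below["ci95"]
    assert blo <= 0.0 <= bhi
    dlo, dhi = fit.slope_diff["ci95"]
    assert dlo <= -1.0 <= dhi


def test_variable_breakpoint_near_true_value():
    x, y = _hinge_data(seed=3)
    fit = fit_piecewise(x, y, "variable", SamplerConfig(seed=3))
    assert 0.4 <= fit.breakpoint["mean"] <= 0.6


def test_linear_mode_recovers_plain_slope():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 1, 1500)
    y = -0.5 * x + rng.normal(0, 0.5, 1500)
    fit = fit_piecewise(x, y, "none", SamplerConfig(seed=4))
    lo, hi = fit.slope["ci95"]
    assert lo <= -0.5 <= hi


def test_constant_outcome_slopes_cover_zero():
    rng = np.random.default_rng(6)
    x = rng.uniform(0, 1, 400)
    y = np.zeros(400) + rng.normal(0, 1e-2, 400)
    fit = fit_piecewise(x, y, "fixed", SamplerConfig(seed=6))
    for s in (fit.slope_below, fit.slope_above):
        lo, hi = s["ci95"]
        assert lo <= 0 <= hi


def test_fixed_mode_needs_points_on_both_sides():
    rng = np.random.default_rng(8)
    x = rng.uniform(0.6, 1.0, 100)
    with pytest.raises(ValueError, match="10 points"):
        fit_piecewise(x, np.zeros(100), "fixed")


def test_scores_outside_unit_interval_rejected():
    with pytest.raises(ValueError, match="0, 1"):
        fit_piecewise(np.array([-0.2, 0.5]), np.zeros(2), "none")


def test_standardize_to_controls():
    y = np.r_[np.zeros(10), np.full(10, 5.0)]
    mask = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    with pytest.raises(ValueError, match="SD is zero"):
        standardize_to_controls(y, mask)
    rng = np.random.default_rng(1)
    y = rng.normal(10, 2, 100)
    z = standardize_to_controls(y, np.ones(100, bool))
    assert abs(z.mean()) < 1e-12 and abs(z.std(ddof=1) - 1) < 1e-12


# --- ELPD ------------------------------------------------------------------

def test_elpd_self_comparison_is_zero():
    x, y = _hinge_data(n=600, seed=5)
    fit = fit_piecewise(x, y, "fixed", SamplerConfig(seed=5))
    cmp_res = compare_elpd({"a": fit, "b": fit})
    diffs = cmp_res.table.set_index("model")["elpd_diff"]
    assert diffs["a"] == 0.0 and diffs["b"] == 0.0


def test_elpd_prefers_breakpoint_on_hinge_data():
    x, y = _hinge_data(n=2000, seed=7)
    f_fix = fit_piecewise(x, y, "fixed", SamplerConfig(seed=7))
    f_none = fit_piecewise(x, y, "none", SamplerConfig(seed=8))
    cmp_res = compare_elpd({"fixed": f_fix, "none": f_none})
    row = cmp_res.table.set_index("model").loc["none"]
    assert row["elpd_diff"] < 0
    assert abs(row["elpd_diff"]) > 2 * row["diff_se"]


def test_elpd_indifferent_on_linear_data():
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 1, 1500)
    y = -0.5 * x + rng.normal(0, 0.5, 1500)
    f_fix = fit_piecewise(x, y, "fixed", SamplerConfig(seed=9))
    f_none = fit_piecewise(x, y, "none", SamplerConfig(seed=10))
    cmp_res = compare_elpd({"fixed": f_fix, "none": f_none})
    worst = cmp_res.table.iloc[1]  # table is sorted best-first
    assert abs(worst["elpd_diff"]) < 2 * max(worst["diff_se"], 1e-9)
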