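import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from adscore.deconfound import apply_deconfounder, fit_deconfounder
from adscore.schema import feature_names
from adscore.synthetic_cohort import (
    CognitionSpec,
    CohortSpec,
    RiskFactorSpec,
    generate_cognition,
    generate_cohort,
    generate_risk_factors,
    null_spec,
)


def test_cohort_shape_matches_default_case_control_mix():
    cohort = generate_cohort(CohortSpec(seed=0))
    dx = cohort.features["diagnosis"].value_counts()
    assert dx["AD"] == 331 and dx["control"] == 405


def test_determinism_byte_identical():
    a = generate_cohort(CohortSpec(n_subjects=80, seed=9)).features
    b = generate_cohort(CohortSpec(n_subjects=80, seed=9)).features
    assert a.to_csv(index=False) == b.to_csv(index=False)
    c = generate_cohort(CohortSpec(n_subjects=80, seed=10)).features
    assert a.to_csv(index=False) != c.to_csv(index=False)


def test_null_generative_model_has_no_group_signal():
    """With zero effects and zero confound slopes, AD and control feature
    means differ by less than 3 standard errors per feature."""
    spec = CohortSpec(
        n_subjects=1000,
        atrophy_effect_sizes={},
        confound_slopes={},
        seed=21,
    )
    cohort = generate_cohort(spec)
    t = cohort.features
    ad = t["diagnosis"] == "AD"
    n_exceed = 0
    for f in feature_names():
        a, b = t.loc[ad, f], t.loc[~ad, f]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        if abs(a.mean() - b.mean()) >= 3 * se:
            n_exceed += 1
    # 3-sigma exceedances should be rare across 155 independent features
    assert n_exceed <= 3


def test_planted_hippocampal_shift_recovered_after_deconfounding():
    """A -1.0 SD hippocampal shift (severity pinned at 1) is recovered as a
    standardized group difference within +/-0.1, averaged over 20 seeds."""
    diffs = []
    for seed in range(20):
        spec = CohortSpec(
            n_subjects=2000,
            atrophy_effect_sizes={"lh_hippocampus_volume": -1.0},
            severity_range=(1.0, 1.0),
            seed=seed,
        )
        cohort = generate_cohort(spec)
        t = cohort.features
        dc = fit_deconfounder(t[t["diagnosis"] == "control"].reset_index(drop=True))
        z = apply_deconfounder(dc, t)
        ad = z["diagnosis"] == "AD"
        diffs.append(z.loc[ad, "lh_hippocampus_volume"].mean() - z.loc[~ad, "lh_hippocampus_volume"].mean())
    assert abs(np.mean(diffs) - (-1.0)) < 0.1


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="ad_fraction"):
        CohortSpec(ad_fraction=1.4).validate()
    with pytest.raises(ValueError, match="unknown feature"):
        CohortSpec(atrophy_effect_sizes={"not_a_region": -1.0}).validate()
    with pytest.raises(ValueError, match="breakpoint"):
        CognitionSpec(control_mean=0, control_sd=1, breakpoint=1.5)
    with pytest.raises(ValueError, match="family"):
        RiskFactorSpec("poisson")


# --- cognition -------------------------------------------------------------

def _cohort_with_scores(n, seed=3):
    cohort = generate_cohort(CohortSpec(n_subjects=n, seed=seed))
    rng = np.random.default_rng(seed + 1)
    return cohort, rng.uniform(0, 1, n)


def test_cognition_no_signal_when_slopes_zero():
    cohort, x = _cohort_with_scores(5000)
    spec = {"c": CognitionSpec(control_mean=0.0, control_sd=1.0)}
    cog = generate_cognition(cohort, x, cognition_spec=spec)
    assert abs(np.corrcoef(x, cog["c"])[0, 1]) < 0.05


def test_cognition_slope_recovered_above_breakpoint():
    cohort, x = _cohort_with_scores(5000)
    spec = {"c": CognitionSpec(control_mean=0.0, control_sd=1.0, slope_above_bp=-1.0)}
    cog = generate_cognition(cohort, x, cognition_spec=spec)
    m = x > 0.5
    X = sm.add_constant(x[m])
    slope = sm.OLS(cog["c"][m].to_numpy(), X).fit().params[1]
    assert abs(slope - (-1.0)) < 0.15


def test_cognition_flat_below_breakpoint_without_noise():
    cohort, x = _cohort_with_scores(500)
    spec = {"c": CognitionSpec(control_mean=5.0, control_sd=1e-12, slope_above_bp=-2.0)}
    with pytest.raises(ValueError):
        CognitionSpec(control_mean=5.0, control_sd=0.0)  # sd must be positive
    cog = generate_cognition(cohort, x, cognition_spec=spec)
    below = cog["c"][x <= 0.5]
    assert np.allclose(below, 5.0, atol=1e-9)


def test_cognition_misaligned_scores_rejected(small_cohort):
    with pytest.raises(ValueError, match="length"):
        generate_cognition(small_cohort, np.zeros(10))


# --- risk factors ----------------------------------------------------------

def test_continuous_risk_shift_recovered():
    cohort, _ = _cohort_with_scores(20000, seed=8)
    mask = np.zeros(20000, bool)
    mask[:9000] = True
    spec = {"sbp": RiskFactorSpec("gaussian", base_mean=135, base_sd=18, shift=2.29)}
    risk = generate_risk_factors(cohort, mask, riskfactor_spec=spec)
    diff = risk["sbp"][mask].mean() - risk["sbp"][~mask].mean()
    assert abs(diff - 2.29) < 0.5


def test_null_binary_shift_covers_zero_across_replicates():
    """With zero log-odds shift the group coefficient CI covers 0 in >=90%
    of seeded refits (oracle: repeated logistic regressions)."""
    n, covered = 4000, 0
    for seed in range(20):
        cohort = generate_cohort(CohortSpec(n_subjects=n, seed=100 + seed))
        mask = np.zeros(n, bool)
        mask[: n // 2] = True
        spec = {"smoker": RiskFactorSpec("bernoulli", base_logit=-0.5, shift=0.0)}
        risk = generate_risk_factors(cohort, mask, riskfactor_spec=spec, seed=seed)
        X = sm.add_constant(mask.astype(float))
        fit = sm.Logit(risk["smoker"].to_numpy(), X).fit(disp=0)
        lo, hi = fit.conf_int()[1]
        covered += lo <= 0 <= hi
    assert covered >= 18


def test_empty_positive_group_matches_control_distribution():
    cohort, _ = _cohort_with_scores(4000, seed=12)
    mask = np.zeros(4000, bool)
    spec = {"v": RiskFactorSpec("gaussian", base_mean=10.0, base_sd=2.0, shift=50.0)}
    risk = generate_risk_factors(cohort, mask, riskfactor_spec=spec, seed=0)
    # shift never applied: same distribution as a zero-shift draw
    spec0 = {"v": RiskFactorSpec("gaussian", base_mean=10.0, base_sd=2.0, shift=0.0)}
    risk0 = generate_risk_factors(cohort, mask, riskfactor_spec=spec0, seed=0)
    pd.testing.assert_frame_equal(risk, risk0)


def test_ordinal_levels_and_shift_direction():
    cohort, _ = _cohort_with_scores(20000, seed=14)
    mask = np.zeros(20000, bool)
    mask[:10000] = True
    spec = {"health": RiskFactorSpec("ordinal", shift=0.5, n_levels=4, thresholds=(-1.0, 0.2, 1.3))}
    risk = generate_risk_factors(cohort, mask, riskfactor_spec=spec)
    assert set(risk["health"].unique()) <= {0, 1, 2, 3}
    assert risk["health"][mask].mean() > risk["health"][~mask].mean()


def test_null_spec_has_no_planted_effects():
    spec = null_spec(n_subjects=50, seed=1)
    assert spec.atrophy_effect_sizes == {}
    assert all(v.shift == 0 for v in spec.riskfactor_spec.values())
    assert all(v.slope_above_bp == 0 for v in spec.cognition_spec.values())
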