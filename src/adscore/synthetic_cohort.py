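"""Synthetic case-control cohorts with the structure the analysis assumes.

The real cohorts behind this kind of study (research case-control imaging
panels, memory-clinic registries, population biobanks) are access-controlled,
so the package ships a generator that emulates the statistical structure the
downstream stages rely on:

* group-level atrophy: AD subjects lose volume/thickness in a configurable
  set of regions (hippocampus and medial-temporal by default), scaled by a
  latent per-subject disease severity;
* linear confound effects: age on thickness; age, estimated total
  intracranial volume (eTIV) and sex on volumes;
* cognitive scores that track the AD score only above a severity breakpoint;
* risk-factor shifts (blood pressure, smoking, ordinal self-rated health)
  in the score-positive group.

Nothing in the generator sees the classifier: atrophy is written in feature
space, cognition/risk factors are written against a supplied score, so
recovery of the planted effects by the pipeline is a genuine test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .morphometry_io import validate_feature_table
from .schema import feature_schema, feature_names

__all__ = [
    "CognitionSpec",
    "RiskFactorSpec",
    "CohortSpec",
    "SyntheticCohort",
    "default_atrophy_effects",
    "generate_cohort",
    "generate_cognition",
    "generate_risk_factors",
]


# ---------------------------------------------------------------------------
# Fixed baseline table: plausible regional means. Absolute scale is
# irrelevant downstream (features are z-scored after residualization); the
# values only need realistic orders of magnitude.
# ---------------------------------------------------------------------------
_SUBCORTICAL_MEANS = {
    "cerebellum_white_matter": 14000.0,
    "cerebellum_cortex": 53000.0,
    "thalamus_proper": 7000.0,
    "caudate": 3600.0,
    "putamen": 4800.0,
    "pallidum": 1700.0,
    "hippocampus": 4000.0,
    "amygdala": 1600.0,
    "accumbens_area": 550.0,
}
_BRAINSTEM_MEAN = 21000.0
_THICKNESS_MEAN = 2.5  # mm
_CORTICAL_VOLUME_BASE = 4000.0  # mm^3, modulated per region below


def _baseline_means() -> dict[str, float]:
    means: dict[str, float] = {}
    cortical_idx = 0
    for desc in feature_schema():
        if desc.kind == "thickness":
            means[desc.name] = _THICKNESS_MEAN
        elif desc.name == "brainstem_volume":
            means[desc.name] = _BRAINSTEM_MEAN
        else:
            sub = desc.name.removeprefix("lh_").removeprefix("rh_").removesuffix("_volume")
            if sub in _SUBCORTICAL_MEANS:
                means[desc.name] = _SUBCORTICAL_MEANS[sub]
            else:
                # cortical volume: spread regions over 2000..10000 mm^3
                means[desc.name] = _CORTICAL_VOLUME_BASE + 180.0 * (cortical_idx % 34)
                cortical_idx += 1
    return means


def _default_noise_sd() -> dict[str, float]:
    """Residual SD per feature: 0.12 mm for thickness, 8% of mean for volume."""
    means = _baseline_means()
    out = {}
    for desc in feature_schema():
        out[desc.name] = 0.12 if desc.kind == "thickness" else 0.08 * means[desc.name]
    return out


def _default_confound_slopes() -> dict[tuple[str, str], float]:
    """Linear confound effects mirroring the residualization design.

    Thickness receives an age slope only; volumes receive age, eTIV and sex
    slopes. eTIV slope is per-mm^3; sex slope is the male-minus-female offset.
    """
    means = _baseline_means()
    slopes: dict[tuple[str, str], float] = {}
    for desc in feature_schema():
        if desc.kind == "thickness":
            slopes[(desc.name, "age")] = -0.004  # mm per year
        else:
            m = means[desc.name]
            slopes[(desc.name, "age")] = -0.002 * m  # per year
            slopes[(desc.name, "etiv")] = 0.6 * m / 1.45e6  # per mm^3 of head size
            slopes[(desc.name, "sex")] = 0.03 * m  # male offset beyond eTIV
    return slopes


def default_atrophy_effects() -> dict[str, float]:
    """Standardized AD shifts (negative = loss) in the classic atrophy pattern."""
    effects: dict[str, float] = {}
    for hemi in ("lh", "rh"):
        effects[f"{hemi}_hippocampus_volume"] = -1.5
        effects[f"{hemi}_amygdala_volume"] = -1.0
        effects[f"{hemi}_entorhinal_thickness"] = -1.2
        effects[f"{hemi}_entorhinal_volume"] = -1.0
        effects[f"{hemi}_parahippocampal_thickness"] = -0.8
        effects[f"{hemi}_fusiform_thickness"] = -0.7
        effects[f"{hemi}_middletemporal_thickness"] = -0.7
        effects[f"{hemi}_inferiortemporal_thickness"] = -0.6
        effects[f"{hemi}_inferiorparietal_thickness"] = -0.5
        effects[f"{hemi}_precuneus_thickness"] = -0.5
    return effects


@dataclass(frozen=True)
class CognitionSpec:
    """Piecewise link between AD score and one cognitive score.

    ``score = control_mean + slope_below*min(x, bp) + slope_above*max(x-bp, 0)
    + Normal(0, control_sd)`` with the AD score ``x`` in [0, 1]. Slopes are in
    raw score units per unit AD score; ``slope_below`` defaults to 0 because
    no association is expected in the score-negative range.
    """

    control_mean: float
    control_sd: float
    slope_below_bp: float = 0.0
    slope_above_bp: float = 0.0
    breakpoint: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.breakpoint < 1:
            raise ValueError("breakpoint must lie in (0, 1)")
        if self.control_sd <= 0:
            raise ValueError("control_sd must be positive")


@dataclass(frozen=True)
class RiskFactorSpec:
    """Group shift for one risk-factor variable.

    ``family`` is "gaussian" (additive shift in raw units), "bernoulli"
    (additive shift on the log-odds) or "ordinal" (probit shift on a latent
    normal cut at ``thresholds``).
    """

    family: str
    base_mean: float = 0.0
    base_sd: float = 1.0
    shift: float = 0.0
    base_logit: float = 0.0
    n_levels: int = 4
    thresholds: tuple[float, ...] = (-1.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "bernoulli", "ordinal"):
            raise ValueError(f"unknown risk-factor family '{self.family}'")


def default_cognition_spec() -> dict[str, CognitionSpec]:
    """MMSE-like and fluency-like scores with a breakpoint at AD score 0.5."""
    return {
        "mmse": CognitionSpec(control_mean=29.0, control_sd=1.2, slope_above_bp=-9.0),
        "semantic_fluency": CognitionSpec(control_mean=20.0, control_sd=5.0, slope_above_bp=-10.0),
    }


def default_riskfactor_spec() -> dict[str, RiskFactorSpec]:
    """Risk-factor families with shifts of the magnitude reported for the
    score-positive group of a healthy population cohort."""
    return {
        "systolic_bp": RiskFactorSpec("gaussian", base_mean=135.0, base_sd=18.0, shift=2.29),
        "diastolic_bp": RiskFactorSpec("gaussian", base_mean=82.0, base_sd=10.0, shift=1.12),
        "pack_years": RiskFactorSpec("gaussian", base_mean=10.0, base_sd=8.0, shift=2.98),
        "smoker": RiskFactorSpec("bernoulli", base_logit=-0.85, shift=0.25),
        "overall_health": RiskFactorSpec(
            "ordinal", shift=0.14, n_levels=4, thresholds=(-1.0, 0.2, 1.3)
        ),
        # genuine nulls: no shift in the positive group
        "sleep_duration": RiskFactorSpec("gaussian", base_mean=7.2, base_sd=1.0, shift=0.0),
        "hip_circumference": RiskFactorSpec("gaussian", base_mean=103.0, base_sd=9.0, shift=0.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full generative recipe for one synthetic cohort."""

    n_subjects: int = 736
    ad_fraction: float = 331 / 736
    age_range: tuple[float, float] = (55.0, 90.0)
    severity_range: tuple[float, float] = (0.3, 1.0)
    atrophy_effect_sizes: dict[str, float] = field(default_factory=default_atrophy_effects)
    confound_slopes: dict[tuple[str, str], float] = field(default_factory=_default_confound_slopes)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    cognition_spec: dict[str, CognitionSpec] = field(default_factory=default_cognition_spec)
    riskfactor_spec: dict[str, RiskFactorSpec] = field(default_factory=default_riskfactor_spec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.ad_fraction <= 1:
            raise ValueError("ad_fraction must lie in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        lo, hi = self.severity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("severity_range must satisfy 0 < low <= high <= 1")
        known = set(feature_names())
        bad = [f for f in self.atrophy_effect_sizes if f not in known]
        if bad:
            raise ValueError(f"atrophy_effect_sizes refers to unknown feature(s): {bad[:3]}")
        bad = [f for (f, _c) in self.confound_slopes if f not in known]
        if bad:
            raise ValueError(f"confound_slopes refers to unknown feature(s): {bad[:3]}")
        missing_sd = [f for f in known if self.noise_sd.get(f, 0.0) <= 0]
        if missing_sd:
            raise ValueError(f"noise_sd must be positive for every feature; bad: {missing_sd[:3]}")


@dataclass
class SyntheticCohort:
    """A generated cohort: validated feature table + latent ground truth."""

    features: pd.DataFrame
    latent_severity: np.ndarray
    truth: CohortSpec

    def __post_init__(self) -> None:
        is_ad = (self.features["diagnosis"] == "AD").to_numpy()
        if len(self.latent_severity) != len(self.features):
            raise ValueError("latent_severity misaligned with features")
        if np.any(self.latent_severity[is_ad] <= 0):
            raise ValueError("AD subjects must have latent_severity > 0")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-stage generator streams from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from the generative model in :class:`CohortSpec`.

    Each feature is ``baseline + sum(confound_slopes * confound)
    + effect_size * noise_sd * severity`` (AD rows only) ``+ Normal(0,
    noise_sd)``. Severity is Uniform(0.3, 1) for AD subjects and 0 for
    controls, so planted atrophy spans mild to severe disease. Same seed and
    spec give a byte-identical table.
    """
    spec.validate()
    rng_demo, rng_sev, rng_noise = _substreams(spec.seed, 3)
    n = spec.n_subjects
    n_ad = int(round(spec.ad_fraction * n))
    is_ad = np.zeros(n, dtype=bool)
    is_ad[:n_ad] = True
    # fixed interleaving (no shuffle) keeps row order deterministic and simple
    perm = rng_demo.permutation(n)
    is_ad = is_ad[perm]

    age = rng_demo.uniform(*spec.age_range, size=n)
    sex = (rng_demo.uniform(size=n) < 0.5).astype(int)
    # head size depends on sex, which makes the eTIV+sex design non-degenerate
    etiv = np.where(
        sex == 1,
        rng_demo.normal(1.55e6, 1.3e5, size=n),
        rng_demo.normal(1.35e6, 1.1e5, size=n),
    )

    severity = np.zeros(n)
    severity[is_ad] = rng_sev.uniform(*spec.severity_range, size=int(is_ad.sum()))

    means = _baseline_means()
    confounds = {"age": age, "etiv": etiv, "sex": sex.astype(float)}
    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    }
    for name in feature_names():
        sd = spec.noise_sd[name]
        vals = np.full(n, means[name])
        for cname, cvals in confounds.items():
            slope = spec.confound_slopes.get((name, cname), 0.0)
            if slope:
                vals = vals + slope * cvals
        effect = spec.atrophy_effect_sizes.get(name, 0.0)
        if effect:
            vals = vals + effect * sd * severity * is_ad
        vals = vals + rng_noise.normal(0.0, sd, size=n)
        data[name] = vals
    data["age"] = age
    data["sex"] = sex
    data["etiv"] = etiv
    data["diagnosis"] = np.where(is_ad, "AD", "control").astype(object)

    table = validate_feature_table(pd.DataFrame(data))
    return SyntheticCohort(features=table, latent_severity=severity, truth=spec)


def generate_cognition(
    cohort: SyntheticCohort,
    ad_scores: np.ndarray,
    cognition_spec: dict[str, CognitionSpec] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw cognitive scores linked to the AD score through a hinge.

    Below the breakpoint the association is ``slope_below_bp`` (0 by
    default); above it, ``slope_above_bp``. Returns one column per score,
    aligned with the cohort rows.
    """
    ad_scores = np.asarray(ad_scores, dtype=float)
    if len(ad_scores) != len(cohort.features):
        raise ValueError(
            f"ad_scores length {len(ad_scores)} != cohort size {len(cohort.features)}"
        )
    if np.any((ad_scores < 0) | (ad_scores > 1)):
        raise ValueError("ad_scores must lie in [0, 1]")
    specs = cognition_spec if cognition_spec is not None else cohort.truth.cognition_spec
    rng = np.random.default_rng(
        np.random.SeedSequence(cohort.truth.seed if seed is None else seed).spawn(4)[3]
    )
    out = {}
    for name, cs in specs.items():
        mean = (
            cs.control_mean
            + cs.slope_below_bp * np.minimum(ad_scores, cs.breakpoint)
            + cs.slope_above_bp * np.maximum(ad_scores - cs.breakpoint, 0.0)
        )
        out[name] = mean + rng.normal(0.0, cs.control_sd, size=len(ad_scores))
    return pd.DataFrame(out, index=cohort.features.index)


def generate_risk_factors(
    cohort: SyntheticCohort,
    ad_positive_mask: np.ndarray,
    riskfactor_spec: dict[str, RiskFactorSpec] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw risk-factor phenotypes with group shifts in the positive cohort.

    Continuous variables get an additive mean shift, binary variables a
    log-odds shift, ordinal variables a probit shift of the latent normal.
    """
    mask = np.asarray(ad_positive_mask, dtype=bool)
    if len(mask) != len(cohort.features):
        raise ValueError("ad_positive_mask misaligned with cohort")
    specs = riskfactor_spec if riskfactor_spec is not None else cohort.truth.riskfactor_spec
    rng = np.random.default_rng(
        np.random.SeedSequence(cohort.truth.seed if seed is None else seed).spawn(5)[4]
    )
    n = len(mask)
    out = {}
    for name, rs in specs.items():
        if rs.family == "gaussian":
            out[name] = rng.normal(rs.base_mean + rs.shift * mask, rs.base_sd, size=n)
        elif rs.family == "bernoulli":
            p = 1.0 / (1.0 + np.exp(-(rs.base_logit + rs.shift * mask)))
            out[name] = (rng.uniform(size=n) < p).astype(int)
        else:  # ordinal via probit-shifted latent
            latent = rng.normal(0.0, 1.0, size=n) + rs.shift * mask
            thr = np.asarray(rs.thresholds)
            if len(thr) != rs.n_levels - 1 or np.any(np.diff(thr) <= 0):
                raise ValueError(f"ordinal spec '{name}' needs {rs.n_levels - 1} ordered thresholds")
            out[name] = np.searchsorted(thr, latent).astype(int)
    return pd.DataFrame(out, index=cohort.features.index)


def null_spec(n_subjects: int = 736, seed: int = 0) -> CohortSpec:
    """A spec with no planted effects anywhere (type-I-error checks)."""
    cog = {k: replace(v, slope_below_bp=0.0, slope_above_bp=0.0) for k, v in default_cognition_spec().items()}
    risk = {k: replace(v, shift=0.0) for k, v in default_riskfactor_spec().items()}
    return CohortSpec(
        n_subjects=n_subjects,
        atrophy_effect_sizes={},
        cognition_spec=cog,
        riskfactor_spec=risk,
        seed=seed,
    )


def ordinal_latent_cdf(spec: RiskFactorSpec, shifted: bool) -> np.ndarray:
    """Exact level probabilities of an ordinal risk factor (testing aid)."""
    thr = np.asarray(spec.thresholds, dtype=float)
    shift = spec.shift if shifted else 0.0
    cum = norm.cdf(thr - shift)
    return np.diff(np.concatenate([[0.0], cum, [1.0]]))
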