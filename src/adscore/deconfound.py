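"""Per-feature confound residualization fitted on the training set only.

One ordinary-least-squares model per morphometric feature removes the linear
effects of nuisance covariates: thickness features are regressed on age;
volume features on age, estimated total intracranial volume and sex. The
residuals are then standardized with the *training* residual mean/SD. The
fitted model is a pure value: applying it to any other table never updates
its statistics, which is what prevents train/test leakage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .morphometry_io import validate_feature_table
from .schema import feature_schema

__all__ = [
    "DeconfoundError",
    "FeatureRegression",
    "DeconfoundModel",
    "fit_deconfounder",
    "apply_deconfounder",
    "save_deconfounder",
    "load_deconfounder",
]

FORMAT_VERSION = 1

THICKNESS_CONFOUNDS = ("age",)
VOLUME_CONFOUNDS = ("age", "etiv", "sex")


class DeconfoundError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureRegression:
    """OLS fit for one feature: intercept-first coefficients + residual stats."""

    name: str
    kind: str
    confounds: tuple[str, ...]
    coef: np.ndarray  # (intercept, *confounds)
    resid_mean: float
    resid_sd: float  # ddof=1 over training residuals


@dataclass(frozen=True)
class DeconfoundModel:
    entries: dict[str, FeatureRegression]
    train_hash: str
    fitted_at: str

    def __post_init__(self) -> None:
        if len(self.entries) != 155:
            raise DeconfoundError(f"expected 155 feature entries, got {len(self.entries)}")
        for e in self.entries.values():
            expected = 2 if e.kind == "thickness" else 4
            if len(e.coef) != expected:
                raise DeconfoundError(
                    f"feature '{e.name}' ({e.kind}) has {len(e.coef)} coefficients, expected {expected}"
                )
            if not e.resid_sd > 0:
                raise DeconfoundError(f"feature '{e.name}' has non-positive residual SD")


def table_hash(table: pd.DataFrame) -> str:
    """SHA-256 of the canonical CSV bytes of a feature table."""
    payload = validate_feature_table(table).to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def _design(table: pd.DataFrame, confounds: tuple[str, ...]) -> np.ndarray:
    X = table[list(confounds)].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def fit_deconfounder(train: pd.DataFrame) -> DeconfoundModel:
    """Fit the 155 per-feature OLS confound models on the training table.

    Raises on rank-deficient designs (e.g. a single-sex cohort makes the sex
    indicator collinear with the intercept) and on degenerate features whose
    residual SD is numerically zero.
    """
    train = validate_feature_table(train)
    if len(train) < 10:
        raise DeconfoundError("need at least 10 training rows")
    for conf in VOLUME_CONFOUNDS:
        if train[conf].nunique() < 2:
            raise DeconfoundError(f"confound '{conf}' is constant in the training set")

    entries: dict[str, FeatureRegression] = {}
    for desc in feature_schema():
        confounds = THICKNESS_CONFOUNDS if desc.kind == "thickness" else VOLUME_CONFOUNDS
        X = _design(train, confounds)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DeconfoundError(
                f"rank-deficient confound design for '{desc.name}' (confounds {confounds})"
            )
        y = train[desc.name].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        resid = y - X @ fit.params
        sd = float(np.std(resid, ddof=1))
        if sd < 1e-12:
            raise DeconfoundError(f"feature '{desc.name}' has degenerate residual SD < 1e-12")
        entries[desc.name] = FeatureRegression(
            name=desc.name,
            kind=desc.kind,
            confounds=confounds,
            coef=np.asarray(fit.params, dtype=float),
            resid_mean=float(np.mean(resid)),
            resid_sd=sd,
        )
    return DeconfoundModel(
        entries=entries,
        train_hash=table_hash(train),
        fitted_at=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def apply_deconfounder(model: DeconfoundModel, table: pd.DataFrame) -> pd.DataFrame:
    """Residualize and standardize a table with training statistics only.

    Output feature = (raw - confound prediction - training residual mean) /
    training residual SD. Applying the model to its own training table gives
    per-feature mean 0 and SD 1 (SD with denominator N-1).
    """
    table = validate_feature_table(table)
    out = table.copy()
    for name, e in model.entries.items():
        X = _design(table, e.confounds)
        resid = table[name].to_numpy(dtype=float) - X @ e.coef
        out[name] = (resid - e.resid_mean) / e.resid_sd
    return out


def save_deconfounder(model: DeconfoundModel, path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "train_hash": model.train_hash,
        "fitted_at": model.fitted_at,
        "entries": [
            {
                "name": e.name,
                "kind": e.kind,
                "confounds": list(e.confounds),
                "coef": [float(c) for c in e.coef],
                "resid_mean": e.resid_mean,
                "resid_sd": e.resid_sd,
            }
            for e in model.entries.values()
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_deconfounder(path, expect_train_hash: str | None = None) -> DeconfoundModel:
    """Load a persisted model; optionally verify the stored training hash."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise DeconfoundError(
            f"unsupported deconfounder format version {payload.get('format_version')!r}"
        )
    entries = {
        d["name"]: FeatureRegression(
            name=d["name"],
            kind=d["kind"],
            confounds=tuple(d["confounds"]),
            coef=np.asarray(d["coef"], dtype=float),
            resid_mean=float(d["resid_mean"]),
            resid_sd=float(d["resid_sd"]),
        )
        for d in payload["entries"]
    }
    model = DeconfoundModel(
        entries=entries, train_hash=payload["train_hash"], fitted_at=payload["fitted_at"]
    )
    if expect_train_hash is not None and expect_train_hash != model.train_hash:
        raise DeconfoundError("training-table hash mismatch on load")
    return model
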