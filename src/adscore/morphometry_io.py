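"""Feature-table I/O, validation and the stratified train/validation split.

Tables are plain pandas DataFrames in the canonical column order:
``subject_id``, the 155 morphometric features (see :mod:`adscore.schema`),
``age``, ``sex`` (0/1), ``etiv`` (mm^3), ``diagnosis`` and any extra
phenotype columns. One row per scan; baseline scans only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CONFOUND_COLUMNS, DIAGNOSIS_LEVELS, REQUIRED_COLUMNS, feature_names

__all__ = [
    "FeatureTableError",
    "SplitResult",
    "validate_feature_table",
    "read_feature_table",
    "write_feature_table",
    "stratified_split",
]


class FeatureTableError(ValueError):
    """A table does not conform to the canonical feature schema."""


def canonical_columns() -> list[str]:
    return ["subject_id", *feature_names(), *CONFOUND_COLUMNS, "diagnosis"]


def validate_feature_table(table: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate and canonicalize a feature table.

    Checks the 155-feature schema, the confound columns, label levels,
    missingness and duplicate ids, and reorders columns into canonical
    order (phenotype columns keep their relative order at the end).

    Parameters
    ----------
    table:
        Candidate table.
    strict:
        If True, unknown feature-like requirements are enforced exactly: any
        missing feature column is an error. (Extra non-feature phenotype
        columns are always allowed.)
    """
    feats = feature_names()
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FeatureTableError(f"missing required column(s): {missing}")
    missing_feats = [c for c in feats if c not in table.columns]
    if missing_feats:
        raise FeatureTableError(
            f"missing {len(missing_feats)} feature column(s), e.g. {missing_feats[:3]}"
        )

    dup = table["subject_id"].duplicated()
    if dup.any():
        raise FeatureTableError(
            f"duplicate subject_id values: {sorted(table.loc[dup, 'subject_id'].unique()[:5])}"
        )

    numeric_cols = feats + list(CONFOUND_COLUMNS)
    for col in numeric_cols:
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            bad = table.index[vals.isna()][0]
            raise FeatureTableError(f"non-numeric or missing value in column '{col}' (row {bad})")

    bad_sex = ~table["sex"].isin([0, 1])
    if bad_sex.any():
        raise FeatureTableError("column 'sex' must be coded 0/1")
    bad_dx = ~table["diagnosis"].isin(DIAGNOSIS_LEVELS)
    if bad_dx.any():
        levels = sorted(table.loc[bad_dx, "diagnosis"].unique())
        raise FeatureTableError(f"unknown diagnosis level(s): {levels}; expected {DIAGNOSIS_LEVELS}")

    phenotypes = [c for c in table.columns if c not in set(canonical_columns())]
    out = table[canonical_columns() + phenotypes].copy()
    out[feats + ["age", "etiv"]] = out[feats + ["age", "etiv"]].astype(float)
    out["sex"] = out["sex"].astype(int)
    out = out.reset_index(drop=True)
    return out


def read_feature_table(path, strict: bool = True) -> pd.DataFrame:
    """Read a delimited-text feature table and validate it.

    Feature columns permuted on disk are reordered to canonical order.
    """
    table = pd.read_csv(path)
    return validate_feature_table(table, strict=strict)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a validated feature table as CSV (round-trips with the reader)."""
    validate_feature_table(table).to_csv(path, index=False)


@dataclass
class SplitResult:
    """Disjoint train/validation id sets plus per-stratum bookkeeping."""

    train_ids: list
    validation_ids: list
    strata_report: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation ids overlap")


def _strata_labels(table: pd.DataFrame, strata: list[str]) -> pd.Series:
    """Joint stratum label; continuous columns are binned into quartiles."""
    parts = []
    for col in strata:
        s = table[col]
        if col in ("age", "etiv") or (s.dtype.kind == "f" and s.nunique() > 8):
            binned = pd.qcut(s, q=4, duplicates="drop", labels=False)
            parts.append(binned.astype(str).rename(col))
        else:
            parts.append(s.astype(str).rename(col))
    lab = parts[0].str.cat(parts[1:], sep="|") if len(parts) > 1 else parts[0]
    return lab


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float,
    strata: list[str] | None = None,
    seed: int = 0,
) -> SplitResult:
    """Split a cohort into train/validation sets preserving strata proportions.

    The total train size is exactly ``round(train_fraction * N)``; within each
    joint stratum (diagnosis x sex x age-quartile x eTIV-quartile by default)
    the train share matches the target fraction to within one subject, using
    largest-remainder apportionment. Strata with fewer than 2 members are
    assigned wholly to train with a warning. If the joint strata become too
    fragmented (more than half of subjects in singleton cells) the stratifier
    falls back to diagnosis x sex.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if strata is None:
        strata = ["diagnosis", "sex", "age", "etiv"]
    for col in strata:
        if col not in table.columns:
            raise ValueError(f"stratum column '{col}' not in table")

    n = len(table)
    n_train = int(round(train_fraction * n))
    labels = _strata_labels(table, strata)
    sizes = labels.value_counts()
    if (sizes == 1).sum() > n / 2 and {"diagnosis", "sex"} <= set(strata):
        labels = _strata_labels(table, ["diagnosis", "sex"])
        sizes = labels.value_counts()

    rng = np.random.default_rng(seed)
    ids = table["subject_id"].to_numpy()

    # Small strata go wholly to train, then apportion the remaining budget.
    small = [s for s in sizes.index if sizes[s] < 2]
    if small:
        warnings.warn(
            f"{len(small)} stratum(s) with <2 members assigned wholly to the training set",
            stacklevel=2,
        )
    forced_train = labels.isin(small)
    budget = n_train - int(forced_train.sum())
    budget = max(budget, 0)

    big = [s for s in sizes.index if sizes[s] >= 2]
    counts = np.array([sizes[s] for s in big], dtype=float)
    report_rows = []
    train_ids: list = list(ids[forced_train.to_numpy()])
    if big:
        ideal = counts * budget / counts.sum()
        base = np.floor(ideal).astype(int)
        base = np.minimum(base, counts.astype(int))
        remainder = budget - base.sum()
        order = np.argsort(-(ideal - base))
        for j in order:
            if remainder <= 0:
                break
            if base[j] < counts[j]:
                base[j] += 1
                remainder -= 1
        for s, k in zip(big, base):
            members = ids[(labels == s).to_numpy()]
            perm = rng.permutation(len(members))
            chosen = members[perm[: int(k)]]
            train_ids.extend(chosen)
            report_rows.append({"stratum": s, "n": len(members), "n_train": int(k)})
    for s in small:
        report_rows.append({"stratum": s, "n": int(sizes[s]), "n_train": int(sizes[s])})

    train_set = set(train_ids)
    val_ids = [i for i in ids if i not in train_set]
    report = pd.DataFrame(report_rows)
    return SplitResult(train_ids=sorted(train_ids), validation_ids=sorted(val_ids), strata_report=report)
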