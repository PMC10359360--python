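"""Canonical morphometric feature schema.

The AD-score model consumes a fixed, ordered table of 155 FreeSurfer-derived
features per scan: cortical thickness (mm) and cortical gray-matter volume
(mm^3) for the 68 surface regions of the Desikan-Killiany atlas (34 per
hemisphere), the brainstem volume, and 9 subcortical volumes per hemisphere.
Every module in this package refers to this single schema; the feature *kind*
(thickness vs volume) also decides the confound design used when
residualizing (thickness ~ age; volume ~ age + eTIV + sex).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

__all__ = [
    "FeatureDescriptor",
    "feature_schema",
    "feature_names",
    "thickness_names",
    "volume_names",
    "CONFOUND_COLUMNS",
    "REQUIRED_COLUMNS",
    "DIAGNOSIS_LEVELS",
]

# 34 cortical regions per hemisphere in the Desikan-Killiany parcellation.
DESIKAN_KILLIANY_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

# 9 subcortical structures segmented per hemisphere.
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "cerebellum_white_matter",
    "cerebellum_cortex",
    "thalamus_proper",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens_area",
)

HEMISPHERES: tuple[str, ...] = ("lh", "rh")

CONFOUND_COLUMNS: tuple[str, ...] = ("age", "sex", "etiv")
REQUIRED_COLUMNS: tuple[str, ...] = ("subject_id",) + CONFOUND_COLUMNS + ("diagnosis",)
DIAGNOSIS_LEVELS: tuple[str, ...] = ("AD", "control", "other", "unknown")

Kind = Literal["thickness", "volume"]


@dataclass(frozen=True)
class FeatureDescriptor:
    """One morphometric feature: its column name, measurement kind and side."""

    name: str
    kind: Kind
    hemisphere: str  # "lh", "rh" or "midline"


@lru_cache(maxsize=1)
def feature_schema() -> tuple[FeatureDescriptor, ...]:
    """Return the ordered 155-entry feature schema.

    Order: 68 cortical thickness (lh then rh), 68 cortical volumes
    (lh then rh), brainstem volume, then 9 subcortical volumes for each
    hemisphere. The tuple is cached and immutable.
    """
    entries: list[FeatureDescriptor] = []
    for hemi in HEMISPHERES:
        for region in DESIKAN_KILLIANY_REGIONS:
            entries.append(FeatureDescriptor(f"{hemi}_{region}_thickness", "thickness", hemi))
    for hemi in HEMISPHERES:
        for region in DESIKAN_KILLIANY_REGIONS:
            entries.append(FeatureDescriptor(f"{hemi}_{region}_volume", "volume", hemi))
    entries.append(FeatureDescriptor("brainstem_volume", "volume", "midline"))
    for hemi in HEMISPHERES:
        for structure in SUBCORTICAL_STRUCTURES:
            entries.append(FeatureDescriptor(f"{hemi}_{structure}_volume", "volume", hemi))
    assert len(entries) == 155
    return tuple(entries)


def feature_names() -> list[str]:
    """Ordered list of the 155 canonical feature column names."""
    return [d.name for d in feature_schema()]


def thickness_names() -> list[str]:
    return [d.name for d in feature_schema() if d.kind == "thickness"]


def volume_names() -> list[str]:
    return [d.name for d in feature_schema() if d.kind == "volume"]
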