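"""Cortical parcellation tables, composite ROIs and lobe groupings.

Regional analyses run over the 34 bilateral cortical regions of the
Desikan-Killiany atlas (68 ROIs total).  A bundled fixture table ships
the ROI names, hemispheres, integer labels and typical adult
gray-matter volumes; real analyses replace the volumes with
subject-specific values from the segmentation.

A ``RegionTable`` is a plain :class:`pandas.DataFrame` with columns
``roi_id, roi_name, hemisphere, volume_mm3, value`` — no wrapper class;
helpers here validate and serialize it.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .frames import volume_weighted_mean

__all__ = [
    "cortical_roi_table",
    "validate_region_table",
    "read_region_table",
    "write_region_table",
    "composite_value",
    "TEMPORAL_META_ROI",
    "LOBES",
    "DK_CORTICAL_NAMES",
]

# Desikan-Killiany cortical parcellation, alphabetical order.
DK_CORTICAL_NAMES: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

# Composite ROI sensitive to AD-related neurodegeneration: the
# volume-weighted average of six temporal-lobe structures.  The amygdala
# is subcortical and therefore not part of the 68-ROI cortical table; the
# synthetic cohort simulates it alongside the cortical set.
TEMPORAL_META_ROI: tuple[str, ...] = (
    "entorhinal", "amygdala", "parahippocampal", "fusiform",
    "inferiortemporal", "middletemporal",
)

# Conventional FreeSurfer lobe groupings of the cortical parcels.
LOBES: dict[str, tuple[str, ...]] = {
    "frontal": ("superiorfrontal", "rostralmiddlefrontal", "caudalmiddlefrontal",
                "parsopercularis", "parstriangularis", "parsorbitalis",
                "lateralorbitofrontal", "medialorbitofrontal", "precentral",
                "paracentral", "frontalpole"),
    "parietal": ("superiorparietal", "inferiorparietal", "supramarginal",
                 "postcentral", "precuneus"),
    "temporal": ("superiortemporal", "middletemporal", "inferiortemporal",
                 "bankssts", "fusiform", "transversetemporal", "entorhinal",
                 "temporalpole", "parahippocampal"),
    "occipital": ("lateraloccipital", "lingual", "cuneus", "pericalcarine"),
    "cingulate": ("rostralanteriorcingulate", "caudalanteriorcingulate",
                  "posteriorcingulate", "isthmuscingulate"),
    "insula": ("insula",),
}

REGION_TABLE_COLUMNS = ["roi_id", "roi_name", "hemisphere", "volume_mm3", "value"]


def cortical_roi_table() -> pd.DataFrame:
    """The bundled bilateral cortical ROI fixture (68 rows).

    Columns ``roi_id, roi_name, hemisphere, volume_mm3``.  Labels follow
    the aparc+aseg convention (1000+/2000+ offsets for left/right
    cortex); volumes are typical adult values in mm^3.
    """
    ref = importlib.resources.files("synpet").joinpath("data/dk_rois.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df


def validate_region_table(df: pd.DataFrame, require_value: bool = True) -> pd.DataFrame:
    cols = REGION_TABLE_COLUMNS if require_value else REGION_TABLE_COLUMNS[:-1]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"region table missing columns {missing}")
    if df["roi_id"].duplicated().any():
        dupes = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValueError(f"duplicate roi_id entries: {dupes}")
    if (df["volume_mm3"] <= 0).any():
        raise ValueError("all ROI volumes must be positive")
    return df


def read_region_table(path) -> pd.DataFrame:
    return validate_region_table(pd.read_csv(path, sep="\t"))


def write_region_table(df: pd.DataFrame, path) -> None:
    validate_region_table(df).to_csv(path, sep="\t", index=False)


def composite_value(table: pd.DataFrame, roi_names, bilateral: bool = True) -> float:
    """Volume-weighted composite over named ROIs (both hemispheres by
    default).  Raises if any requested region is absent."""
    roi_names = list(roi_names)
    sub = table[table["roi_name"].isin(roi_names)]
    present = set(sub["roi_name"])
    absent = [n for n in roi_names if n not in present]
    if absent:
        raise ValueError(f"composite ROI regions missing from table: {absent}")
    if not bilateral:
        sub = sub[sub["hemisphere"] == "lh"]
    return volume_weighted_mean(sub["value"].to_numpy(), sub["volume_mm3"].to_numpy())


def lobe_values(table: pd.DataFrame) -> dict[str, float]:
    """Volume-weighted mean value per lobe grouping."""
    out = {}
    for lobe, names in LOBES.items():
        sub = table[table["roi_name"].isin(names)]
        if len(sub) == 0:
            continue
        out[lobe] = volume_weighted_mean(sub["value"].to_numpy(), sub["volume_mm3"].to_numpy())
    return out
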