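"""Region and measure vocabularies shared across the package.

The cortical parcellation is the 68-region Desikan-Killiany atlas (34
regions per hemisphere, ``lh_``/``rh_`` prefixes).  Behavioral measures are
the four BIS/BAS subscales and the five UPPS-P short-form subscales.
"""

from __future__ import annotations

# 34 Desikan-Killiany cortical region names (one hemisphere).
_DK_BASE = (
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

#: 68 region labels, left hemisphere first then right, mirroring the
#: bilateral ordering used throughout (region j and j+34 are homologues).
DK_REGIONS: tuple[str, ...] = tuple(f"lh_{r}" for r in _DK_BASE) + tuple(
    f"rh_{r}" for r in _DK_BASE
)

N_REGIONS = len(DK_REGIONS)  # 68

#: Neuroanatomical modalities: mean cortical thickness, total surface area,
#: total gray matter volume per region.
MODALITIES: tuple[str, ...] = ("CT", "SA", "GMV")

#: Modalities whose raw values scale with head size and are proportionally
#: corrected by dividing by intracranial volume.  CT is not.
ICV_SCALED_MODALITIES: frozenset[str] = frozenset({"SA", "GMV"})

BIS_BAS_MEASURES: tuple[str, ...] = (
    "bis_inhibition",
    "bas_reward_responsiveness",
    "bas_drive",
    "bas_fun_seeking",
)

UPPS_P_MEASURES: tuple[str, ...] = (
    "upps_negative_urgency",
    "upps_positive_urgency",
    "upps_lack_of_planning",
    "upps_lack_of_perseverance",
    "upps_sensation_seeking",
)

MEASURES: tuple[str, ...] = BIS_BAS_MEASURES + UPPS_P_MEASURES

#: Scale family of each measure; BH-FDR correction is applied within scale.
MEASURE_SCALE: dict[str, str] = {m: "BIS/BAS" for m in BIS_BAS_MEASURES} | {
    m: "UPPS-P" for m in UPPS_P_MEASURES
}

SEX_GROUPS: tuple[str, ...] = ("all", "F", "M")
TIMEPOINTS: tuple[str, ...] = ("baseline", "year2")


def feature_column(modality: str, region: str) -> str:
    """Column name used for one regional feature, e.g. ``ct_lh_insula``."""
    return f"{modality.lower()}_{region}"


def feature_columns(modality: str, regions=DK_REGIONS) -> list[str]:
    return [feature_column(modality, r) for r in regions]
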