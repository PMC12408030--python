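"""Feature preparation: ICV proportional correction and per-cell design
matrices.

SA and GMV scale with head size and are proportionally corrected by dividing
each participant's raw regional values by their intracranial volume; CT is
used as-is.  One analysis cell is a (modality, measure, sex-group,
timepoint) combination with an aligned feature matrix and behavior vector;
feature standardization is deliberately NOT done here — it happens inside
the modeling loop using training-fold statistics only, so no test-set
information ever enters a fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._regions import (
    DK_REGIONS,
    ICV_SCALED_MODALITIES,
    MEASURES,
    MODALITIES,
    SEX_GROUPS,
    feature_columns,
)

__all__ = [
    "FeatureMatrix",
    "AnalysisCell",
    "icv_correct",
    "build_cells",
    "load_column_mapping",
    "apply_column_mapping",
    "residualize",
]

logger = logging.getLogger(__name__)


class IcvError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """n_subjects x n_regions regional values for one modality."""

    values: np.ndarray
    modality: str
    region_labels: tuple[str, ...]
    subject_ids: tuple[str, ...]
    corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != len(self.region_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.region_labels)} region labels"
            )
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.subject_ids)} subject ids"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class AnalysisCell:
    """One modeling unit: features and one behavior for one subject group."""

    modality: str
    measure: str
    sex_group: str
    timepoint: str
    X: FeatureMatrix
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape[0] != self.X.n_subjects:
            raise ValueError("X rows and y entries are not aligned")

    @property
    def cell_id(self) -> str:
        return f"{self.modality}:{self.measure}:{self.sex_group}:{self.timepoint}"

    @property
    def n(self) -> int:
        return self.y.shape[0]


def icv_correct(raw: FeatureMatrix, icv: Sequence[float] | np.ndarray) -> FeatureMatrix:
    """Divide each subject's row by their intracranial volume.

    Only SA and GMV are eligible; applying the correction to CT is refused.
    The operation is exactly inverted by elementwise multiplication with ICV.
    """
    if raw.modality not in ICV_SCALED_MODALITIES:
        raise IcvError(
            f"ICV correction refused for modality {raw.modality!r}: only "
            f"{sorted(ICV_SCALED_MODALITIES)} are proportionally corrected"
        )
    icv = np.asarray(icv, dtype=float)
    if icv.shape[0] != raw.n_subjects:
        raise IcvError(
            f"got {icv.shape[0]} ICV values for {raw.n_subjects} subjects"
        )
    bad = ~(icv > 0) | ~np.isfinite(icv)
    if np.any(bad):
        bad_ids = [raw.subject_ids[i] for i in np.flatnonzero(bad)]
        raise IcvError(f"non-positive or missing ICV for subjects: {bad_ids}")
    return FeatureMatrix(
        values=raw.values / icv[:, None],
        modality=raw.modality,
        region_labels=raw.region_labels,
        subject_ids=raw.subject_ids,
        corrected=True,
    )


def load_column_mapping(path: str | Path) -> dict:
    """Read a YAML/JSON column-mapping config ({their_column: our_column})."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise ValueError(f"column mapping in {path} is not a mapping")
    return dict(mapping)


def apply_column_mapping(cohort: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    return cohort.rename(columns=dict(mapping))


def residualize(X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Optional hook: OLS-residualize feature columns on covariates.

    Not part of the default pipeline (no covariate regression is applied
    before modeling); provided for sensitivity analyses.
    """
    X = np.asarray(X, dtype=float)
    C = np.column_stack([np.ones(len(X)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(C, X, rcond=None)
    return X - C @ beta


@dataclass
class CellManifest:
    """Bookkeeping for a build_cells run: rows dropped and cells excluded."""

    dropped_rows: dict[str, int] = field(default_factory=dict)
    excluded_cells: dict[str, int] = field(default_factory=dict)


def build_cells(
    cohort: pd.DataFrame,
    min_n: int = 100,
    modalities: Sequence[str] = MODALITIES,
    measures: Sequence[str] = MEASURES,
    sex_groups: Sequence[str] = SEX_GROUPS,
    region_labels: Sequence[str] = DK_REGIONS,
    column_mapping: Mapping[str, str] | None = None,
) -> tuple[list[AnalysisCell], CellManifest]:
    """Assemble one AnalysisCell per (modality, measure, sex-group,
    timepoint), applying ICV correction to SA/GMV and complete-case deletion
    per cell.

    Rows missing any feature of the cell's modality or the cell's behavior
    score are dropped from that cell only (count recorded in the manifest).
    Cells below ``min_n`` complete rows are excluded with a warning and a
    manifest entry.
    """
    if column_mapping:
        cohort = apply_column_mapping(cohort, column_mapping)
    required = {"participant_id", "sex", "timepoint", "icv"}
    missing_cols = required - set(cohort.columns)
    if missing_cols:
        raise ValueError(f"cohort table lacks required columns: {sorted(missing_cols)}")

    timepoints = [t for t in ("baseline", "year2") if t in set(cohort["timepoint"])]
    timepoints = timepoints or sorted(set(cohort["timepoint"]))
    cells: list[AnalysisCell] = []
    manifest = CellManifest()

    for tp in timepoints:
        tp_rows = cohort[cohort["timepoint"] == tp]
        for sex_group in sex_groups:
            sub = tp_rows if sex_group == "all" else tp_rows[tp_rows["sex"] == sex_group]
            if len(sub) == 0:
                continue
            for modality in modalities:
                cols = feature_columns(modality, region_labels)
                feats = sub[cols].to_numpy(dtype=float)
                icv = sub["icv"].to_numpy(dtype=float)
                ids = sub["participant_id"].astype(str).to_numpy()
                for measure in measures:
                    y = sub[measure].to_numpy(dtype=float)
                    ok = np.isfinite(feats).all(axis=1) & np.isfinite(y)
                    cell_id = f"{modality}:{measure}:{sex_group}:{tp}"
                    n_drop = int((~ok).sum())
                    if n_drop:
                        manifest.dropped_rows[cell_id] = n_drop
                        logger.info("%s: dropped %d incomplete rows", cell_id, n_drop)
                    if int(ok.sum()) < min_n:
                        manifest.excluded_cells[cell_id] = int(ok.sum())
                        logger.warning(
                            "%s excluded: %d complete rows < min_n=%d",
                            cell_id, int(ok.sum()), min_n,
                        )
                        continue
                    fm = FeatureMatrix(
                        values=feats[ok],
                        modality=modality,
                        region_labels=tuple(region_labels),
                        subject_ids=tuple(ids[ok]),
                        corrected=False,
                    )
                    if modality in ICV_SCALED_MODALITIES:
                        fm = icv_correct(fm, icv[ok])
                    cells.append(
                        AnalysisCell(
                            modality=modality,
                            measure=measure,
                            sex_group=sex_group,
                            timepoint=tp,
                            X=fm,
                            y=y[ok],
                        )
                    )
    return cells, manifest
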