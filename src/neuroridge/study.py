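"""End-to-end study orchestration over all analysis cells.

Runs the full analysis on a cohort table: cell assembly (3 modalities x 9
measures x 3 sex-groups x timepoints), cross-validated ridge fits,
permutation nulls, within-scale FDR, Haufe importance maps for significant
cells, and gated cosine-similarity matrices per modality.  Outputs are tidy
TSV/JSON files mirroring the tables and similarity panels such an analysis
reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._regions import MODALITIES
from .descriptives import compare_groups, measure_correlations
from .importance import ImportanceMap, mean_importance
from .inference import (
    NullDistribution,
    empirical_pvalue,
    summaries_to_frame,
    summarize_runs,
)
from .preprocess import CellManifest, build_cells
from .ridge import ModelConfig, RidgePredictionResults, run_cell
from .similarity import SimilarityMatrix, compare_maps

__all__ = ["StudyResult", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything a full study run produces, in memory."""

    summaries: pd.DataFrame
    importance_maps: dict[str, ImportanceMap]
    similarity: dict[str, SimilarityMatrix]
    manifest: CellManifest
    descriptives: pd.DataFrame | None = None
    correlations: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def significant_cells(self) -> list[str]:
        s = self.summaries
        return list(s.loc[s["significant"].fillna(False), "cell_id"])


def run_study(
    cohort: pd.DataFrame,
    model_config: ModelConfig | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    min_n: int = 100,
    outdir: str | Path | None = None,
    with_descriptives: bool = True,
    importance_for_all: bool = False,
) -> StudyResult:
    """Run the complete pipeline on a cohort table.

    ``seed`` drives the permutation stream (the split plan comes from
    ``model_config.seed``).  Importance maps are computed for significant
    cells only unless ``importance_for_all`` (maps are computable for any
    cell; the gate is about what enters comparisons and reports).
    """
    model_config = model_config or ModelConfig()
    cells, manifest = build_cells(cohort, min_n=min_n)
    logger.info("running %d cells", len(cells))

    runs: list[RidgePredictionResults] = []
    nulls: list[NullDistribution] = []
    rng = np.random.default_rng(seed)
    for cell in cells:
        res = run_cell(cell, model_config)
        null = res.permutation_test(
            n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1))
        )
        res.engine = None  # free the precomputed split plan
        res.response = None
        runs.append(res)
        nulls.append(null)

    summaries = summaries_to_frame(summarize_runs(runs, nulls, q=q))
    sig = dict(zip(summaries["cell_id"], summaries["significant"].fillna(False)))

    maps: dict[str, ImportanceMap] = {}
    for res in runs:
        if importance_for_all or sig.get(res.cell_id, False):
            maps[res.cell_id] = mean_importance(res)

    similarity: dict[str, SimilarityMatrix] = {}
    for modality in MODALITIES:
        mod_maps = [m for m in maps.values() if m.meta.get("modality") == modality]
        if mod_maps:
            similarity[modality] = compare_maps(mod_maps, significant=sig)

    descriptives = None
    correlations: dict[tuple[str, str], pd.DataFrame] = {}
    if with_descriptives:
        descriptives = compare_groups(cohort, q=q)
        for tp in sorted(set(cohort["timepoint"])):
            for grp in ("all", "F", "M"):
                try:
                    correlations[(grp, tp)] = measure_correlations(cohort, grp, tp)
                except ValueError:
                    pass

    result = StudyResult(
        summaries=summaries,
        importance_maps=maps,
        similarity=similarity,
        manifest=manifest,
        descriptives=descriptives,
        correlations=correlations,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.summaries.to_csv(outdir / "summaries.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(
            {
                "dropped_rows": result.manifest.dropped_rows,
                "excluded_cells": result.manifest.excluded_cells,
            },
            indent=1,
        )
    )
    imp_dir = outdir / "importance"
    imp_dir.mkdir(exist_ok=True)
    for cid, m in result.importance_maps.items():
        m.save(imp_dir / f"{cid.replace(':', '_')}.tsv")
    sim_dir = outdir / "similarity"
    sim_dir.mkdir(exist_ok=True)
    for modality, sm in result.similarity.items():
        sm.save(sim_dir / f"{modality}.tsv", sim_dir / f"{modality}_gate.json")
    if result.descriptives is not None:
        result.descriptives.to_csv(outdir / "group_comparisons.tsv", sep="\t", index=False)
    for (grp, tp), corr in result.correlations.items():
        corr.to_csv(outdir / f"correlations_{grp}_{tp}.tsv", sep="\t")
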