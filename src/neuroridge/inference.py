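"""Permutation nulls, empirical p-values and within-scale BH-FDR.

Significance of a cell's prediction accuracy is assessed against a null
distribution built by randomly permuting the behavior vector across
subjects and re-executing the complete pipeline — including penalty
re-selection — for every permutation.  The empirical p-value uses the
standard add-one estimator, one-sided (only high accuracy counts as
signal).  p-values are corrected within each behavioral scale family
(BIS/BAS vs UPPS-P, per modality x sex-group x timepoint batch) with the
Benjamini-Hochberg step-up procedure at q = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._regions import MEASURE_SCALE
from .preprocess import AnalysisCell
from .ridge import CellEngine, ModelConfig, RidgePredictionResults

__all__ = [
    "NullDistribution",
    "PredictionSummary",
    "permutation_null",
    "empirical_pvalue",
    "bh_adjust",
    "bh_fdr",
    "summarize_runs",
]


@dataclass
class NullDistribution:
    """Permutation null for one cell's mean test accuracy."""

    cell_id: str
    null_accuracies: np.ndarray
    seed: int

    @property
    def n_permutations(self) -> int:
        return len(self.null_accuracies)


@dataclass
class PredictionSummary:
    """Observed accuracy with its permutation p and FDR-adjusted p."""

    cell_id: str
    observed_r: float
    p: float
    p_fdr: float
    significant: bool
    scale_group: str


def permutation_null(
    cell: AnalysisCell | RidgePredictionResults,
    model_config: ModelConfig | None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of mean test accuracy under permuted behavior.

    Accepts either an analysis cell (a fresh engine is built) or an already
    fitted :class:`RidgePredictionResults` (its engine — the identical split
    plan used for the observed accuracy — is reused).  Each permutation
    shuffles y across subjects and re-runs the full nested pipeline,
    penalty selection included.  Deterministic given ``seed``.
    """
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} < 100: empirical p-values will "
            "be coarse",
            stacklevel=2,
        )
    if isinstance(cell, RidgePredictionResults):
        if cell.engine is None or cell.response is None:
            raise ValueError(
                "results object carries no engine/response; refit the model "
                "or pass the AnalysisCell instead"
            )
        engine = cell.engine
        y = cell.response
        cell_id = cell.cell_id
    else:
        engine = CellEngine(cell.X.values, model_config or ModelConfig())
        y = cell.y
        cell_id = cell.cell_id
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_permutations)
    block = 256  # batch size: amortizes overhead, caps memory
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        Y = np.empty((len(y), b))
        for j in range(b):
            Y[:, j] = rng.permutation(y)
        nulls[done : done + b] = engine.batch_mean_accuracies(Y)
        done += b
    return NullDistribution(cell_id=cell_id, null_accuracies=nulls, seed=seed)


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """One-sided add-one permutation p: (1 + #{null >= observed}) / (1 + B)."""
    nulls = np.asarray(null.null_accuracies, dtype=float)
    if nulls.size == 0:
        raise ValueError("null distribution is empty")
    n_ge = int(np.sum(nulls >= observed))
    return (1 + n_ge) / (1 + nulls.size)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bh_fdr(
    pvalues: Mapping[str, float],
    groups: Mapping[str, str],
    q: float = 0.05,
) -> dict[str, tuple[float, bool]]:
    """Group-wise BH correction: each group is its own family.

    Returns {name: (p_fdr, significant at p_fdr <= q)}.  Names missing a
    group label raise; empty groups are skipped with a warning.
    """
    names = list(pvalues)
    missing = [n for n in names if n not in groups]
    if missing:
        raise ValueError(f"no scale group for entries: {missing}")
    out: dict[str, tuple[float, bool]] = {}
    for g in dict.fromkeys(groups[n] for n in names):
        members = [n for n in names if groups[n] == g]
        if not members:
            warnings.warn(f"empty FDR group {g!r} skipped", stacklevel=2)
            continue
        adj = bh_adjust([pvalues[n] for n in members])
        for n, a in zip(members, adj):
            out[n] = (float(a), bool(a <= q))
    return out


def summarize_runs(
    runs: Sequence[RidgePredictionResults],
    nulls: Sequence[NullDistribution],
    q: float = 0.05,
) -> list[PredictionSummary]:
    """Empirical p per run, then BH within scale family per
    modality x sex-group x timepoint batch.

    Runs whose observed accuracy is undefined (all splits degenerate) are
    excluded from correction and reported with p = NaN.
    """
    by_id = {n.cell_id: n for n in nulls}
    pvals: dict[str, float] = {}
    fam: dict[str, str] = {}
    obs: dict[str, float] = {}
    meta: dict[str, dict] = {}
    for run in runs:
        cid = run.cell_id
        if cid not in by_id:
            raise ValueError(f"no null distribution for cell {cid}")
        r = run.mean_accuracy
        obs[cid] = r
        meta[cid] = run.meta
        if np.isnan(r):
            continue
        pvals[cid] = empirical_pvalue(r, by_id[cid])
        m = run.meta
        scale = MEASURE_SCALE.get(m.get("measure", ""), "other")
        fam[cid] = (
            f"{scale}|{m.get('modality', '?')}|{m.get('sex_group', '?')}"
            f"|{m.get('timepoint', '?')}"
        )
    adjusted = bh_fdr(pvals, fam, q=q)
    summaries = []
    for run in runs:
        cid = run.cell_id
        scale = MEASURE_SCALE.get(run.meta.get("measure", ""), "other")
        if cid in adjusted:
            p_fdr, sig = adjusted[cid]
            summaries.append(
                PredictionSummary(cid, obs[cid], pvals[cid], p_fdr, sig, scale)
            )
        else:
            summaries.append(
                PredictionSummary(cid, obs[cid], np.nan, np.nan, False, scale)
            )
    return summaries


def summaries_to_frame(summaries: Sequence[PredictionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [s.cell_id for s in summaries],
            "observed_r": [s.observed_r for s in summaries],
            "p": [s.p for s in summaries],
            "p_fdr": [s.p_fdr for s in summaries],
            "significant": [s.significant for s in summaries],
            "scale": [s.scale_group for s in summaries],
        }
    )
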