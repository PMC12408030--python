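"""Cosine similarity between importance maps, with significance gating.

Overlap between the regional patterns associated with different measures,
sexes or timepoints is quantified by the cosine similarity of their mean
Haufe importance maps.  Maps from cells that did not reach significance are
excluded entirely (their rows/columns are masked), so in particular a
female/male contrast is only ever computed when BOTH sexes' cells are
significant.  Cosine is computed on the raw (unnormalized) mean importance;
it is scale-free, so the display normalization would not change it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .importance import ImportanceMap

__all__ = ["SimilarityMatrix", "cosine_similarity", "compare_maps"]


class ZeroNormError(ValueError):
    """Cosine similarity is undefined for a zero-norm vector."""


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """s = (u . v) / (||u|| ||v||), in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D and equal length")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ZeroNormError("cosine similarity undefined for a zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


@dataclass
class SimilarityMatrix:
    """Symmetric cosine-similarity matrix over importance maps.

    Entries involving an ineligible (non-significant or degenerate) map are
    NaN and flagged in ``mask`` (True = defined).  The diagonal is 1 for
    every eligible map.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray
    gate: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def save(self, path: str | Path, gate_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t")
        if gate_path is not None:
            Path(gate_path).write_text(json.dumps(self.gate, indent=1))

    def lookup(self, a: str, b: str) -> float:
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])


def compare_maps(
    maps: Sequence[ImportanceMap],
    significant: Mapping[str, bool] | None = None,
) -> SimilarityMatrix:
    """All pairwise cosine similarities among eligible maps.

    A map is eligible when its cell is flagged significant (all maps are
    eligible if ``significant`` is None — the configurable override) and it
    is not all-zero.  Rows/columns of ineligible maps are masked, mirroring
    blank rows in a similarity panel; consequently no sex or timepoint
    contrast is emitted unless both cells involved are significant.
    """
    if not maps:
        raise ValueError("no maps to compare")
    labels = tuple(m.cell_id for m in maps)
    ref = maps[0].region_labels
    for m in maps[1:]:
        if m.region_labels != ref:
            raise ValueError(
                f"inconsistent region labels between {maps[0].cell_id} and {m.cell_id}"
            )
    if any(len(m.values) != len(maps[0].values) for m in maps):
        raise ValueError("maps have inconsistent lengths")

    gate: dict[str, bool] = {}
    for m in maps:
        ok = True if significant is None else bool(significant.get(m.cell_id, False))
        gate[m.cell_id] = ok and not m.degenerate
    k = len(maps)
    values = np.full((k, k), np.nan)
    for i in range(k):
        if not gate[labels[i]]:
            continue
        values[i, i] = 1.0
        for j in range(i + 1, k):
            if not gate[labels[j]]:
                continue
            s = cosine_similarity(maps[i].values, maps[j].values)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(
        labels=labels, values=values, mask=~np.isnan(values), gate=gate
    )
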