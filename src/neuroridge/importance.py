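"""Haufe-transformed feature importance maps.

Ridge weights are backward-model parameters and are not directly
interpretable region by region; the Haufe transformation converts them into
a forward activation pattern by taking, for each feature, its sample
covariance with the model's fitted scores on the training data:

    a_j = cov(x_j, X w)   equivalently   a = Sigma_hat_X w

with the covariance computed over training subjects only (denominator
n - 1).  Per-split activations are averaged across outer splits to give a
cell's mean importance map; a max-absolute-normalized variant is kept for
display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ridge import RidgePredictionResults

__all__ = ["ImportanceMap", "haufe_transform", "mean_importance"]


def haufe_transform(X_train: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Forward activation pattern of a linear model on its training data.

    ``X_train`` must be the same (standardized) training matrix the weights
    were fitted on.  Returns cov(x_j, X_train @ weights) per column, with
    denominator n - 1.
    """
    X_train = np.asarray(X_train, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if X_train.ndim != 2 or weights.ndim != 1 or X_train.shape[1] != weights.shape[0]:
        raise ValueError(
            f"dimension mismatch: X_train {X_train.shape}, weights {weights.shape}"
        )
    n = X_train.shape[0]
    if n < 2:
        raise ValueError("need at least 2 training rows for a covariance")
    Xc = X_train - X_train.mean(axis=0)
    return Xc.T @ (Xc @ weights) / (n - 1)


def _normalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    peak = float(np.max(np.abs(values))) if values.size else 0.0
    if peak == 0.0:
        return values.copy(), True
    return values / peak, False


@dataclass
class ImportanceMap:
    """Mean Haufe importance for one cell, with a display-normalized copy.

    ``normalized_values`` is ``values`` divided by its maximum absolute
    entry, so the largest-magnitude region is exactly +/-1; an all-zero map
    is flagged ``degenerate`` instead of divided.
    """

    cell_id: str
    values: np.ndarray
    normalized_values: np.ndarray
    n_splits: int
    region_labels: tuple[str, ...] | None = None
    degenerate: bool = False
    meta: dict | None = None

    @classmethod
    def from_values(
        cls,
        cell_id: str,
        values: np.ndarray,
        n_splits: int = 1,
        region_labels=None,
        meta=None,
    ) -> "ImportanceMap":
        values = np.asarray(values, dtype=float)
        normalized, degenerate = _normalize(values)
        return cls(
            cell_id=cell_id,
            values=values,
            normalized_values=normalized,
            n_splits=n_splits,
            region_labels=tuple(region_labels) if region_labels else None,
            degenerate=degenerate,
            meta=meta,
        )

    def normalized(self) -> "ImportanceMap":
        """Max-absolute-normalized copy (idempotent)."""
        return ImportanceMap.from_values(
            self.cell_id,
            self.normalized_values,
            n_splits=self.n_splits,
            region_labels=self.region_labels,
            meta=self.meta,
        )

    def to_frame(self) -> pd.DataFrame:
        labels = self.region_labels or tuple(
            f"region_{i:02d}" for i in range(len(self.values))
        )
        return pd.DataFrame(
            {
                "region": labels,
                "importance": self.values,
                "importance_normalized": self.normalized_values,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def mean_importance(run: RidgePredictionResults) -> ImportanceMap:
    """Average the per-split Haufe activations of a fitted run.

    Importance is computable for any fitted run; whether a map should enter
    downstream comparisons (the significance gate) is decided by the
    comparison stage, not here.
    """
    acts = np.asarray(run.activations, dtype=float)
    if acts.size == 0:
        raise ValueError(f"run {run.cell_id} has no fitted splits to average")
    return ImportanceMap.from_values(
        run.cell_id,
        acts.mean(axis=0),
        n_splits=acts.shape[0],
        region_labels=run.region_labels,
        meta=run.meta,
    )
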