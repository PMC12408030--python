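"""Cross-validated linear ridge regression for brain-behavior prediction.

One model predicts one behavioral measure from 68 regional features for one
subject group.  The resampling scheme is repeated random train/test splits
(default 100 splits, 80/20); within each training set the penalty is chosen
by inner k-fold cross-validation maximizing the held-out correlation between
observed and predicted scores.  Feature standardization and response
centering always use training statistics only, applied unchanged to test
rows, so fitted weights are a pure function of training data.

Performance is quantified as prediction accuracy: the Pearson correlation
between observed and predicted scores on held-out subjects, averaged over
splits.

The public surface follows the model/results idiom:

>>> model = RidgePredictionModel.from_cell(cell)
>>> res = model.fit(ModelConfig(seed=0))
>>> res.mean_accuracy
>>> res.summary()

Internally a :class:`CellEngine` precomputes everything that depends only on
the feature matrix and the split plan (split indices, standardization
statistics, Gram matrices).  Refitting with a new response — the whole job
of a permutation null — then costs only the response-dependent algebra,
while remaining numerically identical to rerunning the full pipeline.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, ShuffleSplit

from .preprocess import AnalysisCell

__all__ = [
    "ModelConfig",
    "RidgePredictionModel",
    "RidgePredictionResults",
    "ModelRun",
    "fit_ridge",
    "select_lambda",
    "run_cell",
    "prediction_accuracy",
    "UndefinedAccuracyError",
    "SingularityError",
]

logger = logging.getLogger(__name__)

_DEFAULT_GRID = tuple(float(x) for x in np.logspace(-3, 4, 16))


class UndefinedAccuracyError(ValueError):
    """Prediction accuracy is undefined (constant input or too few points)."""


class SingularityError(np.linalg.LinAlgError):
    """Unpenalized normal equations are singular (rank-deficient X'X)."""


@dataclass(frozen=True)
class ModelConfig:
    """Resampling and penalty-selection settings for one model.

    The default grid spans under- to over-penalized regimes for
    standardized 68-feature problems.  ``scheme`` may be ``"shuffle"``
    (repeated random splits; default) or ``"kfold"``.
    """

    lambda_grid: tuple[float, ...] = _DEFAULT_GRID
    n_outer_splits: int = 100
    test_fraction: float = 0.2
    n_inner_folds: int = 5
    seed: int = 0
    standardize: bool = True
    scheme: str = "shuffle"

    def __post_init__(self) -> None:
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be nonempty")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("penalties must be >= 0")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.scheme not in ("shuffle", "kfold"):
            raise ValueError("scheme must be 'shuffle' or 'kfold'")


def prediction_accuracy(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation between observed and predicted held-out scores."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if observed.size < 3:
        raise UndefinedAccuracyError("need at least 3 observations")
    if np.ptp(observed) == 0 or np.ptp(predicted) == 0:
        raise UndefinedAccuracyError("constant input: correlation undefined")
    return float(np.corrcoef(observed, predicted)[0, 1])


def fit_ridge(
    X: np.ndarray, y: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Closed-form penalized least squares on centered data.

    Solves (Xc'Xc + lam*I) w = Xc'yc with Xc, yc column/mean-centered;
    intercept = mean(y) - mean(X) @ w.  Deterministic.  With ``lam = 0`` a
    rank-deficient X'X raises :class:`SingularityError`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y are not row-aligned")
    if lam < 0:
        raise ValueError("penalty must be >= 0")
    mu = X.mean(axis=0)
    Xc = X - mu
    yc = y - y.mean()
    G = Xc.T @ Xc
    p = G.shape[0]
    if lam == 0 and np.linalg.matrix_rank(G) < p:
        raise SingularityError(
            "lambda = 0 with rank-deficient X'X: the unpenalized normal "
            "equations are singular; use a positive penalty"
        )
    w = np.linalg.solve(G + lam * np.eye(p), Xc.T @ yc)
    intercept = float(y.mean() - mu @ w)
    return w, intercept


# ---------------------------------------------------------------------------
# Engine internals


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature: leave unscaled
    return mu, sd


@dataclass
class _InnerFold:
    in_idx: np.ndarray      # local indices into the training block
    mu: np.ndarray
    sd: np.ndarray
    evals: np.ndarray       # eigendecomposition of the standardized Gram
    evecs: np.ndarray
    P_val: np.ndarray       # standardized inner-validation rows @ evecs
    val_idx: np.ndarray


@dataclass
class _SplitData:
    train_idx: np.ndarray
    test_idx: np.ndarray
    Xtr: np.ndarray         # raw training block
    mu: np.ndarray
    sd: np.ndarray
    gram: np.ndarray        # standardized outer-train Gram (for activations)
    evals: np.ndarray
    evecs: np.ndarray
    Xs_test: np.ndarray
    P_test: np.ndarray
    inner: list[_InnerFold]


def _inner_folds(
    Xtr: np.ndarray, n_folds: int, random_state: int, standardize: bool
) -> list[_InnerFold]:
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    folds = []
    for in_idx, val_idx in kf.split(Xtr):
        X_in = Xtr[in_idx]
        if standardize:
            mu, sd = _standardize_stats(X_in)
        else:
            mu = np.zeros(Xtr.shape[1])
            sd = np.ones(Xtr.shape[1])
        Xs_in = (X_in - mu) / sd
        evals, evecs = np.linalg.eigh(Xs_in.T @ Xs_in)
        folds.append(
            _InnerFold(
                in_idx=in_idx,
                mu=mu,
                sd=sd,
                evals=evals,
                evecs=evecs,
                P_val=((Xtr[val_idx] - mu) / sd) @ evecs,
                val_idx=val_idx,
            )
        )
    return folds


def _grid_coefs(
    evals: np.ndarray, evecs: np.ndarray, rhs: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Spectral ridge solutions in the eigenbasis, one column per penalty.

    (G + lam*I)^{-1} rhs = V diag(1/(e + lam)) V' rhs; returns the (p, L)
    matrix of eigenbasis coefficients t_i / (e_i + lam).
    """
    t = evecs.T @ rhs
    return t[:, None] / (evals[:, None] + grid[None, :])


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _corr_paired_columns(Y: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between matching columns of Y and P."""
    n, B = Y.shape
    out = np.full(B, np.nan)
    if n < 3:
        return out
    Yc = Y - Y.mean(axis=0)
    Pc = P - P.mean(axis=0)
    ny = np.linalg.norm(Yc, axis=0)
    npred = np.linalg.norm(Pc, axis=0)
    ok = (ny > 0) & (npred > 0)
    out[ok] = np.einsum("ij,ij->j", Yc[:, ok], Pc[:, ok]) / (ny[ok] * npred[ok])
    return out


def _corr_columns(y: np.ndarray, preds: np.ndarray) -> np.ndarray:
    """Pearson r between y and every column of preds (NaN where undefined)."""
    out = np.full(preds.shape[1], np.nan)
    if y.size < 3 or np.ptp(y) == 0:
        return out
    yc = y - y.mean()
    ny = float(np.linalg.norm(yc))
    pc = preds - preds.mean(axis=0)
    npred = np.linalg.norm(pc, axis=0)
    ok = npred > 0
    out[ok] = (yc @ pc[:, ok]) / (ny * npred[ok])
    return out


def _score_grid(
    Xtr: np.ndarray, folds: list[_InnerFold], y_tr: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Mean inner-fold held-out correlation for each grid value (NaN-aware).

    Uses the identity Xs'yc = (X'yc)/sd for mean-centered yc: the
    standardization mean term vanishes because sum(yc) = 0.
    """
    scores = np.full((len(folds), len(grid)), np.nan)
    for i, f in enumerate(folds):
        y_in = y_tr[f.in_idx]
        y_val = y_tr[f.val_idx]
        ybar = float(y_in.mean())
        yc = y_in - ybar
        rhs = (Xtr[f.in_idx].T @ yc) / f.sd
        coefs = _grid_coefs(f.evals, f.evecs, rhs, grid)   # (p, n_lambda)
        preds = f.P_val @ coefs + ybar                     # (n_val, n_lambda)
        scores[i] = _corr_columns(y_val, preds)
    return _nanmean_quiet(scores, axis=0)


def _nanmean_quiet(a: np.ndarray, axis=None):
    """nanmean without the all-NaN RuntimeWarning (NaN is the wanted result)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(invalid="ignore"):
            return np.nanmean(a, axis=axis)


def _pick_lambda(grid: np.ndarray, mean_scores: np.ndarray) -> tuple[int, bool]:
    """Index of the best penalty; ties and all-NaN fall toward the largest.

    Returns (index, fallback_used).  The grid is assumed sorted ascending.
    """
    if np.all(np.isnan(mean_scores)):
        return len(grid) - 1, True
    best = np.nanmax(mean_scores)
    return int(np.flatnonzero(mean_scores == best)[-1]), False


def select_lambda(
    X_train: np.ndarray, y_train: np.ndarray, config: ModelConfig
) -> float:
    """Choose the penalty by inner k-fold CV on training data only.

    Maximizes the mean inner-fold held-out correlation between observed and
    predicted values; ties break toward the larger penalty; if every inner
    correlation is undefined (e.g. constant y) the largest grid value is
    returned with a warning.  Deterministic given ``config.seed``.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    grid = np.sort(np.asarray(config.lambda_grid, dtype=float))
    folds = _inner_folds(
        X_train, config.n_inner_folds, _inner_seed(config), config.standardize
    )
    mean_scores = _score_grid(X_train, folds, y_train, grid)
    idx, fallback = _pick_lambda(grid, mean_scores)
    if fallback:
        logger.warning(
            "all inner-fold correlations undefined; falling back to the "
            "largest penalty %g", grid[-1]
        )
    return float(grid[idx])


def _inner_seed(config: ModelConfig) -> int:
    return (config.seed + 1) % (2**31 - 1)


def _outer_seed(config: ModelConfig) -> int:
    return config.seed % (2**31 - 1)


class CellEngine:
    """Precomputed split plan and feature-side algebra for one cell.

    All response-independent quantities (split memberships, standardization
    statistics, Gram matrices, standardized validation/test blocks) are
    computed once; :meth:`run` then evaluates the full nested pipeline for
    any response vector.  Running with a permuted response is therefore
    numerically identical to rerunning the pipeline from scratch.
    """

    def __init__(self, X: np.ndarray, config: ModelConfig):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n, self.p = self.X.shape
        self.config = config
        self.grid = np.sort(np.asarray(config.lambda_grid, dtype=float))
        if config.scheme == "shuffle":
            splitter = ShuffleSplit(
                n_splits=config.n_outer_splits,
                test_size=config.test_fraction,
                random_state=_outer_seed(config),
            )
        else:
            splitter = KFold(
                n_splits=config.n_outer_splits,
                shuffle=True,
                random_state=_outer_seed(config),
            )
        self.splits: list[_SplitData] = []
        inner_seed = _inner_seed(config)
        for tr, te in splitter.split(self.X):
            Xtr = self.X[tr]
            if config.standardize:
                mu, sd = _standardize_stats(Xtr)
            else:
                mu = np.zeros(self.p)
                sd = np.ones(self.p)
            Xs_tr = (Xtr - mu) / sd
            gram = Xs_tr.T @ Xs_tr
            evals, evecs = np.linalg.eigh(gram)
            Xs_test = (self.X[te] - mu) / sd
            self.splits.append(
                _SplitData(
                    train_idx=tr,
                    test_idx=te,
                    Xtr=Xtr,
                    mu=mu,
                    sd=sd,
                    gram=gram,
                    evals=evals,
                    evecs=evecs,
                    Xs_test=Xs_test,
                    P_test=Xs_test @ evecs,
                    inner=_inner_folds(
                        Xtr, config.n_inner_folds, inner_seed, config.standardize
                    ),
                )
            )

    def _run_split(self, s: _SplitData, y: np.ndarray, want_details: bool):
        y_tr = y[s.train_idx]
        y_te = y[s.test_idx]
        mean_scores = _score_grid(s.Xtr, s.inner, y_tr, self.grid)
        idx, fallback = _pick_lambda(self.grid, mean_scores)
        if fallback:
            logger.debug("inner CV undefined for a split; using largest penalty")
        lam = float(self.grid[idx])
        ybar = float(y_tr.mean())
        yc = y_tr - ybar
        rhs = (s.Xtr.T @ yc) / s.sd
        coef = _grid_coefs(s.evals, s.evecs, rhs, self.grid[idx : idx + 1])[:, 0]
        pred = s.P_test @ coef + ybar
        r = _safe_corr(y_te, pred)
        if not want_details:
            return r
        w = s.evecs @ coef
        n_tr = len(s.train_idx)
        activation = s.gram @ w / (n_tr - 1)  # Haufe activation on training rows
        intercept = ybar - float((s.mu / s.sd) @ w)
        return lam, w, intercept, r, pred, y_te, activation

    def batch_mean_accuracies(self, Y: np.ndarray) -> np.ndarray:
        """Mean held-out accuracy for every column of ``Y`` at once.

        Runs the identical nested pipeline as :meth:`mean_accuracy` — inner
        penalty selection per column included — but with the response-side
        algebra batched across columns, which is what makes thousands of
        permutation refits affordable.  Results agree with the one-column
        path to floating-point accumulation order.
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[0] != self.n:
            raise ValueError("Y must be n x B")
        B = Y.shape[1]
        L = len(self.grid)
        R = np.full((len(self.splits), B), np.nan)
        for si, s in enumerate(self.splits):
            Ytr = Y[s.train_idx]
            Yte = Y[s.test_idx]
            scores = np.full((len(s.inner), L, B), np.nan)
            for fi, f in enumerate(s.inner):
                Yin = Ytr[f.in_idx]
                Yval = Ytr[f.val_idx]
                ybar = Yin.mean(axis=0)
                RHS = (s.Xtr[f.in_idx].T @ (Yin - ybar)) / f.sd[:, None]
                T = f.evecs.T @ RHS
                for k in range(L):
                    coefs = T / (f.evals[:, None] + self.grid[k])
                    preds = f.P_val @ coefs + ybar
                    scores[fi, k] = _corr_paired_columns(Yval, preds)
            mean_scores = _nanmean_quiet(scores, axis=0)      # (L, B)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                best = np.nanmax(mean_scores, axis=0)
            idx = np.full(B, L - 1)
            defined = ~np.isnan(best)
            if np.any(defined):
                eq = mean_scores[:, defined] == best[None, defined]
                # last index among exact ties -> larger penalty
                idx[defined] = L - 1 - np.argmax(eq[::-1, :], axis=0)
            ybar = Ytr.mean(axis=0)
            RHS = (s.Xtr.T @ (Ytr - ybar)) / s.sd[:, None]
            T = s.evecs.T @ RHS
            coefs = T / (s.evals[:, None] + self.grid[idx][None, :])
            preds = s.P_test @ coefs + ybar
            R[si] = _corr_paired_columns(Yte, preds)
        return _nanmean_quiet(R, axis=0)

    def mean_accuracy(self, y: np.ndarray) -> float:
        """Mean held-out accuracy over splits (NaN splits excluded); the
        cheap path used for permutation nulls."""
        y = np.asarray(y, dtype=float)
        rs = np.array([self._run_split(s, y, False) for s in self.splits])
        if np.all(np.isnan(rs)):
            return np.nan
        return float(np.nanmean(rs))

    def run(self, y: np.ndarray, meta: dict | None = None) -> "RidgePredictionResults":
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n:
            raise ValueError("y length does not match the engine's X")
        lams, weights, intercepts, accs, acts = [], [], [], [], []
        preds, obs = [], []
        for s in self.splits:
            lam, w, b0, r, pred, y_te, act = self._run_split(s, y, True)
            lams.append(lam)
            weights.append(w)
            intercepts.append(b0)
            accs.append(r)
            preds.append(pred)
            obs.append(y_te)
            acts.append(act)
        return RidgePredictionResults(
            meta=dict(meta or {}),
            config=self.config,
            lambdas=np.array(lams),
            weights=np.array(weights),
            intercepts=np.array(intercepts),
            split_accuracies=np.array(accs),
            predictions=preds,
            observed=obs,
            activations=np.array(acts),
            train_indices=[s.train_idx for s in self.splits],
            test_indices=[s.test_idx for s in self.splits],
            engine=self,
            response=y,
        )


@dataclass
class RidgePredictionResults:
    """Fitted cross-validated ridge run for one analysis cell.

    Carries per-split selected penalties, weight vectors (standardized
    feature space), held-out predictions and accuracies, and per-split Haufe
    activations; ``mean_accuracy`` is the arithmetic mean of per-split
    held-out Pearson r (undefined splits excluded and counted).
    """

    meta: dict
    config: ModelConfig
    lambdas: np.ndarray
    weights: np.ndarray
    intercepts: np.ndarray
    split_accuracies: np.ndarray
    predictions: list[np.ndarray]
    observed: list[np.ndarray]
    activations: np.ndarray
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]
    engine: CellEngine | None = field(default=None, repr=False)
    response: np.ndarray | None = field(default=None, repr=False)
    region_labels: tuple[str, ...] | None = None

    @property
    def cell_id(self) -> str:
        return self.meta.get("cell_id", "cell")

    @property
    def n_splits(self) -> int:
        return len(self.lambdas)

    @property
    def n_missing_splits(self) -> int:
        return int(np.isnan(self.split_accuracies).sum())

    @property
    def mean_accuracy(self) -> float:
        if np.all(np.isnan(self.split_accuracies)):
            return np.nan
        return float(np.nanmean(self.split_accuracies))

    def permutation_test(self, n_permutations: int = 1000, seed: int = 0):
        """Permutation null for this cell's accuracy (behavior permuted,
        full pipeline re-executed).  Returns a NullDistribution."""
        from .inference import permutation_null

        return permutation_null(self, None, n_permutations=n_permutations, seed=seed)

    def importance_map(self):
        """Mean Haufe-transformed importance over splits (ImportanceMap)."""
        from .importance import mean_importance

        return mean_importance(self)

    def summary(self) -> str:
        acc = self.mean_accuracy
        sd = float(np.nanstd(self.split_accuracies)) if self.n_splits else np.nan
        lines = [
            "Cross-validated ridge prediction results",
            "========================================",
            f"cell:                {self.cell_id}",
            f"splits:              {self.n_splits} "
            f"({self.config.scheme}, test fraction {self.config.test_fraction})",
            f"undefined splits:    {self.n_missing_splits}",
            f"mean test accuracy:  r = {acc:.4f} (split SD {sd:.4f})",
            f"median penalty:      {float(np.median(self.lambdas)):.4g}",
            f"features:            {self.weights.shape[1]}",
        ]
        return "\n".join(lines)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "split": np.arange(self.n_splits),
                "lambda": self.lambdas,
                "accuracy": self.split_accuracies,
            }
        )

    def save(self, directory: str | Path) -> None:
        """Write a JSON scalar summary plus a TSV of per-split accuracies."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = self.cell_id.replace(":", "_")
        payload = {
            "cell": self.meta,
            "mean_accuracy": None if np.isnan(self.mean_accuracy) else self.mean_accuracy,
            "n_splits": self.n_splits,
            "n_missing_splits": self.n_missing_splits,
            "lambdas": self.lambdas.tolist(),
            "mean_weights": self.weights.mean(axis=0).tolist(),
        }
        (directory / f"{stem}.json").write_text(json.dumps(payload, indent=1))
        self.to_frame().to_csv(directory / f"{stem}_splits.tsv", sep="\t", index=False)


#: Alias used in pipeline-facing code: one fitted run for one cell.
ModelRun = RidgePredictionResults


class RidgePredictionModel:
    """Cross-validated ridge model for one analysis cell.

    Construct from arrays or from an :class:`~neuroridge.preprocess.AnalysisCell`;
    ``fit`` runs the full resampling pipeline and returns
    :class:`RidgePredictionResults`.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        region_labels: Sequence[str] | None = None,
        meta: dict | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y are not row-aligned")
        self.region_labels = tuple(region_labels) if region_labels else None
        self.meta = dict(meta or {})

    @classmethod
    def from_cell(cls, cell: AnalysisCell) -> "RidgePredictionModel":
        return cls(
            cell.X.values,
            cell.y,
            region_labels=cell.X.region_labels,
            meta={
                "cell_id": cell.cell_id,
                "modality": cell.modality,
                "measure": cell.measure,
                "sex_group": cell.sex_group,
                "timepoint": cell.timepoint,
                "n": cell.n,
            },
        )

    def fit(self, config: ModelConfig | None = None) -> RidgePredictionResults:
        config = config or ModelConfig()
        engine = CellEngine(self.X, config)
        res = engine.run(self.y, meta=self.meta)
        res.region_labels = self.region_labels
        return res


def run_cell(cell: AnalysisCell, config: ModelConfig | None = None) -> RidgePredictionResults:
    """Fit the full cross-validated ridge pipeline for one analysis cell."""
    return RidgePredictionModel.from_cell(cell).fit(config)
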