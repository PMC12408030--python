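"""Behavioral-measure descriptives: rank tests and correlation matrices.

Impulsivity scores are not normally distributed, so group differences
(female vs male at each timepoint; baseline vs two-year follow-up) are
tested with Mann-Whitney U rank tests: midrank-based U, exact p by
enumeration for small untied samples (n1 + n2 <= 12), otherwise the normal
approximation with tie and continuity corrections.  p-values are corrected
within each behavioral scale (4 BIS/BAS together, 5 UPPS-P together) per
contrast family with BH-FDR at q = 0.05.  Co-expression of the nine
measures is summarized by full (Pearson, optionally Spearman) correlation
matrices per sex group and timepoint — "full" as opposed to partial
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._regions import MEASURES, MEASURE_SCALE
from .inference import bh_fdr

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "measure_correlations",
    "compare_groups",
]

_EXACT_MAX_N = 12


@dataclass
class GroupComparison:
    measure: str
    contrast: str
    u_statistic: float
    z: float
    p: float
    p_fdr: float | None = None
    significant: bool | None = None

    @property
    def scale(self) -> str:
        return MEASURE_SCALE.get(self.measure, "other")


def _u_and_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Midrank U for x, tie/continuity-corrected z; reports tie presence."""
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(counts > 1))
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u1, 0.0, has_ties
    # continuity correction of 0.5 toward the mean
    shift = u1 - mean_u
    shift -= 0.5 * np.sign(shift)
    return u1, float(shift / np.sqrt(var_u)), has_ties


def mann_whitney_u(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two independent samples.

    U is the midrank statistic for the first sample (0 <= U <= n1*n2).
    Exact p when n1 + n2 <= 12 with no ties, else the tie-corrected normal
    approximation with continuity correction (scipy backend for p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    u1, z, has_ties = _u_and_z(x, y)
    method = "exact" if (x.size + y.size <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        measure="", contrast="", u_statistic=u1, z=z, p=float(res.pvalue)
    )


def measure_correlations(
    cohort: pd.DataFrame,
    group: str = "all",
    timepoint: str = "baseline",
    measures=MEASURES,
    method: str = "pearson",
) -> pd.DataFrame:
    """Full correlation matrix among the behavior measures for one sex group
    and timepoint, on pairwise-complete cases.

    Constant measures yield NaN entries (flagged, never zero-filled).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    sub = cohort[cohort["timepoint"] == timepoint]
    if group != "all":
        sub = sub[sub["sex"] == group]
    if len(sub) < 3:
        raise ValueError(
            f"need at least 3 rows for group={group!r}, timepoint={timepoint!r}"
        )
    corr = sub[list(measures)].corr(method=method, min_periods=3)
    # pandas fills constant columns' self-correlation with NaN already;
    # force an exact unit diagonal where the measure varies
    for m in measures:
        if sub[m].nunique(dropna=True) > 1:
            corr.loc[m, m] = 1.0
    return corr


def compare_groups(
    cohort: pd.DataFrame,
    q: float = 0.05,
    measures=MEASURES,
    paired_timepoints: bool = False,
) -> pd.DataFrame:
    """All specified group contrasts with within-scale BH correction.

    Contrasts: F vs M at each timepoint present, and baseline vs year2 per
    measure.  The timepoint comparison treats the two visits as independent
    samples (the overlap between visits is a documented caveat); with
    ``paired_timepoints=True`` a Wilcoxon signed-rank test on participants
    present at both visits is used instead.
    """
    timepoints = [t for t in ("baseline", "year2") if (cohort["timepoint"] == t).any()]
    rows: list[GroupComparison] = []
    for tp in timepoints:
        sub = cohort[cohort["timepoint"] == tp]
        xs = sub[sub["sex"] == "F"]
        ys = sub[sub["sex"] == "M"]
        if len(xs) == 0 or len(ys) == 0:
            continue
        for m in measures:
            gc = mann_whitney_u(xs[m].dropna(), ys[m].dropna())
            gc.measure = m
            gc.contrast = f"F_vs_M@{tp}"
            rows.append(gc)
    if len(timepoints) == 2:
        base = cohort[cohort["timepoint"] == "baseline"]
        year2 = cohort[cohort["timepoint"] == "year2"]
        for m in measures:
            if paired_timepoints:
                merged = base.merge(
                    year2, on="participant_id", suffixes=("_b", "_y")
                )[[f"{m}_b", f"{m}_y"]].dropna()
                res = stats.wilcoxon(merged[f"{m}_b"], merged[f"{m}_y"])
                gc = GroupComparison(
                    measure=m,
                    contrast="baseline_vs_year2_paired",
                    u_statistic=float(res.statistic),
                    z=np.nan,
                    p=float(res.pvalue),
                )
            else:
                gc = mann_whitney_u(base[m].dropna(), year2[m].dropna())
                gc.measure = m
                gc.contrast = "baseline_vs_year2"
            rows.append(gc)

    # BH within scale, per contrast family
    pvals = {f"{gc.contrast}|{gc.measure}": gc.p for gc in rows}
    fams = {
        f"{gc.contrast}|{gc.measure}": f"{gc.contrast}|{gc.scale}" for gc in rows
    }
    adjusted = bh_fdr(pvals, fams, q=q) if pvals else {}
    for gc in rows:
        p_fdr, sig = adjusted[f"{gc.contrast}|{gc.measure}"]
        gc.p_fdr = p_fdr
        gc.significant = sig
    return pd.DataFrame(
        {
            "measure": [gc.measure for gc in rows],
            "contrast": [gc.contrast for gc in rows],
            "scale": [gc.scale for gc in rows],
            "U": [gc.u_statistic for gc in rows],
            "z": [gc.z for gc in rows],
            "p": [gc.p for gc in rows],
            "p_fdr": [gc.p_fdr for gc in rows],
            "significant": [gc.significant for gc in rows],
        }
    )
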