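"""Synthetic ABCD-like cohorts with known generative structure.

Real data for this kind of study (regional cortical thickness, surface area
and gray matter volume over the 68 Desikan-Killiany regions, paired with
BIS/BAS and UPPS-P impulsivity scores) are access-restricted, so every
downstream stage of the package is exercised on synthetic cohorts whose
ground truth is known exactly.

The generative model, per timepoint:

* Each participant has a sex (F/M), an intracranial volume (ICV) drawn
  log-normally, and for each modality a latent 68-region feature vector
  drawn from a multivariate normal with a shared covariance and a
  sex-dependent mean (males receive ``sex_mean_shift``).
* Stored SA and GMV features are the latent value multiplied by ICV, so
  that the standard proportional correction (division by ICV) recovers the
  latent exactly.  CT is stored as the latent itself.
* Each behavior score is a linear function of the latent features plus
  Gaussian noise: ``y = sum_m X_m @ w_m(sex) + eps``, where
  ``w_m(sex) = shared + delta`` for the designated sex and ``shared``
  otherwise.
* The two-year timepoint is a retention subsample of baseline participants
  with freshly drawn features and behaviors (optionally autocorrelated with
  baseline via ``feature_autocorr``).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from ._regions import (
    DK_REGIONS,
    ICV_SCALED_MODALITIES,
    MEASURES,
    MODALITIES,
    MEASURE_SCALE,
    N_REGIONS,
    feature_columns,
)

__all__ = [
    "GenerativeConfig",
    "GroundTruth",
    "generate_cohort",
    "theoretical_max_accuracy",
    "default_region_covariance",
    "default_sex_mean_shift",
    "null_config",
    "single_region_config",
    "random_effect_config",
    "sex_contrast_config",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
]

# Latent feature means per modality (arbitrary latent units: CT on a
# millimetre-like scale, SA/GMV on the ICV-corrected scale).
_BASE_MEAN = {"CT": 2.5, "SA": 5.0, "GMV": 5.0}


class CovarianceError(ValueError):
    """Raised when a region covariance matrix is not symmetric positive-definite."""


def default_region_covariance(n_regions: int = N_REGIONS) -> np.ndarray:
    """Structured, invertible default covariance for regional features.

    A convex combination of an exponential-decay correlation kernel over
    region indices (nearby regions in the atlas ordering correlate) and a
    hemisphere-symmetry component in which region ``j`` and its contralateral
    homologue ``j + n/2`` correlate extra, mimicking bilateral anatomy.
    Both components are positive-definite, so the sum is too; the diagonal
    is exactly 1.
    """
    idx = np.arange(n_regions)
    decay = np.exp(-np.abs(idx[:, None] - idx[None, :]) / 6.0)
    half = n_regions // 2
    homolog = np.eye(n_regions)
    if 2 * half == n_regions and half > 0:
        pair = np.zeros((n_regions, n_regions))
        pair[idx, (idx + half) % n_regions] = 1.0
        # eigenvalues of I + 0.8*P are 1 +/- 0.8 > 0
        homolog = np.eye(n_regions) + 0.8 * pair
    return 0.7 * decay + 0.3 * homolog


def default_sex_mean_shift(n_regions: int = N_REGIONS, amplitude: float = 0.2) -> np.ndarray:
    """Smooth per-region mean offset added to male latent features.

    A sinusoidal profile over the atlas ordering, mirrored across
    hemispheres, with peak amplitude ``amplitude`` latent SD units — some
    regions larger in males, others in females, none extreme.
    """
    half = max(n_regions // 2, 1)
    base = amplitude * np.sin(2.0 * np.pi * np.arange(half) / half)
    if 2 * half == n_regions:
        return np.concatenate([base, base])
    return amplitude * np.sin(2.0 * np.pi * np.arange(n_regions) / n_regions)


@dataclass
class GenerativeConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions: 9,099 baseline participants with
    ~70.7% retained at the two-year follow-up, 68 bilateral regions per
    modality, and per-cell signal fractions around 0.01 (an asymptotic
    prediction-accuracy ceiling near r = 0.1, the scale of brain-behavior
    effects in large youth cohorts).
    """

    n_participants: int = 9099
    n_regions: int = N_REGIONS
    modalities: tuple[str, ...] = MODALITIES
    measures: tuple[str, ...] = MEASURES
    female_fraction: float = 0.48
    region_covariance: np.ndarray | None = None
    sex_mean_shift: np.ndarray | None = None
    # (modality, measure) -> weight vector of length n_regions
    true_weights_shared: Mapping[tuple[str, str], np.ndarray] | None = None
    true_weights_sex_delta: Mapping[tuple[str, str], np.ndarray] | None = None
    sex_delta_applies_to: str = "M"
    noise_sd: float = 1.0
    icv_lognormal_params: tuple[float, float] = (14.2, 0.09)
    followup_retention: float = 6432 / 9099
    feature_autocorr: float = 0.0
    behavior_discretizer: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0

    def resolved_covariance(self) -> np.ndarray:
        cov = self.region_covariance
        if cov is None:
            cov = default_region_covariance(self.n_regions)
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (self.n_regions, self.n_regions):
            raise CovarianceError(
                f"region_covariance has shape {cov.shape}, expected "
                f"({self.n_regions}, {self.n_regions})"
            )
        if not np.allclose(cov, cov.T):
            raise CovarianceError("region_covariance is not symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise CovarianceError(
                "region_covariance is not positive-definite (Cholesky failed)"
            ) from exc
        return cov

    def resolved_sex_shift(self) -> np.ndarray:
        if self.sex_mean_shift is None:
            return default_sex_mean_shift(self.n_regions)
        shift = np.asarray(self.sex_mean_shift, dtype=float)
        if shift.shape != (self.n_regions,):
            raise ValueError(
                f"sex_mean_shift has length {shift.shape}, expected {self.n_regions}"
            )
        return shift

    def resolved_weights(self) -> tuple[dict, dict]:
        """Shared and sex-delta weight dictionaries, filled with defaults.

        Default shared weights: for each (modality, measure), 8 regions with
        standard-normal loadings, rescaled so that w' Sigma w = 0.01 (about
        1% of behavioral variance per modality at noise_sd = 1).  Default
        sex deltas are zero.
        """
        cov = self.resolved_covariance()
        rng = np.random.default_rng(self.seed + 104729)
        shared: dict[tuple[str, str], np.ndarray] = {}
        for mod in self.modalities:
            for meas in self.measures:
                key = (mod, meas)
                if self.true_weights_shared is not None and key in self.true_weights_shared:
                    w = np.asarray(self.true_weights_shared[key], dtype=float)
                elif self.true_weights_shared is not None:
                    w = np.zeros(self.n_regions)
                else:
                    w = np.zeros(self.n_regions)
                    nz = rng.choice(self.n_regions, size=min(8, self.n_regions), replace=False)
                    w[nz] = rng.standard_normal(len(nz))
                    quad = float(w @ cov @ w)
                    if quad > 0:
                        w *= np.sqrt(0.01 / quad)
                if w.shape != (self.n_regions,):
                    raise ValueError(
                        f"weight vector for {key} has length {w.shape[0]}, "
                        f"expected {self.n_regions}"
                    )
                shared[key] = w
        delta: dict[tuple[str, str], np.ndarray] = {}
        for mod in self.modalities:
            for meas in self.measures:
                key = (mod, meas)
                if self.true_weights_sex_delta is not None and key in self.true_weights_sex_delta:
                    d = np.asarray(self.true_weights_sex_delta[key], dtype=float)
                    if d.shape != (self.n_regions,):
                        raise ValueError(
                            f"sex-delta vector for {key} has length {d.shape[0]}, "
                            f"expected {self.n_regions}"
                        )
                else:
                    d = np.zeros(self.n_regions)
                delta[key] = d
        return shared, delta

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 < self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in (0, 1]")
        if not 0.0 < self.followup_retention <= 1.0:
            raise ValueError("followup_retention must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.feature_autocorr < 1.0:
            raise ValueError("feature_autocorr must be in [0, 1)")
        if self.sex_delta_applies_to not in ("F", "M"):
            raise ValueError("sex_delta_applies_to must be 'F' or 'M'")
        self.resolved_covariance()
        self.resolved_sex_shift()


@dataclass
class GroundTruth:
    """Generative truth needed for recovery and calibration tests.

    ``effective_weights[(modality, measure, sex)]`` is the weight vector
    actually applied to that sex's latent features.  ``signal_fraction`` is
    Var(best linear predictor from that modality's features) / Var(behavior)
    for the cell's population; its square root is the asymptotic ceiling on
    held-out prediction accuracy for a linear model.
    """

    effective_weights: dict[tuple[str, str, str], np.ndarray]
    signal_fraction: dict[tuple[str, str, str], float]
    region_covariance: np.ndarray
    noise_sd: float
    modalities: tuple[str, ...]
    measures: tuple[str, ...]

    def activation_pattern(self, modality: str, measure: str, sex: str = "F") -> np.ndarray:
        """Population Haufe activation Sigma @ w for one cell's effective weights."""
        return self.region_covariance @ self.effective_weights[(modality, measure, sex)]

    def to_dict(self) -> dict:
        return {
            "noise_sd": self.noise_sd,
            "modalities": list(self.modalities),
            "measures": list(self.measures),
            "effective_weights": {
                "|".join(k): v.tolist() for k, v in self.effective_weights.items()
            },
            "signal_fraction": {"|".join(k): v for k, v in self.signal_fraction.items()},
            "region_covariance": self.region_covariance.tolist(),
        }


def theoretical_max_accuracy(truth: GroundTruth, cell: tuple[str, str, str]) -> float:
    """Asymptotic ceiling on held-out accuracy r for one (modality, measure,
    sex-group) cell: the square root of its signal fraction."""
    try:
        frac = truth.signal_fraction[tuple(cell)]
    except KeyError:
        raise KeyError(
            f"unknown cell {cell!r}; known cells are (modality, measure, sex_group) "
            f"with modalities {truth.modalities}, measures {truth.measures}, "
            f"sex groups ('all', 'F', 'M')"
        ) from None
    return float(np.sqrt(frac))


def _signal_fractions(
    config: GenerativeConfig,
    cov: np.ndarray,
    shift: np.ndarray,
    shared: dict,
    delta: dict,
) -> tuple[dict, dict]:
    """Exact per-cell signal fractions under the two-sex mixture.

    For a single sex s: Var(y|s) = sum_m w_ms' Sigma w_ms + noise^2 and the
    cell fraction is w_ms' Sigma w_ms / Var(y|s).  For the pooled group the
    best linear predictor from one modality's features has
    R^2 = c' V^{-1} c / Var(y) with mixture moments
    V = Sigma + Var_s(mu_s) and c = E_s[Sigma w_s] + Cov_s(mu_s, M_s),
    where M_s is the sex-conditional behavior mean.
    """
    p_sex = {"F": config.female_fraction, "M": 1.0 - config.female_fraction}
    mu = {  # latent mean per (modality, sex); the mean shift applies to males
        (mod, s): _BASE_MEAN.get(mod, 0.0)
        + (shift if s == "M" else np.zeros_like(shift))
        for mod in config.modalities
        for s in ("F", "M")
    }
    eff: dict[tuple[str, str, str], np.ndarray] = {}
    frac: dict[tuple[str, str, str], float] = {}
    for mod in config.modalities:
        for meas in config.measures:
            for s in ("F", "M"):
                w = shared[(mod, meas)].copy()
                if s == config.sex_delta_applies_to:
                    w = w + delta[(mod, meas)]
                eff[(mod, meas, s)] = w
    noise_var = config.noise_sd**2
    for meas in config.measures:
        # sex-conditional behavior mean and within-sex signal variance
        m_cond = {}
        sig_var = {}
        for s in ("F", "M"):
            m_cond[s] = sum(
                float(mu[(mod, s)] @ eff[(mod, meas, s)]) for mod in config.modalities
            )
            sig_var[s] = {
                mod: float(eff[(mod, meas, s)] @ cov @ eff[(mod, meas, s)])
                for mod in config.modalities
            }
        for s in ("F", "M"):
            var_y = sum(sig_var[s].values()) + noise_var
            for mod in config.modalities:
                frac[(mod, meas, s)] = sig_var[s][mod] / var_y if var_y > 0 else 0.0
        # pooled group
        m_bar = sum(p_sex[s] * m_cond[s] for s in ("F", "M"))
        var_y_all = (
            sum(p_sex[s] * sum(sig_var[s].values()) for s in ("F", "M"))
            + sum(p_sex[s] * (m_cond[s] - m_bar) ** 2 for s in ("F", "M"))
            + noise_var
        )
        for mod in config.modalities:
            mu_bar = sum(p_sex[s] * mu[(mod, s)] for s in ("F", "M"))
            c = sum(p_sex[s] * cov @ eff[(mod, meas, s)] for s in ("F", "M"))
            c = c + sum(
                p_sex[s] * (mu[(mod, s)] - mu_bar) * (m_cond[s] - m_bar) for s in ("F", "M")
            )
            v_x = cov + sum(
                p_sex[s] * np.outer(mu[(mod, s)] - mu_bar, mu[(mod, s)] - mu_bar)
                for s in ("F", "M")
            )
            if var_y_all > 0:
                r2 = float(c @ np.linalg.solve(v_x, c)) / var_y_all
            else:
                r2 = 0.0
            frac[(mod, meas, "all")] = float(np.clip(r2, 0.0, 1.0))
    return eff, frac


def generate_cohort(
    config: GenerativeConfig, keep_latents: bool = False
) -> tuple[pd.DataFrame, GroundTruth] | tuple[pd.DataFrame, GroundTruth, dict]:
    """Draw a synthetic cohort and its ground truth.

    Returns a tidy participant x timepoint table (one row per participant
    per timepoint) and a :class:`GroundTruth`.  With ``keep_latents=True``
    also returns the pre-ICV latent feature arrays keyed by
    ``(timepoint, modality)`` for diagnostic use.

    Identical config and seed give byte-identical output.
    """
    config.validate()
    cov = config.resolved_covariance()
    shift = config.resolved_sex_shift()
    shared, delta = config.resolved_weights()
    eff, frac = _signal_fractions(config, cov, shift, shared, delta)
    truth = GroundTruth(
        effective_weights=eff,
        signal_fraction=frac,
        region_covariance=cov,
        noise_sd=config.noise_sd,
        modalities=tuple(config.modalities),
        measures=tuple(config.measures),
    )

    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    chol = np.linalg.cholesky(cov)

    n_f = int(round(config.female_fraction * n))
    sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sexes)
    has_delta = any(np.any(d != 0) for d in delta.values())
    for s in ("F", "M"):
        if has_delta and np.sum(sexes == s) == 0:
            raise ValueError(
                f"sex-specific weights requested but the cohort contains no "
                f"participants of sex {s!r}"
            )
    ids = np.array([f"sub-{i:05d}" for i in range(n)])
    icv = rng.lognormal(*config.icv_lognormal_params, size=n)
    is_male = sexes == "M"
    delta_rows = sexes == config.sex_delta_applies_to

    def draw_latents(prev: dict | None) -> dict[str, np.ndarray]:
        out = {}
        rho = config.feature_autocorr
        for mod in config.modalities:
            mean = _BASE_MEAN.get(mod, 0.0) + np.where(is_male[:, None], shift, 0.0)
            z = rng.standard_normal((n, config.n_regions)) @ chol.T
            if prev is not None and rho > 0:
                out[mod] = mean + rho * (prev[mod] - mean) + np.sqrt(1 - rho**2) * z
            else:
                out[mod] = mean + z
        return out

    def draw_behaviors(latents: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for meas in config.measures:
            y = np.zeros(n)
            for mod in config.modalities:
                y += latents[mod] @ shared[(mod, meas)]
                d = delta[(mod, meas)]
                if np.any(d != 0):
                    y[delta_rows] += latents[mod][delta_rows] @ d
            y += rng.normal(0.0, config.noise_sd, size=n)
            if config.behavior_discretizer is not None:
                y = config.behavior_discretizer(y)
            out[meas] = y
        return out

    def assemble(tp: str, rows: np.ndarray, latents, behaviors) -> pd.DataFrame:
        data: dict[str, object] = {
            "participant_id": ids[rows],
            "sex": sexes[rows],
            "timepoint": tp,
            "icv": icv[rows],
        }
        regions = DK_REGIONS if config.n_regions == N_REGIONS else tuple(
            f"region_{i:02d}" for i in range(config.n_regions)
        )
        for mod in config.modalities:
            vals = latents[mod][rows]
            if mod in ICV_SCALED_MODALITIES:
                vals = vals * icv[rows, None]
            for j, col in enumerate(feature_columns(mod, regions)):
                data[col] = vals[:, j]
        for meas in config.measures:
            data[meas] = behaviors[meas][rows]
        return pd.DataFrame(data)

    lat_base = draw_latents(None)
    beh_base = draw_behaviors(lat_base)
    frames = [assemble("baseline", np.arange(n), lat_base, beh_base)]
    latents_out = {("baseline", mod): lat_base[mod] for mod in config.modalities}

    n2 = int(round(config.followup_retention * n))
    if n2 > 0:
        retained = np.sort(rng.choice(n, size=n2, replace=False))
        lat_y2 = draw_latents(lat_base)
        beh_y2 = draw_behaviors(lat_y2)
        frames.append(assemble("year2", retained, lat_y2, beh_y2))
        for mod in config.modalities:
            latents_out[("year2", mod)] = lat_y2[mod][retained]

    cohort = pd.concat(frames, ignore_index=True)
    if keep_latents:
        return cohort, truth, latents_out
    return cohort, truth


# ---------------------------------------------------------------------------
# Ready-made configs for calibration and recovery studies


def _cov_and_scale(n_regions: int) -> np.ndarray:
    return default_region_covariance(n_regions)


def null_config(n_participants: int, seed: int, **kwargs) -> GenerativeConfig:
    """Cohort with zero brain-behavior weights: behaviors are pure noise."""
    kwargs.setdefault("sex_mean_shift", np.zeros(kwargs.get("n_regions", N_REGIONS)))
    return GenerativeConfig(
        n_participants=n_participants,
        true_weights_shared={},
        true_weights_sex_delta={},
        noise_sd=1.0,
        seed=seed,
        **kwargs,
    )


def single_region_config(
    n_participants: int,
    signal_fraction: float,
    seed: int,
    modality: str = "CT",
    measure: str = "bas_drive",
    region_index: int = 10,
    **kwargs,
) -> GenerativeConfig:
    """One nonzero weight on one region, scaled so the designated cell has
    exactly the requested signal fraction (behavior variance 1)."""
    n_regions = kwargs.get("n_regions", N_REGIONS)
    cov = kwargs.get("region_covariance")
    cov = _cov_and_scale(n_regions) if cov is None else np.asarray(cov)
    w = np.zeros(n_regions)
    w[region_index] = 1.0
    w *= np.sqrt(signal_fraction / float(w @ cov @ w))
    kwargs.setdefault("sex_mean_shift", np.zeros(n_regions))
    return GenerativeConfig(
        n_participants=n_participants,
        true_weights_shared={(modality, measure): w},
        true_weights_sex_delta={},
        noise_sd=float(np.sqrt(1.0 - signal_fraction)),
        seed=seed,
        **kwargs,
    )


def random_effect_config(
    n_participants: int,
    signal_fraction: float,
    seed: int,
    modality: str = "CT",
    measure: str = "bas_drive",
    n_nonzero: int = 16,
    **kwargs,
) -> GenerativeConfig:
    """Random sparse weight vector scaled to the requested signal fraction."""
    n_regions = kwargs.get("n_regions", N_REGIONS)
    cov = kwargs.get("region_covariance")
    cov = _cov_and_scale(n_regions) if cov is None else np.asarray(cov)
    rng = np.random.default_rng(seed + 7919)
    w = np.zeros(n_regions)
    nz = rng.choice(n_regions, size=min(n_nonzero, n_regions), replace=False)
    w[nz] = rng.standard_normal(len(nz))
    w *= np.sqrt(signal_fraction / float(w @ cov @ w))
    kwargs.setdefault("sex_mean_shift", np.zeros(n_regions))
    return GenerativeConfig(
        n_participants=n_participants,
        true_weights_shared={(modality, measure): w},
        true_weights_sex_delta={},
        noise_sd=float(np.sqrt(1.0 - signal_fraction)),
        seed=seed,
        **kwargs,
    )


def sex_contrast_config(
    n_participants: int,
    signal_fraction: float,
    seed: int,
    mode: str = "shared",
    modality: str = "CT",
    measure: str = "bas_drive",
    **kwargs,
) -> GenerativeConfig:
    """Two-sex cohort for cross-sex importance-map comparisons.

    ``mode='shared'``: both sexes use the same weight vector.
    ``mode='orthogonal'``: the two sexes' population activation patterns
    (Sigma @ w) are exactly orthogonal; both cells keep the requested
    signal fraction.
    """
    if mode not in ("shared", "orthogonal"):
        raise ValueError("mode must be 'shared' or 'orthogonal'")
    n_regions = kwargs.get("n_regions", N_REGIONS)
    cov = kwargs.get("region_covariance")
    cov = _cov_and_scale(n_regions) if cov is None else np.asarray(cov)
    rng = np.random.default_rng(seed + 3571)
    w_f = rng.standard_normal(n_regions)
    w_f *= np.sqrt(signal_fraction / float(w_f @ cov @ w_f))
    if mode == "shared":
        w_m = w_f.copy()
    else:
        # orthogonalize activation patterns: a = Sigma w, want a_m . a_f = 0
        a_f = cov @ w_f
        a_m = rng.standard_normal(n_regions)
        a_m -= a_f * (a_m @ a_f) / (a_f @ a_f)
        w_m = np.linalg.solve(cov, a_m)
        w_m *= np.sqrt(signal_fraction / float(w_m @ cov @ w_m))
    kwargs.setdefault("sex_mean_shift", np.zeros(n_regions))
    kwargs.setdefault("female_fraction", 0.5)
    return GenerativeConfig(
        n_participants=n_participants,
        true_weights_shared={(modality, measure): w_f},
        true_weights_sex_delta={(modality, measure): w_m - w_f},
        sex_delta_applies_to="M",
        noise_sd=float(np.sqrt(1.0 - signal_fraction)),
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# I/O


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy cohort table as CSV (TSV if the suffix is .tsv)."""
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    cohort.to_csv(path, sep=sep, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))
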