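"""Synthetic cohort and ROI time-series generator with planted ground truth.

The generator emulates the statistical structure the downstream models
assume: ages approximately uniform over the adult lifespan, a latent system
segregation (SyS) score per brain state that declines with age (linear +
quadratic on a standardized basis), configurable lifestyle paths
(mid-life-activity score -> SyS, the mediation "a" path; SyS -> cognition,
"b"; a direct activity -> cognition path, "c'"), and cognitive sub-test
scores loading on the latent cognition.  ROI signals are multivariate
Gaussian draws from an exact block correlation matrix (equal
within-network correlation w, single between-network correlation b), so
the pipeline-level SyS estimate has the closed form
(atanh(w) - atanh(b)) / atanh(w).  Nuisance signals and motion spikes are
injected additively with their ground truth recorded, making ideal
confound regression exactly recover the clean signal.

All randomness flows from a single seed through per-participant streams,
so participant i is reproducible independent of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .connectivity import BASE_CONFOUND_COLUMNS, ConfoundSet, ROITimeSeries
from .errors import GenerationError, ValidationError
from .segregation import NetworkPartition

STATES = ("rest", "movie", "smt")

#: Affine map from the standardized latent SyS score to the fraction scale
#: used as a simulation target: fraction = LOC + SCALE * latent, clipped.
SYS_FRACTION_LOC = 0.6
SYS_FRACTION_SCALE = 0.08
SYS_FRACTION_CLIP = (0.02, 0.98)


@dataclass
class CohortSpec:
    """Planted-parameter description of a synthetic cohort.

    Path coefficients are on standardized variables (age z-scored by its
    population moments, activity scores unit normal); ``noise_sd_*`` are
    residual SDs on the same scale.
    """

    n_participants: int = 627
    age_range: tuple[float, float] = (18.0, 88.0)
    beta_age1_sys: float = -0.6
    beta_age2_sys: float = -0.15
    beta_ma_sys: float = 0.0
    beta_sys_cog: float = 0.3
    beta_ma_cog_direct: float = 0.2
    beta_age_cog: float = -0.5
    noise_sd_sys: float = 0.7
    noise_sd_cog: float = 0.7
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValidationError("n_participants must be >= 4")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("age_range must satisfy min < max")
        if self.noise_sd_sys <= 0:
            raise ValidationError("noise_sd_sys must be > 0")
        if self.noise_sd_cog <= 0:
            raise ValidationError("noise_sd_cog must be > 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValidationError("sex_ratio must be in [0, 1]")


@dataclass
class SignalSpec:
    """Description of one simulated ROI run.

    ``within_corr`` (w) and ``between_corr`` (b) define the exact block
    correlation structure; b may be left None and derived from a SyS
    target.  ``confound_amplitude`` scales injected nuisance signals as a
    fraction of the (unit) signal SD; ``spike_rate`` is the expected number
    of high-motion frames per run.
    """

    partition: NetworkPartition
    n_timepoints: int = 261
    sampling_interval: float = 1.97
    within_corr: float = 0.5
    between_corr: float | None = None
    confound_amplitude: float = 0.0
    spike_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 50:
            raise ValidationError("n_timepoints must be >= 50")
        if not 0.0 < self.within_corr < 1.0:
            raise ValidationError("within_corr must be in (0, 1)")
        if self.between_corr is not None and not 0.0 <= self.between_corr < self.within_corr:
            raise ValidationError("need 0 <= between_corr < within_corr")
        if self.confound_amplitude < 0 or self.spike_rate < 0:
            raise ValidationError("confound_amplitude and spike_rate must be >= 0")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0")


def _participant_rng(seed: int, index: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index), int(salt)])


def uniform_age_moments(age_range: tuple[float, float]) -> tuple[float, float]:
    """(mean, SD) of a uniform age distribution over ``age_range``."""
    lo, hi = age_range
    return (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)


def standardized_age(age: np.ndarray, age_range: tuple[float, float]) -> np.ndarray:
    """Z-score age using the population moments of the uniform distribution."""
    mu, sd = uniform_age_moments(age_range)
    return (np.asarray(age, dtype=float) - mu) / sd


def standardized_age_quadratic(z: np.ndarray) -> np.ndarray:
    """Centered, variance-standardized square of standardized age.

    For uniform ages E[z^2] = 1 and Var(z^2) = 4/5, so (z^2 - 1)/sqrt(4/5)
    is unit-variance and uncorrelated with z.
    """
    return (np.asarray(z, dtype=float) ** 2 - 1.0) / np.sqrt(0.8)


def latent_to_fraction(latent: np.ndarray) -> np.ndarray:
    """Map the standardized latent SyS score to the (0, 1) fraction scale."""
    return np.clip(
        SYS_FRACTION_LOC + SYS_FRACTION_SCALE * np.asarray(latent, dtype=float),
        *SYS_FRACTION_CLIP,
    )


def generate_covariates(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a participant table from the planted structural model.

    Returns the table and a ground-truth dict of the planted coefficients.
    Per state, the standardized latent SyS is
    ``beta_age1*z + beta_age2*q + beta_ma*MA + noise`` (z, q the
    standardized linear/quadratic age basis); cognition is driven by age,
    the rest-state SyS and the direct activity path.  Four fluid-reasoning
    sub-tests and three memory scores load on latent cognition with
    independent noise.  Columns ``sys_<state>`` carry the standardized
    latent; ``sys_frac_<state>`` its (0, 1) fraction-scale image used as a
    time-series simulation target.
    """
    n = spec.n_participants
    rows = []
    for i in range(n):
        rng = _participant_rng(spec.seed, i)
        age = rng.uniform(*spec.age_range)
        sex = "F" if rng.uniform() < spec.sex_ratio else "M"
        ma = rng.normal()
        ys = rng.normal()
        z = standardized_age(np.array([age]), spec.age_range)[0]
        q = standardized_age_quadratic(np.array([z]))[0]
        sys_lat = {
            s: spec.beta_age1_sys * z
            + spec.beta_age2_sys * q
            + spec.beta_ma_sys * ma
            + spec.noise_sd_sys * rng.normal()
            for s in STATES
        }
        cog = (
            spec.beta_age_cog * z
            + spec.beta_sys_cog * sys_lat["rest"]
            + spec.beta_ma_cog_direct * ma
            + spec.noise_sd_cog * rng.normal()
        )
        mem = 0.6 * cog + 0.8 * rng.normal()
        row = {
            "participant_id": f"sub-{i:04d}",
            "age": age,
            "sex": sex,
            "leq_ma": ma,
            "leq_ys": ys,
            "cognition_latent": cog,
        }
        for s in STATES:
            row[f"sys_{s}"] = sys_lat[s]
            row[f"sys_frac_{s}"] = latent_to_fraction(np.array([sys_lat[s]]))[0]
        for j in range(4):
            row[f"cattell_{j + 1}"] = 0.8 * cog + 0.6 * rng.normal()
        for name in ("immediate", "delayed", "recognition"):
            row[f"memory_{name}"] = 0.8 * mem + 0.6 * rng.normal()
        rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "beta_age1_sys": spec.beta_age1_sys,
        "beta_age2_sys": spec.beta_age2_sys,
        "beta_ma_sys": spec.beta_ma_sys,
        "beta_sys_cog": spec.beta_sys_cog,
        "beta_ma_cog_direct": spec.beta_ma_cog_direct,
        "beta_age_cog": spec.beta_age_cog,
        "noise_sd_sys": spec.noise_sd_sys,
        "noise_sd_cog": spec.noise_sd_cog,
        "age_basis": "standardized linear z and quadratic q = (z^2 - 1)/sqrt(0.8)",
        "seed": spec.seed,
    }
    return table, truth


def sys_target_to_between_corr(sys_target: float, within_corr: float) -> float:
    """Invert the SyS formula: the b with (z(w) - z(b))/z(w) = sys_target.

    Closed form: b = tanh((1 - sys_target) * atanh(w)).
    """
    if not 0.0 <= sys_target <= 1.0:
        raise ValidationError("sys_target must be in [0, 1]")
    if not 0.0 < within_corr < 1.0:
        raise ValidationError("within_corr must be in (0, 1)")
    return float(np.tanh((1.0 - sys_target) * np.arctanh(within_corr)))


def block_correlation(
    partition: NetworkPartition, roi_ids: list[str], w: float, b: float
) -> np.ndarray:
    """Exact block correlation matrix: w within networks, b between."""
    labels = partition.labels_for(roi_ids)
    same = labels[:, None] == labels[None, :]
    c = np.where(same, w, b)
    np.fill_diagonal(c, 1.0)
    eig_min = float(np.linalg.eigvalsh(c).min())
    if eig_min <= 1e-10:
        raise GenerationError(
            f"block correlation matrix not positive definite (min eig {eig_min:.2e})"
        )
    return c


class SimulatedRun(NamedTuple):
    timeseries: ROITimeSeries
    confounds: ConfoundSet
    truth: dict


def _smooth_series(rng: np.random.Generator, t: int) -> np.ndarray:
    """Unit-SD slow drift: standardized cumulative sum of white noise."""
    x = np.cumsum(rng.normal(size=t))
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_timeseries(spec: SignalSpec, sys_target: float | None = None) -> SimulatedRun:
    """Simulate one ROI run with exact block structure plus nuisance signals.

    The between-network correlation is ``spec.between_corr`` or, if a
    ``sys_target`` is given, derived by :func:`sys_target_to_between_corr`.
    Confound signals (six smooth motion-like series, WM-, CSF- and
    global-like series) are injected additively through random per-ROI
    loadings scaled by ``confound_amplitude``; high-motion spikes (count ~
    Poisson(spike_rate)) displace both the motion parameters and the ROI
    signals.  The returned truth dict records the injected loadings, spike
    frames and the analytic SyS of the noiseless structure.
    """
    if sys_target is not None:
        if not 0.0 <= sys_target <= 1.0:
            raise ValidationError("sys_target must be in [0, 1]")
        b = sys_target_to_between_corr(sys_target, spec.within_corr)
    elif spec.between_corr is not None:
        b = spec.between_corr
    else:
        raise ValidationError("provide either sys_target or spec.between_corr")
    w = spec.within_corr
    roi_ids = sorted(spec.partition.roi_to_network)
    corr = block_correlation(spec.partition, roi_ids, w, b)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(corr)
    t = spec.n_timepoints
    signal = rng.standard_normal((t, len(roi_ids))) @ chol.T

    conf = np.column_stack([_smooth_series(rng, t) for _ in BASE_CONFOUND_COLUMNS])
    base = pd.DataFrame(conf * 0.1, columns=list(BASE_CONFOUND_COLUMNS))
    loadings = rng.normal(size=(len(roi_ids), len(BASE_CONFOUND_COLUMNS)))
    loadings /= np.sqrt(len(BASE_CONFOUND_COLUMNS))
    values = signal + spec.confound_amplitude * conf @ loadings.T

    n_spikes = int(rng.poisson(spec.spike_rate))
    spike_frames = np.sort(rng.choice(t, size=min(n_spikes, t // 10), replace=False))
    for f in spike_frames:
        base.iloc[f, :6] += 10.0 * 0.1  # large displacement on motion columns
        values[f] += rng.normal(scale=8.0, size=len(roi_ids))

    truth = {
        "within_corr": w,
        "between_corr": b,
        "analytic_sys": float(
            (np.arctanh(w) - np.arctanh(b)) / np.arctanh(w)
        ),
        "confound_amplitude": spec.confound_amplitude,
        "confound_loadings": spec.confound_amplitude * loadings,
        "confound_signals": conf,
        "spike_frames": spike_frames,
        "clean_signal": signal,
        "seed": spec.seed,
    }
    ts = ROITimeSeries(values, spec.sampling_interval, roi_ids)
    return SimulatedRun(ts, ConfoundSet(base), truth)
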