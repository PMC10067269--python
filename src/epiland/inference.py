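"""Parametric bootstrap engine, environment-trend regressions, environmental
quality, and cost-of-resistance contrasts.

Measurement uncertainty is propagated by a parametric bootstrap: every genotype
x environment cell is redrawn independently from Normal(w_mean, w_se).  Any
statistic of the fitness table can then be given a percentile confidence
interval.  Streams are reproducible: the same :class:`BootstrapConfig` seed
always yields the same samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    WT_ABR,
    EpilandError,
    InsufficientDataError,
    _as_frame,
    _check_densities,
    _check_fitness_frame,
    check_complete_grid,
    environments_of,
)


class BootstrapError(EpilandError):
    """The bootstrap could not be run (bad SEs or too many metric failures)."""


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the parametric bootstrap.

    n_samples : number of bootstrap samples B (default 1000).
    seed      : RNG seed; identical seeds give bit-identical streams.
    ci_level  : two-sided percentile interval level (default 0.95).
    """

    n_samples: int = 1000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def percentiles(self) -> tuple[float, float]:
        alpha = 1.0 - self.ci_level
        return 100 * alpha / 2, 100 * (1 - alpha / 2)


def prepare_se(fits: pd.DataFrame) -> pd.DataFrame:
    """Fill undefined SEs (single-replicate cells) so the bootstrap has a spread.

    A cell with n = 1 gets the median SE of the other cells in the same
    environment and is flagged via a boolean ``se_imputed`` column.  Negative
    SEs are rejected.
    """
    fits = _check_fitness_frame(fits).copy()
    if (fits["w_se"].dropna() < 0).any():
        raise BootstrapError("negative standard error in fitness table")
    fits["se_imputed"] = fits["w_se"].isna()
    if fits["se_imputed"].any():
        med = fits.groupby(["antibiotic", "temperature"])["w_se"].transform("median")
        fits.loc[fits["se_imputed"], "w_se"] = med[fits["se_imputed"]]
        if fits["w_se"].isna().any():
            raise InsufficientDataError(
                "cannot impute SE: an environment has no replicated cells"
            )
    return fits


def cell_draw_matrix(fits: pd.DataFrame, cfg: BootstrapConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw a (n_samples, n_cells) matrix of Normal(w_mean, w_se) fitness values.

    Row order of ``fits`` defines the cell order.  Vectorised workhorse behind
    :func:`parametric_bootstrap` and the per-slice bootstrap metrics.
    """
    fits = prepare_se(fits)
    mean = fits["w_mean"].to_numpy(float)
    se = fits["w_se"].to_numpy(float)
    rng = rng if rng is not None else cfg.rng()
    return mean[None, :] + se[None, :] * rng.standard_normal((cfg.n_samples, mean.size))


def parametric_bootstrap(fits: pd.DataFrame, cfg: BootstrapConfig):
    """Yield resampled fitness tables, each cell drawn from Normal(w_mean, w_se)."""
    fits = prepare_se(fits)
    draws = cell_draw_matrix(fits, cfg)
    for b in range(cfg.n_samples):
        sample = fits.copy()
        sample["w_mean"] = draws[b]
        yield sample


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lo: float
    hi: float
    samples: np.ndarray
    n_failed: int = 0


def bootstrap_ci(metric: Callable[[pd.DataFrame], float], fits: pd.DataFrame,
                 cfg: BootstrapConfig) -> BootstrapCI:
    """Percentile bootstrap CI for any scalar metric of a fitness table.

    Metric evaluations that raise are dropped if they are <= 10% of samples
    (the count is reported); more than that aborts with an error.
    """
    point = float(metric(fits))
    values, failed = [], 0
    for sample in parametric_bootstrap(fits, cfg):
        try:
            values.append(float(metric(sample)))
        except Exception:  # noqa: BLE001 - metric failures are data, not bugs
            failed += 1
    if failed > 0.10 * cfg.n_samples:
        raise BootstrapError(
            f"metric failed on {failed}/{cfg.n_samples} bootstrap samples"
        )
    arr = np.asarray(values, float)
    p_lo, p_hi = cfg.percentiles()
    lo, hi = np.percentile(arr, [p_lo, p_hi])
    return BootstrapCI(point=point, lo=float(lo), hi=float(hi), samples=arr,
                       n_failed=failed)


def percentile_ci(samples: np.ndarray, cfg: BootstrapConfig,
                  axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    # order-statistic quantiles (no interpolation) keep percentile intervals
    # exactly equivariant under monotone transformations of the metric
    p_lo, p_hi = cfg.percentiles()
    lo = np.percentile(samples, p_lo, axis=axis, method="lower")
    hi = np.percentile(samples, p_hi, axis=axis, method="higher")
    return lo, hi


@dataclass(frozen=True)
class TrendFit:
    """Simple least-squares trend of a per-environment metric on a predictor."""

    slope: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    adj_r2: float
    n: int

    def significant(self, alpha: float = 0.01) -> bool:
        return bool(self.p_value < alpha)


def trend_vs_environment(values, predictor="antibiotic") -> TrendFit:
    """OLS of a per-environment metric on a continuous environmental predictor.

    ``values`` is either a DataFrame with columns (antibiotic, temperature,
    value) or a mapping Environment -> value.  ``predictor`` is one of
    ``"antibiotic"``, ``"temperature"``, or a mapping Environment/(ab, temp)
    -> quality used as the regressor.
    """
    if isinstance(values, dict):
        rows = [
            {"antibiotic": e.antibiotic, "temperature": e.temperature, "value": v}
            for e, v in values.items()
        ]
        values = pd.DataFrame(rows)
    if "value" not in values.columns:
        raise EpilandError("values table needs a 'value' column")
    df = values.dropna(subset=["value"])
    if len(df) < 3:
        raise InsufficientDataError(
            f"trend regression needs >= 3 environments, got {len(df)}"
        )
    if isinstance(predictor, str):
        if predictor not in ("antibiotic", "temperature"):
            raise EpilandError(f"unknown predictor {predictor!r}")
        x = df[predictor].to_numpy(float)
    else:
        def q(row):
            key_env = (row["antibiotic"], row["temperature"])
            for key in (key_env,):
                if key in predictor:
                    return predictor[key]
            for env, val in predictor.items():
                if (getattr(env, "antibiotic", None), getattr(env, "temperature", None)) == key_env:
                    return val
            raise EpilandError(f"no quality value for environment {key_env}")
        x = np.array([q(row) for _, row in df.iterrows()], float)
    y = df["value"].to_numpy(float)
    n = y.size
    if np.ptp(x) == 0:
        raise EpilandError("constant predictor: trend regression is undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    sxy = float(xc @ yc)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_reg = slope * sxy
    sse = syy - ss_reg
    df_den = n - 2
    if syy == 0.0 or (sse <= 0 and ss_reg == 0):
        return TrendFit(0.0, intercept, 0.0, (1, df_den), 1.0, 0.0, n)
    if sse <= 0:
        return TrendFit(float(slope), intercept, math.inf, (1, df_den), 0.0, 1.0, n)
    f = (ss_reg / 1) / (sse / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    r2 = ss_reg / syy
    adj_r2 = 1 - (1 - r2) * (n - 1) / df_den
    return TrendFit(float(slope), intercept, float(f), (1, df_den), p, float(adj_r2), n)


QUALITY_METRICS = ("competitor", "reference", "combined")


def environmental_quality(records, metric: str = "competitor") -> pd.DataFrame:
    """Per-environment quality: mean log growth over strains and replicates.

    The default summarises each environment by the mean over all competitor
    strains and replicates of ln(final density / initial density) of the
    competitor channel; ``"reference"`` uses the reference channel and
    ``"combined"`` the summed channels.
    """
    if metric not in QUALITY_METRICS:
        raise EpilandError(
            f"unknown quality metric {metric!r}; choose from {QUALITY_METRICS}"
        )
    df = _as_frame(records)
    _check_densities(df)
    if metric == "competitor":
        growth = np.log(df["d_comp_final"].to_numpy() / df["d_comp_initial"].to_numpy())
    elif metric == "reference":
        growth = np.log(df["d_ref_final"].to_numpy() / df["d_ref_initial"].to_numpy())
    else:
        growth = np.log(
            (df["d_comp_final"].to_numpy() + df["d_ref_final"].to_numpy())
            / (df["d_comp_initial"].to_numpy() + df["d_ref_initial"].to_numpy())
        )
    out = (
        df.assign(growth=growth)
        .groupby(["antibiotic", "temperature"], sort=True)["growth"]
        .mean()
        .reset_index()
        .rename(columns={"growth": "quality"})
    )
    return out


def quality_mapping(quality: pd.DataFrame) -> dict:
    """Quality table -> {(antibiotic, temperature): quality} for trend regressions."""
    return {
        (r.antibiotic, r.temperature): r.quality for r in quality.itertuples()
    }


def cost_of_resistance(fits: pd.DataFrame, cfg: BootstrapConfig) -> pd.DataFrame:
    """Resistance-cost contrasts w(abr, ko) - w(WT, ko) in antibiotic-free environments.

    Returns one row per (knock-out background, ABR allele, temperature) with the
    point contrast, percentile bootstrap CI, and a ``cost`` flag set when the CI
    lies entirely below zero.
    """
    fits = _check_fitness_frame(fits)
    free = fits[fits["antibiotic"] == 0]
    if len(free) == 0:
        raise InsufficientDataError("no antibiotic-free environments in fitness table")
    check_complete_grid(free)
    rows = []
    for env in environments_of(free):
        sub = free[free["temperature"] == env.temperature].reset_index(drop=True)
        draws = cell_draw_matrix(sub, cfg)
        pos = {
            (r.abr_allele, r.ko_allele): i for i, r in enumerate(sub.itertuples())
        }
        for (abr, ko), i in sorted(pos.items()):
            if abr == WT_ABR:
                continue
            j = pos[(WT_ABR, ko)]
            point = float(sub["w_mean"].iloc[i] - sub["w_mean"].iloc[j])
            contrast = draws[:, i] - draws[:, j]
            lo, hi = percentile_ci(contrast, cfg)
            rows.append(
                {
                    "temperature": env.temperature,
                    "ko_allele": ko,
                    "abr_allele": abr,
                    "contrast": point,
                    "lo": float(lo),
                    "hi": float(hi),
                    "cost": bool(hi < 0),
                }
            )
    return pd.DataFrame(rows)
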