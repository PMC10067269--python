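"""The five epistasis statistics on two-locus fitness landscapes.

* pairwise epistasis   epsilon = w_AB - w_A - w_B + w_WT
* gamma                Pearson correlation of a mutation's fitness effects
                       across the genetic backgrounds it appears on
                       (1 = additive, <= 0 = strong epistasis)
* sign / reciprocal sign classification, with the bootstrap detection rule
  (a category is "detected" when it occurs in > 5% of bootstrap samples)
* roughness-to-slope   RMS residual of the best additive (linear) fit divided
                       by the mean absolute additive slope; 0 when additive
* diminishing returns  regression of a mutational class's fitness effects on
                       the fitness of the background carrying them

Point statistics operate on :class:`~epiland.core.LandscapeSlice` or fitness
tables; the bootstrap variants redraw every genotype x environment cell from
Normal(w_mean, w_se) (see :mod:`epiland.inference`) and are vectorised across
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    KEY_COLS,
    WT_ABR,
    WT_KO,
    Environment,
    InsufficientDataError,
    LandscapeSlice,
    _check_fitness_frame,
    allele_sets,
    check_complete_grid,
    environments_of,
)
from .inference import BootstrapConfig, cell_draw_matrix, percentile_ci

DETECTION_RATE = 0.05  # category present in > 5% of bootstrap samples


def pairwise_epistasis(sl: LandscapeSlice) -> float:
    """Classical pairwise epistasis epsilon = w_double - w_abr - w_ko + w_wt."""
    w_wt, w_abr, w_ko, w_double = sl.means()
    return w_double - w_abr - w_ko + w_wt


def mutation_effects(fits: pd.DataFrame, env: Environment | None = None) -> pd.DataFrame:
    """All single-mutation fitness effects, one per (mutation, background).

    For each focal mutation (an ABR allele != WT or a KO allele != none) and each
    background genotype lacking it, the effect is
    ``w(background + mutation) - w(background)``.  On the study preset this is
    3 x 6 + 5 x 4 = 38 effects per environment.  Columns: ``locus_class``
    (ABR/KO), ``mutation``, ``bg_abr``, ``bg_ko``, ``background_w``, ``effect``
    plus the environment key.
    """
    fits = _check_fitness_frame(fits)
    if env is not None:
        fits = fits[
            (fits["antibiotic"] == env.antibiotic)
            & (fits["temperature"] == env.temperature)
        ]
        if len(fits) == 0:
            raise InsufficientDataError(
                f"no fitness estimates for environment {env}"
            )
    check_complete_grid(fits)
    abr_all, ko_all = allele_sets(fits)
    lut = {
        (r.abr_allele, r.ko_allele, r.antibiotic, r.temperature): r.w_mean
        for r in fits.itertuples()
    }
    rows = []
    for e in environments_of(fits):
        ab, t = e.antibiotic, e.temperature
        for m in abr_all:
            if m == WT_ABR:
                continue
            for k in ko_all:
                bg = lut[(WT_ABR, k, ab, t)]
                rows.append(
                    {
                        "antibiotic": ab,
                        "temperature": t,
                        "locus_class": "ABR",
                        "mutation": m,
                        "bg_abr": WT_ABR,
                        "bg_ko": k,
                        "background_w": bg,
                        "effect": lut[(m, k, ab, t)] - bg,
                    }
                )
        for m in ko_all:
            if m == WT_KO:
                continue
            for a in abr_all:
                bg = lut[(a, WT_KO, ab, t)]
                rows.append(
                    {
                        "antibiotic": ab,
                        "temperature": t,
                        "locus_class": "KO",
                        "mutation": m,
                        "bg_abr": a,
                        "bg_ko": WT_KO,
                        "background_w": bg,
                        "effect": lut[(a, m, ab, t)] - bg,
                    }
                )
    return pd.DataFrame(rows)


def _gamma_pairs_from_effects(effects: pd.DataFrame, focal_class: str):
    """Ordered pairs (s_m(g), s_m(g + d)) pooled over focal mutations.

    For a two-locus landscape the background g shared by both members of a pair
    is the one carrying neither the focal mutation m nor the added mutation d,
    i.e. the wild type at the non-focal locus.
    """
    if focal_class not in ("all", "ABR", "KO"):
        raise ValueError(f"focal_class must be one of all/ABR/KO, got {focal_class!r}")
    xs, ys = [], []
    for (_, _), sub in effects.groupby(["antibiotic", "temperature"], sort=True):
        if focal_class in ("all", "ABR"):
            abr = sub[sub["locus_class"] == "ABR"]
            for m, g in abr.groupby("mutation", sort=True):
                base = g[g["bg_ko"] == WT_KO]
                if len(base) != 1:
                    continue
                x = float(base["effect"].iloc[0])
                for _, row in g[g["bg_ko"] != WT_KO].sort_values("bg_ko").iterrows():
                    xs.append(x)
                    ys.append(float(row["effect"]))
        if focal_class in ("all", "KO"):
            ko = sub[sub["locus_class"] == "KO"]
            for m, g in ko.groupby("mutation", sort=True):
                base = g[g["bg_abr"] == WT_ABR]
                if len(base) != 1:
                    continue
                x = float(base["effect"].iloc[0])
                for _, row in g[g["bg_abr"] != WT_ABR].sort_values("bg_abr").iterrows():
                    xs.append(x)
                    ys.append(float(row["effect"]))
    return np.asarray(xs, float), np.asarray(ys, float)


def gamma_statistic(effects: pd.DataFrame, focal_class: str = "all") -> float:
    """Gamma epistasis: pooled Pearson correlation of paired mutation effects.

    Pairs are (effect of m on the background lacking the other-locus mutation d,
    effect of m on the background carrying d), pooled across focal mutations of
    ``focal_class``.  A fully additive landscape gives gamma = 1.  If either
    pooled vector has zero variance the statistic is degenerate: returns 1.0
    when the two vectors are identical (no epistasis), NaN otherwise.
    """
    x, y = _gamma_pairs_from_effects(effects, focal_class)
    if x.size < 2:
        raise InsufficientDataError(
            f"gamma statistic needs >= 2 pairs, got {x.size}"
        )
    return _pearson_or_degenerate(x, y)


def _pearson_or_degenerate(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 1.0 if np.array_equal(x, y) else math.nan
    return float((xc @ yc) / math.sqrt(sx * sy))


def _sign(v: float, tol: float) -> int:
    if v > tol:
        return 1
    if v < -tol:
        return -1
    return 0


def classify_sign_epistasis(sl: LandscapeSlice, tol: float = 0.0) -> str:
    """Classify a slice as ``none``, ``simple`` or ``reciprocal`` sign epistasis.

    A locus shows a sign change when the fitness effect of its mutation has
    strictly opposite (nonzero) signs on the two backgrounds formed by the other
    locus.  Reciprocal: both loci change sign; simple: exactly one.  Exact-zero
    effects carry no sign (``tol`` widens the zero band; the default compares
    point estimates exactly, uncertainty enters via the bootstrap layer).
    """
    w_wt, w_abr, w_ko, w_double = sl.means()
    s_a0 = _sign(w_abr - w_wt, tol)
    s_a1 = _sign(w_double - w_ko, tol)
    s_b0 = _sign(w_ko - w_wt, tol)
    s_b1 = _sign(w_double - w_abr, tol)
    flip_a = s_a0 != 0 and s_a1 != 0 and s_a0 != s_a1
    flip_b = s_b0 != 0 and s_b1 != 0 and s_b0 != s_b1
    if flip_a and flip_b:
        return "reciprocal"
    if flip_a or flip_b:
        return "simple"
    return "none"


def _env_subtable(fits: pd.DataFrame, env: Environment) -> pd.DataFrame:
    sub = fits[
        (fits["antibiotic"] == env.antibiotic)
        & (fits["temperature"] == env.temperature)
    ].reset_index(drop=True)
    if len(sub) == 0:
        raise InsufficientDataError(f"no fitness estimates for environment {env}")
    check_complete_grid(sub)
    return sub


def _slice_positions(sub: pd.DataFrame) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Cell positions [wt, abr, ko, double] for every slice of one environment."""
    pos = {(r.abr_allele, r.ko_allele): i for i, r in enumerate(sub.itertuples())}
    abr_all, ko_all = allele_sets(sub)
    names, idx = [], []
    for a in abr_all:
        if a == WT_ABR:
            continue
        for k in ko_all:
            if k == WT_KO:
                continue
            names.append((a, k))
            idx.append([pos[(WT_ABR, WT_KO)], pos[(a, WT_KO)], pos[(WT_ABR, k)], pos[(a, k)]])
    return names, np.asarray(idx, int)


@dataclass(frozen=True)
class SignEpistasisResult:
    """Bootstrap summary of sign-epistasis fractions for one environment."""

    environment: Environment
    frac_simple: float          # mean fraction of slices per bootstrap sample
    frac_reciprocal: float
    ci_simple: tuple[float, float]
    ci_reciprocal: tuple[float, float]
    point_simple: float         # deterministic classification of point estimates
    point_reciprocal: float
    per_slice: pd.DataFrame     # slice, simple_rate, reciprocal_rate, detected_*
    n_samples: int


def sign_epistasis_fractions(
    fits: pd.DataFrame, env: Environment, cfg: BootstrapConfig
) -> SignEpistasisResult:
    """Fractions of slices with simple / reciprocal sign epistasis, bootstrapped.

    Every bootstrap sample redraws all cells, classifies all slices, and records
    the fraction in each category; the mean fraction and a percentile CI are
    reported.  Each slice is additionally flagged as *detected* for a category
    occurring in more than 5% of samples.
    """
    sub = _env_subtable(fits, env)
    names, idx = _slice_positions(sub)
    draws = cell_draw_matrix(sub, cfg)  # (B, n_cells)
    w_wt = draws[:, idx[:, 0]]
    w_abr = draws[:, idx[:, 1]]
    w_ko = draws[:, idx[:, 2]]
    w_double = draws[:, idx[:, 3]]
    flip_a = (w_abr - w_wt) * (w_double - w_ko) < 0
    flip_b = (w_ko - w_wt) * (w_double - w_abr) < 0
    recip = flip_a & flip_b
    simple = flip_a ^ flip_b
    frac_simple = simple.mean(axis=1)
    frac_recip = recip.mean(axis=1)
    ci_s = percentile_ci(frac_simple, cfg)
    ci_r = percentile_ci(frac_recip, cfg)
    point = [
        classify_sign_epistasis(_slice_at(sub, a, k, env)) for a, k in names
    ]
    per_slice = pd.DataFrame(
        {
            "abr_mutation": [a for a, _ in names],
            "ko_mutation": [k for _, k in names],
            "classification": point,
            "simple_rate": simple.mean(axis=0),
            "reciprocal_rate": recip.mean(axis=0),
        }
    )
    per_slice["detected_simple"] = per_slice["simple_rate"] > DETECTION_RATE
    per_slice["detected_reciprocal"] = per_slice["reciprocal_rate"] > DETECTION_RATE
    n_slices = len(names)
    return SignEpistasisResult(
        environment=env,
        frac_simple=float(frac_simple.mean()),
        frac_reciprocal=float(frac_recip.mean()),
        ci_simple=(float(ci_s[0]), float(ci_s[1])),
        ci_reciprocal=(float(ci_r[0]), float(ci_r[1])),
        point_simple=sum(c == "simple" for c in point) / n_slices,
        point_reciprocal=sum(c == "reciprocal" for c in point) / n_slices,
        per_slice=per_slice,
        n_samples=cfg.n_samples,
    )


def _slice_at(sub: pd.DataFrame, abr: str, ko: str, env: Environment) -> LandscapeSlice:
    from .core import extract_landscape_slice

    return extract_landscape_slice(sub, abr, ko, env)


_ADDITIVE_DESIGN = np.array(
    [[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0], [1.0, 1.0, 1.0]]
)


def roughness_to_slope(sl: LandscapeSlice) -> float:
    """Roughness-to-slope ratio of the four-genotype diamond.

    Least-squares fit of w on (intercept, ABR indicator, KO indicator);
    roughness is the RMS residual (divide by the number of genotypes, 4) and the
    slope is the mean absolute value of the two non-intercept coefficients.  For
    two loci the ratio equals |epsilon| / (4 * mean |slopes|).  A flat landscape
    (0/0) is defined as 0; nonzero roughness over zero slope returns inf.
    """
    w = np.asarray(sl.means(), float)
    beta, *_ = np.linalg.lstsq(_ADDITIVE_DESIGN, w, rcond=None)
    resid = w - _ADDITIVE_DESIGN @ beta
    roughness = float(np.sqrt(np.mean(resid**2)))
    slope = float((abs(beta[1]) + abs(beta[2])) / 2)
    # an exactly-flat fitted plane comes out of lstsq as slope ~ 1e-16
    tol = 1e-12 * max(1.0, float(np.abs(w).max()))
    if slope <= tol:
        return 0.0 if roughness <= tol else math.inf
    return roughness / slope


def _rs_from_draws(w_wt, w_abr, w_ko, w_double) -> np.ndarray:
    """Vectorised roughness-to-slope via the two-locus closed form."""
    eps = w_double - w_abr - w_ko + w_wt
    b_a = ((w_abr - w_wt) + (w_double - w_ko)) / 2
    b_b = ((w_ko - w_wt) + (w_double - w_abr)) / 2
    slope = (np.abs(b_a) + np.abs(b_b)) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(eps) / 4 / slope
    out = np.where((slope == 0) & (eps == 0), 0.0, out)
    return out


@dataclass(frozen=True)
class DiminishingReturnsResult:
    """Bootstrap regression of a mutational class's effects on background fitness."""

    environment: Environment
    focal_class: str
    slope_point: float
    slope_mean: float
    ci: tuple[float, float]
    significant: bool
    n_points: int
    n_samples: int


def diminishing_returns(
    fits: pd.DataFrame,
    env: Environment,
    focal_class: str,
    cfg: BootstrapConfig,
    exclude_backgrounds: set[str] | None = None,
) -> DiminishingReturnsResult:
    """Diminishing-returns test: do larger-fitness backgrounds see smaller effects?

    Pools the focal class's mutations into a single per-environment regression of
    effect size on background fitness; the slope is averaged over bootstrap
    samples with a percentile CI, significant iff the CI excludes zero.
    ``exclude_backgrounds`` drops backgrounds carrying any of the named alleles
    (sensitivity analysis, e.g. excluding the hypersusceptible waaP deletion).
    """
    if focal_class not in ("ABR", "KO"):
        raise ValueError("focal_class must be 'ABR' or 'KO'")
    sub = _env_subtable(fits, env)
    pos = {(r.abr_allele, r.ko_allele): i for i, r in enumerate(sub.itertuples())}
    abr_all, ko_all = allele_sets(sub)
    excl = exclude_backgrounds or set()
    bg_idx, mut_idx = [], []
    if focal_class == "ABR":
        for m in abr_all:
            if m == WT_ABR:
                continue
            for k in ko_all:
                if k in excl:
                    continue
                bg_idx.append(pos[(WT_ABR, k)])
                mut_idx.append(pos[(m, k)])
    else:
        for m in ko_all:
            if m == WT_KO:
                continue
            for a in abr_all:
                if a in excl:
                    continue
                bg_idx.append(pos[(a, WT_KO)])
                mut_idx.append(pos[(a, m)])
    if len(bg_idx) < 3:
        raise InsufficientDataError(
            f"diminishing-returns regression needs >= 3 points, got {len(bg_idx)}"
        )
    bg_idx = np.asarray(bg_idx, int)
    mut_idx = np.asarray(mut_idx, int)
    mean = sub["w_mean"].to_numpy(float)
    slope_point = _row_slope(
        mean[bg_idx][None, :], (mean[mut_idx] - mean[bg_idx])[None, :]
    )[0]
    draws = cell_draw_matrix(sub, cfg)
    x = draws[:, bg_idx]
    y = draws[:, mut_idx] - draws[:, bg_idx]
    slopes = _row_slope(x, y)
    lo, hi = percentile_ci(slopes, cfg)
    return DiminishingReturnsResult(
        environment=env,
        focal_class=focal_class,
        slope_point=float(slope_point),
        slope_mean=float(slopes.mean()),
        ci=(float(lo), float(hi)),
        significant=bool(lo > 0 or hi < 0),
        n_points=len(bg_idx),
        n_samples=cfg.n_samples,
    )


def _row_slope(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS slope of y on x for each row of two equal-shape matrices."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (xc * yc).sum(axis=1) / sxx


def _gamma_positions(sub: pd.DataFrame, focal_class: str):
    """Cell-position quadruples (m+g, g, m+g+d, g+d) for the gamma pairing."""
    pos = {(r.abr_allele, r.ko_allele): i for i, r in enumerate(sub.itertuples())}
    abr_all, ko_all = allele_sets(sub)
    quads = []
    if focal_class in ("all", "ABR"):
        for m in abr_all:
            if m == WT_ABR:
                continue
            for k in ko_all:
                if k == WT_KO:
                    continue
                quads.append(
                    (pos[(m, WT_KO)], pos[(WT_ABR, WT_KO)], pos[(m, k)], pos[(WT_ABR, k)])
                )
    if focal_class in ("all", "KO"):
        for m in ko_all:
            if m == WT_KO:
                continue
            for a in abr_all:
                if a == WT_ABR:
                    continue
                quads.append(
                    (pos[(WT_ABR, m)], pos[(WT_ABR, WT_KO)], pos[(a, m)], pos[(a, WT_KO)])
                )
    return np.asarray(quads, int)


def _gamma_from_draws(draws: np.ndarray, quads: np.ndarray) -> np.ndarray:
    x = draws[:, quads[:, 0]] - draws[:, quads[:, 1]]
    y = draws[:, quads[:, 2]] - draws[:, quads[:, 3]]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = (xc * xc).sum(axis=1)
    sy = (yc * yc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (xc * yc).sum(axis=1) / np.sqrt(sx * sy)


@dataclass(frozen=True)
class EpistasisSummary:
    """All epistasis metrics with bootstrap CIs for one environment."""

    environment: Environment
    gamma: dict  # class -> (point, lo, hi)
    sign: SignEpistasisResult
    rs_ratios: pd.DataFrame  # per-slice: point, lo, hi
    pairwise: pd.DataFrame  # per-slice: point, lo, hi, detected (CI excludes 0)
    n_samples: int


def summarize_epistasis(
    fits: pd.DataFrame, cfg: BootstrapConfig, envs: list[Environment] | None = None
) -> list[EpistasisSummary]:
    """Per-environment epistasis summaries over the whole fitness table."""
    fits = _check_fitness_frame(fits)
    check_complete_grid(fits)
    out = []
    for env in envs or environments_of(fits):
        sub = _env_subtable(fits, env)
        names, idx = _slice_positions(sub)
        mean = sub["w_mean"].to_numpy(float)
        draws = cell_draw_matrix(sub, cfg)

        gamma = {}
        for cls in ("all", "ABR", "KO"):
            quads = _gamma_positions(sub, cls)
            point = _gamma_from_draws(mean[None, :], quads)[0]
            samples = _gamma_from_draws(draws, quads)
            samples = samples[np.isfinite(samples)]
            if samples.size:
                lo, hi = percentile_ci(samples, cfg)
            else:
                lo = hi = math.nan
            gamma[cls] = (float(point), float(lo), float(hi))

        sign = sign_epistasis_fractions(fits, env, cfg)

        w_wt, w_abr = draws[:, idx[:, 0]], draws[:, idx[:, 1]]
        w_ko, w_double = draws[:, idx[:, 2]], draws[:, idx[:, 3]]
        eps = w_double - w_abr - w_ko + w_wt
        eps_pt = mean[idx[:, 3]] - mean[idx[:, 1]] - mean[idx[:, 2]] + mean[idx[:, 0]]
        eps_lo, eps_hi = percentile_ci(eps, cfg)
        pairwise = pd.DataFrame(
            {
                "abr_mutation": [a for a, _ in names],
                "ko_mutation": [k for _, k in names],
                "epsilon": eps_pt,
                "lo": eps_lo,
                "hi": eps_hi,
            }
        )
        pairwise["detected"] = (pairwise["lo"] > 0) | (pairwise["hi"] < 0)

        rs = _rs_from_draws(w_wt, w_abr, w_ko, w_double)
        rs_pt = _rs_from_draws(
            mean[idx[:, 0]], mean[idx[:, 1]], mean[idx[:, 2]], mean[idx[:, 3]]
        )
        rs_lo, rs_hi = percentile_ci(rs, cfg)
        rs_ratios = pd.DataFrame(
            {
                "abr_mutation": [a for a, _ in names],
                "ko_mutation": [k for _, k in names],
                "rs_ratio": rs_pt,
                "lo": rs_lo,
                "hi": rs_hi,
            }
        )
        out.append(
            EpistasisSummary(
                environment=env,
                gamma=gamma,
                sign=sign,
                rs_ratios=rs_ratios,
                pairwise=pairwise,
                n_samples=cfg.n_samples,
            )
        )
    return out


def summary_frame(summaries: list[EpistasisSummary]) -> pd.DataFrame:
    """Tidy one-row-per-environment table of all epistasis metrics."""
    rows = []
    for s in summaries:
        row = {
            "antibiotic": s.environment.antibiotic,
            "temperature": s.environment.temperature,
        }
        for cls in ("all", "ABR", "KO"):
            pt, lo, hi = s.gamma[cls]
            key = {"all": "gamma_all", "ABR": "gamma_abr", "KO": "gamma_ko"}[cls]
            row.update({key: pt, f"{key}_lo": lo, f"{key}_hi": hi})
        row.update(
            {
                "frac_simple": s.sign.frac_simple,
                "frac_simple_lo": s.sign.ci_simple[0],
                "frac_simple_hi": s.sign.ci_simple[1],
                "frac_reciprocal": s.sign.frac_reciprocal,
                "frac_reciprocal_lo": s.sign.ci_reciprocal[0],
                "frac_reciprocal_hi": s.sign.ci_reciprocal[1],
                "rs_mean": float(s.rs_ratios["rs_ratio"].mean()),
                "epsilon_mean_abs": float(s.pairwise["epsilon"].abs().mean()),
                "n_bootstrap": s.n_samples,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["antibiotic", "temperature"]).reset_index(
        drop=True
    )
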