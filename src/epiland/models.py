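"""Nested linear-model suite for the competitive index.

Three nested OLS models for per-replicate competitive indices w:

1. additive:       w ~ G_rpoB + G_KO + E_AB + E_T
2. + G x E:        ... + G_rpoB x E_AB
3. + G x E, G x G: ... + G_rpoB x E_AB + G_rpoB x G_KO

Genotype factors use treatment coding with the wild type as reference; the
ordered temperature factor uses orthogonal polynomial contrasts (linear,
quadratic); antibiotic concentration is coded as an unordered factor by default
(switchable to continuous).  Nested models are compared with the incremental
F-test F = ((SSR_red - SSR_full)/ddf) / (SSR_full/df_full).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrices
from scipy import stats
from scipy.linalg import qr

from .core import EpilandError, _as_frame, competitive_indices

ADDITIVE_TERMS = ("G_rpoB", "G_KO", "E_AB", "E_T")
GXE_TERMS = ADDITIVE_TERMS + ("G_rpoB:E_AB",)
GXG_TERMS = GXE_TERMS + ("G_rpoB:G_KO",)


class RankDeficiencyError(EpilandError):
    """The design matrix is not of full column rank."""


class NonNestedError(EpilandError):
    """The reduced model's columns are not inside the full model's span."""


@dataclass(frozen=True)
class ModelSpec:
    """Which factors and interactions enter the model, and how they are coded.

    ``terms`` draws from {G_rpoB, G_KO, E_AB, E_T} and ':'-joined interactions
    of those factors.  ``ab_coding`` is 'factor' (level-wise coefficients) or
    'continuous' (ug/ml as a covariate).
    """

    terms: tuple[str, ...] = ADDITIVE_TERMS
    ab_coding: str = "factor"
    abr_ref: str = "WT"
    ko_ref: str = "none"

    def _factor(self, name: str) -> str:
        if name == "G_rpoB":
            return f"C(abr_allele, Treatment({self.abr_ref!r}))"
        if name == "G_KO":
            return f"C(ko_allele, Treatment({self.ko_ref!r}))"
        if name == "E_AB":
            if self.ab_coding == "factor":
                return "C(antibiotic)"
            if self.ab_coding == "continuous":
                return "antibiotic"
            raise EpilandError(f"unknown ab_coding {self.ab_coding!r}")
        if name == "E_T":
            return "C(temperature, Poly)"
        raise EpilandError(f"unknown model term {name!r}")

    def formula(self) -> str:
        if not self.terms:
            return "w ~ 1"
        parts = []
        for term in self.terms:
            parts.append(":".join(self._factor(f) for f in term.split(":")))
        return "w ~ " + " + ".join(parts)


def _with_response(data) -> pd.DataFrame:
    if "w" in getattr(data, "columns", ()):
        return data
    df = _as_frame(data)
    return df.assign(w=competitive_indices(df))


def build_design(data, spec: ModelSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Build (response vector, design matrix) for per-replicate indices.

    ``data`` is either a records table (the competitive index is computed per
    row) or any table with a ``w`` column plus the factor columns.
    """
    df = _with_response(data)
    y, x = dmatrices(spec.formula(), df, return_type="dataframe")
    return y.to_numpy(float).ravel(), x


@dataclass(frozen=True)
class ModelFit:
    """An OLS fit with its design retained for nesting checks."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid: np.ndarray
    fitted: np.ndarray
    df_resid: int
    nobs: int
    ssr: float
    r2: float
    adj_r2: float
    design: pd.DataFrame
    response: np.ndarray
    spec: ModelSpec | None = None

    def coef_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "t": self.tvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )


def fit_ols(design: pd.DataFrame, response: np.ndarray,
            spec: ModelSpec | None = None) -> ModelFit:
    """Least-squares fit; errors on rank deficiency, naming collinear columns."""
    x = np.asarray(design, float)
    y = np.asarray(response, float).ravel()
    n, p = x.shape
    if n < p:
        raise RankDeficiencyError(f"fewer rows ({n}) than columns ({p})")
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        _, r, piv = qr(x, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [design.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [design.columns[j] for j in piv[len(diag):]]
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear column(s): {bad}")
    res = sm.OLS(y, x).fit()
    cols = list(design.columns)
    return ModelFit(
        params=pd.Series(res.params, index=cols),
        bse=pd.Series(res.bse, index=cols),
        tvalues=pd.Series(res.tvalues, index=cols),
        pvalues=pd.Series(res.pvalues, index=cols),
        resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        df_resid=int(res.df_resid),
        nobs=n,
        ssr=float(res.ssr),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        design=design,
        response=y,
        spec=spec,
    )


def fit_model(data, spec: ModelSpec) -> ModelFit:
    """Convenience: build the design for ``spec`` and fit it."""
    y, x = build_design(data, spec)
    return fit_ols(x, y, spec=spec)


@dataclass(frozen=True)
class ModelComparison:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float

    def significant(self, alpha: float = 0.01) -> bool:
        return bool(self.p_value < alpha)


def compare_nested(reduced: ModelFit, full: ModelFit,
                   tol: float = 1e-8) -> ModelComparison:
    """Incremental F-test of a full model against a nested reduced model.

    Verifies that both fits share the response and that every reduced design
    column lies in the span of the full design (projection residual <= tol
    relative to column norm).
    """
    if reduced.nobs != full.nobs or not np.allclose(reduced.response, full.response):
        raise NonNestedError("models were fit to different responses")
    xf = np.asarray(full.design, float)
    xr = np.asarray(reduced.design, float)
    coef, *_ = np.linalg.lstsq(xf, xr, rcond=None)
    resid = xr - xf @ coef
    scale = np.linalg.norm(xr) + 1.0
    if np.linalg.norm(resid) > tol * scale:
        raise NonNestedError(
            "reduced model columns are not in the span of the full model"
        )
    df_num = int(reduced.df_resid - full.df_resid)
    df_den = int(full.df_resid)
    if df_num == 0:
        return ModelComparison(0.0, 0, df_den, 1.0)
    if full.ssr <= 0:
        f = math.inf if reduced.ssr > full.ssr else 0.0
        return ModelComparison(f, df_num, df_den, 0.0 if f == math.inf else 1.0)
    f = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df_num, df_den))
    return ModelComparison(float(f), df_num, df_den, p)


SUITE_SPECS = {
    "additive": ADDITIVE_TERMS,
    "additive+GxE": GXE_TERMS,
    "additive+GxE+GxG": GXG_TERMS,
}


@dataclass(frozen=True)
class ModelSuiteResult:
    fits: dict
    comparisons: dict  # (reduced name, full name) -> ModelComparison
    residual_by_genotype: pd.DataFrame

    def adj_r2_ladder(self) -> list[float]:
        return [self.fits[name].adj_r2 for name in SUITE_SPECS]


def model_suite(data, ab_coding: str = "factor") -> ModelSuiteResult:
    """Fit the additive / +GxE / +GxE+GxG ladder with nested F-tests.

    Residual-by-genotype diagnostics report each rpoB allele's share of the
    additive model's residual sum of squares (the susceptible wild-type alleles
    dominate when G x E structure is present).
    """
    df = _with_response(data)
    fits = {
        name: fit_model(df, ModelSpec(terms=terms, ab_coding=ab_coding))
        for name, terms in SUITE_SPECS.items()
    }
    names = list(SUITE_SPECS)
    comparisons = {
        (names[i], names[i + 1]): compare_nested(fits[names[i]], fits[names[i + 1]])
        for i in range(len(names) - 1)
    }
    resid2 = fits["additive"].resid ** 2
    diag = (
        df.assign(resid2=resid2)
        .groupby("abr_allele", sort=True)["resid2"]
        .sum()
        .reset_index()
        .rename(columns={"resid2": "ssr"})
    )
    diag["share"] = diag["ssr"] / diag["ssr"].sum()
    return ModelSuiteResult(fits=fits, comparisons=comparisons, residual_by_genotype=diag)
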