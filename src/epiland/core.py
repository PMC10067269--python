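"""Domain model and competitive-fitness estimation for two-locus landscapes.

Each competition assay competes a *competitor* genotype (an antibiotic-resistance
allele in *rpoB* combined with a gene knock-out) against a fixed fluorescently
labelled reference strain in one environment (a rifampicin concentration ×
temperature combination).  The competitive index

    w = ln( (D_comp^final / D_ref^final) / (D_comp^initial / D_ref^initial) )

is a log-ratio proxy for relative fitness over one ~20 h growth cycle.  This
module holds the typed containers (genotypes, environments, records, fitness
estimates, four-genotype landscape slices), the index estimator, replicate
aggregation, the dye-swap marker-neutrality check, and landscape assembly.

Tables are plain pandas DataFrames with fixed column schemas (see
:data:`RECORD_COLS` and :data:`FITNESS_COLS`) so every stage is CSV round-trippable.
"""

from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

# Study presets: 4 rpoB alleles x 6 knock-out states on a 4 x 3 environment grid.
ABR_ALLELES = ("WT", "S512F", "H526Y", "I572S")
KO_ALLELES = ("none", "marR", "nuoC", "waaP", "yidK", "ybfG")
ANTIBIOTIC_CONCS = (0.0, 4.0, 8.0, 10.0)  # rifampicin, ug/ml
TEMPERATURES = (37.0, 40.0, 42.0)  # degrees C

WT_ABR = "WT"
WT_KO = "none"

ORIENT_GFP = "competitor-GFP"
ORIENT_MCHERRY = "competitor-mCherry"
ORIENTATIONS = (ORIENT_GFP, ORIENT_MCHERRY)

KEY_COLS = ["abr_allele", "ko_allele", "antibiotic", "temperature"]
REPLICATE_KEY = KEY_COLS + ["replicate", "orientation"]
DENSITY_COLS = ["d_comp_initial", "d_ref_initial", "d_comp_final", "d_ref_final"]
RECORD_COLS = REPLICATE_KEY + DENSITY_COLS
FITNESS_COLS = KEY_COLS + ["w_mean", "w_se", "n"]


class EpilandError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(EpilandError):
    """A competition record violates the measurement model (non-positive density)."""


class DuplicateRecordError(EpilandError):
    """Two records share the same (genotype, environment, replicate, orientation) key."""


class MissingGenotypeError(EpilandError):
    """A landscape slice lookup failed because a genotype cell is absent."""


class IncompleteGridError(EpilandError):
    """The genotype x environment grid has missing cells."""

    def __init__(self, missing: list, message: str | None = None):
        self.missing = list(missing)
        super().__init__(
            message
            or f"incomplete genotype x environment grid; {len(self.missing)} "
            f"missing cell(s): {self.missing[:10]}"
        )


class InsufficientDataError(EpilandError):
    """Not enough observations for the requested estimate."""


class SchemaError(EpilandError):
    """An input table does not conform to the expected column schema."""


@dataclass(frozen=True)
class Genotype:
    """A two-locus genotype: one rpoB allele and one knock-out allele."""

    abr_allele: str
    ko_allele: str

    @property
    def is_wild_type(self) -> bool:
        return self.abr_allele == WT_ABR and self.ko_allele == WT_KO


@dataclass(frozen=True)
class Environment:
    """One abiotic environment: antibiotic concentration (ug/ml) x temperature (C)."""

    antibiotic: float
    temperature: float

    def __post_init__(self):
        if self.antibiotic < 0:
            raise ValueError(f"antibiotic concentration must be >= 0, got {self.antibiotic}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


@dataclass(frozen=True)
class CompetitionRecord:
    """One replicate of a competition assay: four flow-cytometry densities."""

    genotype: Genotype
    environment: Environment
    replicate: int
    orientation: str
    d_comp_initial: float
    d_ref_initial: float
    d_comp_final: float
    d_ref_final: float


@dataclass(frozen=True)
class FitnessEstimate:
    """Mean competitive index for one genotype x environment cell.

    ``w_se`` is the standard error of the mean (sample SD / sqrt(n)); it is NaN
    when only one replicate exists (flagged downstream, see
    :func:`epiland.inference.prepare_se`).
    """

    genotype: Genotype
    environment: Environment
    w_mean: float
    w_se: float
    n: int


@dataclass(frozen=True)
class LandscapeSlice:
    """The four-genotype diamond {WT, ABR single, KO single, double mutant}."""

    environment: Environment
    abr_mutation: str
    ko_mutation: str
    w_wt: FitnessEstimate
    w_abr: FitnessEstimate
    w_ko: FitnessEstimate
    w_double: FitnessEstimate

    def means(self) -> tuple[float, float, float, float]:
        """(w_wt, w_abr, w_ko, w_double) point estimates."""
        return (
            self.w_wt.w_mean,
            self.w_abr.w_mean,
            self.w_ko.w_mean,
            self.w_double.w_mean,
        )

    def ses(self) -> tuple[float, float, float, float]:
        return (self.w_wt.w_se, self.w_abr.w_se, self.w_ko.w_se, self.w_double.w_se)


def slice_from_means(
    w_wt: float,
    w_abr: float,
    w_ko: float,
    w_double: float,
    environment: Environment | None = None,
    abr_mutation: str = "A",
    ko_mutation: str = "B",
    ses: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
) -> LandscapeSlice:
    """Build a slice directly from four fitness values (convenience for analysis)."""
    env = environment or Environment(0.0, 37.0)

    def est(abr, ko, w, se):
        return FitnessEstimate(Genotype(abr, ko), env, w, se, 1)

    return LandscapeSlice(
        environment=env,
        abr_mutation=abr_mutation,
        ko_mutation=ko_mutation,
        w_wt=est(WT_ABR, WT_KO, w_wt, ses[0]),
        w_abr=est(abr_mutation, WT_KO, w_abr, ses[1]),
        w_ko=est(WT_ABR, ko_mutation, w_ko, ses[2]),
        w_double=est(abr_mutation, ko_mutation, w_double, ses[3]),
    )


def records_to_frame(records: Iterable[CompetitionRecord]) -> pd.DataFrame:
    """Convert typed records to the canonical long-format table."""
    rows = [
        {
            "abr_allele": r.genotype.abr_allele,
            "ko_allele": r.genotype.ko_allele,
            "antibiotic": r.environment.antibiotic,
            "temperature": r.environment.temperature,
            "replicate": r.replicate,
            "orientation": r.orientation,
            "d_comp_initial": r.d_comp_initial,
            "d_ref_initial": r.d_ref_initial,
            "d_comp_final": r.d_comp_final,
            "d_ref_final": r.d_ref_final,
        }
        for r in records
    ]
    if not rows:
        raise InsufficientDataError("no competition records supplied")
    return pd.DataFrame(rows, columns=RECORD_COLS)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RECORD_COLS if c not in records.columns]
        if missing:
            raise SchemaError(f"records table is missing column(s): {missing}")
        if len(records) == 0:
            raise InsufficientDataError("empty records table")
        return records
    return records_to_frame(records)


def _check_densities(df: pd.DataFrame) -> None:
    for col in DENSITY_COLS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~(vals > 0) | vals.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise InvalidRecordError(
                f"density '{col}' must be strictly positive; "
                f"offending value {df[col].iloc[i]!r} in row {df.index[i]}"
            )


def competitive_index(record: CompetitionRecord) -> float:
    """Competitive index ln((Dcomp_f/Dref_f) / (Dcomp_i/Dref_i)) for one record.

    Raises :class:`InvalidRecordError` naming the offending field if any density
    is not strictly positive.
    """
    for name in DENSITY_COLS:
        val = getattr(record, name)
        if not (val > 0) or math.isnan(val):
            raise InvalidRecordError(
                f"density '{name}' must be strictly positive, got {val!r}"
            )
    return math.log(
        (record.d_comp_final / record.d_ref_final)
        / (record.d_comp_initial / record.d_ref_initial)
    )


def competitive_indices(records) -> pd.Series:
    """Vectorised competitive index for every row of a records table."""
    df = _as_frame(records)
    _check_densities(df)
    return pd.Series(
        np.log(df["d_comp_final"].to_numpy() / df["d_ref_final"].to_numpy())
        - np.log(df["d_comp_initial"].to_numpy() / df["d_ref_initial"].to_numpy()),
        index=df.index,
        name="w",
    )


def summarize_fitness(records, pool_orientations: bool = True) -> pd.DataFrame:
    """Aggregate per-replicate competitive indices into per-cell fitness estimates.

    Replicates are aggregated as unweighted means over per-replicate indices, with
    standard error = sample SD / sqrt(n).  Cells with a single replicate get
    ``w_se = NaN`` (undefined-SE flag).  Orientations are pooled by default; with
    ``pool_orientations=False`` the orientation becomes part of the cell key.

    Raises on empty input and on duplicated
    (genotype, environment, replicate, orientation) keys.
    """
    df = _as_frame(records)
    dup = df.duplicated(subset=REPLICATE_KEY, keep=False)
    if dup.any():
        keys = df.loc[dup, REPLICATE_KEY].drop_duplicates().values.tolist()
        raise DuplicateRecordError(f"duplicated replicate key(s): {keys[:5]}")
    w = competitive_indices(df)
    group_cols = KEY_COLS if pool_orientations else KEY_COLS + ["orientation"]
    grouped = df.assign(w=w).groupby(group_cols, sort=True)["w"]
    out = grouped.agg(w_mean="mean", w_sd=lambda s: s.std(ddof=1), n="count").reset_index()
    out["w_se"] = out["w_sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "w_se"] = np.nan
    out["n"] = out["n"].astype(int)
    return out[group_cols + ["w_mean", "w_se", "n"]]


@dataclass(frozen=True)
class DyeSwapReport:
    """Marker-neutrality regression of GFP-orientation on mCherry-orientation indices."""

    slope: float
    intercept: float
    adj_r2: float
    slope_ci: tuple[float, float]
    n_pairs: int
    f_environment: float
    df_environment: tuple[int, int]
    p_environment: float
    f_genotype: float
    df_genotype: tuple[int, int]
    p_genotype: float


def _incremental_f(base_res, aug_res) -> tuple[float, tuple[int, int], float]:
    """F-test for adding columns: ((SSR_red-SSR_full)/ddf) / (SSR_full/df_full)."""
    ddf = int(base_res.df_resid - aug_res.df_resid)
    df_full = int(aug_res.df_resid)
    if ddf <= 0 or df_full <= 0:
        return math.nan, (max(ddf, 0), max(df_full, 0)), math.nan
    f = ((base_res.ssr - aug_res.ssr) / ddf) / (aug_res.ssr / df_full)
    p = float(stats.f.sf(f, ddf, df_full))
    return float(f), (ddf, df_full), p


def dye_swap_check(records, ci_level: float = 0.95) -> DyeSwapReport:
    """Check that the fluorophore is a neutral marker.

    Pairs the orientation-wise mean competitive index per genotype x environment
    cell, regresses the GFP-orientation index on the mCherry-orientation index,
    and reports incremental F-tests for adding environment and genotype factors
    to that regression.  A neutral marker gives slope ~1, intercept ~0 and no
    significant factor effects.
    """
    df = _as_frame(records)
    w = competitive_indices(df)
    cell = (
        df.assign(w=w)
        .groupby(KEY_COLS + ["orientation"], sort=True)["w"]
        .mean()
        .unstack("orientation")
    )
    for orient in ORIENTATIONS:
        if orient not in cell.columns:
            raise InsufficientDataError(f"no records with orientation {orient!r}")
    pairs = cell[[ORIENT_GFP, ORIENT_MCHERRY]].dropna().reset_index()
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"dye-swap check needs >= 3 cells with both orientations, got {len(pairs)}"
        )
    pairs["env"] = pairs["antibiotic"].astype(str) + "/" + pairs["temperature"].astype(str)
    pairs["geno"] = pairs["abr_allele"] + "/" + pairs["ko_allele"]

    y = pairs[ORIENT_GFP].to_numpy()
    x_base = sm.add_constant(pairs[[ORIENT_MCHERRY]].to_numpy())
    base = sm.OLS(y, x_base).fit()
    slope = float(base.params[1])
    intercept = float(base.params[0])
    alpha = 1.0 - ci_level
    ci = base.conf_int(alpha=alpha)
    slope_ci = (float(ci[1][0]), float(ci[1][1]))

    def augmented(factor: str):
        dummies = pd.get_dummies(pairs[factor], drop_first=True, dtype=float)
        x_aug = np.column_stack([x_base, dummies.to_numpy()])
        return sm.OLS(y, x_aug).fit()

    f_env, df_env, p_env = _incremental_f(base, augmented("env"))
    f_gen, df_gen, p_gen = _incremental_f(base, augmented("geno"))
    return DyeSwapReport(
        slope=slope,
        intercept=intercept,
        adj_r2=float(base.rsquared_adj),
        slope_ci=slope_ci,
        n_pairs=len(pairs),
        f_environment=f_env,
        df_environment=df_env,
        p_environment=p_env,
        f_genotype=f_gen,
        df_genotype=df_gen,
        p_genotype=p_gen,
    )


def _check_fitness_frame(fits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FITNESS_COLS if c not in fits.columns]
    if missing:
        raise SchemaError(f"fitness table is missing column(s): {missing}")
    return fits


def fitness_lookup(fits: pd.DataFrame) -> dict:
    """Map (abr, ko, antibiotic, temperature) -> (w_mean, w_se, n)."""
    _check_fitness_frame(fits)
    return {
        (r.abr_allele, r.ko_allele, r.antibiotic, r.temperature): (r.w_mean, r.w_se, int(r.n))
        for r in fits.itertuples()
    }


def environments_of(fits: pd.DataFrame) -> list[Environment]:
    """Sorted list of environments present in a fitness table."""
    envs = fits[["antibiotic", "temperature"]].drop_duplicates().sort_values(
        ["antibiotic", "temperature"]
    )
    return [Environment(float(a), float(t)) for a, t in envs.itertuples(index=False)]


def allele_sets(fits: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(ABR alleles, KO alleles) present in a fitness table, wild type first."""

    def ordered(values, wt):
        vals = list(dict.fromkeys(values))
        if wt in vals:
            vals.remove(wt)
            return [wt] + sorted(vals)
        return sorted(vals)

    return (
        ordered(fits["abr_allele"], WT_ABR),
        ordered(fits["ko_allele"], WT_KO),
    )


def extract_landscape_slice(
    fits: pd.DataFrame, abr: str, ko: str, env: Environment
) -> LandscapeSlice:
    """Pull the {WT, abr, ko, double} diamond for one environment from a fitness table."""
    lut = fitness_lookup(fits)

    def cell(a, k) -> FitnessEstimate:
        key = (a, k, env.antibiotic, env.temperature)
        if key not in lut:
            raise MissingGenotypeError(
                f"missing fitness cell for genotype ({a}, {k}) in environment "
                f"{env.antibiotic} ug/ml, {env.temperature} C"
            )
        w, se, n = lut[key]
        return FitnessEstimate(Genotype(a, k), env, float(w), float(se), n)

    return LandscapeSlice(
        environment=env,
        abr_mutation=abr,
        ko_mutation=ko,
        w_wt=cell(WT_ABR, WT_KO),
        w_abr=cell(abr, WT_KO),
        w_ko=cell(WT_ABR, ko),
        w_double=cell(abr, ko),
    )


def check_complete_grid(fits: pd.DataFrame) -> None:
    """Raise :class:`IncompleteGridError` if any genotype x environment cell is absent."""
    abr, ko = allele_sets(fits)
    envs = environments_of(fits)
    have = set(fitness_lookup(fits))
    missing = [
        (a, k, e.antibiotic, e.temperature)
        for a in abr
        for k in ko
        for e in envs
        if (a, k, e.antibiotic, e.temperature) not in have
    ]
    if missing:
        raise IncompleteGridError(missing)


def all_slices(fits: pd.DataFrame) -> list[LandscapeSlice]:
    """All two-locus landscape slices: (ABR != WT) x (KO != none) x environment.

    Requires a complete grid; on the study preset this yields 3 x 5 x 12 = 180
    slices (15 landscapes per environment).
    """
    check_complete_grid(fits)
    abr_all, ko_all = allele_sets(fits)
    lut = fitness_lookup(fits)
    out = []
    for env in environments_of(fits):
        ab, t = env.antibiotic, env.temperature

        def cell(a, k, env=env, ab=ab, t=t):
            w, se, n = lut[(a, k, ab, t)]
            return FitnessEstimate(Genotype(a, k), env, float(w), float(se), n)

        for a in abr_all:
            if a == WT_ABR:
                continue
            for k in ko_all:
                if k == WT_KO:
                    continue
                out.append(
                    LandscapeSlice(
                        environment=env,
                        abr_mutation=a,
                        ko_mutation=k,
                        w_wt=cell(WT_ABR, WT_KO),
                        w_abr=cell(a, WT_KO),
                        w_ko=cell(WT_ABR, k),
                        w_double=cell(a, k),
                    )
                )
    return out
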