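"""Generative model of the competition-assay study design.

True fitness surfaces are built from additive per-allele effects, pairwise
interaction terms, and the reference strain's own additive terms:

    w_true(g, e) = a_abr(g, e) + a_ko(g, e) + i(abr, ko, e) - a(reference, e)

so the reference genotype's own competitive index is exactly 0, all values are
log-ratios relative to the reference, and the true pairwise epistasis of every
slice equals its interaction term.  Competition counts are then emitted with
multiplicative lognormal measurement noise per channel (normal on the log
scale, which makes the log-ratio estimator's errors additive and the
Normal-SE bootstrap well specified).  Named scenarios reproduce the study's
qualitative regimes: additive landscapes, pure G x E, masking, reciprocal sign
epistasis confined to antibiotic-free environments, diminishing returns, and a
paper-like composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ABR_ALLELES,
    ANTIBIOTIC_CONCS,
    KO_ALLELES,
    ORIENT_GFP,
    ORIENT_MCHERRY,
    RECORD_COLS,
    TEMPERATURES,
    WT_ABR,
    WT_KO,
    EpilandError,
)


class ParameterError(EpilandError):
    """A generative parameter cell is missing or invalid."""


@dataclass(frozen=True)
class TruthParams:
    """Generative parameters for one synthetic dataset.

    ``additive_abr`` / ``additive_ko`` map (allele, antibiotic, temperature) to
    the allele's additive effect relative to the locus wild type; wild-type
    alleles implicitly have effect 0 and must not appear.  ``interaction`` maps
    (abr, ko, antibiotic, temperature) to the pairwise term (sparse; missing
    cells are 0).  ``ref_growth`` maps (antibiotic, temperature) to the
    reference strain's 20 h growth factor.  ``noise_sd`` is the SD of the
    lognormal measurement noise on each density channel; ``replicates`` is an
    inclusive (min, max) range drawn per cell; ``dye_bias`` adds a systematic
    shift to the GFP-orientation index (0 = neutral marker).
    """

    abr_alleles: tuple[str, ...] = ABR_ALLELES
    ko_alleles: tuple[str, ...] = KO_ALLELES
    antibiotics: tuple[float, ...] = ANTIBIOTIC_CONCS
    temperatures: tuple[float, ...] = TEMPERATURES
    additive_abr: dict = field(default_factory=dict)
    additive_ko: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    reference: tuple[str, str] = ("H526Y", "none")
    ref_growth: dict = field(default_factory=dict)
    noise_sd: float = 0.05
    inoculum: float = 1e5
    replicates: tuple[int, int] = (3, 4)
    both_orientations: bool = False
    dye_bias: float = 0.0
    seed: int = 0

    def environments(self):
        return [(ab, t) for ab in self.antibiotics for t in self.temperatures]

    def genotypes(self):
        return [(a, k) for a in self.abr_alleles for k in self.ko_alleles]

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.inoculum <= 0:
            raise ParameterError("inoculum must be > 0")
        lo, hi = self.replicates
        if not (1 <= lo <= hi):
            raise ParameterError(f"invalid replicate range {self.replicates}")
        for ab, t in self.environments():
            g = self.ref_growth.get((ab, t), np.e**3)
            if g <= 0:
                raise ParameterError(f"ref_growth must be > 0 in environment {(ab, t)}")
            for allele, table, wt in (
                *(((a, self.additive_abr, WT_ABR)) for a in self.abr_alleles),
                *(((k, self.additive_ko, WT_KO)) for k in self.ko_alleles),
            ):
                if allele != wt and (allele, ab, t) not in table:
                    raise ParameterError(
                        f"missing additive effect for allele {allele!r} in "
                        f"environment {(ab, t)}"
                    )

    def _additive(self, allele: str, table: dict, wt: str, ab: float, t: float) -> float:
        if allele == wt:
            return 0.0
        try:
            return table[(allele, ab, t)]
        except KeyError as exc:
            raise ParameterError(
                f"missing additive effect for allele {allele!r} in environment {(ab, t)}"
            ) from exc

    def raw_fitness(self, abr: str, ko: str, ab: float, t: float) -> float:
        """Additive + interaction terms of a genotype (before the reference shift)."""
        a = self._additive(abr, self.additive_abr, WT_ABR, ab, t)
        k = self._additive(ko, self.additive_ko, WT_KO, ab, t)
        i = 0.0
        if abr != WT_ABR and ko != WT_KO:
            i = self.interaction.get((abr, ko, ab, t), 0.0)
        return a + k + i

    def w_true(self, abr: str, ko: str, ab: float, t: float) -> float:
        ref_abr, ref_ko = self.reference
        return self.raw_fitness(abr, ko, ab, t) - self.raw_fitness(ref_abr, ref_ko, ab, t)

    def growth(self, ab: float, t: float) -> float:
        return self.ref_growth.get((ab, t), float(np.e**3))


@dataclass(frozen=True)
class SimOutput:
    """Simulated records plus the generating truth tables."""

    records: pd.DataFrame
    truth: pd.DataFrame  # per genotype x environment: w_true
    truth_epsilon: pd.DataFrame  # per slice x environment: epsilon_true


def true_fitness(params: TruthParams) -> pd.DataFrame:
    """True competitive index w_true(g, e) for every genotype x environment."""
    params.validate()
    rows = [
        {
            "abr_allele": a,
            "ko_allele": k,
            "antibiotic": ab,
            "temperature": t,
            "w_true": params.w_true(a, k, ab, t),
        }
        for ab, t in params.environments()
        for a, k in params.genotypes()
    ]
    return pd.DataFrame(rows)


def true_epistasis(params: TruthParams) -> pd.DataFrame:
    """True pairwise epistasis per slice (equals the interaction term)."""
    rows = []
    for ab, t in params.environments():
        for a in params.abr_alleles:
            if a == WT_ABR:
                continue
            for k in params.ko_alleles:
                if k == WT_KO:
                    continue
                rows.append(
                    {
                        "abr_mutation": a,
                        "ko_mutation": k,
                        "antibiotic": ab,
                        "temperature": t,
                        "epsilon_true": params.interaction.get((a, k, ab, t), 0.0),
                    }
                )
    return pd.DataFrame(rows)


def simulate_competitions(params: TruthParams) -> SimOutput:
    """Emit competition records under the generative measurement model.

    Per replicate: initial densities are the inoculum with lognormal noise per
    channel; the reference's final density grows by the environment's growth
    factor; the competitor's final density additionally carries exp(w_true).
    With ``both_orientations`` each replicate is recorded in both dye
    orientations; otherwise orientations alternate across replicates within a
    cell so the dye-swap check still finds pairs.  Noise-free simulation is
    exactly inverted by the competitive-index estimator.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = true_fitness(params)
    sd = params.noise_sd
    rep_lo, rep_hi = params.replicates
    rows = []
    for row in truth.itertuples():
        ab, t = row.antibiotic, row.temperature
        growth = params.growth(ab, t)
        n_rep = int(rng.integers(rep_lo, rep_hi + 1))
        for rep in range(1, n_rep + 1):
            if params.both_orientations:
                orients = (ORIENT_GFP, ORIENT_MCHERRY)
            else:
                orients = (ORIENT_GFP if rep % 2 == 1 else ORIENT_MCHERRY,)
            for orient in orients:
                w_eff = row.w_true + (params.dye_bias if orient == ORIENT_GFP else 0.0)
                noise = rng.normal(0.0, sd, size=4) if sd > 0 else np.zeros(4)
                d_comp_i = params.inoculum * np.exp(noise[0])
                d_ref_i = params.inoculum * np.exp(noise[1])
                d_comp_f = d_comp_i * growth * np.exp(w_eff + noise[2])
                d_ref_f = d_ref_i * growth * np.exp(noise[3])
                rows.append(
                    (
                        row.abr_allele,
                        row.ko_allele,
                        ab,
                        t,
                        rep,
                        orient,
                        d_comp_i,
                        d_ref_i,
                        d_comp_f,
                        d_ref_f,
                    )
                )
    records = pd.DataFrame(rows, columns=RECORD_COLS)
    return SimOutput(records=records, truth=truth, truth_epsilon=true_epistasis(params))


# --- scenarios -------------------------------------------------------------

# Dose-response coefficients per ABR allele: effect = base + conc * AB + temp * (T - 37).
# S512F and H526Y are strong resistance alleles, I572S a weak one.  Baselines keep
# every allele's antibiotic-free effect at >= 3 effect-SEs under the default noise
# (effect SE = noise_sd * 2 / sqrt(n) ~ 0.058 at n = 3), so scenarios meant to be
# additive are simulated with clearly detectable single-mutant effects.
_ABR_CONC = {"S512F": 0.40, "H526Y": 0.35, "I572S": 0.12}
_ABR_TEMP = {"S512F": 0.02, "H526Y": 0.03, "I572S": 0.015}
_ABR_BASE_DETECTABLE = {"S512F": 0.20, "H526Y": 0.25, "I572S": 0.18}
_KO_BASE_DETECTABLE = {"marR": -0.20, "nuoC": -0.18, "waaP": -0.30, "yidK": -0.25, "ybfG": 0.18}

# paper-like baselines: near-neutral ABR effects without antibiotic (no cost of
# resistance) and knock-out effects in [-1, 0.2] that ABR effects overshadow.
_ABR_BASE_PAPERLIKE = {"S512F": -0.05, "H526Y": 0.0, "I572S": 0.08}
_KO_BASE_PAPERLIKE = {"marR": 0.10, "nuoC": -0.10, "waaP": -0.30, "yidK": 0.12, "ybfG": 0.05}
_WAAP_DOSE = {0.0: -0.30, 4.0: -1.0, 8.0: -0.50, 10.0: -0.40}

SCENARIOS = (
    "additive",
    "gxe_only",
    "masking",
    "reciprocal_sign_at_zero_ab",
    "diminishing_returns",
    "paper_like",
)


def _ref_growth(params: TruthParams) -> dict:
    # log growth declines with antibiotic and rises mildly with temperature, so
    # environmental quality orders environments the way the assay design expects
    return {
        (ab, t): float(np.exp(3.0 - 0.08 * ab + 0.02 * (t - 37.0)))
        for ab, t in params.environments()
    }


def _base_tables(abr_base: dict, ko_base: dict, envs, conc=_ABR_CONC, temp=_ABR_TEMP):
    a_abr = {
        (m, ab, t): abr_base[m] + conc[m] * ab + temp[m] * (t - 37.0)
        for m in abr_base
        for ab, t in envs
    }
    a_ko = {(k, ab, t): ko_base[k] for k in ko_base for ab, t in envs}
    return a_abr, a_ko


def scenario(name: str, seed: int = 0, **overrides) -> TruthParams:
    """Fully populated :class:`TruthParams` for a named study regime.

    additive                   no interactions anywhere.
    gxe_only                   susceptible genotypes strongly deleterious under
                               antibiotic, widely spread knock-out effects, no
                               interactions.
    masking                    every knock-out's effect is cancelled on ABR
                               backgrounds (ABR mutations dominate).
    reciprocal_sign_at_zero_ab reciprocal sign epistasis on the five I572S
                               slices, only in antibiotic-free environments.
    diminishing_returns        ABR effects shrink linearly (slope -0.4) with
                               background fitness.
    paper_like                 composite: strong ABR dose response, waaP
                               hypersusceptibility at 4 ug/ml masked by ABR
                               mutations, reciprocal sign epistasis at 0 ug/ml,
                               interactions decaying with antibiotic.
    """
    base = TruthParams(seed=seed)
    envs = base.environments()
    if name == "additive":
        a_abr, a_ko = _base_tables(_ABR_BASE_DETECTABLE, _KO_BASE_DETECTABLE, envs)
        inter: dict = {}
    elif name == "gxe_only":
        a_abr, a_ko = _base_tables(_ABR_BASE_DETECTABLE, _KO_BASE_DETECTABLE, envs)
        a_ko = {
            (k, ab, t): {"marR": -0.40, "nuoC": -0.20, "waaP": -0.60, "yidK": -0.30, "ybfG": 0.20}[k]
            for k in _KO_BASE_DETECTABLE
            for ab, t in envs
        }
        inter = {}
    elif name == "masking":
        a_abr, a_ko = _base_tables(_ABR_BASE_DETECTABLE, _KO_BASE_DETECTABLE, envs)
        inter = {
            (m, k, ab, t): -a_ko[(k, ab, t)]
            for m in _ABR_CONC
            for k in _KO_BASE_DETECTABLE
            for ab, t in envs
        }
    elif name == "reciprocal_sign_at_zero_ab":
        a_abr, a_ko = _base_tables(_ABR_BASE_DETECTABLE, _KO_BASE_DETECTABLE, envs)
        for ab, t in envs:
            if ab == 0.0:
                a_abr[("I572S", ab, t)] = 0.25
                for k in _KO_BASE_DETECTABLE:
                    a_ko[(k, ab, t)] = 0.25
        inter = {
            ("I572S", k, ab, t): -1.0
            for k in _KO_BASE_DETECTABLE
            for ab, t in envs
            if ab == 0.0
        }
    elif name == "diminishing_returns":
        # equal ABR baselines so the pooled effect-on-background regression has
        # a single intercept and recovers the injected slope without bias
        a_abr = {(m, ab, t): 0.5 for m in _ABR_CONC for ab, t in envs}
        spread = {"marR": -0.80, "nuoC": -0.40, "waaP": 0.30, "yidK": -0.60, "ybfG": 0.15}
        a_ko = {(k, ab, t): spread[k] for k in spread for ab, t in envs}
        inter = {
            (m, k, ab, t): -0.4 * spread[k]
            for m in _ABR_CONC
            for k in spread
            for ab, t in envs
        }
    elif name == "paper_like":
        a_abr, a_ko = _base_tables(_ABR_BASE_PAPERLIKE, _KO_BASE_PAPERLIKE, envs)
        for ab, t in envs:
            a_ko[("waaP", ab, t)] = _WAAP_DOSE[ab]
        inter = {}
        for ab, t in envs:
            decay = float(np.exp(-0.5 * ab))
            # cryptic reciprocal-sign interactions with the weak ABR allele,
            # fading with antibiotic
            for k in ("marR", "yidK"):
                inter[("I572S", k, ab, t)] = -0.5 * decay
            # ABR mutations mask waaP's extra dose-dependent susceptibility
            if ab > 0:
                rescue = _WAAP_DOSE[0.0] - _WAAP_DOSE[ab]
                for m in _ABR_CONC:
                    inter[(m, "waaP", ab, t)] = rescue
    else:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}"
        )
    params = replace(
        base,
        additive_abr=a_abr,
        additive_ko=a_ko,
        interaction=inter,
        replicates=(4, 4) if name == "paper_like" else (3, 4),
        seed=seed,
    )
    params = replace(params, ref_growth=_ref_growth(params), **overrides)
    params.validate()
    return params
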