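"""Pairwise epsilon, gamma, sign classification, roughness-to-slope, diminishing returns."""

import math

import numpy as np
import pytest
from conftest import fitness_frame
from hypothesis import given
from hypothesis import strategies as st

import epiland as ep
from epiland.core import InsufficientDataError
from epiland.metrics import _rs_from_draws, summary_frame

finite = st.floats(min_value=-5, max_value=5, allow_nan=False)


def slice_of(w_wt, w_abr, w_ko, w_double, **kw):
    return ep.slice_from_means(w_wt, w_abr, w_ko, w_double, **kw)


class TestPairwiseEpistasis:
    @pytest.mark.parametrize(
        "w, expected",
        [
            ((0.0, 0.2, -0.1, 0.1), 0.0),  # additive
            ((0.0, 2.0, -1.0, 2.0), 1.0),  # ABR masks the deleterious KO
        ],
    )
    def test_closed_form(self, w, expected):
        assert ep.pairwise_epistasis(slice_of(*w)) == pytest.approx(expected)

    @given(w=st.tuples(finite, finite, finite, finite), c=finite)
    def test_translation_invariance(self, w, c):
        base = ep.pairwise_epistasis(slice_of(*w))
        shifted = ep.pairwise_epistasis(slice_of(*(v + c for v in w)))
        assert shifted == pytest.approx(base, abs=1e-9)

    @given(w=st.tuples(finite, finite, finite, finite),
           k=st.floats(min_value=0.1, max_value=10))
    def test_scales_linearly(self, w, k):
        base = ep.pairwise_epistasis(slice_of(*w))
        scaled = ep.pairwise_epistasis(slice_of(*(v * k for v in w)))
        assert scaled == pytest.approx(k * base, rel=1e-9, abs=1e-9)


class TestMutationEffects:
    def test_38_effects_per_environment_on_preset(self, paper_like_fits, env0):
        eff = ep.mutation_effects(paper_like_fits, env0)
        assert len(eff) == 38
        assert (eff[eff["locus_class"] == "ABR"].groupby("mutation").size() == 6).all()
        assert (eff[eff["locus_class"] == "KO"].groupby("mutation").size() == 4).all()

    def test_minimal_grid_four_effects(self):
        fits = fitness_frame({("WT", "none"): 0.0, ("A", "none"): 1.0,
                              ("WT", "B"): 0.5, ("A", "B"): 1.5})
        eff = ep.mutation_effects(fits)
        assert len(eff) == 4

    def test_wild_type_alleles_never_emitted(self, paper_like_fits, env0):
        eff = ep.mutation_effects(paper_like_fits, env0)
        assert "WT" not in set(eff["mutation"])
        assert "none" not in set(eff["mutation"])


class TestGamma:
    def test_additive_landscape_gives_one(self):
        # mutation effects {1, 2, -0.5}, no interactions: pairs lie on the identity line
        fits = fitness_frame({
            ("WT", "none"): 0.0, ("A1", "none"): 1.0, ("A2", "none"): 2.0,
            ("WT", "B"): -0.5, ("A1", "B"): 0.5, ("A2", "B"): 1.5,
        })
        assert ep.gamma_statistic(ep.mutation_effects(fits)) == pytest.approx(1.0)

    def test_worked_two_abr_one_ko_example(self):
        # frozen from a brute-force pair enumeration + textbook Pearson oracle
        fits = fitness_frame({
            ("WT", "none"): 0.0, ("A1", "none"): 1.0, ("A2", "none"): 2.0,
            ("WT", "B"): 1.0, ("A1", "B"): 1.5, ("A2", "B"): 3.5,
        })
        gamma = ep.gamma_statistic(ep.mutation_effects(fits))
        assert gamma == pytest.approx(0.8703882797784892, rel=1e-12)

    def test_anticorrelated_effects_give_negative_gamma(self):
        # each mutation's effect across backgrounds reverses magnitude ordering
        fits = fitness_frame({
            ("WT", "none"): 0.0, ("A1", "none"): 1.0, ("A2", "none"): 2.0,
            ("WT", "B"): 1.0, ("A1", "B"): 3.0, ("A2", "B"): 2.0,
        })
        # ABR pairs: (1, 2), (2, 1); KO pairs: (1, 2), (1, 0) -> Pearson < 0
        gamma = ep.gamma_statistic(ep.mutation_effects(fits))
        x = np.array([1.0, 2.0, 1.0, 1.0])
        y = np.array([2.0, 1.0, 2.0, 0.0])
        expected = np.corrcoef(x, y)[0, 1]
        assert gamma == pytest.approx(expected, rel=1e-12)

    def test_focal_class_restriction(self, paper_like_fits, env0):
        eff = ep.mutation_effects(paper_like_fits, env0)
        g_all = ep.gamma_statistic(eff, "all")
        g_abr = ep.gamma_statistic(eff, "ABR")
        g_ko = ep.gamma_statistic(eff, "KO")
        assert all(-1 - 1e-12 <= g <= 1 + 1e-12 for g in (g_all, g_abr, g_ko))

    def test_too_few_pairs_rejected(self):
        fits = fitness_frame({("WT", "none"): 0.0, ("A", "none"): 1.0,
                              ("WT", "B"): 0.5, ("A", "B"): 1.5})
        with pytest.raises(InsufficientDataError):
            ep.gamma_statistic(ep.mutation_effects(fits), "ABR")

    @given(c=finite, k=st.floats(min_value=0.1, max_value=10))
    def test_invariant_to_shift_and_positive_scaling(self, c, k):
        fits = fitness_frame({
            ("WT", "none"): 0.0, ("A1", "none"): 1.0, ("A2", "none"): 2.0,
            ("WT", "B"): 1.0, ("A1", "B"): 1.5, ("A2", "B"): 3.5,
        })
        base = ep.gamma_statistic(ep.mutation_effects(fits))
        fits2 = fits.assign(w_mean=fits["w_mean"] * k + c)
        assert ep.gamma_statistic(ep.mutation_effects(fits2)) == pytest.approx(
            base, abs=1e-9
        )


class TestSignClassification:
    @pytest.mark.parametrize(
        "w, expected",
        [
            ((0.0, 0.5, 0.1, -0.1), "reciprocal"),  # both loci reverse sign
            ((0.0, 0.3, -0.5, -0.9), "simple"),  # only the ABR locus reverses
            ((0.0, 0.2, -0.1, 0.1), "none"),  # additive
            ((0.0, 0.2, 0.2, 0.4), "none"),
        ],
    )
    def test_classification(self, w, expected):
        assert ep.classify_sign_epistasis(slice_of(*w)) == expected

    @given(w=st.tuples(finite, finite, finite, finite))
    def test_reciprocal_implies_nonzero_epistasis(self, w):
        sl = slice_of(*w)
        if ep.classify_sign_epistasis(sl) == "reciprocal":
            assert ep.pairwise_epistasis(sl) != 0.0

    def test_zero_effect_carries_no_sign(self):
        # A's effect is exactly zero on the KO background; B keeps its sign
        assert ep.classify_sign_epistasis(slice_of(0.0, 0.5, -0.1, -0.1)) == "none"


class TestSignFractions:
    def test_zero_se_additive_grid_gives_zero_fractions(self, env0):
        cells = {("WT", "none"): 0.0}
        for i, a in enumerate(["A1", "A2", "A3"]):
            cells[(a, "none")] = 0.2 * (i + 1)
        for j, k in enumerate(["B1", "B2", "B3", "B4", "B5"]):
            cells[("WT", k)] = -0.1 * (j + 1)
        for a in ["A1", "A2", "A3"]:
            for k in ["B1", "B2", "B3", "B4", "B5"]:
                cells[(a, k)] = cells[(a, "none")] + cells[("WT", k)]
        fits = fitness_frame(cells)
        res = ep.sign_epistasis_fractions(fits, env0, ep.BootstrapConfig(50, seed=1))
        assert res.frac_simple == 0.0 and res.frac_reciprocal == 0.0
        assert res.ci_reciprocal == (0.0, 0.0)

    def test_one_reciprocal_slice_among_15_zero_se(self, env0):
        cells = {("WT", "none"): 0.0}
        for i, a in enumerate(["A1", "A2", "A3"]):
            cells[(a, "none")] = 0.2 * (i + 1)
        for j, k in enumerate(["B1", "B2", "B3", "B4", "B5"]):
            cells[("WT", k)] = 0.1 * (j + 1)
        for a in ["A1", "A2", "A3"]:
            for k in ["B1", "B2", "B3", "B4", "B5"]:
                cells[(a, k)] = cells[(a, "none")] + cells[("WT", k)]
        cells[("A1", "B1")] = -0.5  # force both loci to reverse sign
        fits = fitness_frame(cells)
        res = ep.sign_epistasis_fractions(fits, env0, ep.BootstrapConfig(50, seed=1))
        assert res.frac_reciprocal == pytest.approx(1 / 15)
        assert res.point_reciprocal == pytest.approx(1 / 15)
        flagged = res.per_slice[res.per_slice["detected_reciprocal"]]
        assert list(flagged[["abr_mutation", "ko_mutation"]].itertuples(index=False)) \
            == [("A1", "B1")]

    def test_injected_reciprocal_slice_detected_with_noise(self):
        # one reciprocal slice with effects >= 5x SE: detected in >= 90% of repeats,
        # while additive slices stay below the 5% detection rate
        hits, false_pos = 0, 0
        for seed in range(20):
            params = ep.scenario("reciprocal_sign_at_zero_ab", seed=seed)
            sim = ep.simulate_competitions(params)
            fits = ep.summarize_fitness(sim.records)
            res = ep.sign_epistasis_fractions(
                fits, ep.Environment(0.0, 37.0), ep.BootstrapConfig(500, seed=seed)
            )
            per = res.per_slice.set_index(["abr_mutation", "ko_mutation"])
            injected = per.loc[("I572S", "marR")]
            hits += bool(injected["detected_reciprocal"])
            others = per.drop(index=[("I572S", k) for k in
                                     ["marR", "nuoC", "waaP", "yidK", "ybfG"]])
            false_pos += int((others["reciprocal_rate"] > 0.05).any())
        assert hits >= 18
        assert 20 - false_pos >= 18

    def test_fraction_bounds_in_every_sample(self, paper_like_fits, env0):
        res = ep.sign_epistasis_fractions(
            paper_like_fits, env0, ep.BootstrapConfig(200, seed=2)
        )
        per = res.per_slice
        assert ((per["simple_rate"] + per["reciprocal_rate"]) <= 1 + 1e-12).all()
        assert 0 <= res.frac_reciprocal <= 1 - res.frac_simple + 1e-12


class TestRoughnessToSlope:
    def test_additive_slice_is_zero(self):
        assert ep.roughness_to_slope(slice_of(0.0, 0.3, 0.5, 0.8)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_worked_example(self):
        # normal-equations oracle: slopes 0.75/0.75, residuals +-0.125 -> 1/6
        assert ep.roughness_to_slope(slice_of(0.0, 1.0, 1.0, 1.5)) == pytest.approx(
            1 / 6
        )

    @given(w=st.tuples(finite, finite, finite, finite),
           k=st.floats(min_value=0.1, max_value=10))
    def test_invariant_under_positive_scaling(self, w, k):
        base = ep.roughness_to_slope(slice_of(*w))
        scaled = ep.roughness_to_slope(slice_of(*(v * k for v in w)))
        if math.isfinite(base):
            assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)

    def test_flat_landscape_defined_as_zero(self):
        assert ep.roughness_to_slope(slice_of(0.0, 0.0, 0.0, 0.0)) == 0.0

    def test_zero_slope_nonzero_roughness_is_infinite(self):
        # fitted slopes are exactly zero but the double mutant is epistatic
        assert math.isinf(ep.roughness_to_slope(slice_of(0.0, 0.5, 0.5, 0.0)))

    def test_vectorised_closed_form_matches_ols(self, rng):
        w = rng.normal(size=(1000, 4))
        vec = _rs_from_draws(w[:, 0], w[:, 1], w[:, 2], w[:, 3])
        for i in range(0, 1000, 97):
            assert vec[i] == pytest.approx(
                ep.roughness_to_slope(slice_of(*w[i])), abs=1e-10
            )


class TestDiminishingReturns:
    def test_constant_effects_give_zero_slope(self, env0):
        fits = fitness_frame({
            ("WT", "none"): 0.0, ("A", "none"): 0.5,
            ("WT", "B1"): 0.3, ("A", "B1"): 0.8,
            ("WT", "B2"): -0.2, ("A", "B2"): 0.3,
        })
        res = ep.diminishing_returns(fits, env0, "ABR", ep.BootstrapConfig(100, seed=0))
        assert res.slope_point == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_exact_line_zero_se(self, env0):
        # backgrounds (0, 0.5, 1.0) with effects (0.6, 0.3, 0.0) -> slope -0.6
        fits = fitness_frame({
            ("WT", "none"): 0.0, ("A", "none"): 0.6,
            ("WT", "B1"): 0.5, ("A", "B1"): 0.8,
            ("WT", "B2"): 1.0, ("A", "B2"): 1.0,
        })
        res = ep.diminishing_returns(fits, env0, "ABR", ep.BootstrapConfig(200, seed=0))
        assert res.slope_mean == pytest.approx(-0.6)
        assert res.ci == (pytest.approx(-0.6), pytest.approx(-0.6))
        assert res.significant

    def test_too_few_points_rejected(self, env0):
        fits = fitness_frame({("WT", "none"): 0.0, ("A", "none"): 0.5,
                              ("WT", "B"): 0.3, ("A", "B"): 0.8})
        with pytest.raises(InsufficientDataError):
            ep.diminishing_returns(fits, env0, "ABR", ep.BootstrapConfig(10, seed=0),
                                   exclude_backgrounds={"B"})

    def test_excluding_backgrounds_drops_points(self, paper_like_fits, env0):
        cfg = ep.BootstrapConfig(50, seed=0)
        full = ep.diminishing_returns(paper_like_fits, env0, "ABR", cfg)
        red = ep.diminishing_returns(paper_like_fits, env0, "ABR", cfg,
                                     exclude_backgrounds={"waaP"})
        assert full.n_points == 18 and red.n_points == 15


class TestEpistasisSummary:
    def test_summary_frame_columns_and_ci_order(self, paper_like_fits):
        cfg = ep.BootstrapConfig(100, seed=4)
        summaries = ep.summarize_epistasis(
            paper_like_fits, cfg, envs=[ep.Environment(0.0, 37.0),
                                        ep.Environment(10.0, 42.0)]
        )
        frame = summary_frame(summaries)
        assert len(frame) == 2
        for key in ("gamma_all", "frac_reciprocal", "frac_simple"):
            assert (frame[f"{key}_lo"] <= frame[f"{key}_hi"]).all()
        # bootstrap mean fraction lies inside its own percentile CI
        assert (frame["frac_reciprocal_lo"] - 1e-9 <= frame["frac_reciprocal"]).all()
        assert (frame["frac_reciprocal"] <= frame["frac_reciprocal_hi"] + 1e-9).all()
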