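"""Affinity-competition fractions, the doubling-time law and the growth law."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from proteome_allocation import (
    AffinityModel,
    PredictionParams,
    doubling_time,
    growth_rate_from_doubling,
    predicted_fraction,
    proteome_fractions,
    synthesis_rate_multiplier,
)
from proteome_allocation.core_model import LN2, growth_rate, lumped_constant
from proteome_allocation.errors import DegenerateConditionError, ModelInvalidError
from conftest import random_model


class TestProteomeFractions:
    def test_direct_normalization(self, tiny_model):
        frac = proteome_fractions(tiny_model, "c1")
        assert np.allclose(frac.values, [1 / 6, 1 / 3, 1 / 2])
        assert list(frac.index) == ["G0", "G1", "G2"]

    def test_equal_affinities_occupy_equal_fractions(self):
        aff = pd.DataFrame({"c": [2.0, 2.0, 4.0]}, index=["A", "B", "C"])
        frac = proteome_fractions(AffinityModel(aff, ["A"]), "c")
        assert frac["A"] == frac["B"]
        assert frac["C"] == 2 * frac["A"]

    def test_scale_invariance(self, tiny_model):
        scaled = AffinityModel(tiny_model.affinities * 10, ["G0"], t_b=0.5)
        for cond in ("c1", "c2"):
            assert np.allclose(
                proteome_fractions(tiny_model, cond), proteome_fractions(scaled, cond)
            )

    def test_degenerate_and_unknown_condition(self):
        aff2 = pd.DataFrame({"c1": [0.0, 1.0], "c2": [0.0, 0.0]}, index=["A", "B"])
        with pytest.raises(ModelInvalidError):
            AffinityModel(aff2, ["A"])  # W_B = 0
        aff = pd.DataFrame({"c1": [1.0, 1.0], "c2": [1.0, 2.0]}, index=["A", "B"])
        model = AffinityModel(aff, ["A"])
        with pytest.raises(KeyError):
            proteome_fractions(model, "nope")
        # an all-zero column can only arise through external mutation; the guard still fires
        model.affinities["c2"] = 0.0
        with pytest.raises(DegenerateConditionError):
            proteome_fractions(model, "c2")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        for cond in model.condition_ids:
            assert abs(proteome_fractions(model, cond).sum() - 1.0) < 1e-12


class TestGrowthLaw:
    def test_all_biosynthetic_gives_minimal_doubling(self):
        aff = pd.DataFrame({"c": [1.0, 2.0]}, index=["A", "B"])
        model = AffinityModel(aff, ["A", "B"], t_b=0.7)
        assert doubling_time(model, "c") == pytest.approx(0.7)

    @pytest.mark.parametrize("share,factor", [(0.5, 2.0), (0.25, 4.0)])
    def test_doubling_time_inverse_in_biosynthetic_share(self, share, factor):
        # biosynthetic sector holds `share` of total affinity
        w_rest = 1.0 / share - 1.0
        aff = pd.DataFrame({"c": [1.0, w_rest]}, index=["B", "R"])
        model = AffinityModel(aff, ["B"], t_b=0.6)
        assert doubling_time(model, "c") == pytest.approx(factor * 0.6, rel=1e-12)

    def test_growth_rate_from_doubling(self):
        assert growth_rate_from_doubling(LN2) == pytest.approx(1.0)
        assert growth_rate_from_doubling(2 * LN2) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            growth_rate_from_doubling(0.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_growth_rate_equals_share_law(self, seed):
        """g = ln2 * (biosynthetic affinity share) / T_B for any model."""
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        for cond in model.condition_ids:
            share = model.w_b / model.total_affinity(cond)
            assert growth_rate(model, cond) == pytest.approx(LN2 * share / model.t_b, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_model_closure_constant_affinities(self, seed):
        """For condition-independent affinities, p_i = A * w_i * g with A = T_B/(ln2 W_B)."""
        rng = np.random.default_rng(seed)
        model = random_model(rng, constant=True)
        a = lumped_constant(model)
        for cond in model.condition_ids:
            g = growth_rate(model, cond)
            predicted = a * model.affinities[cond].values * g
            observed = proteome_fractions(model, cond).values
            assert np.allclose(predicted, observed, atol=1e-10, rtol=0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_ratio_preservation_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, constant=True)
        c1, c2 = model.condition_ids[0], model.condition_ids[-1]
        f1, f2 = proteome_fractions(model, c1), proteome_fractions(model, c2)
        # constant affinities preserve pairwise fraction ratios across conditions
        assert np.allclose(f1 / f1.iloc[0], f2 / f2.iloc[0])
        # adding affinity to a non-biosynthesis gene slows growth, dilutes others
        bumped_aff = model.affinities.copy()
        outsider = [g for g in model.gene_ids if g not in model.biosynthesis_ids][0]
        bumped_aff.loc[outsider] += 1.0
        bumped = AffinityModel(bumped_aff, model.biosynthesis_ids, model.t_b)
        assert doubling_time(bumped, c1) > doubling_time(model, c1)
        others = [g for g in model.gene_ids if g != outsider]
        assert (proteome_fractions(bumped, c1)[others] < f1[others]).all()


class TestPredictedFraction:
    def test_proportionality_without_degradation(self):
        params = PredictionParams(lumped_constant=0.01)
        assert predicted_fraction(2.0, params, 0.8) == pytest.approx(
            2 * predicted_fraction(2.0, params, 0.4)
        )

    def test_zero_growth_fraction_is_alpha_term(self):
        params = PredictionParams(lumped_constant=0.01, degradation_rate=0.4)
        assert predicted_fraction(3.0, params, 0.0) == pytest.approx(0.01 * 3.0 * 0.4)

    def test_line_crosses_zero_at_minus_alpha(self):
        """Extrapolated x-intercept of the degradation law sits at -alpha."""
        params = PredictionParams(lumped_constant=0.02, degradation_rate=0.3)
        g = np.linspace(0.1, 0.7, 7)
        y = np.array([predicted_fraction(1.0, params, gi) for gi in g])
        slope, intercept = np.polyfit(g, y, 1)
        assert -intercept / slope == pytest.approx(-0.3, rel=1e-9)

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            predicted_fraction(1.0, PredictionParams(lumped_constant=1.0), -0.1)

    def test_fraction_above_one_warns(self):
        with pytest.warns(UserWarning):
            predicted_fraction(10.0, PredictionParams(lumped_constant=1.0), 1.0)


class TestSynthesisRateMultiplier:
    def test_half_maximal_at_g_half(self):
        assert synthesis_rate_multiplier(0.2, 0.2) == pytest.approx(0.5)

    def test_disabled_when_g_half_zero(self):
        for g in (0.05, 0.3, 2.0):
            assert synthesis_rate_multiplier(g, 0.0) == 1.0

    def test_degenerate_zero_growth(self):
        with pytest.warns(UserWarning):
            assert synthesis_rate_multiplier(0.0, 0.2) == 0.0

    def test_saturation_lowers_slope_raises_intercept(self):
        """Over a fitted window the corrected law is flatter with a higher intercept."""
        g = np.linspace(0.12, 0.66, 20)
        base = PredictionParams(lumped_constant=0.01)
        corrected = PredictionParams(lumped_constant=0.01, saturation_g_half=0.2)
        y0 = np.array([predicted_fraction(1.0, base, gi) for gi in g])
        y1 = np.array([predicted_fraction(1.0, corrected, gi) for gi in g])
        # compare on a mean-normalized scale so the lumped constants cancel
        s0, i0 = np.polyfit(g, y0 / y0.mean(), 1)
        s1, i1 = np.polyfit(g, y1 / y1.mean(), 1)
        assert s1 < s0
        assert i1 > i0


class TestSerialization:
    def test_yaml_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "model.yaml"
        tiny_model.to_config(path)
        loaded = AffinityModel.from_config(path)
        assert loaded.biosynthesis_ids == tiny_model.biosynthesis_ids
        assert loaded.t_b == tiny_model.t_b
        assert np.allclose(loaded.affinities.values, tiny_model.affinities.values)

    def test_tsv_round_trip(self, tiny_model, tmp_path):
        path = tmp_path / "affinities.tsv"
        tiny_model.affinities.to_csv(path, sep="\t")
        loaded = AffinityModel.from_tsv(path, ["G0"], t_b=0.5)
        assert np.allclose(loaded.affinities.values, tiny_model.affinities.values)

    def test_invalid_models_rejected(self):
        aff = pd.DataFrame({"c1": [1.0, 2.0], "c2": [1.0, 3.0]}, index=["A", "B"])
        with pytest.raises(ModelInvalidError):
            AffinityModel(aff, ["B"])  # biosynthesis affinity varies
        with pytest.raises(ModelInvalidError):
            AffinityModel(aff, [])
        with pytest.raises(ModelInvalidError):
            AffinityModel(aff, ["A"], t_b=0.0)
        with pytest.raises(ModelInvalidError):
            AffinityModel(aff.assign(c1=[-1.0, 2.0]), ["A"])
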