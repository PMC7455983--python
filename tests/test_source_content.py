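"""Recipe/label source-fraction estimation and processing corrections."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capko.datamodel import LabelRecord, load_fixtures
from capko.rounding import round_half_up
from capko.source_content import (
    SurrogateError,
    blend_dilution,
    combine_recipe_fractions,
    composite_fraction,
    fermentation_correction,
    label_source_fraction,
    recipe_source_fraction,
    salting_weight_correction,
    surrogate_lookup,
)
from capko.synthetic_data import gen_recipe


@pytest.fixture(scope="module")
def recipes():
    return {r.name: r for r in load_fixtures("table3")}


class TestSalting:
    @pytest.mark.parametrize(
        "fresh,loss,expected", [(100, 0.10, 90.0), (7.0, 0.0, 7.0), (45, 0.10, 40.5)]
    )
    def test_values(self, fresh, loss, expected):
        assert salting_weight_correction(fresh, loss) == pytest.approx(expected)

    def test_total_loss_rejected(self):
        with pytest.raises(ValueError):
            salting_weight_correction(100, 1.0)


class TestRecipeFraction:
    @pytest.mark.parametrize(
        "name,expected",
        [("napa_1", 2.9), ("napa_2", 1.4), ("cubed_radish", 2.2),
         ("watery", 0.4), ("young_radish", 3.5)],
    )
    def test_standardized_recipes(self, recipes, name, expected):
        assert recipe_source_fraction(recipes[name]) == expected

    def test_watery_kimchi_total_from_addends(self, recipes):
        # ingredient weights sum to 177.6 (the recomputed total)
        total = sum(i.fresh_weight for i in recipes["watery"].ingredients)
        assert total == pytest.approx(177.6)

    def test_full_precision_flag(self, recipes):
        raw = recipe_source_fraction(recipes["napa_1"], rounded=False)
        assert raw == pytest.approx(100 * 3.5 / 122.7)
        assert round_half_up(raw, 1) == 2.9

    @settings(deadline=None, max_examples=50)
    @given(scale=st.floats(0.1, 50.0), frac=st.floats(0.1, 20.0))
    def test_scale_invariance(self, scale, frac):
        recipe = gen_recipe(seed=3, true_fraction=frac)
        scaled = recipe.model_copy(deep=True)
        for ing in scaled.ingredients:
            ing.fresh_weight *= scale
        a = recipe_source_fraction(recipe, rounded=False)
        b = recipe_source_fraction(scaled, rounded=False)
        assert a == pytest.approx(b, rel=1e-9)
        assert a == pytest.approx(frac, rel=1e-9)


class TestStagedRounding:
    def test_napa_pipeline(self, recipes, config):
        # 2.9 and 1.4 -> mean 2.2 -> 20% fermentation loss -> 1.76
        fracs = [recipe_source_fraction(recipes[n]) for n in ("napa_1", "napa_2")]
        assert fracs == [2.9, 1.4]
        combined = combine_recipe_fractions(fracs)
        assert combined == 2.2
        corrected = fermentation_correction(
            combined, config["fermentation_loss"]["kimchi"]
        )
        assert corrected == pytest.approx(1.76)

    def test_half_up_not_bankers(self):
        # mean of 2.9 and 1.4 is 2.15; half-up gives 2.2
        assert combine_recipe_fractions([2.9, 1.4]) == 2.2


class TestFermentation:
    @pytest.mark.parametrize(
        "fraction,loss,expected",
        [(2.2, 0.20, 1.76), (11.3, 0.10, 10.17), (5.0, 0.0, 5.0)],
    )
    def test_values(self, fraction, loss, expected):
        assert fermentation_correction(fraction, loss) == pytest.approx(expected)

    def test_loss_out_of_range(self):
        with pytest.raises(ValueError):
            fermentation_correction(2.0, 1.2)

    @given(frac=st.floats(0, 50), loss=st.floats(0, 0.9),
           share=st.floats(0.05, 1.0))
    def test_commutes_with_dilution(self, frac, loss, share):
        a = blend_dilution(fermentation_correction(frac, loss), share)
        b = fermentation_correction(blend_dilution(frac, share), loss)
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)


class TestSurrogates:
    def test_configured_donors(self, config):
        m = config["kimchi_surrogates"]
        assert surrogate_lookup("cucumber kimchi", m) == "cubed Korean radish kimchi"
        assert surrogate_lookup("green onion kimchi", m) == "young radish kimchi"

    def test_self_sufficient_food_errors(self, config):
        with pytest.raises(SurrogateError, match="no surrogate"):
            surrogate_lookup("napa cabbage kimchi", config["kimchi_surrogates"])


class TestLabels:
    def test_pollock_roe_mean_full_precision(self):
        labels = load_fixtures("table5")["salted pollock roe"]
        value, assumed = label_source_fraction(labels)
        assert not assumed
        assert value == pytest.approx(22.1 / 7)
        assert round_half_up(value, 1) == 3.2

    def test_default_when_no_labels(self):
        value, assumed = label_source_fraction([], default_pct=5.0)
        assert (value, assumed) == (5.0, True)

    def test_kimchi_dumpling_mean(self):
        value, _ = label_source_fraction(load_fixtures("table8"), "kimchi")
        assert round_half_up(value, 2) == 23.52

    def test_no_data_no_default_errors(self):
        with pytest.raises(ValueError, match="no label"):
            label_source_fraction([])

    def test_mean_within_declared_bounds(self):
        labels = [
            LabelRecord(product_id=str(i), fractions={"x": v})
            for i, v in enumerate([2.0, 3.0, 7.0])
        ]
        value, _ = label_source_fraction(labels, "x")
        assert 2.0 <= value <= 7.0


class TestBlendAndComposite:
    @pytest.mark.parametrize(
        "base,share,expected", [(11.3, 0.80, 9.04), (11.3, 0.25, 2.825), (4.0, 1.0, 4.0)]
    )
    def test_blend(self, base, share, expected):
        assert blend_dilution(base, share) == pytest.approx(expected)

    def test_blend_share_domain(self):
        with pytest.raises(ValueError):
            blend_dilution(10.0, 0.0)

    @pytest.mark.parametrize(
        "container,inner,expected",
        [(9.83, 1.76, 0.173008), (23.515, 1.76, 0.413864), (0.0, 5.0, 0.0)],
    )
    def test_composite(self, container, inner, expected):
        assert composite_fraction(container, inner) == pytest.approx(expected)

    @given(a=st.floats(0, 100), b=st.floats(0, 100))
    def test_composite_recovers_product(self, a, b):
        assert composite_fraction(a, b) == pytest.approx(a * b / 100.0)
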