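"""Tissue weighting, remainder rules and sex averaging."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dosecalc import (
    effective_dose_icrp60,
    effective_dose_icrp103,
    load_weighting_scheme,
    remainder_dose_icrp60,
)
from dosecalc.effective import WeightingScheme

_ALL_TISSUES = (
    "red marrow", "colon", "lungs", "stomach wall", "breast", "gonads",
    "urinary bladder wall", "oesophagus", "liver", "thyroid", "bone surface",
    "brain", "salivary glands", "skin", "adrenals", "extrathoracic region",
    "gall bladder wall", "heart wall", "kidneys", "lymphatic nodes", "muscle",
    "oral mucosa", "pancreas", "prostate", "uterus", "small intestine wall",
    "spleen", "thymus", "upper large intestine",
)


def uniform_table(value):
    return {tissue: value for tissue in _ALL_TISSUES}


class TestSchemes:
    @pytest.mark.parametrize("scheme_id", ["ICRP60", "ICRP103"])
    def test_weights_sum_to_exactly_one(self, scheme_id):
        scheme = load_weighting_scheme(scheme_id)
        total = sum((Fraction(str(w)) for w in scheme.weights.values()), Fraction(0))
        total += Fraction(str(scheme.remainder_weight))
        assert total == 1

    def test_2007_remainder_has_thirteen_tissues_per_sex(self):
        scheme = load_weighting_scheme("ICRP103")
        assert len(scheme.remainder_tissues("male")) == 13
        assert len(scheme.remainder_tissues("female")) == 13
        assert "prostate" in scheme.remainder_tissues("male")
        assert "uterus" in scheme.remainder_tissues("female")

    def test_remainder_disjoint_from_named(self):
        for scheme_id in ("ICRP60", "ICRP103"):
            scheme = load_weighting_scheme(scheme_id)
            named = set(scheme.weights)
            assert not named & set(scheme.remainder_male)
            assert not named & set(scheme.remainder_female)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="ICRP26"):
            load_weighting_scheme("ICRP26")


class TestRemainderRule1990:
    def test_uniform_doses_no_splitting(self):
        result = remainder_dose_icrp60({"a": 2.0, "b": 2.0}, {"a": 1.0, "b": 1.0}, 5.0)
        assert result.dose_term == pytest.approx(2.0)
        assert not result.splitting

    def test_splitting_fires_when_remainder_organ_dominates(self):
        """Doses (2, 4), equal masses, no named organ above 4: 0.5·4 + 0.5·2."""
        result = remainder_dose_icrp60({"a": 2.0, "b": 4.0}, {"a": 1.0, "b": 1.0}, 3.0)
        assert result.splitting
        assert result.dominant == "b"
        assert result.dose_term == pytest.approx(3.0)

    def test_no_splitting_when_named_organ_dominates(self):
        result = remainder_dose_icrp60({"a": 2.0, "b": 4.0}, {"a": 3.0, "b": 1.0}, 9.0)
        assert not result.splitting
        assert result.dose_term == pytest.approx((3 * 2 + 1 * 4) / 4)

    def test_empty_remainder_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            remainder_dose_icrp60({}, {}, 1.0)


class TestEffectiveDose2007:
    def test_uniform_dose_identity(self):
        result = effective_dose_icrp103(uniform_table(2.5), uniform_table(2.5))
        assert result.e_ref == pytest.approx(2.5, rel=1e-12)
        assert result.e_male == pytest.approx(2.5, rel=1e-12)

    def test_reference_person_is_mean_of_sexes(self):
        male = uniform_table(1.07e-1)
        female = uniform_table(9.76e-2)
        result = effective_dose_icrp103(male, female)
        assert result.e_male == pytest.approx(1.07e-1, rel=1e-12)
        assert result.e_female == pytest.approx(9.76e-2, rel=1e-12)
        assert result.e_ref == pytest.approx(0.5 * (result.e_male + result.e_female),
                                             rel=1e-12)
        # reproduces a reference-person coefficient to 3 significant figures
        assert result.e_ref == pytest.approx(1.02e-1, rel=5e-3)

    def test_sex_specific_tissues_contribute_single_sex_dose(self):
        male = uniform_table(1.0)
        female = uniform_table(1.0)
        male["testes"] = 3.0
        del male["uterus"]  # reference male has no uterus
        result = effective_dose_icrp103(male, female)
        # gonads weight 0.08: male uses testes (3.0), female ovaries fallback
        assert result.e_male == pytest.approx(1.0 + 0.08 * 2.0, rel=1e-12)
        assert result.e_female == pytest.approx(1.0, rel=1e-12)

    def test_scaling_female_doses_scales_only_female_half(self):
        male = uniform_table(1.0)
        female = uniform_table(1.0)
        doubled = {k: 2 * v for k, v in female.items()}
        base = effective_dose_icrp103(male, female)
        scaled = effective_dose_icrp103(male, doubled)
        assert scaled.e_male == pytest.approx(base.e_male, rel=1e-12)
        assert scaled.e_female == pytest.approx(2 * base.e_female, rel=1e-12)
        assert scaled.e_ref == pytest.approx(
            0.5 * (base.e_male + 2 * base.e_female), rel=1e-12
        )

    def test_tissue_missing_from_both_sexes_errors(self):
        male = uniform_table(1.0)
        female = uniform_table(1.0)
        del male["thyroid"], female["thyroid"]
        with pytest.raises(ValueError, match="thyroid"):
            effective_dose_icrp103(male, female)


class TestEffectiveDose1990:
    def test_uniform_dose_identity(self):
        result = effective_dose_icrp60(uniform_table(1.7), uniform_table(1.7))
        assert result.e_ref == pytest.approx(1.7, rel=1e-12)

    def test_all_zero_doses(self):
        result = effective_dose_icrp60(uniform_table(0.0), uniform_table(0.0))
        assert result.e_ref == 0.0

    def test_hand_computed_toy_with_dominant_remainder_organ(self):
        """3 named + 2 remainder tissues; kidneys dominate → splitting."""
        scheme = WeightingScheme(
            scheme_id="ICRP60",
            weights={"liver": 0.4, "lungs": 0.3, "thyroid": 0.1},
            remainder_weight=0.2,
            remainder_male=("kidneys", "spleen"),
            remainder_female=("kidneys", "spleen"),
            remainder_rule="mass_weighted_with_splitting",
        )
        doses = {"liver": 1.0, "lungs": 2.0, "thyroid": 3.0,
                 "kidneys": 10.0, "spleen": 4.0}
        result = effective_dose_icrp60(doses, doses, scheme=scheme)
        # E = 0.4·1 + 0.3·2 + 0.1·3 + 0.2·(0.5·10 + 0.5·4) = 2.7
        assert result.e_ref == pytest.approx(2.7, rel=1e-12)
        assert result.breakdown["remainder"]["splitting"]

    def test_sex_average_applied_before_weighting(self):
        male = uniform_table(2.0)
        female = uniform_table(4.0)
        result = effective_dose_icrp60(male, female)
        assert result.e_ref == pytest.approx(3.0, rel=1e-12)
        assert result.e_male == pytest.approx(2.0, rel=1e-12)
        assert result.e_female == pytest.approx(4.0, rel=1e-12)


class TestMonotonicity:
    @given(
        tissue=st.sampled_from(_ALL_TISSUES),
        bump=st.floats(0.0, 10.0),
        scheme_id=st.sampled_from(["ICRP60", "ICRP103"]),
    )
    def test_increasing_any_tissue_dose_never_decreases_e(self, tissue, bump, scheme_id):
        fn = effective_dose_icrp60 if scheme_id == "ICRP60" else effective_dose_icrp103
        base_m, base_f = uniform_table(1.0), uniform_table(1.0)
        bumped_m = dict(base_m, **{tissue: 1.0 + bump})
        bumped_f = dict(base_f, **{tissue: 1.0 + bump})
        before = fn(base_m, base_f).e_ref
        after = fn(bumped_m, bumped_f).e_ref
        assert after >= before - 1e-12
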