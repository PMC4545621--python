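"""Time-integrated activity: integration, voiding, colon/bone/blood rules."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dosecalc import (
    Phantom,
    Region,
    TimeActivityFunction,
    bladder_tia,
    bone_partition,
    colon_convert,
    distribute_blood,
    integrate_time_activity,
    resolve_model,
)
from dosecalc.biokinetics import BiokineticModel, gi_transit_tia

LN2 = math.log(2.0)


def _exp(terms):
    return TimeActivityFunction("exponential_sum", terms=tuple(terms))


def _bladder_series_oracle(terms, lam, tau, n_max=100_000):
    """Independent series oracle: per-cycle exact solution.

    Content in cycle n is f(t) − f(t_n)·e^(−λ(t−t_n)) (same linear ODE as
    the no-void curve, zero content after each void), so
    TIA = ∫₀^∞ f − Σ_{n≥1} f(t_n)·(1−e^(−λτ))/λ.
    """
    def f(t):
        return sum(c * math.exp(-r * t) for c, r in terms)

    total = sum(c / r for c, r in terms)
    factor = (1.0 - math.exp(-lam * tau)) / lam
    deduction = 0.0
    for n in range(1, n_max):
        ft = f(n * tau)
        deduction += ft * factor
        if ft < 1e-16 * abs(total):
            break
    return total - deduction


class TestIntegrateTimeActivity:
    def test_single_exponential_closed_form(self):
        f = _exp([(1.0, LN2 / 6.0)])
        assert integrate_time_activity(f) == pytest.approx(6.0 / LN2, rel=1e-12)
        assert integrate_time_activity(f) == pytest.approx(8.6562, rel=1e-4)

    def test_zero_horizon_gives_zero(self):
        f = _exp([(1.0, 1.0)])
        assert integrate_time_activity(f, 0.0) == 0.0

    def test_linear_in_coefficients(self):
        lam = 0.3
        one = integrate_time_activity(_exp([(1.0, lam)]), 12.0)
        two = integrate_time_activity(_exp([(0.5, lam), (0.5, lam)]), 12.0)
        assert two == pytest.approx(one, rel=1e-12)

    def test_tabulated_value_returned_as_is(self):
        f = TimeActivityFunction("tabulated_tia", tia_hours=4.2)
        assert integrate_time_activity(f, 3.0) == 4.2

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            _exp([(1.0, 0.0)])


class TestBladderTIA:
    def test_instantaneous_arrival_single_cycle_closed_form(self):
        """All activity in the bladder at t=0: TIA = (1−e^(−λτ))/λ."""
        lam = LN2 / 6.0
        tau = 3.5
        tia = bladder_tia(_exp([(1.0, lam)]), tau, lam)
        assert tia == pytest.approx((1 - math.exp(-lam * tau)) / lam, rel=1e-12)

    def test_infinite_interval_reduces_to_plain_integral(self):
        f = _exp([(1.0, 0.2), (-1.0, 1.2)])
        assert bladder_tia(f, math.inf, 0.2) == pytest.approx(
            integrate_time_activity(f), rel=1e-12
        )

    def test_matches_series_oracle_for_gradual_inflow(self):
        """Two-exponential filling curve vs the independent cycle series."""
        lam = LN2 / 6.02
        terms = [(1.0, lam), (-1.0, lam + 1.0)]
        tau = 3.5
        got = bladder_tia(_exp(terms), tau, lam)
        expected = _bladder_series_oracle(terms, lam, tau)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_matches_series_oracle_instantaneous(self):
        lam = LN2 / 6.02
        got = bladder_tia(_exp([(1.0, lam)]), 3.5, lam)
        assert got == pytest.approx(_bladder_series_oracle([(1.0, lam)], lam, 3.5),
                                    rel=1e-10)

    @given(tau=st.floats(0.5, 24.0), shorter=st.floats(0.1, 0.9))
    def test_more_frequent_voiding_never_increases_tia(self, tau, shorter):
        lam = 0.2
        terms = [(1.0, lam), (-1.0, lam + 0.8)]
        tia_long = bladder_tia(_exp(terms), tau, lam)
        tia_short = bladder_tia(_exp(terms), tau * shorter, lam)
        assert tia_short <= tia_long * (1 + 1e-9)

    def test_nonpositive_physical_rate_rejected(self):
        with pytest.raises(ValueError, match="physical decay rate"):
            bladder_tia(_exp([(1.0, 0.1)]), 3.5, 0.0)


class TestColonConvert:
    def test_unit_uli(self):
        assert colon_convert(1.0, 0.0) == (0.71, 0.29, 0.0)

    def test_unit_lli(self):
        assert colon_convert(0.0, 1.0) == (0.0, 0.56, 0.44)

    def test_linear_combination(self):
        right, left, recto = colon_convert(2.0, 1.0)
        assert (right, left, recto) == pytest.approx((1.42, 1.14, 0.44), rel=1e-12)

    @given(uli=st.floats(0, 100), lli=st.floats(0, 100))
    def test_conserves_activity(self, uli, lli):
        assert sum(colon_convert(uli, lli)) == pytest.approx(uli + lli, rel=1e-12,
                                                             abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            colon_convert(-1.0, 0.0)


class TestBonePartition:
    def test_short_half_time_deposits_on_surfaces(self):
        parts = bone_partition(1.0, 2.0)
        assert parts["trabecular bone surface"] + parts["cortical bone surface"] == 1.0
        assert parts["trabecular bone volume"] == parts["cortical bone volume"] == 0.0

    def test_fifteen_day_boundary_is_volume(self):
        """The surface rule requires strictly shorter than 15 days."""
        parts = bone_partition(1.0, 15.0)
        assert parts["trabecular bone volume"] + parts["cortical bone volume"] == 1.0
        assert parts["trabecular bone surface"] == 0.0

    def test_known_split_used_verbatim(self):
        parts = bone_partition(2.0, 30.0, known_split={
            "trabecular bone volume": 0.6, "cortical bone volume": 0.4})
        assert parts == {"trabecular bone volume": pytest.approx(1.2),
                         "cortical bone volume": pytest.approx(0.8)}

    def test_known_split_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            bone_partition(1.0, 30.0, known_split={"trabecular bone volume": 0.7})

    def test_volume_split_is_mass_proportional_with_phantom(self):
        phantom = Phantom("male", (
            Region("trabecular bone volume", "both", 1.0),
            Region("cortical bone volume", "both", 3.0),
        ), 70.0)
        parts = bone_partition(4.0, 20.0, phantom=phantom)
        assert parts["trabecular bone volume"] == pytest.approx(1.0)
        assert parts["cortical bone volume"] == pytest.approx(3.0)

    @given(tia=st.floats(0, 50), t_eff=st.floats(0.1, 100))
    def test_conserves_tia(self, tia, t_eff):
        parts = bone_partition(tia, t_eff)
        assert sum(parts.values()) == pytest.approx(tia, rel=1e-12, abs=1e-12)


class TestDistributeBlood:
    def _phantom(self):
        return Phantom("male", (
            Region("liver", "both", 1.8, blood_fraction=0.5),
            Region("kidneys", "both", 0.3, blood_fraction=0.3),
        ), 70.0)

    def test_proportional_split_with_residue(self):
        dist, residue = distribute_blood(10.0, self._phantom())
        assert dist == {"liver": pytest.approx(5.0), "kidneys": pytest.approx(3.0)}
        assert residue == pytest.approx(2.0)

    def test_zero_blood_tia(self):
        dist, residue = distribute_blood(0.0, self._phantom())
        assert all(v == 0.0 for v in dist.values())
        assert residue == 0.0

    def test_fractions_summing_to_one_leave_no_residue(self):
        phantom = Phantom("male", (
            Region("liver", "both", 1.8, blood_fraction=0.6),
            Region("kidneys", "both", 0.3, blood_fraction=0.4),
        ), 70.0)
        _, residue = distribute_blood(7.0, phantom)
        assert residue == pytest.approx(0.0, abs=1e-12)

    def test_missing_fractions_rejected(self):
        phantom = Phantom("male", (Region("liver", "both", 1.8),), 70.0)
        with pytest.raises(ValueError, match="blood"):
            distribute_blood(1.0, phantom)


class TestGITransit:
    def test_chain_tia_closed_form(self):
        lam = 0.1
        tias = gi_transit_tia(1.0, (2.0, 5.0), lam)
        k1, k2 = 0.5, 0.2
        assert tias[0] == pytest.approx(1.0 / (k1 + lam), rel=1e-12)
        assert tias[1] == pytest.approx((k1 / (k1 + lam)) / (k2 + lam), rel=1e-12)

    def test_total_bounded_by_pure_decay(self):
        lam = 0.05
        tias = gi_transit_tia(1.0, (0.75, 4.0, 12.0, 12.0, 12.0), lam)
        assert sum(tias) <= 1.0 / lam


class TestResolveModel:
    def test_total_body_only_model(self, corpus_objects):
        phantom = corpus_objects["phantom_male"]
        lam = 0.1
        model = BiokineticModel(
            nuclide="Xx-1",
            entries={"total body": _exp([(1.0, lam)])},
            half_life_h=LN2 / lam,
        )
        vec = resolve_model(model, phantom)
        assert vec.entries == {
            "other organs and tissues": pytest.approx(1.0 / lam, rel=1e-12)
        }

    def test_residual_subtraction_rule(self, corpus_objects):
        phantom = corpus_objects["phantom_male"]
        model = BiokineticModel(
            nuclide="Xx-1",
            entries={
                "total body": TimeActivityFunction("tabulated_tia", tia_hours=10.0),
                "liver": TimeActivityFunction("tabulated_tia", tia_hours=4.0),
            },
            half_life_h=10.0,
        )
        vec = resolve_model(model, phantom)
        assert vec.entries["liver"] == 4.0
        assert vec.entries["other organs and tissues"] == pytest.approx(6.0)

    def test_negative_residual_floored_with_warning(self, corpus_objects, caplog):
        phantom = corpus_objects["phantom_male"]
        model = BiokineticModel(
            nuclide="Xx-1",
            entries={
                "total body": TimeActivityFunction("tabulated_tia", tia_hours=3.0),
                "liver": TimeActivityFunction("tabulated_tia", tia_hours=4.0),
            },
            half_life_h=10.0,
        )
        with caplog.at_level("WARNING", logger="dosecalc.biokinetics"):
            vec = resolve_model(model, phantom)
        assert vec.entries["other organs and tissues"] == 0.0
        assert "floored" in caplog.text

    def test_legacy_gut_regions_replaced_by_colon_segments(self, corpus_objects):
        phantom = corpus_objects["phantom_male"]
        model = BiokineticModel(
            nuclide="Xx-1",
            entries={
                "upper large intestine": TimeActivityFunction("tabulated_tia", tia_hours=1.0),
                "lower large intestine": TimeActivityFunction("tabulated_tia", tia_hours=1.0),
            },
            half_life_h=10.0,
        )
        vec = resolve_model(model, phantom)
        assert "upper large intestine" not in vec.entries
        assert vec.entries["right colon wall"] == pytest.approx(0.71)
        assert vec.entries["left colon wall"] == pytest.approx(0.85)
        assert vec.entries["rectosigmoid colon wall"] == pytest.approx(0.44)

    def test_all_corpus_models_obey_physical_decay_bound(self, corpus_objects):
        nuclide = corpus_objects["nuclide"]
        phantom = corpus_objects["phantom_male"]
        bound = nuclide.half_life_h / LN2
        for name, model in corpus_objects["models"].items():
            vec = resolve_model(model, phantom, physical_half_life_h=nuclide.half_life_h)
            assert vec.total() <= bound * (1 + 1e-9), name
            assert all(v >= 0 for v in vec.entries.values()), name

    def test_bookkeeping_records_rules(self, corpus_objects):
        model = corpus_objects["models"]["bladder"]
        vec = resolve_model(model, corpus_objects["phantom_male"])
        assert any("bladder voiding" in line for line in vec.provenance)
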