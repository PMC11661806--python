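"""Core receptor-model tests: scheme topology, steady state, MM reductions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import grkin.model as m
from grkin.ligands import get_ligand


def _scheme(dex, rates):
    return m.reaction_scheme(dex, rates)


class TestReactionScheme:
    def test_edge_count_and_single_export(self, dex, rates):
        edges = _scheme(dex, rates)
        assert len(edges) == 8
        exports = [e for e in edges if e.source.startswith("Rn") and
                   e.target.startswith("Rc") and e.kind == "kinetic"]
        assert len(exports) == 1
        assert (exports[0].source, exports[0].target) == ("Rn", "Rc")

    def test_only_k4_leaves_activated_state(self, dex, rates):
        leaving = [e for e in _scheme(dex, rates) if e.source == "RnGN"]
        assert [e.label for e in leaving] == ["k4"]

    def test_nuclear_recycle_path_avoids_cytoplasm(self, dex, rates):
        # the loop RnGN -> Rn -> RnG -> RnGt -> RnGN must close without
        # visiting any cytoplasmic state
        edges = {(e.source, e.target) for e in _scheme(dex, rates)}
        loop = ["RnGN", "Rn", "RnG", "RnGt", "RnGN"]
        for a, b in zip(loop[:-1], loop[1:]):
            assert (a, b) in edges
            assert not a.startswith("Rc") and not b.startswith("Rc")

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            m.RateConstants(k3=0.0)
        with pytest.raises(ValueError):
            m.RateConstants(k5=-1.0)
        with pytest.raises(ValueError):
            m.LigandParams(name="x", Kc=-5.0, Kn=155.0)


class TestSteadyState:
    def test_closed_form_matches_linear_solve(self, rates):
        """Oracle equivalence over 50 log-spaced concentrations, both ligands."""
        for name in ("dexamethasone", "cortisol"):
            lig = get_ligand(name).params
            for G in np.logspace(-4, 4, 50):
                a = m.steady_state(lig, rates, G).as_array()
                b = m.steady_state(lig, rates, G, method="linear").as_array()
                assert np.allclose(a, b, rtol=1e-8, atol=1e-14)

    def test_occupancies_sum_to_rtot(self, dex, rates):
        for G in np.logspace(-6, 6, 25):
            st_ = m.steady_state(dex, rates, G)
            assert st_.total == pytest.approx(dex.Rtot, rel=1e-10)

    def test_zero_ligand_all_cytoplasmic(self, dex, rates):
        st_ = m.steady_state(dex, rates, 0.0)
        assert st_.Rc == dex.Rtot
        assert m.f_rngn(st_) == 0.0
        assert m.nuclear_fraction(st_) == 0.0

    def test_nadir_cortisol_relative_activity(self, cortisol, rates):
        st_ = m.steady_state(cortisol, rates, 1.45)
        assert m.relative_activity(st_, rates) == pytest.approx(0.074, abs=5e-4)

    def test_saturating_limit(self, dex, rates):
        st_ = m.steady_state(dex, rates, 1e6)
        assert m.f_rngn(st_) == pytest.approx(25 / 31, rel=1e-3)

    def test_monotone_in_concentration(self, rates):
        for name in ("dexamethasone", "cortisol"):
            lig = get_ligand(name).params
            G = np.logspace(-6, 5, 120)
            fr = [m.f_rngn(m.steady_state(lig, rates, g)) for g in G]
            nf = [m.nuclear_fraction(m.steady_state(lig, rates, g)) for g in G]
            assert np.all(np.diff(fr) >= -1e-15)
            assert np.all(np.diff(nf) >= -1e-15)

    def test_negative_concentration_rejected(self, dex, rates):
        with pytest.raises(ValueError):
            m.steady_state(dex, rates, -0.1)

    def test_nuclear_shift_at_low_dex(self, dex, rates):
        nf = m.nuclear_fraction(m.steady_state(dex, rates, 0.01))
        assert nf >= 0.90
        assert nf == pytest.approx(0.92, abs=0.01)
        assert m.nuclear_fraction(m.steady_state(dex, rates, 1e8)) > 0.999


class TestRnGNMax:
    def test_reference_value(self, rates):
        assert m.rngn_max(rates) == pytest.approx(0.806, abs=5e-4)

    def test_symmetric_nuclear_cycle(self):
        r = m.RateConstants(k3=0.1, k4=0.1, k6=0.1)
        assert m.rngn_max(r) == pytest.approx(1 / 3, rel=1e-12)

    def test_matches_large_concentration_steady_state(self, dex, rates):
        st_ = m.steady_state(dex, rates, 1e9)
        assert m.f_rngn(st_) == pytest.approx(m.rngn_max(rates), abs=1e-4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-3, max_value=10.0), min_size=6, max_size=6))
    def test_infinite_dose_limit_for_random_rates(self, ks):
        r = m.RateConstants(*ks)
        lig = m.LigandParams(name="x", Kc=5.0, Kn=155.0)
        st_ = m.steady_state(lig, r, 1e12)
        assert m.f_rngn(st_) == pytest.approx(m.rngn_max(r), rel=1e-4)


class TestMMHigh:
    def test_printed_constants(self, dex, rates):
        mm = m.mm_high(dex, rates)
        assert mm.denom_const == pytest.approx(31.0, rel=1e-12)
        assert round(mm.Vmax, 3) == 0.769
        assert mm.Km == pytest.approx(5.0, rel=1e-12)

    def test_derived_vmax_is_infinite_dose_maximum(self, dex, rates):
        assert m.mm_high(dex, rates, form="derived").Vmax == m.rngn_max(rates)

    def test_symmetric_rates_give_c_three(self, dex):
        r = m.RateConstants(k3=1.0, k4=1.0, k6=1.0)
        assert m.mm_high(dex, r).denom_const == pytest.approx(3.0)

    def test_derived_form_independent_of_cytoplasmic_parameters(self, dex, rates):
        base = m.mm_high(dex, rates, form="derived")
        pert_r = m.RateConstants(k1=3.3, k2=0.77, k5=0.011)
        pert_l = m.LigandParams(name="x", Kc=123.0, Kn=dex.Kn)
        other = m.mm_high(pert_l, pert_r, form="derived")
        assert (other.Vmax, other.Km, other.denom_const) == \
            (base.Vmax, base.Km, base.denom_const)
        # the printed convention keeps C and Km cytoplasm-independent too
        assert m.mm_high(pert_l, pert_r).Km == m.mm_high(dex, rates).Km
        assert m.mm_high(pert_l, pert_r).denom_const == \
            m.mm_high(dex, rates).denom_const


class TestKnFromKmT:
    @pytest.mark.parametrize("kmt,expected", [(5.0, 155.0), (50.0, 1550.0),
                                              (15.0, 465.0)])
    def test_inversion(self, rates, kmt, expected):
        assert m.kn_from_kmt(kmt, rates) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self, rates):
        with pytest.raises(ValueError):
            m.kn_from_kmt(0.0, rates)


class TestMMLow:
    def test_printed_constants(self, dex, rates):
        mm = m.mm_low(dex, rates)
        assert round(mm.denom_const, 1) == 31.5
        assert round(mm.Vmax, 4) == 0.0317
        assert round(mm.Km, 6) == 0.000787

    def test_km_scales_inversely_with_k1(self, dex, rates):
        slow = m.mm_low(dex, m.RateConstants(k1=1.0))
        assert round(slow.Km, 4) == 0.0079
        assert slow.Km == pytest.approx(10 * m.mm_low(dex, rates).Km, rel=1e-12)
        assert slow.Vmax == m.mm_low(dex, rates).Vmax  # Vmax is k1-free

    def test_km_proportional_to_kc(self, dex, cortisol, rates):
        kml_dex = m.mm_low(dex, rates).Km
        kml_cort = m.mm_low(cortisol, rates).Km
        assert kml_cort == pytest.approx(15 * kml_dex, rel=1e-12)
        assert round(kml_cort, 4) == 0.0118

    def test_derived_form(self, dex, rates):
        mm = m.mm_low(dex, rates, form="derived")
        assert mm.denom_const == pytest.approx(24.9, abs=0.05)
        assert mm.Km == pytest.approx(0.000802, abs=5e-7)
        # derived form matches the true slope of the full model at G -> 0
        slope = m.f_rngn(m.steady_state(dex, rates, 1e-9)) / 1e-9
        assert mm.Vmax / mm.Km == pytest.approx(slope, rel=1e-4)


class TestMMActivity:
    def test_relative_activity_at_nadir(self, cortisol):
        mm = m.mm_experimental(cortisol)
        assert round(float(m.mm_activity(mm, 1.45)), 3) == 0.028

    def test_half_saturation_and_zero(self, dex, rates):
        mm = m.mm_high(dex, rates)
        assert m.mm_activity(mm, mm.Km) == pytest.approx(mm.Vmax / 2)
        assert m.mm_activity(mm, 0.0) == 0.0

    def test_negative_concentration_rejected(self, dex, rates):
        with pytest.raises(ValueError):
            m.mm_activity(m.mm_high(dex, rates), -1.0)


class TestRegimeAgreement:
    def test_high_regime_within_five_percent(self, rates):
        """The nuclear-only reduction tracks the full model for G >= KmH."""
        for name in ("dexamethasone", "cortisol"):
            lig = get_ligand(name).params
            mm = m.mm_high(lig, rates, form="derived")
            for G in np.logspace(np.log10(mm.Km), 4, 30):
                full = m.f_rngn(m.steady_state(lig, rates, G))
                approx = float(m.mm_activity(mm, G))
                assert abs(approx - full) / full < 0.05

    def test_low_regime_asymptotic_agreement(self, rates):
        """The low-concentration reduction converges to the full model as
        G -> 0 (within 5 % by one-thousandth of KmT)."""
        for name in ("dexamethasone", "cortisol"):
            lig = get_ligand(name).params
            mm = m.mm_low(lig, rates, form="derived")
            for G in np.logspace(-5, 0, 20) * 1e-3 * lig.KmT:
                full = m.f_rngn(m.steady_state(lig, rates, G))
                approx = float(m.mm_activity(mm, G))
                assert abs(approx - full) / full < 0.05


def test_dose_response_table(dex, rates):
    df = m.dose_response(dex, rates, np.logspace(-3, 2, 11))
    assert list(df.columns) == ["G_nM", "fRnGN", "relative_activity",
                                "nuclear_fraction"]
    assert (df["fRnGN"].diff().dropna() >= 0).all()
    assert df["relative_activity"].iloc[-1] == pytest.approx(
        df["fRnGN"].iloc[-1] / m.rngn_max(rates))
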