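"""Stewart engine: charge balance, pH solving, bicarbonate speciation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respdial import (
    AcidBaseState,
    EquilibriumConstants,
    IonComposition,
    dissolved_co2,
    equilibrate_fluid,
    hh_bicarbonate,
    sid_from_ions,
    solve_ph,
    stewart_sid,
)
from respdial.chemistry import equilibrate_profile
from respdial.errors import ConvergenceError, DomainError, ValidationError


def bisect_ph(sid, pco2, atot, k, n_iter=200):
    """Independent 200-iteration bisection oracle for the charge balance."""
    atot_mol, sid_mol = atot / 1000.0, sid / 1000.0

    def residual(ph):
        h = 10.0 ** (-ph)
        return (
            k.kc * pco2 / h
            + 2 * k.kc * k.k3 * pco2 / h**2
            + k.kw / h
            + k.ka * atot_mol / (k.ka + h)
            - h
            - sid_mol
        )

    lo, hi = 0.0, 14.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if residual(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestConstants:
    def test_printed_defaults(self, k):
        assert (k.kc, k.k3, k.kw, k.ka) == (2.45e-11, 5.76e-11, 2.39e-14, 1.77e-7)
        assert (k.ks, k.vm, k.pk_hh) == (0.0307, 22.4, 6.1)

    def test_kc_consistent_with_hh_constants(self, k):
        # kc and ks*10**(-pK') describe the same bicarbonate equilibrium
        assert k.hh_consistency() < 0.01

    def test_overrides(self, k):
        k2 = k.with_overrides({"ks": 0.0301})
        assert k2.ks == 0.0301 and k2.kc == k.kc
        with pytest.raises(ValidationError):
            k.with_overrides({"k_solubility": 1.0})
        with pytest.raises(ValidationError):
            EquilibriumConstants(ks=-1.0)


class TestSidFromIons:
    @pytest.mark.parametrize(
        "comp, expected",
        [
            (dict(na=134, k=3.5, ca=0, mg=1.0, cl=116, lactate=3.0), 20.5),
            (dict(na=134, k=3.5, ca=0, mg=1.0, cl=135.6, lactate=3.0), 0.9),
            ({}, 0.0),
            (dict(na=140, k=4, ca=2.2, mg=0.9, cl=104, lactate=1.0), 45.2),
        ],
    )
    def test_charge_sum(self, comp, expected):
        assert sid_from_ions(IonComposition(**comp)) == pytest.approx(expected)

    def test_phosphate_and_hco3_excluded(self):
        a = IonComposition(na=140, cl=100)
        b = IonComposition(na=140, cl=100, phosphate=2.0, hco3=24.0)
        assert sid_from_ions(a) == sid_from_ions(b)

    def test_negative_concentration_names_field(self):
        with pytest.raises(ValidationError, match="cl"):
            IonComposition(cl=-1.0)


class TestStewartSid:
    def test_pure_water_neutrality(self, k):
        assert stewart_sid(math.sqrt(k.kw), 0.0, 0.0, k) == pytest.approx(0.0, abs=1e-18)

    def test_physiological_plasma(self, k):
        # 24.62 bicarbonate + 0.07 carbonate + 14.04 weak acid, mmol/L scale
        sid = stewart_sid(10 ** (-7.40), 40.0, 17.2, k)
        assert sid * 1000 == pytest.approx(38.73, abs=0.01)

    def test_two_term_arithmetic(self, k):
        assert stewart_sid(1e-7, 0.0, 0.0, k) == pytest.approx(
            k.kw / 1e-7 - 1e-7, rel=1e-12
        )

    def test_domain_error(self, k):
        with pytest.raises(DomainError):
            stewart_sid(0.0, 40.0, 17.2, k)

    def test_strictly_decreasing_in_h(self, k):
        hs = np.logspace(-12, -4, 60)
        vals = [stewart_sid(h, 40.0, 17.2, k) for h in hs]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSolvePh:
    def test_final_dialysate_reports_ten(self, k):
        ph = solve_ph(0.9, 0.0, 0.5, k)
        assert ph == pytest.approx(10.22, abs=0.01)
        assert round(ph) == 10

    def test_plasma_inverse(self, k):
        assert solve_ph(38.7, 40.0, 17.2, k) == pytest.approx(7.40, abs=0.005)

    def test_neutral_water_closed_form(self, k):
        assert solve_ph(0.0, 0.0, 0.0, k) == pytest.approx(
            -math.log10(math.sqrt(k.kw)), abs=1e-9
        )

    def test_unbracketed_root_raises(self, k):
        with pytest.raises(ConvergenceError):
            solve_ph(5000.0, 0.0, 0.0, k)  # more charge than pH 14 can balance

    def test_against_bisection_oracle(self, k):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            sid = rng.uniform(-5, 60)
            pco2 = rng.uniform(0, 120)
            atot = rng.uniform(0, 25)
            assert solve_ph(sid, pco2, atot, k) == pytest.approx(
                bisect_ph(sid, pco2, atot, k), abs=1e-6
            )

    def test_monotone_in_sid_and_pco2(self, k):
        phs = [solve_ph(s, 40.0, 17.2, k) for s in np.linspace(10, 60, 11)]
        assert all(a < b for a, b in zip(phs, phs[1:]))
        phs = [solve_ph(38.7, p, 17.2, k) for p in np.linspace(5, 120, 11)]
        assert all(a > b for a, b in zip(phs, phs[1:]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        logh=st.floats(min_value=-12, max_value=-4),
        pco2=st.floats(min_value=0, max_value=150),
        atot=st.floats(min_value=0, max_value=40),
    )
    def test_round_trip_recovers_ph(self, logh, pco2, atot):
        k = EquilibriumConstants()
        h = 10.0**logh
        sid = stewart_sid(h, pco2, atot, k) * 1000
        assert solve_ph(sid, pco2, atot, k) == pytest.approx(-logh, abs=1e-9)


class TestBicarbonate:
    @pytest.mark.parametrize(
        "ph, pco2, expected",
        [(7.40, 40.0, 24.5), (6.1, 40.0, 1.228), (7.1, 0.0, 0.0)],
    )
    def test_hh_values(self, k, ph, pco2, expected):
        assert hh_bicarbonate(ph, pco2, k) == pytest.approx(expected, abs=0.005)

    def test_at_pk_equals_dissolved(self, k):
        assert hh_bicarbonate(k.pk_hh, 40.0, k) == pytest.approx(
            dissolved_co2(40.0, k)
        )

    @pytest.mark.parametrize("pco2, expected", [(40.0, 1.228), (0.0, 0.0), (100.0, 3.07)])
    def test_dissolved(self, k, pco2, expected):
        assert dissolved_co2(pco2, k) == pytest.approx(expected)

    def test_speciation_consistency_with_charge_balance(self, k):
        # the Stewart bicarbonate term and the HH bicarbonate agree to <1%
        for ph in np.linspace(6.0, 8.0, 21):
            h = 10.0**-ph
            stewart_term = k.kc * 40.0 / h  # mol/L
            assert stewart_term == pytest.approx(
                hh_bicarbonate(ph, 40.0, k) / 1000.0, rel=0.01
            )


class TestEquilibrateFluid:
    def test_co2_free_degenerate(self, k):
        st_ = equilibrate_fluid(0.0, 20.0, 5.0, k)
        assert st_.pco2 == 0.0 and st_.hco3 == 0.0
        assert st_.ph == pytest.approx(solve_ph(20.0, 0.0, 5.0, k))

    def test_plasma_composition_round_trip(self, k):
        st_ = equilibrate_fluid(25.7, 38.7, 17.2, k)
        assert st_.ph == pytest.approx(7.40, abs=0.005)
        assert st_.pco2 == pytest.approx(40.0, abs=0.2)
        assert st_.hco3 == pytest.approx(24.5, abs=0.1)
        assert st_.total_co2 == pytest.approx(st_.dissolved_co2 + st_.hco3)

    def test_self_consistency_round_trip(self, k):
        for sid, pco2, atot in [(38.7, 40, 17.2), (10, 80, 5), (0.9, 1e-3, 0.5)]:
            ph = solve_ph(sid, pco2, atot, k)
            total = dissolved_co2(pco2, k) + hh_bicarbonate(ph, pco2, k)
            st_ = equilibrate_fluid(total, sid, atot, k)
            assert st_.ph == pytest.approx(ph, abs=1e-6)
            assert st_.pco2 == pytest.approx(pco2, rel=1e-6)

    def test_profile_matches_scalar(self, k, rng):
        tc = rng.uniform(0, 40, 50)
        sid = rng.uniform(-5, 60, 50)
        atot = rng.uniform(0, 50, 50)
        ph, pco2, hco3 = equilibrate_profile(tc, sid, atot, k)
        for i in range(50):
            st_ = equilibrate_fluid(tc[i], sid[i], atot[i], k)
            assert ph[i] == pytest.approx(st_.ph, abs=1e-9)
            assert pco2[i] == pytest.approx(st_.pco2, rel=1e-8, abs=1e-12)


class TestAcidBaseState:
    def test_validation(self):
        with pytest.raises(ValidationError):
            AcidBaseState(ph=15, pco2=40, hco3=24, sid=38, atot=17,
                          dissolved_co2=1.2, total_co2=25)
        with pytest.raises(ValidationError):
            AcidBaseState(ph=7.4, pco2=-1, hco3=24, sid=38, atot=17,
                          dissolved_co2=1.2, total_co2=25)

    def test_h_consistent_with_ph(self):
        s = AcidBaseState(ph=7.4, pco2=40, hco3=24.5, sid=38.7, atot=17.2,
                          dissolved_co2=1.228, total_co2=25.7)
        assert s.h == pytest.approx(10**-7.4)
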