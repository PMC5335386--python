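"""Transporter kinetics: Q10 scaling, scheme construction, well-mixed propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gluclear import kinetics as K


class TestQ10:
    def test_one_decade_triples(self):
        assert K.q10_scale(2000.0, 3.0, 25.0, 35.0) == pytest.approx(6000.0)

    def test_identity_at_equal_temperature(self):
        assert K.q10_scale(123.0, 3.0, 30.0, 30.0) == 123.0

    def test_fractional_exponent(self):
        assert K.q10_scale(50.0, 3.0, 25.0, 30.0) == pytest.approx(
            50.0 * math.sqrt(3.0))

    @given(rate=st.floats(1e-3, 1e8), q10=st.floats(1.0, 5.0),
           ta=st.floats(0.0, 40.0), tb=st.floats(0.0, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_invertible(self, rate, q10, ta, tb):
        back = K.q10_scale(K.q10_scale(rate, q10, ta, tb), q10, tb, ta)
        assert back == pytest.approx(rate, rel=1e-9)


class TestTransporterScheme:
    def test_default_rates_exact(self):
        scheme = K.build_transporter_scheme(apply_q10=False)
        rates = {(t.source, t.target): t.rate for t in scheme.transitions}
        assert rates[("T", "TG")] == 6e6
        assert rates[("TG", "T")] == 601.0
        assert rates[("TG", "Tin")] == 2000.0
        assert rates[("Tin", "T")] == 50.0

    def test_q10_triples_all_rates(self):
        scheme = K.build_transporter_scheme(apply_q10=True)
        rates = {(t.source, t.target): t.rate for t in scheme.transitions}
        assert rates[("TG", "Tin")] == pytest.approx(6000.0)
        assert rates[("Tin", "T")] == pytest.approx(150.0)
        assert rates[("T", "TG")] == pytest.approx(18e6)

    def test_q10_can_exclude_bimolecular(self):
        scheme = K.build_transporter_scheme(apply_q10=True,
                                            scale_bimolecular=False)
        rates = {(t.source, t.target): t.rate for t in scheme.transitions}
        assert rates[("T", "TG")] == 6e6
        assert rates[("TG", "Tin")] == pytest.approx(6000.0)

    def test_zero_translocation_reduces_to_binding_site(self):
        p = K.TransporterParams(k_trans=0.0)
        scheme = K.build_transporter_scheme(p)
        conc = 100e-6
        occ = K.steady_state(scheme, {"glutamate": conc})
        kd = p.k_off / p.k_on  # 100.17 uM equilibrium dissociation constant
        assert occ[scheme.state_index("TG")] == pytest.approx(
            conc / (conc + kd), rel=1e-6)
        assert occ[scheme.state_index("Tin")] == pytest.approx(0.0, abs=1e-9)


class TestApparentKm:
    def test_value_with_printed_rates(self):
        assert K.apparent_km() * 1e6 == pytest.approx(10.573, rel=1e-3)

    def test_no_translocation_limit_is_kd(self):
        p = K.TransporterParams(k_trans=1e-9)
        assert K.apparent_km(p) == pytest.approx(601.0 / 6e6, rel=1e-6)

    def test_doubling_kon_halves_km(self):
        base = K.apparent_km()
        doubled = K.apparent_km(K.TransporterParams(k_on=12e6))
        assert doubled == pytest.approx(base / 2)

    def test_half_saturation_property(self):
        """Steady-state cycle flux is hyperbolic in [glu] with half
        saturation at the apparent Km (checked at 10 ligand levels)."""
        p = K.TransporterParams()
        km = K.apparent_km(p)
        sat = K.transporter_cycle_flux(p, 1.0)
        for conc in np.geomspace(km / 30, km * 30, 10):
            flux = K.transporter_cycle_flux(p, conc)
            assert flux == pytest.approx(sat * conc / (conc + km), rel=1e-3)
        assert K.transporter_cycle_flux(p, km) == pytest.approx(sat / 2,
                                                                rel=1e-3)


class TestWellMixed:
    def test_two_state_steady_state(self):
        kp, km_, lig = 1e6, 500.0, 200e-6
        scheme = K.KineticScheme(
            ["C", "O"],
            [K.Transition("C", "O", kp, ligand="glutamate"),
             K.Transition("O", "C", km_)],
            conducting=["O"],
        )
        _, occ = K.integrate_wellmixed(scheme, {"glutamate": lig}, 0.01, 3000)
        expected = kp * lig / (kp * lig + km_)
        assert occ[-1, 1] == pytest.approx(expected, rel=1e-4)

    def test_zero_ligand_stays_in_resting_state(self):
        scheme = K.build_transporter_scheme()
        _, occ = K.integrate_wellmixed(scheme, {"glutamate": 0.0}, 0.01, 500)
        assert np.all(occ[:, 0] == pytest.approx(1.0))

    def test_conservation_over_many_steps(self):
        scheme = K.build_transporter_scheme()
        _, occ = K.integrate_wellmixed(scheme, {"glutamate": 13e-6}, 0.01,
                                       1_000_000)
        assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-9

    def test_rk4_matches_expm(self):
        scheme = K.build_transporter_scheme()
        _, a = K.integrate_wellmixed(scheme, {"glutamate": 50e-6}, 0.005,
                                     4000, method="expm")
        _, b = K.integrate_wellmixed(scheme, {"glutamate": 50e-6}, 0.005,
                                     4000, method="rk4")
        assert np.abs(a - b).max() < 1e-6

    def test_rk4_step_size_error(self):
        scheme = K.build_transporter_scheme()
        with pytest.raises(K.SchemeError, match="step size"):
            K.integrate_wellmixed(scheme, {"glutamate": 1e-2}, 0.5, 100,
                                  method="rk4")

    def test_time_varying_ligand(self):
        scheme = K.build_transporter_scheme()
        lig = np.concatenate([np.full(500, 1e-3), np.zeros(1500)])
        _, occ = K.integrate_wellmixed(scheme, {"glutamate": lig}, 0.01, 2000)
        i_tin = scheme.state_index("Tin")
        i_t = scheme.state_index("T")
        # during a 5 ms mM pulse the slow reorientation step accumulates
        # most carriers inward-facing; the outward pool then recovers
        assert occ[500, i_tin] > 0.5
        assert occ[500, i_t] < 0.1
        assert occ[-1, i_t] > occ[500, i_t]


class TestSchemeIO:
    def test_yaml_round_trip(self, tmp_path):
        scheme = K.build_transporter_scheme()
        path = tmp_path / "scheme.yaml"
        scheme.to_yaml(path)
        loaded = K.KineticScheme.from_yaml(path)
        assert loaded.states == scheme.states
        assert [(t.source, t.target, t.rate, t.ligand, t.effect)
                for t in loaded.transitions] == [
            (t.source, t.target, t.rate, t.ligand, t.effect)
            for t in scheme.transitions]

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("states: [A, B]\nbogus: 1\ntransitions:\n"
                        "  - {from: A, to: B, rate: 1.0}\n")
        with pytest.raises(K.SchemeError, match="bogus"):
            K.KineticScheme.from_yaml(path)

    def test_disconnected_graph_rejected(self):
        with pytest.raises(K.SchemeError, match="connected"):
            K.KineticScheme(["A", "B", "C"],
                            [K.Transition("A", "B", 1.0)])

    def test_negative_rate_rejected(self):
        with pytest.raises(K.SchemeError):
            K.Transition("A", "B", -1.0)


class TestSealedBoxOracle:
    def test_equilibrium_solves_mass_action(self):
        n_g, n_t, v = 2000, 1000, 1.0
        kon, koff = 6e6, 100.0
        t = np.linspace(0, 200.0, 50)
        b = K.sealed_box_binding_ode(n_g, n_t, v, kon, koff, t)
        beq = b[-1]
        kon_count = kon / (K.AVOGADRO * v * 1e-15)
        assert kon_count * (n_g - beq) * (n_t - beq) == pytest.approx(
            koff * beq, rel=1e-3)
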