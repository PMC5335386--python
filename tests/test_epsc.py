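"""Kinetic EPSC simulations: integration, competitive block, trains."""

from importlib import resources

import numpy as np
import pytest

from gluclear import epsc as E
from gluclear.kinetics import KineticScheme, Transition


@pytest.fixture(scope="module")
def glua_scheme():
    path = resources.files("gluclear.schemes") / "glua_synthetic.yaml"
    return KineticScheme.from_yaml(str(path))


@pytest.fixture(scope="module")
def two_state_competitive():
    """C ⇌ O gated by glutamate, C ⇌ B by the antagonist (both K_d = 1 mM)."""
    return KineticScheme(
        ["C", "O", "B"],
        [Transition("C", "O", 1e6, ligand="glutamate"),
         Transition("O", "C", 1000.0),
         Transition("C", "B", 1e6, ligand="antagonist"),
         Transition("B", "C", 1000.0)],
        conducting=["O"],
    )


class TestSimulateEpsc:
    def test_zero_peak_flat_response(self, glua_scheme):
        r = E.simulate_epsc(glua_scheme, E.GlutTransient(0.0, 1.0))
        assert r.peak == pytest.approx(0.0, abs=1e-12)

    def test_two_state_constant_ligand_closed_form(self, two_state_competitive):
        lig = 5e-4
        cfg = E.EPSCConfig(duration_ms=50.0)
        r = E.simulate_epsc(two_state_competitive,
                            E.GlutTransient(lig, 1e4), config=cfg)
        expected = lig / (lig + 1e-3)  # K_d = koff/kon = 1 mM
        assert r.open_prob[-1] == pytest.approx(expected, rel=0.01)

    def test_occupancy_conserved(self, glua_scheme):
        r = E.simulate_epsc(glua_scheme, E.GlutTransient(1e-3, 1.2))
        assert r.max_conservation_error < 1e-9

    def test_step_halving_converged(self, glua_scheme):
        tr = E.GlutTransient(1e-3, 1.2)
        p5 = E.simulate_epsc(glua_scheme, tr, config=E.EPSCConfig(step_us=5.0))
        p25 = E.simulate_epsc(glua_scheme, tr,
                              config=E.EPSCConfig(step_us=2.5))
        assert p25.peak == pytest.approx(p5.peak, rel=1e-3)

    def test_antagonist_without_binding_states_rejected(self):
        scheme = KineticScheme(
            ["C", "O"],
            [Transition("C", "O", 1e6, ligand="glutamate"),
             Transition("O", "C", 1000.0)],
            conducting=["O"],
        )
        with pytest.raises(E.EPSCError, match="antagonist"):
            E.simulate_epsc(scheme, E.GlutTransient(1e-3, 1.0), 100e-6)


class TestBlockRatio:
    def test_no_antagonist_is_unity(self, glua_scheme):
        assert E.block_ratio(glua_scheme, E.GlutTransient(1e-3, 1.2), 0.0) \
            == pytest.approx(1.0)

    def test_equilibrium_competitive_closed_form(self, two_state_competitive):
        """Schild-type limit: for slow transients the peak shift is
        (1 + L/K_D) / (1 + L/K_D + B/K_B), within 2%."""
        lig, b = 5e-4, 2e-3
        cfg = E.EPSCConfig(duration_ms=400.0)
        got = E.block_ratio(two_state_competitive,
                            E.GlutTransient(lig, 500.0), b, cfg)
        expected = (1 + lig / 1e-3) / (1 + lig / 1e-3 + b / 1e-3)
        assert got == pytest.approx(expected, rel=0.02)

    def test_monotone_decreasing_in_antagonist(self, glua_scheme):
        tr = E.GlutTransient(1e-3, 1.2)
        ratios = [E.block_ratio(glua_scheme, tr, b)
                  for b in (100e-6, 300e-6, 1e-3)]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_less_block_for_larger_transients(self, glua_scheme):
        small = E.block_ratio(glua_scheme, E.GlutTransient(2e-4, 1.2), 300e-6)
        large = E.block_ratio(glua_scheme, E.GlutTransient(3e-3, 1.2), 300e-6)
        assert large > small

    def test_zero_control_peak_rejected(self, glua_scheme):
        with pytest.raises(E.EPSCError, match="zero control peak"):
            E.block_ratio(glua_scheme, E.GlutTransient(0.0, 1.0), 300e-6)


class TestBlockContour:
    def test_single_point_consistent_with_block_ratio(self, glua_scheme):
        tr = E.GlutTransient(1e-3, 1.2)
        mat = E.block_contour(glua_scheme, np.array([1e-3]),
                              np.array([1.2]), 300e-6)
        direct = E.block_ratio(glua_scheme, tr, 300e-6,
                               E.EPSCConfig(duration_ms=8 * 1.2 + 20.0))
        assert mat[0, 0] == pytest.approx(direct, rel=1e-6)

    def test_monotone_small_grid(self, glua_scheme):
        peaks = np.geomspace(1e-4, 5e-3, 4)
        taus = np.geomspace(0.3, 4.0, 4)
        mat = E.block_contour(glua_scheme, peaks, taus, 300e-6)
        assert np.all(np.diff(mat, axis=0) >= -1e-9)
        assert np.all(np.diff(mat, axis=1) >= -1e-9)

    def test_level_set_extraction(self, glua_scheme):
        peaks = np.geomspace(1e-4, 1e-2, 6)
        taus = np.geomspace(0.2, 5.0, 5)
        mat = E.block_contour(glua_scheme, peaks, taus, 300e-6)
        pts = E.iso_block_level_set(peaks, taus, mat, 0.29)
        assert len(pts) >= 1
        for tau, peak in pts:
            j = list(taus).index(tau)
            col = mat[:, j]
            assert col.min() <= 0.29 <= col.max()
            assert peaks.min() <= peak <= peaks.max()

    def test_empty_grid_rejected(self, glua_scheme):
        with pytest.raises(E.EPSCError, match="empty"):
            E.block_contour(glua_scheme, np.array([]), np.array([1.0]),
                            300e-6)


class TestTrains:
    def test_long_interval_full_recovery(self, two_state_competitive):
        # no desensitized state and an interval >> all time constants
        r = E.simulate_train(two_state_competitive,
                             E.GlutTransient(5e-4, 1.0),
                             n_pulses=3, interval_ms=200.0)
        assert r.summation_index == pytest.approx(1.0, rel=0.01)
        assert np.allclose(r.pulse_peaks, r.pulse_peaks[0], rtol=0.01)

    def test_desensitization_depresses_second_pulse(self, glua_scheme):
        r = E.simulate_train(glua_scheme, E.GlutTransient(2e-3, 1.2),
                             n_pulses=2, interval_ms=20.0)
        assert r.pulse_peaks[1] < r.pulse_peaks[0]

    def test_smaller_transients_summate_more(self, glua_scheme):
        big = E.simulate_train(glua_scheme, E.GlutTransient(2e-3, 1.2),
                               n_pulses=5, interval_ms=100.0)
        small = E.simulate_train(glua_scheme, E.GlutTransient(2e-4, 1.2),
                                 n_pulses=5, interval_ms=100.0)
        assert small.summation_index > big.summation_index

    def test_single_pulse_rejected(self, glua_scheme):
        with pytest.raises(E.EPSCError, match="at least 2"):
            E.simulate_train(glua_scheme, E.GlutTransient(1e-3, 1.2),
                             n_pulses=1)


class TestTransient:
    def test_waveform(self):
        tr = E.GlutTransient(2e-3, 3.0, onset_ms=10.0)
        assert tr.concentration(9.9) == 0.0
        assert tr.concentration(10.0) == pytest.approx(2e-3)
        assert tr.concentration(13.0) == pytest.approx(2e-3 * np.exp(-1.0))

    def test_invalid_parameters(self):
        with pytest.raises(E.EPSCError):
            E.GlutTransient(-1.0, 1.0)
        with pytest.raises(E.EPSCError):
            E.GlutTransient(1e-3, 0.0)
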