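"""Forward circuit model: impedances, configuration algebra, transients."""

import numpy as np
import pytest

from stimsafe.circuit import (
    build_cpe_ladder,
    configuration_spectrum,
    cpe_impedance,
    interface_impedance,
    medium_impedance,
    simulate_transient,
)
from stimsafe.types import CircuitParams, InterfaceParams, MediumParams, StimPulse


def brute_interface(p, f):
    """Independent series/parallel complex arithmetic for the interface."""
    w = 2 * np.pi * f
    z_dl = (q := p.q_dl, 1.0 / (q * (1j * w) ** p.n_dl))[1]
    z_far = p.r_ct + (1.0 / (p.q_f * (1j * w) ** p.n_f) if p.q_f > 0 else 0.0)
    return 1.0 / (1.0 / z_dl + 1.0 / z_far)


def brute_medium(p, f):
    w = 2 * np.pi * f
    z = p.r_lead + p.r_spread
    if p.c_in > 0:
        z_in = p.r_in + 1.0 / (1j * w * p.c_in)
        z += 1.0 / (1.0 / p.r_ex + 1.0 / z_in)
    else:
        z += p.r_ex
    return z


class TestCPE:
    def test_ideal_capacitor_limit(self):
        z = cpe_impedance(1e-6, 1.0, 1.0 / (2 * np.pi))
        assert z == pytest.approx(-1e6j)

    def test_pure_resistor_limit(self):
        for f in (0.1, 42.0, 1e5):
            assert cpe_impedance(0.01, 0.0, f) == pytest.approx(100.0 + 0j)

    def test_phase_is_minus_n_times_90(self):
        z = cpe_impedance(1e-6, 0.8, 1000.0)
        assert np.degrees(np.angle(z)) == pytest.approx(-72.0)
        brute = 1.0 / (1e-6 * (1j * 2 * np.pi * 1000.0) ** 0.8)
        assert z == pytest.approx(brute, rel=1e-14)

    @pytest.mark.parametrize("bad", [dict(q=0, n=0.5, f=1.0), dict(q=1e-6, n=0.5, f=0.0),
                                     dict(q=-1, n=0.5, f=1.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            cpe_impedance(bad["q"], bad["n"], bad["f"])


class TestInterface:
    def test_dc_limit_is_charge_transfer(self):
        p = InterfaceParams(q_dl=1e-6, n_dl=0.9, r_ct=1e4)
        assert abs(interface_impedance(p, 1e-6)) == pytest.approx(1e4, rel=1e-3)

    def test_high_frequency_shorts(self):
        p = InterfaceParams(q_dl=1e-6, n_dl=0.9, r_ct=1e4)
        z_lo = abs(interface_impedance(p, 1e-6))
        assert abs(interface_impedance(p, 1e9)) < 1e-3 * z_lo

    def test_matches_brute_force_complex_algebra(self):
        p = InterfaceParams(q_dl=1e-5, n_dl=0.9, r_ct=1e6, q_f=1e-6, n_f=0.8)
        z = interface_impedance(p, 1e3)
        assert z == pytest.approx(brute_interface(p, 1e3), rel=1e-12)


class TestMedium:
    P = MediumParams(r_spread=500.0, r_ex=1000.0, r_in=400.0, c_in=1e-7, r_lead=50.0)

    def test_dc_limit(self):
        z = medium_impedance(self.P, 1e-6)
        assert abs(z) == pytest.approx(50 + 500 + 1000, rel=1e-3)

    def test_high_frequency_limit(self):
        z = medium_impedance(self.P, 1e9)
        r_par = 1000 * 400 / 1400
        assert abs(z) == pytest.approx(50 + 500 + r_par, rel=1e-3)

    def test_midband_matches_brute_force(self):
        z = medium_impedance(self.P, 1e3)
        assert z == pytest.approx(brute_medium(self.P, 1e3), rel=1e-12)


class TestConfigurations:
    def test_four_contact_is_medium_only(self, example_circuit):
        f = np.logspace(0, 5, 25)
        s = configuration_spectrum(example_circuit, "four_contact", f)
        assert np.allclose(s.z, medium_impedance(example_circuit.medium, f), rtol=1e-14)

    def test_two_equals_three_plus_working_interface(self, example_circuit):
        f = np.logspace(0, 5, 25)
        z2 = configuration_spectrum(example_circuit, "two_contact", f).z
        z3 = configuration_spectrum(example_circuit, "three_contact", f).z
        ziface = interface_impedance(example_circuit.working, f)
        assert np.allclose(z2, z3 + ziface, rtol=1e-12)

    def test_three_minus_four_is_interface(self, example_circuit):
        f = np.logspace(0, 5, 25)
        z3 = configuration_spectrum(example_circuit, "three_contact", f).z
        z4 = configuration_spectrum(example_circuit, "four_contact", f).z
        assert np.allclose(
            z3 - z4, interface_impedance(example_circuit.working, f), rtol=1e-12
        )

    def test_magnitude_ordering(self, example_circuit):
        f = np.logspace(0, 5, 40)
        mags = [
            np.abs(configuration_spectrum(example_circuit, c, f).z)
            for c in ("two_contact", "three_contact", "four_contact")
        ]
        assert np.all(mags[0] >= mags[1]) and np.all(mags[1] >= mags[2])

    def test_unknown_config_rejected(self, example_circuit):
        with pytest.raises(ValueError, match="configuration"):
            configuration_spectrum(example_circuit, "five_contact", np.array([1.0, 10.0]))


class TestLadder:
    @pytest.mark.parametrize("n", [0.3, 0.5, 0.8, 0.9, 0.95])
    def test_fidelity_within_5pct_over_band(self, n):
        lad = build_cpe_ladder(1e-6, n, 1e2, 1e6, rungs_per_decade=8)
        f = np.logspace(2, 6, 300)
        rel = np.abs(lad.impedance(f)) / np.abs(cpe_impedance(1e-6, n, f)) - 1
        assert np.max(np.abs(rel)) < 0.05

    def test_limits_realised_exactly(self):
        assert build_cpe_ladder(2e-6, 1.0, 1, 1e6).c_ideal == 2e-6
        assert build_cpe_ladder(0.01, 0.0, 1, 1e6).r0 == pytest.approx(100.0)


class TestTransient:
    def test_pure_resistor_network_is_flat(self):
        iface = InterfaceParams(q_dl=0.01, n_dl=1e-8, r_ct=1e12)  # CPE -> 100 ohm
        p = CircuitParams(
            working=iface, counter=iface,
            medium=MediumParams(r_spread=50.0, r_ex=25.0),
        )
        pulse = StimPulse(i_inj=1e-3, t_pw=1e-3)
        vt = simulate_transient(p, pulse, dt=1e-5, config="two_contact")
        catho = (vt.t > 0) & (vt.t <= pulse.t_pw)
        assert np.allclose(vt.v[catho], -1e-3 * (100 + 100 + 75), rtol=1e-9)

    def test_ideal_capacitor_ramp(self):
        iface = InterfaceParams(q_dl=1e-6, n_dl=1.0, r_ct=1e12)
        p = CircuitParams(
            working=iface, counter=iface, medium=MediumParams(r_spread=0.0, r_ex=0.0)
        )
        pulse = StimPulse(i_inj=1e-4, t_pw=1e-4)
        vt = simulate_transient(p, pulse, dt=1e-6, config="three_contact")
        v_end = vt.v[vt.t <= pulse.t_pw * (1 + 1e-9)][-1]
        assert v_end == pytest.approx(-1e-4 * 1e-4 / 1e-6, rel=0.01)

    def test_series_rc_matches_closed_form(self):
        iface = InterfaceParams(q_dl=1e-6, n_dl=1.0, r_ct=1e12)
        p = CircuitParams(
            working=iface, counter=iface, medium=MediumParams(r_spread=1000.0, r_ex=0.0)
        )
        pulse = StimPulse(i_inj=1e-4, t_pw=1e-4)
        vt = simulate_transient(p, pulse, dt=1e-6, config="three_contact")
        catho = vt.t <= pulse.t_pw * (1 + 1e-9)
        closed = -1e-4 * 1000.0 - 1e-4 * vt.t[catho] / 1e-6
        assert np.allclose(vt.v[catho], closed, rtol=0.01)

    def test_cathodal_phase_is_negative(self, example_circuit):
        vt = simulate_transient(example_circuit, StimPulse(i_inj=1e-4, t_pw=2e-4), dt=2e-6)
        catho = (vt.t > 0) & (vt.t < 2e-4)
        assert np.all(vt.v[catho] < 0)

    def test_linearity_without_faradaic_bias(self, example_circuit):
        v1 = simulate_transient(example_circuit, StimPulse(i_inj=1e-4, t_pw=2e-4), dt=2e-6).v
        v2 = simulate_transient(example_circuit, StimPulse(i_inj=2e-4, t_pw=2e-4), dt=2e-6).v
        assert np.allclose(v2, 2 * v1, atol=1e-12)

    def test_faradaic_bias_breaks_linearity_sublinearly(self):
        iface = InterfaceParams(
            q_dl=1e-6, n_dl=0.85, r_ct=1e5, faradaic_nonlinearity=5.0
        )
        p = CircuitParams(
            working=iface, counter=iface,
            medium=MediumParams(r_spread=500.0, r_ex=100.0),
        )
        v1 = simulate_transient(p, StimPulse(i_inj=1e-4, t_pw=2e-4), dt=2e-6).v
        v2 = simulate_transient(p, StimPulse(i_inj=2e-4, t_pw=2e-4), dt=2e-6).v
        k = np.argmin(v1)  # deepest cathodal polarization
        assert abs(v2[k]) < 2 * abs(v1[k])  # conductance grows with bias

    def test_coarse_dt_rejected_with_required_resolution(self):
        p = CircuitParams(
            working=InterfaceParams(q_dl=1e-6, n_dl=0.9, r_ct=1e6),
            counter=InterfaceParams(q_dl=1e-6, n_dl=0.9, r_ct=1e6),
            medium=MediumParams(r_spread=100.0, r_ex=0.0),
        )
        with pytest.raises(ValueError, match="t_pw/100"):
            simulate_transient(p, StimPulse(i_inj=1e-4, t_pw=1e-4), dt=5e-6)
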