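"""Echo sequence engines: Hahn, dressed primary echo, empty-bath reference."""

import numpy as np
import pytest

from spinbath import (
    CouplingSet,
    SequenceSpec,
    build_cluster_hamiltonian,
    couplings_for_orientation,
    dressed_echo_trace,
    hahn_echo_trace,
    ideal_pulse,
    locked_fraction,
    slow_fraction,
    w_empty,
)
from spinbath.hamiltonian import electron_op
from spinbath.sequences import empty_couplings

TIMES = np.linspace(0.0, 40.0, 81)


def _pair_eseem_oracle(A_MHz, wnn_kHz, times_us):
    """Closed-form two-proton Hahn modulation (modulation depth lambda and
    nuclear zero-quantum frequency), evaluated independently."""
    da = (A_MHz[0] - A_MHz[1]) * 2 * np.pi
    wn = wnn_kHz * 2 * np.pi * 1e-3
    lam = da**2 * wn**2 / (da**2 + wn**2) ** 2
    wzq = 0.5 * np.sqrt(da**2 + wn**2)
    return (
        1.0
        - 1.5 * lam
        - 0.5 * lam * np.cos(wzq * times_us)
        + 2.0 * lam * np.cos(0.5 * wzq * times_us)
    )


def _hahn_fullspace_oracle(couplings, spec):
    """Spec-literal Hahn echo: full-space density-operator propagation with
    ideal pulses, independent of the block-diagonal fast path."""
    c = couplings.n
    h = build_cluster_hamiltonian(
        couplings,
        Omega_S_MHz=spec.Omega_S_MHz,
        include_pseudosecular=spec.include_pseudosecular,
    )
    sx = electron_op("x", c)
    sp = electron_op("+", c)
    rho0 = -sx  # after the ideal pi/2 from -S_z
    ref = None
    out = np.empty(len(spec.times_us))
    for i, t in enumerate(spec.times_us):
        u = h.propagator(t / 2.0)
        rho = u @ rho0 @ u.conj().T
        rho = ideal_pulse(rho, "x", np.pi)
        rho = u @ rho @ u.conj().T
        s = np.trace(rho @ sp)
        if ref is None:
            rho_ref = ideal_pulse(rho0, "x", np.pi)
            ref = np.trace(rho_ref @ sp)
        out[i] = (s / ref).real
    return out


class TestHahnEcho:
    def test_single_proton_secular_no_decay(self):
        cpl = CouplingSet(
            proton_ids=(1,),
            A_MHz=np.array([2.0]),
            B_MHz=np.zeros((1, 2)),
            omega_zz_kHz=np.zeros((1, 1)),
            omega_nn_kHz=np.zeros((1, 1)),
        )
        tr = hahn_echo_trace(cpl, SequenceSpec(mode="bare", times_us=TIMES))
        assert np.allclose(tr.values, 1.0, atol=1e-9)

    def test_two_proton_secular_matches_pair_eseem(self, two_proton_secular):
        tr = hahn_echo_trace(two_proton_secular, SequenceSpec(mode="bare", times_us=TIMES))
        oracle = _pair_eseem_oracle(two_proton_secular.A_MHz, 80.0, TIMES)
        assert np.max(np.abs(tr.values - oracle)) < 1e-6

    def test_t_zero_is_one(self, two_proton_secular):
        tr = hahn_echo_trace(two_proton_secular, SequenceSpec(mode="bare", times_us=TIMES))
        assert tr.values[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("offset", [0.0, 5.0, -7.0])
    def test_offset_independence_with_ideal_pulses(self, two_proton_secular, offset):
        base = hahn_echo_trace(two_proton_secular, SequenceSpec(mode="bare", times_us=TIMES))
        tr = hahn_echo_trace(
            two_proton_secular,
            SequenceSpec(mode="bare", times_us=TIMES, Omega_S_MHz=offset),
        )
        assert np.max(np.abs(tr.values - base.values)) < 1e-9

    def test_static_secular_bath_gives_no_decoherence(self, rng, orientation):
        # no pseudo-secular terms and no flip-flops: the bath is static and
        # the pi pulse refocuses everything
        from conftest import random_secular_system

        s = random_secular_system(rng, 3)
        cpl = couplings_for_orientation(s, orientation)
        cpl.omega_nn_kHz[:] = 0.0
        spec = SequenceSpec(mode="bare", times_us=TIMES, include_pseudosecular=False)
        tr = hahn_echo_trace(cpl, spec)
        assert np.allclose(tr.values, 1.0, atol=1e-9)

    def test_block_fast_path_matches_fullspace_oracle(self, matched_methyl_system,
                                                      orientation):
        cpl = couplings_for_orientation(matched_methyl_system, orientation)
        cpl.B_MHz[:, 0] = [0.1, -0.05, 0.07]  # exercise pseudo-secular terms
        spec = SequenceSpec(mode="bare", times_us=np.linspace(0, 15, 16))
        fast = hahn_echo_trace(cpl, spec).values
        slow = _hahn_fullspace_oracle(cpl, spec)
        assert np.max(np.abs(fast - slow)) < 1e-9


class TestDressedEcho:
    def test_empty_bath_on_resonance_is_constant(self):
        spec = SequenceSpec(mode="dressed", times_us=np.linspace(0, 30, 31))
        tr = dressed_echo_trace(empty_couplings(), spec)
        assert np.allclose(tr.values, 1.0, atol=1e-9)
        assert tr.raw_scale == pytest.approx(1.0, abs=1e-9)

    def test_locked_fraction_matches_configuration_sum(self):
        # numerical eigenbasis extraction of the slow fraction against the
        # analytical enumeration over nuclear spin configurations
        A = np.array([3.0, -1.5, 7.0])
        cpl = CouplingSet(
            proton_ids=(1, 2, 3),
            A_MHz=A,
            B_MHz=np.zeros((3, 2)),
            omega_zz_kHz=np.zeros((3, 3)),
            omega_nn_kHz=np.zeros((3, 3)),
        )
        h = build_cluster_hamiltonian(cpl, Omega_S_MHz=4.0, omega1_MHz=100.0)
        assert locked_fraction(h) == pytest.approx(
            slow_fraction(A, 4.0, 100.0), abs=1e-12
        )

    def test_methyl_dressed_decays_slower_than_bare(self, matched_methyl_system,
                                                    orientation):
        cpl = couplings_for_orientation(matched_methyl_system, orientation)
        bare = hahn_echo_trace(cpl, SequenceSpec(mode="bare", times_us=TIMES))
        dressed = dressed_echo_trace(
            cpl, SequenceSpec(mode="dressed", times_us=TIMES, omega1_MHz=100.0)
        )
        assert np.min(bare.values) < 0.5  # bare decays deeply (matched pair)
        assert np.all(dressed.values >= bare.values - 1e-9)
        assert np.max(1 - dressed.values) < 0.1 * np.max(1 - bare.values)

    def test_zeroed_hyperfine_equals_empty_bath_signal(self, matched_methyl_system,
                                                       orientation):
        cpl = couplings_for_orientation(matched_methyl_system, orientation)
        cpl.A_MHz[:] = 0.0
        cpl.B_MHz[:] = 0.0
        spec = SequenceSpec(
            mode="dressed", times_us=np.linspace(0, 20, 21), Omega_S_MHz=4.0
        )
        tr = dressed_echo_trace(cpl, spec)
        ref = dressed_echo_trace(empty_couplings(), spec)
        assert np.max(np.abs(tr.values - ref.values)) < 1e-9

    def test_explicit_pm_validates_ideal_on_resonance(self):
        times = np.linspace(0, 10, 11)
        ideal = dressed_echo_trace(
            empty_couplings(), SequenceSpec(mode="dressed", times_us=times)
        )
        explicit = dressed_echo_trace(
            empty_couplings(),
            SequenceSpec(mode="dressed", times_us=times, pm_model="explicit"),
        )
        assert np.max(np.abs(explicit.values - ideal.values)) < 1e-6
        assert explicit.raw_scale == pytest.approx(1.0, abs=0.05)


class TestWEmpty:
    def test_bare_mode_is_unity(self):
        spec = SequenceSpec(mode="bare", times_us=TIMES)
        assert np.all(w_empty(spec).values == 1.0)

    def test_zero_offset_width_is_constant(self):
        spec = SequenceSpec(mode="dressed", times_us=np.linspace(0, 20, 21))
        tr = w_empty(spec, sigma_MHz=0.0)
        assert np.allclose(tr.values, 1.0, atol=1e-9)

    def test_offset_average_stays_locked(self):
        # sigma = 4 MHz at omega1 = 100 MHz: at most ~0.5 % of the
        # magnetization is unlocked at a 10 MHz offset, so the averaged
        # empty-bath signal varies slowly
        spec = SequenceSpec(mode="dressed", times_us=np.linspace(0, 30, 61))
        tr = w_empty(spec, sigma_MHz=4.0)
        assert np.all(tr.values >= 0.98)


class TestSpecValidation:
    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            SequenceSpec(mode="bare", times_us=[0.0, 2.0, 1.0])

    def test_dressed_needs_positive_omega1(self):
        with pytest.raises(ValueError):
            SequenceSpec(mode="dressed", times_us=[0.0, 1.0], omega1_MHz=0.0)

    def test_mode_mismatch_rejected(self, two_proton_secular):
        spec = SequenceSpec(mode="bare", times_us=[0.0, 1.0])
        with pytest.raises(ValueError):
            dressed_echo_trace(two_proton_secular, spec)
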