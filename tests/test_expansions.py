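"""Decay-trace assembly: APPA, CCE, partial CCE, cluster factorization."""

from math import comb

import numpy as np
import pytest

from spinbath import (
    ClusterTrace,
    Partition,
    SequenceSpec,
    appa_trace,
    cce_trace,
    cf_trace,
    couplings_for_orientation,
    dressed_echo_trace,
    hahn_echo_trace,
    partition_by_methyl,
    pcce_trace,
    powder_expansion,
    reject_unstable,
    superclusters,
)
from spinbath.fixtures import make_trityl_like
from spinbath.powder import orientation_grid

from conftest import random_secular_system

TIMES = np.linspace(0.0, 20.0, 21)
BARE = SequenceSpec(mode="bare", times_us=TIMES)


class TestAppa:
    def test_pair_factor_is_one_at_t_zero(self, two_proton_secular):
        tr = appa_trace(two_proton_secular, TIMES)
        assert tr.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_modulation_depth_maximal_at_matching(self):
        # lambda = dA^2 wnn^2 / (dA^2 + wnn^2)^2 attains 1/4 iff |dA| = wnn;
        # at matching the pair factor dips to 1 - 4 lambda = 0
        def depth(da, wn):
            return da**2 * wn**2 / (da**2 + wn**2) ** 2

        assert depth(80.0, 80.0) == pytest.approx(0.25)
        grid = np.linspace(1.0, 400.0, 400)
        assert np.all(depth(grid, 80.0) <= 0.25 + 1e-12)

    def test_matches_cce2_on_random_secular_systems(self, rng, orientation):
        spec = SequenceSpec(mode="bare", times_us=TIMES, include_pseudosecular=False)
        for n in (2, 3, 4):
            s = random_secular_system(rng, n)
            cpl = couplings_for_orientation(s, orientation)
            appa = appa_trace(cpl, TIMES).values
            cce2 = cce_trace(s, 2, spec, orientation).trace.values
            assert np.max(np.abs(appa - cce2)) < 1e-6


class TestCce:
    def test_full_order_reproduces_direct_simulation(self, matched_methyl_system,
                                                     orientation):
        cpl = couplings_for_orientation(matched_methyl_system, orientation)
        direct = hahn_echo_trace(cpl, BARE).values
        res = cce_trace(matched_methyl_system, 3, BARE, orientation)
        assert np.max(np.abs(res.trace.values - direct)) < 1e-6
        assert not res.rejected

    def test_full_order_reproduces_direct_simulation_dressed(
        self, matched_methyl_system, orientation
    ):
        spec = SequenceSpec(
            mode="dressed", times_us=TIMES, omega1_MHz=100.0, Omega_S_MHz=3.0
        )
        cpl = couplings_for_orientation(matched_methyl_system, orientation)
        direct = dressed_echo_trace(cpl, spec).values
        res = cce_trace(matched_methyl_system, 3, spec, orientation)
        assert np.max(np.abs(res.trace.values - direct)) < 1e-6

    def test_order_one_secular_bare_is_unity(self, rng, orientation):
        s = random_secular_system(rng, 3)
        spec = SequenceSpec(mode="bare", times_us=TIMES, include_pseudosecular=False)
        res = cce_trace(s, 1, spec, orientation)
        assert np.allclose(res.trace.values, 1.0, atol=1e-9)

    def test_monotone_refinement_on_four_protons(self, rng, orientation):
        # |L_exact - L(o)| shrinks with o within the first decay
        s = random_secular_system(rng, 4)
        cpl = couplings_for_orientation(s, orientation)
        times = np.linspace(0.0, 15.0, 31)
        spec = SequenceSpec(mode="bare", times_us=times)
        exact = hahn_echo_trace(cpl, spec).values
        i_e = np.argmax(exact < np.exp(-1.0)) or len(times)
        errors = []
        for o in (1, 2, 3, 4):
            approx = cce_trace(s, o, spec, orientation).trace.values
            errors.append(np.max(np.abs(approx - exact)[:i_e]))
        assert errors[-1] < 1e-9  # order N is exact
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))


class TestPcce:
    def test_supercluster_counts_match_binomials(self):
        for m, s, u in ((12, 3, 3), (12, 4, 2), (6, 2, 3), (5, 2, 2)):
            part = Partition([tuple(range(s * i + 1, s * i + s + 1)) for i in range(m)])
            assert len(superclusters(part, u)) == comb(m, u)

    def test_full_coverage_reproduces_direct_simulation(self, rng, orientation):
        s = random_secular_system(rng, 4)
        # add pseudo-secular character via anisotropic tensors
        cpl = couplings_for_orientation(s, orientation)
        part = Partition([(1, 2), (3, 4)])
        direct = hahn_echo_trace(cpl, BARE).values
        res = pcce_trace(s, part, 2, BARE, orientation)
        assert np.max(np.abs(res.trace.values - direct)) < 1e-6
        assert res.supercluster_count == 1

    def test_u_one_equals_cluster_factorization(self, rng, orientation):
        s = random_secular_system(rng, 4)
        part = Partition([(1, 2), (3, 4)])
        a = pcce_trace(s, part, 1, BARE, orientation).trace.values
        b = cf_trace(s, part, BARE, orientation).trace.values
        assert np.array_equal(a, b)

    def test_invalid_u_rejected(self, rng, orientation):
        s = random_secular_system(rng, 4)
        part = Partition([(1, 2), (3, 4)])
        with pytest.raises(ValueError):
            pcce_trace(s, part, 3, BARE, orientation)


class TestCf:
    def test_single_cluster_covering_all_is_exact(self, matched_methyl_system,
                                                  orientation):
        part = partition_by_methyl(matched_methyl_system)
        cpl = couplings_for_orientation(matched_methyl_system, orientation)
        direct = hahn_echo_trace(cpl, BARE).values
        res = cf_trace(matched_methyl_system, part, BARE, orientation)
        assert np.max(np.abs(res.trace.values - direct)) < 1e-9

    def test_exact_for_non_interacting_clusters(self, rng, orientation):
        # two clusters with zeroed inter-cluster couplings factorize exactly
        s = random_secular_system(rng, 4)
        cpl = couplings_for_orientation(s, orientation)
        for i in (0, 1):
            for j in (2, 3):
                cpl.omega_nn_kHz[i, j] = cpl.omega_nn_kHz[j, i] = 0.0
                cpl.omega_zz_kHz[i, j] = cpl.omega_zz_kHz[j, i] = 0.0
        direct = hahn_echo_trace(cpl, BARE).values
        part = Partition([(1, 2), (3, 4)])
        # factorization over the pre-modified coupling set
        from spinbath.sequences import hahn_echo_trace as hahn

        prod = hahn(cpl.restrict((1, 2)), BARE).values * hahn(
            cpl.restrict((3, 4)), BARE
        ).values
        assert np.max(np.abs(prod - direct)) < 1e-9


class TestRejection:
    def test_in_range_trace_kept(self):
        tr = ClusterTrace(times_us=TIMES, values=np.linspace(1.0, 0.2, len(TIMES)))
        assert not reject_unstable(tr)

    def test_overshoot_rejected(self):
        v = np.ones(len(TIMES))
        v[5] = 1.2
        assert reject_unstable(ClusterTrace(times_us=TIMES, values=v))

    def test_negative_rejected(self):
        v = np.ones(len(TIMES))
        v[5] = -0.01
        assert reject_unstable(ClusterTrace(times_us=TIMES, values=v))

    def test_window_excludes_late_instability(self):
        v = np.ones(len(TIMES))
        v[-1] = 1.5
        tr = ClusterTrace(times_us=TIMES, values=v)
        assert reject_unstable(tr)
        assert not reject_unstable(tr, window_us=TIMES[-2])


class TestPowderExpansion:
    def test_trityl_partition_and_engine_agreement(self):
        system = make_trityl_like(n_methyls=4, seed=5)
        part = partition_by_methyl(system)
        assert part.n_clusters == 4 and part.size == 3
        grid = orientation_grid(2)
        spec = SequenceSpec(mode="bare", times_us=np.linspace(0.0, 8.0, 9))
        cf_avg, diag_cf = powder_expansion(system, spec, grid, engine="cf",
                                           partition=part)
        pcce_avg, diag_p = powder_expansion(system, spec, grid, engine="pcce",
                                            partition=part, u=2)
        assert diag_p["supercluster_count"] == comb(4, 2)
        assert 0.0 <= diag_cf["rejected_fraction"] <= 1.0
        # engines agree closely at early times on a weakly coupled ring
        assert np.max(np.abs(cf_avg.values[:5] - pcce_avg.values[:5])) < 0.05
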