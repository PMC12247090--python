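# Methods

## Physical model

The simulator treats a single electron spin S = 1/2 (a trityl-type radical
in a glassy, deuterated matrix) coupled to a bath of N proton spins
I = 1/2.  In the rotating frame, after dropping the nuclear Zeeman term
(which commutes with everything retained) and keeping only the secular and
pseudo-secular parts of the hyperfine interaction, the cluster Hamiltonian
is

    H = Omega_S S_z + sum_n A_n S_z I_nz + B_nx S_z I_nx + B_ny S_z I_ny
        + sum_{k<l} omega_zz,kl I_kz I_lz
        - sum_{k<l} (omega_nn,kl / 4) (I_k+ I_l- + I_k- I_l+)
        + omega1 S_x ,

where Omega_S is the electron resonance offset, (A_n, B_nx, B_ny) are the
orientation-projected hyperfine components, and omega1 is the mw drive
amplitude (zero for bare-spin simulations).  The frame transformation that
reduces (B_x, B_y) to a single transverse component is deliberately not
applied: it would complicate the nuclear-nuclear coupling terms, and only
the field direction enters the projections.

Methyl-group quantum rotation enters as a pairwise exchange coupling
between the three protons of a rotor.  In the high-temperature limit the
A-E tunnel splitting omega_t modifies the intra-methyl pair coefficients
to

    omega_zz = omega_dd - 2 omega_t / 3 ,
    omega_nn = omega_dd + 4 omega_t / 3 ,

while all other pairs keep the bare secular dipolar coupling
omega_dd = d_HH (1 - 3 cos^2 theta) / r^3 with d_HH/2pi = 120.1 kHz A^3
from CODATA constants.  Rotor-rotor coupling and any temperature
dependence of the tunnel splitting are neglected.

Assumptions: low radical concentration (no electron-electron
contribution), low temperature (no spatial dynamics), protons only
(deuterons of the matrix are treated as absent), ideal mw pulses for the
bare sequence.

## Units

All interfaces use cyclic frequencies — MHz for electron-related
quantities, kHz for nuclear-nuclear couplings, kJ/mol for torsional
barriers, Angstrom for geometry, microseconds for time.  Internally the
Hamiltonian builder converts to angular frequencies in rad/us; a single
conversion site avoids factor-of-2pi mistakes.

## Sequences and observables

*Bare-spin Hahn echo* (pi/2 - T/2 - pi - T/2): without the drive the
Hamiltonian is block-diagonal in the electron state, and the normalized
echo is W(T) = 2^-c Tr[U_b U_a U_b^+ U_a^+] with U_{a,b} the
half-interval bath propagators in the two electron manifolds.  This is
algebraically identical to propagating the full density operator through
the pulse sequence (a test checks this) and is what makes nine-spin
superclusters affordable.  With pseudo-secular couplings the echo
coherence carries a small genuine phase; the detected in-phase component
(the real part) is returned.  Ideal pulses refocus any resonance offset,
so Omega_S defaults to 0 in bare mode.

*Dressed-spin primary echo*: the initial state is -S_x (ideal pi/2 from
thermal -S_z).  The system evolves under the full Hamiltonian including
omega1 S_x for a settle delay (default 0.996 us, mirroring the
experiment), then a pi/2 - T/2 - pi - T/2 - pi/2 sequence of
phase-modulation (PM) pulses is applied and <-S_x> is read out,
normalized at the smallest T; the unnormalized locked amplitude is kept
on the trace (`raw_scale`).  PM pulses are by default ideal instantaneous
dressed-frame rotations exp(-i beta S_z) (the hard-pulse limit; the
rotation axis is perpendicular to the lock axis x).  An explicit model
propagates the cosine-phase-modulated drive
phi(t) = a_PM cos(omega_PM t + phi_PM) with omega_PM = omega1 and
a_PM = 0.3 in steps of at most 1/(20 omega1), with the modulation
referenced to global time so it stays phase-coherent with the dressed
precession; on resonance it reproduces the ideal trace and serves as its
validation.  Pulse durations follow the first-order dressed nutation rate
a_PM omega1 / 2.

*Empty-bath reference* W_empty(T): identically 1 in bare mode; in dressed
mode the c = 0 signal, averaged over a Gaussian resonance-offset
distribution on deterministic Gauss-Hermite nodes.  The default offset
width corresponds to a FWHM of 12 MHz, a typical trityl EPR linewidth at
Q band.  Within a CCE/pCCE assembly the c = 0 signal at the single
Omega_S of the sequence spec is used instead of the offset average:
cluster signals are computed at that one offset, and dividing them by an
offset-averaged reference would mix inconsistent quantities.

## Expansion engines

* APPA: product over all proton pairs of the closed-form two-proton Hahn
  modulation factor with modulation depth
  lambda = dA^2 omega_nn^2 / (dA^2 + omega_nn^2)^2 and zero-quantum
  frequency omega_zq = sqrt(dA^2 + omega_nn^2)/2.  Identical to CCE-2
  when only secular hyperfine couplings are retained (tested to 1e-6).
* CCE-o: all clusters up to size o are simulated; each cluster signal is
  divided by the product of all proper-subcluster tilde factors and the
  empty-bath signal.  Tilde factors are computed in increasing cluster
  size and memoized.  The expansion telescopes to the exact signal at
  o = N.
* pCCE(s, u*s): the bath is partitioned into disjoint clusters of size s
  (a helper builds one cluster per methyl group; the optimal partitioning
  of generic baths is an open problem, so partitions are user-supplied).
  Each cluster signal is corrected for the empty-bath signal only, and
  inter-cluster correlations are kept within each of the C(M, u)
  superclusters.  u = 1 is cluster factorization, u = M is exact on the
  covered protons.
* CF: the u = 1 special case, exposed by name.

Numerical safeguards: all propagation uses the cached eigendecomposition
U(t) = V exp(-i Lambda t) V^+ rather than Pade-type matrix exponentials,
and expansion divisions are floored at 1e-10 — a division that hits the
floor flags the cluster rather than silently patching the trace.  A whole
orientation is rejected when its assembled normalized signal becomes
negative or exceeds 1.1 within the comparison window, and the powder
average renormalizes the surviving weights and reports the rejected
fraction.  The floor value is this package's choice; rejection thresholds
(0 and 1.1) follow established practice for unstable CCE orientations.

## Torsional solver

The barrier-to-tunnel-splitting map diagonalizes
H = -B d^2/dphi^2 + V3 [cos(3 phi) + 1]/2 in a free-rotor plane-wave
basis partitioned by symmetry (A: m = 0 mod 3; E: m = 1 mod 3), each
block tridiagonal.  The default rotational constant B = 158.4 GHz
(~5.3 cm^-1) comes from a rigid CH3 with C-H = 1.09 A and tetrahedral
angles; it is configurable.  The basis is doubled until the splitting
changes by less than 1e-6 relative — or by less than the double-precision
eigenvalue noise floor (machine epsilon times the spectral norm of the
truncated Hamiltonian), which for barriers above ~15 kJ/mol is the
binding limit because the A-E gap lies ten orders of magnitude below the
zero-point energy scale.  With the default B, barriers of 15.8 and
20.0 kJ/mol map to 55.1 and 4.7 kHz.  The phase phi0 of the barrier fit
function shifts the potential origin only and is ignored by the solver.
An independent periodic finite-difference diagonalization serves as the
test oracle (2 % agreement).

## Orientation grids and powder averaging

Hemispherical grids with k knots place rings at theta = 90 (i-1)/(k-1)
degrees, one orientation at the pole and 4(i-1) per ring otherwise —
2k(k-1)+1 orientations in total (9 knots -> 145, 7 -> 85, 23 -> 1013).
Ring weights are the solid angles of the theta bands, split equally among
the ring's points; the reference grids' exact weights are not public, so
sub-percent differences from other implementations are expected.  The
hemisphere suffices because the Hamiltonian depends on the field
direction only up to inversion.

## Synthetic fixtures

The generator emulates a trityl-like core: an even number of rigid methyl
fragments placed as geminal pairs above and below a ring around the
electron (default radius 4.5 A), point-dipole hyperfine tensors
(d_eH/2pi = 79.06 MHz A^3), and alternating tunnel splittings of 4.8 and
54.5 kHz for the two barrier classes of the inner and outer methyls.
What it does not emulate: real DFT hyperfine tensors (including isotropic
contact contributions and tensor tilts), side-chain conformational
distributions, methylene/matrix protons, and g anisotropy.  Tests passing
on these fixtures therefore validate the machinery — couplings,
sequences, expansions, averaging — not quantitative agreement with any
measured decay curve.

## Problem sizes in the test suite

The suite exercises full-order oracle equivalences on 3-4 proton systems
(where CCE and pCCE are exact by construction), pair-level analytics
against closed forms, and an end-to-end powder run on a 12-proton
(4-methyl) fixture with cluster factorization and pCCE(3,6)/pCCE(3,9),
using a 2-knot grid and 25 time points out to 12 us.  These sizes were
chosen so the whole suite runs in minutes on one core while still
covering every assembly path; larger baths (24-48 protons, 85-1013
orientations) use the same code paths and only cost more time.

## Known limitations

* Dressed-mode CCE beyond order ~3 inherits the documented numerical
  instability of repeated signal divisions; the rejection machinery
  reports, but does not cure, this.
* The torsional solver's accuracy saturates at the double-precision noise
  floor (absolute error ~1e-4 kHz at the default B); barriers beyond
  ~35 kJ/mol give splittings below that floor.
* The explicit PM pulse model uses the first-order nutation rate for its
  duration; higher-order (Bloch-Siegert-type) corrections shift effective
  flip angles by a few percent, visible as a slightly reduced locked
  amplitude.
* No relaxation superoperators, no finite-duration bare-sequence pulses,
  no nuclei with I > 1/2, no instantaneous diffusion.
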