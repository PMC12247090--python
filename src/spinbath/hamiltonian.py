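"""Cluster Hamiltonians and eigenbasis propagation.

A cluster of c protons plus the electron lives in a 2^(c+1)-dimensional
Hilbert space ordered electron (x) proton_1 (x) ... (x) proton_c, each spin
in {alpha, beta}.  Hamiltonians are stored in angular-frequency units of
rad/us; all propagation goes through the cached eigendecomposition
U(t) = V exp(-i Lambda t) V^dagger, which is markedly more stable than
Pade-type matrix exponentials when many cluster signals are multiplied and
divided.
"""

from __future__ import annotations

import numpy as np

from .constants import KHZ_TO_RAD_PER_US, MHZ_TO_RAD_PER_US
from .spin_system import CouplingSet

__all__ = [
    "ClusterHamiltonian",
    "build_cluster_hamiltonian",
    "propagate",
    "propagator",
    "ideal_pulse",
    "electron_op",
    "spin_half_ops",
]

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
_SP = np.array([[0, 1.0], [0, 0]], dtype=complex)
_SM = np.array([[0, 0], [1.0, 0]], dtype=complex)
_PAULI = {"x": _SX, "y": _SY, "z": _SZ, "+": _SP, "-": _SM}


def spin_half_ops(site: int, n_spins: int, which: str) -> np.ndarray:
    """Operator ``which`` in {x,y,z,+,-} on ``site`` of an n-spin register."""
    op = np.array([[1.0]], dtype=complex)
    for k in range(n_spins):
        op = np.kron(op, _PAULI[which] if k == site else np.eye(2))
    return op


def electron_op(which: str, n_bath: int) -> np.ndarray:
    """Electron operator (site 0) in a space with ``n_bath`` protons."""
    return spin_half_ops(0, n_bath + 1, which)


class ClusterHamiltonian:
    """Hermitian Hamiltonian (rad/us) with a lazily cached eigendecomposition."""

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("Hamiltonian must be square")
        dim = m.shape[0]
        if dim & (dim - 1) != 0:
            raise ValueError("Hamiltonian dimension must be a power of 2")
        scale = max(np.linalg.norm(m), 1.0)
        if np.linalg.norm(m - m.conj().T) > 1e-10 * scale:
            raise ValueError("Hamiltonian is not Hermitian")
        self.matrix = 0.5 * (m + m.conj().T)
        self._evals = None
        self._evecs = None

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_protons(self) -> int:
        return int(np.log2(self.dim)) - 1

    def eig(self):
        if self._evals is None:
            self._evals, self._evecs = np.linalg.eigh(self.matrix)
        return self._evals, self._evecs

    def propagator(self, t_us: float) -> np.ndarray:
        vals, vecs = self.eig()
        phases = np.exp(-1j * vals * t_us)
        return (vecs * phases) @ vecs.conj().T

    def to_eigenbasis(self, op: np.ndarray) -> np.ndarray:
        _, vecs = self.eig()
        return vecs.conj().T @ op @ vecs


def build_cluster_hamiltonian(
    couplings: CouplingSet,
    Omega_S_MHz: float = 0.0,
    omega1_MHz: float = 0.0,
    include_pseudosecular: bool = True,
) -> ClusterHamiltonian:
    """Assemble the cluster Hamiltonian in rad/us.

    H = Omega_S S_z + sum_n A_n S_z I_nz (+ B_nx S_z I_nx + B_ny S_z I_ny)
        + sum_{k<l} omega_zz,kl I_kz I_lz
        - sum_{k<l} (omega_nn,kl / 4)(I_k+ I_l- + I_k- I_l+)
        + omega1 S_x

    The nuclear Zeeman term commutes with everything retained here and is
    omitted.  A cluster of size 0 gives the bare (dressed) electron
    two-level system.
    """
    c = couplings.n
    n_spins = c + 1
    dim = 2**n_spins
    h = np.zeros((dim, dim), dtype=complex)

    # basis states as bit patterns: site 0 (electron) is the most
    # significant bit, bit 0 = |alpha> (m = +1/2); all couplings below are
    # filled by index arithmetic instead of Kronecker-product algebra
    idx = np.arange(dim)
    bit_pos = np.arange(n_spins - 1, -1, -1)
    m = 0.5 - ((idx[:, None] >> bit_pos[None, :]) & 1)  # spin projections
    m_e = m[:, 0]

    diag = Omega_S_MHz * MHZ_TO_RAD_PER_US * m_e
    for n in range(c):
        diag = diag + couplings.A_MHz[n] * MHZ_TO_RAD_PER_US * m_e * m[:, n + 1]
    for k in range(c):
        for l in range(k + 1, c):
            zz = couplings.omega_zz_kHz[k, l] * KHZ_TO_RAD_PER_US
            if zz:
                diag = diag + zz * m[:, k + 1] * m[:, l + 1]
    h[idx, idx] = diag

    if omega1_MHz:
        j = idx ^ (1 << bit_pos[0])
        h[idx, j] += 0.5 * omega1_MHz * MHZ_TO_RAD_PER_US

    if include_pseudosecular:
        for n in range(c):
            bx = couplings.B_MHz[n, 0] * MHZ_TO_RAD_PER_US
            by = couplings.B_MHz[n, 1] * MHZ_TO_RAD_PER_US
            if bx or by:
                j = idx ^ (1 << bit_pos[n + 1])
                # <b|I_x|1-b> = 1/2, <b|I_y|1-b> = -i m_n(row)
                h[idx, j] += m_e * (0.5 * bx - 1j * by * m[:, n + 1])

    for k in range(c):
        for l in range(k + 1, c):
            nn = couplings.omega_nn_kHz[k, l] * KHZ_TO_RAD_PER_US
            if nn:
                anti = m[:, k + 1] != m[:, l + 1]
                j = idx[anti] ^ (1 << bit_pos[k + 1]) ^ (1 << bit_pos[l + 1])
                h[idx[anti], j] += -0.25 * nn
    return ClusterHamiltonian(h)


def propagator(h: ClusterHamiltonian, t_us: float) -> np.ndarray:
    """Unitary propagator exp(-i H t) from the cached eigendecomposition."""
    return h.propagator(t_us)


def propagate(h: ClusterHamiltonian, rho0: np.ndarray, t_us: float) -> np.ndarray:
    """Evolve a density (or deviation) operator: rho(t) = U rho0 U^dagger."""
    rho0 = np.asarray(rho0, dtype=complex)
    scale = max(np.linalg.norm(rho0), 1.0)
    if np.linalg.norm(rho0 - rho0.conj().T) > 1e-10 * scale:
        raise ValueError("initial operator must be Hermitian")
    u = h.propagator(t_us)
    return u @ rho0 @ u.conj().T


def _rotation(axis: str, angle: float, n_bath: int) -> np.ndarray:
    """exp(-i angle S_axis) on the electron; closed form for spin 1/2."""
    pauli2 = 2.0 * _PAULI[axis]  # Pauli matrix
    r2 = np.cos(angle / 2) * np.eye(2) - 1j * np.sin(angle / 2) * pauli2
    return np.kron(r2, np.eye(2**n_bath))


def ideal_pulse(rho: np.ndarray, axis: str, angle: float, n_bath: int = None) -> np.ndarray:
    """Ideal instantaneous electron pulse: rho -> R rho R^dagger.

    ``axis`` is x, y or z in the rotating frame; ``angle`` in rad.  The
    number of bath spins is inferred from the operator dimension when not
    given.
    """
    rho = np.asarray(rho, dtype=complex)
    if n_bath is None:
        n_bath = int(np.log2(rho.shape[0])) - 1
    if axis not in ("x", "y", "z"):
        raise ValueError("pulse axis must be x, y or z")
    if not np.isfinite(angle):
        raise ValueError("pulse angle must be finite")
    r = _rotation(axis, angle, n_bath)
    return r @ rho @ r.conj().T
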