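"""Domain model of a central electron spin coupled to a proton bath.

The structural description (proton coordinates in Angstrom, 3x3 hyperfine
tensors in MHz, methyl-group membership with tunnel splittings in kHz) is
converted, for one orientation of the external field in the molecular
frame, into the scalar coupling constants that enter the secular /
pseudo-secular spin Hamiltonian: per-proton (A_n, B_nx, B_ny) in MHz and
per-pair (omega_zz, omega_nn) in kHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import D_HH_KHZ_A3
from . import tunneling

__all__ = [
    "HyperfineTensor",
    "Proton",
    "MethylGroup",
    "SpinSystem",
    "Orientation",
    "CouplingSet",
    "dipolar_coupling",
    "project_hyperfine",
    "couplings_for_orientation",
    "field_direction",
    "lab_axes",
]


class HyperfineTensor:
    """3x3 hyperfine tensor in MHz, molecular frame.

    Only the symmetric part enters the secular/pseudo-secular projections;
    an antisymmetric component in the input is discarded with a warning.
    """

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"hyperfine tensor must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("hyperfine tensor entries must be finite")
        asym = 0.5 * (m - m.T)
        scale = max(np.linalg.norm(m), 1.0)
        if np.linalg.norm(asym) > 1e-10 * scale:
            warnings.warn(
                "hyperfine tensor has an antisymmetric component; "
                "it is discarded (only the symmetric part couples here)",
                stacklevel=2,
            )
        self.matrix = 0.5 * (m + m.T)

    @classmethod
    def isotropic(cls, a_iso_MHz: float) -> "HyperfineTensor":
        return cls(a_iso_MHz * np.eye(3))

    def __repr__(self):  # pragma: no cover
        return f"HyperfineTensor({self.matrix.tolist()})"


@dataclass
class Proton:
    """A bath proton: integer id, position (Angstrom), hyperfine tensor."""

    id: int
    position: np.ndarray
    tensor: HyperfineTensor

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("proton position must be a finite 3-vector")


@dataclass
class MethylGroup:
    """Three protons undergoing quantum rotation with tunnel splitting.

    ``tunnel_kHz`` is the A-E torsional ground-state splitting expressed as
    a cyclic frequency in kHz (omega_t / 2 pi).
    """

    proton_ids: tuple
    tunnel_kHz: float

    def __post_init__(self):
        ids = tuple(int(i) for i in self.proton_ids)
        if len(ids) != 3 or len(set(ids)) != 3:
            raise ValueError("a methyl group needs exactly 3 distinct proton ids")
        self.proton_ids = ids
        if not (self.tunnel_kHz >= 0):
            raise ValueError("tunnel splitting must be non-negative")


@dataclass
class SpinSystem:
    """Electron spin S=1/2 plus N protons, some grouped into methyl rotors.

    ``offset_sigma_MHz`` is the standard deviation of the Gaussian electron
    resonance-offset distribution (g anisotropy + unresolved couplings).
    The default corresponds to a FWHM of about 12 MHz, typical of a trityl
    radical at Q band.
    """

    protons: list
    methyls: list = field(default_factory=list)
    electron_position: np.ndarray = None
    offset_sigma_MHz: float = 12.0 / 2.3548200450309493  # FWHM 12 MHz

    def __post_init__(self):
        if self.electron_position is None:
            self.electron_position = np.zeros(3)
        self.electron_position = np.asarray(self.electron_position, dtype=float)
        if len(self.protons) < 1:
            raise ValueError("a spin system needs at least one proton")
        ids = [p.id for p in self.protons]
        if len(set(ids)) != len(ids):
            raise ValueError("proton ids must be unique")
        id_set = set(ids)
        seen = set()
        for m in self.methyls:
            for pid in m.proton_ids:
                if pid not in id_set:
                    raise ValueError(f"methyl references unknown proton id {pid}")
                if pid in seen:
                    raise ValueError(f"proton {pid} belongs to two methyl groups")
                seen.add(pid)

    @property
    def n_protons(self) -> int:
        return len(self.protons)

    @property
    def proton_ids(self):
        return tuple(p.id for p in self.protons)

    def index_of(self, proton_id: int) -> int:
        for i, p in enumerate(self.protons):
            if p.id == proton_id:
                return i
        raise KeyError(f"unknown proton id {proton_id}")

    def methyl_membership(self) -> dict:
        """Map proton id -> methyl index (only for methyl protons)."""
        out = {}
        for mi, m in enumerate(self.methyls):
            for pid in m.proton_ids:
                out[pid] = mi
        return out


@dataclass
class Orientation:
    """Direction of the external field in the molecular frame, with weight."""

    theta_deg: float
    phi_deg: float
    weight: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ValueError("theta must lie in [0, 90] degrees (hemisphere)")
        if not (0.0 <= self.phi_deg < 360.0):
            raise ValueError("phi must lie in [0, 360) degrees")
        if self.weight < 0:
            raise ValueError("orientation weight must be non-negative")


def field_direction(orientation: Orientation) -> np.ndarray:
    """Unit vector of the lab field (z) axis in the molecular frame."""
    th = np.deg2rad(orientation.theta_deg)
    ph = np.deg2rad(orientation.phi_deg)
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def lab_axes(orientation: Orientation) -> np.ndarray:
    """Rows are the lab x, y, z axes expressed in the molecular frame.

    The rotation is the ZYZ Euler convention (phi, theta, 0): lab z is the
    field direction, lab y lies in the molecular xy plane.
    """
    th = np.deg2rad(orientation.theta_deg)
    ph = np.deg2rad(orientation.phi_deg)
    z = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    x = np.array([np.cos(th) * np.cos(ph), np.cos(th) * np.sin(ph), -np.sin(th)])
    y = np.array([-np.sin(ph), np.cos(ph), 0.0])
    return np.vstack([x, y, z])


def dipolar_coupling(r_vec, field_dir) -> float:
    """Secular homonuclear dipolar coupling omega_dd/2pi in kHz.

    ``r_vec`` is the proton-proton displacement in Angstrom and
    ``field_dir`` the unit field direction.  Returns
    d_HH (1 - 3 cos^2 theta) / r^3 with d_HH = 120.1 kHz A^3.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r <= 0.5:
        raise ValueError(
            f"proton-proton distance {r:.3f} A is below 0.5 A; "
            "coincident or unphysically close protons"
        )
    n = np.asarray(field_dir, dtype=float)
    n = n / np.linalg.norm(n)
    cos_t = np.dot(r_vec, n) / r
    return D_HH_KHZ_A3 * (1.0 - 3.0 * cos_t**2) / r**3


def project_hyperfine(tensor: HyperfineTensor, orientation: Orientation):
    """Project a hyperfine tensor onto one field orientation.

    Returns (A, B_x, B_y) in MHz: the secular coupling A = z.T@A@z and the
    two pseudo-secular components B_x = x.T@A@z, B_y = y.T@A@z in the lab
    frame defined by the orientation.
    """
    axes = lab_axes(orientation)
    t = tensor.matrix
    az = t @ axes[2]
    return float(axes[2] @ az), float(axes[0] @ az), float(axes[1] @ az)


@dataclass
class CouplingSet:
    """All scalar couplings of a system at one orientation.

    ``A_MHz``/``B_MHz`` are per-proton secular and pseudo-secular hyperfine
    couplings; ``omega_zz_kHz``/``omega_nn_kHz`` are symmetric per-pair
    matrices holding the Ising and flip-flop coupling coefficients with the
    methyl-tunnel substitution already applied (same-methyl pairs carry
    omega_dd - 2 omega_t/3 and omega_dd + 4 omega_t/3).
    """

    proton_ids: tuple
    A_MHz: np.ndarray
    B_MHz: np.ndarray  # shape (N, 2): columns B_x, B_y
    omega_zz_kHz: np.ndarray
    omega_nn_kHz: np.ndarray
    orientation: Orientation = None

    @property
    def n(self) -> int:
        return len(self.proton_ids)

    def restrict(self, proton_ids) -> "CouplingSet":
        """Sub-CouplingSet for a cluster of protons, by id."""
        try:
            idx = [self.proton_ids.index(pid) for pid in proton_ids]
        except ValueError as exc:
            raise KeyError(f"cluster references unknown proton id: {exc}") from exc
        idx = np.asarray(idx, dtype=int)
        return CouplingSet(
            proton_ids=tuple(proton_ids),
            A_MHz=self.A_MHz[idx],
            B_MHz=self.B_MHz[idx],
            omega_zz_kHz=self.omega_zz_kHz[np.ix_(idx, idx)],
            omega_nn_kHz=self.omega_nn_kHz[np.ix_(idx, idx)],
            orientation=self.orientation,
        )


def couplings_for_orientation(system: SpinSystem, orientation: Orientation) -> CouplingSet:
    """Assemble the full CouplingSet of a system at one field orientation."""
    n = system.n_protons
    A = np.zeros(n)
    B = np.zeros((n, 2))
    for i, p in enumerate(system.protons):
        A[i], B[i, 0], B[i, 1] = project_hyperfine(p.tensor, orientation)

    membership = system.methyl_membership()
    n_dir = field_direction(orientation)
    zz = np.zeros((n, n))
    nn = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r_vec = system.protons[j].position - system.protons[i].position
            w_dd = dipolar_coupling(r_vec, n_dir)
            mi = membership.get(system.protons[i].id)
            mj = membership.get(system.protons[j].id)
            same = mi is not None and mi == mj
            w_t = system.methyls[mi].tunnel_kHz if same else 0.0
            w_zz, w_nn = tunneling.combine_couplings(w_dd, w_t, same)
            zz[i, j] = zz[j, i] = w_zz
            nn[i, j] = nn[j, i] = w_nn
    return CouplingSet(
        proton_ids=system.proton_ids,
        A_MHz=A,
        B_MHz=B,
        omega_zz_kHz=zz,
        omega_nn_kHz=nn,
        orientation=orientation,
    )
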