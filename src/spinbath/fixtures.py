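"""Synthetic spin-system generators.

These build methyl-group and trityl-like geometries with point-dipole
hyperfine tensors so that every engine can be exercised without any
electronic-structure input.  Geometries are idealized: rigid CH3 fragments
with tetrahedral angles, methyls arranged on a ring around the electron,
alternating between an inner (high-barrier, small tunnel splitting) and an
outer (low-barrier, large tunnel splitting) class as in a Finland-trityl
core.
"""

from __future__ import annotations

import numpy as np

from .constants import D_EH_MHZ_A3, TETRAHEDRAL_ANGLE
from .spin_system import HyperfineTensor, MethylGroup, Proton, SpinSystem

__all__ = [
    "make_methyl",
    "point_dipole_tensor",
    "make_trityl_like",
    "make_random_bath",
]


def _orthonormal_frame(axis: np.ndarray) -> tuple:
    """Two unit vectors orthogonal to ``axis`` (deterministic choice)."""
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm < 1e-12:
        raise ValueError("methyl axis must be a non-zero vector")
    a = a / norm
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(a, ref)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return a, u, v


def make_methyl(
    center,
    axis,
    r_CH: float = 1.09,
    tunnel_kHz: float = 0.0,
    start_id: int = 1,
    phase_deg: float = 0.0,
    electron_position=None,
) -> tuple:
    """Three methyl protons around ``center`` (the carbon), plus the group.

    The three H sit at the tetrahedral angle from ``axis`` (the C->C bond
    direction), 120 degrees apart; ``phase_deg`` rotates the fragment
    about its axis.  Hyperfine tensors are point-dipole from
    ``electron_position`` when given, otherwise zero (to be filled in by
    the caller).  Returns (list of Proton, MethylGroup).
    """
    if not (0.9 <= r_CH <= 1.3):
        raise ValueError("C-H bond length must lie in [0.9, 1.3] Angstrom")
    center = np.asarray(center, dtype=float)
    a, u, v = _orthonormal_frame(axis)
    # H-C-axis angle is tetrahedral; protons point away from the axis
    cos_t = np.cos(np.pi - TETRAHEDRAL_ANGLE)
    sin_t = np.sin(np.pi - TETRAHEDRAL_ANGLE)
    protons = []
    for k in range(3):
        ang = np.deg2rad(phase_deg + 120.0 * k)
        direction = -cos_t * a + sin_t * (np.cos(ang) * u + np.sin(ang) * v)
        pos = center + r_CH * direction
        if electron_position is not None:
            tensor = point_dipole_tensor(pos - np.asarray(electron_position, float))
        else:
            tensor = HyperfineTensor(np.zeros((3, 3)))
        protons.append(Proton(id=start_id + k, position=pos, tensor=tensor))
    group = MethylGroup(tuple(p.id for p in protons), tunnel_kHz)
    return protons, group


def point_dipole_tensor(r_vec) -> HyperfineTensor:
    """Point-dipole electron-proton hyperfine tensor, MHz.

    T = d_eH (3 n n^T - 1) / r^3, traceless and axial with eigenvalues in
    ratio (2, -1, -1).  Invalid below 2 Angstrom, where spin density
    delocalization makes the point-dipole picture meaningless.
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r < 2.0:
        raise ValueError(
            f"electron-proton distance {r:.2f} A too short for a point-dipole tensor"
        )
    n = r_vec / r
    return HyperfineTensor(D_EH_MHZ_A3 * (3.0 * np.outer(n, n) - np.eye(3)) / r**3)


def make_trityl_like(
    n_methyls: int = 12,
    ring_radius: float = 4.5,
    tunnel_inner_kHz: float = 4.8,
    tunnel_outer_kHz: float = 54.5,
    seed: int = 0,
    offset_sigma_MHz: float = 12.0 / 2.3548200450309493,
) -> SpinSystem:
    """Trityl-core-like fixture: methyls on a ring around the electron.

    ``n_methyls`` methyl fragments (must be even) are placed as geminal
    pairs above and below the ring plane on n_methyls/2 sites at
    ``ring_radius`` Angstrom from the electron at the origin, axes tilted
    radially outward.  The two methyls of each pair take the inner and
    outer tunnel splittings, mirroring the two barrier classes of a
    Finland-trityl core (defaults 4.8 and 54.5 kHz).  Hyperfine tensors
    are point-dipole.  The azimuthal phase of each methyl about its own
    axis is drawn reproducibly from ``seed``.
    """
    if n_methyls < 2 or n_methyls % 2:
        raise ValueError("n_methyls must be a positive even number")
    rng = np.random.default_rng(seed)
    z_off = 1.5  # Angstrom, geminal displacement out of plane
    protons: list = []
    methyls: list = []
    n_sites = n_methyls // 2
    for m in range(n_methyls):
        site, updown = divmod(m, 2)
        sign = 1.0 if updown == 0 else -1.0
        ang = 2 * np.pi * site / n_sites
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        center = ring_radius * radial + np.array([0.0, 0.0, sign * z_off])
        axis = radial + np.array([0.0, 0.0, sign * 0.8])
        tunnel = tunnel_inner_kHz if updown == 0 else tunnel_outer_kHz
        frag, group = make_methyl(
            center,
            axis,
            tunnel_kHz=tunnel,
            start_id=3 * m + 1,
            phase_deg=float(rng.uniform(0, 360)),
            electron_position=np.zeros(3),
        )
        protons.extend(frag)
        methyls.append(group)
    _check_no_overlap(protons)
    return SpinSystem(
        protons=protons,
        methyls=methyls,
        electron_position=np.zeros(3),
        offset_sigma_MHz=offset_sigma_MHz,
    )


def _check_no_overlap(protons, min_dist: float = 1.0):
    pos = np.array([p.position for p in protons])
    n = len(pos)
    for i in range(n):
        d = np.linalg.norm(pos[i + 1 :] - pos[i], axis=1)
        if d.size and d.min() < min_dist:
            raise ValueError(
                f"overlapping fragments: proton-proton distance {d.min():.2f} A "
                f"below {min_dist} A"
            )


def make_random_bath(
    n_protons: int,
    r_min: float = 3.0,
    r_max: float = 8.0,
    seed: int = None,
    offset_sigma_MHz: float = 12.0 / 2.3548200450309493,
) -> SpinSystem:
    """Random proton bath in a spherical shell around the electron.

    Positions are drawn uniformly in the shell [r_min, r_max] Angstrom
    (resampling any pair closer than 1.5 Angstrom); tensors are
    point-dipole.  A seed is mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("a seed is required for random bath generation")
    rng = np.random.default_rng(seed)
    positions: list = []
    attempts = 0
    while len(positions) < n_protons:
        attempts += 1
        if attempts > 10000 * n_protons:
            raise RuntimeError("could not place protons without overlap")
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        r = (rng.uniform(r_min**3, r_max**3)) ** (1.0 / 3.0)
        pos = r * v
        if all(np.linalg.norm(pos - q) >= 1.5 for q in positions):
            positions.append(pos)
    protons = [
        Proton(id=i + 1, position=p, tensor=point_dipole_tensor(p))
        for i, p in enumerate(positions)
    ]
    return SpinSystem(
        protons=protons, methyls=[], offset_sigma_MHz=offset_sigma_MHz
    )
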