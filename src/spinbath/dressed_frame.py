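"""Analytical dressed-spin quantities.

For each nuclear spin configuration c the secular hyperfine couplings add
up to a local field Delta_omega_hfi,c that tilts the electron quantization
axis away from the spin-lock direction by 90 deg - theta_c, with
theta_c = arctan(-omega1 / (Omega_S + Delta_omega_hfi,c)).  These closed
forms quantify hyperfine decoupling (the collapse of the effective
splitting A_eff,c under on-resonance irradiation) and the spin-locked
fraction f_slow = sum_c sin(theta_c) / 2^N, and serve as independent
diagnostics for the numerical engines.

All frequency arguments are cyclic (MHz); the formulas are homogeneous of
degree zero or one, so no angular-frequency conversion is needed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hyperfine_field",
    "tilt_angle",
    "effective_splitting",
    "slow_fraction",
    "NuclearConfiguration",
]

#: a nuclear configuration is simply a sequence of magnetic quantum
#: numbers +-1/2, one per proton
NuclearConfiguration = np.ndarray


def hyperfine_field(config, A_MHz) -> float:
    """Total secular hyperfine field of a configuration, MHz.

    Delta_omega_hfi,c = sum_n A_n m_I,n with m_I,n in {+1/2, -1/2}.
    """
    config = np.asarray(config, dtype=float)
    A = np.asarray(A_MHz, dtype=float)
    if config.shape != A.shape:
        raise ValueError("configuration and coupling list must have equal length")
    if config.size and not np.all(np.isin(config, (0.5, -0.5))):
        raise ValueError("magnetic quantum numbers must be +-1/2")
    return float(np.sum(A * config))


def tilt_angle(Omega_S_MHz: float, delta_hfi_MHz: float, omega1_MHz: float) -> float:
    """Tilt angle theta_c of the dressed quantization axis, degrees.

    theta_c = arctan(-omega1 / (Omega_S + Delta_omega_hfi,c)), with the
    branch chosen in (0, 180) deg so that theta_c passes continuously
    through 90 deg when the effective offset crosses zero.
    """
    denom = Omega_S_MHz + delta_hfi_MHz
    if omega1_MHz == 0.0 and denom == 0.0:
        raise ValueError("tilt angle undefined for omega1 = 0 at zero offset")
    theta = np.degrees(np.arctan2(omega1_MHz, denom))
    return float(theta)


def effective_splitting(
    Omega_S_MHz: float, delta_hfi_MHz: float, omega1_MHz: float
) -> float:
    """Residual hyperfine splitting of the dressed electron spin, MHz.

    A_eff,c = sqrt((Omega_S + d)^2 + omega1^2) - sqrt((Omega_S - d)^2 + omega1^2)
    with d = Delta_omega_hfi,c.  Vanishes for on-resonance irradiation and
    reduces to 2 d for omega1 = 0, Omega_S > d > 0 — the hyperfine
    decoupling effect of the mw field.
    """
    o, d, w = Omega_S_MHz, delta_hfi_MHz, omega1_MHz
    return float(np.hypot(o + d, w) - np.hypot(o - d, w))


def _hyperfine_field_distribution(A_MHz: np.ndarray) -> np.ndarray:
    """All 2^N values of Delta_omega_hfi,c (exact enumeration)."""
    fields = np.zeros(1)
    for a in A_MHz:
        fields = np.concatenate([fields + a / 2.0, fields - a / 2.0])
    return fields


def slow_fraction(
    A_MHz,
    Omega_S_MHz: float,
    omega1_MHz: float,
    max_exact: int = 20,
    n_samples: int = None,
    seed: int = None,
) -> float:
    """Long-lived (spin-locked) fraction f_slow = sum_c sin(theta_c) / 2^N.

    Enumerates all 2^N nuclear configurations for N <= ``max_exact``; for
    larger baths a seeded Monte Carlo sample over configurations must be
    requested explicitly via ``n_samples``.
    """
    A = np.asarray(A_MHz, dtype=float)
    n = len(A)
    if n > max_exact:
        if n_samples is None:
            raise ValueError(
                f"exact enumeration limited to {max_exact} protons; "
                "pass n_samples (and a seed) for Monte Carlo evaluation"
            )
        rng = np.random.default_rng(seed)
        signs = rng.choice((-0.5, 0.5), size=(n_samples, n))
        fields = signs @ A
    else:
        fields = _hyperfine_field_distribution(A)
    denom = Omega_S_MHz + fields
    theta = np.arctan2(omega1_MHz, denom)
    return float(np.mean(np.sin(theta)))
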