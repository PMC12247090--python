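import numpy as np
import pytest

from spinbath import (
    CouplingSet,
    HyperfineTensor,
    MethylGroup,
    Orientation,
    Proton,
    SpinSystem,
)
from spinbath.fixtures import make_methyl


@pytest.fixture
def orientation():
    return Orientation(40.0, 70.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_proton_secular():
    """Two protons with secular hyperfine and a flip-flop coupling."""
    return CouplingSet(
        proton_ids=(1, 2),
        A_MHz=np.array([1.3, 0.9]),
        B_MHz=np.zeros((2, 2)),
        omega_zz_kHz=np.array([[0.0, 30.0], [30.0, 0.0]]),
        omega_nn_kHz=np.array([[0.0, 80.0], [80.0, 0.0]]),
    )


@pytest.fixture
def matched_methyl_system():
    """A tunnelling methyl whose hyperfine differences (~0.1 MHz) are
    comparable to the tunnel-enhanced flip-flop couplings (~0.1 MHz), the
    matching condition for deep nuclear-pair modulation."""
    protons, group = make_methyl([0, 0, 0], [0, 0, 1], tunnel_kHz=54.5)
    for p, a in zip(protons, (0.30, 0.20, 0.10)):
        p.tensor = HyperfineTensor(a * np.eye(3))
    return SpinSystem(protons=protons, methyls=[group])


def random_secular_system(rng, n):
    """Random bath with isotropic (purely secular) hyperfine tensors."""
    protons = [
        Proton(
            id=k + 1,
            position=rng.normal(0.0, 3.0, 3),
            tensor=HyperfineTensor(rng.normal(0.0, 2.0) * np.eye(3)),
        )
        for k in range(n)
    ]
    return SpinSystem(protons=protons)
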