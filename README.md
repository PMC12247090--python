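# spinbath

Electron-spin decoherence in proton spin baths: bare-spin Hahn echo decay
and dressed-spin (spin-locked) primary echo decay, with methyl-group
quantum tunnelling treated as a proton exchange coupling.

## Who this is for

Pulsed-EPR and DNP practitioners who want to predict how the
intramolecular protons of a radical — for example the 36 methyl protons
in a Finland-trityl core — limit the phase-memory time T_m of a Hahn echo
and the rotating-frame decoherence time T_2rho of an electron spin
dressed by continuous microwave irradiation.

## Model

A central electron spin S = 1/2 couples to N protons I = 1/2 through the
rotating-frame Hamiltonian

    H = Omega_S S_z + sum_n (A_n S_z I_nz + B_nx S_z I_nx + B_ny S_z I_ny)
        + sum_{k<l} omega_zz,kl I_kz I_lz
        - sum_{k<l} (omega_nn,kl/4)(I_k+ I_l- + I_k- I_l+) + omega1 S_x .

Tunnelling of a methyl rotor with A-E splitting omega_t acts as a
pairwise exchange coupling between its three protons, shifting the
intra-methyl pair coefficients to omega_zz = omega_dd - 2 omega_t/3 and
omega_nn = omega_dd + 4 omega_t/3.  Echo decays are assembled from
cluster simulations by four engines:

* **APPA** — analytical pair product: W(T) = prod_{k<l} W_kl(T) with the
  closed-form two-proton modulation factor (depth
  lambda = dA^2 w_nn^2/(dA^2+w_nn^2)^2, zero-quantum frequency
  sqrt(dA^2+w_nn^2)/2);
* **CCE-o** — cluster correlation expansion with subcluster tilde-factor
  division, exact at o = N;
* **pCCE(s, u·s)** — partial CCE over a disjoint partition (for example
  one cluster per methyl group), keeping inter-cluster correlations
  within C(M, u) superclusters;
* **CF** — plain cluster factorization (pCCE with u = 1).

Powder averages run over deterministic hemispherical grids
(2k(k-1)+1 orientations for k knots) with automatic rejection of
orientations whose normalized signal leaves [0, 1.1] — the documented
instability of CCE-type divisions at long times.

A hindered-rotor solver maps threefold barrier heights V3 to tunnel
splittings by diagonalizing −B d²/dφ² + V3[cos 3φ + 1]/2 in
symmetry-partitioned plane-wave blocks.

## Worked example

```
$ spinbath fixture --kind trityl --n-methyls 4 --seed 3 system.json
wrote 12 protons, 4 methyls -> system.json

$ spinbath barrier2tunnel -b 15.8 -b 20.0
V3 = 15.8 kJ/mol -> tunnel splitting 55.14 kHz
V3 = 20 kJ/mol -> tunnel splitting 4.733 kHz

$ spinbath pcce system.json -u 2 --t-max 10 --n-points 21 --knots 2 -o pcce.csv
pcce: 0/5 orientations rejected (0.0 %) -> pcce.csv
```

The first command writes a 12-proton, 4-methyl trityl-like fixture with
point-dipole hyperfine tensors.  The second converts the two barrier
classes of such a core (15.8 and 20.0 kJ/mol) into tunnel splittings of
55.1 and 4.7 kHz: a ~25 % higher barrier suppresses the A-E splitting —
and with it the exchange coupling that drives echo modulation — by more
than a factor of ten.  The third
runs a partial-CCE powder average (clusters = methyl groups, u = 2, a
5-orientation grid) and reports that no orientation had to be discarded
for numerical instability; `pcce.csv` holds the normalized echo decay
W(T) at 21 evolution times up to 10 us.

Library use mirrors the CLI:

```python
import numpy as np
from spinbath import (SequenceSpec, make_trityl_like, partition_by_methyl,
                      powder_expansion, orientation_grid)

system = make_trityl_like(n_methyls=4, seed=3)
spec = SequenceSpec(mode="bare", times_us=np.linspace(0, 10, 21))
trace, diag = powder_expansion(system, spec, orientation_grid(2),
                               engine="pcce",
                               partition=partition_by_methyl(system), u=2)
print(trace.values[-1], diag["rejected_fraction"])
```

which prints `0.7254925080222617 0.0`: after 10 us the powder-averaged
Hahn echo has decayed to 73 % of its initial amplitude, driven almost
entirely by the tunnel-enhanced flip-flop couplings within the methyl
groups, and no orientation was numerically unstable.

Dressed-spin simulations use `mode="dressed"` with a spin-lock amplitude
`omega1_MHz` (default 100); at that amplitude hyperfine decoupling makes
the dressed echo decay far more slowly than the bare Hahn echo of the
same cluster.

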