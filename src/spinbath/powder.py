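"""Deterministic hemispherical orientation grids and powder averaging.

The grid places k rings of field orientations at theta_i = 90 (i-1)/(k-1)
degrees; ring 1 is the single pole orientation and ring i carries 4(i-1)
equally spaced phi values, giving 2k(k-1)+1 orientations in total (9 knots
-> 145, 7 -> 85, 23 -> 1013).  Each ring is weighted by the solid angle of
its theta band, divided equally among its points.  A hemisphere suffices
because the Hamiltonian depends on the field direction only up to
inversion (Ci symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import ClusterTrace
from .spin_system import Orientation

__all__ = ["OrientationGrid", "orientation_grid", "powder_average"]


@dataclass
class OrientationGrid:
    knots: int
    orientations: list

    def __len__(self):
        return len(self.orientations)

    @property
    def weights(self) -> np.ndarray:
        return np.array([o.weight for o in self.orientations])


def orientation_grid(knots: int) -> OrientationGrid:
    """Hemispherical grid with ``knots`` theta rings (count 2k(k-1)+1)."""
    k = int(knots)
    if k < 2:
        raise ValueError("a grid needs at least 2 knots")
    d_theta = 90.0 / (k - 1)
    orientations = []
    for i in range(1, k + 1):
        theta = d_theta * (i - 1)
        lo = np.deg2rad(max(theta - d_theta / 2.0, 0.0))
        hi = np.deg2rad(min(theta + d_theta / 2.0, 90.0))
        band = np.cos(lo) - np.cos(hi)  # solid angle of the ring / 2 pi
        n_phi = 1 if i == 1 else 4 * (i - 1)
        w = band / n_phi
        for j in range(n_phi):
            phi = 360.0 * j / n_phi
            orientations.append(Orientation(theta, phi, w))
    total = sum(o.weight for o in orientations)
    for o in orientations:
        o.weight /= total
    return OrientationGrid(knots=k, orientations=orientations)


def powder_average(traces, grid: OrientationGrid, reject_mask=None) -> tuple:
    """Weighted mean trace over non-rejected orientations.

    ``traces`` is one ClusterTrace per grid orientation, ``reject_mask`` a
    boolean array marking orientations to discard; the weights of the
    surviving set are renormalized.  Returns (trace, rejected_fraction).
    """
    if len(traces) != len(grid):
        raise ValueError("need one trace per grid orientation")
    weights = grid.weights
    if reject_mask is None:
        reject_mask = np.zeros(len(grid), dtype=bool)
    reject_mask = np.asarray(reject_mask, dtype=bool)
    keep = ~reject_mask
    if not np.any(keep):
        raise ValueError("all orientations were rejected; no powder average")
    w = weights[keep]
    w = w / np.sum(w)
    values = np.zeros_like(traces[0].values)
    times = traces[0].times_us
    for wi, tr in zip(w, [t for t, k in zip(traces, keep) if k]):
        if not np.array_equal(tr.times_us, times):
            raise ValueError("all traces must share the same time axis")
        values = values + wi * tr.values
    rejected_fraction = float(np.count_nonzero(reject_mask)) / len(grid)
    return ClusterTrace(times_us=times, values=values), rejected_fraction
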