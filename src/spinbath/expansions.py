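"""Decay-trace assembly engines.

Four approximations to the many-proton echo decay are provided:

* APPA   — analytical pair product approximation: the product of
           closed-form two-proton ESEEM factors over all pairs,
* CCE-o  — cluster correlation expansion truncated at cluster size o,
           dividing lower-order contributions out of every cluster signal,
* pCCE(s, u*s) — partial CCE on a user-supplied partition into disjoint
           clusters of size s, with inter-cluster correlations kept only
           within superclusters of u clusters,
* CF     — cluster factorization, the product of disjoint-cluster signals
           (identical to pCCE with u = 1).

The repeated divisions of numerically computed signals make CCE-type
assemblies unstable at long times; clusters whose running denominator
drops below a floor are flagged, and whole orientations whose assembled
trace leaves [0, 1.1] can be rejected before powder averaging, mirroring
the practice of discarding unstable orientations rather than patching
traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .sequences import (
    ClusterTrace,
    SequenceSpec,
    dressed_echo_trace,
    empty_couplings,
    hahn_echo_trace,
)
from .spin_system import CouplingSet, Orientation, SpinSystem, couplings_for_orientation

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "ExpansionResult",
    "appa_trace",
    "cce_trace",
    "pcce_trace",
    "cf_trace",
    "reject_unstable",
    "powder_expansion",
    "superclusters",
    "partition_by_methyl",
    "DIVISION_FLOOR",
]

#: denominator floor below which a cluster division is flagged unstable
DIVISION_FLOOR = 1e-10


@dataclass
class Partition:
    """Disjoint equal-size clusters of proton ids."""

    clusters: list

    def __post_init__(self):
        cl = [tuple(sorted(int(i) for i in c)) for c in self.clusters]
        if not cl:
            raise ValueError("partition must contain at least one cluster")
        sizes = {len(c) for c in cl}
        if len(sizes) != 1:
            raise ValueError(f"clusters must have equal sizes, got {sorted(sizes)}")
        flat = [i for c in cl for i in c]
        if len(set(flat)) != len(flat):
            raise ValueError("partition clusters must be disjoint")
        self.clusters = cl

    @property
    def size(self) -> int:
        return len(self.clusters[0])

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def partition_by_methyl(system: SpinSystem) -> Partition:
    """Partition covering the methyl protons, one cluster per methyl group."""
    if not system.methyls:
        raise ValueError("system has no methyl groups to partition by")
    return Partition([m.proton_ids for m in system.methyls])


@dataclass
class ExpansionResult:
    """Assembled decay trace plus per-orientation diagnostics."""

    trace: ClusterTrace
    engine: str
    order: tuple
    rejected: bool = False
    supercluster_count: int = 0
    unstable_clusters: list = field(default_factory=list)

    @property
    def unstable(self) -> bool:
        return bool(self.unstable_clusters)


def reject_unstable(trace: ClusterTrace, window_us: float = None) -> bool:
    """True iff the normalized signal leaves [0, 1.1] within the window.

    ``window_us`` restricts the check to times not exceeding the length of
    the (experimental) trace one intends to compare against; by default
    the whole trace is checked.
    """
    if window_us is None:
        window_us = float(trace.times_us[-1])
    mask = trace.times_us <= window_us
    v = trace.values[mask]
    return bool(np.any(v < 0.0) | np.any(v > 1.1))


def appa_trace(couplings: CouplingSet, times_us) -> ClusterTrace:
    """Analytical pair product approximation of the Hahn echo decay.

    W(T) = prod_{k<l} [1 - (3/2) l_kl - (1/2) l_kl cos(w_kl T)
                         + 2 l_kl cos(w_kl T / 2)]
    with modulation depth l_kl = dA^2 wnn^2 / (dA^2 + wnn^2)^2 and nuclear
    zero-quantum frequency w_kl = sqrt(dA^2 + wnn^2) / 2, where
    dA = A_k - A_l; the flip-flop coefficient wnn carries the
    methyl-tunnel substitution.
    """
    times_us = np.asarray(times_us, dtype=float)
    n = couplings.n
    a = couplings.A_MHz * 2 * np.pi  # rad/us
    wnn = couplings.omega_nn_kHz * 2 * np.pi * 1e-3  # rad/us
    w = np.ones_like(times_us)
    for k in range(n):
        for l in range(k + 1, n):
            da = a[k] - a[l]
            wn = wnn[k, l]
            s2 = da**2 + wn**2
            if s2 == 0.0:
                continue
            lam = da**2 * wn**2 / s2**2
            wzq = 0.5 * np.sqrt(s2)
            w = w * (
                1.0
                - 1.5 * lam
                - 0.5 * lam * np.cos(wzq * times_us)
                + 2.0 * lam * np.cos(0.5 * wzq * times_us)
            )
    return ClusterTrace(times_us=times_us, values=w)


def _cluster_signal(
    full: CouplingSet, cluster_ids: tuple, spec: SequenceSpec
) -> np.ndarray:
    """Raw normalized signal of one cluster (values array)."""
    cpl = full.restrict(cluster_ids)
    if spec.mode == "bare":
        return hahn_echo_trace(cpl, spec).values
    return dressed_echo_trace(cpl, spec).values


def _w_empty_values(spec: SequenceSpec) -> np.ndarray:
    if spec.mode == "bare":
        return np.ones(len(spec.times_us))
    return dressed_echo_trace(empty_couplings(), spec).values


def _safe_divide(num: np.ndarray, den: np.ndarray, label, unstable: list) -> np.ndarray:
    """Elementwise division with floor-based instability flagging."""
    if np.any(np.abs(den) < DIVISION_FLOOR):
        unstable.append(label)
        logger.warning("division floor hit while correcting cluster %s", label)
        den = np.where(np.abs(den) < DIVISION_FLOOR,
                       np.sign(den) * DIVISION_FLOOR + (den == 0) * DIVISION_FLOOR,
                       den)
    return num / den


def cce_trace(
    system: SpinSystem,
    order: int,
    spec: SequenceSpec,
    orientation: Orientation,
    reject_window_us: float = None,
) -> ExpansionResult:
    """Cluster correlation expansion truncated at cluster size ``order``.

    Every cluster of size <= order is simulated; tilde factors divide out
    all proper subcluster contributions (and the empty-bath signal), and
    the truncated expansion is the product of the empty-bath signal with
    all tilde factors.  Computation proceeds in increasing cluster size
    with memoization, so shared subclusters are simulated once.
    """
    if order < 1:
        raise ValueError("CCE order must be >= 1")
    ids = system.proton_ids
    if order > len(ids):
        raise ValueError("CCE order exceeds the number of protons")
    full = couplings_for_orientation(system, orientation)
    w0 = _w_empty_values(spec)

    unstable: list = []
    tilde: dict = {}
    total = w0.copy()
    for size in range(1, order + 1):
        for cluster in combinations(ids, size):
            w_c = _cluster_signal(full, cluster, spec)
            den = w0.copy()
            for sub_size in range(1, size):
                for sub in combinations(cluster, sub_size):
                    den = den * tilde[sub]
            t = _safe_divide(w_c, den, cluster, unstable)
            tilde[cluster] = t
            total = total * t
    trace = ClusterTrace(times_us=spec.times_us, values=total)
    rejected = reject_unstable(trace, reject_window_us)
    return ExpansionResult(
        trace=trace,
        engine="cce",
        order=(order,),
        rejected=rejected,
        unstable_clusters=unstable,
    )


def superclusters(partition: Partition, u: int) -> list:
    """All C(M, u) superclusters: unions of u distinct partition clusters.

    Each supercluster is returned as (member clusters, sorted union of
    proton ids)."""
    m = partition.n_clusters
    if not (1 <= u <= m):
        raise ValueError(f"u must lie in [1, {m}]")
    out = []
    for combo in combinations(partition.clusters, u):
        ids = tuple(sorted(i for cl in combo for i in cl))
        out.append((combo, ids))
    return out


def pcce_trace(
    system: SpinSystem,
    partition: Partition,
    u: int,
    spec: SequenceSpec,
    orientation: Orientation,
    reject_window_us: float = None,
) -> ExpansionResult:
    """Partial CCE over a partition into clusters of size s.

    Each disjoint cluster signal is corrected only for the empty-bath
    signal; inter-cluster correlations are retained within each of the
    C(M, u) superclusters of u clusters.  u = 1 reduces to cluster
    factorization, u = M to the exact signal of the covered protons.
    """
    m = partition.n_clusters
    if not (1 <= u <= m):
        raise ValueError(f"u must lie in [1, {m}]")
    full = couplings_for_orientation(system, orientation)
    w0 = _w_empty_values(spec)
    unstable: list = []

    s_tilde = {}
    total = w0.copy()
    for cl in partition.clusters:
        s_j = _cluster_signal(full, cl, spec)
        s_tilde[cl] = _safe_divide(s_j, w0, cl, unstable)
        total = total * s_tilde[cl]

    n_super = 0
    if u > 1:
        for combo, ids in superclusters(partition, u):
            s_o = _cluster_signal(full, ids, spec)
            den = w0.copy()
            for cl in combo:
                den = den * s_tilde[cl]
            total = total * _safe_divide(s_o, den, ids, unstable)
            n_super += 1
    else:
        n_super = m
    expected = comb(m, u)
    if n_super != expected:  # pragma: no cover - combinatorial bookkeeping
        raise AssertionError(f"supercluster count {n_super} != C({m},{u})")

    trace = ClusterTrace(times_us=spec.times_us, values=total)
    rejected = reject_unstable(trace, reject_window_us)
    return ExpansionResult(
        trace=trace,
        engine="pcce",
        order=(partition.size, u * partition.size),
        rejected=rejected,
        supercluster_count=n_super,
        unstable_clusters=unstable,
    )


def powder_expansion(
    system: SpinSystem,
    spec: SequenceSpec,
    grid,
    engine: str = "cce",
    order: int = 2,
    partition: Partition = None,
    u: int = None,
    reject_window_us: float = None,
):
    """Powder-averaged decay trace for one engine.

    Runs the chosen engine (appa | cce | pcce | cf) at every orientation
    of ``grid``, rejects orientations flagged unstable, and returns
    (ClusterTrace, diagnostics) where diagnostics reports the rejected
    fraction in the style of an instability report.
    """
    from .powder import powder_average  # local import to avoid a cycle

    results = []
    for i, ori in enumerate(grid.orientations):
        if engine == "appa":
            cpl = couplings_for_orientation(system, ori)
            trace = appa_trace(cpl, spec.times_us)
            res = ExpansionResult(trace=trace, engine="appa", order=(2,))
        elif engine == "cce":
            res = cce_trace(system, order, spec, ori, reject_window_us)
        elif engine == "pcce":
            if partition is None or u is None:
                raise ValueError("pcce requires a partition and u")
            res = pcce_trace(system, partition, u, spec, ori, reject_window_us)
        elif engine == "cf":
            if partition is None:
                raise ValueError("cf requires a partition")
            res = cf_trace(system, partition, spec, ori, reject_window_us)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        logger.info(
            "orientation %d/%d (theta=%.1f phi=%.1f): rejected=%s unstable=%d",
            i + 1, len(grid.orientations), ori.theta_deg, ori.phi_deg,
            res.rejected, len(res.unstable_clusters),
        )
        results.append(res)
    traces = [r.trace for r in results]
    mask = np.array([r.rejected for r in results])
    avg, rejected_fraction = powder_average(traces, grid, mask)
    diagnostics = {
        "rejected_fraction": rejected_fraction,
        "n_orientations": len(grid.orientations),
        "n_rejected": int(mask.sum()),
        "supercluster_count": results[0].supercluster_count,
    }
    return avg, diagnostics


def cf_trace(
    system: SpinSystem,
    partition: Partition,
    spec: SequenceSpec,
    orientation: Orientation,
    reject_window_us: float = None,
) -> ExpansionResult:
    """Cluster factorization: W_empty times the product of corrected
    disjoint-cluster signals (no inter-cluster correlations)."""
    res = pcce_trace(system, partition, 1, spec, orientation, reject_window_us)
    return ExpansionResult(
        trace=res.trace,
        engine="cf",
        order=(partition.size,),
        rejected=res.rejected,
        supercluster_count=0,
        unstable_clusters=res.unstable_clusters,
    )
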