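"""Readers and writers.

Spin systems are stored as JSON or YAML (by file extension) with blocks
``protons`` (id, xyz_angstrom, tensor_MHz 3x3), ``methyls`` (ids,
tunnel_kHz) and ``electron`` (xyz_angstrom, offset_sigma_MHz), under a
versioned ``schema`` key.  Decay traces go to CSV with ``#``-prefixed
header metadata; per-orientation trace stacks can optionally be written
to HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .sequences import ClusterTrace
from .spin_system import HyperfineTensor, MethylGroup, Proton, SpinSystem

__all__ = [
    "SCHEMA_VERSION",
    "system_to_dict",
    "system_from_dict",
    "save_system",
    "load_system",
    "save_trace_csv",
    "load_trace_csv",
    "save_trace_stack_hdf5",
    "save_xyz",
]

SCHEMA_VERSION = 1


def system_to_dict(system: SpinSystem) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "protons": [
            {
                "id": int(p.id),
                "xyz_angstrom": [float(x) for x in p.position],
                "tensor_MHz": [[float(x) for x in row] for row in p.tensor.matrix],
            }
            for p in system.protons
        ],
        "methyls": [
            {"ids": [int(i) for i in m.proton_ids], "tunnel_kHz": float(m.tunnel_kHz)}
            for m in system.methyls
        ],
        "electron": {
            "xyz_angstrom": [float(x) for x in system.electron_position],
            "offset_sigma_MHz": float(system.offset_sigma_MHz),
        },
    }


def system_from_dict(data: dict) -> SpinSystem:
    version = data.get("schema", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported spin-system schema version: {version!r}")
    protons = [
        Proton(
            id=int(p["id"]),
            position=np.asarray(p["xyz_angstrom"], dtype=float),
            tensor=HyperfineTensor(np.asarray(p["tensor_MHz"], dtype=float)),
        )
        for p in data["protons"]
    ]
    methyls = [
        MethylGroup(tuple(m["ids"]), float(m["tunnel_kHz"]))
        for m in data.get("methyls", [])
    ]
    el = data.get("electron", {})
    return SpinSystem(
        protons=protons,
        methyls=methyls,
        electron_position=np.asarray(el.get("xyz_angstrom", [0, 0, 0]), dtype=float),
        offset_sigma_MHz=float(el.get("offset_sigma_MHz", 12.0 / 2.3548200450309493)),
    )


def save_system(system: SpinSystem, path) -> None:
    path = Path(path)
    data = system_to_dict(system)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


def load_system(path) -> SpinSystem:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return system_from_dict(data)


def save_trace_csv(trace: ClusterTrace, path, metadata: dict = None) -> None:
    """Write a trace as CSV (columns T_us, signal) with '#' metadata lines."""
    path = Path(path)
    lines = []
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append("T_us,signal")
    for t, v in zip(trace.times_us, trace.values):
        lines.append(f"{t:.9g},{v:.12g}")
    path.write_text("\n".join(lines) + "\n")


def load_trace_csv(path) -> ClusterTrace:
    path = Path(path)
    rows = [
        line for line in path.read_text().splitlines()
        if line and not line.startswith("#") and not line.startswith("T_us")
    ]
    data = np.array([[float(x) for x in row.split(",")] for row in rows])
    return ClusterTrace(times_us=data[:, 0], values=data[:, 1])


def save_trace_stack_hdf5(traces, grid, path, metadata: dict = None) -> None:
    """Optional HDF5 stack of per-orientation traces (rows = orientations)."""
    import h5py

    path = Path(path)
    values = np.vstack([t.values for t in traces])
    with h5py.File(path, "w") as f:
        f.create_dataset("times_us", data=traces[0].times_us)
        f.create_dataset("values", data=values)
        f.create_dataset(
            "orientations_deg",
            data=np.array([[o.theta_deg, o.phi_deg, o.weight] for o in grid.orientations]),
        )
        for key, val in (metadata or {}).items():
            f.attrs[key] = val


def save_xyz(system: SpinSystem, path, comment: str = "spinbath fixture") -> None:
    """XYZ export of the fixture coordinates (electron as X, protons as H)."""
    path = Path(path)
    lines = [str(system.n_protons + 1), comment]
    e = system.electron_position
    lines.append(f"X {e[0]:.6f} {e[1]:.6f} {e[2]:.6f}")
    for p in system.protons:
        x, y, z = p.position
        lines.append(f"H {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")
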