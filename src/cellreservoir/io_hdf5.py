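"""HDF5 / CSV serialization of geometries, reservoirs and trajectories."""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .dynamics import Trajectory
from .geometry import CellGeometry, Region
from .reservoir import ReservoirGraph, build_graph


def save_geometry(geom: CellGeometry, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=geom.labels, dtype=np.uint8, compression="gzip")
        f.attrs.update(
            voxel_size=geom.voxel_size,
            r_cm=geom.r_cm,
            r_pc=geom.r_pc,
            r_co=geom.r_co,
            cs_fraction=geom.cs_fraction,
            seed=-1 if geom.seed is None else geom.seed,
        )


def load_geometry(path: str | Path) -> CellGeometry:
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        a = f.attrs
        geom = CellGeometry(
            float(a["voxel_size"]), float(a["r_cm"]), float(a["r_pc"]), float(a["r_co"]),
            labels, float(a["cs_fraction"]),
            None if int(a["seed"]) < 0 else int(a["seed"]),
        )
    return geom


def save_graph(graph: ReservoirGraph, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("occupancy", data=graph.occupancy, dtype=np.uint8, compression="gzip")
        if graph.conductance is not None:
            f.create_dataset("conductance", data=graph.conductance, compression="gzip")
        f.create_dataset("I", data=graph.I, compression="gzip")
        f.create_dataset("S", data=graph.S, compression="gzip")
        f.attrs.update(
            n=graph.n,
            conduction_map=sorted(int(c) for c in graph.conduction_map),
            conductance_seed=-1 if graph.conductance_seed is None else graph.conductance_seed,
        )
        g = f.create_group("geometry")
        g.create_dataset("labels", data=graph.geom.labels, dtype=np.uint8, compression="gzip")
        g.attrs.update(
            voxel_size=graph.geom.voxel_size, r_cm=graph.geom.r_cm,
            r_pc=graph.geom.r_pc, r_co=graph.geom.r_co,
            cs_fraction=graph.geom.cs_fraction,
            seed=-1 if graph.geom.seed is None else graph.geom.seed,
        )


def load_graph(path: str | Path) -> ReservoirGraph:
    with h5py.File(path, "r") as f:
        g = f["geometry"]
        a = g.attrs
        geom = CellGeometry(
            float(a["voxel_size"]), float(a["r_cm"]), float(a["r_pc"]), float(a["r_co"]),
            g["labels"][...], float(a["cs_fraction"]),
            None if int(a["seed"]) < 0 else int(a["seed"]),
        )
        cmap = frozenset(Region(int(c)) for c in f.attrs["conduction_map"])
        graph = build_graph(geom, cmap)
        if "conductance" in f:
            graph.conductance = f["conductance"][...]
        graph.I = f["I"][...]
        graph.S = f["S"][...]
        seed = int(f.attrs["conductance_seed"])
        graph.conductance_seed = None if seed < 0 else seed
    return graph


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("co_states", data=traj.co_states, compression="gzip")
        f.create_dataset("co_vertices", data=traj.co_vertices)
        f.create_dataset("informed_counts", data=np.asarray(traj.informed_counts))
        f.attrs.update(
            co_arrival=-1 if traj.co_arrival is None else traj.co_arrival,
            saturation_step=-1 if traj.saturation_step is None else traj.saturation_step,
            n_inputs=traj.n_inputs,
        )


def trajectory_summary(traj: Trajectory) -> pd.DataFrame:
    """CSV-friendly per-step summary: step, informed count, mean |I|, mean S."""
    steps = np.arange(1, len(traj.informed_counts) + 1)
    return pd.DataFrame(
        {
            "step": steps,
            "informed_count": traj.informed_counts,
            "mean_abs_I": traj.mean_abs_I,
            "mean_S": traj.mean_S,
        }
    )


def read_waveform_csv(path: str | Path) -> np.ndarray:
    """Read a two-column (t, amplitude) CSV input waveform."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("waveform CSV needs two columns: t, amplitude")
    return df.iloc[:, 1].to_numpy(dtype=float)


def report(frame: pd.DataFrame, path: str | Path, seeds: dict | None = None,
           config_hash: str | None = None) -> None:
    """Write a result table with a commented metadata header.

    The header records the tool version, a config hash and every consumed
    seed, so identical configs reproduce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# cellreservoir {__version__}"]
    if config_hash:
        lines.append(f"# config_hash {config_hash}")
    for name, value in sorted((seeds or {}).items()):
        lines.append(f"# seed {name}={value}")
    body = frame.to_csv(index=False)
    path.write_text("\n".join(lines) + "\n" + body)


def config_hash(cfg) -> str:
    import yaml

    return hashlib.sha256(
        yaml.safe_dump(cfg.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:12]
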