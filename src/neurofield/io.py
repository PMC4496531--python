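"""HDF5 persistence of solution paths and weight functions."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .grid import GridSpec
from .solver import SolutionPath
from .weights import WeightFunction


def _write_grid(h: h5py.Group, grid: GridSpec) -> None:
    h.attrs["dimension"] = grid.dimension
    h.attrs["half_width"] = grid.half_width
    h.attrs["points_per_axis"] = grid.points_per_axis


def _read_grid(h: h5py.Group) -> GridSpec:
    return GridSpec(int(h.attrs["dimension"]), float(h.attrs["half_width"]),
                    int(h.attrs["points_per_axis"]))


def save_path(path: str, sol: SolutionPath, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("Y", data=sol.values)
        f.create_dataset("t", data=sol.times)
        _write_grid(f, sol.grid)
        f.attrs["scheme"] = sol.scheme
        if sol.seed is not None:
            f.attrs["seed"] = sol.seed
        if sol.config_hash:
            f.attrs["config_hash"] = sol.config_hash
        if config is not None:
            f.attrs["config_json"] = json.dumps(config)


def load_path(path: str) -> SolutionPath:
    with h5py.File(path, "r") as f:
        return SolutionPath(values=f["Y"][...], times=f["t"][...],
                            grid=_read_grid(f), scheme=str(f.attrs["scheme"]),
                            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
                            config_hash=str(f.attrs.get("config_hash", "")) or None)


def save_weight(path: str, rho: WeightFunction) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rho", data=rho.values)
        _write_grid(f, rho.grid)
        f.attrs["Lambda"] = rho.Lambda
        f.attrs["construction"] = rho.construction
        f.attrs["l1_norm"] = rho.l1_norm


def load_weight(path: str) -> WeightFunction:
    with h5py.File(path, "r") as f:
        return WeightFunction(values=f["rho"][...], grid=_read_grid(f),
                              Lambda=float(f.attrs["Lambda"]),
                              construction=str(f.attrs["construction"]),
                              l1_norm=float(f.attrs["l1_norm"]))
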