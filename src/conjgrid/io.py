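"""HDF5 state/weight persistence, CSV exports and config (de)serialisation."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from conjgrid.network1d import RateState

__all__ = ["save_state", "load_state", "save_weights", "load_weights",
           "save_config", "load_config", "lookup_to_csv", "ratemap_to_csv"]


def save_state(path, state: RateState, attrs: Optional[dict] = None) -> None:
    """Write /state/m and /state/t plus parameter attributes."""
    with h5py.File(path, "w") as f:
        g = f.create_group("state")
        g.create_dataset("m", data=state.m)
        g.create_dataset("t", data=state.t)
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def load_state(path) -> RateState:
    with h5py.File(path, "r") as f:
        return RateState(t=float(f["state/t"][()]), m=f["state/m"][:])


def save_weights(path, W: np.ndarray, attrs: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=W)
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def load_weights(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["weights"][:]


def save_config(path, cfg: dict) -> None:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2, default=float))


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


def lookup_to_csv(path, centers: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"bin_center_cm_s": centers, "vhat": values}).to_csv(
        path, index=False)


def ratemap_to_csv(path, rm) -> None:
    """Flatten a RateMap into long format (bin centres, occupancy, rate)."""
    centers = rm.centers
    mesh = np.meshgrid(*centers, indexing="ij")
    cols = {f"axis{i}": m.ravel() for i, m in enumerate(mesh)}
    cols["occupancy"] = rm.occupancy.ravel()
    cols["rate"] = rm.rate.ravel()
    pd.DataFrame(cols).to_csv(path, index=False)
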