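"""HDF5 / CSV / JSON persistence for simulation runs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .geometry import Geometry, geometry_from_dict
from .model_core import FieldState, ModelParams
from .simulator import Trajectory


def save_trajectory(path, traj: Trajectory, params: ModelParams,
                    geometry: Geometry) -> None:
    """Write snapshots under /fields/t_XXXX and diagnostics under /scalars."""
    with h5py.File(path, "w") as f:
        f.attrs["params"] = json.dumps(params.to_dict())
        f.attrs["geometry"] = json.dumps(geometry.to_dict())
        f.create_dataset("mask", data=geometry.mask, compression="gzip")
        grp = f.create_group("fields")
        for i, (t, snap) in enumerate(zip(traj.times, traj.snapshots)):
            g = grp.create_group(f"t_{i:05d}")
            g.attrs["t_tilde"] = t
            g.create_dataset("phi_s", data=snap.phi_s, compression="gzip")
            g.create_dataset("phi_ns", data=snap.phi_ns, compression="gzip")
        sc = f.create_group("scalars")
        for key, vals in traj.scalars.items():
            sc.create_dataset(key, data=np.asarray(vals, dtype=float))


def load_trajectory(path):
    """Read a saved run; returns (Trajectory, ModelParams, Geometry)."""
    traj = Trajectory()
    with h5py.File(path, "r") as f:
        params = ModelParams.from_dict(json.loads(f.attrs["params"]))
        geometry = geometry_from_dict(json.loads(f.attrs["geometry"]))
        geometry.mask = f["mask"][...].astype(bool)
        h = geometry.h
        for name in sorted(f["fields"]):
            g = f["fields"][name]
            state = FieldState(g["phi_s"][...], g["phi_ns"][...],
                               float(g.attrs["t_tilde"]), h)
            traj.times.append(state.t_tilde)
            traj.snapshots.append(state)
        for key in f["scalars"]:
            traj.scalars[key] = list(f["scalars"][key][...])
    return traj, params, geometry


def save_scalars_csv(path, traj: Trajectory) -> None:
    pd.DataFrame(traj.scalars).to_csv(path, index=False)


def render_snapshot_png(path, state: FieldState, geometry: Geometry,
                        title: Optional[str] = None) -> None:
    """Quick-look rendering of total protein concentration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    total = state.phi_s + state.phi_ns
    total = np.where(geometry.mask, total, np.nan)
    fig, ax = plt.subplots(figsize=(5, 5 * geometry.Ny / geometry.Nx))
    im = ax.imshow(total, origin="lower", cmap="viridis", vmin=0.0)
    fig.colorbar(im, ax=ax, label=r"$\phi_s + \phi_{ns}$")
    ax.set_title(title or f"t = {state.t_tilde:.1f}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
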