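"""File formats: HDF5 trajectory containers, CSV summaries, JSON manifests.

One run maps to one HDF5 file holding the phase records, the coupling-matrix
snapshots and all model parameters, so that any output can be regenerated
bit-identically from the manifest written next to it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .integrate import Trajectory
from .model import DuplexState, ModelParams

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "write_manifest",
    "load_manifest",
    "ManifestExistsError",
    "MANIFEST_NAME",
]

MANIFEST_NAME = "manifest.json"
_FORMAT_VERSION = 1


class ManifestExistsError(FileExistsError):
    """Refusing to overwrite a completed run manifest."""


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a :class:`Trajectory` to an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = _FORMAT_VERSION
        fh.attrs["dt"] = traj.dt
        fh.attrs["kappa_abs_max"] = traj.kappa_abs_max
        fh.attrs["meta"] = json.dumps(traj.meta)
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("phases1", data=traj.phases1)
        fh.create_dataset("phases2", data=traj.phases2)
        fh.create_dataset("kappa_times", data=traj.kappa_times)
        fh.create_dataset("kappa1", data=traj.kappa1)
        fh.create_dataset("kappa2", data=traj.kappa2)
        fin = fh.create_group("final_state")
        fin.create_dataset("phi1", data=traj.final_state.phi1)
        fin.create_dataset("phi2", data=traj.final_state.phi2)
        fin.create_dataset("kappa1", data=traj.final_state.kappa1)
        fin.create_dataset("kappa2", data=traj.final_state.kappa2)
        par = fh.create_group("params")
        par.attrs["n"] = traj.params.n
        par.attrs["omega2"] = traj.params.omega2
        par.attrs["alpha"] = traj.params.alpha
        par.attrs["beta"] = traj.params.beta
        par.attrs["eps1"] = traj.params.eps1
        par.attrs["eps2"] = traj.params.eps2
        par.attrs["sigma"] = traj.params.sigma
        par.attrs["literal_adaptation"] = traj.params.literal_adaptation
        par.create_dataset("omega1", data=traj.params.omega1)
        par.create_dataset("adjacency", data=traj.params.adjacency)


def load_trajectory(path) -> Trajectory:
    """Read back a trajectory written by :func:`save_trajectory`."""
    with h5py.File(path, "r") as fh:
        par = fh["params"]
        params = ModelParams(
            n=int(par.attrs["n"]),
            omega1=par["omega1"][...],
            omega2=float(par.attrs["omega2"]),
            alpha=float(par.attrs["alpha"]),
            beta=float(par.attrs["beta"]),
            eps1=float(par.attrs["eps1"]),
            eps2=float(par.attrs["eps2"]),
            sigma=float(par.attrs["sigma"]),
            adjacency=par["adjacency"][...],
            literal_adaptation=bool(par.attrs["literal_adaptation"]),
        )
        fin = fh["final_state"]
        final_state = DuplexState(
            fin["phi1"][...], fin["phi2"][...], fin["kappa1"][...], fin["kappa2"][...]
        )
        return Trajectory(
            times=fh["times"][...],
            phases1=fh["phases1"][...],
            phases2=fh["phases2"][...],
            kappa_times=fh["kappa_times"][...],
            kappa1=fh["kappa1"][...],
            kappa2=fh["kappa2"][...],
            params=params,
            dt=float(fh.attrs["dt"]),
            kappa_abs_max=float(fh.attrs["kappa_abs_max"]),
            final_state=final_state,
            meta=json.loads(fh.attrs["meta"]),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_manifest(out_dir, manifest: dict, overwrite: bool = False) -> Path:
    """Write the machine-readable run manifest into ``out_dir``.

    A manifest marks a completed run; an existing one is never overwritten
    unless ``overwrite`` is explicitly requested.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / MANIFEST_NAME
    if path.exists() and not overwrite:
        raise ManifestExistsError(
            f"{path} already exists (completed run); use overwrite/--force to replace"
        )
    tmp = path.with_suffix(".json.tmp")
    with open(tmp, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    tmp.replace(path)
    return path


def load_manifest(out_dir) -> dict:
    with open(Path(out_dir) / MANIFEST_NAME) as fh:
        return json.load(fh)
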