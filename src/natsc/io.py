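"""File formats: HDF5 for raw k-space/trajectories, NIfTI-1 for volumes.

HDF5 layouts
------------
Trajectory:  /k (n_readouts, n_samples, 3), /t (ms), /w (optional),
             /cone_angle; protocol fields as root attributes; delay model
             as ``delay_applied_us`` / ``hysteresis_tau_us`` attributes.
K-space:     /samples (complex), provenance and protocol as attributes,
             plus an embedded /trajectory group in the same layout.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .protocol import AcquisitionProtocol
from .recon import ImageVolume
from .simulate import KSpaceData
from .trajectory import ConesTrajectory

__all__ = ["save_trajectory", "load_trajectory", "save_kspace", "load_kspace",
           "save_volume", "load_volume"]


def _write_protocol_attrs(node, protocol: AcquisitionProtocol) -> None:
    for key, val in protocol.to_dict().items():
        node.attrs[f"protocol_{key}"] = val


def _read_protocol_attrs(node) -> AcquisitionProtocol:
    d = {k[len("protocol_"):]: v for k, v in node.attrs.items()
         if k.startswith("protocol_")}
    for int_key in ("n_readouts", "n_averages"):
        if int_key in d:
            d[int_key] = int(d[int_key])
    return AcquisitionProtocol.from_dict(d)


def _write_traj_group(g, traj: ConesTrajectory) -> None:
    g.create_dataset("k", data=traj.k, compression="gzip")
    g.create_dataset("t", data=traj.t)
    g.create_dataset("cone_angle", data=traj.cone_angle)
    if traj.w is not None:
        g.create_dataset("w", data=traj.w, compression="gzip")
    if traj.k_ideal is not None and traj.delay_applied_us != 0.0:
        g.create_dataset("k_ideal", data=traj.k_ideal, compression="gzip")
    g.attrs["delay_applied_us"] = traj.delay_applied_us
    g.attrs["hysteresis_tau_us"] = traj.hysteresis_tau_us
    _write_protocol_attrs(g, traj.protocol)


def _read_traj_group(g) -> ConesTrajectory:
    return ConesTrajectory(
        k=g["k"][...], t=g["t"][...], cone_angle=g["cone_angle"][...],
        protocol=_read_protocol_attrs(g),
        w=g["w"][...] if "w" in g else None,
        k_ideal=g["k_ideal"][...] if "k_ideal" in g else None,
        delay_applied_us=float(g.attrs.get("delay_applied_us", 0.0)),
        hysteresis_tau_us=float(g.attrs.get("hysteresis_tau_us", 0.0)))


def save_trajectory(path: str | Path, traj: ConesTrajectory) -> None:
    with h5py.File(path, "w") as f:
        _write_traj_group(f, traj)


def load_trajectory(path: str | Path) -> ConesTrajectory:
    with h5py.File(path, "r") as f:
        return _read_traj_group(f)


def save_kspace(path: str | Path, kdata: KSpaceData,
                traj: ConesTrajectory | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=kdata.samples, compression="gzip")
        f.attrs["noise_sd"] = kdata.noise_sd
        for key, val in kdata.provenance.items():
            f.attrs[f"prov_{key}"] = val if val is not None else "none"
        _write_protocol_attrs(f, kdata.protocol)
        if traj is not None:
            _write_traj_group(f.create_group("trajectory"), traj)


def load_kspace(path: str | Path) -> tuple[KSpaceData, ConesTrajectory | None]:
    with h5py.File(path, "r") as f:
        prov = {k[len("prov_"):]: v for k, v in f.attrs.items()
                if k.startswith("prov_")}
        kdata = KSpaceData(samples=f["samples"][...],
                           protocol=_read_protocol_attrs(f),
                           noise_sd=float(f.attrs["noise_sd"]),
                           provenance=prov)
        traj = _read_traj_group(f["trajectory"]) if "trajectory" in f else None
    return kdata, traj


def save_volume(path: str | Path, volume, affine: np.ndarray | None = None) -> None:
    """Write an ImageVolume / TSCMap / bare array as float32 NIfTI-1."""
    values = getattr(volume, "values", volume)
    aff = affine if affine is not None else getattr(volume, "affine", np.eye(4))
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), aff), str(path))


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(values=np.asarray(img.get_fdata(), dtype=float),
                       affine=np.asarray(img.affine), provenance={"path": str(path)})
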