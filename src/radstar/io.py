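"""File I/O for k-space containers and parameter maps, and coil-array
preprocessing.

The k-space container is an HDF5 file with groups ``/data`` (complex
samples [coil, echo, spoke, sample]), ``/traj`` (angles, frame offsets,
coordinates and the integer counts), ``/echoes`` (the echo-time train) and
``/meta`` (FOV, noise level, seed, provenance); the root carries a
``format_version`` attribute.  Parameter maps are written as NIfTI volumes
(complex maps as separate real/imaginary files) whose affine encodes the
in-plane voxel size.  See docs/FORMATS.md for the exact layouts.
"""

from __future__ import annotations

import numpy as np

from .containers import MultiEchoKspace
from .signal_model import ParameterMaps, fat_fraction
from .trajectory import EchoTrain, RadialTrajectory

__all__ = [
    "KspaceFormatError",
    "FORMAT_VERSION",
    "write_kspace",
    "read_kspace",
    "write_maps",
    "read_maps",
    "coil_compress",
    "export_trajectory_table",
]

FORMAT_VERSION = "1"


class KspaceFormatError(RuntimeError):
    """Raised when an HDF5 k-space container violates the documented schema."""


def write_kspace(y: MultiEchoKspace, path) -> None:
    """Write a :class:`MultiEchoKspace` container losslessly to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("data", data=y.data)
        tg = f.create_group("traj")
        tg.attrs["n_shots"] = y.traj.n_shots
        tg.attrs["n_echoes"] = y.traj.n_echoes
        tg.attrs["samples_per_spoke"] = y.traj.samples_per_spoke
        tg.attrs["n_frames"] = y.traj.n_frames
        tg.create_dataset("angles", data=y.traj.angles)
        tg.create_dataset("frame_offsets", data=y.traj.frame_offsets)
        tg.create_dataset("coords", data=y.traj.coords)
        eg = f.create_group("echoes")
        eg.attrs["te_first"] = y.echoes.te_first
        eg.attrs["delta_te"] = y.echoes.delta_te
        eg.attrs["n_echoes"] = y.echoes.n_echoes
        mg = f.create_group("meta")
        mg.attrs["fov_mm"] = y.fov_mm
        mg.attrs["noise_sd"] = y.noise_sd
        mg.attrs["seed"] = -1 if y.seed is None else y.seed
        mg.attrs["provenance"] = y.provenance


def read_kspace(path) -> MultiEchoKspace:
    """Read a k-space container; schema violations raise KspaceFormatError."""
    import h5py

    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None:
            raise KspaceFormatError("missing root attribute 'format_version'")
        if str(version) != FORMAT_VERSION:
            raise KspaceFormatError(
                f"unsupported format version {version!r} (expected {FORMAT_VERSION!r})"
            )
        for group in ("data", "traj", "echoes", "meta"):
            if group not in f:
                raise KspaceFormatError(f"missing required group '/{group}'")
        tg = f["traj"]
        for ds in ("angles", "frame_offsets", "coords"):
            if ds not in tg:
                raise KspaceFormatError(f"missing dataset '/traj/{ds}'")
        traj = RadialTrajectory(
            n_shots=int(tg.attrs["n_shots"]),
            n_echoes=int(tg.attrs["n_echoes"]),
            samples_per_spoke=int(tg.attrs["samples_per_spoke"]),
            n_frames=int(tg.attrs["n_frames"]),
            angles=tg["angles"][...],
            frame_offsets=tg["frame_offsets"][...],
            coords=tg["coords"][...],
        )
        eg = f["echoes"]
        echoes = EchoTrain(
            te_first=float(eg.attrs["te_first"]),
            delta_te=float(eg.attrs["delta_te"]),
            n_echoes=int(eg.attrs["n_echoes"]),
        )
        mg = f["meta"]
        seed = int(mg.attrs["seed"])
        return MultiEchoKspace(
            data=f["data"][...],
            traj=traj,
            echoes=echoes,
            fov_mm=float(mg.attrs["fov_mm"]),
            noise_sd=float(mg.attrs["noise_sd"]),
            seed=None if seed < 0 else seed,
            provenance=str(mg.attrs["provenance"]),
        )


def _affine(fov_mm: float, n: int, slice_thickness_mm: float = 3.0) -> np.ndarray:
    vox = fov_mm / n
    return np.diag([vox, vox, slice_thickness_mm, 1.0])


def write_maps(maps: ParameterMaps, path_prefix, fov_mm: float) -> list:
    """Write parameter maps as NIfTI volumes.

    Produces ``<prefix>_water_{real,imag}.nii.gz``, likewise for fat, plus
    real-valued ``r2star`` (1/s), ``fb0`` (Hz) and ``fat_fraction`` (%).
    Returns the list of file paths written.
    """
    import nibabel as nib

    n = maps.shape[0]
    aff = _affine(fov_mm, n)
    vols = {
        "water_real": np.real(maps.water),
        "water_imag": np.imag(maps.water),
        "fat_real": np.real(maps.fat),
        "fat_imag": np.imag(maps.fat),
        "r2star": np.asarray(maps.r2star, dtype=float),
        "fb0": np.asarray(maps.fb0, dtype=float),
        "fat_fraction": fat_fraction(maps.water, maps.fat),
    }
    written = []
    for name, vol in vols.items():
        img = nib.Nifti1Image(vol[..., None].astype(np.float64), aff)
        fn = f"{path_prefix}_{name}.nii.gz"
        nib.save(img, fn)
        written.append(fn)
    return written


def read_maps(path_prefix) -> ParameterMaps:
    """Read maps written by :func:`write_maps`."""
    import nibabel as nib

    def load(name):
        return np.asarray(
            nib.load(f"{path_prefix}_{name}.nii.gz").dataobj
        )[..., 0]

    return ParameterMaps(
        water=load("water_real") + 1j * load("water_imag"),
        fat=load("fat_real") + 1j * load("fat_imag"),
        r2star=load("r2star"),
        fb0=load("fb0"),
    )


def coil_compress(y: MultiEchoKspace, n_virtual: int):
    """Principal-component coil compression.

    The SVD of the (coils x everything-else) data matrix defines virtual
    coils; the leading ``n_virtual`` are kept.  Returns the compressed
    container and the retained-energy fraction.
    """
    K = y.n_coils
    if not 1 <= n_virtual <= K:
        raise ValueError(f"n_virtual must lie in 1..{K}, got {n_virtual}")
    X = y.data.reshape(K, -1)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    retained = float(np.sum(s[:n_virtual] ** 2) / np.sum(s**2))
    comp = (U[:, :n_virtual].conj().T @ X).reshape((n_virtual,) + y.data.shape[1:])
    out = MultiEchoKspace(
        data=comp,
        traj=y.traj,
        echoes=y.echoes,
        fov_mm=y.fov_mm,
        noise_sd=y.noise_sd,
        seed=y.seed,
        provenance=y.provenance + f" | coil_compress({K}->{n_virtual})",
    )
    return out, retained


def export_trajectory_table(traj: RadialTrajectory, path, frame: int = 0) -> None:
    """Plain-text table of (echo, spoke, sample, kx, ky) in cycles/FOV."""
    M, S, T = traj.n_echoes, traj.n_shots, traj.samples_per_spoke
    with open(path, "w") as f:
        f.write("# echo spoke sample kx ky\n")
        for m in range(M):
            for s in range(S):
                for t in range(T):
                    kx, ky = traj.coords[frame, m, s, t]
                    f.write(f"{m} {s} {t} {kx:.9g} {ky:.9g}\n")
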