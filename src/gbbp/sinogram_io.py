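"""Sinogram and image containers on disk.

Sinograms are stored in an HDF5 file with datasets ``rf[Nd][Nt]`` and
``angles_deg[Nd]`` plus root attributes {modality, sampling_rate_mhz, t0_us,
speed_of_sound_mm_us, virtual_radius_mm, focal_length_mm, imaging_radius_mm}.
A plain two-file fallback (raw float64 matrix + YAML sidecar) covers
environments without HDF5 tooling.  Images are written as 16-bit PNG
(normalized for display) alongside a float ``.npy`` dump that preserves the
absolute scale.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import yaml

from .geometry import ScanGeometry
from .recon import ReconImage, Sinogram

__all__ = [
    "save_sinogram",
    "load_sinogram",
    "save_sinogram_raw",
    "load_sinogram_raw",
    "save_image",
]


def save_sinogram(path, sino: Sinogram, *, focal_length_mm: float | None = None) -> None:
    geom = sino.geometry
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rf", data=sino.rf)
        fh.create_dataset("angles_deg", data=np.rad2deg(geom.angles_rad))
        fh.attrs["modality"] = sino.modality
        fh.attrs["sampling_rate_mhz"] = geom.sampling_rate_mhz
        fh.attrs["t0_us"] = sino.t0_us
        fh.attrs["speed_of_sound_mm_us"] = geom.speed_of_sound_mm_us
        fh.attrs["virtual_radius_mm"] = geom.virtual_radius_mm
        fh.attrs["imaging_radius_mm"] = geom.imaging_radius_mm
        if focal_length_mm is not None:
            fh.attrs["focal_length_mm"] = focal_length_mm


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as fh:
        rf = fh["rf"][()]
        angles = np.deg2rad(fh["angles_deg"][()])
        geom = ScanGeometry(
            angles_rad=angles,
            virtual_radius_mm=float(fh.attrs["virtual_radius_mm"]),
            imaging_radius_mm=float(fh.attrs["imaging_radius_mm"]),
            speed_of_sound_mm_us=float(fh.attrs["speed_of_sound_mm_us"]),
            sampling_rate_mhz=float(fh.attrs["sampling_rate_mhz"]),
            n_samples=rf.shape[1],
        )
        return Sinogram(
            rf=rf,
            modality=str(fh.attrs["modality"]),
            geometry=geom,
            t0_us=float(fh.attrs["t0_us"]),
        )


def save_sinogram_raw(prefix, sino: Sinogram) -> None:
    """Two-file fallback: ``<prefix>.f64`` raw matrix + ``<prefix>.yaml``."""
    geom = sino.geometry
    sino.rf.astype("<f8").tofile(f"{prefix}.f64")
    meta = {
        "modality": sino.modality,
        "n_angles": geom.n_angles,
        "n_samples": sino.n_samples,
        "angles_deg": [float(x) for x in np.rad2deg(geom.angles_rad)],
        "sampling_rate_mhz": float(geom.sampling_rate_mhz),
        "t0_us": float(sino.t0_us),
        "speed_of_sound_mm_us": float(geom.speed_of_sound_mm_us),
        "virtual_radius_mm": float(geom.virtual_radius_mm),
        "imaging_radius_mm": float(geom.imaging_radius_mm),
    }
    with open(f"{prefix}.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_sinogram_raw(prefix) -> Sinogram:
    with open(f"{prefix}.yaml") as fh:
        meta = yaml.safe_load(fh)
    rf = np.fromfile(f"{prefix}.f64", dtype="<f8").reshape(
        meta["n_angles"], meta["n_samples"]
    )
    geom = ScanGeometry(
        angles_rad=np.deg2rad(np.asarray(meta["angles_deg"], dtype=float)),
        virtual_radius_mm=meta["virtual_radius_mm"],
        imaging_radius_mm=meta["imaging_radius_mm"],
        speed_of_sound_mm_us=meta["speed_of_sound_mm_us"],
        sampling_rate_mhz=meta["sampling_rate_mhz"],
        n_samples=meta["n_samples"],
    )
    return Sinogram(
        rf=rf, modality=meta["modality"], geometry=geom, t0_us=meta["t0_us"]
    )


def save_image(prefix, image: ReconImage) -> None:
    """Write ``<prefix>.npy`` (float, absolute scale) and ``<prefix>.png``
    (16-bit, normalized per image to its maximum for display)."""
    import imageio.v3 as iio

    np.save(f"{prefix}.npy", image.values)
    vals = np.abs(image.values)
    peak = vals.max()
    display = vals / peak if peak > 0 else vals
    png = (display * 65535).astype(np.uint16)
    tmp = f"{prefix}.png.tmp"
    iio.imwrite(tmp, png, extension=".png")
    os.replace(tmp, f"{prefix}.png")
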