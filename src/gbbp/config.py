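"""Flat YAML experiment configuration with validated defaults.

The defaults reproduce the reference simulation study: a 10 MHz, 60%
bandwidth transducer with a 7 mm focal length and NA 0.5054, rotationally
scanned over a 30 degree sector at 0.25 degree steps, sampled at 200 MHz,
5%-of-peak Gaussian noise, 200 noise trials.  The default virtual-transducer
radius L = 0 places the focus at exactly 7 mm from the rotation center.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .geometry import (
    GaussianBeamParams,
    ScanGeometry,
    TransducerSpec,
    derive_gaussian_params,
)
from .simulate import DEFAULT_FIELD_MODEL, NoiseSpec, PulseModel

__all__ = ["ExperimentConfig", "load_config", "save_config", "atomic_write"]

_DEFAULTS = {
    "center_frequency_mhz": 10.0,
    "fractional_bandwidth": 0.6,
    "focal_length_mm": 7.0,
    "numerical_aperture": 0.5054,
    "aperture_diameter_mm": None,
    "virtual_radius_mm": 0.0,
    "imaging_radius_mm": 12.5,
    "speed_of_sound_mm_us": 1.5,
    "angles_deg_start": -15.0,
    "angles_deg_stop": 15.25,   # half-open: includes +15.0, 121 angles
    "angles_deg_step": 0.25,
    "sampling_rate_mhz": 200.0,
    "n_samples": 4000,
    "beam_waist_mm": None,       # explicit Gaussian-beam override
    "beam_z0_mm": None,
    "z0_max_mm": 1.0e6,
    "field_model": DEFAULT_FIELD_MODEL,
    "scene": "nine",
    "scene_y_offset_mm": 2.0,
    "noise_sigma_fraction": 0.05,
    "trials": 200,
    "radial_pitch_mm": 0.005,
    "recon_r_min_mm": 0.5,
    "output_prefix": "gbbp_run",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully validated experiment description (see module docstring for
    the default values)."""

    center_frequency_mhz: float = _DEFAULTS["center_frequency_mhz"]
    fractional_bandwidth: float = _DEFAULTS["fractional_bandwidth"]
    focal_length_mm: float = _DEFAULTS["focal_length_mm"]
    numerical_aperture: float = _DEFAULTS["numerical_aperture"]
    aperture_diameter_mm: float | None = _DEFAULTS["aperture_diameter_mm"]
    virtual_radius_mm: float = _DEFAULTS["virtual_radius_mm"]
    imaging_radius_mm: float = _DEFAULTS["imaging_radius_mm"]
    speed_of_sound_mm_us: float = _DEFAULTS["speed_of_sound_mm_us"]
    angles_deg_start: float = _DEFAULTS["angles_deg_start"]
    angles_deg_stop: float = _DEFAULTS["angles_deg_stop"]
    angles_deg_step: float = _DEFAULTS["angles_deg_step"]
    sampling_rate_mhz: float = _DEFAULTS["sampling_rate_mhz"]
    n_samples: int = _DEFAULTS["n_samples"]
    beam_waist_mm: float | None = _DEFAULTS["beam_waist_mm"]
    beam_z0_mm: float | None = _DEFAULTS["beam_z0_mm"]
    z0_max_mm: float = _DEFAULTS["z0_max_mm"]
    field_model: str = _DEFAULTS["field_model"]
    scene: str = _DEFAULTS["scene"]
    scene_y_offset_mm: float = _DEFAULTS["scene_y_offset_mm"]
    noise_sigma_fraction: float = _DEFAULTS["noise_sigma_fraction"]
    trials: int = _DEFAULTS["trials"]
    radial_pitch_mm: float = _DEFAULTS["radial_pitch_mm"]
    recon_r_min_mm: float = _DEFAULTS["recon_r_min_mm"]
    output_prefix: str = _DEFAULTS["output_prefix"]

    def __post_init__(self) -> None:
        # constructing the domain objects performs the physical validation
        self.transducer()
        self.geometry()
        self.pulse()
        if self.trials < 0:
            raise ValueError("trials must be >= 0")
        if self.noise_sigma_fraction < 0:
            raise ValueError("noise_sigma_fraction must be >= 0")

    def transducer(self) -> TransducerSpec:
        return TransducerSpec(
            center_frequency_mhz=self.center_frequency_mhz,
            fractional_bandwidth=self.fractional_bandwidth,
            focal_length_mm=self.focal_length_mm,
            numerical_aperture=self.numerical_aperture,
            aperture_diameter_mm=self.aperture_diameter_mm,
        )

    def geometry(self) -> ScanGeometry:
        return ScanGeometry.from_span(
            self.angles_deg_start,
            self.angles_deg_stop,
            self.angles_deg_step,
            virtual_radius_mm=self.virtual_radius_mm,
            imaging_radius_mm=self.imaging_radius_mm,
            speed_of_sound_mm_us=self.speed_of_sound_mm_us,
            sampling_rate_mhz=self.sampling_rate_mhz,
            n_samples=self.n_samples,
        )

    def beam(self) -> GaussianBeamParams:
        if self.beam_waist_mm is not None or self.beam_z0_mm is not None:
            return derive_gaussian_params(
                self.transducer(),
                self.speed_of_sound_mm_us,
                strategy="explicit",
                waist_mm=self.beam_waist_mm,
                semi_focal_depth_mm=self.beam_z0_mm,
                z0_max_mm=self.z0_max_mm,
            )
        return derive_gaussian_params(
            self.transducer(), self.speed_of_sound_mm_us, z0_max_mm=self.z0_max_mm
        )

    def pulse(self) -> PulseModel:
        return PulseModel(
            center_frequency_mhz=self.center_frequency_mhz,
            fractional_bandwidth=self.fractional_bandwidth,
        )

    def noise(self, seed: int = 0) -> NoiseSpec:
        return NoiseSpec(sigma_fraction=self.noise_sigma_fraction, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    """Load a flat key-value YAML config; unknown keys are an error and
    missing keys fall back to the reference-study defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat key-value mapping")
    unknown = sorted(set(data) - set(_DEFAULTS))
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return ExperimentConfig(**data)


def save_config(config: ExperimentConfig, path) -> None:
    atomic_write(path, yaml.safe_dump(config.to_dict(), sort_keys=True))


def atomic_write(path, data) -> None:
    """Write-then-rename so readers never observe a partial file."""
    path = os.fspath(path)
    tmp = path + ".tmp"
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(tmp, mode) as fh:
        fh.write(data)
    os.replace(tmp, path)
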