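"""Forward simulation of side-scan sinograms for point-target phantoms.

Each A-line is the superposition over targets of a bandwidth-limited pulse
arriving at the Gaussian-beam delay of the target's beam coordinates, scaled
by the transducer's receive sensitivity at that position and by geometric
spreading.  Pulse-echo ultrasound uses the two-way delay and the squared
one-way sensitivity (transmit x receive).  Measurement noise is Gaussian,
generated explicitly by the Box-Muller transform from a seeded uniform
stream at a standard deviation given as a fraction of the peak signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    GaussianBeamParams,
    InvalidParameterError,
    ScanGeometry,
    TransducerSpec,
    pixel_beam_coords,
    transducer_pose,
)
from .recon import Sinogram, delay_pa, delay_us

__all__ = [
    "PointTarget",
    "PulseModel",
    "NoiseSpec",
    "field_sensitivity",
    "simulate_pa",
    "simulate_us",
    "box_muller_noise",
    "nine_target_scene",
    "lateral_target_scene",
]

DEFAULT_FIELD_MODEL = "broadband"


@dataclass(frozen=True)
class PointTarget:
    """A point absorber (PA) / point scatterer (US) in the imaging plane."""

    x_mm: float
    y_mm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise InvalidParameterError("amplitude must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x_mm, self.y_mm])


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-envelope cosine pulse with a -6 dB fractional bandwidth.

    p(t) = exp(-t^2 / (2 sigma_t^2)) * cos(2 pi f0 t), with sigma_t chosen so
    the -6 dB (half-amplitude) full width of the spectral envelope equals
    ``fractional_bandwidth * f0``.
    """

    center_frequency_mhz: float = 10.0
    fractional_bandwidth: float = 0.6
    kind: str = "gaussian_cosine"

    def __post_init__(self) -> None:
        if self.center_frequency_mhz <= 0:
            raise InvalidParameterError("center_frequency must be > 0")
        if not 0 < self.fractional_bandwidth < 2:
            raise InvalidParameterError("fractional_bandwidth must be in (0, 2)")
        if self.kind != "gaussian_cosine":
            raise InvalidParameterError(f"unknown pulse kind {self.kind!r}")

    @property
    def sigma_t_us(self) -> float:
        bw_mhz = self.fractional_bandwidth * self.center_frequency_mhz
        return np.sqrt(2.0 * np.log(2.0)) / (np.pi * bw_mhz)

    @property
    def duration_fwhm_us(self) -> float:
        """FWHM of the temporal envelope."""
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma_t_us

    def __call__(self, t_us):
        t = np.asarray(t_us, dtype=float)
        env = np.exp(-(t * t) / (2.0 * self.sigma_t_us**2))
        return env * np.cos(2.0 * np.pi * self.center_frequency_mhz * t)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise, std = sigma_fraction * max|signal|."""

    sigma_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_fraction < 0:
            raise InvalidParameterError("sigma_fraction must be >= 0")


def field_sensitivity(
    a,
    b,
    beam: GaussianBeamParams,
    *,
    model: str = DEFAULT_FIELD_MODEL,
    spec: TransducerSpec | None = None,
    pulse: PulseModel | None = None,
    v: float | None = None,
):
    """One-way receive sensitivity of the focused transducer at (a, b).

    ``model="broadband"`` (default): lateral Gaussian-field profile
    exp(-b^2 / w(a)^2) times an axial defocus factor 1 / (1 + delta/Lp),
    where delta = |a| (1 - cos(asin(NA))) is the path-length spread across
    the receive cone at axial offset a and Lp = v * pulse FWHM duration is
    the spatial pulse length.  For a short pulse an out-of-focus on-axis
    point is attenuated because its wavefront arrives smeared over delta
    rather than in phase, an effect the narrowband (CW) beam profile
    overstates badly; this factor is the standard pulse-limited estimate.
    Requires ``spec``, ``pulse`` and ``v``.

    ``model="cw-weight"``: the continuous-wave Gaussian amplitude used as the
    reconstruction weight, z0^2/(z0^2+a^2) * exp(-2 b^2 / w(a)^2).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    z0 = beam.semi_focal_depth_mm
    w0 = beam.waist_mm
    denom = a * a + z0 * z0
    if model == "cw-weight":
        return (z0 * z0 / denom) * np.exp(-2.0 * b * b * z0 * z0 / (w0 * w0 * denom))
    if model == "broadband":
        if spec is None or pulse is None or v is None:
            raise InvalidParameterError(
                "broadband sensitivity requires spec, pulse and v"
            )
        w_a2 = w0 * w0 * denom / (z0 * z0)  # w(a)^2
        lateral = np.exp(-b * b / w_a2)
        cos_half = np.sqrt(1.0 - spec.numerical_aperture**2)
        delta = np.abs(a) * (1.0 - cos_half)
        pulse_length = v * pulse.duration_fwhm_us
        axial = 1.0 / (1.0 + delta / pulse_length)
        return lateral * axial
    raise InvalidParameterError(f"unknown field model {model!r}")


def _simulate(
    targets,
    geom: ScanGeometry,
    spec: TransducerSpec,
    beam: GaussianBeamParams,
    pulse: PulseModel,
    modality: str,
    field_model: str,
) -> Sinogram:
    times = np.arange(geom.n_samples) / geom.sampling_rate_mhz
    rf = np.zeros((geom.n_angles, geom.n_samples))
    v = geom.speed_of_sound_mm_us
    eps = v / spec.center_frequency_mhz  # one wavelength
    t_max = times[-1]
    half_window = 5.0 * pulse.sigma_t_us
    fs = geom.sampling_rate_mhz
    n_win = int(np.ceil(half_window * fs))

    for target in targets:
        pos = target.position
        clipped = False
        for i in range(geom.n_angles):
            pose = transducer_pose(geom, beam, i)
            a, b = pixel_beam_coords(pos, pose)
            if modality == "pa":
                dt = float(delay_pa(a, b, beam, v))
                sens = field_sensitivity(
                    a, b, beam, model=field_model, spec=spec, pulse=pulse, v=v
                )
            else:
                dt = float(delay_us(a, b, beam, v))
                sens = (
                    field_sensitivity(
                        a, b, beam, model=field_model, spec=spec, pulse=pulse, v=v
                    )
                    ** 2
                )
            if dt > t_max:
                clipped = True
            dist = np.linalg.norm(pos - pose.transducer_position)
            amp = target.amplitude * float(sens) / max(dist, eps)
            center = int(round(dt * fs))
            lo = max(center - n_win, 0)
            hi = min(center + n_win + 1, geom.n_samples)
            if lo >= hi:
                continue
            rf[i, lo:hi] += amp * pulse(times[lo:hi] - dt)
        if clipped:
            warnings.warn(
                f"target at ({target.x_mm}, {target.y_mm}) arrives beyond the "
                "recording window for some angles; contribution clipped",
                stacklevel=3,
            )
    return Sinogram(rf=rf, modality=modality, geometry=geom)


def simulate_pa(
    targets,
    geom: ScanGeometry,
    spec: TransducerSpec,
    beam: GaussianBeamParams,
    pulse: PulseModel,
    *,
    field_model: str = DEFAULT_FIELD_MODEL,
) -> Sinogram:
    """Noise-free photoacoustic sinogram of point absorbers (one-way)."""
    return _simulate(targets, geom, spec, beam, pulse, "pa", field_model)


def simulate_us(
    targets,
    geom: ScanGeometry,
    spec: TransducerSpec,
    beam: GaussianBeamParams,
    pulse: PulseModel,
    *,
    field_model: str = DEFAULT_FIELD_MODEL,
) -> Sinogram:
    """Noise-free pulse-echo ultrasound sinogram (two-way delay, squared
    one-way sensitivity for transmit x receive)."""
    return _simulate(targets, geom, spec, beam, pulse, "us", field_model)


def box_muller_noise(sino: Sinogram, noise: NoiseSpec) -> Sinogram:
    """Add white Gaussian noise generated by the Box-Muller transform.

    The noise standard deviation is ``noise.sigma_fraction`` times the peak
    absolute signal amplitude of the sinogram.  Normal variates are produced
    explicitly from a seeded 64-bit uniform stream via the basic Box-Muller
    transform (both variates of each pair are used), so the same seed yields
    a bit-identical sinogram.
    """
    if noise.sigma_fraction == 0:
        return sino
    sigma = noise.sigma_fraction * np.max(np.abs(sino.rf))
    n = sino.rf.size
    n_pairs = (n + 1) // 2
    rng = np.random.Generator(np.random.PCG64(noise.seed))
    u1 = rng.random(n_pairs)
    u2 = rng.random(n_pairs)
    radius = np.sqrt(-2.0 * np.log(1.0 - u1))  # 1-u1 in (0, 1]: log is finite
    z = np.empty(2 * n_pairs)
    z[0::2] = radius * np.cos(2.0 * np.pi * u2)
    z[1::2] = radius * np.sin(2.0 * np.pi * u2)
    noisy = sino.rf + sigma * z[:n].reshape(sino.rf.shape)
    return replace(sino, rf=noisy)


def nine_target_scene() -> list[PointTarget]:
    """Nine unit-amplitude point targets at x = 3, 4, ..., 11 mm, y = 0."""
    return [PointTarget(x_mm=float(x), y_mm=0.0) for x in range(3, 12)]


def lateral_target_scene(
    depths=None, y_offset_mm: float = 2.0
) -> list[PointTarget]:
    """The nine-target scene plus a parallel row offset laterally by
    ``y_offset_mm`` (default 2 mm)."""
    if depths is None:
        on_axis = nine_target_scene()
    else:
        on_axis = [PointTarget(x_mm=float(x), y_mm=0.0) for x in depths]
    off_axis = [
        PointTarget(x_mm=t.x_mm, y_mm=t.y_mm + y_offset_mm, amplitude=t.amplitude)
        for t in on_axis
    ]
    if y_offset_mm == 0:
        return on_axis
    return on_axis + off_axis
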