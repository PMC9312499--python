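"""Scan/transducer geometry and the equivalent Gaussian acoustic field.

The side-scanning probe rotates about a fixed center; at each scan angle the
focused transducer sits at radius ``L`` from the rotation center and looks
radially outward, with its focus a further focal length ``F`` out along the
viewing axis.  The focused acoustic field is approximated by an equivalent
Gaussian beam (waist ``w0`` at the focus, semi-focal depth ``z0``), which is
what gives the reconstruction its delay and weighting rules.

Canonical units throughout the package: mm, µs, MHz (so the speed of sound in
soft tissue is ~1.5 mm/µs and every geometric quantity is O(1–20)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransducerSpec",
    "ScanGeometry",
    "GaussianBeamParams",
    "TransducerPose",
    "BeamCoords",
    "PositionLimits",
    "derive_gaussian_params",
    "transducer_pose",
    "pixel_beam_coords",
    "position_limits",
]


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class TransducerSpec:
    """Physical parameters of the focused ultrasound transducer.

    Parameters
    ----------
    center_frequency_mhz : float
        Center frequency of the transducer, MHz.
    fractional_bandwidth : float
        −6 dB fractional bandwidth (0–2, dimensionless).
    focal_length_mm : float
        Geometric focal length F, mm.
    numerical_aperture : float
        NA = sin of the aperture half-angle, in (0, 1).
    aperture_diameter_mm : float, optional
        Physical aperture diameter; redundant with NA + F, kept for record.
    """

    center_frequency_mhz: float
    fractional_bandwidth: float
    focal_length_mm: float
    numerical_aperture: float
    aperture_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.center_frequency_mhz <= 0:
            raise InvalidParameterError("center_frequency must be > 0")
        if not 0 < self.fractional_bandwidth < 2:
            raise InvalidParameterError("fractional_bandwidth must be in (0, 2)")
        if self.focal_length_mm <= 0:
            raise InvalidParameterError("focal_length must be > 0")
        if not 0 < self.numerical_aperture < 1:
            raise InvalidParameterError("numerical_aperture must be in (0, 1)")


@dataclass(frozen=True)
class ScanGeometry:
    """Rotational side-scan description.

    ``angles_rad`` are the scan (viewing-axis) angles, strictly increasing.
    ``virtual_radius_mm`` is L, the distance from the virtual transducer to
    the rotation center; ``imaging_radius_mm`` is R, the radius of the imaging
    area measured from the rotation center.
    """

    angles_rad: np.ndarray
    virtual_radius_mm: float
    imaging_radius_mm: float
    speed_of_sound_mm_us: float
    sampling_rate_mhz: float
    n_samples: int
    rotation_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_rad, dtype=float)
        object.__setattr__(self, "angles_rad", angles)
        if angles.ndim != 1 or angles.size == 0:
            raise InvalidParameterError("angles must be a non-empty 1-D array")
        if angles.size > 1 and not np.all(np.diff(angles) > 0):
            raise InvalidParameterError("angles must be strictly increasing")
        if self.virtual_radius_mm < 0:
            raise InvalidParameterError("virtual_radius L must be >= 0")
        if self.imaging_radius_mm <= 0:
            raise InvalidParameterError("imaging_radius R must be > 0")
        if self.speed_of_sound_mm_us <= 0:
            raise InvalidParameterError("speed of sound must be > 0")
        if self.sampling_rate_mhz <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if self.n_samples <= 0:
            raise InvalidParameterError("n_samples must be > 0")

    @property
    def n_angles(self) -> int:
        return int(self.angles_rad.size)

    def check_sampling(self, spec: TransducerSpec) -> None:
        """Warn if the sampling rate violates Nyquist for the transducer."""
        if self.sampling_rate_mhz < 2 * spec.center_frequency_mhz:
            warnings.warn(
                "sampling rate below 2x transducer center frequency",
                stacklevel=2,
            )

    @classmethod
    def from_span(
        cls,
        start_deg: float,
        stop_deg: float,
        step_deg: float,
        **kwargs,
    ) -> "ScanGeometry":
        """Build angles as ``start + k*step`` on the half-open [start, stop)."""
        n = int(np.ceil((stop_deg - start_deg) / step_deg - 1e-9))
        angles_deg = start_deg + step_deg * np.arange(n)
        return cls(angles_rad=np.deg2rad(angles_deg), **kwargs)


@dataclass(frozen=True)
class GaussianBeamParams:
    """Equivalent Gaussian field of the focused transducer.

    ``waist_mm`` is the beam waist radius w0 at the focus and
    ``semi_focal_depth_mm`` the semi-focal depth z0 (Rayleigh-range analogue)
    over which the beam stays near its waist.
    """

    focal_length_mm: float
    waist_mm: float
    semi_focal_depth_mm: float

    def __post_init__(self) -> None:
        for name in ("focal_length_mm", "waist_mm", "semi_focal_depth_mm"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def beam_radius(self, a):
        """Beam radius w(a) = w0*sqrt(1 + a^2/z0^2) at axial offset a (mm)."""
        a = np.asarray(a, dtype=float)
        return self.waist_mm * np.sqrt(1.0 + (a / self.semi_focal_depth_mm) ** 2)


@dataclass(frozen=True)
class TransducerPose:
    """Pose of the (virtual) transducer at one scan angle."""

    origin: np.ndarray           # rotation center O_i
    transducer_position: np.ndarray
    focus: np.ndarray            # focal point F_i
    axis_unit: np.ndarray        # from transducer through focus, outward

    def __post_init__(self) -> None:
        for name in ("origin", "transducer_position", "focus", "axis_unit"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(np.linalg.norm(self.axis_unit) - 1.0) > 1e-12:
            raise InvalidParameterError("axis_unit must be a unit vector")


@dataclass(frozen=True)
class BeamCoords:
    """Axial (a, signed) and radial (b >= 0) distances from the focal point."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.b < 0:
            raise InvalidParameterError("b must be non-negative")


@dataclass(frozen=True)
class PositionLimits:
    """Bounds (a1<=a<=a2, b1<=b<=b2) of the delayed-superposition region."""

    a1: float
    a2: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if self.a1 > self.a2 or self.b1 > self.b2:
            raise InvalidParameterError("limits must satisfy a1<=a2 and b1<=b2")


def derive_gaussian_params(
    spec: TransducerSpec,
    v: float,
    *,
    strategy: str = "na-match",
    waist_mm: float | None = None,
    semi_focal_depth_mm: float | None = None,
    z0_max_mm: float = 1e6,
) -> GaussianBeamParams:
    """Derive the equivalent Gaussian beam for a focused transducer.

    The default ``na-match`` strategy matches the far-field divergence of a
    Gaussian beam to the transducer aperture: with wavelength λ = v/f0,

        w0 = λ / (π · NA),    z0 = w0 / NA  (= π w0² / λ).

    The ``explicit`` strategy takes user-provided ``waist_mm`` and
    ``semi_focal_depth_mm`` verbatim (the focal length is always taken from
    ``spec``).  ``z0_max_mm`` caps the semi-focal depth so the unfocused
    limit NA→0 stays finite.
    """
    if v <= 0:
        raise InvalidParameterError("speed of sound must be > 0")
    if strategy == "na-match":
        wavelength = v / spec.center_frequency_mhz
        w0 = wavelength / (np.pi * spec.numerical_aperture)
        z0 = min(w0 / spec.numerical_aperture, z0_max_mm)
    elif strategy == "explicit":
        if waist_mm is None or semi_focal_depth_mm is None:
            raise InvalidParameterError(
                "explicit strategy requires waist_mm and semi_focal_depth_mm"
            )
        w0 = waist_mm
        z0 = min(semi_focal_depth_mm, z0_max_mm)
    else:
        raise InvalidParameterError(f"unknown strategy {strategy!r}")
    return GaussianBeamParams(
        focal_length_mm=spec.focal_length_mm,
        waist_mm=w0,
        semi_focal_depth_mm=z0,
    )


def transducer_pose(
    geom: ScanGeometry, beam: GaussianBeamParams, i: int
) -> TransducerPose:
    """Pose of the virtual transducer at angle index ``i``.

    The transducer sits at radius L from the rotation center on the viewing
    axis and looks radially outward; the focus lies a focal length further
    out, at L + F from the center.
    """
    if not 0 <= i < geom.n_angles:
        raise IndexError(f"angle index {i} out of range [0, {geom.n_angles})")
    theta = float(geom.angles_rad[i])
    u = np.array([np.cos(theta), np.sin(theta)])
    center = np.asarray(geom.rotation_center, dtype=float)
    position = center + geom.virtual_radius_mm * u
    focus = position + beam.focal_length_mm * u
    return TransducerPose(
        origin=center, transducer_position=position, focus=focus, axis_unit=u
    )


def pixel_beam_coords(r, pose: TransducerPose):
    """Map pixel position(s) ``r`` into beam coordinates (a, b) of ``pose``.

    ``a`` is the signed projection of (r − F) onto the rotation-center→focus
    axis (positive beyond the focus), ``b`` the non-negative distance from
    the axis.  ``r`` may be a single 2-vector or an (N, 2) array; returns a
    pair of floats or a pair of length-N arrays accordingly.
    """
    axis = pose.focus - pose.origin
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise InvalidParameterError(
            "degenerate pose: focus coincides with rotation center"
        )
    u = axis / norm
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    rel = np.atleast_2d(r) - pose.focus
    a = rel @ u
    perp = rel - np.outer(a, u)
    b = np.linalg.norm(perp, axis=1)
    if single:
        return float(a[0]), float(b[0])
    return a, b


def position_limits(geom: ScanGeometry, beam: GaussianBeamParams) -> PositionLimits:
    """Bounds of the superposition region for this scan geometry.

    a1 = L − F, a2 = R − F + L, b1 = −R, b2 = R.  Since b >= 0 by
    construction, b1 is never binding and the radial test reduces to b <= R.
    """
    L = geom.virtual_radius_mm
    F = beam.focal_length_mm
    R = geom.imaging_radius_mm
    return PositionLimits(a1=L - F, a2=R - F + L, b1=-R, b2=R)
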