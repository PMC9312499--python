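import numpy as np
import pytest

from gbbp import (
    GaussianBeamParams,
    PulseModel,
    ScanGeometry,
    TransducerSpec,
    derive_gaussian_params,
)

SPEED_OF_SOUND = 1.5  # mm/us, soft tissue


@pytest.fixture(scope="session")
def spec() -> TransducerSpec:
    """The 10 MHz / 60% bandwidth / F=7 mm / NA=0.5054 focused transducer."""
    return TransducerSpec(
        center_frequency_mhz=10.0,
        fractional_bandwidth=0.6,
        focal_length_mm=7.0,
        numerical_aperture=0.5054,
    )


@pytest.fixture(scope="session")
def beam(spec) -> GaussianBeamParams:
    return derive_gaussian_params(spec, SPEED_OF_SOUND)


@pytest.fixture(scope="session")
def study_geometry() -> ScanGeometry:
    """30 degree sector at 0.25 degree steps (121 angles), 200 MHz, R=12.5."""
    return ScanGeometry.from_span(
        -15.0, 15.25, 0.25,
        virtual_radius_mm=0.0,
        imaging_radius_mm=12.5,
        speed_of_sound_mm_us=SPEED_OF_SOUND,
        sampling_rate_mhz=200.0,
        n_samples=4000,
    )


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """Coarse sector scan for fast unit tests."""
    return ScanGeometry.from_span(
        -15.0, 16.0, 1.0,
        virtual_radius_mm=0.0,
        imaging_radius_mm=12.5,
        speed_of_sound_mm_us=SPEED_OF_SOUND,
        sampling_rate_mhz=200.0,
        n_samples=2400,
    )


@pytest.fixture(scope="session")
def pulse() -> PulseModel:
    return PulseModel(center_frequency_mhz=10.0, fractional_bandwidth=0.6)
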