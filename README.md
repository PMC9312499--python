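# gbbp — Gaussian-beam back-projection for photoacoustic/ultrasound endoscopy

Side-scanning acoustic-resolution photoacoustic/ultrasound endoscopes image
with a single focused transducer rotating inside a lumen. Conventional B-mode
display paints each received A-line along its beam axis, so lateral
resolution and SNR collapse away from the acoustic focus. This package
implements **Gaussian-beam back-projection (GB-BP)**: a delay-and-sum
reconstruction that models the focused transducer as an equivalent Gaussian
beam and refocuses every depth coherently (virtual-point-detector synthetic
aperture focusing), restoring out-of-focus lateral resolution and SNR.

It is aimed at people building or evaluating rotational-scan photoacoustic /
ultrasound endoscopy systems: it bundles the reconstruction, a B-mode
baseline, a forward sinogram simulator for point-target phantoms, and the
evaluation protocol (lateral FWHM, repeated-noise-trial SNR) used to compare
algorithms.

## The algorithm

The transducer (focal length F, numerical aperture NA) is replaced by an
equivalent Gaussian beam with waist w0 = λ/(π·NA) at the focus and
semi-focal depth z0 = w0/NA. With a and b the axial and radial distances of
a pixel from the focal point of scan position i, each pixel is formed as

    I(r) = Σ_i A(i, r) · S(i, Δt(i, r)),

with the delay following the Gaussian-beam phase front through the virtual
focal point,

    Δt = ( F + a·√(1 + b²/(a² + z0²)) ) / v      (photoacoustic, one-way)
    Δt = 2·( F + a·√(1 + b²/(a² + z0²)) ) / v    (pulse-echo ultrasound)

and the weight following the beam's amplitude profile, gated to the scanned
region (a1 ≤ a ≤ a2, b ≤ R):

    A = z0²/(z0² + a²) · exp( −2 b² z0² / (w0² (a² + z0²)) ).

Envelope detection runs after the coherent sum, along radial lines of the
polar working grid; `scan_convert` resamples to a Cartesian display grid.
The B-mode baseline envelope-detects each A-line and maps it at range v·t
(one-way) or v·t/2 (pulse-echo) with no cross-angle synthesis.

## Worked example

Nine point targets at 3–11 mm depth, 10 MHz / 60% bandwidth transducer
focused at 7 mm (NA 0.5054), 30° sector at 0.25° steps, 200 MHz sampling —
the package's default configuration:

```python
import numpy as np
from gbbp import (ExperimentConfig, NoiseSpec, PolarGrid, envelope, lateral_fwhm,
                  reconstruct_bmode, reconstruct_gbbp, snr_trials)
from gbbp.simulate import nine_target_scene, simulate_us

config = ExperimentConfig()          # the reference study conditions
spec, geom = config.transducer(), config.geometry()
beam, pulse = config.beam(), config.pulse()
print(f"equivalent Gaussian beam: w0 = {beam.waist_mm:.4f} mm, z0 = {beam.semi_focal_depth_mm:.4f} mm")

targets = nine_target_scene()
sino = simulate_us(targets, geom, spec, beam, pulse)   # noise-free pulse-echo
radii = np.arange(0.5, 12.5, 0.005)
grid = PolarGrid(geom.angles_rad.copy(), radii)
gbbp_img = envelope(reconstruct_gbbp(sino, beam, grid))
bmode_img = reconstruct_bmode(sino, radii)
for name, img in (("GB-BP", gbbp_img), ("B-mode", bmode_img)):
    fwhm = lateral_fwhm(img, (3.0, 0.0))
    print(f"{name:6s} lateral FWHM of the 3 mm target: {fwhm:.3f} mm")

snr = snr_trials(targets, geom, spec, beam, pulse, NoiseSpec(0.05, seed=1),
                 algo="gbbp", modality="us", n_trials=50, clean_sino=sino)
print(f"GB-BP  SNR of the 3 mm target (50 noise trials): {snr[0]:.1f} dB")
```

prints

```
equivalent Gaussian beam: w0 = 0.0945 mm, z0 = 0.1869 mm
GB-BP  lateral FWHM of the 3 mm target: 0.111 mm
B-mode lateral FWHM of the 3 mm target: 0.842 mm
GB-BP  SNR of the 3 mm target (50 noise trials): 36.3 dB
```

The 3 mm target sits 4 mm inside the 7 mm focus; B-mode leaves it smeared to
0.84 mm laterally while GB-BP recovers it to the pulse-limited 0.11 mm, and
the trial-based SNR (20·log10 of mean peak amplitude over its standard
deviation across repeated 5%-of-peak noise realizations) stays high because
the coherent sum averages the noise across all 121 A-lines.

The same pipelines are scriptable from the shell (`gbbp simulate`,
`gbbp reconstruct`, `gbbp evaluate`, `gbbp repro-depth-scan`,
`gbbp repro-lateral`); each run writes a CSV report plus a manifest with the
configuration digest and seed so it can be reproduced bit-exactly.

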