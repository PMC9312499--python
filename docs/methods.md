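# Methods

## Geometry and units

All computations use mm / µs / MHz, so the soft-tissue speed of sound is
v ≈ 1.5 mm/µs and every geometric quantity is O(1–20). The probe rotates
about a fixed center; at scan angle θᵢ the virtual transducer sits at radius
L from the rotation center and looks radially outward, with the acoustic
focus a focal length F further out. The beam axis used for the coordinates
(a, b) is the rotation-center→focus direction, so a > 0 beyond the focus and
b ≥ 0 off-axis.

The default configuration places the transducer at the rotation center
(L = 0), which puts the focus at exactly 7 mm from the center — the focal
depth at which the reference point-target study evaluates both algorithms —
with the imaging radius R = 12.5 mm. L is an ordinary config key
(`virtual_radius_mm`) for probes where the element is offset from the
rotation axis.

Scan angles are generated bit-exactly as `start + k·step` on a half-open
interval; the default `−15°, 15.25°, 0.25°` yields 121 angles spanning the
30° sector symmetrically about the target row.

## Equivalent Gaussian beam

The focused field is summarized by a waist w0 and semi-focal depth z0. The
default derivation matches the far-field divergence of a Gaussian beam to
the transducer aperture:

    λ = v / f0,   w0 = λ / (π·NA),   z0 = w0 / NA  (= π w0²/λ).

For the 10 MHz, NA 0.5054 transducer this gives w0 = 0.0945 mm and
z0 = 0.1869 mm. Users with a characterized field can bypass the rule with
explicit `beam_waist_mm` / `beam_z0_mm` overrides. z0 is capped
(`z0_max_mm`, default 10⁶ mm) so the unfocused limit NA → 0 stays finite;
in that limit single-angle GB-BP degenerates to plain range mapping and
coincides with the B-mode baseline, which the test suite exercises.

The lateral weight exponent is exp(−2b²z0²/(w0²(a²+z0²))) =
exp(−2b²/w(a)²) with w(a) = w0·√(1+a²/z0²): the Gaussian-beam lateral
intensity profile, reducing to exp(−2b²/w0²) in the focal plane. A variant
with the factor-of-two in the denominator of the exponent is selectable
(`exponent="half"` in `gaussian_weight`) for comparison with
implementations that read the weight that way.

## Reconstruction

GB-BP is implemented exactly as the weighted delay-and-sum above: no
normalization by the weight sum (a normalized variant sits behind a flag),
linear interpolation of each A-line in time (at 20 samples per carrier
period the worst-case interpolation error is (π f/fs)²/2 ≈ 1.25%;
nearest-neighbor is available for speed), and samples requested outside the
recorded window contribute zero rather than raising — pixels near the grid
edge must not poison the sum. Delays are one-way for photoacoustic
reception and exactly doubled for pulse-echo ultrasound.

The working grid is polar (scan angles × radii), pixel centers at the grid
nodes. Envelope detection (magnitude of the analytic signal) runs **after**
the coherent summation, along radial lines — summation must happen in the
RF domain to preserve phase coherence, standard synthetic-aperture
practice. `scan_convert` bilinearly resamples to a Cartesian display grid
with pixel centers at (min + (j+½)·pitch); pixels outside the angular span
are zero. Repeated reconstructions of a fixed grid (the trial loop of the
SNR protocol) go through `GBBPOperator`, which precomputes the per-(pixel,
angle) weights and fractional sample indices once.

The B-mode baseline is the literal conventional display: per-A-line
envelope, painted along the beam axis at range v·t (one-way) or v·t/2
(pulse-echo) from the virtual transducer, no apodization, no cross-angle
summation.

## Forward simulator

The simulator emulates a rotational side-scan acquisition of point targets:
each A-line is a superposition over targets of a Gaussian-envelope cosine
pulse (−6 dB fractional bandwidth 0.6 at 10 MHz by default — the minimal
pulse matching a stated center frequency and bandwidth) arriving at the
Gaussian-beam delay of the target's (a, b), scaled by the transducer's
receive sensitivity and by 1/max(distance, λ) geometric spreading.
Ultrasound uses the two-way delay and the squared one-way sensitivity
(transmit × receive as a product of one-way amplitudes).

Two sensitivity models are provided (`field_model`):

- `broadband` (default): lateral Gaussian field exp(−b²/w(a)²) times an
  axial defocus factor 1/(1 + δ/Lp), where δ = |a|·(1 − cos(asin NA)) is
  the path-length spread across the receive cone at axial offset a and
  Lp = v·(pulse envelope FWHM) is the spatial pulse length. For broadband
  reception the on-axis response of a defocused point is limited by this
  wavefront smear, not by the continuous-wave beam profile.
- `cw-weight`: the CW Gaussian amplitude that GB-BP itself uses as a
  weight, z0²/(z0²+a²)·exp(−2b²/w(a)²).

The broadband model is the default because the CW axial factor, with
z0 ≈ 0.19 mm, attenuates a target 4 mm from the focus by ~46 dB one-way
(~92 dB pulse-echo): out-of-focus targets then sit far below any realistic
noise floor, which contradicts the phenomenon the reconstruction exists to
demonstrate (visible out-of-focus targets whose resolution and SNR the
refocusing recovers) and makes algorithm comparisons degenerate into
comparisons of noise statistics. The broadband factor keeps the 3 mm target
~14 dB below the focal one in pulse-echo mode — defocused but measurable.

Noise is added per the stated protocol: white Gaussian samples with
standard deviation equal to 5% of the sinogram's peak absolute amplitude,
generated explicitly by the basic Box–Muller transform (both variates of
each pair used) from a seeded 64-bit uniform stream, so a seed fully
determines the realization.

What the simulator does **not** model: diffraction from a physical aperture
(no spatial impulse response), frequency-dependent attenuation, speed-of-
sound heterogeneity, refraction, elevational (out-of-plane) geometry, and
extended absorbers beyond collections of points. Passing tests therefore
demonstrate the reconstruction's behavior under its own field model — the
self-consistent setting in which delay errors are zero — not its
performance on measured data, where tissue heterogeneity and aperture
diffraction will degrade both algorithms.

## Evaluation protocol

**Lateral FWHM.** The target's peak is located within ±0.5 mm of its
nominal position (reconstruction can shift peaks slightly; the window is
configurable). The lateral profile is the tangential cut through the peak —
perpendicular to the radial beam axis, the resolution-limited direction in
this geometry — read at the peak radius of the polar image with arc length
as the coordinate (on Cartesian images, a bilinearly interpolated line
profile along a supplied direction). Half-maximum crossings are located by
linear interpolation walking outward from the peak; a profile that never
falls to half (e.g. clipped by the sector edge) raises an undefined-FWHM
error rather than returning a number.

**Trial-based SNR.** Trial t adds noise with seed base+t (any single trial
is independently reproducible), reconstructs, and records each target's
peak envelope amplitude in its search window; the statistic is
20·log10(mean/std) over trials, with an infinite-SNR sentinel (and a
warning) if the std is exactly zero. GB-BP trials reconstruct only a small
polar patch per target through a precomputed operator, which keeps the
200-trial × 2-algorithm × 2-modality protocol under two minutes on one
CPU. A background-region variant (peak over the std of a user-specified
box at similar depth) supports externally acquired phantom sinograms where
repeated noise realizations are unavailable.

Both algorithms see the same noisy sinogram in each trial (shared seed
ladder), so algorithm comparisons are paired.

**Improvement percent** is 100·(baseline − improved)/baseline. Note that
for the published phantom pair (3.975 → 1.857 mm) the formula yields
53.3%, not the 52.3% sometimes quoted alongside those inputs; the
discrepancy is asserted in the tests rather than reconciled.

## Numerical choices and degenerate inputs

- Time interpolation: linear (default) or nearest; out-of-window → 0.
- Envelope requires an RF-stage polar image; B-mode output is already
  envelope-stage.
- A pose whose focus coincides with the rotation center has no defined
  beam axis and is rejected.
- b ≥ 0 by construction, so the b ≥ −R limit is never binding and the
  radial gate reduces to b ≤ R.
- Peak search windows that contain no grid pixels raise, as do profiles
  whose maximum sits on the grid edge.
- Simulated arrivals beyond the recording window are clipped with a
  warning (per-angle), not an error.
- Default grids: radial pitch 5 µm (≈ 15 samples per pulse-echo carrier
  period along the envelope axis); the tangential sampling is the 0.25°
  scan pitch, ≈ 13 µm at the 3 mm target.

## Problem sizes

The shipped study configuration is the full protocol: 121 angles × 4000
samples per sinogram, 2400-radius × 121-angle working images, 200 noise
trials. The acceptance script runs it in ~90 s on one CPU; the test suite
additionally extends the trial ladder to 400 to bound the sampling error of
the SNR estimate (each estimate moves < 1 dB when the trial count doubles).

## Known limitations

- The forward model shares its delay rule with the reconstruction, so
  GB-BP operates under zero model mismatch; measured data will not be so
  kind. The B-mode arc of a near target is consequently curved in
  (angle, radius), which narrows its fixed-radius tangential profile
  relative to a simulator with flat per-angle ranges — B-mode FWHMs of
  near targets here are optimistic in that specific sense.
- The Eq.-12-style SNR statistic applied to a peak search window is biased
  upward for weak signals (the extremum of a noise field has a large
  mean-to-std ratio); B-mode SNR values for deeply defocused ultrasound
  targets should be read with that in mind.
- Targets whose tangential search window falls outside the scanned sector
  (e.g. the near end of a y = 2 mm row under a 30° sector centered on the
  axis) have undefined FWHM and are reported as NaN, not extrapolated.
- No attenuation, heterogeneity, or 3-D effects; see the simulator section.
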