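# Methods

## Imaging model

The instrument is modelled as an incoherent imager with a circular pupil
of diameter `D` (default 6.7 mm) at imaging wavelength `λ` (850 nm),
giving a diffraction-limited cutoff `f_c = D/λ ≈ 137.6` cycles/degree
(cpd).  The generalized pupil is a hard-edged disc times
`exp(i·2π·a·Z4)` with `Z4 = √3(2ρ²−1)` the unit-RMS defocus polynomial
and `a` the defocus in waves RMS; the PSF is `|IFFT(pupil)|²` normalized
to unit sum, so the OTF is exactly the pupil autocorrelation with support
`f_c`.  The in-focus layer uses `a = 0` (the wavefront corrector is
assumed to have removed all aberrations except an intentional focus
offset); the background layer uses `a = 1.5` waves RMS by default — large
enough that the background PSF is a broad halo which absorbs out-of-focus
and multiply-scattered content, which is the job of the second layer.

The fringe pattern is `mean·(1 + c·cos(2π f_m (x cosθ + y sinθ) + φ))`
with `f_m = 34` cpd and orientations ±45°, static in the instrument frame;
eye motion shifts the object *under* the pattern, which is what produces
the fringe-phase diversity.  On the defocused layer the fringe contrast is
0 by default (blurring erases the grid).  The in-focus fringe contrast
defaults to **0.3**: projection through the eye's optics attenuates the
grating once by the system MTF at 34 cpd, and the scattering background
dilutes the visible modulation further, so realistic raw frames show only
faint fringes.  This value matters: the residual bias that fringe
sidebands exert on correlation-based shift estimation scales with the
contrast squared, and at contrast ≳ 0.5 it exceeds a few hundredths of a
pixel.  Controlled experiments that need strong modulation (the two-point
and probe-sinusoid tests) construct their own illumination model with
contrast 0.9 explicitly.

Shifts are applied as Fourier phase ramps with periodic boundary; integer
shifts coincide with circular rolls, and fractional shifts are exact for
content below the Nyquist bin (the Nyquist component of a real signal has
no well-defined subpixel translation, which is why round-trip tests use
band-limited images).  Decimation is comb sampling (every q-th pixel) and
its exact adjoint is zero insertion; the object grid is `q = 2` times
finer than the camera grid so the fringe-extended band
`f_c + f_m ≈ 171.6` cpd stays below the reconstruction Nyquist frequency
(403 cpd at 403 px/degree camera sampling).  The apodization taper applied
to the measured frames can be folded into the operator (`window=`), so the
model predicts tapered data consistently.

## Reconstruction

The criterion is the least-squares data term over all selected frames,
scaled by a single homogeneous noise variance, plus quadratic Fourier
penalties on each layer weighted by inverse radial power-spectrum models
`S(f) = k/(1+(f/f0)^p)`.  Minimization is bound-constrained L-BFGS-B over
both layers jointly (positivity on every pixel), with the analytic
gradient assembled from the exact operator adjoint.  Initialization puts
the non-negative-clipped, counter-shifted mean of the frames in `o0` and
starts `od` at zero: when fringes are present the sidebands pin down
`o0` across the band and the descent moves unmodulated content into
`od`; when they are absent the data cannot distinguish the layers and
this start resolves the degeneracy in favour of the in-focus layer.
Iteration stops at a relative criterion decrease below `tol` (default
1e-6) or `max_iter` (default 300); the accepted-iterate criterion trace is
non-increasing by construction of the line search.

Hyperparameters are estimated from the data: the noise variance is the
mean of the circularly averaged per-pixel periodogram (`|FFT|²/Npix`) over
radial frequencies more than one bin above `f_c`, where the optics admit
no signal; `(k, f0, p)` of `S_o0` are fitted by log-space least squares to
the excess periodogram below `f_c`; and `S_od` reuses the fit with its
corner frequency scaled by the ratio of half-power MTF radii of the two
PSFs (an RMS-bandwidth summary was rejected because a ringing defocused
MTF does not shrink by that measure).  `λ` is fixed at 0.3 and exposed in
the configuration.

The positivity constraint produces spectral extrapolation for objects on
a dark background: the constrained solution of a point-object problem
carries strictly more energy beyond `f_c + f_m` than the unconstrained
quadratic solution, which the test suite asserts as an inequality.

## Registration

Shift estimation runs on notch-filtered copies of the *cropped, untapered*
frames.  The plain phase-correlation estimate is biased toward zero on
small tapered fields because the apodization window is static while the
scene moves; the taper is therefore excluded from the registration input
(it is still applied to the reconstruction data, where the imaging model
accounts for it).  The estimator is: integer phase correlation, then
re-estimation of the subpixel part on the integer-aligned overlap of the
two frames (mean-removed and cosine-tapered — tapering *after* alignment
is unbiased), then two passes of re-registration against the
counter-shifted temporal mean, which has higher SNR than any single frame.
On the synthetic SNR-5 fixture this recovers shifts with ≈0.05 px RMS
error.  Frames whose registered correlation with the reference falls below
a floor are flagged invalid rather than raising.

The Fourier notch removes the fringe carrier but not the modulated
sidebands; the residual sideband-sideband correlation biases the peak by
an amount proportional to the squared fringe contrast (≈0.01–0.03 px at
the default contrast 0.3).  This is why shift estimates are
fringe-insensitive at the study conditions but would not be under strong
modulation.

## Synthetic data

The generator emulates the statistical structure of a fringe-illuminated
retinal acquisition:

- **in-focus layer** — hexagonal cone lattice (default pitch 5 µm at
  300 µm/degree retinal magnification), positions jittered by 10% of the
  pitch, Gaussian cone profiles (σ = 1.2 µm), log-normal reflectances
  with CV 0.2;
- **background layer** — Gaussian-correlated positive random field
  (correlation length 15 µm) scaled to twice the mean in-focus intensity,
  emulating the strong scattering background that dominates wide-field
  frame contrast;
- **motion** — Gaussian random-walk drift (0.5 px/frame RMS at 100 Hz,
  ≈0.12 deg/s, the low end of fixational drift speeds) plus
  Poisson-timed microsaccade jumps (0.5 /s, 8 px amplitude — deliberately
  small so the content stays inside the scaled-down field);
- **acquisition** — 100 Hz frame rate with 2 Hz orientation switching
  (50-frame blocks), camera dark offset 100 counts, additive homogeneous
  Gaussian noise, and a configurable fraction of blink-surrogate frames
  (Gaussian blur σ = 3 px and 50% intensity drop, which the
  gradient-energy selection step must reject).

Everything is a pure function of the specs and a seed.  What the generator
does *not* emulate: intra-frame (rolling) motion blur, spatially varying
fringe contrast across the field, AO-correction dynamics, photoreceptor
reflectance fluctuations over time, and non-Gaussian detector noise.
Passing tests therefore demonstrate the correctness and the qualitative
resolution/sectioning behaviour of the chain under the modelled physics,
not performance on clinical data.

## Problem sizes

The native geometry (2048² frames cropped to 1024², 1000-frame records)
is scaled down so full pipelines run in seconds: the default synthetic
scene uses a 256×256-pixel camera field (cropped to 128×128) at the
native 403 px/degree scale, records of 48–500 frames, and 7–48 frames per
orientation in reconstructions.  Registration-accuracy and
phase-coverage checks run at the native timing (2 s at 100 Hz, 50-frame
blocks) because phase diversity accumulates with the number of frames in
the selection window.  The acceptance script uses the 128×128 crop with
8 frames per orientation after selection.

## Numerical choices and edge cases

- Periodograms are `|FFT|²` scaled by the pixel count once (hyperparameter
  estimation, plateau = pixel variance) or twice (radial PSD metric,
  Parseval: annulus-weighted sum equals the mean square).
- The effective cutoff compares a 3-bin moving-average of the radial PSD
  against 1.1× the supplied noise floor and takes the lowest frequency
  beyond which the spectrum stays under it, evaluated only inside the
  circular band (corner bins hold too few samples); if the spectrum never
  settles, the band edge is returned.
- Frame selection breaks quality ties in favour of earlier frames;
  candidate contrast windows always span the full window length
  (maximizing a mean over shrinking slivers would degenerate); orientation
  balancing drops the lowest-contrast frames of the larger group.
- Cone detection thresholds local maxima at the Otsu split of the
  smoothed image — background versus foreground — rather than of the
  peak-amplitude distribution, which is unimodal on a clean mosaic and
  would be bisected arbitrarily.
- Dark-subtracted intensities are kept signed; clipping would bias the
  noise plateau used for `σ²`.
- Counter-shift averaging suppresses the fringe carrier by roughly an
  order of magnitude in power on a 5-s record; the residual is limited by
  the number of effectively independent fringe phases a temporally
  correlated drift walk visits, not by the frame count.

## Known limitations

- The two-layer split is identifiable only through the fringe modulation;
  with weak contrast and few frames, low-frequency content can leak
  between layers (the priors arbitrate).
- Per-frame noise variances (`σ_j`) are supported in the data structures
  but the estimator returns a single homogeneous value.
- The defocus of the background PSF is a fixed model parameter, not
  estimated from data.
- No intra-frame distortion or torsion correction; shifts are pure
  translations.
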