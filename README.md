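# sio — structured illumination ophthalmoscopy

`sio` simulates and reconstructs **structured illumination ophthalmoscopy
(SIO)** acquisitions: wide-field retinal imaging in which a static
sinusoidal fringe pattern is projected onto the retina while the eye's own
fixational motion supplies the phase diversity that structured illumination
microscopy normally obtains by stepping the pattern.  Exploiting that
motion, the package reconstructs an in-focus retinal layer that is both
**super-resolved** (the fringes down-modulate object frequencies beyond the
optical cutoff into the passband) and **optically sectioned** (out-of-focus
and multiply-scattered light is rejected into a separate background layer).
It is aimed at researchers in adaptive-optics retinal imaging who want to
prototype or validate motion-aware SIM reconstruction without access to an
instrument.

## The model

Each camera frame `i_j` of a two-layer retinal object `o = (o0, od)` —
`o0` the in-focus cone-mosaic layer, `od` the defocused scattering
background — is modelled as

```
M_j(o0, od) = [ h0 ⋆ (m_j,0 · t_j[o0]) ]↓ + [ hd ⋆ (m_j,d · t_j[od]) ]↓
```

where `t_j` is the subpixel retinal shift of frame *j*, `m_j,0` / `m_j,d`
the fringe patterns seen by each layer (the fringes are washed out on the
defocused layer), `h0` / `hd` the in-focus and defocused PSFs of the
circular pupil, `⋆` circular convolution and `↓` decimation from an
oversampled object grid to the camera grid.  The layers are estimated by
minimizing, under a positivity constraint, the MAP criterion

```
J(o0, od) = 1/2 Σ_j ‖ (i_j − M_j(o0, od)) / σ ‖² 
          + λ/2 [ Σ_f |õ0(f)|²/S_o0(f) + Σ_f |õd(f)|²/S_od(f) ]
```

with the noise variance `σ²` and the radial object power spectra `S_o0`,
`S_od` estimated from the data in an unsupervised way and `λ = 0.3`.

Around the reconstruction core the package provides the full processing
chain: dark subtraction, centre cropping and cosine-taper apodization;
three-step frame selection (gradient-energy quality filter, best
fringe-contrast time window, orientation balancing); notch filtering and
subpixel shift estimation; wide-field reference construction; radial power
spectral densities with a noise-limited effective cutoff frequency; and
cone detection with density-versus-eccentricity profiles.  A synthetic
acquisition generator (jittered hexagonal cone mosaic, smooth scattering
background, drift + microsaccade eye motion, blink-degraded frames, camera
offset and Gaussian noise) makes every stage testable end to end.

## Worked example

```bash
sio simulate --seed 7 --out run_dir
sio run --data-dir run_dir
```

which prints, for the default synthetic scene (256×256 camera pixels at
403 px/degree, 34 cpd fringes at ±45°, 6.7 mm pupil at 850 nm):

```
simulated acquisition written to run_dir
widefield cutoff 176.3 cpd, SIO cutoff 251.9 cpd
```

The first number is the radial frequency at which the wide-field image's
periodogram falls to its noise floor — the SNR-limited resolution of a
conventional flood-illumination image built from the very same frames.
The second is the same measurement on the reconstructed in-focus layer:
the fringe demodulation and deconvolution keep signal above the noise
floor tens of cycles/degree further out, i.e. the reconstruction resolves
finer cone spacings than the wide-field average.  `run_dir/output/`
contains the reconstructed layers (`o0.tif`, `od.tif`), the wide-field
reference, the selection report, the shift trajectory, the radial spectra
and a cone-density map, plus a manifest that makes the run reproducible.

The same chain is available as a library:

```python
from sio.forward_model import OpticalModel, IlluminationModel
from sio.bossa_sim import reconstruct

result = reconstruct(selected_stack, shifts, OpticalModel(), IlluminationModel())
result.object.o0        # super-resolved, sectioned in-focus layer
result.hyper            # unsupervised noise variance and object spectra
```

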