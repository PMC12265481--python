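"""Imaging model of a fringe-illuminated flood ophthalmoscope.

The model images a two-layer retinal object through a circular pupil: an
in-focus layer ``o0`` seen through the in-focus PSF ``h0`` under contrasted
sinusoidal fringes, and a defocused layer ``od`` seen through a strongly
blurred PSF ``hd`` on which the fringes are washed out.  For frame *j* with
inter-frame retinal shift ``t_j`` the noiseless camera image is::

    M_j(o0, od) = down( h0 * (m_j0 . t_j[o0]) ) + down( hd * (m_jd . t_j[od]) )

where ``*`` is circular 2-D convolution, ``.`` pointwise multiplication,
``m_j0``/``m_jd`` the per-frame illumination patterns, and ``down`` comb
decimation from the oversampled object grid to the camera grid.  The object
grid is ``q`` times finer than the camera grid so that the fringe-extended
band (optical cutoff plus modulation frequency) remains below the
reconstruction Nyquist frequency.

Conventions: arrays are (row=y, col=x), 0-based; shifts are (dy, dx) in
camera pixels of the retina relative to the reference frame; spatial
frequencies are in cycles/degree via the camera pixel scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2

from .units import DEFAULT_RETINAL_SCALE_UM_PER_DEG, diffraction_cutoff_cpd


class SamplingError(ValueError):
    """Raised when a grid is too coarse to represent the optical band."""


@dataclass
class OpticalModel:
    """Pupil geometry and sampling of the instrument.

    Parameters
    ----------
    pupil_diameter_mm : eye-pupil diameter D in millimetres.
    imaging_wavelength_nm : centre wavelength of the imaging source.
    pixel_scale : camera sampling in degrees of visual angle per pixel.
    oversampling_factor : integer q; the object grid is q times finer.
    defocus_infocus, defocus_background : RMS defocus (waves) of the
        in-focus and background PSFs.
    retinal_scale : µm of retina per degree of visual angle.
    """

    pupil_diameter_mm: float = 6.7
    imaging_wavelength_nm: float = 850.0
    pixel_scale: float = 1.0 / 403.0
    oversampling_factor: int = 2
    defocus_infocus: float = 0.0
    defocus_background: float = 1.5
    retinal_scale: float = DEFAULT_RETINAL_SCALE_UM_PER_DEG

    def __post_init__(self) -> None:
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil diameter must be positive")
        if self.imaging_wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel scale must be positive")
        q = self.oversampling_factor
        if not (isinstance(q, (int, np.integer)) and q >= 1):
            raise ValueError("oversampling factor must be an integer >= 1")
        if self.object_nyquist_cpd() < self.cutoff_cpd():
            raise SamplingError(
                f"object-grid Nyquist {self.object_nyquist_cpd():.1f} cpd is "
                f"below the optical cutoff {self.cutoff_cpd():.1f} cpd"
            )

    def cutoff_cpd(self) -> float:
        """Incoherent diffraction cutoff D/lambda in cycles/degree."""
        return diffraction_cutoff_cpd(
            self.pupil_diameter_mm, self.imaging_wavelength_nm
        )

    @property
    def object_pixel_scale(self) -> float:
        """Degrees per pixel of the oversampled object grid."""
        return self.pixel_scale / self.oversampling_factor

    def object_nyquist_cpd(self) -> float:
        return 0.5 / self.object_pixel_scale

    def camera_nyquist_cpd(self) -> float:
        return 0.5 / self.pixel_scale


@dataclass
class IlluminationModel:
    """Sinusoidal fringe illumination, static in the instrument frame.

    ``orientations`` lists the fringe orientations cycled through in blocks
    of ``frames_per_block`` frames; the pattern value is
    ``mean_level * (1 + contrast * cos(2 pi f_m (x cos t + y sin t) + phase))``
    with (x, y) in degrees.  ``contrast_background`` applies to the defocused
    layer, where blurring normally erases the fringes (default 0).
    """

    modulation_frequency_cpd: float = 34.0
    orientations: tuple[float, ...] = (45.0, -45.0)
    frames_per_block: int = 50
    phase_per_frame: float | Sequence[float] = 0.0
    contrast_infocus: float = 0.3
    contrast_background: float = 0.0
    mean_level: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_level <= 0:
            raise ValueError("mean_level must be positive")
        for c in (self.contrast_infocus, self.contrast_background):
            if not 0.0 <= c <= 1.0:
                raise ValueError("contrast must lie in [0, 1]")
        if self.modulation_frequency_cpd <= 0:
            raise ValueError("modulation frequency must be positive")
        if self.frames_per_block < 1:
            raise ValueError("frames_per_block must be >= 1")

    def orientation_of(self, frame_index: int) -> float:
        block = frame_index // self.frames_per_block
        return self.orientations[block % len(self.orientations)]

    def phase_of(self, frame_index: int) -> float:
        if np.isscalar(self.phase_per_frame):
            return float(self.phase_per_frame)
        return float(self.phase_per_frame[frame_index])


@dataclass
class TwoLayerObject:
    """In-focus layer ``o0`` and defocused layer ``od`` on the object grid."""

    o0: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.o0 = np.asarray(self.o0, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.o0.shape != self.od.shape:
            raise ValueError("o0 and od must share a grid")
        if self.o0.ndim != 2:
            raise ValueError("layers must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.o0.shape


@dataclass
class ShiftTrajectory:
    """Per-frame (dy, dx) retinal shifts in camera pixels, plus validity."""

    shifts: np.ndarray
    valid: np.ndarray = None
    reference_index: int = 0

    def __post_init__(self) -> None:
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=float))
        if self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n, 2) of (dy, dx)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")
        if self.valid is None:
            self.valid = np.ones(len(self.shifts), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.shifts)

    def __getitem__(self, j: int) -> tuple[float, float]:
        return tuple(self.shifts[j])


# ---------------------------------------------------------------------------
# PSF / pattern constructors


def make_psf(
    optical: OpticalModel,
    defocus_waves: float,
    grid_shape: tuple[int, int],
    pixel_scale_deg: float | None = None,
) -> np.ndarray:
    """Incoherent PSF of a circular pupil with a pure-defocus aberration.

    The generalized pupil is ``P(f) = circ(|f| <= fc/2) exp(i 2 pi a Z4)``
    with ``Z4 = sqrt(3)(2 rho^2 - 1)`` the unit-RMS defocus polynomial and
    ``a`` the defocus in waves RMS; the PSF is ``|IFFT(P)|^2`` normalized to
    unit sum, returned in wrap-around (origin at [0, 0]) layout ready for
    circular convolution.  Its OTF support is exactly the incoherent cutoff
    D/lambda.
    """
    ps = optical.object_pixel_scale if pixel_scale_deg is None else pixel_scale_deg
    ny, nx = grid_shape
    if 0.5 / ps < optical.cutoff_cpd():
        raise SamplingError(
            f"grid Nyquist {0.5 / ps:.1f} cpd below cutoff "
            f"{optical.cutoff_cpd():.1f} cpd"
        )
    fy = fftfreq(ny, d=ps)
    fx = fftfreq(nx, d=ps)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    pupil_radius = optical.cutoff_cpd() / 2.0  # coherent (amplitude) cutoff
    rho2 = f2 / pupil_radius**2
    aperture = f2 <= pupil_radius**2
    z4 = np.sqrt(3.0) * (2.0 * rho2 - 1.0)
    pupil = aperture * np.exp(2j * np.pi * defocus_waves * z4)
    amplitude = ifft2(pupil)
    psf = np.abs(amplitude) ** 2
    return psf / psf.sum()


def otf(psf: np.ndarray) -> np.ndarray:
    """OTF (unit DC) of a PSF given in wrap-around layout."""
    h = fft2(psf)
    return h / h[0, 0]


def make_pattern(
    illum: IlluminationModel,
    frame_index: int,
    grid_shape: tuple[int, int],
    pixel_scale_deg: float,
) -> np.ndarray:
    """Fringe pattern seen by frame ``frame_index`` on the given grid."""
    theta = illum.orientation_of(frame_index)
    return fringe_pattern(
        grid_shape,
        pixel_scale_deg,
        illum.modulation_frequency_cpd,
        theta,
        phase=illum.phase_of(frame_index),
        contrast=illum.contrast_infocus,
        mean_level=illum.mean_level,
    )


def fringe_pattern(
    grid_shape: tuple[int, int],
    pixel_scale_deg: float,
    frequency_cpd: float,
    orientation_deg: float,
    phase: float = 0.0,
    contrast: float = 1.0,
    mean_level: float = 1.0,
) -> np.ndarray:
    """Non-negative sinusoidal intensity pattern on a pixel grid."""
    if contrast > mean_level:
        raise ValueError("contrast above mean_level would yield negative intensity")
    ny, nx = grid_shape
    y = np.arange(ny)[:, None] * pixel_scale_deg
    x = np.arange(nx)[None, :] * pixel_scale_deg
    t = np.deg2rad(orientation_deg)
    arg = 2.0 * np.pi * frequency_cpd * (x * np.cos(t) + y * np.sin(t)) + phase
    return mean_level * (1.0 + contrast * np.cos(arg))


# ---------------------------------------------------------------------------
# Elementary operators


def apply_shift(img: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Subpixel translation by (dy, dx) with periodic boundary.

    Implemented as a Fourier-domain phase ramp; integer shifts coincide with
    a circular roll and (0, 0) is the identity.
    """
    dy, dx = shift
    if not (np.isfinite(dy) and np.isfinite(dx)):
        raise ValueError("shift must be finite")
    if dy == 0 and dx == 0:
        return np.array(img, dtype=float, copy=True)
    ny, nx = img.shape
    ramp = np.exp(
        -2j
        * np.pi
        * (fftfreq(ny)[:, None] * dy + fftfreq(nx)[None, :] * dx)
    )
    return np.real(ifft2(fft2(img) * ramp))


def downsample(img: np.ndarray, q: int) -> np.ndarray:
    """Comb decimation: keep every q-th sample starting at index 0."""
    if q == 1:
        return np.asarray(img)
    ny, nx = img.shape
    if ny % q or nx % q:
        raise ValueError(f"shape {img.shape} not divisible by q={q}")
    return img[::q, ::q]


def upsample(img: np.ndarray, q: int) -> np.ndarray:
    """Zero-insertion upsampling, the exact adjoint of :func:`downsample`."""
    if q == 1:
        return np.asarray(img)
    ny, nx = img.shape
    out = np.zeros((ny * q, nx * q), dtype=img.dtype)
    out[::q, ::q] = img
    return out


# ---------------------------------------------------------------------------
# Full per-frame operator


def _layer_kernels(optical: OpticalModel, grid_shape: tuple[int, int]):
    h0 = make_psf(optical, optical.defocus_infocus, grid_shape)
    hd = make_psf(optical, optical.defocus_background, grid_shape)
    return fft2(h0), fft2(hd)


def _background_pattern(
    illum: IlluminationModel,
    frame_index: int,
    grid_shape: tuple[int, int],
    pixel_scale_deg: float,
) -> np.ndarray:
    return fringe_pattern(
        grid_shape,
        pixel_scale_deg,
        illum.modulation_frequency_cpd,
        illum.orientation_of(frame_index),
        phase=illum.phase_of(frame_index),
        contrast=illum.contrast_background,
        mean_level=illum.mean_level,
    )


def forward(
    obj: TwoLayerObject,
    shifts: ShiftTrajectory,
    optical: OpticalModel,
    illum: IlluminationModel,
    frame_index: int,
) -> np.ndarray:
    """Noiseless camera image of frame ``frame_index`` (shift -> illuminate
    -> convolve -> decimate, per layer, summed)."""
    op = StackOperator(
        obj.shape,
        optical,
        illum,
        shifts.shifts[frame_index : frame_index + 1],
        orientations=[illum.orientation_of(frame_index)],
        phases=[illum.phase_of(frame_index)],
    )
    return op.forward_frame(obj, 0)


def adjoint(
    residual: np.ndarray,
    shifts: ShiftTrajectory,
    optical: OpticalModel,
    illum: IlluminationModel,
    frame_index: int,
) -> TwoLayerObject:
    """Adjoint of :func:`forward` applied to a camera-grid residual."""
    q = optical.oversampling_factor
    obj_shape = (residual.shape[0] * q, residual.shape[1] * q)
    op = StackOperator(
        obj_shape,
        optical,
        illum,
        shifts.shifts[frame_index : frame_index + 1],
        orientations=[illum.orientation_of(frame_index)],
        phases=[illum.phase_of(frame_index)],
    )
    return op.adjoint_frame(residual, 0)


class StackOperator:
    """Cached multi-frame imaging operator.

    Precomputes the two OTFs, the per-frame illumination patterns and the
    Fourier shift ramps once, so that repeated forward/adjoint evaluations
    inside the reconstruction loop cost four FFTs per frame and layer.

    An optional camera-grid ``window`` (the apodization taper applied to the
    measured frames) can be folded into the operator so the model predicts
    tapered data consistently.
    """

    def __init__(
        self,
        obj_shape: tuple[int, int],
        optical: OpticalModel,
        illum: IlluminationModel,
        shifts: np.ndarray,
        orientations: Sequence[float] | None = None,
        phases: Sequence[float] | None = None,
        window: np.ndarray | None = None,
    ) -> None:
        self.optical = optical
        self.illum = illum
        self.obj_shape = tuple(obj_shape)
        q = optical.oversampling_factor
        if self.obj_shape[0] % q or self.obj_shape[1] % q:
            raise ValueError("object grid must be divisible by the oversampling q")
        self.cam_shape = (self.obj_shape[0] // q, self.obj_shape[1] // q)
        self.q = q
        self.shifts = np.atleast_2d(np.asarray(shifts, dtype=float))
        n = len(self.shifts)
        if orientations is None:
            orientations = [illum.orientation_of(j) for j in range(n)]
        if phases is None:
            phases = [illum.phase_of(j) for j in range(n)]
        self.orientations = np.asarray(orientations, dtype=float)
        self.phases = np.asarray(phases, dtype=float)
        if len(self.orientations) != n or len(self.phases) != n:
            raise ValueError("orientations/phases must match the shift count")
        self.window = None if window is None else np.asarray(window, dtype=float)
        if self.window is not None and self.window.shape != self.cam_shape:
            raise ValueError("window must live on the camera grid")

        ps = optical.object_pixel_scale
        self.H0, self.Hd = _layer_kernels(optical, self.obj_shape)
        # patterns depend only on (orientation, phase); cache unique pairs
        self._m0: dict[tuple[float, float], np.ndarray] = {}
        self._md: dict[tuple[float, float], np.ndarray] = {}
        for theta, phi in zip(self.orientations, self.phases):
            key = (float(theta), float(phi))
            if key not in self._m0:
                self._m0[key] = fringe_pattern(
                    self.obj_shape, ps, illum.modulation_frequency_cpd, theta,
                    phase=phi, contrast=illum.contrast_infocus,
                    mean_level=illum.mean_level,
                )
                self._md[key] = fringe_pattern(
                    self.obj_shape, ps, illum.modulation_frequency_cpd, theta,
                    phase=phi, contrast=illum.contrast_background,
                    mean_level=illum.mean_level,
                )
        fy = fftfreq(self.obj_shape[0])[:, None]
        fx = fftfreq(self.obj_shape[1])[None, :]
        self._ramps = [
            np.exp(-2j * np.pi * (fy * dy * q + fx * dx * q))
            for dy, dx in self.shifts
        ]

    def __len__(self) -> int:
        return len(self.shifts)

    def _patterns(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        key = (float(self.orientations[j]), float(self.phases[j]))
        return self._m0[key], self._md[key]

    def forward_frame(self, obj: TwoLayerObject, j: int) -> np.ndarray:
        if obj.shape != self.obj_shape:
            raise ValueError(
                f"object grid {obj.shape} does not match operator {self.obj_shape}"
            )
        m0, md = self._patterns(j)
        ramp = self._ramps[j]
        img = np.zeros(self.cam_shape)
        for layer, m, H in ((obj.o0, m0, self.H0), (obj.od, md, self.Hd)):
            shifted = np.real(ifft2(fft2(layer) * ramp))
            blurred = np.real(ifft2(fft2(m * shifted) * H))
            img += downsample(blurred, self.q)
        if self.window is not None:
            img = img * self.window
        return img

    def adjoint_frame(self, residual: np.ndarray, j: int) -> TwoLayerObject:
        if residual.shape != self.cam_shape:
            raise ValueError(
                f"residual grid {residual.shape} does not match camera "
                f"{self.cam_shape}"
            )
        if self.window is not None:
            residual = residual * self.window
        m0, md = self._patterns(j)
        ramp = self._ramps[j]
        up = upsample(np.asarray(residual, dtype=float), self.q)
        Fup = fft2(up)
        grads = []
        for m, H in ((m0, self.H0), (md, self.Hd)):
            back = np.real(ifft2(Fup * np.conj(H)))
            g = np.real(ifft2(fft2(m * back) * np.conj(ramp)))
            grads.append(g)
        return TwoLayerObject(grads[0], grads[1])

    def forward_stack(self, obj: TwoLayerObject) -> np.ndarray:
        return np.stack([self.forward_frame(obj, j) for j in range(len(self))])

    def adjoint_stack(self, residuals: np.ndarray) -> TwoLayerObject:
        g0 = np.zeros(self.obj_shape)
        gd = np.zeros(self.obj_shape)
        for j in range(len(self)):
            g = self.adjoint_frame(residuals[j], j)
            g0 += g.o0
            gd += g.od
        return TwoLayerObject(g0, gd)


__all__ = [
    "OpticalModel",
    "IlluminationModel",
    "TwoLayerObject",
    "ShiftTrajectory",
    "SamplingError",
    "make_psf",
    "otf",
    "make_pattern",
    "fringe_pattern",
    "apply_shift",
    "downsample",
    "upsample",
    "forward",
    "adjoint",
    "StackOperator",
]
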