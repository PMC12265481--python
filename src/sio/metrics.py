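"""Post-reconstruction analysis.

Wide-field reference construction, radial power spectral densities, the
noise-limited effective cutoff frequency, smooth-background correction,
cone detection and cone-density mapping with a reliability mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .forward_model import ShiftTrajectory, apply_shift
from .stack import FrameStack


@dataclass
class RadialSpectrum:
    """Circularly averaged periodogram.

    ``psd`` holds the mean of ``|FFT|^2 / Npix^2`` over each radial
    annulus, so that ``sum(psd * counts)`` equals the mean square of the
    frame (Parseval).  ``freqs`` are the annulus centre frequencies in
    cycles/degree.
    """

    freqs: np.ndarray
    psd: np.ndarray
    counts: np.ndarray
    noise_floor: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency bins must increase")
        if np.any(self.psd < 0):
            raise ValueError("PSD must be non-negative")

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass
class ConeDensityMap:
    """Sliding-window cone density (cones/mm^2) and eccentricity profile."""

    density_grid: np.ndarray
    window_centers_deg: np.ndarray
    ecc_bins_deg: np.ndarray
    mean_density: np.ndarray
    std_density: np.ndarray
    reliable: np.ndarray


def build_widefield(stack: FrameStack, shifts: ShiftTrajectory) -> np.ndarray:
    """Fringe-free flood-illumination reference: counter-shift and average.

    Registering by the opposite of each retinal shift aligns the retina
    across frames while the static fringes land at a different phase in
    every frame, so they cancel in the temporal average.
    """
    if len(shifts) != len(stack):
        raise ValueError("one shift per frame is required")
    use = np.nonzero(shifts.valid)[0]
    if len(use) == 0:
        raise ValueError("no valid shifts")
    acc = np.zeros(stack.frame_shape)
    for j in use:
        dy, dx = shifts.shifts[j]
        acc += apply_shift(stack.frames[j], (-dy, -dx))
    return acc / len(use)


def radial_psd(frame: np.ndarray, pixel_scale_deg: float) -> RadialSpectrum:
    """Periodogram of a square frame, circularly averaged in cpd bins."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != frame.shape[1]:
        raise ValueError("frame must be square")
    n = frame.shape[0]
    npix = n * n
    spec = np.abs(fft2(frame)) ** 2 / npix**2
    fy = fftfreq(n, d=pixel_scale_deg)
    fr = np.hypot(fy[:, None], fy[None, :])
    df = 1.0 / (n * pixel_scale_deg)
    bins = np.round(fr / df).astype(int)
    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=spec.ravel())
    return RadialSpectrum(
        freqs=np.arange(len(counts)) * df,
        psd=sums / counts,
        counts=counts,
    )


def noise_floor(spectrum: RadialSpectrum, above_cpd: float) -> float:
    """Mean radial PSD over frequencies above ``above_cpd`` (noise plateau)."""
    mask = spectrum.freqs > above_cpd
    if not mask.any():
        raise ValueError("no bins above the requested frequency")
    return float(spectrum.psd[mask].mean())


def effective_cutoff(
    spectrum: RadialSpectrum,
    noise_floor: float,
    tolerance: float = 1.1,
    smooth_bins: int = 3,
) -> float:
    """Radial frequency where the PSD falls to the noise floor for good.

    The radial PSD is smoothed with a short moving average, and the cutoff
    is the smallest non-DC frequency beyond which it stays below
    ``tolerance * noise_floor`` for every higher bin; returns the Nyquist
    frequency if the spectrum never settles at the floor.
    """
    if noise_floor <= 0:
        raise ValueError("noise floor must be positive")
    # restrict to the circular band: corner bins (f > Nyquist of the axes)
    # hold few samples and fluctuate wildly
    axis_nyquist = spectrum.freqs[-1] / np.sqrt(2.0)
    last = int(np.searchsorted(spectrum.freqs, axis_nyquist, side="right"))
    psd = spectrum.psd[:last].copy()
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        psd = np.convolve(psd, kernel, mode="same")
    below = psd <= tolerance * noise_floor
    below[0] = False  # DC never counts
    # smallest i>0 with below[i:] all True
    tail_ok = np.flip(np.cumprod(np.flip(below.astype(bool))))
    idx = np.nonzero(tail_ok)[0]
    idx = idx[idx > 0]
    if len(idx) == 0:
        return float(spectrum.freqs[last - 1])
    return float(spectrum.freqs[idx[0]])


def background_correct(
    frame: np.ndarray,
    low_cut_cpd: float,
    high_cut_cpd: float,
    pixel_scale_deg: float,
) -> np.ndarray:
    """Gaussian bandpass (difference of Gaussians) in the Fourier domain.

    Suppresses the smooth illumination falloff below ``low_cut_cpd`` while
    leaving the cone-mosaic band untouched; the DC component is removed so
    the output is zero-mean.
    """
    ny, nx = frame.shape
    if not 0 < low_cut_cpd < high_cut_cpd:
        raise ValueError("require 0 < low_cut < high_cut")
    fy = fftfreq(ny, d=pixel_scale_deg)
    fx = fftfreq(nx, d=pixel_scale_deg)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    h = np.exp(-f2 / (2.0 * high_cut_cpd**2)) - np.exp(-f2 / (2.0 * low_cut_cpd**2))
    return np.real(ifft2(fft2(frame) * h))


def detect_cones(frame: np.ndarray, min_separation_px: float) -> np.ndarray:
    """(k, 2) array of (y, x) cone centres.

    Local maxima of a lightly smoothed frame (sigma = separation / 3) with
    non-maximum suppression at ``min_separation_px``, keeping maxima above
    the Otsu foreground/background threshold of the smoothed frame (cone
    centres sit on the bright side; spurious maxima in the dark background
    do not).  Deterministic.
    """
    if min_separation_px < 2:
        raise ValueError("min_separation must be at least 2 px")
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        return np.empty((0, 2))
    smooth = gaussian_filter(frame, min_separation_px / 3.0)
    peaks = peak_local_max(
        smooth, min_distance=int(round(min_separation_px)), exclude_border=False
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    vals = smooth[peaks[:, 0], peaks[:, 1]]
    thr = threshold_otsu(smooth)
    return peaks[vals >= thr]


def cone_density_map(
    positions: np.ndarray,
    field_shape: tuple[int, int],
    pixel_scale_deg: float,
    retinal_scale: float,
    window_px: int,
    fovea_center_px: tuple[float, float] | None = None,
    ecc_bin_deg: float = 0.1,
) -> ConeDensityMap:
    """Sliding-window density map and eccentricity profile.

    Windows of side ``window_px`` slide with half-window stride; each
    window's density is its cone count over its retinal area in mm^2
    (through the µm/degree retinal scale).  Windows are grouped by the
    eccentricity of their centre from ``fovea_center_px`` (field centre by
    default); a bin is reliable where std/mean <= 0.1.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    ny, nx = field_shape
    if window_px > min(ny, nx):
        raise ValueError("window larger than the field")
    if fovea_center_px is None:
        fovea_center_px = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    stride = max(window_px // 2, 1)
    area_mm2 = (window_px * pixel_scale_deg * retinal_scale * 1e-3) ** 2

    centers = []
    dens = []
    rows = range(0, ny - window_px + 1, stride)
    cols = range(0, nx - window_px + 1, stride)
    grid = np.zeros((len(list(rows)), len(list(cols))))
    for i, y0 in enumerate(range(0, ny - window_px + 1, stride)):
        for k, x0 in enumerate(range(0, nx - window_px + 1, stride)):
            if len(positions):
                inside = (
                    (positions[:, 0] >= y0)
                    & (positions[:, 0] < y0 + window_px)
                    & (positions[:, 1] >= x0)
                    & (positions[:, 1] < x0 + window_px)
                )
                count = int(inside.sum())
            else:
                count = 0
            d = count / area_mm2
            grid[i, k] = d
            cy = y0 + window_px / 2.0
            cx = x0 + window_px / 2.0
            ecc = np.hypot(cy - fovea_center_px[0], cx - fovea_center_px[1])
            centers.append(ecc * pixel_scale_deg)
            dens.append(d)
    centers = np.asarray(centers)
    dens = np.asarray(dens)

    n_bins = int(np.ceil((centers.max() + 1e-9) / ecc_bin_deg)) if len(centers) else 1
    bins = np.arange(n_bins + 1) * ecc_bin_deg
    mids = 0.5 * (bins[:-1] + bins[1:])
    mean = np.zeros(n_bins)
    std = np.zeros(n_bins)
    for b in range(n_bins):
        sel = (centers >= bins[b]) & (centers < bins[b + 1])
        if sel.any():
            mean[b] = dens[sel].mean()
            std[b] = dens[sel].std()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), np.inf)
    reliable = ratio <= 0.1
    return ConeDensityMap(
        density_grid=grid,
        window_centers_deg=centers,
        ecc_bins_deg=mids,
        mean_density=mean,
        std_density=std,
        reliable=reliable,
    )
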