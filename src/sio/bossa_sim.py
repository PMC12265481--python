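"""Two-layer MAP reconstruction with unsupervised hyperparameters.

The reconstruction minimizes, under a positivity constraint on both
layers,

    J(o0, od) = 1/2 sum_j || (i_j - M_j(o0, od)) / sigma ||^2
              + lambda/2 [ sum_f |O0(f)|^2 / S_o0(f)
                         + sum_f |Od(f)|^2 / S_od(f) ]

where M_j is the motion-aware fringe-illumination imaging model, sigma^2
the homogeneous noise variance, S_o0/S_od radial power-spectral-density
priors on the two layers and O0/Od the 2-D DFTs of the layers.  The noise
variance is read off the pure-noise plateau of the frame periodograms
above the optical cutoff, and the object PSDs are fitted to the excess
periodogram below the cutoff — no hand tuning per dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy.optimize import least_squares, minimize

from .forward_model import (
    IlluminationModel,
    OpticalModel,
    ShiftTrajectory,
    StackOperator,
    TwoLayerObject,
    apply_shift,
    make_psf,
    otf,
)
from .stack import FrameStack


@dataclass
class PsdModel:
    """Radial object PSD model  S(f) = k / (1 + (f/f0)^p)."""

    k: float
    f0: float
    p: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.f0 <= 0 or self.p <= 0:
            raise ValueError("PSD parameters must be positive")

    def __call__(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return self.k / (1.0 + (f / self.f0) ** self.p)


@dataclass
class Hyperparameters:
    noise_variance: float
    s_o0: PsdModel
    s_od: PsdModel
    lam: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_variance <= 0:
            raise ValueError("noise variance must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class ReconstructionResult:
    object: TwoLayerObject
    hyper: Hyperparameters
    criterion_trace: list[float]
    iterations: int
    converged: bool
    widefield: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Unsupervised hyperparameter estimation


def _radial_periodogram(frames: np.ndarray, pixel_scale_deg: float):
    """Mean per-pixel periodogram |FFT|^2 / Npix, radially binned (cpd)."""
    n, ny, nx = frames.shape
    npix = ny * nx
    spec = np.zeros((ny, nx))
    for f in frames:
        spec += np.abs(fft2(f)) ** 2
    spec /= n * npix
    fy = fftfreq(ny, d=pixel_scale_deg)
    fx = fftfreq(nx, d=pixel_scale_deg)
    fr = np.hypot(fy[:, None], fx[None, :])
    df = 1.0 / (ny * pixel_scale_deg)
    bins = np.round(fr / df).astype(int)
    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=spec.ravel())
    radial = sums / counts
    freqs = np.arange(len(radial)) * df
    return freqs, radial


def _half_power_bandwidth_cpd(optical: OpticalModel, defocus_waves: float) -> float:
    """Radius where the radially averaged MTF first drops below 0.5."""
    n = 128
    ps = optical.object_pixel_scale
    h = make_psf(optical, defocus_waves, (n, n), pixel_scale_deg=ps)
    H = np.abs(otf(h))
    fy = fftfreq(n, d=ps)
    fr = np.hypot(fy[:, None], fy[None, :])
    df = 1.0 / (n * ps)
    bins = np.round(fr / df).astype(int)
    radial = np.bincount(bins.ravel(), weights=H.ravel()) / np.bincount(bins.ravel())
    below = np.nonzero(radial < 0.5)[0]
    idx = below[0] if len(below) else len(radial) - 1
    return float(max(idx, 1) * df)


def estimate_hyperparameters(
    stack: FrameStack,
    optical: OpticalModel,
    lam: float = 0.3,
) -> Hyperparameters:
    """Estimate sigma^2 and the two object PSD models from the data.

    sigma^2 is the mean of the radially averaged frame periodogram over
    frequencies above the optical cutoff (where only noise has power),
    converted back to pixel variance through Parseval.  The in-focus PSD
    parameters (k, f0, p) are fitted by log-space least squares to the
    excess periodogram below the cutoff, and the defocused-layer PSD reuses
    the fit with its corner frequency scaled down by the background-PSF
    bandwidth ratio.
    """
    if len(stack) < 10:
        raise ValueError("need at least 10 frames for a stable estimate")
    frames = stack.frames
    npix = frames.shape[1] * frames.shape[2]
    freqs, radial = _radial_periodogram(frames, optical.pixel_scale)
    fc = optical.cutoff_cpd()
    # one-bin margin: the radial bin straddling the cutoff still contains
    # in-band signal
    df = freqs[1] if len(freqs) > 1 else 0.0
    plateau = freqs > fc + df
    if not plateau.any():
        raise ValueError(
            "no frequency bins above the optical cutoff; cannot isolate noise"
        )
    # per-pixel periodogram |FFT|^2/Npix has expectation sigma^2 in every
    # bin for white noise, so the plateau mean IS the pixel variance
    sigma2 = float(radial[plateau].mean())
    noise_level = sigma2
    signal_power = float(frames.var())
    sigma2 = max(sigma2, 1e-12 * max(signal_power, 1e-300))

    passband = (freqs > 0) & (freqs <= fc)
    excess = radial[passband] - noise_level
    f_pass = freqs[passband]
    good = excess > 0
    if good.sum() >= 3:
        f_fit = f_pass[good]
        y_fit = np.log(excess[good])  # per-pixel periodogram units

        def resid(x):
            logk, logf0, logp = x
            model = logk - np.log1p((f_fit / np.exp(logf0)) ** np.exp(logp))
            return model - y_fit

        k0 = float(np.exp(y_fit[0]))
        below = np.nonzero(y_fit < y_fit[0] - np.log(2.0))[0]
        half = f_fit[below[0]] if len(below) else float(np.median(f_fit))
        x0 = np.log([max(k0, 1e-12), max(half, f_fit[0]), 3.0])
        try:
            sol = least_squares(resid, x0, max_nfev=200)
            k, f0, p = np.exp(sol.x)
        except Exception:  # pragma: no cover - fit pathologies
            k, f0, p = max(k0, 1e-12), max(half, f_fit[0]), 3.0
        p = float(np.clip(p, 0.5, 12.0))
    else:
        # essentially pure noise: weak flat-ish prior
        k, f0, p = max(signal_power, sigma2), fc / 4.0, 2.0
    s_o0 = PsdModel(float(k), float(f0), float(p))

    bw0 = _half_power_bandwidth_cpd(optical, optical.defocus_infocus)
    bwd = _half_power_bandwidth_cpd(optical, optical.defocus_background)
    ratio = max(bwd / bw0, 1e-3)
    s_od = PsdModel(float(k), float(f0 * ratio), float(p))
    return Hyperparameters(float(sigma2), s_o0, s_od, lam=lam)


# ---------------------------------------------------------------------------
# Criterion and gradient


def _psd_weights(
    hyper: Hyperparameters, obj_shape: tuple[int, int], pixel_scale_deg: float
):
    """Inverse prior spectra 1/S on the object-grid DFT frequencies.

    The radial models are scaled by the pixel count so they weight raw
    (unnormalized) DFT coefficients; a relative floor guards against
    division blow-up in the far tail.
    """
    ny, nx = obj_shape
    npix = ny * nx
    fy = fftfreq(ny, d=pixel_scale_deg)
    fx = fftfreq(nx, d=pixel_scale_deg)
    fr = np.hypot(fy[:, None], fx[None, :])
    out = []
    for model in (hyper.s_o0, hyper.s_od):
        s = model(fr) * npix
        s = np.maximum(s, model.k * npix * 1e-9)
        out.append(1.0 / s)
    return out


def criterion(
    obj: TwoLayerObject,
    stack: FrameStack,
    shifts: ShiftTrajectory,
    optical: OpticalModel,
    illum: IlluminationModel,
    hyper: Hyperparameters,
    window: np.ndarray | None = None,
) -> float:
    """MAP criterion value J for a candidate two-layer object."""
    op = _operator(obj.shape, stack, shifts, optical, illum, window)
    J, _ = _criterion_and_gradient(obj, stack.frames, op, optical, hyper, want_grad=False)
    return J


def criterion_gradient(
    obj: TwoLayerObject,
    stack: FrameStack,
    shifts: ShiftTrajectory,
    optical: OpticalModel,
    illum: IlluminationModel,
    hyper: Hyperparameters,
    window: np.ndarray | None = None,
) -> TwoLayerObject:
    """Analytic gradient of J with respect to (o0, od)."""
    op = _operator(obj.shape, stack, shifts, optical, illum, window)
    _, grad = _criterion_and_gradient(obj, stack.frames, op, optical, hyper, want_grad=True)
    return grad


def _operator(obj_shape, stack, shifts, optical, illum, window):
    return StackOperator(
        obj_shape,
        optical,
        illum,
        shifts.shifts,
        orientations=stack.orientations,
        phases=[illum.phase_of(j) for j in range(len(stack))],
        window=window,
    )


def _criterion_and_gradient(
    obj: TwoLayerObject,
    frames: np.ndarray,
    op: StackOperator,
    optical: OpticalModel,
    hyper: Hyperparameters,
    want_grad: bool = True,
):
    if hyper.noise_variance <= 0:
        raise ZeroDivisionError("noise variance must be positive")
    sigma2 = hyper.noise_variance
    inv_s0, inv_sd = _psd_weights(hyper, obj.shape, optical.object_pixel_scale)
    npix = obj.shape[0] * obj.shape[1]

    J = 0.0
    g0 = np.zeros(obj.shape) if want_grad else None
    gd = np.zeros(obj.shape) if want_grad else None
    for j in range(len(op)):
        model = op.forward_frame(obj, j)
        r = model - frames[j]
        J += 0.5 * np.sum(r**2) / sigma2
        if want_grad:
            g = op.adjoint_frame(r / sigma2, j)
            g0 += g.o0
            gd += g.od

    O0 = fft2(obj.o0)
    Od = fft2(obj.od)
    J += 0.5 * hyper.lam * float(np.sum(np.abs(O0) ** 2 * inv_s0))
    J += 0.5 * hyper.lam * float(np.sum(np.abs(Od) ** 2 * inv_sd))
    if want_grad:
        g0 += hyper.lam * npix * np.real(ifft2(O0 * inv_s0))
        gd += hyper.lam * npix * np.real(ifft2(Od * inv_sd))
        return float(J), TwoLayerObject(g0, gd)
    return float(J), None


# ---------------------------------------------------------------------------
# Reconstruction


def registered_mean(frames: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Average of counter-shifted frames (fringe-cancelling wide-field)."""
    acc = np.zeros(frames.shape[1:])
    for f, (dy, dx) in zip(frames, shifts):
        acc += apply_shift(f, (-dy, -dx))
    return acc / len(frames)


def _initial_object(
    frames: np.ndarray, shifts: np.ndarray, q: int
) -> tuple[TwoLayerObject, np.ndarray]:
    wf = registered_mean(frames, shifts)
    up = np.repeat(np.repeat(wf, q, axis=0), q, axis=1)
    # start with everything in the in-focus layer; the fringe sidebands
    # determine o0 across the band, and od then absorbs the unmodulated
    # remainder during the descent
    o0 = np.clip(up, 0.0, None)
    od = np.zeros_like(o0)
    return TwoLayerObject(o0, od), wf


def reconstruct(
    stack: FrameStack,
    shifts: ShiftTrajectory,
    optical: OpticalModel,
    illum: IlluminationModel,
    hyper: Hyperparameters | None = None,
    lam: float = 0.3,
    max_iter: int = 300,
    tol: float = 1e-6,
    window: np.ndarray | None = None,
    init: TwoLayerObject | None = None,
    positivity: bool = True,
) -> ReconstructionResult:
    """Bound-constrained quasi-Newton minimization of the MAP criterion.

    Requires balanced per-orientation frame counts; warns when fewer than
    7 frames per orientation are supplied (the theoretical minimum phase
    diversity for a noiseless reconstruction).  Hyperparameters are
    estimated from the stack when not given.  Deterministic given inputs.
    """
    counts = stack.orientation_counts()
    if len(set(counts.values())) > 1:
        raise ValueError(f"unbalanced orientation counts: {counts}")
    if min(counts.values()) < 7:
        warnings.warn(
            "fewer than 7 frames per orientation: below the theoretical "
            "phase-diversity minimum for fringe demodulation",
            stacklevel=2,
        )
    if len(stack) != len(shifts):
        raise ValueError("one shift per frame is required")
    if hyper is None:
        hyper = estimate_hyperparameters(stack, optical, lam=lam)

    q = optical.oversampling_factor
    cam = stack.frame_shape
    obj_shape = (cam[0] * q, cam[1] * q)
    op = _operator(obj_shape, stack, shifts, optical, illum, window)

    if init is None:
        init_obj, wf = _initial_object(stack.frames, shifts.shifts, q)
    else:
        init_obj, wf = init, registered_mean(stack.frames, shifts.shifts)

    npix = obj_shape[0] * obj_shape[1]
    frames = stack.frames
    trace: list[float] = []
    last = {"f": None}

    def fun(x):
        obj = TwoLayerObject(
            x[:npix].reshape(obj_shape), x[npix:].reshape(obj_shape)
        )
        J, g = _criterion_and_gradient(obj, frames, op, optical, hyper)
        if not np.isfinite(J):
            raise FloatingPointError(
                f"criterion non-finite at iteration {len(trace)}"
            )
        last["f"] = J
        return J, np.concatenate([g.o0.ravel(), g.od.ravel()])

    def cb(xk):
        trace.append(last["f"])

    x0 = np.concatenate([init_obj.o0.ravel(), init_obj.od.ravel()])
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * x0.size if positivity else None,
        callback=cb,
        options={"maxiter": max_iter, "ftol": tol, "maxcor": 10},
    )
    obj = TwoLayerObject(
        res.x[:npix].reshape(obj_shape), res.x[npix:].reshape(obj_shape)
    )
    return ReconstructionResult(
        object=obj,
        hyper=hyper,
        criterion_trace=trace,
        iterations=int(res.nit),
        converged=bool(res.success),
        widefield=wf,
    )
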