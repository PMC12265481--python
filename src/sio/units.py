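"""Optical and retinal unit conversions used throughout the pipeline.

All spatial frequencies are expressed in cycles/degree (cpd) of visual
angle, the standard unit in retinal imaging.  The emmetropic eye maps
roughly 300 µm of retina to one degree of visual angle.
"""

from __future__ import annotations

import numpy as np

DEG_PER_RAD = 180.0 / np.pi

#: retinal magnification of the emmetropic eye, µm of retina per degree
DEFAULT_RETINAL_SCALE_UM_PER_DEG = 300.0


def diffraction_cutoff_cpd(pupil_diameter_mm: float, wavelength_nm: float) -> float:
    """Incoherent diffraction-limited cutoff frequency D/lambda in cycles/degree.

    D/lambda is the cutoff in cycles/radian; dividing by degrees-per-radian
    converts to cycles/degree.
    """
    if pupil_diameter_mm <= 0 or wavelength_nm <= 0:
        raise ValueError("pupil diameter and wavelength must be positive")
    cycles_per_radian = (pupil_diameter_mm * 1e-3) / (wavelength_nm * 1e-9)
    return cycles_per_radian / DEG_PER_RAD


def scale_fringe_frequency(base_cpd: float, period_factor: float) -> float:
    """Fringe frequency after scaling the projected grating period.

    Doubling the period of a binary grating (e.g. from the finest
    2-micromirror pattern) halves its retinal spatial frequency.
    """
    if period_factor <= 0:
        raise ValueError("period_factor must be positive")
    return base_cpd / period_factor


def spacing_to_frequency_cpd(
    spacing_um: float, retinal_scale: float = DEFAULT_RETINAL_SCALE_UM_PER_DEG
) -> float:
    """Spatial frequency (cpd) of a periodic structure of given period in µm."""
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    return retinal_scale / spacing_um


def frames_per_block(frame_rate_hz: float, switching_rate_hz: float) -> int:
    """Number of consecutive frames sharing one fringe orientation.

    The pattern orientation alternates at ``switching_rate_hz`` while the
    camera runs at ``frame_rate_hz``; the ratio must be a whole number of
    frames.
    """
    ratio = frame_rate_hz / switching_rate_hz
    block = int(round(ratio))
    if not np.isclose(ratio, block) or block < 1:
        raise ValueError(
            f"frame_rate/switching_rate = {ratio} is not a positive integer"
        )
    return block


def relative_gain_percent(value: float, reference: float) -> float:
    """Relative increase of ``value`` over ``reference``, in percent."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def hexagonal_density_per_mm2(spacing_um: float) -> float:
    """Areal density (per mm^2) of a hexagonal lattice with pitch ``spacing_um``."""
    return 2.0 / (np.sqrt(3.0) * (spacing_um * 1e-3) ** 2)
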