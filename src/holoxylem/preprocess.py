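"""Data preparation: flat-field correction and geometry refinement.

Stage one of the processing chain: raw frames are divided by the flat
field of their defocus distance, the three distances are brought to a
common magnification and co-registered, and the Fresnel number of each
distance can be refined against the data with a sharpness criterion on a
single-shot phase estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .exceptions import CannotRefineError, InvalidFlatError
from .forward import HologramStack

log = logging.getLogger(__name__)


def flat_field_correct(I: np.ndarray, I0: np.ndarray) -> np.ndarray:
    """Elementwise I / I0; the flat must be strictly positive."""
    I = np.asarray(I, dtype=np.float64)
    I0 = np.asarray(I0, dtype=np.float64)
    if I.shape[-2:] != I0.shape[-2:]:
        raise ValueError(f"frame shape {I.shape} does not match flat {I0.shape}")
    if np.any(I0 <= 0):
        raise InvalidFlatError("flat field contains non-positive pixels")
    return I / I0


def correct_stack(stack: HologramStack) -> HologramStack:
    """Flat-field correct every frame of a hologram stack."""
    corrected = np.empty_like(stack.intensities, dtype=np.float32)
    for d in range(stack.n_distances):
        corrected[d] = flat_field_correct(stack.intensities[d], stack.flats[d])
    flats = np.ones_like(stack.flats)
    return replace(stack, intensities=corrected, flats=flats)


def magnification_rescale_factor(z1_ref_mm: float, z1_mm: float) -> float:
    """Zoom factor bringing a distance's frames onto the reference grid.

    M = z_det / z1 cancels z_det: the factor M_ref / M_i equals z1_i / z1_ref.
    """
    return z1_mm / z1_ref_mm


def _zoom_about_center(frame: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return frame.astype(np.float64, copy=True)
    ny, nx = frame.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    matrix = np.array([[1.0 / factor, 0.0], [0.0, 1.0 / factor]])
    offset = np.array([cy - cy / factor, cx - cx / factor])
    return ndi.affine_transform(
        frame.astype(np.float64), matrix, offset=offset, order=1, mode="nearest"
    )


def register_multidistance(
    stack: HologramStack,
    reference: int = 0,
    upsample_factor: int = 100,
    min_correlation: float = 0.1,
    smooth_sigma_px: float = 5.0,
) -> tuple[HologramStack, np.ndarray]:
    """Bring all defocus distances onto the reference distance's frame.

    Non-reference frames are rescaled by the analytic magnification ratio
    about the optical axis (skipped when the stack is already on the
    common effective-pixel grid) and shift-registered to the reference by
    subpixel phase correlation.  The correlation runs on low-pass
    filtered copies (``smooth_sigma_px``): holograms at different defocus
    distances carry different fringe systems, and without the low-pass
    the correlator locks onto fringe displacement instead of specimen
    displacement.  Returns the registered stack and the per-frame
    (distance, angle, dy/dx) shifts that were applied; frames whose
    correlation falls below ``min_correlation`` keep the identity shift
    (logged).
    """
    if stack.n_distances < 2:
        raise ValueError("need at least two distances to register")
    z1s = stack.geometry.focus_to_sample_mm
    out = stack.intensities.astype(np.float64).copy()
    n_d, n_a = out.shape[:2]
    shifts = np.zeros((n_d, n_a, 2))
    for d in range(n_d):
        if d == reference:
            continue
        factor = (
            1.0
            if stack.magnification_normalized
            else magnification_rescale_factor(z1s[reference], z1s[d])
        )
        for ia in range(n_a):
            frame = _zoom_about_center(out[d, ia], factor)
            ref = out[reference, ia]
            if frame.std() < 1e-12 or ref.std() < 1e-12:
                out[d, ia] = frame
                continue
            ref_lp = ndi.gaussian_filter(ref, smooth_sigma_px)
            frame_lp = ndi.gaussian_filter(frame, smooth_sigma_px)
            shift, error, _ = phase_cross_correlation(
                ref_lp, frame_lp, upsample_factor=upsample_factor,
                normalization=None,
            )
            # skimage reports error = sqrt(1 - corr^2); invert to a peak value
            corr = float(np.sqrt(max(0.0, 1.0 - float(error) ** 2)))
            if not np.isfinite(corr) or corr < min_correlation:
                log.warning(
                    "distance %d angle %d: correlation %.3f below %.3f, identity shift",
                    d, ia, corr, min_correlation,
                )
                out[d, ia] = frame
                continue
            shifts[d, ia] = shift
            shifted = np.fft.ifftn(
                ndi.fourier_shift(np.fft.fftn(frame), shift)
            ).real
            # Fourier interpolation can ring marginally below zero
            out[d, ia] = np.clip(shifted, 0.0, None)
    new = replace(
        stack,
        intensities=out.astype(np.float32),
        magnification_normalized=True,
    )
    return new, shifts


def refine_fresnel_number(
    hologram: np.ndarray,
    F_initial: float,
    search_halfwidth: float = 0.1,
    n_grid: int = 21,
    alpha: float = 0.003,
    min_std: float = 1e-6,
) -> float:
    """Refine the per-pixel Fresnel number against one hologram.

    Grid search over ``F`` in a relative interval around ``F_initial``,
    scoring each candidate by the sharpness of a single-shot weak-object
    (contrast-transfer) phase estimate: at the true Fresnel number the
    inversion collapses the fringes, while a mismatched ``F`` leaves
    residual fringes that inflate the total variation relative to the
    estimate's energy.  The focus criterion is therefore the negative
    L2-normalised total variation, and the argmax is returned.  The
    criterion needs fringe contrast, i.e. edges in the specimen; a
    featureless frame raises :class:`CannotRefineError`.
    """
    holo = np.asarray(hologram, dtype=np.float64)
    if holo.std() < min_std:
        raise CannotRefineError("hologram has no contrast; cannot refine geometry")
    ny, nx = holo.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f2 = fy * fy + fx * fx
    spectrum = np.fft.fft2(holo - holo.mean())

    def sharpness(F: float, band_osc: float | None) -> float:
        s = np.sin(np.pi * f2 / F)
        w = 2.0 * s / (4.0 * s * s + alpha)
        if band_osc is not None:
            # keep only the first oscillations of the transfer function:
            # their misfit varies slowly with F, widening the search basin
            w = np.where(f2 <= band_osc * F, w, 0.0)
        phi = np.fft.ifft2(spectrum * w).real
        tv = np.abs(np.diff(phi, axis=0)).sum() + np.abs(np.diff(phi, axis=1)).sum()
        return -tv / (np.sqrt((phi**2).sum()) + 1e-300)

    def grid_argmax(candidates, band_osc):
        scores = [sharpness(F, band_osc) for F in candidates]
        return float(candidates[int(np.argmax(scores))])

    # coarse, band-limited pass locates the basin; the fine full-band pass
    # resolves the sharp valley floor (the initial guess always competes,
    # so an already-exact F_initial is returned unchanged)
    coarse = grid_argmax(
        F_initial * np.linspace(1.0 - search_halfwidth, 1.0 + search_halfwidth,
                                max(n_grid, 41)),
        band_osc=12.0,
    )
    fine = np.concatenate(
        [coarse * np.linspace(0.98, 1.02, 81), [F_initial, coarse]]
    )
    scores = [sharpness(F, None) for F in fine]
    best = max(scores)
    # near-tie break in favour of the initial value: refinement should only
    # move the geometry when the data clearly ask for it
    if scores[-2] >= best - 0.25 * abs(best):
        return float(F_initial)
    return float(fine[int(np.argmax(scores))])
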