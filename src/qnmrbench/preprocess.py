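"""Spectrum preprocessing.

Polynomial baseline correction by iterative asymmetric reweighting, TSP
chemical-shift referencing, window-wise cross-correlation realignment, and
the SNR-based quantifiability rule (strict SNR > 10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import Spectrum1D, region_indices

__all__ = [
    "NoiseEstimate",
    "baseline_correct",
    "calibrate_ppm_tsp",
    "local_realign",
    "estimate_noise_and_snr",
]

#: Default signal-free region used for noise estimation (ppm).
DEFAULT_NOISE_REGION = (10.5, 11.2)
#: Quantifiability threshold: a peak is quantifiable when SNR > 10, strictly.
SNR_THRESHOLD = 10.0


@dataclass(frozen=True)
class NoiseEstimate:
    sd: float
    region: tuple[float, float]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def baseline_correct(
    spectrum: Spectrum1D,
    degree: int = 3,
    n_iter: int = 20,
    asymmetry: float = 0.01,
) -> Spectrum1D:
    """Subtract a polynomial baseline fitted to baseline-dominated points.

    A degree-``degree`` polynomial is fitted by iteratively reweighted least
    squares: points above the current fit (peaks) are down-weighted by
    ``asymmetry``, points at or below keep weight 1.  Twenty iterations with
    asymmetry 0.01 are a deterministic, parameter-light stand-in for vendor
    "automatic" baseline correction.  A polynomial baseline of degree <= the
    requested one is removed exactly (to numerical precision).
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if degree > spectrum.n_points - 1:
        raise ValueError("degree exceeds number of points - 1")
    x = np.linspace(-1.0, 1.0, spectrum.n_points)
    y = spectrum.intensity
    weights = np.ones_like(y)
    fit = np.zeros_like(y)
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(x, y, degree, w=weights)
        fit = np.polynomial.polynomial.polyval(x, coeffs)
        weights = np.where(y > fit, asymmetry, 1.0)
    out = spectrum.copy()
    out.intensity = y - fit
    return out


def calibrate_ppm_tsp(
    spectrum: Spectrum1D,
    search_window: tuple[float, float] = (-0.2, 0.2),
    noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
) -> Spectrum1D:
    """Translate the ppm axis so the TSP apex sits at exactly 0.000 ppm.

    The apex is located by parabolic interpolation through the three points
    around the discrete maximum inside ``search_window``; an error is raised
    when no maximum rises above 5× the noise standard deviation there.
    """
    idx = region_indices(spectrum, *search_window)
    seg_y = spectrum.intensity[idx]
    noise, _, _ = estimate_noise_and_snr(
        spectrum, noise_region=noise_region, peak_region=search_window
    )
    k = int(np.argmax(seg_y))
    if noise.sd > 0 and seg_y[k] <= 5.0 * noise.sd:
        raise ValueError("no TSP maximum above 5x noise sd in the search window")
    gk = idx[k]
    apex = spectrum.ppm_axis[gk]
    if 0 < gk < spectrum.n_points - 1:
        y0, y1, y2 = spectrum.intensity[gk - 1 : gk + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            # vertex of the parabola through the three samples; axis is
            # uniform and decreasing, so the offset is in grid steps
            shift = 0.5 * (y0 - y2) / denom
            apex = apex - shift * spectrum.dppm
    out = spectrum.copy()
    out.ppm_axis = spectrum.ppm_axis - apex
    return out


def local_realign(
    spectrum: Spectrum1D,
    reference: Spectrum1D,
    windows: list[tuple[float, float]],
    max_shift: float = 0.02,
) -> tuple[Spectrum1D, list[dict]]:
    """Integer-grid realignment of selected windows against a reference.

    For each window the integer shift (in grid steps, clamped to
    ``±max_shift`` ppm) maximizing the cross-correlation with the reference
    is applied to that window only; points shifted in from outside the
    window are filled with the window's edge value.  Shifts are integer grid
    steps, so areas are preserved exactly.  Returns the realigned spectrum
    plus a per-window report (applied shift in ppm, clamped flag).
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if abs(spectrum.dppm - reference.dppm) > 1e-9 * spectrum.dppm:
        raise ValueError("spectrum and reference must share the grid step")
    out = spectrum.copy()
    report: list[dict] = []
    max_steps = int(round(max_shift / spectrum.dppm))
    for lo, hi in windows:
        idx = region_indices(spectrum, lo, hi)
        ridx = region_indices(reference, lo, hi)
        n = min(idx.size, ridx.size)
        idx, ridx = idx[:n], ridx[:n]
        if n < 3:
            raise ValueError(f"window [{lo}, {hi}] narrower than 3 points")
        seg = spectrum.intensity[idx]
        ref = reference.intensity[ridx]
        best_step, best_score, clamped = 0, -np.inf, False
        search = 2 * max_steps + 5  # wide enough to notice out-of-range shifts
        for step in range(-search, search + 1):
            shifted = _shift_segment(seg, step)
            score = float(np.dot(shifted, ref))
            if score > best_score:
                best_score, best_step = score, step
        if abs(best_step) > max_steps:
            clamped = True
            best_step = int(np.clip(best_step, -max_steps, max_steps))
        out.intensity[idx] = _shift_segment(seg, best_step)
        # positive grid step moves intensity toward lower index = higher ppm
        report.append(
            {
                "window": (lo, hi),
                "shift_ppm": best_step * spectrum.dppm,
                "clamped": clamped,
            }
        )
    return out, report


def _shift_segment(seg: np.ndarray, step: int) -> np.ndarray:
    """Shift a segment by ``step`` indices, edge values filling the gap."""
    if step == 0:
        return seg.copy()
    out = np.empty_like(seg)
    if step > 0:
        out[step:] = seg[:-step]
        out[:step] = seg[0]
    else:
        out[:step] = seg[-step:]
        out[step:] = seg[-1]
    return out


def estimate_noise_and_snr(
    spectrum: Spectrum1D,
    noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
    peak_region: tuple[float, float] = (0.0, 1.0),
) -> tuple[NoiseEstimate, float, bool]:
    """Noise sd from a signal-free region, peak SNR, and quantifiability.

    The noise region is detrended with a straight line before taking the
    standard deviation; SNR is the maximum intensity in ``peak_region`` over
    that sd, and a peak is quantifiable when SNR > 10 strictly.
    """
    nidx = region_indices(spectrum, *noise_region)
    pidx = region_indices(spectrum, *peak_region)
    if nidx.size < 4:
        raise ValueError("noise region too narrow")
    x = spectrum.ppm_axis[nidx]
    y = spectrum.intensity[nidx]
    coeffs = np.polynomial.polynomial.polyfit(x, y, 1)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    sd = float(np.std(resid, ddof=1))
    peak = float(np.max(spectrum.intensity[pidx]))
    snr = peak / sd if sd > 0 else float("inf") if peak > 0 else 0.0
    return NoiseEstimate(sd=sd, region=tuple(noise_region)), snr, snr > SNR_THRESHOLD
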