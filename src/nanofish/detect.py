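"""Candidate focus extraction and quality control.

A transcription focus is usable for super-resolution measurement only if it
looks like an isolated diffraction-limited spot: Gaussian-like shape,
adequate signal-to-noise and adequate local contrast. ``qc_focus`` encodes
that gate; ``find_candidate_foci`` automates the initial selection that an
operator would otherwise do by eye (a user-supplied list of click
coordinates can replace it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.feature import peak_local_max

from .core import EdgeError, Image, ROI, UnfittableSpotError
from .localize import fit_gaussian_lsq, gaussian_model_image, theoretical_width

__all__ = [
    "QCThresholds",
    "QCReport",
    "Candidate",
    "default_half_width_px",
    "extract_roi",
    "qc_focus",
    "find_candidate_foci",
]


@dataclass(frozen=True)
class QCThresholds:
    """Acceptance gates for a candidate focus.

    ``snr`` is the minimum peak/background brightness ratio (foci should be
    at least 3x brighter than the background); ``gaussian_likeness`` the
    minimum Pearson correlation between the ROI and its best-fit Gaussian;
    ``local_contrast`` the minimum peak excess in units of the background
    standard deviation.
    """

    snr: float = 3.0
    gaussian_likeness: float = 0.7
    local_contrast: float = 5.0


@dataclass
class QCReport:
    snr: float
    gaussian_likeness: float
    local_contrast: float
    passed: bool
    failure_reasons: list[str] = field(default_factory=list)


@dataclass
class Candidate:
    """A detected focus: pixel-center index plus its ROI and QC report."""

    center_px: tuple[int, int]  # (row, col)
    peak_counts: float
    roi: ROI
    qc: QCReport


def default_half_width_px(s_nm: float, pixel_size_nm: float) -> int:
    """ROI half-width covering the spot plus a few pixels beyond:
    ceil(3 s / a) + 2."""
    return math.ceil(3.0 * s_nm / pixel_size_nm) + 2


def extract_roi(image: Image, center_px: tuple[int, int],
                half_width_px: int) -> ROI:
    """Cut a square ROI of side ``2*half_width_px + 1`` around a pixel."""
    i, j = center_px
    h, w = image.data.shape
    if not (0 <= i < h and 0 <= j < w):
        raise EdgeError(f"center {center_px} outside image")
    if i - half_width_px < 0 or j - half_width_px < 0 or \
            i + half_width_px >= h or j + half_width_px >= w:
        raise EdgeError(f"ROI around {center_px} crosses the image edge")
    block = image.data[i - half_width_px:i + half_width_px + 1,
                       j - half_width_px:j + half_width_px + 1]
    return ROI(data=np.array(block, dtype=float),
               anchor=(i - half_width_px, j - half_width_px),
               pixel_size_nm=image.frame.pixel_size_nm,
               gain=image.camera.gain_counts_per_photon,
               optics=image.optics)


def qc_focus(roi: ROI, thresholds: Optional[QCThresholds] = None,
             s_theory_nm: Optional[float] = None) -> QCReport:
    """Score a ROI against the three spot criteria.

    snr               = brightest pixel / perimeter mean
    gaussian_likeness = Pearson r between ROI and its best-fit Gaussian
    local_contrast    = (brightest pixel - perimeter mean) / perimeter std
    """
    if thresholds is None:
        thresholds = QCThresholds()
    perim = roi.perimeter_values()
    bg_mean = float(perim.mean())
    bg_std = float(perim.std(ddof=0))
    peak = float(roi.data.max())
    reasons: list[str] = []

    snr = peak / bg_mean if bg_mean > 0 else float("inf")
    if snr < thresholds.snr:
        reasons.append(f"snr {snr:.2f} < {thresholds.snr}")

    if bg_std == 0:
        contrast = float("nan")
        if bg_mean == peak:
            reasons.append("flat ROI: local contrast undefined")
        # a noiseless spot on a perfectly uniform background has infinite
        # contrast in spirit; treat it as passing
        elif peak > bg_mean:
            contrast = float("inf")
    else:
        contrast = (peak - bg_mean) / bg_std
        if contrast < thresholds.local_contrast:
            reasons.append(f"local_contrast {contrast:.2f} < {thresholds.local_contrast}")

    likeness = 0.0
    try:
        if s_theory_nm is None and roi.optics is not None:
            s_theory_nm = theoretical_width(roi.optics.wavelength_nm,
                                            roi.optics.numerical_aperture)
        fit = fit_gaussian_lsq(roi, s_theory_nm=s_theory_nm)
        model = gaussian_model_image(roi, fit.z0, fit.A, fit.x0_nm, fit.y0_nm,
                                     fit.sx_nm, fit.sy_nm)
        obs = roi.data.ravel()
        if obs.std() > 0 and model.std() > 0:
            likeness = float(np.corrcoef(obs, model.ravel())[0, 1])
    except (UnfittableSpotError, ValueError):
        reasons.append("gaussian fit failed")
    if likeness < thresholds.gaussian_likeness:
        reasons.append(f"gaussian_likeness {likeness:.2f} < {thresholds.gaussian_likeness}")

    return QCReport(snr=snr, gaussian_likeness=likeness, local_contrast=contrast,
                    passed=not reasons, failure_reasons=reasons)


def find_candidate_foci(
    image: Image,
    thresholds: Optional[QCThresholds] = None,
    k_mad: float = 5.0,
    half_width_px: Optional[int] = None,
    centers_px: Optional[Sequence[tuple[int, int]]] = None,
) -> list[Candidate]:
    """Detect candidate foci that pass QC, brightest first.

    Local maxima above ``median + k_mad * MAD`` are found, non-maximum
    suppressed at two PSF widths, then each surviving peak is cut into a
    ROI and gated by :func:`qc_focus`. Peaks whose ROI would cross the
    image edge are skipped. Pass ``centers_px`` to supply manually selected
    coordinates instead of running the detector.
    """
    s = theoretical_width(image.optics.wavelength_nm,
                          image.optics.numerical_aperture)
    a = image.frame.pixel_size_nm
    if half_width_px is None:
        half_width_px = default_half_width_px(s, a)
    if centers_px is None:
        med = float(np.median(image.data))
        mad = float(np.median(np.abs(image.data - med)))
        thr = med + k_mad * mad
        peaks = peak_local_max(np.asarray(image.data, dtype=float),
                               min_distance=1, threshold_abs=thr,
                               exclude_border=False)
        # greedy non-maximum suppression at two PSF widths (never below
        # 1.5 px, so plateau duplicates merge), brightest kept first
        suppress_px = max(1.5, 2.0 * s / a)
        order = sorted(peaks, key=lambda p: (-image.data[p[0], p[1]],
                                             int(p[0]), int(p[1])))
        centers = []
        for p in order:
            if all((p[0] - c[0]) ** 2 + (p[1] - c[1]) ** 2 > suppress_px ** 2
                   for c in centers):
                centers.append((int(p[0]), int(p[1])))
    else:
        centers = [tuple(int(v) for v in c) for c in centers_px]
    out: list[Candidate] = []
    for c in centers:
        try:
            roi = extract_roi(image, c, half_width_px)
        except EdgeError:
            continue
        report = qc_focus(roi, thresholds)
        if report.passed:
            out.append(Candidate(center_px=c, peak_counts=float(image.data[c]),
                                 roi=roi, qc=report))
    out.sort(key=lambda cand: (-cand.peak_counts, cand.center_px))
    return out
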