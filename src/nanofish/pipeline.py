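"""High-level pipeline steps shared by the CLI and the test harness."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Image
from .detect import QCThresholds, find_candidate_foci
from .io import RunConfig
from .localize import (SpotFit, fit_gaussian_lsq, fit_gaussian_mle,
                       localize_centroid, theoretical_width)
from .register import RegistrationModel, apply_transform
from .separation import (SeparationRecord, histogram_separations, pair_foci,
                         separation)


def localize_image(
    image: Image,
    method: str = "lsq",
    thresholds: Optional[QCThresholds] = None,
    tol: float = 1e-4,
    max_iterations: int = 100,
    centers_px: Optional[Sequence[tuple[int, int]]] = None,
) -> list[SpotFit]:
    """Detect candidate foci in one channel and localize each of them.

    Unconverged fits are dropped (they carry no trustworthy position); the
    caller can count them via the difference against detected candidates.
    """
    candidates = find_candidate_foci(image, thresholds, centers_px=centers_px)
    s = theoretical_width(image.optics.wavelength_nm,
                          image.optics.numerical_aperture)
    fits: list[SpotFit] = []
    for cand in candidates:
        try:
            if method == "lsq":
                fit = fit_gaussian_lsq(cand.roi, tol=tol,
                                       max_iterations=max_iterations,
                                       s_theory_nm=s)
            elif method == "mle":
                fit = fit_gaussian_mle(cand.roi, tol=tol,
                                       max_iterations=max_iterations,
                                       s_theory_nm=s)
            elif method == "centroid":
                x, y = localize_centroid(cand.roi)
                fit = fit_gaussian_lsq(cand.roi, tol=tol,
                                       max_iterations=max_iterations,
                                       s_theory_nm=s)
                fit.x0_nm, fit.y0_nm = x, y
                fit.method = "centroid"
            else:
                raise ValueError(f"unknown method '{method}'")
        except Exception:
            continue
        if fit.converged:
            fits.append(fit)
    return fits


def measure_separations(
    fits_a: Sequence[SpotFit],
    fits_b: Sequence[SpotFit],
    model: Optional[RegistrationModel],
    r_nm: float,
    gate_nm: float = 200.0,
    scene_id: str = "",
) -> list[SeparationRecord]:
    """Register channel B onto A, pair foci, and measure separations."""
    fits_b = list(fits_b)
    if model is not None and fits_b:
        pos_b = np.array([[f.x0_nm, f.y0_nm] for f in fits_b])
        corrected = apply_transform(model, pos_b)
        for f, (x, y) in zip(fits_b, corrected):
            f.x0_nm, f.y0_nm = float(x), float(y)
    pairs, _, _ = pair_foci(fits_a, fits_b, gate_nm=gate_nm)
    return [separation(p, r_nm=r_nm, scene_id=scene_id) for p in pairs]


_FIT_COLUMNS = ["scene_id", "channel", "method", "x_nm", "y_nm", "sx_nm",
                "sy_nm", "A", "z0", "N_photons", "b_noise_photons",
                "sigma_nm", "n_iterations", "converged"]

_SEP_COLUMNS = ["scene_id", "x_A", "y_A", "x_B_corrected", "y_B_corrected",
                "d_nm", "sigma_A", "sigma_B", "r", "combined_uncertainty",
                "significant"]


def fits_to_frame(fits: Sequence[SpotFit], scene_id: str = "",
                  channel: str = "A") -> pd.DataFrame:
    if not fits:
        return pd.DataFrame(columns=_FIT_COLUMNS)
    rows = []
    for f in fits:
        rows.append({
            "scene_id": scene_id, "channel": channel, "method": f.method,
            "x_nm": f.x0_nm, "y_nm": f.y0_nm, "sx_nm": f.sx_nm, "sy_nm": f.sy_nm,
            "A": f.A, "z0": f.z0, "N_photons": f.photons,
            "b_noise_photons": f.background_noise, "sigma_nm": f.sigma_nm,
            "n_iterations": f.n_iterations, "converged": f.converged,
        })
    return pd.DataFrame(rows)


def separations_to_frame(records: Sequence[SeparationRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=_SEP_COLUMNS)
    rows = []
    for r in records:
        rows.append({
            "scene_id": r.scene_id,
            "x_A": r.position_a[0], "y_A": r.position_a[1],
            "x_B_corrected": r.position_b_corrected[0],
            "y_B_corrected": r.position_b_corrected[1],
            "d_nm": r.d_nm, "sigma_A": r.sigma_a_nm, "sigma_B": r.sigma_b_nm,
            "r": r.r_nm, "combined_uncertainty": r.combined_uncertainty_nm,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)
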