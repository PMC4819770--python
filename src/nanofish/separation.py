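"""Two-color separation measurement with propagated uncertainty.

After localization and channel registration, each allele appears as one
focus per channel. Foci are paired across channels (mutual nearest
neighbors within a gate set by the diffraction limit), the Euclidean
distance d between the channel-A position and the registration-corrected
channel-B position is computed, and the combined measurement uncertainty

    u = sqrt(sigma_A^2 + sigma_B^2 + r^2)

is attached — the root-sum-square of the two localization precisions and
the residual channel misalignment r. A separation is *significant* only
when d exceeds u.

Populations of separations are summarized as fixed-width histograms
(default 30-nm bins) with a least-squares Gaussian fitted to the binned
counts; fitted curves are rescaled to a common analytic area so different
conditions can be compared directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .core import NanofishError
from .localize import SpotFit

__all__ = [
    "SeparationRecord",
    "SeparationDistribution",
    "GaussianSummary",
    "pair_foci",
    "separation",
    "histogram_separations",
    "fit_histogram_gaussian",
    "normalize_distributions",
    "chance_colocalization",
]

#: default pairing gate: the diffraction limit of visible light, ~200 nm
DEFAULT_GATE_NM = 200.0


@dataclass
class SeparationRecord:
    fit_a: Optional[SpotFit]
    fit_b: Optional[SpotFit]
    d_nm: float
    sigma_a_nm: float
    sigma_b_nm: float
    r_nm: float
    combined_uncertainty_nm: float
    significant: bool
    scene_id: str = ""
    position_a: tuple[float, float] = (float("nan"), float("nan"))
    position_b_corrected: tuple[float, float] = (float("nan"), float("nan"))


@dataclass
class GaussianSummary:
    mean_nm: float
    sd_nm: float
    amplitude: float
    area: float
    empirical: bool = False  # True when too few bins forced a fallback


@dataclass
class SeparationDistribution:
    bin_width_nm: float
    bin_edges_nm: np.ndarray
    counts: np.ndarray
    n: int
    gaussian: Optional[GaussianSummary] = None

    @property
    def bin_centers_nm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])


def _positions(foci: Sequence) -> np.ndarray:
    out = []
    for f in foci:
        if isinstance(f, SpotFit):
            out.append([f.x0_nm, f.y0_nm])
        else:
            out.append([float(f[0]), float(f[1])])
    return np.array(out) if out else np.empty((0, 2))


def pair_foci(
    foci_a: Sequence,
    foci_b: Sequence,
    gate_nm: float = DEFAULT_GATE_NM,
) -> tuple[list[tuple], list, list]:
    """Mutual-nearest-neighbor pairing of two-color foci.

    ``foci_b`` must already be registered into the channel-A frame. Returns
    (pairs, unpaired_a, unpaired_b); a pair is kept only when the two foci
    are each other's nearest neighbor closer than ``gate_nm``.
    """
    fa, fb = list(foci_a), list(foci_b)
    if not fa or not fb:
        return [], fa, fb
    pa, pb = _positions(fa), _positions(fb)
    tb, ta = cKDTree(pb), cKDTree(pa)
    d_ab, nn_ab = tb.query(pa)
    _, nn_ba = ta.query(pb)
    pairs, used_b = [], set()
    for ia, (ib, dist) in enumerate(zip(nn_ab, d_ab)):
        if nn_ba[ib] == ia and dist < gate_nm:
            pairs.append((fa[ia], fb[ib]))
            used_b.add(int(ib))
    paired_a = {id(a) for a, _ in pairs}
    unpaired_a = [f for f in fa if id(f) not in paired_a]
    unpaired_b = [f for i, f in enumerate(fb) if i not in used_b]
    return pairs, unpaired_a, unpaired_b


def combined_uncertainty(sigma_a: float, sigma_b: float, r: float) -> float:
    """Root-sum-square of the per-channel precisions and registration residual."""
    return math.sqrt(sigma_a**2 + sigma_b**2 + r**2)


def separation(
    pair: tuple,
    sigma_a_nm: Optional[float] = None,
    sigma_b_nm: Optional[float] = None,
    r_nm: Optional[float] = None,
    scene_id: str = "",
) -> SeparationRecord:
    """Distance between a two-color pair with its propagated uncertainty.

    The pair is (focus_A, focus_B_corrected): SpotFits or raw (x, y) nm
    positions, channel B already mapped into the A frame. Per-channel
    precisions default to the fits' own ``sigma_nm``; the registration
    residual ``r_nm`` has no default — a distance without its uncertainty
    is meaningless, so all three components are mandatory.
    """
    a, b = pair
    fa = a if isinstance(a, SpotFit) else None
    fb = b if isinstance(b, SpotFit) else None
    if sigma_a_nm is None:
        if fa is None:
            raise ValueError("sigma_a_nm required for raw positions")
        sigma_a_nm = fa.sigma_nm
    if sigma_b_nm is None:
        if fb is None:
            raise ValueError("sigma_b_nm required for raw positions")
        sigma_b_nm = fb.sigma_nm
    if r_nm is None:
        raise ValueError("registration residual r_nm is mandatory")
    for name, v in (("sigma_a_nm", sigma_a_nm), ("sigma_b_nm", sigma_b_nm),
                    ("r_nm", r_nm)):
        if v is None or not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be a finite non-negative number")
    (xa, ya), (xb, yb) = _positions([a])[0], _positions([b])[0]
    d = math.hypot(xb - xa, yb - ya)
    u = combined_uncertainty(sigma_a_nm, sigma_b_nm, r_nm)
    return SeparationRecord(
        fit_a=fa, fit_b=fb, d_nm=d, sigma_a_nm=sigma_a_nm,
        sigma_b_nm=sigma_b_nm, r_nm=r_nm, combined_uncertainty_nm=u,
        significant=d > u, scene_id=scene_id,
        position_a=(xa, ya), position_b_corrected=(xb, yb))


def histogram_separations(
    records: Sequence[Union[SeparationRecord, float]],
    bin_width_nm: float = 30.0,
) -> SeparationDistribution:
    """Histogram separations into half-open bins [k*w, (k+1)*w)."""
    if len(records) == 0:
        raise ValueError("no separations to histogram")
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    d = np.array([r.d_nm if isinstance(r, SeparationRecord) else float(r)
                  for r in records])
    n_bins = int(math.floor(d.max() / bin_width_nm)) + 1
    edges = np.arange(n_bins + 1) * bin_width_nm
    idx = np.floor(d / bin_width_nm).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return SeparationDistribution(bin_width_nm=bin_width_nm,
                                  bin_edges_nm=edges, counts=counts, n=len(d))


def _gauss(x: np.ndarray, amp: float, mu: float, sd: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_histogram_gaussian(
    dist: SeparationDistribution,
    reference_area: Optional[float] = None,
) -> GaussianSummary:
    """Least-squares Gaussian through the binned counts.

    The fitted curve's analytic area (amp * sd * sqrt(2 pi)) is rescaled to
    ``reference_area`` when given, so distributions with different n can be
    overlaid on equal areas. With fewer than three nonzero bins the fit is
    degenerate and the empirical mean is reported instead (flagged).
    """
    x = dist.bin_centers_nm
    y = dist.counts.astype(float)
    nz = int((y > 0).sum())
    if nz < 3:
        mean = float((x * y).sum() / y.sum())
        sd = float(math.sqrt(max(((x - mean) ** 2 * y).sum() / y.sum(), 0.0)))
        amp = float(y.max())
        summary = GaussianSummary(mean_nm=mean, sd_nm=max(sd, dist.bin_width_nm / 4),
                                  amplitude=amp, area=amp * max(sd, 1e-9) * math.sqrt(2 * math.pi),
                                  empirical=True)
    else:
        mu0 = float((x * y).sum() / y.sum())
        sd0 = float(math.sqrt(max(((x - mu0) ** 2 * y).sum() / y.sum(),
                                  (dist.bin_width_nm / 2) ** 2)))
        p0 = [float(y.max()), mu0, sd0]
        popt, _ = curve_fit(_gauss, x, y, p0=p0, maxfev=20000)
        amp, mean, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        summary = GaussianSummary(mean_nm=mean, sd_nm=sd, amplitude=amp,
                                  area=amp * sd * math.sqrt(2 * math.pi))
    if reference_area is not None and summary.area > 0:
        scale = reference_area / summary.area
        summary.amplitude *= scale
        summary.area = reference_area
    dist.gaussian = summary
    return summary


def normalize_distributions(dists: Sequence[SeparationDistribution],
                            reference_area: Optional[float] = None) -> list[GaussianSummary]:
    """Fit Gaussians to several distributions and equalize their areas."""
    fits = [fit_histogram_gaussian(d) for d in dists]
    if reference_area is None:
        reference_area = fits[0].area
    out = []
    for d, f in zip(dists, fits):
        if f.area > 0:
            f.amplitude *= reference_area / f.area
            f.area = reference_area
        out.append(f)
    return out


def chance_colocalization(
    spot_area_nm2: float,
    nuclear_area_nm2: float,
    n_a: int,
    n_b: int,
) -> float:
    """Probability that any A focus overlaps any B focus by chance.

    For foci scattered uniformly over the visible nuclear area, two discs of
    equal area overlap when their centers fall within the sum of their
    radii, an exclusion disc of area 4x the spot area. The probability that
    at least one of the ``n_b`` B foci lands in the union of the ``n_a``
    exclusion discs is approximately

        p = 1 - (1 - n_a * 4 * spot_area / nuclear_area)^n_b

    (the small-number Poisson form is p = 1 - exp(-n_a n_b * 4 s / S)).
    Because transcription foci are tiny relative to the nucleus, chance
    overlap is rare: colocalizing spots almost always come from one allele.
    """
    if spot_area_nm2 <= 0 or nuclear_area_nm2 <= 0:
        raise ValueError("areas must be positive")
    if spot_area_nm2 >= nuclear_area_nm2:
        raise ValueError("spot area must be small compared to the nuclear area")
    if n_a < 0 or n_b < 0:
        raise ValueError("focus counts must be non-negative")
    if n_a == 0 or n_b == 0:
        return 0.0
    overlap = 4.0 * spot_area_nm2
    frac = min(n_a * overlap / nuclear_area_nm2, 1.0)
    return 1.0 - (1.0 - frac) ** n_b
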